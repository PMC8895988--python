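"""Readers, writers and validation for the tables the pipeline touches.

Canonical on-disk form for everything is tab-separated text with a header.
Genotype calls are additionally accepted as HapMap text (the 11 standard
leading columns) and as VCF (read-only, GT field only).  Internally a
genotype call is one of four codes: 0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternate, -1 = missing; the accepted missing
symbols ("NA", "NN", "./.", empty) are all normalised to -1 on ingest.
Readers never silently drop rows: malformed input raises, and ingest counts
are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    IntegrityError,
    ParseError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "read_genotype_table",
    "write_genotype_matrix",
    "read_plot_table",
    "write_plot_table",
    "read_spectra_table",
    "write_spectra_table",
    "read_group_map",
    "write_group_map",
    "validate_spectra_table",
]

MISSING = np.int8(-1)
REF_HOM = np.int8(0)
HET = np.int8(1)
ALT_HOM = np.int8(2)

_MISSING_SYMBOLS = {"NA", "NN", "./.", ".", ""}

#: key columns of a plot table; any further column is a trait
PLOT_KEY_COLUMNS = ["genotype", "environment", "replicate", "block"]

#: key columns of a plot-level spectra table ("repetition" optional)
SPECTRA_KEY_COLUMNS = ["genotype", "environment", "replicate"]

HAPMAP_LEADING = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

MAJOR_GROUPS = ("ED", "EF", "LR")
LANDRACE_SUBGROUPS = ("CG", "GB", "RT", "SM", "SF", "WA")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls, markers x genotypes, with marker metadata.

    ``calls`` holds the int8 codes defined at module level.  Positions, when
    present, are 1-based and never used in computation.
    """

    calls: np.ndarray  # int8, shape (n_markers, n_genotypes)
    marker_ids: list[str]
    genotype_ids: list[str]
    chrom: list | None = None
    pos: np.ndarray | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.genotype_ids)):
            raise DimensionError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.marker_ids)} markers x {len(self.genotype_ids)} genotypes"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise IntegrityError("marker ids are not unique")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ParseError(f"{bad.sum()} calls outside the canonical alphabet")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    def subset(self, marker_idx=None, genotype_idx=None) -> "GenotypeMatrix":
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        gi = (
            np.arange(self.n_genotypes)
            if genotype_idx is None
            else np.asarray(genotype_idx)
        )
        return GenotypeMatrix(
            calls=self.calls[np.ix_(mi, gi)],
            marker_ids=[self.marker_ids[i] for i in mi],
            genotype_ids=[self.genotype_ids[i] for i in gi],
            chrom=[self.chrom[i] for i in mi] if self.chrom is not None else None,
            pos=self.pos[mi] if self.pos is not None else None,
        )


# ---------------------------------------------------------------------------
# genotype tables


def _decode_symbol(sym: str, line_no: int) -> np.int8:
    s = sym.strip()
    if s in _MISSING_SYMBOLS:
        return MISSING
    if s in ("0", "1", "2"):
        return np.int8(int(s))
    raise ParseError(f"unknown call symbol {sym!r} on line {line_no}")


def _read_matrix_tsv(path, orientation="auto"):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: malformed header on line 1")
    width = len(header)
    ids_col, rows = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != width:
            raise DimensionError(
                f"{path}: row of width {len(parts)} != header width {width} "
                f"on line {i}"
            )
        ids_col.append(parts[0])
        rows.append([_decode_symbol(s, i) for s in parts[1:]])
    calls = np.asarray(rows, dtype=np.int8)
    col_ids = header[1:]
    if orientation == "auto":
        # markers usually far outnumber genotypes; fall back to id sniffing
        orientation = "markers-in-rows" if calls.shape[0] >= calls.shape[1] else (
            "markers-in-columns"
        )
        logger.info("matrix orientation sniffed as %s", orientation)
    if orientation == "markers-in-columns":
        return GenotypeMatrix(calls.T, marker_ids=col_ids, genotype_ids=ids_col)
    return GenotypeMatrix(calls, marker_ids=ids_col, genotype_ids=col_ids)


def _read_hapmap(path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 12 or header[0] not in ("rs#", "rs"):
        raise ParseError(f"{path}: malformed HapMap header on line 1")
    genotype_ids = header[11:]
    width = len(header)
    marker_ids, chrom, pos, rows = [], [], [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != width:
            raise DimensionError(f"{path}: row width mismatch on line {i}")
        marker_ids.append(parts[0])
        alleles = parts[1].split("/")
        if len(alleles) != 2:
            raise ParseError(f"{path}: bad alleles field {parts[1]!r} on line {i}")
        ref, alt = alleles
        chrom.append(parts[2])
        pos.append(int(parts[3]) if parts[3] else -1)
        row = []
        for sym in parts[11:]:
            s = sym.strip()
            if s in _MISSING_SYMBOLS:
                row.append(MISSING)
            elif len(s) == 2:
                a, b = s[0], s[1]
                if a == ref and b == ref:
                    row.append(REF_HOM)
                elif a == alt and b == alt:
                    row.append(ALT_HOM)
                elif {a, b} == {ref, alt}:
                    row.append(HET)
                else:
                    raise ParseError(
                        f"{path}: call {s!r} outside alleles {parts[1]!r} "
                        f"on line {i}"
                    )
            else:
                raise ParseError(f"{path}: unknown call symbol {s!r} on line {i}")
        rows.append(row)
    return GenotypeMatrix(
        np.asarray(rows, dtype=np.int8),
        marker_ids=marker_ids,
        genotype_ids=genotype_ids,
        chrom=chrom,
        pos=np.asarray(pos),
    )


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    genotype_ids = list(vcf.samples)
    marker_ids, chrom, pos, rows = [], [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = {0: REF_HOM, 1: HET, 2: MISSING, 3: ALT_HOM}
    for var in vcf:
        vid = var.ID if var.ID else f"{var.CHROM}_{var.POS}"
        marker_ids.append(vid)
        chrom.append(var.CHROM)
        pos.append(var.POS)
        rows.append([remap[int(t)] for t in var.gt_types])
    return GenotypeMatrix(
        np.asarray(rows, dtype=np.int8),
        marker_ids=marker_ids,
        genotype_ids=genotype_ids,
        chrom=chrom,
        pos=np.asarray(pos),
    )


def read_genotype_table(path, dialect="matrix-tsv", orientation="auto") -> GenotypeMatrix:
    """Read a genotype matrix; dialect in {matrix-tsv, hapmap, vcf}."""
    if dialect == "matrix-tsv":
        gm = _read_matrix_tsv(path, orientation=orientation)
    elif dialect == "hapmap":
        gm = _read_hapmap(path)
    elif dialect == "vcf":
        gm = _read_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info(
        "read %d markers x %d genotypes from %s (%s)",
        gm.n_markers, gm.n_genotypes, path, dialect,
    )
    return gm


def write_genotype_matrix(gm: GenotypeMatrix, path) -> None:
    """Write calls as canonical marker-rows TSV (codes 0/1/2, missing NA)."""
    sym = {0: "0", 1: "1", 2: "2", -1: "NA"}
    with open(path, "w") as fh:
        fh.write("marker_id\t" + "\t".join(gm.genotype_ids) + "\n")
        for i, mid in enumerate(gm.marker_ids):
            fh.write(mid + "\t" + "\t".join(sym[int(c)] for c in gm.calls[i]) + "\n")


# ---------------------------------------------------------------------------
# plot tables


def read_plot_table(path) -> pd.DataFrame:
    """Read a plot-level phenotype table (one row per field plot).

    Requires the key columns genotype/environment/replicate/block plus at
    least one trait column; missing trait cells stay missing (never zero).
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in PLOT_KEY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns {missing_cols}")
    traits = [c for c in df.columns if c not in PLOT_KEY_COLUMNS]
    if not traits:
        raise SchemaError(f"{path}: no trait columns found")
    dup = df.duplicated(subset=["genotype", "environment", "replicate"])
    if dup.any():
        raise IntegrityError(
            f"{path}: duplicated (genotype, environment, replicate) keys, "
            f"e.g. row {int(df.index[dup][0]) + 2}"
        )
    df["replicate"] = df["replicate"].astype(int)
    df["block"] = df["block"].astype(int)
    if (df["replicate"] < 1).any() or (df["block"] < 1).any():
        raise IntegrityError(f"{path}: replicate and block must be >= 1")
    logger.info("read %d plot rows (%d traits) from %s", len(df), len(traits), path)
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# spectra tables


def validate_spectra_table(df: pd.DataFrame) -> np.ndarray:
    """Check key columns and the wavelength grid; return the grid (nm)."""
    for c in SPECTRA_KEY_COLUMNS:
        if c not in df.columns:
            raise SchemaError(f"spectra table missing column {c!r}")
    wl_cols = [c for c in df.columns
               if c not in SPECTRA_KEY_COLUMNS + ["block", "repetition"]]
    try:
        grid = np.asarray([int(c) for c in wl_cols])
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-wavelength column in spectra table: {exc}")
    if len(grid) < 2 or not np.all(np.diff(grid) == 1):
        raise SchemaError("wavelength grid must be strictly increasing, 1 nm step")
    vals = df[wl_cols].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise IntegrityError("non-finite reflectance values in spectra table")
    return grid


def read_spectra_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [
        int(c) if str(c).lstrip("-").isdigit() else c for c in df.columns
    ]
    validate_spectra_table(df)
    logger.info("read %d spectra rows from %s", len(df), path)
    return df


def write_spectra_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# group maps


def derive_major_group(subgroup: str) -> str:
    """ED and EF are their own major group, the six landraces map to LR;
    any other name (synthetic panels) is its own major group."""
    if subgroup in LANDRACE_SUBGROUPS:
        return "LR"
    return subgroup


def read_group_map(path) -> pd.DataFrame:
    """Read genotype -> subgroup map; the major group (ED/EF/LR) is derived."""
    df = pd.read_csv(path, sep="\t")
    for c in ("genotype_id", "subgroup"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c!r}")
    if df["genotype_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicated genotype ids")
    df["major_group"] = df["subgroup"].map(derive_major_group)
    return df[["genotype_id", "subgroup", "major_group"]]


def write_group_map(df: pd.DataFrame, path) -> None:
    df[["genotype_id", "subgroup"]].to_csv(path, sep="\t", index=False)
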