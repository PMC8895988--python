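"""Stepwise SNP quality control, numeric coding, imputation and merging.

The pipeline mirrors common breeding practice for array data on inbred
material: an overall pass removes uninformative markers (all-missing,
excess missingness, excess heterozygosity, monomorphic), then the panel is
split into its material groups and each group is cleaned again
(all-missing, monomorphic, low minor allele frequency), heterozygous calls
are set to missing, the remaining gaps are mean-imputed per group, a final
per-group MAF filter is applied and the groups are merged on the common
marker set into one genotypes x markers dosage matrix.

All thresholds are strict inequalities (> 50% missing, > 5% het, < 3% and
< 5% MAF) and every step's detected and newly-removed counts are recorded
in an ordered, additive report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix
from .errors import ConfigError, PhenopredError

__all__ = [
    "QCReport",
    "DosageMatrix",
    "qc_overall",
    "qc_per_group",
    "impute_naive",
    "maf_filter_and_merge",
    "call_stats",
]


@dataclass
class QCReport:
    """Ordered bookkeeping of a QC run: each step's counts and thresholds.

    ``detected`` counts markers matching a criterion regardless of earlier
    steps; ``removed`` counts those actually newly removed, so n_remaining
    decreases exactly by ``removed`` at every step.
    """

    thresholds: dict = field(default_factory=dict)
    steps: list = field(default_factory=list)
    genotype_flags: list = field(default_factory=list)
    n_input: int = 0

    def add(self, step: str, detected: int, removed: int, n_remaining: int):
        self.steps.append(
            {
                "step": step,
                "detected": int(detected),
                "removed": int(removed),
                "n_remaining": int(n_remaining),
            }
        )

    @property
    def n_remaining(self) -> int:
        return self.steps[-1]["n_remaining"] if self.steps else self.n_input

    def validate(self) -> None:
        prev = self.n_input
        for s in self.steps:
            if s["n_remaining"] != prev - s["removed"]:
                raise PhenopredError(f"non-additive QC report at {s['step']}")
            prev = s["n_remaining"]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "n_input": self.n_input,
                "thresholds": self.thresholds,
                "steps": self.steps,
                "genotype_flags": self.genotype_flags,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class DosageMatrix:
    """Genotypes x markers numeric dosages with no missing values."""

    values: np.ndarray  # float, (n_genotypes, n_markers), in [0, 2]
    genotype_ids: list
    marker_ids: list
    provenance: str = "genomic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise PhenopredError("dosage matrix shape inconsistent with ids")
        if np.isnan(self.values).any():
            raise PhenopredError("dosage matrix contains missing values")
        if self.values.min() < 0 or self.values.max() > 2:
            raise PhenopredError("dosages must lie in [0, 2]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.genotype_ids, columns=self.marker_ids
        )
        df.attrs["provenance"] = self.provenance
        return df


def call_stats(calls: np.ndarray) -> dict:
    """Per-marker missing/het fractions, allele counts and MAF.

    Fractions are over non-missing calls; a heterozygous call contributes
    one copy of each allele to the frequencies, so a het-only marker is
    polymorphic.
    """
    missing = calls == -1
    n_geno = calls.shape[1]
    n_nonmiss = n_geno - missing.sum(axis=1)
    het = (calls == 1).sum(axis=1)
    ref_hom = (calls == 0).sum(axis=1)
    alt_hom = (calls == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        miss_frac = missing.sum(axis=1) / n_geno
        het_frac = np.where(n_nonmiss > 0, het / n_nonmiss, np.nan)
        ref_count = 2 * ref_hom + het
        alt_count = 2 * alt_hom + het
        total = ref_count + alt_count
        alt_freq = np.where(total > 0, alt_count / total, np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    monomorphic = (n_nonmiss > 0) & ((ref_count == 0) | (alt_count == 0))
    return {
        "n_nonmissing": n_nonmiss,
        "miss_frac": miss_frac,
        "het_frac": het_frac,
        "alt_freq": alt_freq,
        "maf": maf,
        "monomorphic": monomorphic,
        "all_missing": n_nonmiss == 0,
    }


def qc_overall(
    gm: GenotypeMatrix,
    miss_thr: float = 0.50,
    het_thr: float = 0.05,
    geno_miss_thr: float = 0.20,
    geno_het_thr: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Overall marker QC in the fixed order of the pipeline.

    Removes, in order: all-missing markers; markers with a missing fraction
    > ``miss_thr``; markers with a heterozygous fraction > ``het_thr``;
    monomorphic markers still present.  Monomorphism is detected over all
    markers with any data, so the report shows both the detected and the
    newly removed count.  Finally each genotype is checked against
    > ``geno_miss_thr`` missing or > ``geno_het_thr`` het; failures are
    flagged in the report, never silently dropped.
    """
    report = QCReport(
        thresholds={
            "marker_missing": miss_thr,
            "marker_het": het_thr,
            "genotype_missing": geno_miss_thr,
            "genotype_het": geno_het_thr,
        },
        n_input=gm.n_markers,
    )
    stats = call_stats(gm.calls)
    keep = np.ones(gm.n_markers, dtype=bool)

    allmiss = stats["all_missing"]
    keep &= ~allmiss
    report.add("all_missing", allmiss.sum(), allmiss.sum(), keep.sum())

    highmiss = stats["miss_frac"] > miss_thr
    removed = highmiss & keep
    keep &= ~highmiss
    report.add("missing_gt_threshold", highmiss.sum(), removed.sum(), keep.sum())

    highhet = np.nan_to_num(stats["het_frac"]) > het_thr
    removed = highhet & keep
    keep &= ~highhet
    report.add("het_gt_threshold", highhet.sum(), removed.sum(), keep.sum())

    mono = stats["monomorphic"]
    removed = mono & keep
    keep &= ~mono
    report.add("monomorphic", mono.sum(), removed.sum(), keep.sum())

    out = gm.subset(marker_idx=np.where(keep)[0])

    # genotype-level screen on the filtered matrix
    calls = out.calls
    gmiss = (calls == -1).mean(axis=0)
    nonmiss = (calls != -1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ghet = np.where(nonmiss > 0, (calls == 1).sum(axis=0) / nonmiss, 0.0)
    for j, gid in enumerate(out.genotype_ids):
        if gmiss[j] > geno_miss_thr or ghet[j] > geno_het_thr:
            report.genotype_flags.append(
                {
                    "genotype_id": gid,
                    "missing_frac": float(gmiss[j]),
                    "het_frac": float(ghet[j]),
                }
            )
    report.validate()
    return out, report


def qc_per_group(
    gm: GenotypeMatrix,
    group_map: pd.DataFrame,
    maf_thr: float = 0.03,
    level: str = "major_group",
) -> dict:
    """Per-group QC after the overall pass; returns group -> (matrix, report).

    Within each group: all-missing and monomorphic markers and markers with
    MAF < ``maf_thr`` (strict, over non-missing calls) are removed, and the
    surviving heterozygous calls are set to missing rather than excluded.
    Marker sets may differ between groups afterwards.
    """
    if level not in group_map.columns:
        raise ConfigError(f"group map lacks column {level!r}")
    id_to_col = {g: j for j, g in enumerate(gm.genotype_ids)}
    out = {}
    for grp, members in group_map.groupby(level)["genotype_id"]:
        cols = [id_to_col[g] for g in members if g in id_to_col]
        if not cols:
            raise ConfigError(f"group {grp!r} has no genotypes in the matrix")
        sub = gm.subset(genotype_idx=cols)
        report = QCReport(thresholds={"maf": maf_thr}, n_input=sub.n_markers)
        stats = call_stats(sub.calls)
        keep = np.ones(sub.n_markers, dtype=bool)

        allmiss = stats["all_missing"]
        keep &= ~allmiss
        report.add("all_missing", allmiss.sum(), allmiss.sum(), keep.sum())

        mono = stats["monomorphic"]
        removed = mono & keep
        keep &= ~mono
        report.add("monomorphic", mono.sum(), removed.sum(), keep.sum())

        lowmaf = np.nan_to_num(stats["maf"], nan=1.0) < maf_thr
        removed = lowmaf & keep
        keep &= ~lowmaf
        report.add("maf_lt_threshold", lowmaf.sum(), removed.sum(), keep.sum())

        filtered = sub.subset(marker_idx=np.where(keep)[0])
        calls = filtered.calls.copy()
        n_het = int((calls == 1).sum())
        calls[calls == 1] = -1  # het -> missing, not removed
        filtered = GenotypeMatrix(
            calls,
            marker_ids=filtered.marker_ids,
            genotype_ids=filtered.genotype_ids,
            chrom=filtered.chrom,
            pos=filtered.pos,
        )
        report.thresholds["het_calls_set_missing"] = n_het
        report.validate()
        out[grp] = (filtered, report)
    return out


def impute_naive(group_matrices: dict) -> dict:
    """Numeric coding and within-group mean imputation, per group.

    Calls are coded REF=0, HET=1, ALT=2; missing calls are replaced by the
    marker's within-group mean dosage (non-integer dosages allowed).  This
    is a deliberately simple single-pass imputer; it uses no linkage or
    haplotype information.
    """
    out = {}
    for grp, item in group_matrices.items():
        gm = item[0] if isinstance(item, tuple) else item
        calls = gm.calls.astype(float)
        calls[calls == -1] = np.nan
        col_ok = ~np.all(np.isnan(calls), axis=1)
        assert col_ok.all(), (
            f"group {grp!r}: marker entirely missing after QC; "
            "qc_per_group must run first"
        )
        means = np.nanmean(calls, axis=1)
        idx = np.where(np.isnan(calls))
        calls[idx] = means[idx[0]]
        out[grp] = DosageMatrix(
            values=calls.T,
            genotype_ids=list(gm.genotype_ids),
            marker_ids=list(gm.marker_ids),
        )
    return out


def maf_filter_and_merge(
    group_dosages: dict, maf_thr: float = 0.05
) -> DosageMatrix:
    """Final per-group MAF filter, then merge on the common marker set.

    Markers with MAF < ``maf_thr`` (from mean dosage / 2) are removed per
    group; the merged matrix keeps the intersection of the surviving marker
    sets — required so every genotype carries every predictor column —
    stacking all groups' genotypes.
    """
    survivors = {}
    for grp, dm in group_dosages.items():
        freq = dm.values.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        keep = maf >= maf_thr  # strict removal of MAF < threshold
        survivors[grp] = (
            dm.values[:, keep],
            [m for m, k in zip(dm.marker_ids, keep) if k],
            dm.genotype_ids,
        )
    common = None
    for grp, (_, mids, _) in survivors.items():
        s = set(mids)
        common = s if common is None else common & s
    if not common:
        counts = {g: len(v[1]) for g, v in survivors.items()}
        raise PhenopredError(
            f"no marker survives in every group; per-group survivors {counts}"
        )
    first = next(iter(survivors.values()))[1]
    order = [m for m in first if m in common]

    blocks, genotype_ids = [], []
    for grp, (vals, mids, gids) in survivors.items():
        pos = {m: j for j, m in enumerate(mids)}
        blocks.append(vals[:, [pos[m] for m in order]])
        genotype_ids.extend(gids)
    return DosageMatrix(
        values=np.vstack(blocks),
        genotype_ids=genotype_ids,
        marker_ids=order,
    )
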