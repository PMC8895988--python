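"""Synthetic populations, traits, plot data and NIR spectra.

The generator reproduces the statistical structure of a diverse maize panel
evaluated in multi-environment trials:

* a structured population of inbred/doubled-haploid lines from several
  groups whose allele frequencies diverged from a common ancestor
  (Balding-Nichols model, one FST parameter);
* an additive trait whose group means may additionally be shifted by a
  structure-confounded offset;
* plot-level phenotypes generated exactly under the plot model
  (genotype + environment + GxE + replicate + block + error, all
  independent normals);
* smooth plot-level reflectance spectra built from Gaussian absorption
  bands whose heights are driven by latent "chemistry" components that
  correlate with the genotype's *within-group* genetic deviation — so the
  spectra carry trait signal but, by construction, no group signal.

Default sizes mirror the study panel the package is written for: 400
genotypes in 8 groups (two elite pools of 100, six landraces of 11/33/14/
53/30/59), three environments, two replicates, a 1,250-2,400 nm grid at
1 nm and 24 cup repetitions per plot.  One integer seed fixes the whole
stream; stage sub-generators are derived from it by fixed offsets so each
stage can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix, derive_major_group
from .errors import ConfigError, DesignError

__all__ = [
    "PopulationConfig",
    "TraitConfig",
    "DesignConfig",
    "SpectraConfig",
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_population",
    "simulate_trait",
    "simulate_plots",
    "simulate_latent",
    "simulate_spectra",
    "simulate_dataset",
    "variance_components_for_h2",
    "STUDY_GROUP_SIZES",
]

#: panel composition of the study the generator emulates
STUDY_GROUP_SIZES = {
    "ED": 100, "EF": 100,
    "CG": 11, "GB": 33, "RT": 14, "SM": 53, "SF": 30, "WA": 59,
}

# fixed seed offsets deriving each stage's RNG from the master seed
_SEED_POP, _SEED_TRAIT, _SEED_PLOTS, _SEED_SPECTRA = 11, 13, 17, 19


@dataclass
class PopulationConfig:
    group_sizes: dict = field(default_factory=lambda: dict(STUDY_GROUP_SIZES))
    n_markers: int = 57840
    fst: float = 0.15
    #: fraction of assays that fail outright (all calls missing), as on
    #: real arrays where a sizeable share of probes returns nothing
    fail_rate: float = 0.14
    #: mean per-marker missingness / heterozygosity among working assays;
    #: marker-level rates are Beta-dispersed around these means so that a
    #: tail of poor assays exceeds the QC thresholds
    missing_rate: float = 0.03
    het_rate: float = 0.01
    rate_concentration: float = 3.0
    #: nested family structure: lines within a group come in families
    #: (e.g. doubled haploids derived from the same source plants) whose
    #: allele frequencies diverge from the group's by ``family_fst``;
    #: within-group relatedness variation is what lets kinship-based
    #: prediction work inside a group.  family_size <= 1 disables it.
    family_size: int = 8
    family_fst: float = 0.3

    def __post_init__(self):
        if not (0.0 < self.fst < 1.0):
            raise ConfigError(f"fst must be in (0, 1), got {self.fst}")
        if any(n < 1 for n in self.group_sizes.values()):
            raise ConfigError("all group sizes must be >= 1")
        if not (0.0 <= self.fail_rate < 1.0):
            raise ConfigError("fail_rate must be in [0, 1)")


@dataclass
class TraitConfig:
    name: str = "trait"
    n_qtl: int = 100
    h2_target: float = 0.8
    group_mean_shift: float = 0.0  # delta, in units of within-group genetic sd
    #: genetic correlation of QTL effects across major groups; below 1 the
    #: same loci act with partially group-specific effects, so marker-based
    #: prediction transfers poorly between unrelated groups
    group_effect_corr: float = 1.0
    units: str = "a.u."

    def __post_init__(self):
        if not (0.0 < self.h2_target < 1.0):
            raise ConfigError("h2_target must be in (0, 1)")
        if not (0.0 <= self.group_effect_corr <= 1.0):
            raise ConfigError("group_effect_corr must be in [0, 1]")


@dataclass
class DesignConfig:
    n_env: int = 3
    n_rep: int = 2
    n_blocks: int = 20  # incomplete blocks per replicate

    def __post_init__(self):
        if self.n_env < 1 or self.n_rep < 1:
            raise DesignError("need at least one environment and one replicate")
        if self.n_blocks < 1:
            raise DesignError("need at least one block per replicate")


@dataclass
class SpectraConfig:
    grid: tuple = (1250, 2400)  # nm, inclusive, 1 nm step
    n_bands: int = 12
    band_sigma: float = 30.0  # nm
    n_latent: int = 3
    chem_trait_corr: float = 0.85  # corr(latent, within-group genetic value)
    band_height_scale: float = 0.02  # reflectance units per latent sd
    env_effect_sd: float = 0.01
    noise_sd: float = 0.004  # per-repetition iid noise
    n_repetitions: int = 24
    band_centers: tuple | None = None  # nm; drawn if None


@dataclass
class SimConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    trait: TraitConfig = field(default_factory=TraitConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth stored alongside every generated dataset."""

    ancestral_freqs: np.ndarray | None = None
    group_freqs: pd.DataFrame | None = None
    true_dosages: np.ndarray | None = None  # markers x genotypes, no missing
    qtl_indices: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None
    genetic_values: pd.Series | None = None
    within_group_values: pd.Series | None = None
    group_offsets: pd.Series | None = None
    variance_components: dict | None = None
    mu: float = 0.0
    latent: pd.DataFrame | None = None
    band_centers: np.ndarray | None = None
    loadings: np.ndarray | None = None

    def realized_h2(self) -> float:
        vc = self.variance_components
        vg = float(self.genetic_values.var(ddof=1))
        ne, nr = vc["ne"], vc["nr"]
        return vg / (vg + vc["sigma2_gxe"] / ne + vc["sigma2_eps"] / (ne * nr))


@dataclass
class SimDataset:
    config: SimConfig
    genotypes: GenotypeMatrix
    group_map: pd.DataFrame
    plots: pd.DataFrame
    spectra: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------


def simulate_population(config: SimConfig):
    """Draw a structured panel of inbred lines under the Balding-Nichols model.

    Ancestral allele frequencies are Uniform(0.1, 0.9); each group's
    frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p.
    Lines are (near-)fully homozygous: each call is drawn as one allele,
    doubled, with a small heterozygosity and missingness rate applied to
    the observed calls only (the truth keeps complete dosages).
    """
    pop = config.population
    rng = np.random.default_rng(config.seed + _SEED_POP)
    m = pop.n_markers
    p_anc = rng.uniform(0.1, 0.9, size=m)
    F = pop.fst
    a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F

    # marker-level assay quality: some probes fail outright, the rest have
    # Beta-dispersed missingness and heterozygosity rates
    k = pop.rate_concentration
    failed = rng.random(m) < pop.fail_rate
    if pop.missing_rate > 0:
        miss_r = rng.beta(pop.missing_rate * k, (1 - pop.missing_rate) * k,
                          size=m)
    else:
        miss_r = np.zeros(m)
    if pop.het_rate > 0:
        het_r = rng.beta(pop.het_rate * k, (1 - pop.het_rate) * k, size=m)
    else:
        het_r = np.zeros(m)

    groups = sorted(pop.group_sizes)
    group_freqs = {}
    cols_calls, cols_true = [], []
    genotype_ids, subgroup_of, family_of = [], [], []
    for g in groups:
        pg = rng.beta(a, b)
        group_freqs[g] = pg
        n_g = pop.group_sizes[g]
        if pop.family_size > 1 and pop.family_fst > 0:
            n_fam = max(1, round(n_g / pop.family_size))
            Ff = pop.family_fst
            af, bf = pg * (1 - Ff) / Ff, (1 - pg) * (1 - Ff) / Ff
            fam_members = np.array_split(np.arange(n_g), n_fam)
            alleles = np.empty((m, n_g), dtype=bool)
            fam_label = np.empty(n_g, dtype=int)
            for f, members in enumerate(fam_members):
                pf = rng.beta(af, bf)
                alleles[:, members] = (
                    rng.random((m, len(members))) < pf[:, None]
                )
                fam_label[members] = f
        else:
            alleles = rng.random((m, n_g)) < pg[:, None]
            fam_label = np.zeros(n_g, dtype=int)
        true_dos = (alleles * 2).astype(np.int8)
        calls = true_dos.copy()
        calls[rng.random((m, n_g)) < het_r[:, None]] = 1
        calls[rng.random((m, n_g)) < miss_r[:, None]] = -1
        calls[failed, :] = -1
        cols_calls.append(calls)
        cols_true.append(true_dos)
        genotype_ids.extend(f"{g}_{i + 1:03d}" for i in range(n_g))
        subgroup_of.extend([g] * n_g)
        family_of.extend(f"{g}_F{f + 1}" for f in fam_label)

    gm = GenotypeMatrix(
        calls=np.concatenate(cols_calls, axis=1),
        marker_ids=[f"M{i + 1:06d}" for i in range(m)],
        genotype_ids=genotype_ids,
    )
    group_map = pd.DataFrame(
        {
            "genotype_id": genotype_ids,
            "subgroup": subgroup_of,
            "major_group": [derive_major_group(s) for s in subgroup_of],
            "family": family_of,
        }
    )
    truth = SimTruth(
        ancestral_freqs=p_anc,
        group_freqs=pd.DataFrame(group_freqs, index=gm.marker_ids),
        true_dosages=np.concatenate(cols_true, axis=1),
    )
    return gm, group_map, truth


def simulate_trait(
    gm: GenotypeMatrix,
    group_map: pd.DataFrame,
    truth: SimTruth,
    trait: TraitConfig,
    seed: int,
    effects: np.ndarray | None = None,
) -> pd.Series:
    """Additive genetic values plus an optional structure-confounded offset.

    QTL effects act on the true (complete) dosages.  The additive part is
    scaled so its pooled within-group standard deviation is 1; group
    offsets are evenly spaced, centred, and spaced by ``group_mean_shift``
    in those units, confounding group identity with trait performance.
    """
    if trait.n_qtl > gm.n_markers:
        raise ConfigError("n_qtl cannot exceed n_markers")
    rng = np.random.default_rng(seed + _SEED_TRAIT)
    qtl = rng.choice(gm.n_markers, size=trait.n_qtl, replace=False)
    ids = pd.Index(gm.genotype_ids, name="genotype")
    majors = group_map.set_index("genotype_id")["major_group"].reindex(ids)
    dos = truth.true_dosages[qtl, :].astype(float)
    if effects is None:
        common = rng.normal(0.0, 1.0, size=trait.n_qtl)
        rho_g = trait.group_effect_corr
        if rho_g < 1.0:
            g_raw = np.zeros(len(ids))
            for grp in sorted(majors.unique()):
                own = rng.normal(0.0, 1.0, size=trait.n_qtl)
                eff = rho_g * common + np.sqrt(1 - rho_g**2) * own
                cols = (majors == grp).to_numpy()
                g_raw[cols] = eff @ dos[:, cols]
        else:
            g_raw = common @ dos
        effects = common
    else:
        effects = np.asarray(effects, dtype=float)
        g_raw = effects @ dos
    g_raw = pd.Series(g_raw, index=ids)
    sub = group_map.set_index("genotype_id")["subgroup"].reindex(ids)

    within = g_raw - g_raw.groupby(sub).transform("mean")
    sd_w = float(within.std(ddof=1))
    if sd_w > 0:
        g_add = (g_raw - g_raw.mean()) / sd_w
    else:
        g_add = g_raw - g_raw.mean()

    groups = sorted(sub.unique())
    spacing = trait.group_mean_shift
    offs = {
        g: (i - (len(groups) - 1) / 2.0) * spacing for i, g in enumerate(groups)
    }
    offsets = sub.map(offs).astype(float)

    values = g_add + offsets
    truth.qtl_indices = qtl
    truth.qtl_effects = effects
    truth.genetic_values = values
    truth.within_group_values = g_add - g_add.groupby(sub).transform("mean")
    truth.group_offsets = offsets
    return values


def variance_components_for_h2(
    var_g: float,
    h2_target: float,
    ne: int,
    nr: int,
    gxe_ratio: float = 0.5,
    env_ratio: float = 1.0,
    rep_ratio: float = 0.1,
    block_ratio: float = 0.1,
) -> dict:
    """Error-side variance components giving the target entry-mean H2.

    The GxE and plot-error variances keep the fixed shape
    sigma2_gxe = gxe_ratio * s, sigma2_eps = s and the scale s solves
    H2 = var_g / (var_g + sigma2_gxe/ne + sigma2_eps/(ne*nr)).
    """
    if not (0.0 < h2_target < 1.0):
        raise ConfigError("h2_target must be in (0, 1)")
    denom = gxe_ratio / ne + 1.0 / (ne * nr)
    s = var_g * (1.0 - h2_target) / (h2_target * denom)
    return {
        "sigma2_gxe": gxe_ratio * s,
        "sigma2_eps": s,
        "sigma2_env": env_ratio * var_g,
        "sigma2_rep": rep_ratio * var_g,
        "sigma2_block": block_ratio * var_g,
        "mu": 0.0,
        "ne": ne,
        "nr": nr,
    }


def simulate_plots(
    genetic_values: pd.Series,
    design: DesignConfig,
    vc: dict,
    seed: int,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Plot-level phenotypes under the plot model with independent normals.

    Every genotype appears once per (environment, replicate); within each
    replicate the genotypes are randomly partitioned into incomplete
    blocks, as in an alpha-lattice layout.  Row count is
    n_genotypes * n_env * n_rep.
    """
    for key in ("sigma2_gxe", "sigma2_eps", "sigma2_env", "sigma2_rep",
                "sigma2_block"):
        if vc.get(key, 0.0) < 0:
            raise ConfigError(f"variance component {key} must be >= 0")
    rng = np.random.default_rng(seed + _SEED_PLOTS)
    genos = list(genetic_values.index)
    n = len(genos)
    envs = [f"ENV{j + 1}" for j in range(design.n_env)]
    mu = vc.get("mu", 0.0)

    e_eff = rng.normal(0, np.sqrt(vc["sigma2_env"]), size=design.n_env)
    ge_eff = rng.normal(0, np.sqrt(vc["sigma2_gxe"]), size=(n, design.n_env))
    rows = []
    for j, env in enumerate(envs):
        for k in range(1, design.n_rep + 1):
            r_eff = rng.normal(0, np.sqrt(vc["sigma2_rep"]))
            order = rng.permutation(n)
            block_of = np.empty(n, dtype=int)
            splits = np.array_split(order, design.n_blocks)
            b_eff = rng.normal(0, np.sqrt(vc["sigma2_block"]),
                               size=design.n_blocks)
            for bi, members in enumerate(splits):
                block_of[members] = bi
            eps = rng.normal(0, np.sqrt(vc["sigma2_eps"]), size=n)
            for i, geno in enumerate(genos):
                rows.append(
                    (
                        geno, env, k, block_of[i] + 1,
                        mu + genetic_values.iloc[i] + e_eff[j]
                        + ge_eff[i, j] + r_eff + b_eff[block_of[i]] + eps[i],
                    )
                )
    return pd.DataFrame(
        rows, columns=["genotype", "environment", "replicate", "block",
                       trait_name]
    )


def simulate_latent(
    genetic_values: pd.Series,
    group_map: pd.DataFrame,
    spectra: SpectraConfig,
    seed: int,
) -> pd.DataFrame:
    """Latent chemistry components, correlated with the within-group
    genetic deviation at ``chem_trait_corr`` and independent of group."""
    rng = np.random.default_rng(seed + _SEED_SPECTRA)
    ids = genetic_values.index
    sub = group_map.set_index("genotype_id")["subgroup"].reindex(ids)
    within = genetic_values - genetic_values.groupby(sub).transform("mean")
    sd = float(within.std(ddof=1))
    w = within / sd if sd > 0 else within * 0.0
    rho = spectra.chem_trait_corr
    if not (-1.0 <= rho <= 1.0):
        raise ConfigError("chem_trait_corr must be in [-1, 1]")
    cols = {}
    for l in range(spectra.n_latent):
        z = rng.normal(size=len(ids))
        cols[f"latent{l + 1}"] = rho * w.to_numpy() + np.sqrt(1 - rho**2) * z
    return pd.DataFrame(cols, index=ids)


def _baseline(grid: np.ndarray) -> np.ndarray:
    lo, hi = grid[0], grid[-1]
    t = (grid - lo) / (hi - lo)
    return 0.45 + 0.08 * t + 0.05 * np.sin(2 * np.pi * t)


def simulate_spectra(
    latent: pd.DataFrame,
    plots_layout: pd.DataFrame,
    spectra: SpectraConfig,
    seed: int,
    emit_repetitions: bool = False,
) -> pd.DataFrame:
    """Plot-level reflectance spectra on the configured grid.

    Each genotype's spectrum is the smooth baseline plus Gaussian bands
    whose heights are linear in the latent chemistry, plus a smooth
    per-environment deviation and iid measurement noise.  By default the
    ``n_repetitions`` cup repetitions are averaged to one spectrum per plot
    (their iid noise enters with variance/n_repetitions); with
    ``emit_repetitions=True`` one row per repetition is emitted instead.
    """
    rng = np.random.default_rng(seed + _SEED_SPECTRA + 1)
    lo, hi = spectra.grid
    grid = np.arange(lo, hi + 1)
    if spectra.band_centers is not None:
        centers = np.asarray(spectra.band_centers, dtype=float)
        if centers.min() < lo or centers.max() > hi:
            raise ConfigError("band centers outside the wavelength grid")
    else:
        margin = min(2 * spectra.band_sigma, (hi - lo) / 4.0)
        centers = rng.uniform(lo + margin, hi - margin, size=spectra.n_bands)
    loadings = rng.normal(0.0, spectra.band_height_scale,
                          size=(len(centers), latent.shape[1]))
    bands = np.exp(
        -((grid[None, :] - centers[:, None]) ** 2)
        / (2 * spectra.band_sigma**2)
    )  # n_bands x n_wl

    heights = latent.to_numpy() @ loadings.T  # n_geno x n_bands
    geno_spec = pd.DataFrame(
        _baseline(grid)[None, :] + heights @ bands,
        index=latent.index, columns=grid,
    )

    envs = sorted(plots_layout["environment"].unique())
    env_dev = {}
    for env in envs:
        # smooth environment deviation: a few broad Gaussian humps
        c = rng.uniform(lo, hi, size=3)
        amp = rng.normal(0, spectra.env_effect_sd, size=3)
        width = (hi - lo) / 4.0
        env_dev[env] = (
            amp[:, None] * np.exp(-((grid[None, :] - c[:, None]) ** 2)
                                  / (2 * width**2))
        ).sum(axis=0)

    key_cols = ["genotype", "environment", "replicate"]
    if "block" in plots_layout.columns:
        key_cols.append("block")
    layout = plots_layout[key_cols].drop_duplicates().reset_index(drop=True)
    base = geno_spec.loc[layout["genotype"]].to_numpy()
    base = base + np.stack([env_dev[e] for e in layout["environment"]])

    meta = {"band_centers": centers, "loadings": loadings}
    if emit_repetitions:
        reps = []
        for rep in range(1, spectra.n_repetitions + 1):
            noise = rng.normal(0, spectra.noise_sd, size=base.shape)
            df = layout.copy()
            df["repetition"] = rep
            reps.append(
                pd.concat(
                    [df, pd.DataFrame(base + noise, columns=grid)], axis=1
                )
            )
        out = pd.concat(reps, ignore_index=True)
        out.attrs.update(meta)
        return out
    noise = rng.normal(
        0, spectra.noise_sd / np.sqrt(spectra.n_repetitions), size=base.shape
    )
    out = pd.concat(
        [layout, pd.DataFrame(base + noise, columns=grid)], axis=1
    )
    out.attrs.update(meta)
    return out


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full synthetic dataset: genotypes, group map, plots, spectra, truth."""
    gm, group_map, truth = simulate_population(config)
    values = simulate_trait(gm, group_map, truth, config.trait, config.seed)
    vc = variance_components_for_h2(
        var_g=float(values.var(ddof=1)),
        h2_target=config.trait.h2_target,
        ne=config.design.n_env,
        nr=config.design.n_rep,
    )
    truth.variance_components = vc
    plots = simulate_plots(
        values, config.design, vc, config.seed, trait_name=config.trait.name
    )
    latent = simulate_latent(values, group_map, config.spectra, config.seed)
    truth.latent = latent
    spectra = simulate_spectra(latent, plots, config.spectra, config.seed)
    truth.band_centers = spectra.attrs.get("band_centers")
    truth.loadings = spectra.attrs.get("loadings")
    return SimDataset(
        config=config,
        genotypes=gm,
        group_map=group_map,
        plots=plots,
        spectra=spectra,
        truth=truth,
    )
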