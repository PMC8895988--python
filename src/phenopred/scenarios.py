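"""Packaged seeded scenarios: full pipeline runs on synthetic panels.

Two study-condition scenarios are bundled, both running the complete
pipeline (population -> marker QC -> dosages; spectra -> derivative ->
per-wavelength BLUEs -> standardization; plots -> trait BLUEs):

``confounded_landraces``
    Six landrace subpopulations whose trait differences come from group
    mean shifts only — the trait has no within-group genetic signal.  This
    is the setting in which pooled genomic cross-validation reports a high
    overall predictive ability that evaporates within every subgroup (a
    population-structure artifact), while spectra-based prediction, whose
    predictors carry no group signal, does not produce the artifact.

``elite_landrace_panel``
    The full two-elite-pools-plus-landraces panel with a genuinely
    polygenic trait (no group mean shift) whose signal the spectra carry
    through latent chemistry.  Used for among-group prediction and
    composite-training-set evaluation.

Problem sizes are desk-scale (hundreds of markers, a ~100 nm spectral
window) so a scenario builds in a couple of minutes; the statistical
structure, group sizes and trial design match the full-size panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import markers as mk
from . import simulate as sim
from . import spectra as sp
from .phenostats import compute_blues

__all__ = [
    "Scenario",
    "confounded_landraces",
    "elite_landrace_panel",
    "LANDRACE_SIZES",
]

#: landrace subpopulation sizes of the emulated panel
LANDRACE_SIZES = {"CG": 11, "GB": 33, "RT": 14, "SM": 53, "SF": 30, "WA": 59}


@dataclass
class Scenario:
    name: str
    group_map: pd.DataFrame
    subgroups: pd.Series  # genotype -> subgroup, aligned to y
    major_groups: pd.Series
    y: pd.Series  # trait BLUEs
    genomic: pd.DataFrame  # genotypes x markers dosage matrix
    phenomic: pd.DataFrame  # genotypes x wavelengths, standardized
    raw_spectra: pd.DataFrame
    genotypes: object
    truth: sim.SimTruth


def _run_pipeline(name, gm, group_map, plots, spectra_table, truth,
                  qc_level="major_group") -> Scenario:
    qc, _ = mk.qc_overall(gm)
    per_group = mk.qc_per_group(qc, group_map, level=qc_level)
    dosages = mk.impute_naive(per_group)
    merged = mk.maf_filter_and_merge(dosages)
    genomic = merged.to_frame()

    processed, _ = sp.preprocess(spectra_table)
    wl_blues, _ = sp.wavelength_blues(processed, compute_h2=False)
    phenomic = sp.standardize(wl_blues)

    y = compute_blues(plots, ["trait"])["trait"]
    ids = [g for g in y.index if g in set(genomic.index)]
    sub = group_map.set_index("genotype_id")
    return Scenario(
        name=name,
        group_map=group_map,
        subgroups=sub["subgroup"].reindex(ids),
        major_groups=sub["major_group"].reindex(ids),
        y=y.reindex(ids),
        genomic=genomic.reindex(ids),
        phenomic=phenomic.reindex(ids),
        raw_spectra=spectra_table,
        genotypes=gm,
        truth=truth,
    )


def confounded_landraces(seed: int = 0) -> Scenario:
    """Landrace panel whose trait is driven by group mean shifts only.

    The trait carries no within-group genetic signal (all QTL effects
    zero); subpopulation means are separated by three plot-error standard
    deviations' worth of spacing.  Spectra are generated as usual, so
    their latent chemistry reduces to structure-free noise.
    """
    import numpy as np

    cfg = sim.SimConfig(
        population=sim.PopulationConfig(
            group_sizes=dict(LANDRACE_SIZES), n_markers=800, fst=0.15
        ),
        trait=sim.TraitConfig(n_qtl=60, h2_target=0.8, group_mean_shift=3.0),
        design=sim.DesignConfig(n_env=3, n_rep=2, n_blocks=10),
        spectra=sim.SpectraConfig(grid=(1250, 1349), n_bands=8,
                                  band_sigma=12.0),
        seed=seed,
    )
    gm, group_map, truth = sim.simulate_population(cfg)
    values = sim.simulate_trait(
        gm, group_map, truth, cfg.trait, cfg.seed,
        effects=np.zeros(cfg.trait.n_qtl),  # structure only, no QTL signal
    )
    vc = {
        "sigma2_env": 4.0, "sigma2_gxe": 2.0, "sigma2_rep": 0.4,
        "sigma2_block": 0.4, "sigma2_eps": 8.0, "mu": 50.0,
        "ne": 3, "nr": 2,
    }
    truth.variance_components = vc
    plots = sim.simulate_plots(values, cfg.design, vc, cfg.seed)
    latent = sim.simulate_latent(values, group_map, cfg.spectra, cfg.seed)
    truth.latent = latent
    spectra_table = sim.simulate_spectra(latent, plots, cfg.spectra, cfg.seed)
    return _run_pipeline(
        "confounded_landraces", gm, group_map, plots, spectra_table, truth,
        qc_level="subgroup",
    )


def elite_landrace_panel(seed: int = 0) -> Scenario:
    """Two elite pools plus six landraces; polygenic structure-free trait.

    The trait is additive with no group mean shift, but its QTL effects
    are almost entirely group-specific (genetic correlation 0.1 across the
    three major groups), the regime in which marker-based prediction works
    within a group yet transfers poorly between unrelated groups.  The
    latent spectral chemistry tracks each genotype's own within-group
    genetic deviation closely (correlation 0.9), so spectra-based
    prediction transfers across groups regardless.
    """
    sizes = {"ED": 100, "EF": 100, **LANDRACE_SIZES}
    cfg = sim.SimConfig(
        population=sim.PopulationConfig(
            group_sizes=sizes, n_markers=1000, fst=0.15, family_fst=0.4
        ),
        trait=sim.TraitConfig(
            n_qtl=150, h2_target=0.9, group_mean_shift=0.0,
            group_effect_corr=0.1,
        ),
        design=sim.DesignConfig(n_env=3, n_rep=2, n_blocks=20),
        spectra=sim.SpectraConfig(grid=(1250, 1349), n_bands=8,
                                  band_sigma=12.0, chem_trait_corr=0.9),
        seed=seed,
    )
    gm, group_map, truth = sim.simulate_population(cfg)
    values = sim.simulate_trait(gm, group_map, truth, cfg.trait, cfg.seed)
    vc = sim.variance_components_for_h2(
        var_g=float(values.var(ddof=1)),
        h2_target=cfg.trait.h2_target,
        ne=cfg.design.n_env,
        nr=cfg.design.n_rep,
    )
    truth.variance_components = vc
    plots = sim.simulate_plots(values, cfg.design, vc, cfg.seed)
    latent = sim.simulate_latent(values, group_map, cfg.spectra, cfg.seed)
    truth.latent = latent
    spectra_table = sim.simulate_spectra(latent, plots, cfg.spectra, cfg.seed)
    return _run_pipeline(
        "elite_landrace_panel", gm, group_map, plots, spectra_table, truth,
        qc_level="major_group",
    )
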