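"""Shared plumbing for the numbered analysis scripts.

Scenario datasets take a couple of minutes to build (the per-wavelength
mixed-model fits dominate), so they are cached as pickles under scratch/
and rebuilt only when absent.  Delete scratch/ to force a fresh build.
"""

import pickle
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = 1  # panel seed used throughout the analysis scripts


def get_scenario(name: str, seed: int = SEED):
    from phenopred import scenarios

    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"{name}_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    builder = {
        "confounded": scenarios.confounded_landraces,
        "panel": scenarios.elite_landrace_panel,
    }[name]
    sc = builder(seed=seed)
    with open(cache, "wb") as fh:
        pickle.dump(sc, fh)
    return sc


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
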