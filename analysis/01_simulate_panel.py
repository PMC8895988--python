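#!/usr/bin/env python
"""Generate the two synthetic panels and summarise what was built.

Builds (and caches) the confounded-landrace scenario and the full
elite-plus-landrace panel: structured genotypes, multi-environment plot
phenotypes, plot-level NIR spectra, and the processed predictor matrices.
Writes a one-row-per-panel summary to results/panel_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_results, get_scenario  # noqa: E402


def main():
    rows = []
    for name in ("confounded", "panel"):
        sc = get_scenario(name)
        counts = sc.group_map["subgroup"].value_counts()
        rows.append(
            {
                "scenario": sc.name,
                "n_genotypes": len(sc.y),
                "n_subgroups": counts.size,
                "n_plots": len(sc.y) * 6,  # 3 environments x 2 replicates
                "n_markers_after_qc": sc.genomic.shape[1],
                "n_wavelengths": sc.phenomic.shape[1],
                "trait_sd": round(float(sc.y.std()), 3),
            }
        )
        print(f"{sc.name}: {len(sc.y)} genotypes in {counts.size} groups, "
              f"{sc.genomic.shape[1]} markers, "
              f"{sc.phenomic.shape[1]} wavelengths after processing")
    out = ensure_results() / "panel_summary.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
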