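#!/usr/bin/env python
"""Stepwise marker quality control on the synthetic panel.

Runs the overall pass (all-missing, missingness, heterozygosity,
monomorphic), splits the panel into its three major groups for the
per-group pass (monomorphic, MAF < 3%, het -> missing), imputes, applies
the final MAF < 5% filter and merges.  Writes the ordered step table to
results/marker_qc.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SEED, ensure_results  # noqa: E402

from phenopred import markers, scenarios, simulate  # noqa: E402


def main():
    sizes = {"ED": 100, "EF": 100, **scenarios.LANDRACE_SIZES}
    cfg = simulate.SimConfig(
        population=simulate.PopulationConfig(group_sizes=sizes, n_markers=2000),
        seed=SEED,
    )
    gm, gmap, _ = simulate.simulate_population(cfg)
    filtered, report = markers.qc_overall(gm)
    print(f"overall QC: {gm.n_markers} -> {report.n_remaining} markers")
    for step in report.steps:
        print(f"  {step['step']}: removed {step['removed']} "
              f"(detected {step['detected']}), {step['n_remaining']} left")

    per_group = markers.qc_per_group(filtered, gmap)
    payload = {"overall": json.loads(report.to_json()), "per_group": {}}
    for grp, (sub, rep) in per_group.items():
        print(f"group {grp}: {rep.n_remaining} markers survive")
        payload["per_group"][grp] = json.loads(rep.to_json())

    dosages = markers.impute_naive(per_group)
    merged = markers.maf_filter_and_merge(dosages)
    print(f"merged predictor matrix: {len(merged.genotype_ids)} genotypes "
          f"x {len(merged.marker_ids)} markers")
    payload["merged_markers"] = len(merged.marker_ids)

    out = ensure_results() / "marker_qc.json"
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
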