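#!/usr/bin/env python
"""Among-group prediction and composite training sets.

Reciprocal among-group predictions between the three major groups for
both predictor sets, then composite training sets for the elite Flint
target: 80% of the target plus one whole donor group predicting the
held-out 20%, 100 runs.  Writes results/among_composite.tsv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_results, get_scenario  # noqa: E402

from phenopred import evaluate  # noqa: E402

warnings.simplefilter("ignore")


def main():
    sc = get_scenario("panel")
    mg = sc.major_groups
    ids = {g: list(mg[mg == g].index) for g in ("ED", "EF", "LR")}
    rows = []
    print("among-group predictions (train -> test):")
    for name, Z in (("genomic", sc.genomic), ("phenomic", sc.phenomic)):
        for a in ids:
            for b in ids:
                if a == b:
                    continue
                r = evaluate.run_among(sc.y, Z, ids[a], ids[b])
                rows.append({"design": "among", "predictor": name,
                             "train": a, "test": b, "r": r})
                print(f"  {name:8s} {a}->{b}: r = {r:+.3f}")

    print("composite training sets (target EF, 100 runs):")
    scheme = evaluate.CVScheme(kind="composite", n_runs=100, seed=22)
    for name, Z in (("genomic", sc.genomic), ("phenomic", sc.phenomic)):
        for donor in ("ED", "LR"):
            res = evaluate.run_composite(
                sc.y, Z, ids["EF"], [ids[donor]], scheme
            )
            rows.append({"design": f"composite+{donor}", "predictor": name,
                         "train": f"EF80+{donor}", "test": "EF20",
                         "r": res.mean})
            print(f"  {name:8s} EF80+{donor}: mean r = {res.mean:.3f} "
                  f"(sd {res.sd:.3f})")
    out = ensure_results() / "among_composite.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
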