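#!/usr/bin/env python
"""Within-group cross-validated predictive ability, genomic vs phenomic.

For every group of at least 30 genotypes (the two elite pools, the
landraces as a whole, and the individual landraces above the size cutoff)
runs stratified 5-fold cross-validation with both predictor sets and
writes the per-fold abilities to results/within_cv.tsv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_results, get_scenario  # noqa: E402

from phenopred import evaluate  # noqa: E402

warnings.simplefilter("ignore")

N_RUNS = 20  # cross-validation partitions per group


def main():
    sc = get_scenario("panel")
    groups = {"ED": None, "EF": None, "LR": None}
    mg, sub = sc.major_groups, sc.subgroups
    frames = []
    for grp in list(groups) + sorted(
        s for s, n in sub.value_counts().items()
        if n >= evaluate.MIN_STANDALONE_GROUP and s not in ("ED", "EF")
    ):
        ids = list(
            (mg if grp in ("ED", "EF", "LR") else sub)
            .pipe(lambda s: s[s == grp]).index
        )
        stratify = grp == "LR"
        for name, Z in (("genomic", sc.genomic), ("phenomic", sc.phenomic)):
            scheme = evaluate.CVScheme(
                kind="within", n_runs=N_RUNS,
                stratify_by_subgroup=stratify, seed=11,
            )
            res = evaluate.run_within_cv(
                sc.y, Z, ids, scheme,
                subgroups=sub.reindex(ids) if stratify else None,
            )
            print(f"{grp:3s} {name:8s}: mean r = {res.mean:.3f} "
                  f"(sd {res.sd:.3f}, n={len(ids)})")
            tidy = res.runs.assign(group=grp, predictor=name)
            frames.append(tidy)
    out = ensure_results() / "within_cv.tsv"
    pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
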