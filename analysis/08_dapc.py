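#!/usr/bin/env python
"""Group discrimination: DAPC on marker data versus raw NIR spectra.

Discriminant analysis of principal components on the confounded landrace
panel.  Marker data should separate the subpopulations almost perfectly;
the raw spectra, whose variation carries no group signal by construction,
should sit near the majority-class chance level.  Writes
results/dapc.tsv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ensure_results, get_scenario  # noqa: E402

from phenopred import evaluate  # noqa: E402

warnings.simplefilter("ignore")


def main():
    sc = get_scenario("confounded")
    sub = sc.subgroups
    chance = sub.value_counts(normalize=True).max()
    rows = []
    marker = evaluate.dapc(sc.genomic, sub.reindex(sc.genomic.index))
    wl = [c for c in sc.raw_spectra.columns if isinstance(c, (int, np.integer))]
    spec_mat = sc.raw_spectra.groupby("genotype")[wl].mean().reindex(sub.index)
    spec = evaluate.dapc(spec_mat, sub)
    for name, res in (("markers", marker), ("spectra", spec)):
        print(f"{name}: {res.n_pc} PCs retained, "
              f"DA1 {res.explained[0]:.1f}% / DA2 {res.explained[1]:.1f}%, "
              f"reassignment {100 * res.reassignment_rate:.1f}% "
              f"(chance {100 * chance:.1f}%)")
        rows.append({"features": name, "n_pc": res.n_pc,
                     "da1_pct": res.explained[0],
                     "da2_pct": res.explained[1],
                     "reassignment_pct": 100 * res.reassignment_rate,
                     "chance_pct": 100 * chance})
    out = ensure_results() / "dapc.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
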