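#!/usr/bin/env python
"""Differential abundance between phenotype groups.

For each comparison (H vs ICD, H vs CCD, ICD vs CCD): prefilter (>5 counts in
>=4 runs), Wilcoxon rank-sum, Storey q-values, and the dual significance
criterion (q < 0.05 and |median difference| > 5).  Writes one table per
comparison and level.
"""

from pathlib import Path

import pandas as pd

from mproteo import io as mio
from mproteo.quant import AbundanceMatrix
from mproteo.stats import call_differential

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
COMPARISONS = [("H", "ICD"), ("H", "CCD"), ("ICD", "CCD")]


def main() -> None:
    run_meta = pd.read_csv(OUT / "runs.tsv", sep="\t")
    runs_of = {
        g: run_meta.loc[run_meta["group"] == g, "run_id"].tolist()
        for g in run_meta["group"].unique()
    }
    for level in ("cluster", "human"):
        path = OUT / f"abundance_{level}.tsv"
        if not path.exists():
            continue
        matrix = AbundanceMatrix(mio.read_matrix(path), level, True)
        for a, b in COMPARISONS:
            res = call_differential(matrix, runs_of[a], runs_of[b])
            res.to_csv(
                OUT / f"differential_{level}_{a}_vs_{b}.tsv",
                sep="\t", index=False,
            )
            n_sig = int(res["significant"].sum())
            print(f"{level:8s} {a} vs {b}: {n_sig} significant of "
                  f"{len(res)} eligible"
                  + (" (low power)" if res.attrs["low_power"] else ""))


if __name__ == "__main__":
    main()
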