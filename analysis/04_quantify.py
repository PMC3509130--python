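#!/usr/bin/env python
"""Attribute accepted spectra to clusters and human proteins; normalize.

Unique-attribution spectral counts per ortholog cluster (a spectrum counts
only when all its matched ORFs share one cluster), shared-peptide counting for
human proteins, then scaling by alpha_i = N/n_i.  Writes the normalized
matrices under results/cohort/.
"""

from pathlib import Path

import pandas as pd

from mproteo import io as mio
from mproteo.psm import FilterPolicy, protein_level_filter
from mproteo.quant import (
    RunProfile,
    attribute_spectra,
    human_protein_counts,
    normalize_counts,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    accepted = mio.read_psms(OUT / "psms_accepted.tsv")
    run_meta = pd.read_csv(OUT / "runs.tsv", sep="\t")
    mapping = {
        r.orf_id: (r.cluster_id if isinstance(r.cluster_id, str) and r.cluster_id else None)
        for r in pd.read_csv(OUT / "orf_mapping.tsv", sep="\t").itertuples()
    }
    targets = accepted[~accepted["is_decoy"]]
    human_mask = targets["protein_ids"].str.split(";").map(
        lambda ps: all(p.startswith("HUMAN") for p in ps)
    )
    microbial, _ = protein_level_filter(
        targets[~human_mask], "mm", FilterPolicy(), mapping
    )
    human, _ = protein_level_filter(targets[human_mask], "hmrg", FilterPolicy())

    run_ids = run_meta["run_id"].tolist()
    profiles = [
        RunProfile(r.run_id, r.sample_id, r.group, int(r.n_spectra))
        for r in run_meta.itertuples()
    ]
    cluster_counts = attribute_spectra(microbial, mapping, run_ids=run_ids)
    norm = normalize_counts(cluster_counts, profiles)
    mio.write_matrix(OUT / "abundance_cluster.tsv", norm.values)
    h_counts = human_protein_counts(human, run_ids=run_ids)
    if len(h_counts):
        mio.write_matrix(
            OUT / "abundance_human.tsv",
            normalize_counts(h_counts, profiles, "human").values,
        )

    dropped = len(microbial) - int(cluster_counts.to_numpy().sum())
    print(f"microbial PSMs retained: {len(microbial)}; attributed: "
          f"{int(cluster_counts.to_numpy().sum())} "
          f"({dropped} shared across clusters, dropped)")
    print(f"cluster matrix: {cluster_counts.shape[0]} features x "
          f"{cluster_counts.shape[1]} runs; human proteins: {len(h_counts)}")


if __name__ == "__main__":
    main()
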