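#!/usr/bin/env python
"""Build ortholog clusters from the reference proteome and map sample ORFs.

Collapses redundant reference entries, builds the >80%-identity graph, runs
Markov clustering (inflation 1.5), and maps every sample ORF onto the cluster
of its best-matching representative.  Writes clusters.tsv and orf_mapping.tsv
under results/cohort/.
"""

from pathlib import Path

import pandas as pd

from mproteo import io as mio
from mproteo.seqdb import cluster_proteins, map_orfs_to_clusters, remove_redundant

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    refs = mio.read_fasta(OUT / "references.fasta")
    microbial = [p for p in refs if p.source == "reference"]
    nr = remove_redundant(microbial)
    clusters = cluster_proteins(nr)
    mio.write_clusters(OUT / "clusters.tsv", clusters)

    orfs = []
    for fasta in sorted(OUT.glob("orfs_*.fasta")):
        orfs += [p for p in mio.read_fasta(fasta) if p.source == "metagenome"]
    mapping = map_orfs_to_clusters(orfs, clusters, {p.id: p for p in nr})
    pd.DataFrame(
        [(o, c or "") for o, c in sorted(mapping.items())],
        columns=["orf_id", "cluster_id"],
    ).to_csv(OUT / "orf_mapping.tsv", sep="\t", index=False)

    unmapped = sum(1 for c in mapping.values() if c is None)
    sizes = sorted((len(c.members) for c in clusters), reverse=True)
    print(f"{len(microbial)} reference proteins -> {len(nr)} non-redundant "
          f"-> {len(clusters)} clusters (largest: {sizes[:5]})")
    print(f"ORFs mapped: {len(mapping) - unmapped}/{len(mapping)} "
          f"({unmapped} singletons)")


if __name__ == "__main__":
    main()
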