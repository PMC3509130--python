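#!/usr/bin/env python
"""Simulate the default twin cohort and write its artifacts.

Generates the study-shaped cohort (4 healthy, 6 ileal-CD, 2 colonic-CD
subjects, two technical MS runs each; Faecalibacterium and Roseburia depleted
in ICD) and writes reference proteomes, per-sample search databases, PSM
tables, run metadata, module definitions and the ground truth to
results/cohort/.
"""

from pathlib import Path

from mproteo import io as mio
from mproteo.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_reference_proteomes,
    simulate_psm_tables,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=1)
    refs, module_defs = generate_reference_proteomes(spec)
    cohort = generate_cohort(spec, refs, module_defs)
    psms, run_meta = simulate_psm_tables(spec, cohort, refs)

    mio.write_fasta(OUT / "references.fasta", refs)
    for s, db in cohort.sample_dbs.items():
        mio.write_fasta(OUT / f"orfs_{s}.fasta", db)
    mio.write_psms(OUT / "psms.tsv", psms)
    run_meta.to_csv(OUT / "runs.tsv", sep="\t", index=False)
    mio.write_module_definitions(OUT / "modules.tsv", module_defs)
    cohort.truth.abundances.to_csv(
        OUT / "truth_abundances.tsv", sep="\t", index_label="sample_id"
    )

    n_micro = sum(p.source == "reference" for p in refs)
    print(f"reference proteins: {n_micro} microbial + "
          f"{len(refs) - n_micro} human")
    print(f"samples: {len(cohort.samples)}; runs: {len(run_meta)}; "
          f"PSM rows: {len(psms)}")
    print(f"depletion planted in ICD: {spec.depletion}")
    print(f"wrote artifacts to {OUT}")


if __name__ == "__main__":
    main()
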