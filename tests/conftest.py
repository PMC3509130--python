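from pathlib import Path

import pytest

from mproteo.io import read_fasta, read_psms
import pandas as pd

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_proteins():
    return read_fasta(DATA / "toy_proteins.fasta")


@pytest.fixture(scope="session")
def toy_psms():
    return read_psms(DATA / "toy_psms.tsv")


@pytest.fixture(scope="session")
def toy_runs():
    return pd.read_csv(DATA / "toy_runs.tsv", sep="\t")


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared by read-only tests."""
    from mproteo.synthetic import (
        CohortSpec,
        generate_cohort,
        generate_reference_proteomes,
        simulate_psm_tables,
    )

    spec = CohortSpec(
        n_genera=4,
        proteins_per_genus=6,
        groups=(("H", 2), ("ICD", 2)),
        reads_per_sample=120,
        spectra_per_run=(800.0, 0.1),
        seed=42,
    )
    refs, module_definitions = generate_reference_proteomes(spec)
    cohort = generate_cohort(spec, refs, module_definitions)
    psms, run_meta = simulate_psm_tables(spec, cohort, refs)
    return spec, refs, module_definitions, cohort, psms, run_meta
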