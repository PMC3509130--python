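"""Synthetic cohort generator: contracts, determinism, planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mproteo.errors import ConfigurationError, DataError
from mproteo.io import write_fasta
from mproteo.seqdb import remove_redundant
from mproteo.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_reference_proteomes,
    simulate_psm_tables,
)


def small_spec(**kw):
    base = dict(
        n_genera=3,
        proteins_per_genus=10,
        groups=(("H", 2), ("ICD", 2)),
        reads_per_sample=80,
        spectra_per_run=(400.0, 0.1),
        depletion={},
        seed=7,
    )
    base.update(kw)
    return CohortSpec(**base)


def fasta_bytes(proteins, tmp_path, name):
    path = tmp_path / name
    write_fasta(path, proteins)
    return path.read_bytes()


class TestReferenceProteomes:
    def test_counts_forced_by_spec(self):
        spec = small_spec()
        refs, module_defs = generate_reference_proteomes(spec)
        microbial = [p for p in refs if p.source == "reference"]
        assert len(microbial) == 30
        assert len({p.genus for p in microbial}) == 3
        assert all(p.ko and p.cog for p in microbial)
        # every genus owns at least one multi-KO module
        for genus in {p.genus for p in microbial}:
            kos = {p.ko for p in microbial if p.genus == genus}
            assert any(
                len(set(m) & kos) >= 2 for m in module_defs.values()
            )

    def test_determinism_identical_fasta_bytes(self, tmp_path):
        spec = small_spec()
        refs1, _ = generate_reference_proteomes(spec)
        refs2, _ = generate_reference_proteomes(small_spec())
        assert fasta_bytes(refs1, tmp_path, "a.fasta") == fasta_bytes(
            refs2, tmp_path, "b.fasta"
        )

    def test_zero_mutation_strains_collapse(self):
        spec = small_spec(strains_per_genus=2, strain_mutation_rate=0.0)
        refs, _ = generate_reference_proteomes(spec)
        microbial = [p for p in refs if p.source == "reference"]
        assert len(microbial) == 60
        assert len(remove_redundant(microbial)) == 30

    def test_shared_family_peptides_cross_genera(self):
        spec = small_spec(n_shared_families=1)
        refs, _ = generate_reference_proteomes(spec)
        fam = [p for p in refs if p.id.endswith("_p09")]
        from mproteo.synthetic import tryptic_peptides

        pepsets = [
            {pep for pep, *_ in tryptic_peptides(p.sequence)} for p in fam
        ]
        shared = set.intersection(*pepsets)
        assert shared, "conserved tryptic peptide must be shared across genera"

    def test_invalid_field_names_the_field(self):
        with pytest.raises(ConfigurationError, match="decoy_hit_rate"):
            small_spec(decoy_hit_rate=1.5).validate()
        with pytest.raises(ConfigurationError, match="groups"):
            small_spec(groups=(("H", 0),)).validate()
        with pytest.raises(ConfigurationError, match="depletion"):
            small_spec(depletion={"NotAGenus": 0.5}).validate()


class TestCohort:
    def test_abundances_sum_to_one(self):
        spec = small_spec()
        refs, defs = generate_reference_proteomes(spec)
        cohort = generate_cohort(spec, refs, defs)
        assert np.allclose(cohort.truth.abundances.sum(axis=1), 1.0)

    def test_null_depletion_keeps_groups_exchangeable(self):
        spec = small_spec(depletion={"Faecalibacterium": 1.0, "Roseburia": 1.0})
        refs, defs = generate_reference_proteomes(spec)
        cohort = generate_cohort(spec, refs, defs)
        ab = cohort.truth.abundances
        h = ab.loc[["H1", "H2"]].mean()
        d = ab.loc[["ICD1", "ICD2"]].mean()
        # identical marginal distribution; a single draw differs only by noise
        assert np.abs(h - d).max() < 1.0

    def test_depletion_fold_recovered_across_seeds(self):
        ratios = []
        for seed in range(24):
            spec = small_spec(
                depletion={"Roseburia": 0.2},
                groups=(("H", 3), ("ICD", 3)),
                seed=seed,
            )
            refs, defs = generate_reference_proteomes(spec)
            cohort = generate_cohort(spec, refs, defs)
            ab = cohort.truth.abundances["Roseburia"]
            h = ab[[s for s in ab.index if s.startswith("H")]].mean()
            d = ab[[s for s in ab.index if s.startswith("ICD")]].mean()
            ratios.append(d / h)
        # relative abundance ratio ~ 0.2x (renormalization shifts it slightly)
        assert np.mean(ratios) == pytest.approx(0.2, abs=0.07)

    def test_seeded_cohort_reproducible(self):
        spec = small_spec()
        refs, defs = generate_reference_proteomes(spec)
        c1 = generate_cohort(spec, refs, defs)
        c2 = generate_cohort(spec, refs, defs)
        pd.testing.assert_frame_equal(c1.truth.abundances, c2.truth.abundances)
        assert [p.sequence for s in c1.orfs for p in c1.orfs[s]] == [
            p.sequence for s in c2.orfs for p in c2.orfs[s]
        ]


class TestPsmSimulation:
    def test_no_decoys_when_rate_zero(self, small_cohort):
        spec, refs, defs, *_ = small_cohort
        spec0 = dataclasses.replace(spec, decoy_hit_rate=0.0)
        cohort = generate_cohort(spec0, refs, defs)
        psms, _ = simulate_psm_tables(spec0, cohort, refs)
        assert not psms["is_decoy"].any()

    def test_per_run_totals_near_requested_mean(self):
        spec = small_spec(
            groups=(("H", 6), ("ICD", 6)),
            spectra_per_run=(5000.0, 0.1),
            reads_per_sample=60,
        )
        refs, defs = generate_reference_proteomes(spec)
        cohort = generate_cohort(spec, refs, defs)
        _, run_meta = simulate_psm_tables(spec, cohort, refs)
        totals = run_meta["n_spectra"].to_numpy()
        assert len(totals) == 24
        assert totals.mean() == pytest.approx(5000, rel=0.08)
        assert totals.std() == pytest.approx(500, rel=0.5)

    def test_absent_protein_receives_no_psms(self, small_cohort):
        spec, refs, defs, cohort, psms, _ = small_cohort
        for s, db in cohort.sample_dbs.items():
            present = {p.id for p in db}
            sample_psms = psms[(psms["sample_id"] == s) & ~psms["is_decoy"]]
            matched = {
                pid
                for ids in sample_psms["protein_ids"]
                for pid in ids.split(";")
            }
            assert matched <= present

    def test_empty_proteome_rejected(self):
        spec = small_spec()
        refs, defs = generate_reference_proteomes(spec)
        cohort = generate_cohort(spec, refs, defs)
        cohort.sample_dbs = {
            s: [p for p in db if p.source == "human"]
            for s, db in cohort.sample_dbs.items()
        }
        with pytest.raises(DataError):
            simulate_psm_tables(spec, cohort, refs)

    def test_psm_tables_reproducible(self, small_cohort):
        spec, refs, defs, cohort, psms, run_meta = small_cohort
        cohort2 = generate_cohort(spec, refs, defs)
        psms2, run_meta2 = simulate_psm_tables(spec, cohort2, refs)
        pd.testing.assert_frame_equal(psms, psms2)
        pd.testing.assert_frame_equal(run_meta, run_meta2)

    def test_ground_truth_correct_fraction_tracks_rate(self, small_cohort):
        spec, _, _, cohort, psms, _ = small_cohort
        fracs = np.array(list(cohort.truth.correct_psm_fraction.values()))
        assert fracs.mean() == pytest.approx(1 - spec.decoy_hit_rate, abs=0.05)
        n_incorrect = psms["spectrum_id"].isin(
            cohort.truth.incorrect_spectra
        ).sum()
        assert n_incorrect / len(psms) == pytest.approx(
            spec.decoy_hit_rate, abs=0.05
        )
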