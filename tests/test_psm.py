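"""PSM filtering rules, protein-level inference and target-decoy FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import parser as pyt_parser

from mproteo.psm import (
    PSM_COLUMNS,
    FilterPolicy,
    PsmRecord,
    count_miscleavages,
    estimate_fdr,
    filter_psms,
    frame_to_records,
    is_fully_tryptic,
    protein_level_filter,
    records_to_frame,
)
from mproteo.synthetic import tryptic_peptides


def make_psm(**kw):
    base = dict(
        spectrum_id="s1",
        run_id="r1",
        sample_id="x1",
        peptide="LVNDESTAR",
        prev_aa="K",
        next_aa="F",
        charge=2,
        xcorr=3.0,
        deltcn=0.1,
        ppm_error=0.0,
        protein_ids="P1",
        is_decoy=False,
    )
    base.update(kw)
    return base


def frame(*rows):
    out = []
    for i, r in enumerate(rows):
        r = dict(r)
        r.setdefault("spectrum_id", f"s{i}")
        out.append(make_psm(**r))
    df = pd.DataFrame(out)
    df["spectrum_id"] = [f"s{i}" for i in range(len(df))]
    return df[PSM_COLUMNS]


def accepted_ids(df, **kw):
    acc, _ = filter_psms(df, FilterPolicy(), kw.pop("search_kind", "mm"))
    return set(acc["spectrum_id"])


class TestSpectrumFilter:
    @pytest.mark.parametrize(
        "charge, xcorr, ok",
        [
            (1, 1.79, False), (1, 1.80, True),
            (2, 2.49, False), (2, 2.50, True),
            (3, 3.49, False), (3, 3.50, True),
            (4, 3.49, False), (4, 3.50, True),  # >=3+ uses the 3+ threshold
        ],
    )
    def test_xcorr_boundaries_inclusive(self, charge, xcorr, ok):
        df = frame({"charge": charge, "xcorr": xcorr})
        assert (len(accepted_ids(df)) == 1) is ok

    @pytest.mark.parametrize(
        "ppm, ok", [(10.0, True), (10.1, False), (-10.0, True), (-10.1, False)]
    )
    def test_ppm_window_closed(self, ppm, ok):
        df = frame({"ppm_error": ppm})
        assert (len(accepted_ids(df)) == 1) is ok

    def test_ppm_window_not_applied_for_hmrg(self):
        df = frame({"ppm_error": 42.0})
        assert len(accepted_ids(df, search_kind="hmrg")) == 1

    def test_miscleavage_cap(self):
        four = "AKSKTKDKEFGHIR"  # 4 internal K
        five = "AKSKTKDKEKFGHR"  # 5 internal K
        assert count_miscleavages(four) == 4
        assert count_miscleavages(five) == 5
        df = frame({"peptide": four}, {"peptide": five})
        assert accepted_ids(df) == {"s0"}

    @pytest.mark.parametrize(
        "pep, prev, nxt, ok",
        [
            ("LVNDESTAR", "K", "F", True),   # K. ... R. fully tryptic
            ("LVNDESTAR", "A", "F", False),  # N-side not after K/R
            ("LVNDESTAQ", "K", "F", False),  # C-side not K/R
            ("LVNDESTAR", "K", "P", False),  # cleavage before P suppressed
            ("PVNDESTAR", "K", "F", False),  # starts with P after K
            ("LVNDESTAQ", "K", "-", True),   # protein C-terminus
            ("LVNDESTAR", "-", "F", True),   # protein N-terminus
        ],
    )
    def test_fully_tryptic_rules(self, pep, prev, nxt, ok):
        assert is_fully_tryptic(pep, prev, nxt) is ok
        df = frame({"peptide": pep, "prev_aa": prev, "next_aa": nxt})
        assert (len(accepted_ids(df)) == 1) is ok

    def test_missing_flank_rejected_with_warning(self):
        df = frame({"prev_aa": None})
        acc, stats = filter_psms(df)
        assert len(acc) == 0
        assert stats["missing_flank_warnings"] == 1

    @given(
        xcorr_shift=st.floats(0, 1),
        ppm_shrink=st.floats(0, 5),
        misc_cap=st.integers(0, 4),
    )
    @settings(max_examples=30, deadline=None)
    def test_filter_monotone_in_thresholds(self, xcorr_shift, ppm_shrink, misc_cap):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            rows.append(
                {
                    "charge": int(rng.integers(1, 4)),
                    "xcorr": float(rng.uniform(1.0, 5.0)),
                    "ppm_error": float(rng.uniform(-15, 15)),
                    "peptide": "AK" * int(rng.integers(1, 4)) + "LVNDESTAR",
                }
            )
        df = frame(*rows)
        base = FilterPolicy()
        stricter = FilterPolicy(
            xcorr_min_by_charge=tuple(
                (c, t + xcorr_shift) for c, t in base.xcorr_min_by_charge
            ),
            ppm_window=(-10 + ppm_shrink, 10 - ppm_shrink),
            max_miscleavages=misc_cap,
        )
        loose, _ = filter_psms(df, base)
        tight, _ = filter_psms(df, stricter)
        assert set(tight["spectrum_id"]) <= set(loose["spectrum_id"])


class TestProteinLevel:
    def test_hmrg_requires_two_distinct_peptides(self):
        # one peptide seen in many spectra is not enough
        df = frame(
            *[{"peptide": "LVNDESTAR", "protein_ids": "P1"} for _ in range(10)],
            {"peptide": "AAAGWTEK", "protein_ids": "P2"},
            {"peptide": "TTTGWVEK", "protein_ids": "P2"},
        )
        kept, units = protein_level_filter(df, "hmrg")
        assert units == {"P2"}
        assert set(kept["spectrum_id"]) == {"s10", "s11"}

    def test_mm_two_stage_cluster_rule(self):
        # reads O1, O2 map to the same cluster: each contributes one peptide,
        # together they satisfy the >=2-peptides-per-cluster stage
        df = frame(
            {"peptide": "LVNDESTAR", "protein_ids": "O1"},
            {"peptide": "FGQYLMKAR", "protein_ids": "O2"},
            {"peptide": "WWDNESTAK", "protein_ids": "O3"},
        )
        mapping = {"O1": "C1", "O2": "C1", "O3": None}
        kept, units = protein_level_filter(df, "mm", orf_mapping=mapping)
        assert units == {"C1"}
        assert set(kept["spectrum_id"]) == {"s0", "s1"}


class TestFdr:
    def test_hand_counts(self):
        rows = [{"is_decoy": False} for _ in range(98)] + [
            {"is_decoy": True} for _ in range(2)
        ]
        df = frame(*rows)
        assert estimate_fdr(df)["pooled"] == pytest.approx(2 * 2 / 100)

    def test_no_decoys_is_zero(self):
        df = frame(*[{"is_decoy": False} for _ in range(5)])
        assert estimate_fdr(df)["pooled"] == 0.0

    def test_all_decoys_capped_at_one(self):
        df = frame(*[{"is_decoy": True} for _ in range(4)])
        assert estimate_fdr(df)["pooled"] == 1.0

    def test_empty_is_nan(self):
        df = pd.DataFrame(columns=PSM_COLUMNS)
        assert np.isnan(estimate_fdr(df)["pooled"])

    def test_alternative_estimator(self):
        rows = [{"is_decoy": False} for _ in range(98)] + [
            {"is_decoy": True} for _ in range(2)
        ]
        df = frame(*rows)
        assert estimate_fdr(df, estimator="dt")["pooled"] == pytest.approx(2 / 98)


class TestDigestion:
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=10, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_matches_pyteomics_cleave(self, seq):
        ours = {
            p
            for p, _, _, _ in tryptic_peptides(
                seq, max_missed=3, min_len=1, max_len=10_000
            )
        }
        theirs = pyt_parser.cleave(
            seq, pyt_parser.expasy_rules["trypsin"], missed_cleavages=3
        )
        assert ours == set(theirs)

    def test_flanks_and_miscleavages_consistent(self):
        seq = "MAGWTEKLVNDESTARFGQYLMK"
        for pep, prev, nxt, miss in tryptic_peptides(seq, min_len=1):
            assert is_fully_tryptic(pep, prev, nxt)
            assert count_miscleavages(pep) == miss


def test_record_frame_roundtrip():
    rec = PsmRecord(
        spectrum_id="s1",
        run_id="r1",
        sample_id="x1",
        peptide="LVNDESTAR",
        prev_aa="K",
        next_aa="F",
        charge=2,
        xcorr=2.5,
        deltcn=0.1,
        ppm_error=1.0,
        protein_ids=frozenset({"P1", "P2"}),
    )
    (back,) = frame_to_records(records_to_frame([rec]))
    assert back == rec
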