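"""PSM acceptance filtering and target-decoy FDR estimation.

Peptide-spectrum matches arrive as a table from a database search (the search
scores — XCorr, deltCN, precursor ppm error — are consumed, not computed).
Acceptance follows the classic DTASelect-style rules: fully tryptic peptides
only, a per-charge XCorr floor (1.8 / 2.5 / 3.5 for 1+/2+/3+, boundary
inclusive), a deltCN floor of 0.0, at most 4 missed cleavages, and — for
matched-metagenome (MM) searches only — a closed precursor-mass window of
−10 ≤ ppm ≤ +10 applied post-search.  Protein-level inference then requires
≥2 distinct peptides per protein (HMRG) or the two-stage ≥1-peptide-per-read
followed by ≥2-peptides-per-cluster rule (MM).

The empirical FDR of an accepted set from a concatenated target–decoy search
is estimated as 2·D/(T+D): an incorrect match is equally likely to land in
either database half, so the decoy count D stands in for an equal number of
hidden incorrect target matches.  D/T is available as the alternative
(target-list) estimator.

Bulk operations work on pandas DataFrames with the PSM-table schema
(:data:`PSM_COLUMNS`); a frozen :class:`PsmRecord` mirrors one row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

#: Canonical PSM table schema (tab-delimited on disk).
PSM_COLUMNS = [
    "spectrum_id",
    "run_id",
    "sample_id",
    "peptide",
    "prev_aa",
    "next_aa",
    "charge",
    "xcorr",
    "deltcn",
    "ppm_error",
    "protein_ids",  # semicolon-separated
    "is_decoy",
]

TERMINUS = "-"  # flanking-residue marker for a protein terminus

_MISCLEAVAGE_RE = re.compile(r"[KR](?=[^P])")


@dataclass(frozen=True)
class PsmRecord:
    spectrum_id: str
    run_id: str
    sample_id: str
    peptide: str
    prev_aa: str
    next_aa: str
    charge: int
    xcorr: float
    deltcn: float
    ppm_error: float
    protein_ids: frozenset = field(default_factory=frozenset)
    is_decoy: bool = False

    def __post_init__(self):
        if self.charge < 1:
            raise DataError(f"spectrum {self.spectrum_id!r}: charge < 1")


@dataclass(frozen=True)
class FilterPolicy:
    """Acceptance thresholds; defaults are the study values."""

    xcorr_min_by_charge: tuple = ((1, 1.8), (2, 2.5), (3, 3.5))
    deltcn_min: float = 0.0
    max_miscleavages: int = 4
    require_fully_tryptic: bool = True
    ppm_window: tuple = (-10.0, 10.0)
    min_peptides_per_protein: int = 2
    min_peptide_length: int = 6

    def __post_init__(self):
        lo, hi = self.ppm_window
        if not lo <= hi:
            raise ConfigurationError("ppm_window: bounds out of order")
        for c, t in self.xcorr_min_by_charge:
            if not np.isfinite(t):
                raise ConfigurationError("xcorr_min_by_charge: non-finite")

    def xcorr_min(self, charge: int) -> float:
        d = dict(self.xcorr_min_by_charge)
        if charge in d:
            return d[charge]
        # charge states beyond the table use the highest-charge threshold
        return d[max(d)]


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                **{k: getattr(r, k) for k in PSM_COLUMNS if k != "protein_ids"},
                "protein_ids": ";".join(sorted(r.protein_ids)),
            }
        )
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PsmRecord(
                spectrum_id=row.spectrum_id,
                run_id=row.run_id,
                sample_id=row.sample_id,
                peptide=row.peptide,
                prev_aa=row.prev_aa,
                next_aa=row.next_aa,
                charge=int(row.charge),
                xcorr=float(row.xcorr),
                deltcn=float(row.deltcn),
                ppm_error=float(row.ppm_error),
                protein_ids=frozenset(
                    p for p in str(row.protein_ids).split(";") if p
                ),
                is_decoy=bool(row.is_decoy),
            )
        )
    return out


def count_miscleavages(peptide: str) -> int:
    """Internal K/R not followed by P (trypsin misses); the C-terminal residue
    is a cleavage product, not a miss."""
    return len(_MISCLEAVAGE_RE.findall(peptide))


def is_fully_tryptic(peptide: str, prev_aa: str, next_aa: str) -> bool:
    """Tryptic at both termini: N-side preceded by K/R (and the peptide does
    not start with P, which would suppress that cleavage) or the protein
    N-terminus; C-side ends in K/R with the next residue not P, or the protein
    C-terminus."""
    if not peptide or not prev_aa or not next_aa:
        return False
    n_ok = prev_aa == TERMINUS or (prev_aa in "KR" and peptide[0] != "P")
    c_ok = next_aa == TERMINUS or (peptide[-1] in "KR" and next_aa != "P")
    return n_ok and c_ok


def filter_psms(
    psms: pd.DataFrame,
    policy: FilterPolicy = FilterPolicy(),
    search_kind: str = "mm",
):
    """Spectrum-level acceptance filter.

    Returns ``(accepted, stats)`` where ``stats`` counts rejections by reason
    (a PSM is tallied under the first failing rule) plus missing-flank
    warnings.
    """
    if search_kind not in ("mm", "hmrg"):
        raise ConfigurationError(f"search_kind: unknown value {search_kind!r}")
    df = psms.copy()
    n = len(df)
    stats = {"input": n}
    if n == 0:
        stats.update(accepted=0)
        return df, stats

    pep = df["peptide"].astype(str)
    prev = df["prev_aa"].fillna("").astype(str)
    nxt = df["next_aa"].fillna("").astype(str)

    missing_flank = (prev == "") | (nxt == "")
    n_ok = (prev == TERMINUS) | (prev.isin(list("KR")) & (pep.str[0] != "P"))
    c_ok = (nxt == TERMINUS) | (pep.str[-1].isin(list("KR")) & (nxt != "P"))
    tryptic = n_ok & c_ok & ~missing_flank
    if not policy.require_fully_tryptic:
        tryptic = ~missing_flank

    misc = pep.str.count(_MISCLEAVAGE_RE.pattern)
    misc_ok = misc <= policy.max_miscleavages

    thr = df["charge"].astype(int).map(policy.xcorr_min)
    xcorr_ok = df["xcorr"] >= thr  # "at least": boundary inclusive
    deltcn_ok = df["deltcn"] >= policy.deltcn_min
    len_ok = pep.str.len() >= policy.min_peptide_length

    if search_kind == "mm":
        lo, hi = policy.ppm_window
        ppm_ok = (df["ppm_error"] >= lo) & (df["ppm_error"] <= hi)
    else:
        ppm_ok = pd.Series(True, index=df.index)

    keep = tryptic & misc_ok & xcorr_ok & deltcn_ok & len_ok & ppm_ok
    stats.update(
        missing_flank_warnings=int(missing_flank.sum()),
        rejected_tryptic=int((~tryptic).sum()),
        rejected_miscleavage=int((tryptic & ~misc_ok).sum()),
        rejected_xcorr=int((tryptic & misc_ok & ~xcorr_ok).sum()),
        rejected_deltcn=int((tryptic & misc_ok & xcorr_ok & ~deltcn_ok).sum()),
        rejected_length=int(
            (tryptic & misc_ok & xcorr_ok & deltcn_ok & ~len_ok).sum()
        ),
        rejected_ppm=int(
            (tryptic & misc_ok & xcorr_ok & deltcn_ok & len_ok & ~ppm_ok).sum()
        ),
        accepted=int(keep.sum()),
    )
    return df[keep].copy(), stats


def _exploded(df: pd.DataFrame) -> pd.DataFrame:
    out = df[["spectrum_id", "peptide", "protein_ids"]].copy()
    out["protein_id"] = out["protein_ids"].astype(str).str.split(";")
    return out.explode("protein_id")


def protein_level_filter(
    psms: pd.DataFrame,
    search_kind: str = "mm",
    policy: FilterPolicy = FilterPolicy(),
    orf_mapping: dict | None = None,
):
    """Protein/cluster-level inference on spectrum-filtered PSMs.

    HMRG: a protein is retained with >= ``min_peptides_per_protein`` distinct
    peptide sequences.  MM: every read-level identification survives stage 1
    (>=1 peptide); stage 2 maps reads to clusters (``orf_mapping``; unmapped
    reads count as their own singletons) and keeps clusters with >=2 distinct
    peptides.  PSMs all of whose matched proteins were dropped are discarded.

    Returns ``(retained_psms, kept_ids)`` where ``kept_ids`` are protein ids
    (HMRG) or cluster/singleton ids (MM).
    """
    if len(psms) == 0:
        return psms.copy(), set()
    ex = _exploded(psms)
    if search_kind == "hmrg":
        ex["unit"] = ex["protein_id"]
    elif search_kind == "mm":
        mapping = orf_mapping or {}
        ex["unit"] = ex["protein_id"].map(
            lambda p: mapping.get(p) or f"singleton:{p}"
        )
    else:
        raise ConfigurationError(f"search_kind: unknown value {search_kind!r}")

    pep_per_unit = ex.groupby("unit")["peptide"].nunique()
    kept_units = set(
        pep_per_unit[pep_per_unit >= policy.min_peptides_per_protein].index
    )
    ex["kept"] = ex["unit"].isin(kept_units)
    spectra_kept = ex.groupby("spectrum_id")["kept"].any()
    retained = psms[psms["spectrum_id"].map(spectra_kept).fillna(False)].copy()
    return retained, kept_units


def estimate_fdr(psms: pd.DataFrame, estimator: str = "2d") -> dict:
    """Empirical FDR of an accepted PSM set from a concatenated target–decoy
    search, pooled and per run.

    ``2d``: 2·D/(T+D), capped at 1 — the expected incorrect fraction among all
    accepted PSMs.  ``dt``: D/T, the target-list estimator.  Runs with no
    accepted PSMs report NaN.
    """
    if estimator not in ("2d", "dt"):
        raise ConfigurationError(f"estimator: unknown value {estimator!r}")

    def est(d, t):
        if t + d == 0:
            return float("nan")
        if estimator == "2d":
            return min(1.0, 2.0 * d / (t + d))
        return min(1.0, d / t) if t else 1.0

    decoy = psms["is_decoy"].astype(bool)
    pooled = est(int(decoy.sum()), int((~decoy).sum()))
    per_run = {}
    for run_id, grp in psms.groupby("run_id"):
        d = int(grp["is_decoy"].astype(bool).sum())
        per_run[run_id] = est(d, len(grp) - d)
    return {"pooled": pooled, "per_run": per_run}
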