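"""Differential-abundance decision procedure.

For each comparison of two phenotype groups the pipeline (1) keeps only
features with more than five spectral counts in at least four of the pooled
runs, (2) computes a two-sided Wilcoxon rank-sum p-value per feature (exact
when the pooled size is small and tie-free, tie-corrected normal approximation
otherwise), (3) converts p-values to Storey q-values with pi0 estimated at
lambda = 0.5, and (4) flags a feature significant when q < 0.05 *and* the two
group medians of normalized counts differ by more than 5.  The same procedure
serves microbial clusters, COG/KO/genus aggregates and human proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .quant import AbundanceMatrix

EXACT_MAX_POOLED = 12


@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    feature_kind: str
    median_a: float
    median_b: float
    median_diff: float  # median_a - median_b
    p: float
    q: float
    significant: bool
    direction: str  # "higher-in-A" | "higher-in-B" | "none"


def prefilter_features(
    matrix: AbundanceMatrix,
    runs_a,
    runs_b,
    min_count: float = 5.0,
    min_runs: int = 4,
    per_group: bool = False,
) -> list:
    """Eligibility gate: count strictly greater than ``min_count`` in at least
    ``min_runs`` of the runs under comparison (pooled across both groups by
    default)."""
    for name, runs in (("runs_a", runs_a), ("runs_b", runs_b)):
        if len(runs) < 2:
            raise ConfigurationError(f"{name}: need >= 2 runs per group")
    df = matrix.values
    if per_group:
        ok = ((df[list(runs_a)] > min_count).sum(axis=1) >= min_runs) & (
            (df[list(runs_b)] > min_count).sum(axis=1) >= min_runs
        )
    else:
        pooled = df[list(runs_a) + list(runs_b)]
        ok = (pooled > min_count).sum(axis=1) >= min_runs
    return list(df.index[ok])


def wilcoxon_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when len(x)+len(y) <= 12 with no ties; mid-rank
    normal approximation with tie correction otherwise.  Identical values in
    both groups give p = 1.0.  Symmetric in (x, y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("wilcoxon_p: need >= 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= EXACT_MAX_POOLED and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def storey_q(pvalues, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0_hat = #{p > lambda} / ((1 - lambda) * m), clamped to [1/m, 1] (pass
    ``pi0`` to override, e.g. 1.0 for the Benjamini-Hochberg limit);
    q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("pvalues: outside [0, 1]")
    if pi0 is None:
        pi0 = np.count_nonzero(p > lam) / ((1.0 - lam) * m)
        pi0 = min(1.0, max(1.0 / m, pi0))
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_differential(
    matrix: AbundanceMatrix,
    runs_a,
    runs_b,
    alpha_q: float = 0.05,
    min_median_diff: float = 5.0,
    prefilter_min_count: float = 5.0,
    prefilter_min_runs: int = 4,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Full decision procedure for one two-group comparison.

    Returns one row per eligible feature (feature_id, medians, p, q,
    significant, direction), sorted by q then feature_id.  The frame carries
    ``attrs['low_power'] = True`` when fewer than two features were eligible.
    """
    eligible = prefilter_features(
        matrix, runs_a, runs_b, prefilter_min_count, prefilter_min_runs
    )
    df = matrix.values.loc[eligible]
    a = df[list(runs_a)].to_numpy(dtype=float)
    b = df[list(runs_b)].to_numpy(dtype=float)
    rows = []
    pvals = [wilcoxon_p(a[i], b[i]) for i in range(len(df))]
    qvals = storey_q(pvals, pi0=pi0) if pvals else np.array([])
    for i, fid in enumerate(df.index):
        med_a = float(np.median(a[i]))
        med_b = float(np.median(b[i]))
        diff = med_a - med_b
        sig = bool(qvals[i] < alpha_q and abs(diff) > min_median_diff)
        rows.append(
            {
                "feature_id": fid,
                "feature_kind": matrix.feature_kind,
                "median_a": med_a,
                "median_b": med_b,
                "median_diff": diff,
                "p": pvals[i],
                "q": float(qvals[i]),
                "significant": sig,
                "direction": (
                    "higher-in-A" if diff > 0 else "higher-in-B" if diff < 0 else "none"
                ),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "feature_kind",
            "median_a",
            "median_b",
            "median_diff",
            "p",
            "q",
            "significant",
            "direction",
        ],
    )
    if len(out):
        out = out.sort_values(["q", "feature_id"], kind="mergesort").reset_index(
            drop=True
        )
    out.attrs["low_power"] = len(out) < 2
    return out
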