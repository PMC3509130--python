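"""KEGG-module level analysis.

Modules (curated KO sets forming metabolic units) are analysed only when more
than 30% of their member KOs are detected.  Module abundance is the sum of its
member KOs' normalized spectral counts per run; differential modules are
called by Wilcoxon rank-sum with Benjamini-Hochberg correction (significant at
adjusted p < 0.10 and |median difference| > 5, two-sided).  The deviation
analysis asks whether a (taxon, module) abundance shift between groups exceeds
what the taxon's own abundance shift predicts: observed log2 fold changes are
regressed on the taxon-level expected log2 fold changes by OLS, and points
outside the prediction interval of the fit are flagged as deviating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .quant import AbundanceMatrix
from .stats import wilcoxon_p

LOG2_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ModuleRecord:
    module_id: str
    member_kos: frozenset
    detected_kos: frozenset
    coverage: float

    def __post_init__(self):
        if not self.detected_kos <= self.member_kos:
            raise DataError(f"module {self.module_id!r}: detected not in members")


@dataclass(frozen=True)
class DeviationResult:
    taxon: str
    module_id: str
    observed_lfc: float
    expected_lfc: float
    fitted_value: float
    interval_low: float
    interval_high: float
    deviating: bool
    significant: bool


def module_coverage(
    detected_kos, module_definitions: dict, min_coverage: float = 0.30
):
    """Coverage of each module by the detected KO set.

    Returns ``(records, passing_ids)``; a module passes with coverage strictly
    greater than ``min_coverage``.
    """
    detected = set(detected_kos)
    records = []
    passing = []
    for module_id in sorted(module_definitions):
        members = set(module_definitions[module_id])
        if not members:
            raise ConfigurationError(f"module {module_id!r}: empty member set")
        cov = len(detected & members) / len(members)
        records.append(
            ModuleRecord(
                module_id=module_id,
                member_kos=frozenset(members),
                detected_kos=frozenset(detected & members),
                coverage=cov,
            )
        )
        if cov > min_coverage:
            passing.append(module_id)
    return records, passing


def module_abundance(
    ko_matrix: AbundanceMatrix, module_definitions: dict, module_ids=None
) -> AbundanceMatrix:
    """Module abundance = sum of member-KO counts per run."""
    ids = sorted(module_definitions) if module_ids is None else list(module_ids)
    rows = {}
    for mid in ids:
        members = [k for k in module_definitions[mid] if k in ko_matrix.values.index]
        rows[mid] = (
            ko_matrix.values.loc[members].sum(axis=0)
            if members
            else pd.Series(0.0, index=ko_matrix.values.columns)
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "feature_id"
    return AbundanceMatrix(values=df, feature_kind="module", normalized=ko_matrix.normalized)


def differential_modules(
    matrix: AbundanceMatrix,
    runs_a,
    runs_b,
    alpha: float = 0.10,
    min_median_diff: float = 5.0,
) -> pd.DataFrame:
    """Wilcoxon + Benjamini-Hochberg module calls (two-sided)."""
    for name, runs in (("runs_a", runs_a), ("runs_b", runs_b)):
        if len(runs) < 2:
            raise ConfigurationError(f"{name}: need >= 2 runs per group")
    df = matrix.values
    a = df[list(runs_a)].to_numpy(float)
    b = df[list(runs_b)].to_numpy(float)
    pvals = [wilcoxon_p(a[i], b[i]) for i in range(len(df))]
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
    else:
        adj = np.array([])
    rows = []
    for i, mid in enumerate(df.index):
        med_a, med_b = float(np.median(a[i])), float(np.median(b[i]))
        diff = med_a - med_b
        rows.append(
            {
                "feature_id": mid,
                "feature_kind": "module",
                "median_a": med_a,
                "median_b": med_b,
                "median_diff": diff,
                "p": pvals[i],
                "q": float(adj[i]),
                "significant": bool(adj[i] < alpha and abs(diff) > min_median_diff),
                "direction": (
                    "higher-in-A" if diff > 0 else "higher-in-B" if diff < 0 else "none"
                ),
            }
        )
    return pd.DataFrame(
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


def median_log2_fold_change(values_b, values_a, pseudocount: float = LOG2_PSEUDOCOUNT):
    """log2((median(B)+c)/(median(A)+c)) — group B relative to group A."""
    return float(
        np.log2(
            (np.median(np.asarray(values_b, float)) + pseudocount)
            / (np.median(np.asarray(values_a, float)) + pseudocount)
        )
    )


def taxon_module_deviation(
    points: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Flag (taxon, module) shifts outside the prediction interval of the
    observed-vs-expected OLS fit.

    ``points`` needs columns taxon, module_id, observed_lfc, expected_lfc and
    optionally significant (module-level test flag, carried through).  Returns
    the input plus fitted_value, interval_low/high, deviating.
    """
    if len(points) < 3:
        raise ConfigurationError("points: need >= 3 (taxon, module) points")
    x = points["expected_lfc"].to_numpy(float)
    y = points["observed_lfc"].to_numpy(float)
    if np.ptp(x) == 0:
        raise DataError("degenerate fit: all expected_lfc equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    pred = model.get_prediction(sm.add_constant(x)).summary_frame(alpha=1 - level)
    out = points.copy().reset_index(drop=True)
    out["fitted_value"] = pred["mean"].to_numpy()
    out["interval_low"] = pred["obs_ci_lower"].to_numpy()
    out["interval_high"] = pred["obs_ci_upper"].to_numpy()
    out["deviating"] = (out["observed_lfc"] < out["interval_low"]) | (
        out["observed_lfc"] > out["interval_high"]
    )
    if "significant" not in out.columns:
        out["significant"] = False
    return out
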