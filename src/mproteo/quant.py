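"""Spectral-count attribution and cross-run normalization.

Label-free quantification by spectral counting: a microbial spectrum is
attributed to an ortholog cluster only when *every* protein its peptide
matches belongs to that one cluster (peptides spanning two or more clusters
contribute nothing — the unique-attribution rule).  Human proteins are
quantified the other way, with shared peptides counting toward every matching
protein.  Counts are made comparable across MS runs by the scaling factor
alpha_i = N / n_i, where n_i is run i's total acquired MS/MS spectra and N is
the cohort mean of the n_i; after scaling, each run's all-feature total equals
N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class RunProfile:
    run_id: str
    sample_id: str
    group: str
    n_spectra: int  # total acquired MS/MS in the run (n_i)

    def __post_init__(self):
        if self.n_spectra <= 0:
            raise DataError(f"run {self.run_id!r}: n_spectra must be > 0")


@dataclass
class AbundanceMatrix:
    """Features x runs matrix of (normalized) spectral counts."""

    values: pd.DataFrame  # index = feature ids, columns = run ids
    feature_kind: str = "cluster"
    normalized: bool = False


def scaling_factors(profiles) -> pd.Series:
    """alpha_i = N / n_i with N the mean total-MS/MS count over the runs."""
    if not profiles:
        raise ConfigurationError("profiles: empty run set")
    n = pd.Series({p.run_id: p.n_spectra for p in profiles}, dtype=float)
    return n.mean() / n


def _resolve_units(psms: pd.DataFrame, mapping: dict, unmapped_as_singleton=True):
    ex = psms[["spectrum_id", "run_id", "protein_ids"]].copy()
    ex["protein_id"] = ex["protein_ids"].astype(str).str.split(";")
    ex = ex.explode("protein_id")
    unknown = sorted(
        set(ex["protein_id"]) - set(mapping) if not unmapped_as_singleton else ()
    )
    if unknown:
        raise DataError(f"PSMs reference unknown protein ids: {unknown[:10]}")
    if unmapped_as_singleton:
        ex["unit"] = ex["protein_id"].map(
            lambda p: mapping.get(p) or f"singleton:{p}"
        )
    else:
        ex["unit"] = ex["protein_id"].map(mapping)
    return ex


def attribute_spectra(
    psms: pd.DataFrame,
    orf_mapping: dict,
    run_ids=None,
    strict_ids: bool = False,
) -> pd.DataFrame:
    """Unique-attribution raw counts per (cluster, run).

    ``orf_mapping`` maps protein/ORF id -> cluster id (``None`` for unmapped
    ORFs, which act as their own singleton clusters).  A spectrum whose
    matched proteins resolve to more than one cluster is discarded.  With
    ``strict_ids`` an unknown protein id raises; otherwise ids absent from the
    mapping are treated as unmapped singletons.
    """
    if len(psms) == 0:
        return pd.DataFrame(columns=list(run_ids or []), dtype=int)
    ex = _resolve_units(psms, orf_mapping, unmapped_as_singleton=not strict_ids)
    per_spec = ex.groupby(["spectrum_id", "run_id"])["unit"].agg(["nunique", "first"])
    unique = per_spec[per_spec["nunique"] == 1].reset_index()
    counts = (
        unique.groupby(["first", "run_id"])
        .size()
        .unstack(fill_value=0)
        .rename_axis(index="feature_id", columns=None)
    )
    if run_ids is not None:
        counts = counts.reindex(columns=list(run_ids), fill_value=0)
    return counts.astype(int)


def human_protein_counts(psms: pd.DataFrame, run_ids=None) -> pd.DataFrame:
    """Raw counts per (human protein, run): shared peptides count toward every
    matching protein, unique peptides toward their single protein."""
    if len(psms) == 0:
        return pd.DataFrame(columns=list(run_ids or []), dtype=int)
    ex = psms[["spectrum_id", "run_id", "protein_ids"]].copy()
    ex["protein_id"] = ex["protein_ids"].astype(str).str.split(";")
    ex = ex.explode("protein_id")
    counts = (
        ex.groupby(["protein_id", "run_id"])
        .size()
        .unstack(fill_value=0)
        .rename_axis(index="feature_id", columns=None)
    )
    if run_ids is not None:
        counts = counts.reindex(columns=list(run_ids), fill_value=0)
    return counts.astype(int)


def normalize_counts(
    raw: pd.DataFrame, profiles, feature_kind: str = "cluster"
) -> AbundanceMatrix:
    """Multiply each run's counts by its scaling factor alpha_i = N/n_i."""
    alpha = scaling_factors(profiles)
    missing = [c for c in raw.columns if c not in alpha.index]
    if missing:
        raise ConfigurationError(f"profiles: runs missing n_spectra: {missing}")
    values = raw.astype(float).mul(alpha.reindex(raw.columns), axis=1)
    return AbundanceMatrix(values=values, feature_kind=feature_kind, normalized=True)


def aggregate_by(matrix: AbundanceMatrix, feature_map: dict, kind: str) -> AbundanceMatrix:
    """Sum features into coarser groups (cluster -> COG / KO / genus views).

    Features absent from ``feature_map`` are dropped.  Summation commutes with
    per-run normalization, so views may be built before or after scaling.
    """
    df = matrix.values
    groups = df.index.map(lambda f: feature_map.get(f))
    keep = groups.notna() if hasattr(groups, "notna") else np.array(
        [g is not None for g in groups]
    )
    agg = df[keep].groupby(np.asarray(groups)[keep]).sum()
    agg.index.name = "feature_id"
    return AbundanceMatrix(
        values=agg, feature_kind=kind, normalized=matrix.normalized
    )
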