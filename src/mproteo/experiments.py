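"""Calibration and recovery experiments over synthetic cohorts.

These are the package's headline computations: each function builds cohorts
from a frozen scenario, runs the real pipeline end to end, and scores the
result against the generator's ground truth.  Problem sizes are desk-scale
(small proteomes, a few thousand spectra per run) so a full experiment runs in
minutes; docs/methods.md records the scenario definitions.

Every function takes a ``base_seed``; cohort seeds are derived from it so the
whole battery is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, run_pipeline
from .psm import estimate_fdr, filter_psms
from .seqdb import IdentityEdge, mcl_cluster
from .synthetic import CohortSpec
from .modules import taxon_module_deviation

_SEED_MOD = 2**31 - 1


def _seed(base_seed: int, stream: int, i: int) -> int:
    return (base_seed * 1_000_003 + stream * 10_007 + i) % _SEED_MOD


# ---------------------------------------------------------------------------
# scenario definitions (study conditions; see docs/methods.md)

def recovery_spec(seed: int) -> CohortSpec:
    """4 healthy vs 6 disease runs; 10 clusters planted at 5-fold depletion
    against a flat background so every cluster's baseline sits near 20
    spectral counts per run."""
    genera = CohortSpec(n_genera=6).genera()
    planted = tuple((f"{genera[i % 6]}_p{i // 6:02d}", 0.2) for i in range(10))
    return CohortSpec(
        n_genera=6,
        proteins_per_genus=8,
        groups=(("H", 4), ("ICD", 6)),
        runs_per_subject=1,
        reads_per_sample=250,
        spectra_per_run=(2400.0, 0.08),
        depletion={},
        genus_sigma=0.0,
        subject_sigma=0.25,
        detectability_sigma=0.0,
        planted_diff_clusters=planted,
        seed=seed,
    )


def null_spec(seed: int) -> CohortSpec:
    """The recovery scenario with every planted effect at 1.0 (global null)."""
    import dataclasses

    return dataclasses.replace(
        recovery_spec(seed), planted_diff_clusters=(), depletion={}
    )


def fdr_spec(seed: int) -> CohortSpec:
    """Two deep runs (~10,000 PSMs each) of one subject with 20% of PSMs
    drawn from the random-match model."""
    return CohortSpec(
        n_genera=6,
        proteins_per_genus=8,
        groups=(("H", 1),),
        runs_per_subject=2,
        reads_per_sample=250,
        spectra_per_run=(16000.0, 0.05),
        depletion={},
        affected_groups=(),
        decoy_hit_rate=0.20,
        genus_sigma=0.0,
        detectability_sigma=0.0,
        seed=seed,
    )


def deviation_spec(seed: int) -> CohortSpec:
    """Genus-level shifts in the disease group spreading the expected-shift
    axis, plus one module planted 4-fold below its host genus's shift."""
    return CohortSpec(
        n_genera=6,
        proteins_per_genus=12,
        n_shared_families=0,
        groups=(("H", 4), ("ICD", 6)),
        runs_per_subject=1,
        reads_per_sample=250,
        spectra_per_run=(2600.0, 0.08),
        depletion={
            "Faecalibacterium": 0.4,
            "Roseburia": 0.7,
            "Coprococcus": 1.6,
        },
        planted_module_effects=(
            ("Bacteroides", "MD_Bacteroides_01", 0.25),
        ),
        genus_sigma=0.0,
        subject_sigma=0.2,
        detectability_sigma=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# experiments

def _cluster_of(result):
    return {m: c.cluster_id for c in result.clusters for m in c.members}


def run_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Planted-cluster recovery: sensitivity and false-discovery proportion
    of the q<0.05 & |median diff|>5 calls, per cohort."""
    sens, fdp = [], []
    for i in range(n_seeds):
        spec = recovery_spec(_seed(base_seed, 1, i))
        result = run_pipeline(PipelineConfig(cohort=spec, with_taxonomy=False))
        c_of = _cluster_of(result)
        true_clusters = {
            c_of[p] for p in result.cohort.truth.planted_clusters
        }
        res = result.differential[("H", "ICD")]["cluster"]
        flagged = set(res.loc[res["significant"], "feature_id"])
        tp = len(flagged & true_clusters)
        sens.append(tp / len(true_clusters))
        fdp.append((len(flagged) - tp) / max(1, len(flagged)))
    return {
        "sensitivity": sens,
        "fdp": fdp,
        "median_sensitivity": float(np.median(sens)),
        "median_fdp": float(np.median(fdp)),
        "n_seeds": n_seeds,
    }


def run_null_calibration(n_cohorts: int = 50, base_seed: int = 1) -> dict:
    """Global-null cohorts: fraction of eligible features flagged
    significant."""
    fractions = []
    for i in range(n_cohorts):
        spec = null_spec(_seed(base_seed, 2, i))
        result = run_pipeline(PipelineConfig(cohort=spec, with_taxonomy=False))
        res = result.differential[("H", "ICD")]["cluster"]
        fractions.append(
            float(res["significant"].mean()) if len(res) else 0.0
        )
    fractions = np.asarray(fractions)
    return {
        "flagged_fraction_mean": float(fractions.mean()),
        "flagged_fraction_stderr": float(
            fractions.std(ddof=1) / np.sqrt(len(fractions))
        ),
        "n_cohorts": n_cohorts,
    }


def run_fdr_calibration(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Concatenated target-decoy estimator vs the known random-match fraction
    among accepted PSMs, after full spectrum-level filtering."""
    est, truth = [], []
    for i in range(n_seeds):
        spec = fdr_spec(_seed(base_seed, 3, i))
        from .synthetic import (
            generate_cohort,
            generate_reference_proteomes,
            simulate_psm_tables,
        )

        refs, mods = generate_reference_proteomes(spec)
        cohort = generate_cohort(spec, refs, mods)
        psms, _meta = simulate_psm_tables(spec, cohort, refs)
        accepted, _stats = filter_psms(psms)
        est.append(estimate_fdr(accepted)["pooled"])
        truth.append(
            float(
                accepted["spectrum_id"]
                .isin(cohort.truth.incorrect_spectra)
                .mean()
            )
        )
    mean_est, mean_truth = float(np.mean(est)), float(np.mean(truth))
    return {
        "estimated_fdr": mean_est,
        "true_incorrect_fraction": mean_truth,
        "relative_error": (mean_est - mean_truth) / mean_truth
        if mean_truth
        else float("nan"),
        "n_seeds": n_seeds,
    }


def run_deviation_experiment(n_cohorts: int = 50, base_seed: int = 1) -> dict:
    """How often the planted (genus, module) effect lands outside the
    prediction interval of the observed-vs-expected fit."""
    flagged = []
    null_outside = []
    for i in range(n_cohorts):
        spec = deviation_spec(_seed(base_seed, 4, i))
        result = run_pipeline(PipelineConfig(cohort=spec))
        dev = result.deviation[("H", "ICD")]
        if not len(dev):
            flagged.append(False)
            continue
        planted = {(g, m) for g, m, _ in result.cohort.truth.deviating_modules}
        mask = [
            (t, m) in planted
            for t, m in zip(dev["taxon"], dev["module_id"])
        ]
        mask = np.asarray(mask)
        flagged.append(bool(dev.loc[mask, "deviating"].all()) if mask.any() else False)
        if (~mask).any():
            null_outside.append(float(dev.loc[~mask, "deviating"].mean()))
    return {
        "planted_flag_rate": float(np.mean(flagged)),
        "null_outside_rate": float(np.mean(null_outside)) if null_outside else 0.0,
        "n_cohorts": n_cohorts,
    }


def run_interval_calibration(
    n_points: int = 40, n_reps: int = 400, level: float = 0.95, base_seed: int = 1
) -> dict:
    """Prediction-interval calibration on synthetic linear data with Gaussian
    residuals: the outside rate should match 1-level."""
    rng = np.random.default_rng(_seed(base_seed, 5, 0))
    outside = []
    for _ in range(n_reps):
        x = rng.uniform(-2, 2, n_points)
        y = 0.5 + 1.2 * x + rng.normal(0, 0.4, n_points)
        points = pd.DataFrame(
            {
                "taxon": [f"t{i}" for i in range(n_points)],
                "module_id": [f"m{i}" for i in range(n_points)],
                "observed_lfc": y,
                "expected_lfc": x,
            }
        )
        dev = taxon_module_deviation(points, level=level)
        outside.append(float(dev["deviating"].mean()))
    return {
        "outside_rate": float(np.mean(outside)),
        "nominal": 1.0 - level,
        "n_points": n_points,
        "n_reps": n_reps,
    }


def run_mcl_component_check(n_graphs: int = 100, base_seed: int = 1) -> dict:
    """Disjoint-clique graphs: MCL output must equal the connected components
    (counted via union-find, independent of the MCL code path)."""
    rng = np.random.default_rng(_seed(base_seed, 6, 0))
    agree = 0
    for _ in range(n_graphs):
        n_nodes = int(rng.integers(4, 13))
        sizes = []
        left = n_nodes
        while left > 0:
            s = int(rng.integers(1, min(4, left) + 1))
            sizes.append(s)
            left -= s
        nodes = [f"n{i:02d}" for i in range(n_nodes)]
        edges = []
        start = 0
        parent = list(range(n_nodes))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for s in sizes:
            block = nodes[start : start + s]
            for i in range(s):
                for j in range(i + 1, s):
                    edges.append(
                        IdentityEdge(block[i], block[j], 90.0, 1.0, 100)
                    )
                    parent[find(start + j)] = find(start + i)
            start += s
        clusters = mcl_cluster(edges, nodes=nodes)
        got = sorted(sorted(c.members) for c in clusters)
        want = {}
        for i, v in enumerate(nodes):
            want.setdefault(find(i), []).append(v)
        expected = sorted(sorted(v) for v in want.values())
        agree += got == expected
    return {"agreement": agree, "n_graphs": n_graphs}
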