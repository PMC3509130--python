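"""End-to-end orchestration: simulate (optional) -> cluster -> filter ->
quantify -> classify -> differential -> modules.

A single :class:`PipelineConfig` drives all stages with the study thresholds
as defaults (>80% identity, MCL inflation 1.5, XCorr 1.8/2.5/3.5, ±10 ppm,
≥2 peptides, prefilter >5 counts in ≥4 runs, q<0.05 & median diff>5, module
coverage >30%, module FDR 10%).  :func:`run_pipeline` returns everything in
memory and, when ``outdir`` is set, writes the TSV tables, an FDR report, a
manifest (thresholds, seed, versions) and a machine-readable summary.  Output
is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .io import (
    write_clusters,
    write_fasta,
    write_json,
    write_matrix,
    write_psms,
)
from .modules import (
    differential_modules,
    median_log2_fold_change,
    module_abundance,
    module_coverage,
    taxon_module_deviation,
)
from .psm import FilterPolicy, estimate_fdr, filter_psms, protein_level_filter
from .quant import (
    AbundanceMatrix,
    RunProfile,
    attribute_spectra,
    human_protein_counts,
    normalize_counts,
)
from .seqdb import cluster_proteins, map_orfs_to_clusters, remove_redundant
from .stats import call_differential
from .synthetic import (
    Cohort,
    CohortSpec,
    generate_cohort,
    generate_reference_proteomes,
    simulate_psm_tables,
)
from .taxonomy import FALLBACK_TAXON, ReferenceIndex, contig_taxon, genus_profile


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One config object for the whole pipeline (YAML-loadable).

    Exactly one of ``cohort`` (simulate) or ``inputs`` (paths to psms/run
    metadata/reference FASTA/ORF FASTA/module TSV) must be given.
    """

    cohort: CohortSpec | None = None
    inputs: dict | None = None
    comparisons: tuple = (("H", "ICD"),)
    min_identity: float = 80.0
    inflation: float = 1.5
    min_aln_len: int = 30
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    alpha_q: float = 0.05
    min_median_diff: float = 5.0
    prefilter_min_count: float = 5.0
    prefilter_min_runs: int = 4
    module_fdr: float = 0.10
    module_min_coverage: float = 0.30
    pi_level: float = 0.95
    min_taxon_id: float = 80.0
    min_taxon_cov: float = 0.80
    fdr_estimator: str = "2d"
    #: classification is the most expensive stage; experiments that only need
    #: cluster-level quantities may turn it off (genus/KO-by-taxon views and
    #: the deviation analysis are then skipped)
    with_taxonomy: bool = True
    outdir: str | None = None

    def validate(self):
        if (self.cohort is None) == (self.inputs is None):
            raise ConfigurationError(
                "config: exactly one of cohort / inputs must be set"
            )
        if self.cohort is not None:
            self.cohort.validate()
            labels = {g for g, _ in self.cohort.groups}
            for a, b in self.comparisons:
                if a not in labels or b not in labels:
                    raise ConfigurationError(
                        f"comparisons: undefined group in ({a!r}, {b!r})"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs and kwargs["cohort"] is not None:
            c = dict(kwargs["cohort"])
            for key in ("groups", "planted_diff_clusters", "planted_module_effects",
                        "affected_groups", "seq_length_range", "spectra_per_run",
                        "xcorr_correct", "xcorr_incorrect"):
                if key in c and c[key] is not None:
                    c[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in c[key]
                    ) if isinstance(c[key], list) else c[key]
            kwargs["cohort"] = CohortSpec(**c)
        if "policy" in kwargs and kwargs["policy"] is not None:
            p = dict(kwargs["policy"])
            if "xcorr_min_by_charge" in p:
                p["xcorr_min_by_charge"] = tuple(
                    (int(k), float(v)) for k, v in p["xcorr_min_by_charge"]
                )
            if "ppm_window" in p:
                p["ppm_window"] = tuple(p["ppm_window"])
            kwargs["policy"] = FilterPolicy(**p)
        if "comparisons" in kwargs:
            kwargs["comparisons"] = tuple(tuple(c) for c in kwargs["comparisons"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    refs: list
    module_definitions: dict
    cohort: Cohort | None
    psms: pd.DataFrame
    run_meta: pd.DataFrame
    profiles: list
    clusters: list
    orf_mapping: dict
    filter_stats: dict
    fdr_report: dict
    accepted: pd.DataFrame
    matrices: dict  # level -> AbundanceMatrix (normalized)
    orf_taxon: dict
    genus_profiles: pd.DataFrame
    differential: dict  # (a, b) -> {level -> DataFrame}
    module_records: list
    module_differential: dict  # (a, b) -> DataFrame
    deviation: dict  # (a, b) -> DataFrame


def _split_human(psms: pd.DataFrame) -> pd.Series:
    """True where every matched protein is a human entry."""
    return psms["protein_ids"].astype(str).str.split(";").map(
        lambda ps: all(p.startswith("HUMAN") for p in ps)
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    stage = "load"
    try:
        if config.cohort is not None:
            stage = "simulate"
            spec = config.cohort
            refs, module_definitions = generate_reference_proteomes(spec)
            cohort = generate_cohort(spec, refs, module_definitions)
            psms, run_meta = simulate_psm_tables(spec, cohort, refs)
        else:
            stage = "load-inputs"
            from .io import (
                read_fasta,
                read_module_definitions,
                read_psms,
            )

            paths = config.inputs
            refs = read_fasta(paths["references"])
            psms = read_psms(paths["psms"])
            run_meta = pd.read_csv(paths["runs"], sep="\t")
            module_definitions = (
                read_module_definitions(paths["modules"])
                if paths.get("modules")
                else {}
            )
            orfs_by_sample = {}
            if paths.get("orfs"):
                from collections import defaultdict

                orfs_by_sample = defaultdict(list)
                for p in read_fasta(paths["orfs"]):
                    orfs_by_sample[p.id.split("_", 1)[0]].append(p)
            cohort = None

        profiles = [
            RunProfile(r.run_id, r.sample_id, r.group, int(r.n_spectra))
            for r in run_meta.itertuples(index=False)
        ]
        run_ids = run_meta["run_id"].tolist()
        runs_of = {
            g: run_meta.loc[run_meta["group"] == g, "run_id"].tolist()
            for g in run_meta["group"].unique()
        }

        stage = "sequence_db"
        microbial_refs = [p for p in refs if p.source == "reference"]
        nr_refs = remove_redundant(microbial_refs)
        clusters = cluster_proteins(
            nr_refs,
            min_identity=config.min_identity,
            inflation=config.inflation,
            min_aln_len=config.min_aln_len,
        )
        refs_by_id = {p.id: p for p in nr_refs}
        if cohort is not None:
            all_orfs = [
                p
                for s in cohort.sample_dbs
                for p in cohort.sample_dbs[s]
                if p.source == "metagenome"
            ]
        else:
            all_orfs = [p for s in orfs_by_sample for p in orfs_by_sample[s]]
        orf_mapping = map_orfs_to_clusters(
            all_orfs,
            clusters,
            refs_by_id,
            min_identity=config.min_identity,
            min_aln_len=config.min_aln_len,
        )

        stage = "psm_quality"
        accepted_all, filter_stats = filter_psms(psms, config.policy, "mm")
        fdr_report = estimate_fdr(accepted_all, estimator=config.fdr_estimator)
        accepted = accepted_all[~accepted_all["is_decoy"].astype(bool)]
        human_mask = _split_human(accepted)
        human_psms = accepted[human_mask]
        microbial_psms = accepted[~human_mask]
        microbial_psms, _kept = protein_level_filter(
            microbial_psms, "mm", config.policy, orf_mapping
        )
        human_psms, _kept_h = protein_level_filter(
            human_psms, "hmrg", config.policy
        )

        stage = "taxonomy"
        if config.with_taxonomy:
            ref_index = ReferenceIndex(
                microbial_refs,
                min_id=config.min_taxon_id,
                min_cov=config.min_taxon_cov,
            )
            assignments = {o.id: ref_index.classify(o) for o in all_orfs}
        else:
            assignments = {}
        orf_taxon = {}
        genus_profiles = pd.DataFrame()
        if config.with_taxonomy:
            contig_members = {}
            contig_lookup = cohort.contig_of if cohort is not None else {}
            for oid, cid in contig_lookup.items():
                contig_members.setdefault(cid, []).append(oid)
            contig_taxa = {
                cid: contig_taxon(
                    [assignments[m] for m in members if m in assignments]
                )
                for cid, members in contig_members.items()
            }
            for o in all_orfs:
                cid = contig_lookup.get(o.id)
                orf_taxon[o.id] = (
                    contig_taxa[cid]
                    if cid is not None
                    else assignments[o.id].taxon
                )
            by_sample = {}
            for o in all_orfs:
                by_sample.setdefault(o.id.split("_orf")[0], []).append(
                    assignments[o.id]
                )
            if by_sample:
                genus_profiles = genus_profile(by_sample)

        stage = "quantification"
        cluster_counts = attribute_spectra(
            microbial_psms, orf_mapping, run_ids=run_ids
        )
        matrices = {
            "cluster": normalize_counts(cluster_counts, profiles, "cluster")
        }
        human_counts = human_protein_counts(human_psms, run_ids=run_ids)
        if len(human_counts):
            matrices["human"] = normalize_counts(human_counts, profiles, "human")
        cog_map = {}
        ko_map = {}
        taxon_map = {}
        taxon_ko_map = {}
        for o in all_orfs:
            cog_map[o.id] = o.cog
            ko_map[o.id] = o.ko
            t = orf_taxon.get(o.id)
            taxon_map[o.id] = t if t and t != FALLBACK_TAXON else None
            if taxon_map[o.id] and ko_map[o.id]:
                taxon_ko_map[o.id] = f"{t}|{ko_map[o.id]}"
        views = [("cog", cog_map), ("ko", ko_map)]
        if config.with_taxonomy:
            views += [("genus", taxon_map), ("taxon_ko", taxon_ko_map)]
        for kind, mapping in views:
            raw = attribute_spectra(microbial_psms, mapping, run_ids=run_ids)
            raw = raw[~raw.index.astype(str).str.startswith("singleton:")]
            matrices[kind] = normalize_counts(raw, profiles, kind)

        stage = "differential"
        differential = {}
        for a, b in config.comparisons:
            per_level = {}
            for level in ("cluster", "cog", "genus", "human"):
                if level not in matrices:
                    continue
                per_level[level] = call_differential(
                    matrices[level],
                    runs_of[a],
                    runs_of[b],
                    alpha_q=config.alpha_q,
                    min_median_diff=config.min_median_diff,
                    prefilter_min_count=config.prefilter_min_count,
                    prefilter_min_runs=config.prefilter_min_runs,
                )
            differential[(a, b)] = per_level

        stage = "module_analysis"
        module_records = []
        module_differential = {}
        deviation = {}
        if module_definitions:
            detected_kos = set(
                matrices["ko"].values.index[matrices["ko"].values.sum(axis=1) > 0]
            )
            module_records, passing = module_coverage(
                detected_kos, module_definitions, config.module_min_coverage
            )
            mod_matrix = module_abundance(
                matrices["ko"], module_definitions, passing
            )
            for a, b in config.comparisons:
                module_differential[(a, b)] = differential_modules(
                    mod_matrix,
                    runs_of[a],
                    runs_of[b],
                    alpha=config.module_fdr,
                    min_median_diff=config.min_median_diff,
                )
                if "taxon_ko" in matrices:
                    deviation[(a, b)] = _deviation_table(
                        matrices,
                        module_definitions,
                        runs_of[a],
                        runs_of[b],
                        config,
                    )

        result = PipelineResult(
            config=config,
            refs=refs,
            module_definitions=module_definitions,
            cohort=cohort,
            psms=psms,
            run_meta=run_meta,
            profiles=profiles,
            clusters=clusters,
            orf_mapping=orf_mapping,
            filter_stats=filter_stats,
            fdr_report=fdr_report,
            accepted=accepted,
            matrices=matrices,
            orf_taxon=orf_taxon,
            genus_profiles=genus_profiles,
            differential=differential,
            module_records=module_records,
            module_differential=module_differential,
            deviation=deviation,
        )
        if config.outdir:
            stage = "write-outputs"
            _write_outputs(result, Path(config.outdir))
        return result
    except Exception as exc:
        if config.outdir:
            out = Path(config.outdir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"FAILED_{stage}").write_text(str(exc) + "\n")
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc


def _deviation_table(matrices, module_definitions, runs_a, runs_b, config):
    """(taxon, module) observed-vs-expected log2 fold-change points with
    per-taxon coverage gating and module-level significance flags."""
    tk = matrices["taxon_ko"].values
    taxon_tot = matrices["genus"].values
    if tk.empty or taxon_tot.empty:
        return pd.DataFrame()
    split = tk.index.to_series().str.split("|", expand=True)
    rows = []
    tm_values = {}
    for taxon in sorted(split[0].unique()):
        kos = set(split.loc[split[0] == taxon, 1])
        _, passing = module_coverage(
            kos,
            {m: k for m, k in module_definitions.items()},
            config.module_min_coverage,
        )
        if taxon not in taxon_tot.index:
            continue
        expected = median_log2_fold_change(
            taxon_tot.loc[taxon, runs_b], taxon_tot.loc[taxon, runs_a]
        )
        for mid in passing:
            members = [
                f"{taxon}|{k}" for k in module_definitions[mid] if f"{taxon}|{k}" in tk.index
            ]
            vals = tk.loc[members].sum(axis=0)
            tm_values[(taxon, mid)] = vals
            observed = median_log2_fold_change(vals[runs_b], vals[runs_a])
            rows.append(
                {
                    "taxon": taxon,
                    "module_id": mid,
                    "observed_lfc": observed,
                    "expected_lfc": expected,
                }
            )
    if len(rows) < 3:
        return pd.DataFrame(rows)
    points = pd.DataFrame(rows)
    # per-(taxon, module) significance, BH at the module FDR
    tm_matrix = AbundanceMatrix(
        values=pd.DataFrame(
            {f"{t}|{m}": v for (t, m), v in tm_values.items()}
        ).T,
        feature_kind="taxon_module",
        normalized=True,
    )
    sig = differential_modules(
        tm_matrix, runs_a, runs_b, alpha=config.module_fdr,
        min_median_diff=config.min_median_diff,
    ).set_index("feature_id")["significant"]
    points["significant"] = [
        bool(sig.get(f"{t}|{m}", False))
        for t, m in zip(points["taxon"], points["module_id"])
    ]
    return taxon_module_deviation(points, level=config.pi_level)


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "references.fasta", result.refs)
    write_clusters(outdir / "clusters.tsv", result.clusters)
    write_psms(outdir / "psms_accepted.tsv", result.accepted)
    pd.DataFrame(
        [
            {"orf_id": o, "cluster_id": c if c is not None else ""}
            for o, c in sorted(result.orf_mapping.items())
        ]
    ).to_csv(outdir / "orf_mapping.tsv", sep="\t", index=False)
    result.run_meta.to_csv(outdir / "runs.tsv", sep="\t", index=False)
    for level, matrix in result.matrices.items():
        write_matrix(outdir / f"abundance_{level}.tsv", matrix.values)
    if len(result.genus_profiles):
        result.genus_profiles.to_csv(
            outdir / "genus_profile_metagenome.tsv", sep="\t",
            index_label="sample_id",
        )
    for (a, b), per_level in result.differential.items():
        for level, df in per_level.items():
            df.to_csv(
                outdir / f"differential_{level}_{a}_vs_{b}.tsv",
                sep="\t",
                index=False,
            )
    for (a, b), df in result.module_differential.items():
        df.to_csv(outdir / f"modules_{a}_vs_{b}.tsv", sep="\t", index=False)
    for (a, b), df in result.deviation.items():
        df.to_csv(outdir / f"deviation_{a}_vs_{b}.tsv", sep="\t", index=False)
    fdr = {
        "pooled": result.fdr_report["pooled"],
        "per_run": result.fdr_report["per_run"],
        "filter_stats": result.filter_stats,
    }
    write_json(outdir / "fdr_report.json", fdr)
    manifest = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": _config_dict(result.config),
    }
    write_json(outdir / "manifest.json", manifest)
    summary = {
        "n_psms": int(len(result.psms)),
        "n_accepted": int(result.filter_stats.get("accepted", 0)),
        "fdr_pooled": result.fdr_report["pooled"],
        "n_clusters": len(result.clusters),
        "significant": {
            f"{a}_vs_{b}:{level}": int(df["significant"].sum())
            for (a, b), per in result.differential.items()
            for level, df in per.items()
        },
    }
    write_json(outdir / "summary.json", summary)


def _config_dict(config: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: clean(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (str, int, float, bool)) or obj is None:
            return obj
        return str(obj)

    return clean(config)
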