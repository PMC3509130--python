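"""Synthetic twin-cohort generator.

Produces fully specified cohorts with the statistical structure the analysis
assumes: a reference proteome of gut genera (with cross-genus paralog families
and optional near-identical strain variants), per-subject genus abundance
profiles with planted depletion in the disease group, per-sample metagenome
ORF "reads" (mutated copies of reference proteins, grouped into pseudo-contigs),
and per-run PSM tables from an in-silico tryptic digest with a planted fraction
of random matches against a concatenated target-decoy database.  Every planted
effect is recorded in a :class:`GroundTruth` so downstream recovery can be
scored.

Abundances are log-normal (heavy-tailed, renormalized to proportions); correct
matches draw XCorr from a shifted gamma and small Normal ppm errors, random
matches from a low-mean gamma with wide uniform ppm spread, so the charge
thresholds and the +/-10 ppm window are both informative.

All randomness flows from the spec's single integer seed through spawned
``numpy.random.Generator`` streams (one per stage), so regeneration is
bit-reproducible.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .seqdb import ProteinRecord, remove_redundant

GENUS_POOL = (
    "Faecalibacterium",
    "Roseburia",
    "Coprococcus",
    "Dialister",
    "Bacteroides",
    "Prevotella",
    "Ruminococcus",
    "Alistipes",
    "Eubacterium",
    "Blautia",
    "Bifidobacterium",
    "Akkermansia",
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# loosely natural composition; K+R ~ 11% so tryptic peptides average ~9 aa
AA_FREQS = np.array(
    [
        0.08, 0.02, 0.05, 0.06, 0.04, 0.07, 0.02, 0.06, 0.06, 0.09,
        0.02, 0.04, 0.045, 0.04, 0.05, 0.065, 0.055, 0.07, 0.012, 0.033,
    ]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

CHARGES = np.array([1, 2, 3])
CHARGE_PROBS = np.array([0.15, 0.60, 0.25])

#: divergence of cross-genus paralog family copies outside the conserved window
#: (pairwise copy identity ~ (1-d)^2 ~ 88%, safely above the 80% cluster gate)
FAMILY_DIVERGENCE = 0.06
SHARED_WINDOW = 14  # conserved K...R tryptic peptide shared across the family

PEPTIDE_MIN_LEN = 6
PEPTIDE_MAX_LEN = 45
MISCLEAVAGE_DECAY = 0.45  # sampling weight ~ decay**n_missed


@dataclass
class CohortSpec:
    """Generator configuration; defaults mirror the study's metaproteome arm
    (twin cohort: 4 healthy, 6 ileal-CD, 2 colonic-CD subjects, two technical
    MS runs each)."""

    n_genera: int = 8
    proteins_per_genus: int = 12
    seq_length_range: tuple = (90, 220)
    strain_mutation_rate: float = 0.02
    strains_per_genus: int = 1
    n_shared_families: int = 2
    n_human_proteins: int = 10
    groups: tuple = (("H", 4), ("ICD", 6), ("CCD", 2))
    runs_per_subject: int = 2
    depletion: dict = field(
        default_factory=lambda: {"Faecalibacterium": 0.2, "Roseburia": 0.25}
    )
    affected_groups: tuple = ("ICD",)
    planted_diff_clusters: tuple = ()  # ((reference protein id, fold), ...)
    planted_module_effects: tuple = ()  # ((genus, module_id, fold), ...)
    reads_per_sample: int = 300
    spectra_per_run: tuple = (3000.0, 0.15)  # acquired MS/MS: mean, cv
    identification_rate: float = 0.5  # expected correct PSMs / acquired spectra
    decoy_hit_rate: float = 0.10  # fraction of emitted PSMs that are random matches
    human_spectra_fraction: float = 0.12
    xcorr_correct: tuple = (1.5, 3.5, 0.6)  # shift, gamma shape, gamma scale
    xcorr_incorrect: tuple = (0.0, 2.5, 0.6)
    ppm_sigma_correct: float = 3.0
    ppm_spread_incorrect: float = 50.0
    genus_sigma: float = 1.0  # log-normal sigma of cohort genus means
    subject_sigma: float = 0.25  # per-subject log-normal noise
    detectability_sigma: float = 0.5  # per-protein log-normal detectability
    kos_per_module: int = 4
    seed: int = 0

    def genera(self) -> list:
        if self.n_genera <= len(GENUS_POOL):
            return list(GENUS_POOL[: self.n_genera])
        extra = [f"Genus{i:02d}" for i in range(self.n_genera - len(GENUS_POOL))]
        return list(GENUS_POOL) + extra

    def validate(self):
        def positive(name, v):
            if not v > 0:
                raise ConfigurationError(f"{name}: must be > 0 (got {v!r})")

        for name in ("n_genera", "proteins_per_genus", "runs_per_subject",
                     "reads_per_sample", "strains_per_genus", "kos_per_module"):
            positive(name, getattr(self, name))
        for name in ("strain_mutation_rate", "decoy_hit_rate",
                     "human_spectra_fraction", "identification_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}: must be in [0, 1] (got {v!r})")
        lo, hi = self.seq_length_range
        if not (SHARED_WINDOW + 10 <= lo <= hi):
            raise ConfigurationError("seq_length_range: bounds out of order/too short")
        if not self.groups:
            raise ConfigurationError("groups: empty")
        for label, n in self.groups:
            if n <= 0:
                raise ConfigurationError(f"groups: group {label!r} has 0 subjects")
        genera = set(self.genera())
        if not set(self.depletion) <= genera:
            raise ConfigurationError(
                f"depletion: unknown genera {sorted(set(self.depletion) - genera)}"
            )
        for m in list(self.depletion.values()) + [
            f for _, f in self.planted_diff_clusters
        ] + [f for _, _, f in self.planted_module_effects]:
            if not m > 0:
                raise ConfigurationError("fold-change: must be > 0")
        mean, cv = self.spectra_per_run
        positive("spectra_per_run mean", mean)
        if cv < 0:
            raise ConfigurationError("spectra_per_run: cv must be >= 0")
        labels = {g for g, _ in self.groups}
        if not set(self.affected_groups) <= labels:
            raise ConfigurationError("affected_groups: unknown group label")


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream recovery scoring."""

    abundances: pd.DataFrame  # samples x genera, rows sum to 1
    orf_parent: dict  # orf id -> reference protein id
    planted_clusters: dict  # reference protein id -> fold change
    deviating_modules: list  # (genus, module_id, fold) triples
    depletion: dict  # genus -> fold change
    correct_psm_fraction: dict = field(default_factory=dict)  # run id -> frac
    incorrect_spectra: set = field(default_factory=set)  # spectrum ids of random matches


@dataclass
class Cohort:
    samples: pd.DataFrame  # sample_id, pair_id, group
    orfs: dict  # sample id -> list[ProteinRecord] (raw reads)
    sample_dbs: dict  # sample id -> non-redundant search database
    contig_of: dict  # orf id -> contig id
    truth: GroundTruth
    module_definitions: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference proteomes

def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length, p=AA_FREQS))


def _shared_window(rng) -> str:
    """A conserved fully tryptic peptide: K + non-K/R/P core + R."""
    inner = [a for a in AMINO_ACIDS if a not in "KRP"]
    core = "".join(rng.choice(inner, size=SHARED_WINDOW - 2))
    return "K" + core + "R"


def _mutate(rng, seq: str, rate: float, protected=()) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if any(lo <= i < hi for lo, hi in protected):
            continue
        choices = AMINO_ACIDS[AMINO_ACIDS != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


def generate_reference_proteomes(spec: CohortSpec):
    """Reference proteins with genus labels, KO/COG annotations and KO->module
    definitions.

    Returns ``(proteins, module_definitions)``.  The last
    ``n_shared_families`` protein slots of every genus hold cross-genus
    paralog-family copies that conserve one tryptic peptide exactly, so some
    peptides are shared across genera.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    genera = spec.genera()
    lo, hi = spec.seq_length_range

    families = []
    for _ in range(spec.n_shared_families):
        length = int(rng.integers(lo, hi + 1))
        base = _random_sequence(rng, length)
        w0 = int(rng.integers(5, length - SHARED_WINDOW - 5))
        base = base[:w0] + _shared_window(rng) + base[w0 + SHARED_WINDOW:]
        families.append((base, (w0, w0 + SHARED_WINDOW)))

    proteins = []
    module_definitions: dict = {}
    ko_counter = 1
    cog_counter = 1
    for genus in genera:
        genus_kos = []
        for j in range(spec.proteins_per_genus):
            fam_idx = j - (spec.proteins_per_genus - spec.n_shared_families)
            if 0 <= fam_idx < len(families):
                base, window = families[fam_idx]
                seq = _mutate(rng, base, FAMILY_DIVERGENCE, protected=[window])
            else:
                seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
            ko = f"K{ko_counter:05d}"
            cog = f"COG{cog_counter:04d}"
            ko_counter += 1
            cog_counter += 1
            genus_kos.append(ko)
            base_id = f"{genus}_p{j:02d}"
            proteins.append(
                ProteinRecord(
                    id=base_id,
                    sequence=seq,
                    source="reference",
                    genus=genus,
                    annotations=frozenset({ko, cog}),
                )
            )
            for s in range(2, spec.strains_per_genus + 1):
                proteins.append(
                    ProteinRecord(
                        id=f"{base_id}_s{s}",
                        sequence=_mutate(rng, seq, spec.strain_mutation_rate),
                        source="reference",
                        genus=genus,
                        annotations=frozenset({ko, cog}),
                    )
                )
        # consecutive KOs grouped into multi-KO modules
        k = spec.kos_per_module
        for m, start in enumerate(range(0, len(genus_kos), k)):
            chunk = genus_kos[start : start + k]
            if len(chunk) >= 2:
                module_definitions[f"MD_{genus}_{m:02d}"] = set(chunk)

    for _genus, module_id, _fold in spec.planted_module_effects:
        if module_id not in module_definitions:
            raise ConfigurationError(
                f"planted_module_effects: unknown module {module_id!r}"
            )

    human = [
        ProteinRecord(
            id=f"HUMAN{j:02d}",
            sequence=_random_sequence(rng, int(rng.integers(lo, hi + 1))),
            source="human",
        )
        for j in range(spec.n_human_proteins)
    ]
    return proteins + human, module_definitions


# ---------------------------------------------------------------------------
# cohort: samples, abundances, reads

def generate_cohort(spec: CohortSpec, refs, module_definitions=None) -> Cohort:
    """Sample metadata, genus abundance profiles, per-sample read ORFs and
    pseudo-contigs, plus the filled :class:`GroundTruth`."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    genera = spec.genera()
    microbial = [p for p in refs if p.source == "reference"]
    if not microbial:
        raise DataError("refs: no reference proteins")

    rows = []
    for label, n in spec.groups:
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{label}{i + 1}",
                    "pair_id": f"T{i + 1:02d}",
                    "group": label,
                }
            )
    samples = pd.DataFrame(rows)

    genus_mean = rng.lognormal(0.0, spec.genus_sigma, size=len(genera))
    abund = {}
    for row in samples.itertuples(index=False):
        a = genus_mean * rng.lognormal(0.0, spec.subject_sigma, size=len(genera))
        if row.group in spec.affected_groups:
            for g, fold in spec.depletion.items():
                a[genera.index(g)] *= fold
        abund[row.sample_id] = a / a.sum()
    abundances = pd.DataFrame.from_dict(
        abund, orient="index", columns=genera
    ).loc[samples["sample_id"]]

    by_genus = defaultdict(list)
    for p in microbial:
        by_genus[p.genus].append(p)

    orfs = {}
    sample_dbs = {}
    contig_of = {}
    orf_parent = {}
    human = [p for p in refs if p.source == "human"]
    for row in samples.itertuples(index=False):
        s = row.sample_id
        weights = np.array(
            [
                abundances.loc[s, p.genus] / len(by_genus[p.genus])
                for p in microbial
            ]
        )
        weights = weights / weights.sum()
        counts = rng.multinomial(spec.reads_per_sample, weights)
        reads = []
        k = 0
        for p, c in zip(microbial, counts):
            for _ in range(c):
                oid = f"{s}_orf{k:04d}"
                reads.append(
                    ProteinRecord(
                        id=oid,
                        sequence=_mutate(rng, p.sequence, spec.strain_mutation_rate),
                        source="metagenome",
                        annotations=p.annotations,
                    )
                )
                base = p.id.split("_s")[0]
                orf_parent[oid] = base
                k += 1
        orfs[s] = reads
        sample_dbs[s] = remove_redundant(reads + human)
        # pseudo-contigs: chunks of reads from the same genus
        genus_reads = defaultdict(list)
        for r in reads:
            parent = orf_parent[r.id]
            genus_reads[parent.rsplit("_p", 1)[0]].append(r.id)
        ctg = 0
        for g in sorted(genus_reads):
            ids = genus_reads[g]
            i = 0
            while i < len(ids):
                size = int(rng.integers(2, 5))
                for oid in ids[i : i + size]:
                    contig_of[oid] = f"{s}_ctg{ctg:03d}"
                ctg += 1
                i += size

    truth = GroundTruth(
        abundances=abundances,
        orf_parent=orf_parent,
        planted_clusters=dict(spec.planted_diff_clusters),
        deviating_modules=list(spec.planted_module_effects),
        depletion=dict(spec.depletion),
    )
    ref_ids = {p.id for p in microbial}
    unknown = set(truth.planted_clusters) - ref_ids
    if unknown:
        raise ConfigurationError(
            f"planted_diff_clusters: unknown reference ids {sorted(unknown)}"
        )
    return Cohort(
        samples=samples,
        orfs=orfs,
        sample_dbs=sample_dbs,
        contig_of=contig_of,
        truth=truth,
        module_definitions=dict(module_definitions or {}),
    )


# ---------------------------------------------------------------------------
# in-silico tryptic digestion

def tryptic_peptides(
    sequence: str,
    max_missed: int = 4,
    min_len: int = PEPTIDE_MIN_LEN,
    max_len: int = PEPTIDE_MAX_LEN,
):
    """Fully tryptic peptides (cleave after K/R, not before P) with 0 to
    ``max_missed`` missed cleavages.

    Yields ``(peptide, prev_aa, next_aa, n_missed)`` with '-' marking protein
    termini.
    """
    n = len(sequence)
    sites = [
        i + 1
        for i in range(n - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + sites + [n]
    out = []
    for bi in range(len(bounds) - 1):
        for miss in range(max_missed + 1):
            ei = bi + 1 + miss
            if ei >= len(bounds):
                break
            start, end = bounds[bi], bounds[ei]
            if not min_len <= end - start <= max_len:
                continue
            pep = sequence[start:end]
            prev_aa = sequence[start - 1] if start > 0 else "-"
            next_aa = sequence[end] if end < n else "-"
            out.append((pep, prev_aa, next_aa, miss))
    return out


class _PeptideIndex:
    """Digest-derived peptide -> protein-id index for one search database."""

    def __init__(self, proteins, max_missed=4):
        self.entries = {}  # protein id -> list of digest tuples
        self.by_peptide = defaultdict(set)
        for p in proteins:
            peps = tryptic_peptides(p.sequence, max_missed=max_missed)
            self.entries[p.id] = peps
            for pep, *_ in peps:
                self.by_peptide[pep].add(p.id)


# ---------------------------------------------------------------------------
# PSM simulation

def _protein_weights(spec, cohort, refs, sample_id, group):
    """Per-ORF expected-spectrum weights for one sample.

    Returns ``(w_microbial, folds, w_human)``: ``w_microbial`` are base
    weights (genus abundance x protein detectability, split evenly over the
    sample's copies of the same parent, normalized to sum 1 over microbial
    entries); ``folds`` carry planted cluster/module fold changes, applied
    *after* normalization so a planted depletion lowers that protein's
    expected yield without redistributing it to others.
    """
    rng_det = np.random.default_rng([spec.seed, 2])
    microbial_bases = sorted(
        {p.id.split("_s")[0] for p in refs if p.source == "reference"}
    )
    detect = dict(
        zip(
            microbial_bases,
            rng_det.lognormal(0.0, spec.detectability_sigma, len(microbial_bases)),
        )
    )
    ko_of = {
        p.id.split("_s")[0]: p.ko for p in refs if p.source == "reference"
    }
    # (genus, KO) -> extra fold from planted module effects
    ko_fold = {}
    for genus, module_id, fold in spec.planted_module_effects:
        for ko in cohort.module_definitions.get(module_id, ()):
            ko_fold[(genus, ko)] = fold

    affected = group in spec.affected_groups
    abund = cohort.truth.abundances.loc[sample_id]
    db = cohort.sample_dbs[sample_id]
    copies = defaultdict(int)
    for p in db:
        if p.source == "metagenome":
            copies[cohort.truth.orf_parent[p.id]] += 1

    w_microbial = {}
    folds = {}
    w_human = {}
    for p in db:
        if p.source == "human":
            w_human[p.id] = 1.0
            continue
        base = cohort.truth.orf_parent[p.id]
        genus = base.rsplit("_p", 1)[0]
        w_microbial[p.id] = abund[genus] * detect[base] / copies[base]
        fold = 1.0
        if affected:
            fold *= cohort.truth.planted_clusters.get(base, 1.0)
            fold *= ko_fold.get((genus, ko_of.get(base)), 1.0)
        folds[p.id] = fold
    total = sum(w_microbial.values())
    if total > 0:
        w_microbial = {k: v / total for k, v in w_microbial.items()}
    n_h = len(w_human)
    if n_h:
        w_human = {k: 1.0 / n_h for k in w_human}
    return w_microbial, folds, w_human


def simulate_psm_tables(spec: CohortSpec, cohort: Cohort, refs):
    """PSM table (one pooled DataFrame) and per-run totals.

    Each run acquires ``n_spectra`` MS/MS (the normalization denominator);
    only a fraction yields identifications.  A protein's correct-PSM count is
    an independent Poisson draw with rate acquired x identification_rate x
    its abundance-detectability weight (x planted folds), the peptide drawn
    from its tryptic digest down-weighted by missed cleavages.  Random
    (incorrect) matches draw a peptide uniformly from the concatenated
    target+decoy digest, at a rate making them ``decoy_hit_rate`` of emitted
    PSMs in expectation.  Returns ``(psms, run_meta)`` with run_id, sample_id,
    group, n_spectra; ``cohort.truth`` gains per-run correct-PSM fractions and
    the spectrum ids of the planted random matches.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 3])
    mean, cv = spec.spectra_per_run

    shift_c, shape_c, scale_c = spec.xcorr_correct
    shift_i, shape_i, scale_i = spec.xcorr_incorrect

    psm_rows = []
    run_rows = []
    for row in cohort.samples.itertuples(index=False):
        s = row.sample_id
        db = cohort.sample_dbs[s]
        if not any(p.source != "human" for p in db):
            raise DataError(f"sample {s!r}: empty microbial proteome")
        index = _PeptideIndex(db)
        decoys = [
            ProteinRecord(
                id=f"rev_{p.id}", sequence=p.sequence[::-1], source="decoy"
            )
            for p in db
        ]
        decoy_index = _PeptideIndex(decoys)
        pool = [("t", pep) for pep in sorted(index.by_peptide)] + [
            ("d", pep) for pep in sorted(decoy_index.by_peptide)
        ]

        w_microbial, folds, w_human = _protein_weights(
            spec, cohort, refs, s, row.group
        )
        # proteins whose digest is empty cannot yield spectra
        ids_m = sorted(
            pid
            for pid, w in w_microbial.items()
            if w > 0 and len(index.entries[pid]) > 0
        )
        ids_h = sorted(p for p in w_human if len(index.entries[p]) > 0)

        micro_share = 1.0 - spec.human_spectra_fraction
        for r in range(1, spec.runs_per_subject + 1):
            run_id = f"{s}_r{r}"
            n_spectra = max(50, int(round(rng.normal(mean, cv * mean))))
            yield_rate = n_spectra * spec.identification_rate

            spec_counter = 0

            def emit(pep_entry, correct, is_decoy, idx):
                pep, prev_aa, next_aa, _miss = pep_entry
                if correct:
                    xcorr = shift_c + rng.gamma(shape_c, scale_c)
                    ppm = rng.normal(0.0, spec.ppm_sigma_correct)
                    deltcn = rng.uniform(0.05, 0.5)
                else:
                    xcorr = shift_i + rng.gamma(shape_i, scale_i)
                    ppm = rng.uniform(
                        -spec.ppm_spread_incorrect, spec.ppm_spread_incorrect
                    )
                    deltcn = rng.uniform(0.0, 0.3)
                prots = (
                    decoy_index.by_peptide[pep] if is_decoy else index.by_peptide[pep]
                )
                sid = f"{run_id}_s{idx:06d}"
                if not correct:
                    cohort.truth.incorrect_spectra.add(sid)
                psm_rows.append(
                    (
                        sid,
                        run_id,
                        s,
                        pep,
                        prev_aa,
                        next_aa,
                        int(rng.choice(CHARGES, p=CHARGE_PROBS)),
                        round(float(xcorr), 4),
                        round(float(deltcn), 4),
                        round(float(ppm), 3),
                        ";".join(sorted(prots)),
                        bool(is_decoy),
                    )
                )

            n_good = 0

            def sample_correct(ids, weight_of, share):
                nonlocal spec_counter, n_good
                for pid in ids:
                    lam = yield_rate * share * weight_of(pid)
                    c = rng.poisson(lam)
                    if c == 0:
                        continue
                    entries = index.entries[pid]
                    pw = np.array([MISCLEAVAGE_DECAY ** e[3] for e in entries])
                    pw /= pw.sum()
                    picks = rng.choice(len(entries), size=c, p=pw)
                    for k in picks:
                        emit(entries[k], True, False, spec_counter)
                        spec_counter += 1
                        n_good += 1

            sample_correct(
                ids_m, lambda p: w_microbial[p] * folds[p], micro_share
            )
            sample_correct(ids_h, w_human.get, spec.human_spectra_fraction)

            # random matches: decoy_hit_rate of emitted PSMs in expectation
            r_bad = spec.decoy_hit_rate
            lam_bad = yield_rate * r_bad / (1.0 - r_bad) if r_bad < 1 else 0.0
            n_bad = rng.poisson(lam_bad)
            for _ in range(n_bad):
                side, pep = pool[int(rng.integers(len(pool)))]
                is_decoy = side == "d"
                src = decoy_index if is_decoy else index
                pid = sorted(src.by_peptide[pep])[0]
                entry = next(e for e in src.entries[pid] if e[0] == pep)
                emit(entry, False, is_decoy, spec_counter)
                spec_counter += 1

            run_rows.append(
                {
                    "run_id": run_id,
                    "sample_id": s,
                    "group": row.group,
                    "n_spectra": n_spectra,
                }
            )
            total_psms = n_good + n_bad
            cohort.truth.correct_psm_fraction[run_id] = (
                n_good / total_psms if total_psms else float("nan")
            )

    from .psm import PSM_COLUMNS

    psms = pd.DataFrame(psm_rows, columns=PSM_COLUMNS)
    run_meta = pd.DataFrame(run_rows)
    return psms, run_meta


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same cohort with every planted effect set to 1.0 (global null)."""
    return replace(
        spec,
        depletion={},
        planted_diff_clusters=(),
        planted_module_effects=(),
    )
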