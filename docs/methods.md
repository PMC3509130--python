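# Methods

This note documents the models, parameters and numerical choices behind the
package, and what the synthetic cohorts do and do not establish about real
data.

## Pipeline model and assumptions

The analysis treats label-free spectral counts as the abundance proxy: the
number of accepted MS/MS spectra attributed to a feature, scaled per run by
α_i = N/n_i with n_i the run's *acquired* MS/MS total (not the accepted
subset) and N the cohort mean of the n_i. Scaling is linear, so aggregation
views (COG, KO, genus, module) commute with normalization, and doubling every
n_i changes nothing.

Assumptions worth naming:

- **Runs are the statistical unit.** Technical duplicate runs enter the
  Wilcoxon tests as separate observations. Duplicates of one sample share
  that subject's protein levels, so run-level tests are anti-conservative in
  the presence of strong interpersonal variation; the median-difference gate
  (|Δmedian| > 5) absorbs much of this in practice.
- **Unique attribution.** A spectrum counts for a cluster/genus/KO only when
  all proteins matching its peptide agree on that feature. This discards
  shared-peptide evidence (conservative for closely related genomes) and is
  what makes strain-collapsed clusters the natural quantification unit.
- **Peptide-level FDR.** The concatenated target–decoy estimator 2D/(T+D) is
  computed on the spectrum-filtered PSM set. It estimates the incorrect
  fraction among all accepted PSMs of the concatenated search, which is what
  the calibration experiment verifies. It is *not* applied after the
  ≥2-peptide protein gate: on a desk-scale proteome most target proteins are
  identified anyway, so incorrect target matches frequently land on retained
  proteins while decoy matches almost never accumulate two peptides — the
  gate is asymmetric between halves in a way it is not on a realistically
  large database. D/T is available (`estimator="dt"`) for target-list FDR.

## Sequence comparison

All identity computations share one scoring scheme: Smith–Waterman local
alignment, BLOSUM62, gap open −11 / extend −1 (constants in `seqdb`).
Percent identity is identities over alignment columns (gaps included);
coverage is the aligned span over the shorter sequence (over the read, for
taxonomy). A BLAST-like seeding step (≥2 shared 5-mers) prunes hopeless
pairs before alignment; a minimum alignment length of 30 residues replaces a
database-size-dependent e-value gate. The toy fixture uses
`min_aln_len=10` because its hand-checkable sequences are 32–40-mers.

MCL follows standard practice where the clustering itself is concerned:
edge weights are percent identities, self-loops at each node's maximum
incident weight, expansion power 2, elementwise inflation (default 1.5)
with renormalization, pruning of entries below 1e-8, convergence when the
matrix changes by less than 1e-8 (200-iteration cap, error on
non-convergence). Nodes attracted by several attractors go to the largest
flow, ties to the smallest cluster id; representatives are the longest
member, ties broken lexicographically. Output is deterministic and always a
partition (isolated nodes become singletons).

Statistical engines are delegated where a standard tool exists: Wilcoxon
through `scipy.stats.mannwhitneyu` (exact when the pooled sample is ≤12 and
tie-free, mid-rank normal approximation with tie correction otherwise; two
identical groups short-circuit to p = 1), Benjamini–Hochberg through
statsmodels, OLS prediction intervals through statsmodels. Storey q-values
are computed in-package: π̂₀ = #{p > λ}/((1−λ)m) at λ = 0.5 clamped to
[1/m, 1], step-down minimum of π̂₀·m·p_(j)/j. With π̂₀ forced to 1 this is
exactly BH, which the tests assert to 1e-12.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
mass spectra: reference proteomes for up to 12 named gut genera (random
sequences under a loosely natural amino-acid composition), cross-genus
paralog families conserving one tryptic peptide exactly (6% divergence
elsewhere), optional strain variants, per-subject genus abundances
(log-normal cohort means × log-normal subject noise, renormalized to
proportions), per-sample read ORFs (mutated reference copies, multinomial in
abundance, chunked into same-genus pseudo-contigs), and PSM tables from an
in-silico tryptic digest.

Key defaults (one value per scientific choice; all configurable on
`CohortSpec`):

| parameter | default | rationale |
|---|---|---|
| groups | H:4, ICD:6, CCD:2 subjects × 2 runs | the cohort shape of a twin-pair stool study |
| depletion | Faecalibacterium 0.2×, Roseburia 0.25× in ICD | Firmicutes-like disease signal |
| spectra per run | mean 3000, cv 0.15 (Normal, floor 50) | desk-scale version of deep 2D-LC-MS/MS runs |
| identification rate | 0.5 | only a fraction of acquired spectra yield PSMs; keeps n_i (acquired) distinct from identified counts |
| strain mutation rate | 0.02/residue | reads sit ~98% identical to their reference |
| genus / subject / detectability σ (log) | 1.0 / 0.25 / 0.5 | heavy-tailed profiles, moderate interpersonal and per-protein variation |
| XCorr models | correct 1.5 + Γ(3.5, 0.6); incorrect Γ(2.5, 0.6) | overlap makes the charge thresholds informative |
| ppm errors | correct N(0, 3); incorrect U(−50, 50) | makes the ±10 ppm window selective (~20% of random matches pass) |
| decoy_hit_rate | 0.10 | fraction of emitted PSMs that are random matches against the concatenated target+decoy digest |

Correct-PSM counts per protein are **independent Poisson draws** with rate
acquired × identification_rate × weight, where the weight is genus abundance
× per-protein detectability (normalized) and planted cluster/module fold
changes multiply the rate *after* normalization. Two consequences: planted
depletion does not artificially inflate the remaining features (no fixed-sum
redistribution — realistic, because most acquired spectra are unidentified
and absorb the difference), and n_i stays an instrument-side quantity.
Genus-level depletion, by contrast, acts through the renormalized abundance
proportions, which is the compositional behavior relative abundances really
have. Incorrect matches draw peptides uniformly from the concatenated
target+decoy digest (full sequence reversals), so they land in either half
with near-equal probability — the premise of the 2D/(T+D) estimator. All
randomness flows from the single spec seed through spawned generator
streams; outputs are byte-reproducible.

What the generator does **not** model: chromatography/retention time,
isotope envelopes and raw spectra; semi-tryptic or modified peptides;
correlated peptide detectability; read fragmentation (ORFs are full-length
mutated copies); nucleotide-space assembly. Passing tests therefore show the
*statistical machinery* is calibrated under the stated generative
assumptions — not that a real cohort of this size would have the same power.

## Experiment scenarios (frozen in `experiments.py`)

- **Recovery**: 6 genera × 8 proteins, 4 H vs 6 ICD independent runs
  (one run per subject, reading the "4-vs-6 runs" design as independent
  observations), 250 reads/sample so every protein is represented, 2400
  acquired spectra/run putting every cluster's baseline near 20 counts,
  genus and detectability σ = 0 to pin that baseline, subject σ = 0.25;
  10 clusters planted at 0.2×. Scored: sensitivity and false-discovery
  proportion of the significant set, median over seeds.
- **Null calibration**: the same scenario with no planted effects.
- **FDR calibration**: one subject, two runs of ~10,000 emitted PSMs, 20%
  random matches; the pooled 2D/(T+D) estimate is compared with the known
  random-match fraction among accepted PSMs.
- **Deviation**: 6 genera × 12 proteins (3 four-KO modules per genus),
  genus shifts 0.4× / 0.7× / 1.6× in ICD spreading the expected-shift axis,
  one module planted at a further 0.25× (4-fold beyond its genus). 18
  (genus, module) points per cohort; the planted point must fall outside the
  95% prediction interval.
- **Interval calibration**: OLS prediction intervals on simulated Gaussian
  linear panels. In-sample prediction intervals are mildly conservative
  (leverage and t-quantiles), so the observed outside rate sits slightly
  below 1−level; panels of 100 points keep it within one panel's binomial
  error of the nominal 5%.

Problem sizes were chosen so the full battery (tests plus acceptance script)
completes in minutes on a single CPU; they are stated here as the package's
study conditions.

## Numerical details and edge cases

- Redundancy removal is exact substring containment (100% identity over 100%
  of the shorter), keeps the longer sequence, lexicographically smaller id on
  ties; idempotent.
- Filter boundaries are inclusive ("at least"): XCorr 2.50 at 2+ passes,
  2.49 fails; ppm +10.0 passes, +10.1 fails; deltCN ≥ 0.0 is a
  non-negativity gate only. Unknown charge states above the table use the
  highest-charge threshold. PSMs with missing flanking residues are rejected
  and counted as warnings.
- Prefilter is strict (>5 counts) over the pooled runs of the two groups
  (per-group gating available); groups need ≥2 runs.
- Degenerate inputs raise typed errors: empty module definitions, all-equal
  expected fold changes (deviation fit), <3 deviation points, iterations <1
  (rarefaction), zero-spectra runs.
- Module FDR defaults to 10% with the 5% variant one config switch away
  (`module_fdr`); both thresholds appear in the run manifest. Log2 fold
  changes use a pseudo-count of 1 on group medians.
- Rarefaction subsamples without replacement via multivariate
  hypergeometric draws; equal-depth samples reproduce raw proportions
  exactly.

## Known limitations

- Genus-rank taxonomy only; no taxonomy-tree traversal above genus.
- The identity machinery is protein-space; nucleotide-level contig alignment
  is out of scope.
- The Wilcoxon/Storey machinery ignores twin pairing and duplicate-run
  correlation by design (rank tests on runs, as in the analysis it
  implements); a mixed-model or paired variant would be a methodological
  extension, not a bug fix.
- Spectral-count FDR, attribution and normalization are exact re-creations
  of the described procedure; where the procedure itself is known to be
  conservative (unique attribution) or anti-conservative (duplicate runs),
  the package reproduces that behavior rather than correcting it.
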