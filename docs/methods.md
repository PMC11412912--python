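# Methods

This note documents the models, conventions and numerical choices
behind `synprot`, in the order the pipeline applies them, together with
what the synthetic-data generator does and does not emulate.

## Quantification model

Peptide tables hold one row per (peptide, protein-assignment) with one
reporter-ion intensity column per TMT channel.  Protein quantities are
obtained by summing member-peptide intensities per channel.  Peptides
shared between accessions (delimiter `;`) contribute to **every**
listed accession; no razor-peptide assignment is attempted, so protein
lists include subset proteins.

Channel normalization divides each channel by the median summed
intensity of a user-supplied reference set of cytosolic/ER proteins —
proteins whose true abundance should not depend on which probe or
sample occupies the channel — and then multiplies by the grand mean of
the per-channel factors.  The rescale is our own convention: only
cross-channel comparability is required, and keeping the output on the
input's order of magnitude makes tables easier to read.  Median uses
the midpoint convention for even counts.  The operation is idempotent,
and after it the reference median is identical in every channel.

Compositional phosphopeptide renormalization maps each peptide's
intensity to `x_i / Σ_j x_j × 2,000,000` per channel, with missing
values treated as zero.  A channel whose peptides are all zero stays
all-zero rather than raising, since zero-filled missing data make
empty channels legal.

## Differential testing

*Protein level.*  Welch's unequal-variance *t*-test, one-tailed.  The
direction convention is configurable: `greater`/`less` fix the tested
direction; `auto` (the default used for screening) tests in the
direction of the observed mean difference.  `auto` is anticonservative
under the null — its p-values concentrate below 0.5 — so all
calibration work uses a fixed direction.  Fold change is the plain
ratio of group means.

*Isoform level.*  Two-way ANOVA with factors Genotype and Peptide and
their interaction, fitted on natural-log intensities because
reporter-ion noise is multiplicative (log-normal noise becomes exactly
normal on the log scale, so the F null distribution is exact in the
simulated setting).  For balanced complete designs — the default in
both simulation and practice, where every channel quantifies every
peptide — the classical closed-form decomposition is used; it is
algebraically identical to Type-II sums of squares in that case and
roughly two orders of magnitude faster than a formula-interface OLS
fit, which matters for calibration studies with thousands of
replicates.  Unbalanced designs fall back to an OLS fit with Type-II
ANOVA (statsmodels), and the unit tests assert the two paths agree to
floating precision on balanced inputs.  A protein with a single
quantified peptide has no interaction contrast and is flagged
not-assessable instead of receiving a p-value.

A protein is called isoform-divergent when the Genotype × Peptide
interaction p-value falls below alpha.  Raw p-values are reported
(mirroring common supplementary-table practice); Benjamini–Hochberg
columns are appended for convenience but play no role in the flags.

*Fold profiles and heteroscedasticity.*  `peptide_fold_profile`
returns per-peptide group-mean ratios, the variance of their logs, and
normal Q–Q pairs of the standardized log folds.  The variance of
per-peptide log folds is the quantity that blows up when a peptide
subset is silenced in one group (a bimodal fold distribution) — that
location-heterogeneity is what the isoform interaction tests.  The
additional Brown–Forsythe (median-centered Levene) p-value is a
*scale*-homogeneity summary across peptides of the within-cell
residuals; it is an artifact-added convenience diagnostic, deliberately
separate from the divergence call.

*Fisher's exact test* uses the two-sided hypergeometric convention;
the all-zero table returns p = 1 by definition.

## Postsynaptic library

Training-set assembly follows three set-algebra rules: genes curated
both pre- and postsynaptic are postsynaptic; the exclusively
presynaptic set is subtracted from the broad postsynaptic database;
the cleaned broad set is unioned with the curated postsynaptic set.
The negative class is not dictated by any single source, so we define
it as exclusively-presynaptic ∪ non-synaptic-membrane ∪ cytosolic/ER
genes — mirroring the two contaminant categories against which library
FDR is reported.  When a quantified-gene universe is supplied, zero
overlap with the training genes raises an identifier-namespace error
(e.g. Ensembl IDs against gene symbols).

Features per protein: spectral count, sequence coverage (interval
union of peptide matches), average molecular weight, isoelectric point
(Henderson–Hasselbalch bisection via Biopython), log₁₀(total
intensity / length), pre/cyto and post/cyto fold, and the three
normalized probe-channel intensities.  Proteins need ≥2 quantified
peptides; among isoform accessions of one gene only the
highest-total-intensity accession is kept (ties break
lexicographically).

The classifier is a random forest (500 trees, √p features per split,
fixed seed) — robust defaults in the absence of any reason to tune.
Labeled rows are scored out-of-fold (stratified 5-fold) so ROC curves
are leakage-free; unlabeled rows are scored by a forest fit on all
labeled rows.  The default call threshold is 0.5, and library
inclusion requires a positive call in ≥2 independent experiments.
Library FDRs are simple annotated-contaminant fractions of the
included set; with real database snapshots and deep MS data these land
in the low percent range, but their value here depends entirely on the
synthetic contamination level, so they are a reporting format, not a
target.

## Proteoform fingerprinting

Gene models carry ordered exons with in-frame amino-acid segments;
isoforms are ordered exon sublists, optionally prefixed by an
alternative N-terminal segment (AST) whose residues carry a dedicated
label.  No nucleotide-level splicing is modeled.

Digestion is fully tryptic with zero missed cleavages: cleave
C-terminal to K/R, by default **without** the "not before proline"
exception (search engines differ; a config switch enables the proline
rule).  Retained peptides are 8–35 aa inclusive — the window outside
which peptides are rarely observed.  Pre-filter fragments concatenate
exactly to the input, and the digestion is cross-checked in tests
against an independent enumerator and against `pyteomics.parser`.

Molecular weight is the sum of average residue masses plus one water,
reported in kDa; it is additive up to one water and agrees with
Biopython's average-mass computation to <0.01%.  Gel-slice gating
keeps isoforms whose theoretical MW falls inside the slice's
user-supplied kDa window (closed interval); cut points are
configuration because real slices are cut against a protein ladder.

Each detected peptide is one detection event for its label: the single
covering exon, the junction `A & B` for a peptide spanning two
adjacent exons, or a chained `A & B & C` for three or more (the
two-exon junction is the canonical case; chaining keeps the
denominator well-defined).  Detection events are counted at the
peptide level — unique peptide occurrences, not spectral counts —
because peptide-level counts are stable across acquisition settings; a
spectral-count mode can be had by passing each occurrence repeatedly.
The frequency of every label is its event count divided by the total
event count over all exon/AST **and** junction labels; this single
shared denominator is the only reading under which the frequencies of
a table sum to 1, and that unit-sum invariant is property-tested to
1e-12.

Standards are the frequency tables of each translatable isoform's
complete theoretical retained peptide set (each theoretical peptide
counted once).  Assignment union-aligns the observed table with all
standards (missing labels zero-filled) and ranks standards by
Euclidean distance, ties broken by name — fully deterministic.  A
t-SNE layout (fixed seed, perplexity = min(5, n−1)) can be attached
for visualization, but the assignment never depends on it: t-SNE
distances are not metric-faithful.

## Morphometry rules

Spine classification, precedence mushroom → stubby → thin/filopodia:
mushroom = distinct head wider than 0.5 µm or more than twice the neck
width (head-based, regardless of length, hence first); stubby = length
≤ 0.5 µm with an indistinct head; thin/filopodia = length > 0.5 µm
with head absent or narrower than 0.5 µm.  "Indistinct head" is
encoded as an absent head width.  A 0.5 µm-long spine with a head
exactly 0.5 µm wide satisfies no rule and is returned as
`unclassified` rather than silently assigned.  Particle localization
reports integer-rounded percentages (cleft vs intra-spine) alongside
exact fractions.

## Synthetic data: what it emulates and what it does not

Channel intensities are baseline × protein group fold × peptide-subset
fold × multiplicative log-normal noise (noise parameterized by a
coefficient of variation; the log-normal is mean-corrected so the
noise has unit mean).  Defaults reflect the emulated designs: 5
biological replicates per group for two-group 10-plex comparisons,
three-channel probe designs for classifier features, and a default
`noise_cv` of 0.2 — the replicate variance structure is not something
one can read off published summary figures, so the CV is a free,
surfaced parameter and 20% is a realistic inter-replicate spread for
in-vivo TMT material.  Genotypes are expressed as exon deletions
applied to gene models: peptides that no surviving isoform of a
group's genotype encodes drop to a floor of 1e-3 × baseline — small
but positive, so downstream log/ratio math stays defined.  Generated
sequences use the 20 standard amino acids only (no B/Z/X, keeping MW
and digestion exact) with K/R placed at an average rate of one per 15
residues so tryptic fragments mostly fall inside, but meaningfully
exercise, the 8–35 retention window.

The generator does **not** simulate spectra, retention time, peptide
detectability bias, interference/ratio compression, search-engine
scoring, or missing-value structure beyond all-or-nothing dropout in
the proteoform detection simulator.  Passing tests therefore
demonstrate correctness of the statistical and combinatorial machinery
under the stated noise model, not robustness to instrument-level
artifacts.

## Problem sizes and determinism

The shipped verification suite runs at desk scale: 2000 null
replicates for test calibration, 500 for interaction power, 100
dropout replicates for proteoform recovery, 200 proteins per class for
classifier checks, ~10⁴-row tables for I/O round-trips.  All
randomness flows from explicit integer seeds (the pipeline uses one
config seed; the acceptance script derives independent substreams from
its `--seed`), and two runs with identical configuration produce
byte-identical TSV outputs — floating-point text serialization uses
round-trip precision on read.

## Known limitations

* The isoform-level ANOVA treats channels as independent replicates;
  plex-level batch structure is not modeled.
* Shared-peptide handling is inclusive, which can double-count signal
  across homologous accessions; razor logic is deliberately absent.
* The one-tailed `auto` direction is a screening convenience and not a
  calibrated test; use fixed directions for inference.
* Proteoform assignment assumes the candidate isoform set is complete;
  an unmodeled isoform is assigned to its nearest modeled neighbor
  with no novelty detection.
* pI and MW ignore post-translational modifications.
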