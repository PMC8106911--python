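# Methods

## Model

Lifestyle prediction is a binary classification over a fixed ordered set of
lysogeny-associated conserved protein domains. For a genome *g* with
translation products *T(g)* and domain set *D = (d₁ … d_p)*, the feature
vector is xⱼ = 1 iff some product in *T(g)* hits profile dⱼ with
full-sequence E-value ≤ τ (default τ = 10⁻⁵). A random forest
*f: {0,1}ᵖ → [0,1]* estimates P(temperate | x) as the mean vote of its
trees. The call is temperate iff P(temperate) > 0.5; an exact tie is
resolved to virulent, encoding the prior that a complete genome lacking
positive lysogeny evidence is assumed virulent. Calls with max class
probability ≥ 0.95 (inclusive) are flagged high-confidence.

### Assumptions

- The input is a **complete** genome. Missing sequence can only remove
  domain evidence, so incompleteness biases calls toward virulent; the CLI
  warns about this on every run.
- Lifestyle is binary. Chronic/carrier states and defective prophages are
  outside the model.
- Domain presence is a 0/1 property of the whole genome; copy number,
  domain order and synteny are deliberately ignored.

## Six-frame translation

Products are maximal stop-free codon runs, not ORFs: no start-codon model
is applied because domain search needs amino-acid content, not gene
boundaries. The standard genetic code is used (identical to the bacterial
code for internal codons; start-codon differences are irrelevant to
stop-delimited runs). Codons containing any non-ACGT base translate to `X`
and never terminate a run — an ambiguous base therefore cannot split a
product, only blur it. Trailing partial codons are dropped. The length
threshold is inclusive (≥ 40 residues). Coordinates are 0-based on the
strand of the frame and are verified by a re-translation round-trip
property test.

## Domain search

The search backend is pluggable. The production backend runs HMMER3
in-process through pyhmmer; an external `hmmsearch --tblout` run can be
substituted by parsing its per-target table, and an exact-substring motif
backend serves the offline fixtures. Presence is decided on the
**full-sequence E-value** (not the per-domain conditional E-value) with
threshold 10⁻⁵ — the simplest defensible notion of "the domain occurs in
this genome"; both the statistic and the threshold are configuration knobs,
since no canonical value exists for this task. Hits referencing accessions
outside the model's domain set are dropped with a warning. Multi-record
FASTA input is treated per-record by default; `whole_file` mode unions
detections across records for multi-contig single genomes.

## Domain selection

Candidate domains are screened by their free-text descriptions using six
case-insensitive substrings (integrase, excisionase, recombinase,
transposase, lysogen, temperate) plus one case-sensitive pattern
`parA |ParA |parB |ParB ` whose alternatives keep their trailing space:
"par" is a fragment of many ordinary English and biological words, so only
exact gene-name forms are accepted. On the **training split only**, a
domain is then removed if it is present in fewer than 3 training genomes
(counting both classes), or if its prevalence *fraction* among virulent
genomes strictly exceeds that among temperate genomes. Fractions rather
than raw counts are compared because the class sizes are unequal; equal
fractions retain the domain. The two rules commute, so their order is
immaterial (asserted by an idempotence test).

## Training protocol

The labeled dataset is split 60:40 (train n = round(0.6·N), test the
remainder; 1,057 genomes give 634/423) by a uniform, non-stratified random
permutation. The test partition carries a `test` tag and every
model-development operation refuses it, so test leakage is a raised
exception rather than a convention. Within the training set, 20 random
75:25 train/validation resplits are drawn once (deterministically from the
seed) and shared by all hyperparameter combinations. The grid spans
bootstrap {True, False}, class_weight {balanced, balanced_subsample},
min_samples_leaf {1, 2}, n_estimators 10–100 in steps of 5 (19 values) and
max_depth 10–40 in steps of 2 (16 values): 2,432 combinations, enumerated
in that fixed order with the rightmost field varying fastest. The selected
combination maximizes the **minimum** validation accuracy across the 20
resplits — a conservative rule preferring settings that never perform
badly — with ties broken by higher mean accuracy, then by enumeration
order; per-resplit F1 (temperate-positive) is recorded alongside for
inspection but does not drive selection. The winner is refit on the full
training set. The final default configuration is bootstrap = False,
class_weight = balanced_subsample, min_samples_leaf = 1, n_estimators = 80,
max_depth = 40. The resplit ratio (75:25) and non-stratified splitting are
package choices where no canonical values exist; both are exposed on
`SplitSpec`.

## Evaluation metrics

All scores are derived from the 2×2 confusion matrix (rows true, columns
predicted, order virulent/temperate): accuracy = trace/n; adjusted balanced
accuracy = (mean of the two per-class recalls − 0.5)/0.5, so random
guessing scores 0; F1 with **temperate as the positive class** — the
convention under which published scores of domain-based lifestyle
classifiers are recovered from their printed matrices; and MCC by the
standard formula with the zero-marginal convention MCC = 0. An independent
oracle test recomputes all four from expanded per-sample label lists with
scikit-learn on 100 randomized instances. Table values are compared at
3 decimal places and percentages at 1 decimal, the precision at which such
results are conventionally printed. Confidence stratification recomputes
stratum membership from the stored probabilities, so any threshold
(including the degenerate 0) can be probed.

## Independence filter

To measure performance free of phylogenetic replication, test genomes with
a close training relative are excluded, where *related* means estimated
identity > 0.8 AND aligned coverage > 0.8 (both strict). Similarity is
estimated from canonical k-mer containment (k = 16): coverage is the
shared fraction of the smaller genome's distinct canonical k-mer set, and
identity is recovered as containment^(1/k). Canonical k-mers make the
estimate strand-insensitive; measuring coverage against the shorter genome
makes the asymmetric case explicit. This estimator is a defined,
dependency-free stand-in for alignment-based ANI: it agrees with an exact
edit-distance identity on calls far from the threshold (tested), but
near-threshold parity with alignment tools is not claimed — a precomputed
pairwise table can be supplied to use external ANI values instead.
Exclusion is single-linkage: one related training genome suffices.

## Synthetic fixtures

The generator emulates the pipeline's real inputs offline. Each synthetic
domain is a unique random 45-residue motif reverse-translated (random
synonymous codons) into a 135-nt stop-free insert; temperate genomes
receive a fixed number of distinct markers at random non-overlapping
positions on random strands, virulent genomes receive each marker with
probability `leak_rate` (default 0). Background sequence is seeded-random
A/C/G/T, and generation verifies that each finished genome's six-frame
products contain exactly the intended motifs, regenerating on the (rare)
collision. Because markers are stop-free by construction, the exact-motif
backend and a profile-HMM backend built from single-sequence profiles of
the same motifs must agree — this is the surface on which backend
equivalence (motif vs pyhmmer vs tblout parsing) is tested.

Default study conditions: 20 + 20 genomes of 2,000 nt, 6 domains, 3
markers per temperate genome, leak 0 — large enough that a 60:40 split
leaves both classes on both sides and the noiseless problem is perfectly
separable, small enough that the full suite runs in seconds. The golden
case fixes the seed and bundles a model trained on a disjoint 50-genome
set, giving hand-checkable expected vectors and calls derived from the
construction bookkeeping rather than from the code path under test.

What the fixtures do **not** emulate: realistic phage genome composition,
gene content, domain sequence divergence (fixture hits are exact),
mis-annotated labels, incomplete genomes, or phylogenetic structure.
Passing the synthetic end-to-end test therefore demonstrates that the
machinery is correct (translation, search, vectorization, split hygiene,
training, persistence), not that real-genome accuracy will match the
noiseless 100 %; real-data accuracy depends on the domain database and
labeled corpus supplied by the user.

## Numerical and degenerate-input choices

- Empty or all-ambiguous sequences yield empty product lists, not errors;
  characters outside the IUPAC DNA alphabet raise with position. RNA (`U`)
  input is rejected by design.
- Probabilities sum to 1 by construction (vote shares); the prediction
  table prints them at 4 decimal places.
- Model files embed a format-version string; loading any other version, a
  truncated file, or a non-model file raises a clear error instead of
  mispredicting.
- Feature-importance tables sort descending with a stable tie-break
  (original column order) and carry a cumulative-share column; with an
  all-zero importance vector the share column is NaN rather than a
  division error.
- Seeds: every stochastic component (splits, resplits, forest, fixture
  generation) takes an explicit seed; resplit child seeds are derived
  arithmetically from the parent seed and kept below 2³¹.

## Known limitations

- The keyword screen is text-matching over description fields; domains with
  unhelpful descriptions are invisible to it.
- The k-mer independence filter is an estimator, not an aligner; near the
  80 % thresholds its calls can differ from FastANI/CD-HIT-style tools.
- Per-domain E-value thresholding uses the full-sequence statistic; tools
  that threshold on domain-conditional E-values may disagree on marginal
  hits.
- Training assumes the label corpus is ground truth; label noise propagates
  directly into the model.
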