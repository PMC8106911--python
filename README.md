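# lysotyper

Bacteriophages follow one of two broad lifestyles: **temperate** phages can
enter a latent (lysogenic) phase inside their host, while **virulent**
phages replicate and lyse the host immediately. Knowing the lifestyle of a
phage from its genome alone matters for phage therapy candidate selection,
for interpreting metagenomes, and for understanding phage–host coevolution —
but experimental determination is slow, and most sequenced phages have no
lifestyle annotation.

`lysotyper` predicts the lifestyle of a phage from its nucleotide sequence.
The model is deliberately interpretable: lysogeny requires specific
machinery (integrases, excisionases, recombinases, transposases,
partitioning proteins, …), so the genome is scanned for a fixed ordered set
of lysogeny-associated conserved protein domains, and the resulting binary
presence/absence vector **x** ∈ {0,1}ᵖ is fed to a random-forest classifier
that outputs P(temperate | x) and P(virulent | x). The input genome is
assumed complete and virulent a priori; only positive domain evidence can
override that assumption (a probability tie is therefore called virulent).

The pipeline:

1. **Six-frame translation** — every maximal stop-free codon run of ≥ 40
   amino acids, in all three frames of both strands (standard genetic code;
   ambiguous codons translate to `X`, never to a stop).
2. **Domain search** — HMMER3 profile-HMM search (in-process via pyhmmer,
   or by parsing external `hmmsearch --tblout` output) over the translation
   products; a domain is *present* when any product hits it with
   full-sequence E-value ≤ 10⁻⁵.
3. **Classification** — random forest (scikit-learn) over the
   presence/absence vector; calls with max probability ≥ 0.95 are flagged
   high-confidence.

Beyond prediction, the package ships the full model-development and
evaluation machinery: keyword + training-set-prevalence domain selection,
the 60:40 train/test split, hyperparameter grid evaluation over 20
train/validation resplits with *max-min accuracy* selection, confusion-matrix
metrics (accuracy, adjusted balanced accuracy, MCC, F1 with temperate as
the positive class), confidence-stratified error analysis, a k-mer
containment filter for building phylogenetically independent test subsets
(> 80 % identity over > 80 % of the genome defines "related"), and a
deterministic synthetic-fixture generator so everything is testable offline.

## Worked example

The bundled golden fixture is a deterministic 10-genome case (5 temperate
genomes carrying three embedded lysogeny-domain markers each, 5 virulent
genomes carrying none) with a model trained on a disjoint 50-genome set:

```bash
python - <<'EOF'
from lysotyper import synthetic, classifier
case = synthetic.golden_pipeline_case()
case.write_fixtures("fixtures")
classifier.save_model(case.model, "fixtures/model.joblib")
EOF

lysotyper predict fixtures/genomes.fasta \
    --model fixtures/model.joblib \
    --motif-table fixtures/motifs.tsv \
    --output-dir out
head -6 out/genomes.fasta.predictions.tsv
```

prints

```
genome_id	p_virulent	p_temperate	call	confident
T025	0.0000	1.0000	temperate	True
T026	0.0000	1.0000	temperate	True
T027	0.0000	1.0000	temperate	True
T028	0.0000	1.0000	temperate	True
T029	0.0000	1.0000	temperate	True
```

Each row is one genome: the two class probabilities (forest vote shares),
the lifestyle call (temperate iff p_temperate > 0.5), and whether the call
clears the 0.95 confidence threshold. The five virulent genomes (`V025`…)
follow with `p_virulent = 1.0000`. On real genomes use `--hmm-db` with a
profile-HMM database instead of the fixture `--motif-table`, and heed the
logged warning: fragmented or incomplete genomes can hide lysogeny
machinery and bias calls toward virulent.

`lysotyper train` runs the full protocol (split → grid → max-min selection →
refit → held-out report) and `lysotyper evaluate` scores a prediction table
against labels, writing the confusion matrix, metric report, and
confidence-stratified error table.

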