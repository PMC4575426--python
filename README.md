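# tcspred

Meta-prediction of histidine kinase / response regulator pairings in
prokaryotic two-component systems.

## The problem

Two-component systems (TCS) are the dominant signalling pathways of
prokaryotes: a sensor **histidine kinase (HK)** autophosphorylates on a
His residue in response to a stimulus and transfers the phosphoryl group
to an Asp residue of its cognate **response regulator (RR)**.  The
pairing is highly specific, but most genomes encode dozens of HKs and
RRs, and many of the genes are not adjacent on the chromosome ("orphan"
HKs and RRs), so working out *which HK talks to which RR* from sequence
alone is hard — and experimentally expensive to resolve.

`tcspred` scores a candidate HK–RR pair with six independent
sequence-based interaction signals and fuses them with a support vector
machine:

| feature | signal |
|---------|--------|
| `i2h`   | in-silico two-hybrid: correlated (compensatory) mutations between the two proteins' alignment columns |
| `mt`    | mirror-tree: correlation of the two proteins' inter-species distance matrices (tree similarity) |
| `gf`    | gene fusion (Rosetta stone): some genome encodes the two proteins as one hybrid coding unit |
| `pp`    | phylogenetic profiling: mutual information between presence/absence patterns across reference genomes |
| `gn`    | gene neighbourhood: orthologs within 200 bp of each other |
| `go`    | gene operon: orthologs sharing a transcription unit |

The six scores form the feature vector
x = (s_i2h, s_MT, s_GF, s_PP, s_GN, s_GO) of an RBF-kernel SVM,
f(x) = Σᵢ αᵢ K(xᵢ, x) + b with K(u, v) = exp(−g‖u−v‖²).  The error cost
c and kernel width g are selected by grid search over the powers-of-two
lattice maximising mean k-fold cross-validated AUC; the minority
(interacting) class is up-weighted by the class ratio, since curated
data carries roughly ten non-interacting pairs per interacting one; and
decision values are min–max normalised to [0, 1] with bounds frozen at
training time.  Classifiers are assessed by sensitivity, specificity,
accuracy, MCC and ROC AUC, with a paired DeLong test for comparing two
ROC curves on the same examples.

Because the full-scale inputs (UniProtKB-scale alignments, hundreds of
reference genomes) cannot ship with a package, `tcspred` includes a
first-class synthetic-fixture generator that plants each signal —
coupled MSA columns, fused proteins, neighbouring genes, shared operons,
correlated presence/absence profiles — with a truth table, so every
stage of the pipeline is testable offline.

## Worked example

Generate a small fixture (4 interacting, 8 non-interacting pairs),
compute features, train and evaluate:

```sh
$ tcspred simulate demo --seed 11 --n-pos 4 --n-neg 8
fixture with 4+8 pairs written to demo
$ tcspred features --pairs demo/pairs.csv --msa-dir demo/msas \
      --genomes demo/genomes --out demo/features.csv
12 pairs scored -> demo/features.csv (0 with no feature at all)
$ tcspred train --features demo/features.csv --out demo/model.json --k 3 --seed 1
model c=0.03125 g=3.0517578125e-05 cv_auc=1.0000 -> demo/model.json
$ tcspred predict --model demo/model.json --features demo/features.csv \
      --out demo/scores.csv
$ head -4 demo/scores.csv
hk_id,rr_id,label,species,score
hkP00,rrP00,interacting,Synthspecies sp001,0.9974243295148961
hkP01,rrP01,interacting,Synthspecies sp001,1.0
hkP02,rrP02,interacting,Synthspecies sp001,0.9908718971715262
```

Interacting pairs score near 1 and non-interacting pairs near 0 (e.g.
`hkN11,rrN11,...,0.0244`): the planted signals separate the classes, so
3-fold cross-validation reports a pooled AUC of 1.0 and MCC of 1.0:

```sh
$ tcspred evaluate --features demo/features.csv --out demo/report.json --k 3 --seed 1
{
 "overall": {"n": 12, "pooled_auc": 1.0, "mean_fold_auc": 1.0,
             "sensitivity": 1.0, "specificity": 1.0,
             "accuracy": 1.0, "mcc": 1.0}
}
```

`tcspred ablate` sweeps leave-one-method-out models (the
feature-contribution protocol), and `tcspred compare-roc` runs the
paired DeLong test between two score files.

## Layout

- `src/tcspred/io_data.py` — MSAs, pair datasets, genome bundles,
  dataset splitting and train/test orthogonalisation
- `src/tcspred/coevolution.py` — i2h and mirror-tree scores
- `src/tcspred/genome_context.py` — local-alignment search backend and
  the GF/PP/GN/GO scores with 16S-distance-weighted aggregation
- `src/tcspred/meta_svm.py` — feature assembly, grid-searched
  class-weighted RBF-SVM, score normalisation
- `src/tcspred/evaluation.py` — confusion metrics, ROC/AUC, stratified
  k-fold CV, DeLong ROC comparison
- `src/tcspred/synthetic_fixtures.py` — seeded planted-signal generators
- `src/tcspred/cli.py` — the `tcspred` command

See `docs/methods.md` for the modelling choices and their rationale.
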