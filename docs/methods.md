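# Methods

This note records how each score is defined, the tunable parameters and
their defaults, what the synthetic generators do and do not emulate, and
the design decisions taken where the method family leaves room.

## Inputs and conventions

MSAs are aligned FASTA, one file per protein, with the source species
parsed from a trailing bracketed organism name in each header
(`>P0AE82 ... [Escherichia coli]`); the convention is a regex and can be
overridden.  The first record is the query.  Pair lists are CSV
(`hk_id, rr_id, label, species[, adjacent]`); labels are taken from the
input and never inferred.  Genome bundles are a JSON manifest plus, per
genome, a proteome FASTA, a five-column gene table
(`gene_id, start, end, strand, operon_id`; 1-based inclusive
coordinates, GFF3 convention) and a 16S rRNA FASTA.

Homolog lists feeding MSA construction can be filtered to an identity
window (default 30–95 %) with minimum query coverage (default 70 %):
near-identical homologs add no divergence signal and very remote ones
add alignment noise.

Two MSAs are matched on their common species.  At least 25 and at most
50 common species are used (both configurable): fewer gives correlation
estimates too noisy to trust, more dilutes diversity with redundancy.
Above the cap, the species whose rows are most identical to the
respective queries are kept (mean of the two percent identities; ties
broken lexicographically by species name, so selection is
deterministic).  A pair below the minimum has its coevolution features
recorded as *missing*, not zero signal.

## Coevolution scores

**In-silico two-hybrid (i2h).**  For each alignment column, a vector of
residue-pair similarities over all unordered sequence pairs is computed
from the McLachlan amino-acid similarity table (the table is pluggable;
any Biopython-shipped matrix or a labelled TSV can be named).  Entries
touching a gap are missing.  Columns are *variable* when they hold at
least two distinct non-gap residues with at most 50 % gaps; constant or
gappy columns carry no covariation signal and are skipped.  Every
inter-protein pair of variable columns is Pearson-correlated over the
shared non-missing entries, and the i2h score is the fraction of column
pairs with r ≥ 0.8.  Correlations over fewer than 10 shared entries, or
with a zero-variance side, are defined as 0 rather than NaN so
downstream feature vectors stay numeric.  The high-correlation fraction
was chosen as the score because the meta-layer only needs a monotone
interaction signal; it is symmetric in the two proteins and invariant to
row order.

**Mirror-tree (MT).**  Each protein's inter-species distance matrix is
the fractional-identity distance d = 1 − identical/compared over
columns where neither row is gapped — a cheap, deterministic proxy for
the phylogenetic tree that stays within the mirror-tree family without
inferring trees or fitting molecular clocks.  The MT score is the
Pearson correlation of the two matrices' upper triangles over the common
species.  A constant matrix (no divergence on one side) yields a
missing feature.

## Genome-context scores

**Search backend.**  Presence and ortholog calls use optimal local
alignment (Smith–Waterman with affine gaps, Biopython's pairwise
aligner; BLOSUM50, gap open 10, extend 2 — a run of L gap positions
costs 10 + 2(L−1)).  Significance uses a Karlin–Altschul-style model
E = K·m·n·exp(−λS) with the cutoff E ≤ 1e−5.  λ = 0.143 and K = 0.025
were calibrated by fitting a Gumbel distribution (moment matching) to
optimal local scores of random uniform-composition protein pairs under
this exact scheme; with them, the best random hit in a small synthetic
proteome sits around E ≈ 1e−3, two orders of magnitude above the
cutoff, while a true homolog of a 60-residue protein scores E ≈ 1e−21.
The parameters must be re-calibrated if the matrix or penalties change.
Tabular hit lists from an external search tool can be substituted for
the built-in scan.

**Gene fusion (GF).**  A genome provides evidence when a single protein
aligns significantly to *both* the HK and the RR and the two aligned
spans on that protein overlap by less than 20 % of the shorter span —
the overlap rule separates a genuine two-domain fusion from one shared
domain matched twice.

**Phylogenetic profiling (PP).**  Presence/absence profiles over the
reference genomes are compared by mutual information (base 2, 0·log 0
= 0).  The feature passes the MI through clamped to [0, 1] — graded
evidence for the SVM — but zeroes values below 0.35 bits, the
conventional evidence cutoff for profile comparison.  A constant profile
(present everywhere or nowhere) is uninformative and yields a missing
feature.  Note MI is large for anti-correlated profiles too; on real
data that is the desired behaviour for detecting functional linkage,
and the cutoff suppresses weak incidental dependence.

**Gene neighbourhood (GN) / gene operon (GO).**  In each reference
genome the HK and RR orthologs are located by best significant hit
(reciprocal-best-hit validation is available when the query proteome is
supplied).  GN evidence: intergenic gap ≤ 200 bp, strand-agnostic
(overlapping genes count as gap 0); GO evidence: identical operon ids,
with a missing call on either side conservatively counted as no
evidence.  Operon assignments are consumed as input, never predicted.
A genome lacking either ortholog — or where one fused unit absorbs
both — is *not evaluable* and excluded from aggregation.

**Aggregation.**  Per-genome evidence is combined as a weighted fraction
Σ w_g·1[evidence] / Σ w_g over evaluable genomes, with w = 1/(1+d) and
d the Jukes–Cantor-corrected 16S rRNA distance between reference and
target organism (d = −(3/4)·ln(1 − 4p/3) on the aligned proportion p of
differing sites; p ≥ 0.75 saturates the correction and is capped at
d = 5).  The weight is bounded, positive and decreasing in distance:
shared context in close relatives is weighted up.  Adding an evidence
genome never decreases a score; adding a no-evidence genome never
increases it.  No evaluable genome at all means the feature is missing.

## The SVM meta-layer

Features are assembled in the fixed order (i2h, MT, GF, PP, GN, GO).
A method that cannot produce evidence contributes 0 and sets a bit in a
missing mask; the mask is *not* part of the SVM input, keeping the
vector six-dimensional.  A pair with all six missing is rejected as
unpredictable.

Training selects (c, g) from the standard coarse powers-of-two lattice
(c ∈ 2⁻⁵…2¹⁵, g ∈ 2⁻¹⁵…2³, step 2²) by mean stratified k-fold CV AUC
(default k = 10); AUC is the criterion because it is threshold-free.
Ties go to the smaller c, then smaller g (less regularisation pressure,
smoother kernel).  The minority class is weighted by
N_majority/N_minority.  After refitting on all data the decision-value
range of the training set is frozen as (norm_min, norm_max); prediction
min–max scales into [0, 1] and clamps values outside the training
range.  Frozen bounds were chosen over per-batch normalisation so that
a stored model scores identically regardless of batch composition.  The
classification threshold on the normalised score is 0.5.  Models are
serialised as JSON holding (c, g, class weights, support vectors, dual
coefficients, intercept, normalisation bounds, seed, feature order);
the decision function is reproduced from these arrays, and training
asserts the reconstruction matches the fitted SVM.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN));
a zero denominator defines the metric as 0 with a degeneracy flag so
reports stay numeric.  ROC curves come from a threshold sweep over
unique scores with trapezoidal AUC (ties count one half, i.e. AUC =
P(s₊ > s₋) + ½P(s₊ = s₋)).  k-fold CV is stratified and deterministic
given a seed; per-fold models freeze their own normalisation bounds from
the training folds, and both the pooled-score AUC over all held-out
examples and the per-fold mean are reported, since the two conventions
differ slightly.  Within cross-validation, orthogonalisation utilities
can strip training pairs sharing a pair or a protein with the held-out
set.  Two ROC curves built from paired scores on the same examples are
compared with DeLong's test for correlated AUCs (midrank placements,
two-sided normal p); a degenerate variance returns p = 1 with a
warning.

## Synthetic fixtures

The generators produce the statistical structure each score assumes,
not biological realism:

* **Coupled MSAs** — per-column categorical drift over a private
  4-letter alphabet; a `coupling` fraction of column pairs shares the
  latent state and alphabet between the two proteins (lock-step
  mutation), with a 2 % per-site noise rate.  No tree shape, no indels,
  no rate heterogeneity: passing tests show the scores detect planted
  covariation, not that they handle real alignment pathologies.
* **Reference genomes** — random-composition background proteins
  (length 100 by default, far below any significance cutoff), with
  planted fusions (HK+RR concatenated as one protein), neighbouring
  genes (gap 150 bp by default), shared operons and explicit
  presence/absence patterns; 16S sequences diverge from a common base at
  1–20 % so aggregation weights vary.  Background intergenic gaps are
  drawn ≥ 250 bp so no neighbourhood evidence arises by accident.
* **Feature tables** — six-dimensional Gaussians with the positive
  class shifted by `class_separation` times (1.0, 0.5, 0.25, 0.25,
  0.25, 0.25): the coevolution slots dominate, i2h most of all, at the
  default 113:1134 class imbalance of curated TCS interaction data.
* **Gold-standard stand-in** — 113 interacting (56 neighbouring / 57
  orphan by construction of toy gene coordinates) and 1134
  non-interacting pairs across six model organisms with the per-species
  class ratios of curated species-specific testing sets.  It reproduces
  the *structure* of curated data, not its sequences.

All generators are bit-reproducible at a fixed seed.

Default problem sizes (30 species × 150 columns, 8 genomes × ~12
proteins, 100-replicate orderings at 25 species × 60 columns) were
chosen as the smallest at which every planted signal is recovered with
wide margin.

## Known limitations

* The e-value model is calibrated for the default scoring scheme and
  uniform-composition sequences; biased-composition proteomes would need
  re-calibration or an external search tool.
* The i2h high-correlation fraction is one of several indices in the
  correlated-mutation family; alternatives (mean inter-protein r,
  z-scored indices) would need their own thresholds.
* MT uses identity distances, not maximum-likelihood branch lengths;
  fast-evolving sites are not down-weighted.
* Ortholog resolution defaults to best significant hit; full reciprocal
  validation requires the query proteome and is slower.
* No probability calibration of SVM scores and no kernels beyond RBF;
  no bootstrap confidence intervals on AUC.
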