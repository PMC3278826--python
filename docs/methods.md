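# Methods

## Problem and model

γ-glutamyl carboxylation converts specific glutamate (E) residues into
γ-carboxyglutamate (Gla), a vitamin-K-dependent modification central to
coagulation factors and other Gla-domain proteins. `glapred` frames Gla-site
identification as binary classification of Glu-centered sequence windows: a
fragment of `2n+1` residues around each Glu is encoded as a numeric vector
and classified with an RBF-kernel support vector machine. Every Glu in a
carboxylated protein yields a training sample — annotated positions are
positives, all remaining Glu residues are negatives — so the class ratio of
the training data is whatever the annotation density produces (roughly 1:2
in both the curated reference data and the synthetic benchmark).

## Windows and homology reduction

Windows use half-width `n ∈ 4..10` (default `n = 7`, i.e. 15-mers, the
length at which a window sweep with the composition feature plateaus).
Terminal overhangs are padded with `'-'`, treated as the 21st alphabet
symbol; the pad never occurs at offset 0.

Redundancy is removed in two stages before training. Proteins with more
than 30% pairwise sequence similarity are flagged as homologous; among
fragments whose parents are homologous, any pair above 50% similarity is
collapsed to the first-encountered fragment. Similarity is defined as
identities divided by alignment length (gap columns included) on the best
local alignment under BLOSUM62 with affine gaps costing 11 + 1 per gap
residue (`Bio.Align.PairwiseAligner`, open −12 / extend −1 so that a
length-L gap costs 11 + L). Keep-first scanning makes reduction
deterministic and idempotent for a fixed input order; positive and negative
sets are reduced independently. Fragment padding is stripped before
aligning. Within-protein duplicates are never removed — the reduction is
strictly a between-homolog operation.

## Features

* **AA_PWM** — a positional weighted matrix holds, for each window offset,
  the frequency of each of the 21 symbols among the *positive training
  fragments only*; no pseudocounts. A fragment encodes as the `2n+1` vector
  of its own symbols' frequencies (symbols unseen in training encode to 0;
  `'X'` always encodes to 0). A flattened per-position one-hot variant
  (`pwm_encoding="onehot"`, `(2n+1)×21` columns) is available because the
  compact lookup reading is a design choice, but the lookup form is the
  default. During cross-validation the PWM is rebuilt from each training
  split, never from validation fragments.
* **AAC** — 20-vector of residue frequencies in the window; padding and
  `'X'` are excluded from both numerator and denominator.
* **ASA** — per-residue solvent-accessible surface area percent, divided by
  100 (the direct reading of "percentage normalized to zero to one"; no
  per-protein min–max). Padded positions contribute 0.
* **SS** — 3-state secondary structure, one-hot per position in the order
  (H, E, C); pad positions encode as 000.

Blocks concatenate in the fixed order AA_PWM, AAC, ASA, SS. All encodings
already lie in [0, 1], so no further rescaling is applied before the SVM.
For `n = 7` the best-performing selection AA_PWM+AAC+ASA spans
15 + 20 + 15 = 50 dimensions.

ASA values are ingested from a neutral 3-column TSV (id, 1-based position,
percent) rather than any predictor's native output; secondary structure
from PSIPRED VFORMAT `.ss2` files. The upstream predictors themselves are
consumed, not reimplemented.

## Classifier and evaluation

The SVM is scikit-learn's `SVC` with an RBF kernel. Defaults are cost 1 and
gamma 0.5 (on 50-dimensional [0, 1] features this sits in the flat middle
of the tuning surface); `grid_search` tunes (cost, gamma) over the libsvm
guide grid `2^-5..2^15 × 2^-15..2^3` by k-fold CV accuracy, breaking ties
toward the smaller cost then gamma so the result is order-invariant. No
class weighting by default (exposed as an option). The decision threshold
is fixed at 0; no probability calibration.

Cross-validation is stratified at the fragment level (k = 5), per-fold
predictions are pooled into a single confusion matrix, and the five metrics
— precision, sensitivity, specificity, accuracy, Matthews correlation
coefficient — are computed from the pooled counts. MCC is defined as 0 when
any denominator factor vanishes. Textual reports **truncate** to three
decimals rather than round; truncation is what reproduces published
worked-example tables of this kind (e.g. 0.89298 → 0.892). Protein-level
folding (`kfold_split_by_protein`) is available for the stricter protocol.
Independent testing refuses any protein id shared with the training set.

The published headline numbers on the curated UniProt/HPRD data are not
recomputable without re-curating that data; what the package reproduces
exactly is the metric arithmetic from the pooled confusion counts
(260/42/51/516 for CV and 50/10/18/81 for independent testing — the
published table's FP/FN row labels are internally inconsistent with the
stated class sizes, and these assignments are the unique ones consistent
with 302:567 and 60:99).

## Motif statistics

`frequency_matrix` gives per-offset residue frequencies (pad excluded, each
offset renormalized). `two_sample_diff` tests each (offset, residue) cell
with a pooled two-proportion z-test at α = 0.05 — the classic two-sample
logo statistic — reporting direction by the sign of the frequency
difference. No multiple-testing correction is applied by default, matching
the convention of two-sample logo tools; the α parameter is exposed.
`mean_asa_curve` averages ASA percent per offset (padding excluded);
`ss_fractions` tallies H/E/C at the central Glu.

## Synthetic benchmark

The generator (`glapred.synthetic`) draws datasets with the statistical
structure observed around real Gla sites, so each stage is testable without
downloads: 80 proteins of length 200–600 with 4 planted positive and 2
planted negative 15-mer windows each. Positive flanks enrich Glu
(probability 0.12 at offsets −7, −6, −4, −3, −1, +1, +3, +4, +6, +7,
depleted to 0.005 at ±2, background 0.02 elsewhere) and arginine (0.15 at
−7, −5, −4, −1, +3). ASA is normal with sd 8%, mean 37.8% at the site,
35% over the −7..−4 shoulder, dips to 22% at ±2, 30% elsewhere in positive
windows and 24%/25% for negative windows/background, clipped to [0, 100].
Site secondary structure is drawn with (H, E, C) = (0.426, 0.044, 0.53);
flanks and negatives use broader coil/helix mixes. Because every
non-annotated Glu becomes a negative fragment, the Glu-rich positive flanks
necessarily contribute incidental negatives; with these rates each protein
yields ≈9 negatives against 4 positives, near the ≈1:1.9 ratio of the
curated data. Effect sizes are deliberately strong so that recovery tests
(binomial/multinomial 3σ) and the end-to-end accuracy floor (>0.8) are
reliable at this scale.

What the generator does **not** emulate: residues are drawn independently
(no autocorrelation, no realistic secondary-structure runs, no homologous
families except the optional duplicated-protein injection used to exercise
the reduction stage), ASA and SS are independent of the sequence given the
window class, and the background composition is near-uniform rather than
natural. Passing tests therefore demonstrate that the pipeline recovers
planted signal of realistic magnitude and shape — not that the model
attains any particular performance on real proteomes.

## Numerical choices and edge cases

* Similarity of sequences whose best local alignment scores ≤ 0 is 0.
* Co-optimal alignments: the first optimal alignment reported by the
  aligner is used; tests accept any optimum's identities/length.
* A protein without Glu yields an empty fragment list (not an error); an
  all-pad window cannot arise from valid extraction.
* `kfold_split` uses stratified shuffled folds seeded explicitly; per-class
  fold sizes differ by at most one.
* Grid-search CV accuracy is computed on pooled fold predictions with the
  same fold partition for every candidate.
* Degenerate z-test cells (zero pooled variance or an empty side) get
  p = 1 and are never reported.

## Problem sizes

Default study sizes — 80 training proteins (~1100 fragments, 50-feature
vectors), 20 held-out proteins, k = 5 — were chosen to mirror the curated
data's scale (79 training / 14 independent proteins, 302:567 sites). The
statistical recovery tests use larger draws (250 proteins) where tighter
binomial bands require them.

## Known limitations

* The published tuned (cost, gamma) values are unknown; they can only be
  re-tuned, not reproduced.
* Protein-level ASA normalization and the exact two-sample logo statistic
  variant are undocumented upstream; the choices here (percent/100, pooled
  z-test) are the most direct readings and are exposed as parameters.
* The 30% protein-level similarity stage uses the same local-alignment
  similarity definition as the fragment stage; coverage-weighted
  alternatives are not implemented.
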