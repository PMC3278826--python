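# glapred

Prediction of γ-glutamyl carboxylation (Gla) sites on glutamate residues
from protein sequence and structure features.

γ-carboxyglutamate is produced by vitamin-K-dependent carboxylation of
specific Glu residues and is essential to coagulation factors and other
Gla-domain proteins. Experimentally verified sites are scarce, so
`glapred` provides the standard machine-learning treatment of the problem
for computational biologists: every Glu residue of a protein is represented
by a `2n+1`-residue window (default 15-mer, offsets −7..+7), encoded with

* **AA_PWM** — per-position frequencies from a positional weighted matrix
  built on the positive training fragments (21 symbols: 20 amino acids +
  terminal pad),
* **AAC** — amino-acid composition of the window,
* **ASA** — per-residue solvent-accessible surface area, percent / 100,
* **SS** — one-hot 3-state secondary structure (H/E/C),

and classified with an RBF-kernel SVM. Redundancy is removed before
training: proteins over 30% local-alignment similarity are homologous, and
fragments over 50% similarity between homologous proteins are collapsed.
Performance is estimated by stratified five-fold cross-validation (pooled
confusion counts) and an independent protein-disjoint test, reported as
precision, sensitivity, specificity, accuracy and the Matthews correlation
coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

The package also produces the motif statistics behind sequence-logo
analyses (per-position frequency matrices, two-proportion enrichment tests,
mean-ASA curves, secondary-structure fractions) and ships a synthetic
benchmark generator that plants the documented Gla-site signatures (Glu
enrichment in the flanks with depletion at ±2, Arg enrichment at −7, −5,
−4, −1, +3, elevated site ASA of 37.8%, coil/helix-dominated structure) so
the whole pipeline is testable offline. See `docs/methods.md` for the full
model description.

## Worked example

```sh
# a synthetic benchmark: 80 proteins with planted Gla-site signal
glapred make-data --out data --seed 1

# train on 15-mers with the best feature combination and report pooled CV
glapred train --fasta data/sequences.fasta --sites data/sites.tsv \
    --asa data/asa.tsv --ss2-dir data/ss2 --out run --seed 1
```

which prints

```
cross-validation: precision=0.882 sensitivity=0.775 specificity=0.956 accuracy=0.901 mcc=0.760
```

i.e. on 1070 Glu-centered fragments (320 carboxylated, 750 not), pooled
five-fold cross-validation of the RBF-SVM on AA_PWM+AAC+ASA features calls
77.5% of true sites and 95.6% of non-sites correctly, for an overall
accuracy of 0.901 and a balanced MCC of 0.760. A model trained on data the
classifier has never seen can then be scored with
`glapred eval --model run/model.joblib ...` (held-out proteins must not
overlap the training set), new proteins scanned Glu-by-Glu with
`glapred predict`, and motif matrices exported with `glapred logo`.

The same workflow is available as a library:

```python
from glapred import (GeneratorSpec, generate, extract_all_fragments,
                     WindowConfig, SvmConfig, cross_validate)

ds = generate(GeneratorSpec(seed=1))
frags = extract_all_fragments(ds.records, WindowConfig(7))
cv = cross_validate(frags, ds.profiles, ("AA_PWM", "AAC", "ASA"), SvmConfig())
print(cv.report.truncated())
```

## Input formats

FASTA for sequences; 2-column TSV (`protein_id`, 1-based Glu position) for
site annotations; 3-column TSV (`protein_id`, position, percent) for ASA;
PSIPRED VFORMAT `.ss2` per protein for secondary structure. Fragments,
matrices and reports are exported as TSV.
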