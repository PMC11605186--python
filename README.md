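# epicrossnet

Separating cancer-associated from normal N6-methyladenosine (m6A) sites
with an interpretable deep cross network, and identifying the
genome-derived signatures that drive the separation.

m6A methylomes are broadly remodelled in cancer, but the 41-nt sequence
context of a site barely distinguishes cancer-associated from normal
sites. This package implements the full analysis that makes that point
quantitatively: pan-cancer site selection by per-site Fisher exact
tests over cancer/normal condition occurrence (log2(OR) > 2,
Benjamini–Hochberg q < 0.05, balanced 1:1), one-hot sequence encoding
plus a 52-feature genome-derived vector, a deep cross network classifier

    x_embed = W·x + b
    deep:    stacked ReLU layers ending at width 1
    cross:   x_cross = W_c·(x_embed ⊙ x_embed) + b_c + x_embed
    ŷ        = σ(deep + proj(cross))

trained with Adam on binary cross entropy, a sequence-only convolutional
baseline, AUROC evaluation with cross-condition transfer matrices and
condition clustering, and Shapley-value attribution (exact subset
enumeration as oracle, permutation sampling at scale) with bar/beeswarm
summaries. A synthetic-data generator with planted occurrence asymmetry
and feature effects makes every stage testable without any download; the
neural network and the Shapley machinery are implemented in plain numpy
with hand-derived, finite-difference-verified gradients.

Intended users: computational epigenomics groups who want a tested,
seeded, desk-scale reimplementation of this analysis pattern to run on
their own site catalogs or to benchmark against.

## Worked example

```python
from epicrossnet.pipeline import run_core_experiment

res = run_core_experiment(seed=1)
print(f"sequence-only test AUROC: {res['sequence_auroc']:.3f}")
print(f"integrated  test AUROC: {res['integrated_auroc']:.3f}")
print(res["attribution"].ranking.head(5).to_string(index=False))
```

Output:

```
sequence-only test AUROC: 0.564
integrated  test AUROC: 0.966
          feature  schema_index  mean_abs  rank
      isoform_num            45  0.204483     1
      rel_pos_cds            51  0.106984     2
     rel_pos_utr3            52  0.100794     3
 struct_hybridize            30  0.070385     4
constitutive_exon             8  0.055897     5
```

The generator planted no sequence signal and five genomic feature
effects. The sequence-only convolutional model sits at chance (0.56),
the integrated deep cross network separates the classes (0.97), and the
Shapley ranking recovers exactly the five planted features — the
package's miniature of the claim that cancer m6A changes are driven by
genomic context, not local sequence.

The same pipeline is scriptable from the shell:

```bash
epicrossnet simulate --outdir fixture --seed 1
epicrossnet select --fixture fixture --out selection.tsv --seed 1
epicrossnet run-all --outdir run1 --seed 1
```

## Layout

- `src/epicrossnet/simulate.py` — synthetic catalog/feature generator
- `src/epicrossnet/selection.py` — Fisher/BH pan-cancer site selection
- `src/epicrossnet/schema.py`, `encoding.py`, `annotate.py` — 52-feature
  schema, one-hot + normalization + splits, GFF3 transcript annotation
- `src/epicrossnet/models.py` — `CrossNetClassifier`,
  `SequenceConvClassifier` (sklearn-style, numpy backprop)
- `src/epicrossnet/interpret.py` — exact and sampled Shapley values
- `src/epicrossnet/evaluation.py` — AUROC, transfer matrix, clustering
- `src/epicrossnet/pipeline.py`, `cli.py`, `io.py` — orchestration,
  `epicrossnet` CLI, BED/FASTA/TSV/JSON round-trips
- `docs/methods.md` — model, parameters, design choices, limitations
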