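# Methods

## Problem and overall design

N6-methyladenosine (m6A) is the most abundant internal mRNA modification,
and its deposition is broadly remodelled in cancer. Given base-resolution
m6A site catalogs observed across many cancer and normal conditions, the
package addresses two questions: (i) can cancer-associated sites be told
apart from normal ones, and from what information — local sequence alone,
or sequence plus genome-derived context; and (ii) which genomic features
carry that signal. The pipeline has six stages: synthetic catalog
generation, pan-cancer site selection, feature encoding, model training,
evaluation (including cross-condition transfer), and Shapley-value
interpretation.

Real data at the scale this analysis was designed for (hundreds of
MeRIP-seq datasets) cannot ship with a software package, so a first-class
synthetic generator stands in for them. Every quantitative claim the test
suite and `scripts/acceptance.py` make is therefore about *recovery of
planted structure*, not about reproducing any specific biological site
catalog.

## Synthetic data generator

`GeneratorParams` defines a universe of `n_sites` sites (default 4000)
observed across `n_cancer_conditions` + `n_normal_conditions` binary
occurrence columns (default 10 + 10). Site classes:

* **pan-positive** (fraction `frac_pan_positive`, default 0.25): present
  in each cancer condition with probability `p_high` (0.9) and in each
  normal condition with `p_low` (0.1);
* **pan-negative** (default 0.25): the mirror image;
* **background**: `p_background` (0.5) on both sides.

Validation enforces `p_high > p_background > p_low` whenever signal is
planted. Study support per site is `1 + Poisson(1)`, so the
high-confidence filter (support ≥ 2) has something to remove. Each site
carries a 41-nt RNA window with the methylated A fixed at 0-based index
20 inside a random DRACH core (D∈{A,G,U}, R∈{A,G}, H∈{A,C,U}, 0-based
indices 18–22); the 36 flanking bases are uniform unless
`sequence_effect > 0`, in which case positive-class windows tilt toward
A/G and the rest toward C/U with weight proportional to the effect. The
default `sequence_effect = 0` encodes the null hypothesis that sequence
alone carries no cancer signal; raising it provides the positive control
that falsifies the sequence-only baseline's chance-level behaviour.

Genomic features are drawn class-conditionally from per-feature
distribution families (`bernoulli`, `beta`, `poisson_plus1`, `normal`).
Five defaults plant the signature the downstream interpretation should
recover: `rel_pos_cds` Beta(5,2) vs Beta(2,2) (positives sit deep in the
CDS), `rel_pos_utr3` Beta(2,5) vs Beta(2,2), `struct_hybridize`
Bernoulli 0.7 vs 0.3, `isoform_num` 1+Poisson(5) vs 1+Poisson(2), and
`constitutive_exon` Bernoulli 0.3 vs 0.7. All other features are drawn
identically across classes from a kind-appropriate null. These effect
sizes were chosen once as a "clearly detectable at a few thousand
samples" regime — strong enough that a correct implementation separates
classes well, weak enough that no single feature suffices.

What the generator does **not** emulate: read-level MeRIP-seq noise,
peak-calling artifacts, correlated occurrence between related conditions,
linkage between features (all 52 are drawn independently given the
class), or realistic genomic coordinates (windows are fabricated
directly, since only window content reaches the models). Passing tests
therefore demonstrate the machinery is correct and sensitive, not that
real cancer methylomes have this structure.

## Site selection

Three labeling procedures:

* **High-confidence filter** — keep sites with study support ≥
  `min_studies`.
* **Cancer-specific labels** — positives are sites present in a cancer
  condition but absent from its matched normal (and conversely for
  negatives); shared sites are dropped from both.
* **Pan-cancer selection** — for each site, the 2×2 table (present /
  absent × cancer / normal conditions) is tested with a two-sided
  Fisher exact test (probability-mass criterion, delegated to
  `scipy.stats.fisher_exact`), p-values are Benjamini–Hochberg adjusted
  (`statsmodels`), and positives are sites with log2(OR) > 2 **and**
  q < 0.05 (strict inequalities). The odds ratio is (a·d)/(b·c) with the
  Haldane–Anscombe +0.5 applied to every cell only when some cell is
  zero, and only for the OR — never the p-value. The negative pool uses
  the symmetric criterion (log2(OR) < −2, q < 0.05); this mirror rule is
  a documented design choice. A `adjusted=False` flag thresholds the raw
  p instead of q. Balanced 1:1 sets are drawn uniformly without
  replacement under a seed; the pipeline-level balancer trims whichever
  side is larger, since with symmetric planting either side can win the
  coin flip.

The test suite holds the Fisher p against an independent exact-rational
enumeration of the conditional hypergeometric distribution, and BH
against a hand step-up implementation and a simulated global-null FDR
check.

## Feature encoding

Sequence windows are one-hot encoded row-per-base in the order A, C, G,
U (T read as U; N becomes an all-zero row), giving a 41×4 block that is
flattened to 164 values and concatenated ahead of the genomic block.

The 52 genome-derived features are a versioned schema in eight groups:
13 region dummies, 6 region lengths, 6 clustering statistics, 4
conservation scores, 2 secondary-structure flags, 13 gene attributes
(housekeeping/sncRNA-host/lncRNA plus binding flags for the ten
canonical m6A writers, erasers and readers), 4 transcript properties,
and 4 metagene relative positions (position from the region 5′ end over
region length, computed per transcript, 5′UTR, CDS and 3′UTR). Features
whose upstream computation is out of scope (conservation, structure,
regulator binding) are declared `external_column` and copied from an
auxiliary table; the rest are computed from annotation. For real sites,
a gene is resolved to its single longest transcript before any region
math; GFF3's 1-based closed coordinates are converted to the internal
0-based half-open convention at the parsing boundary, and all distances
are computed in strand-aware transcript coordinates. A site outside a
region gets relative position 0 for that region with the region dummy 0,
so the sentinel is identifiable downstream. Clustering windows (±100 and
±1000 nt site counts, ±50 nt adenosine counts via the 41-nt window) are
documented defaults, not published values.

Continuous features are z-scored with statistics fitted on the training
split only; binary features pass through; a zero-variance feature maps
to 0 with a logged warning. Datasets are split 8:1:1 into
train/validation/test with per-class stratified rounding (so class
ratios per split are within one sample of the global ratio),
deterministically under a seed.

## Models

**Deep cross network.** The input x (164 + 52 = 216 for the integrated
model; 52 for genomic-only) flows through

    x_embed = W_embed·x + b_embed                       (embedding, width 128)
    deep:    h_k = ReLU(W_k·h_{k−1} + b_k), widths (64, 64, 1), no ReLU after the last
    cross:   x_cross = W_cross·(x_embed ⊙ x_embed) + b_cross + x_embed
    out      = deep(x_embed) + (W_proj·x_cross + b_proj)
    y_pred   = σ(out)

The cross branch keeps an explicit residual, so zero weights make it the
identity — a contract the tests pin down. Because the deep branch ends
at width 1 while the cross branch is embedding-wide, summing them is
ill-typed as stated; a learned scalar projection (`W_proj`, `b_proj`) of
the cross output reconciles the two. This is the single largest
architectural judgement call in the package. One cross transformation is
used (matching the single published cross equation); the deep depth
(64, 64, 1) is configurable since only the width 64 is fixed by the
recipe.

Training: mean binary cross entropy (predictions clipped to
[1e−7, 1−1e−7]), mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at
learning rate 1e−3, 10 epochs, batch size 64, with seeded per-epoch
shuffling. Per-epoch train and validation losses are recorded and the
returned parameters are the minimum-validation-loss checkpoint
(`checkpoint="last"` disables this). Weights are initialised
fan-in-scaled uniform from a seeded generator. The whole network is
plain numpy with hand-derived backpropagation; correctness is enforced
by central-finite-difference gradient checks (relative error < 1e−4)
and fixed-weight forward fixtures checked against hand arithmetic.

**Sequence-only baseline.** A small 1-D convolutional classifier on the
41×4 one-hot tensor: two valid-mode conv blocks (kernel 5, 32 then 64
channels, ReLU), global max-pool, dense layer, sigmoid — trained with
the identical Adam/BCE recipe. Its gradient path (im2col convolutions,
argmax-routed pooling) is finite-difference checked as well.

Both models are scikit-learn estimators (`fit` / `predict_proba` /
`get_params`, fitted attributes with trailing underscores), so they
compose with sklearn model selection if desired.

## Evaluation

AUROC is computed by two independent routes that must agree to 1e−12:
the rank-based pairwise-concordance statistic (ties half-credited, the
Mann–Whitney convention) and the trapezoidal area under the
threshold-swept ROC curve (TPR = TP/(TP+FN) against FPR = FP/(FP+TN),
tied scores grouped into one step). Cross-condition transfer testing
fits one model per condition pair and evaluates every model on every
pair's held-out test split (test split rather than full data, to avoid
leakage), producing a K×K AUROC matrix. Conditions are clustered by
average-linkage hierarchical clustering on the symmetrised distance
d(i,j) = 1 − (M[i,j] + M[j,i])/2 clipped to [0,1]; the raw matrix is
always exported so other methods can be applied.

## Interpretation

Shapley values follow the standard coalition formula with the masking
convention of perturbation-based explainers: "feature absent" means
replaced by a background row drawn from the training split, and v(S) is
the mean model output over those rows. Exact enumeration over all 2^F
subsets is used for F ≤ 15 (the test oracle; efficiency, null-player and
symmetry axioms are asserted on fixed-weight networks), and Castro-style
permutation sampling — identical masking rule, averaged marginal
contributions over random orderings — handles the full 52-feature model.
For dataset-level attribution the permutations are shared across samples
so each walk step is a single batched model call; this leaves each
per-sample estimate unbiased and makes the whole attribution
deterministic under its seed. Attribution is computed over the 52
genomic features with each sample's sequence block fixed at its observed
values, on the test split by default. Aggregations are the bar ranking
(mean |φ| per feature, descending, ties broken by schema index) and a
long-format beeswarm table (per-sample signed φ, raw feature value,
per-feature colour rank in [0,1], and a sign summary — the Pearson
correlation of φ with the feature value).

## Pipeline, determinism, problem sizes

All stages hang off one global seed; each stage derives its own seed as
CRC32("seed:stage") mod 2³¹, so toggling one stage never shifts
another's randomness. `run_all` writes every artifact (BED6/FASTA/TSV
fixture, association table, training-loss JSONL, metrics JSON, Shapley
tables, transfer matrix) plus a manifest of SHA-256 digests; rerunning
an identical configuration reproduces identical digests, which the test
suite asserts.

The shipped analysis sizes are chosen for a minutes-scale desk run: the
default end-to-end experiment uses 4000 sites (≈ 2000 after selection
and balancing), attribution uses 20 permutations × 30 background rows ×
≤ 100 test samples, and the transfer study uses four condition pairs of
1200 sites each. Recovery at these sizes is comfortable (integrated
AUROC ≈ 0.95, all five planted features in the Shapley top ten);
sharper estimates simply scale with these knobs.

## Known limitations

* Features are class-conditionally independent in the generator, so
  interactions the cross layer could exploit in real data are not
  simulated; the integrated model's advantage here comes from main
  effects.
* The exact rule generating the negative (normal) site pool is a
  symmetric mirror of the positive criterion by assumption.
* Shapley values are computed against a finite background sample; with
  very small backgrounds the attribution of correlated features is
  unstable (mitigated by the default 30–100 training rows).
* The transcript annotator resolves multi-gene overlaps by preferring
  exonic hits and then the lexicographically first gene id — adequate
  for desk-scale annotation, not a general-purpose overlap resolver.
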