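# Methods

## Model and assumptions

`mirank` ranks miRNAs by how plausibly they drive network-wide expression
change in a tumor cohort. The underlying assumption is that driver miRNAs
are (i) abundantly expressed, (ii) correlated — directly or indirectly —
with a large part of the transcriptome, and (iii) equipped with many
sequence-predicted binding targets. None of the three signals is treated as
sufficient on its own; the method's contribution is the aggregation.

Formally, feature vectors F1 = {a_i}, F2 = {c_i}, F3 = {t_i} over M miRNAs
are reduced to per-miRNA ranking-ratio triples and combined through the
joint cumulative distribution of uniform order statistics:

    Q(r_1, ..., r_N) = P(U_(1) <= r_(1), ..., U_(N) <= r_(N)),
    V_0 = 1,  V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} r_(N-k+1)^i / i!,
    Q = N! V_N,

with the ratios sorted ascending (the recursive solution of Stuart et al.
for this joint CDF). The recursion is exact, not approximate, for fixed
ratios; the identity Q(r, ..., r) = r^N and the N = 1, 2 closed forms hold
to machine precision and are asserted in the test suite, alongside direct
numerical integration over the ordered simplex and Monte-Carlo estimates.

The integration is bidirectional: Q1 uses descending ratios (small when the
miRNA is good everywhere), Q2 ascending ratios (large when the miRNA is
nowhere bad). Final score R_Q = rank(Q1 ascending) + rank(Q2 descending),
ranked ascending. The second direction exists because rank(Q1) alone can be
dominated by a single strong feature; requiring a good rank in both
directions rewards uniformly strong profiles. A consequence, proved by the
monotonicity of Q and checked property-wise in the tests, is that weak
dominance on all three features can never worsen R_Q.

## Conventions and numerical choices

* **Ranking ratios** are rank/M in (0, 1], with average ranks for ties; the
  best value gets 1/M, not 0, so Q of a uniformly best miRNA is small but
  positive. Descending and ascending ratios of a tie-free vector sum to
  (M+1)/M per entry.
* **Tie-breaking** of the final order: smaller R_Q, then smaller R_Q1, then
  lexicographic miRNA id. Rank vectors themselves use average ties, so
  fully tied inputs produce identical R_Q and a deterministic id order.
* **F2** excludes zero-variance genes globally (PCC undefined), so every
  miRNA is averaged over the same gene universe; a zero-variance miRNA gets
  c_i = 0 with a logged warning. Correlations are computed as inner
  products of unit-normalized centered rows; F2 is invariant to affine
  rescaling of any row.
* **Hypergeometric tails** are always upper-tail P(X >= x) including the
  observed count — the standard over-representation convention — and are
  evaluated in log-space (`hypergeom.logsf`) so p-values below 1e-40 remain
  finite and accurate; the suite validates against exact integer-arithmetic
  suffix sums on a full grid up to M = 60.
* **Identifier normalization**: lowercase, trim, strip a leading `hsa-`.
  Exact match thereafter; no mature/precursor mapping is attempted, because
  any such mapping is database-version-specific and silently lossy.
* **Missing values**: rows with any missing entry are dropped at load and
  counted, rather than imputed.
* **BH correction** is applied per miRNA across the gene sets of one
  collection (the enrichment question is asked per miRNA), via
  `statsmodels.multipletests(method="fdr_bh")`; q < 0.05 flags
  significance. The enrichment background defaults to the union of the
  collection's member genes.
* **Top-correlate selection** for the related-gene set keeps
  ceil(fraction·G) genes by |PCC| and includes all genes tied with the
  cutoff value.
* **Survival groups** use nearest-rank quantiles: the lowest and highest
  ceil(fraction·n) expression values (default fraction 0.10) among samples
  with clinical records, boundary ties included; overlapping extreme groups
  (e.g. constant expression) raise an error instead of producing a silent
  imbalance. Group comparison is the two-group log-rank test (chi-square,
  1 df) — the standard companion to Kaplan–Meier estimation — via
  lifelines, which also provides the product-limit estimator.
* The **t-test baseline** uses Welch's unequal-variance form, the safer
  default when group sizes are very unequal (a handful of normals against
  hundreds of tumors).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `transform` | `none` | optional log2(x+1) at load, the RNA-Seq count convention |
| `fraction` (pathways) | 0.01 | top absolute-PCC fraction defining a miRNA's correlated genes |
| `fraction` (survival) | 0.10 | extreme-expression quantile per group |
| integration `weights` | (1, 1, 1) | only for the weighted-average baseline |
| significance `q` | 0.05 | BH threshold for enrichment calls |

## The synthetic-data generator

The generator emulates the inputs the method was designed for — a tumor
cohort with paired expression, predicted interactions, a disease annotation
list, gene sets and clinical follow-up — with a planted ground truth.
Defaults: 100 samples, 1000 genes, 200 miRNAs, 10 drivers, a 3-noise-SD
mean-expression elevation, 50 vs 5 predicted targets, latent-factor loading
0.8, a 3x hazard for driver-high samples, ~30% censoring.

Design choices worth knowing:

* Each driver carries one Gaussian latent factor shared with its target
  genes; loading signs are randomized per gene so the signal lives in |PCC|
  only, mirroring the method's use of absolute correlation. With loading
  rho, driver-target correlation is rho²; at rho = 0.8 a driver's c_i rises
  to ~0.11 against a ~0.08 background (E|r| ≈ sqrt(2/(pi n)) for null pairs
  at n = 100).
* Between-entity baseline means are N(5, 0.5), half the within-sample noise
  SD (1.0), so the planted shift expressed in noise units translates into
  clear between-miRNA separation.
* Non-driver predicted targets are *not* coupled to expression: predicted
  interactions are sequence-derived and need not be functional, and this
  keeps F3 informative independently of F2.
* Survival follows an exponential proportional-hazards model (baseline
  hazard 1/500 per day, i.e. 500-day mean survival); samples in the top
  decile of the *first* driver's expression have hazard multiplied by
  `survival_effect`. Tying the hazard to one designated driver gives the
  planted effect a well-defined target for the log-rank recovery check.
  Censoring is an independent exponential whose rate is chosen so the
  expected censored fraction equals `censor_rate` in the baseline group.
* All randomness flows from a single integer seed through one generator
  instance; identical configs produce byte-identical fixture files.

What the generator does **not** emulate: real marginal distributions of
microarray/RNA-Seq intensities, batch effects, correlated miRNA families,
annotation sparsity patterns, or non-proportional hazards. Passing the
planted-recovery tests therefore demonstrates that the implementation
extracts the three signals it claims to extract and combines them sanely —
not that the feature set is sufficient on real cohorts.

## Problem sizes used in the checks

The simulation-based checks run 50 replicates of the 200-miRNA strong
cohort for driver recovery, 20 null replicates for the chance-level
comparison, and 11 replicates at 300 samples for the survival-effect
detection rate; the exhaustive hypergeometric validation covers every
(M <= 60, K, n, x). These sizes give stable statistics (4-SE bands on all
stochastic assertions) at a few minutes of single-core runtime.

## Known limitations

* Q is a deterministic aggregation statistic; no null distribution or
  p-value is attached to R_Q, and none is claimed.
* F2 at RNA-Seq scale depends on whether values are log-transformed; both
  are supported via the loader flag and the choice is the user's.
* Exact string matching after normalization will treat unmapped mature vs
  precursor names as distinct entities.
* The log-rank choice for group comparison is a convention; no alternative
  (e.g. weighted log-rank, Cox) is exposed.
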