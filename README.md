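# mirank

`mirank` prioritizes candidate cancer-related microRNAs (miRNAs) from paired
miRNA/mRNA tumor expression data. It is aimed at computational biologists who
have, for one tumor cohort, a miRNA expression matrix and a gene expression
matrix over the same samples plus a table of sequence-predicted miRNA→target
interactions, and who want a single ranked list of miRNAs most likely to
drive network-wide expression changes — together with the standard machinery
to evaluate such a list (annotation-enrichment curves, hypergeometric overlap
tests, pathway enrichment, Kaplan–Meier survival stratification).

## The method

For each of the *M* miRNAs three features are computed:

* **F1** — *a_i*: mean expression across all tumor samples,
* **F2** — *c_i*: mean absolute Pearson correlation between the miRNA and
  *every* gene in the matrix (zero-variance genes excluded globally),
* **F3** — *t_i*: number of distinct predicted target genes.

Each feature vector is converted to **ranking ratios**: rank the values in a
direction (average ranks for ties) and divide by *M*, giving values in
(0, 1]. For one miRNA, its three descending ratios r₁ ≤ r₂ ≤ r₃ (sorted) are
treated as thresholds on the order statistics of three iid Uniform(0, 1)
variables, and the **Q statistic** is the joint probability

    Q(r₁, …, r_N) = P(U₍₁₎ ≤ r₁, …, U₍N₎ ≤ r_N),

evaluated with the recursion V₀ = 1,
V_k = Σ_{i=1..k} (−1)^{i−1} V_{k−i} r_{N−k+1}^i / i!, Q = N!·V_N.
A miRNA ranking uniformly well on all features has a small Q.

Two Q values are computed per miRNA: **Q₁** from descending ratios
(relevance) and **Q₂** from ascending ratios (irrelevance). Ranking Q₁
ascending gives R_Q1, ranking Q₂ descending gives R_Q2, and the final score
is **R_Q = R_Q1 + R_Q2**, ranked ascending. The second direction penalizes
miRNAs whose good Q₁ is carried by a single feature. Baseline integrators
(weighted average of ranking ratios; inverse-normal transformation) and a
differential-expression Welch *t*-test ranking are included for comparison.

## Worked example

Everything below runs without any external data: the built-in generator
plants 10 "driver" miRNAs (high expression, 50 predicted targets each, a
shared latent factor correlating each driver with its targets) among 200
miRNAs, 1000 genes and 100 samples.

```python
from mirank import (SyntheticConfig, generate, build_feature_table,
                    integrate, cumulative_ratio, hypergeom_overlap)

bundle = generate(SyntheticConfig(seed=42))
table = build_feature_table(bundle.dataset, bundle.interactions)
result = integrate(table)

ranked = result.ranked_ids()
print(result.to_frame(table).sort_values("final_rank").head(5).round(4))

curve = cumulative_ratio(ranked, bundle.annotation)
print(f"cumulative annotation ratio at k=20: {curve.at(20):.2f}")

hits = int(round(curve.at(20) * 20))
test = hypergeom_overlap(M=table.M, K=len(bundle.annotation.mirna_ids), n=20, x=hits)
print(f"top-20 overlap: {hits}/20 drivers, hypergeometric p = {test.p:.3e}")
```

Output:

```
               a       c   t   q1      q2  rq1  rq2    rq  final_rank
mirna
mir-0004  8.9527  0.1064  50  0.0  0.9997  1.0  1.0   2.0           1
mir-0000  8.4501  0.1070  50  0.0  0.9850  2.0  3.0   5.0           2
mir-0001  7.7453  0.1216  50  0.0  0.9985  3.0  2.0   5.0           3
mir-0008  8.6443  0.1008  50  0.0  0.9842  4.0  4.0   8.0           4
mir-0003  8.3925  0.1036  50  0.0  0.9556  5.0  5.0  10.0           5

cumulative annotation ratio at k=20: 0.50
top-20 overlap: 10/20 drivers, hypergeometric p = 8.229e-12
```

The five top-ranked miRNAs are all planted drivers: elevated mean expression
(`a` ≈ 8–9 vs ≈ 5 background), elevated mean |PCC| (`c` ≈ 0.10–0.12 vs
≈ 0.08) and the full 50 predicted targets (`t`). Their relevance Q₁ is
vanishingly small (rounded to 0.0) and the combined score R_Q places all 10
drivers in the top 10, so the top-20 annotation ratio is 10/20 = 0.50 — an
overlap with the planted annotation set that a hypergeometric draw would
produce with probability ~8·10⁻¹².

The same pipeline is available from the shell:

```bash
mirank simulate --outdir fixtures/ --seed 42
mirank features --mirna fixtures/mirna_expression.tsv \
                --genes fixtures/gene_expression.tsv \
                --interactions fixtures/interactions.tsv --out features.tsv
mirank integrate --features features.tsv --out ranking.tsv
mirank evaluate --ranking ranking.tsv --annotation fixtures/annotation.tsv \
                --out curve.tsv
```

or end-to-end with `mirank run --config config.yaml` (see
`mirank run --help` for the config keys; pathway enrichment and survival
analysis run whenever a GMT collection / clinical table is configured).

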