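# exprdiv

Distance measures for cross-species gene-expression divergence.

When the expression of orthologous genes is compared across homologous
tissues of two species, the answer to "which genes have conserved
expression?" depends on the distance measure used to quantify divergence.
`exprdiv` implements the comparative machinery for studying that
dependence as a tested, end-to-end pipeline:

* **Transforms** — relative expression
  `x^R_ij = x^A_ij / Σ_j x^A_ij` (level-free profiles whose rows sum
  to 1), the binary transform `x^B_ij = 1 iff x^A_ij ≥ mean_j(x^A_ij)`,
  and profile entropy `H_i = −Σ_j p_ij log2 p_ij` (0 bits for a
  one-tissue gene up to `log2 T` bits for a uniform one).
* **Four divergence measures** — Euclidean distance on relative
  profiles `d_E = √Σ_j (x^R_hj − x^R_rj)²`; correlation-based distance
  `d_cor = 1 − r` (Pearson); the same `1 − r` on binary profiles; and the
  **generalized-average (GA) family** on binary profiles,

  `d_λ = 1 − X_mn / B_λ`,  `B_λ = ((m^λ + n^λ)/2)^(1/λ)`,

  where `X_mn` is the scalar product of the two 0/1 vectors and `m`, `n`
  their one-counts. The power mean `B_λ` sweeps the family through
  Simpson (`λ → −∞`), cosine/Ochiai (`λ = 0`), Dice (`λ = 1`) and
  maximum-overlap (`λ → +∞`) dissimilarities.
* **Moment-based exponent selection** — skewness/kurtosis scan of the
  distance distribution over a λ grid; exponents attaining the extreme
  moments are flagged (ties reported, never broken).
* **Cross-species tissue clustering** — average-link agglomeration of
  the 2T pooled tissue samples under each measure, Newick export, and a
  strict cherry score counting tissues whose two species samples are
  each other's nearest tree neighbours.
* **Conserved-pair calling** — an empirical null from distances between
  randomly re-paired (deranged) genes; ortholog pairs at or below the
  nearest-rank lower-tail `α` quantile of the null are called conserved.
* **A paired-species simulator** — tissue-specific, housekeeping and
  background gene classes, a tunable between-species conservation
  parameter, a species-wide intensity shift, and per-measurement noise,
  with full ground truth for every downstream test.

## Worked example

```python
import math
from exprdiv import (SyntheticConfig, generate_paired_expression,
                     generate_random_pairs, to_relative, pairwise_distances,
                     build_null, call_conserved, sample_distance_matrix,
                     average_link_cluster, homologous_pairing_score)

mat1, mat2, pairs, truth = generate_paired_expression(SyntheticConfig(seed=5))
rel1, rel2 = to_relative(mat1), to_relative(mat2)

null = build_null(pairwise_distances(rel1, rel2,
                                     generate_random_pairs(pairs, seed=50),
                                     "correlation"), alpha=0.01)
report = call_conserved(pairwise_distances(rel1, rel2, pairs, "correlation"), null)
print(report.threshold, report.n_called, report.n_tested)
# 0.03500584319606215 750 3152

tree = average_link_cluster(sample_distance_matrix(mat1, mat2, pairs, "correlation"))
print(homologous_pairing_score(tree))   # 8  (of 8 tissues)
```

The null threshold 0.035 is the 1% lower-tail quantile of the 3152
random-pair distances; 750 of the 3152 ortholog pairs fall at or below
it — a ~24-fold enrichment over the 1% expected by chance, reflecting
the conserved tissue effects built into the simulated orthologs. The
pairing score of 8 says every homologous tissue pair (human kidney with
rat kidney, etc.) forms a cherry in the average-link tree, despite the
simulated species-wide intensity shift, which both the relative
transform and the correlation cancel.

The `examples/` directory holds one short narrative script per
capability (simulation, transforms, the GA sweep, the exponent scan,
tissue clustering, conserved-pair calling); each prints the numbers it
computes and a line on what they mean. A thin CLI mirrors the pipeline
(`exprdiv simulate|transform|distances|scan-lambda|cluster|conserved|entropy|analyze`);
`exprdiv analyze` runs everything and writes a JSON run summary
recording the configuration, seeds and every numerical convention in
force.

See `docs/methods.md` for the model, parameter defaults, numerical
conventions and known limitations.

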