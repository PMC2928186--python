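# Methods

## The problem

Expression divergence — the dissimilarity between two genes' expression
profiles across matched tissues — behaves like an evolving phenotypic
trait, but unlike sequence divergence it has no settled distance measure.
Different measures read out different signals: a Euclidean distance on
level-free profiles responds to the *uniform* component of divergence and
is smallest for flat profiles, while a correlation-based distance
responds to *concerted* (shape) changes and ignores level entirely.
`exprdiv` implements the comparative machinery for studying this
dependence on a two-species, T-tissue design with one-to-one orthologs,
together with a generative simulator that makes every stage testable
without external data.

## Transforms

All inputs are gene × tissue matrices of non-negative intensities on a
linear scale, one per species.

* **Relative expression**: `x^R_ij = x^A_ij / Σ_j x^A_ij`. Rows sum to
  1; any per-gene (and hence also any species-wide) multiplicative scale
  cancels. A row summing to zero is an error naming the gene.
* **Binary transform**: `x^B_ij = 1` iff `x^A_ij ≥ mean_j(x^A_ij)`.
  Ties at the mean map to 1, so a perfectly flat housekeeping row
  becomes all ones rather than all zeros. Because the row maximum is
  always ≥ the row mean, an all-zero row cannot occur; because all
  entries ≥ their own mean forces equality, a noisy row is never all
  ones either.
* **Entropy**: Shannon entropy (base 2) of the relative row with
  `0·log 0 ≡ 0`. No closed formula was fixed by the endpoints alone, but
  this is the only standard definition that is 0 for a one-tissue gene
  and `log2 T` for a uniform one, which pins it down.

## Distance measures

* `euclidean`: `√Σ_j (u_j − v_j)²` on relative profiles.
* `correlation`: `1 − r` (Pearson), in [0, 2]; negative correlations
  are kept, not truncated. Undefined (NaN) for a zero-variance profile.
* `binary_correlation`: the same statistic on binary profiles.
* `ga`: `1 − X_mn / B_λ` with `X_mn` the scalar product and `B_λ` the
  power mean of the one-counts `m`, `n`. Conventions: `λ = 0` is the
  geometric mean (the continuity limit of the power mean), `λ → −∞` is
  `min(m, n)` (Simpson), `λ = 1` is `(m+n)/2` (Dice), `λ → +∞` is
  `max(m, n)`. `λ = 1` is special-cased to the exact arithmetic mean so
  the Dice identity holds to the last bit. Undefined when `m = 0` or
  `n = 0`. Since `X ≤ min(m,n) ≤ B_λ`, the distance lies in [0, 1] and
  is non-decreasing in λ (power-mean monotonicity), constant when
  `m = n`.

**Numerical note (large |λ|).** `B_λ` is computed in max-factored form,
`B_λ = hi · ((1 + (lo/hi)^λ)/2)^(1/λ)` for `λ > 0` (symmetrically via
`lo` for `λ < 0`), which cannot overflow for any float exponent. The
convergence to the `±∞` limits is slow — the error is bounded by
`ln 2 / |λ|`, about 1.4 × 10⁻² at `|λ| = 50` and reaching 10⁻⁶ only
around `|λ| ≈ 7 × 10⁵`; the extreme ends of the family should therefore
be requested as `math.inf` / `-math.inf`, which are handled exactly.

**Undefined-pair policy.** Pairs whose distance is undefined are
excluded and counted, never imputed: an imputed value would distort the
moment statistics that drive exponent selection. Exclusions are
reported in every `PairDistanceVector` and written to side-car files.

## Exponent selection

The scan computes, for each λ on a grid (default
`−∞, −10, −5, −2, −1, 0, 1, 2, 5, 10, +∞`, with binary correlation as a
comparator row), the sample skewness `g1 = m3/m2^{3/2}` and excess
kurtosis `g2 = m4/m2² − 3` using biased (÷N) central moments. The
selection reports the exponents attaining the minimum skewness and the
minimum and maximum kurtosis, with ties listed rather than broken: the
extreme-moment rule is a heuristic, and because the scan compares
distributions of identical N, bias corrections could not change any
ranking — the convention is fixed (and recorded in run summaries)
purely for reproducibility.

## Tissue clustering

The 2T pooled tissue samples of both species are compared column-wise
over the aligned ortholog genes, *after* the per-gene transform
(relative for the Euclidean/correlation panels — level-free profiles
are what make the two species comparable — binary for the binary
panels). An undefined column pair (a degenerate sample) is an error
naming the samples, not a silent exclusion. Average-link agglomeration
is implemented with the size-weighted Lance–Williams update; ties are
broken by the lexicographically smallest index pair in the current
cluster ordering (merged clusters appended last), making trees
bit-reproducible. Average-link heights are non-decreasing toward the
root, so the Newick export (branch length = parent height − child
height) is well-formed.

The **pairing score** counts tissues whose two species samples form a
cherry. This is deliberately strict: a topology such as
`(((thymus@rat, spleen@rat), thymus@human), spleen@human)` credits
neither thymus nor spleen, even though a coarser clade criterion might.

## Conserved-pair calling

The null is the empirical distribution of distances between randomly
re-paired genes. The re-pairing is a uniform permutation redrawn until
fixed-point free (a derangement): with ~3000 genes a plain permutation
retains one true ortholog pair on average, which would contaminate the
null's lower tail. The significance threshold is the nearest-rank lower
quantile — the `⌈αN⌉`-th smallest null distance — and a pair is called
conserved iff its distance is ≤ the threshold (conserved = unusually
*small* divergence, so the lower tail is the only coherent reading; the
empirical rather than fitted null is recorded as an assumption in the
run summary). Raising α can only add calls (nested thresholds).

Called sets are characterized by their *untransformed* mean expression
per species — level is precisely what the transforms erase, and what
separates "conserved because flat near background" (the population the
Euclidean distance favours) from "conserved because concertedly
expressed" (the correlation-favoured population). The upper entropy
quartile is the top `⌈N/4⌉` genes by rank (ties at the cut resolved by
ascending gene id), which maps 3152 genes to exactly 788. The contrast
between two called sets reports medians of mean expression and
across-tissue coefficients of variation with a two-sided Mann–Whitney U
statistic attached as a descriptive — not inferential — quantity; the
underlying claim is qualitative, and no p-value thresholding is done.

## The simulator

Log2-scale model for gene *i*, tissue *t*, species *s*:

```
y[s,i,t] = b[i] + δ·1{s=2} + c[i]·e[i,t] + (1−c[i])·e'[s,i,t] + ε[s,i,t]
```

with returned intensities `2^y` (strictly positive, linear scale, as the
relative transform requires). `b[i]` is a Gaussian draw around the
class baseline; `e` is the shared tissue-effect profile (a bump of
`tissue_effect_size` at the target tissue for tissue-specific genes,
zero for the flat classes); `e'` is an independently drawn per-species
profile of the same shape (for tissue-specific genes, a bump at a
per-species random tissue); `c[i] ∈ [0,1]` blends them; `ε` is i.i.d.
Gaussian noise independent between species. Class labels are assigned
in exact `⌊n·frac⌋` blocks and then shuffled by the seed, so class
counts are deterministic.

Defaults (the study conditions; all intensities in log2 units):

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 3152 | the ortholog-set size of the motivating design |
| `n_tissues` | 8 | the classic eight-tissue comparison panel |
| fractions ts/hk/bg | 0.25 / 0.25 / 0.50 | most array features sit near background; tissue-restricted and flat moderately-expressed genes split the rest |
| baseline means | 8 / 9 / 4 | housekeeping moderately high; background near the noise floor |
| `baseline_sd` | 1.0 | order-of-magnitude spread of per-gene levels |
| `tissue_effect_size` | 4.0 | a 16-fold tissue bump, typical of strongly tissue-restricted genes |
| conservation (per class) | ts 0.9, hk 0.0, bg 0.0 | tissue patterns are largely shared between species; flat classes have no pattern to share, so their between-species variation is noise only |
| `species_shift` | 1.0 | a platform-scale offset between the two species' intensity distributions |
| `noise_sd` | 0.5 | ~1.4-fold typical measurement scatter |

What the simulator does **not** emulate: probe-level structure,
normalization artifacts, replicate arrays, correlated noise between
tissues, many-to-many orthology, and expression patterns beyond
"one dominant tissue / flat". Tests passing on these data show the
pipeline's statistics behave as designed under a clean generative model;
they do not certify behaviour on real arrays, where for example the
flat classes are not cleanly separable and conservation varies
continuously.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed
(`numpy.random.default_rng`); identical configurations reproduce
byte-identical outputs, and run summaries record versions, seeds and
all conventions above. The test suite runs the full default problem
size (3152 genes × 8 tissues) throughout; directional/stochastic
checks use 20 seeded replicates, and combinatorial identities of the
GA family are verified exhaustively over all ~65 000 pairs of nonzero
length-8 binary vectors.

## Known limitations

* **Discrete nulls.** Over 8 tissues the binary-profile distances take
  finitely many values, so the null's lower tail carries tie mass: the
  nearest-rank threshold plus the inclusive `≤` call rule can make the
  realized false-call rate deviate from α (typically upward) for the
  binary measures. Under the default conditions the 1% calibration
  holds, but it sits closer to the edge of its binomial band than for
  the continuous measures, and with other mixtures it need not hold
  exactly. A mid-p or randomized-tie rule would smooth this at the cost
  of the simple quantile semantics.
* The GA and correlation distances are dissimilarities, not metrics —
  no triangle inequality is guaranteed or used.
* The extreme-moment selection rule is a heuristic; the scan therefore
  reports all extremes (min skewness, min and max kurtosis) instead of
  committing to a single winner.
* Bootstrap support for the tissue trees is out of scope (2 samples per
  tissue cannot support meaningful resampling); the cherry score is the
  intended summary.
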