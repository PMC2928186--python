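"""Conserved-pair calling against the random-pair null, plus the contrast.

Builds the empirical null by deranging the ortholog map, calls ortholog
pairs below the 1% lower-tail threshold, and contrasts the expression
level of Euclidean-called versus correlation-called genes.
"""

from exprdiv import (
    SyntheticConfig,
    build_null,
    call_conserved,
    contrast_called_sets,
    generate_paired_expression,
    generate_random_pairs,
    pairwise_distances,
    to_relative,
)

mat1, mat2, pairs, _ = generate_paired_expression(SyntheticConfig(seed=5))
random_pairs = generate_random_pairs(pairs, seed=50)
rel1, rel2 = to_relative(mat1), to_relative(mat2)

reports = {}
for measure in ("euclidean", "correlation"):
    null = build_null(pairwise_distances(rel1, rel2, random_pairs, measure), alpha=0.01)
    reports[measure] = call_conserved(
        pairwise_distances(rel1, rel2, pairs, measure), null, mat1, mat2
    )
    r = reports[measure]
    print(f"{measure:>12}: threshold {r.threshold:.4f}, "
          f"{r.n_called}/{r.n_tested} ortholog pairs called conserved")

contrast = contrast_called_sets(reports["euclidean"], reports["correlation"], mat1, mat2)
print(f"\nmedian mean expression, euclidean-called:   {contrast.medians[0]:9.1f}")
print(f"median mean expression, correlation-called: {contrast.medians[1]:9.1f}")
print(f"difference (euclidean - correlation):       {contrast.median_difference:9.1f}")
# Orthologs are strongly enriched below the null's 1% threshold.  The
# two measures favour different gene populations: Euclidean-on-relative
# calls flat genes near the noise floor, correlation calls concertedly
# expressed (tissue-patterned, higher-level) genes.
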