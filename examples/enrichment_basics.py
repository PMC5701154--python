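"""Exact enrichment statistics on a hand-sized example.

A 5-gene query is tested against a 4-gene annotation term inside a
20-gene universe; the term shares 3 genes with the query. Prints the
one-sided hypergeometric (Fisher) tail p-value, the conservative EASE
score, and the resulting one-row enrichment table.
"""

from hairnet import (
    AnnotationCatalog,
    AnnotationTerm,
    GeneUniverse,
    ease_score,
    enrich_catalog,
    hypergeometric_tail,
)

universe = GeneUniverse.from_iterable(f"G{i:02d}" for i in range(1, 21))
catalog = AnnotationCatalog(
    terms=[AnnotationTerm("termA", "GO", frozenset({"G01", "G02", "G03", "G10"}))],
    universe=universe,
)
query = ["G01", "G02", "G03", "G04", "G05"]

p_fisher = hypergeometric_tail(k=3, K=4, n=5, N=20)
p_ease = ease_score(k=3, K=4, n=5, N=20)
print(f"hypergeometric tail P(X >= 3) = {p_fisher:.6f}")
print(f"EASE (jackknifed Fisher)      = {p_ease:.6f}")
# The EASE score removes one overlapping gene before computing the tail,
# so it is always the more conservative of the two.

table = enrich_catalog(query, catalog, universe, method="hypergeometric", alpha=0.05)
print(table.frame.to_string(index=False))
# One row per term with nonzero overlap: counts (k of K term genes hit by
# the n-gene query in the N-gene universe), the p-value, a BH-FDR column
# for information, and the significance flag at alpha.
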