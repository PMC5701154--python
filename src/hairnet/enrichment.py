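"""Annotation enrichment of a query gene list against a background universe.

The statistical engine is a local replacement for web-based functional
annotation services: a one-sided hypergeometric (Fisher) upper-tail test and
its conservative jackknifed variant, the EASE score, in which the
list-by-term overlap cell of the 2x2 table is reduced by one before the tail
probability is computed. Both are evaluated exactly, by integer binomial
coefficient summation, so that p-values are reproducible to floating-point
precision for universes up to tens of thousands of genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Annotation names carrying no molecular information, removed by default
#: from enrichment output before clustering.
DEFAULT_BLOCKLIST = ("disease mutation", "polymorphism", "sequence variant")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene identifier: strip whitespace, uppercase.

    No alias resolution is attempted; identifiers are assumed to be
    standardized (HGNC-style) symbols upstream.
    """
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneUniverse:
    """The background gene universe enrichment is computed against."""

    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene universe must be non-empty")

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GeneUniverse":
        return cls(frozenset(normalize_symbol(g) for g in genes if g.strip()))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, gene: str) -> bool:
        return gene in self.symbols


@dataclass(frozen=True)
class AnnotationTerm:
    """A named annotation term with a category label and a member gene set."""

    term_id: str
    category: str
    genes: frozenset[str]


@dataclass
class AnnotationCatalog:
    """An ordered collection of annotation terms restricted to a universe.

    At construction every term's member set is intersected with the
    universe; terms left empty by the intersection are dropped (an
    annotation with no member in the background cannot be tested).
    """

    terms: list[AnnotationTerm]
    universe: GeneUniverse

    def __post_init__(self) -> None:
        seen: set[str] = set()
        kept: list[AnnotationTerm] = []
        for t in self.terms:
            if t.term_id in seen:
                raise ValueError(f"duplicate term_id {t.term_id!r} in catalog")
            seen.add(t.term_id)
            members = frozenset(normalize_symbol(g) for g in t.genes) & self.universe.symbols
            if members:
                kept.append(AnnotationTerm(t.term_id, t.category, members))
            else:
                logger.warning("term %s has no member in the universe; dropped", t.term_id)
        self.terms = kept

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def term(self, term_id: str) -> AnnotationTerm:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


@dataclass
class EnrichmentTable:
    """Per-term overlap counts and enrichment p-values.

    Wraps a DataFrame with columns
    (term_id, category, k, K, n, N, p_value, bh_fdr, significant),
    sorted ascending by p_value. ``alpha`` and ``method`` record how the
    significant flag was derived.
    """

    frame: pd.DataFrame
    alpha: float
    method: str

    COLUMNS = ("term_id", "category", "k", "K", "n", "N", "p_value", "bh_fdr", "significant")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"enrichment table missing columns: {sorted(missing)}")

    @property
    def significant_terms(self) -> list[str]:
        return self.frame.loc[self.frame["significant"], "term_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if K > N:
        raise ValueError(f"inconsistent counts: K={K} > N={N}")
    if n > N:
        raise ValueError(f"inconsistent counts: n={n} > N={N}")
    if k > K:
        raise ValueError(f"inconsistent counts: k={k} > K={K}")
    if k > n:
        raise ValueError(f"inconsistent counts: k={k} > n={n}")
    if min(k, K, n) < 0 or N <= 0:
        raise ValueError(f"counts must be non-negative with N > 0: k={k} K={K} n={n} N={N}")


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size within the universe, n the query
    size within the universe and k the observed overlap. Evaluation is exact:
    the point masses C(K,i) C(N-K,n-i) / C(N,n) are accumulated as integer
    ratios before a single float division, so results are stable for N up to
    ~50,000.
    """
    _check_counts(k, K, n, N)
    if k <= 0:
        return 1.0
    lo = max(k, 0)
    hi = min(K, n)
    if lo > hi:
        return 0.0
    numer = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(lo, hi + 1))
    return min(1.0, numer / math.comb(N, n))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """DAVID-style EASE score: jackknifed Fisher upper-tail probability.

    One gene is removed from the list-by-term cell of the 2x2 table (the
    other three cells are untouched) and the margins are recomputed from the
    cells, giving the tail P(X >= k-1) under Hypergeometric(N-1, K-1, n-1).
    The jackknife penalizes terms supported by very small overlaps, so
    ``ease_score >= hypergeometric_tail`` always holds on the same counts.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        raise ValueError("EASE score requires overlap k >= 1; use hypergeometric_tail for k = 0")
    if k == 1:
        return 1.0  # reduced overlap 0: upper tail at zero is certain
    return hypergeometric_tail(k - 1, K - 1, n - 1, N - 1)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def enrich_catalog(
    query: Iterable[str],
    catalog: AnnotationCatalog,
    universe: GeneUniverse | None = None,
    method: Literal["hypergeometric", "ease"] = "ease",
    alpha: float = 0.05,
) -> EnrichmentTable:
    """Test every catalog term for over-representation in the query list.

    Query genes outside the universe are dropped with a warning before
    testing. One row is emitted per term with overlap k >= 1; the
    ``significant`` flag is ``p_value < alpha`` (raw, uncorrected — a
    Benjamini-Hochberg column is carried for information only). The table is
    sorted ascending by p-value.
    """
    if universe is None:
        universe = catalog.universe
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if len(catalog) == 0:
        raise ValueError("annotation catalog is empty")
    query_norm = {normalize_symbol(g) for g in query}
    dropped = query_norm - universe.symbols
    if dropped:
        logger.warning(
            "%d query gene(s) outside the universe dropped before testing: %s",
            len(dropped), ", ".join(sorted(dropped)[:10]),
        )
    query_in = query_norm & universe.symbols
    if not query_in:
        raise ValueError("query list is empty after intersection with the universe")

    N = len(universe)
    n = len(query_in)
    stat = hypergeometric_tail if method == "hypergeometric" else ease_score
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown enrichment method {method!r}")

    rows = []
    for term in catalog:
        k = len(term.genes & query_in)
        if k == 0:
            continue
        K = len(term.genes)
        rows.append((term.term_id, term.category, k, K, n, N, stat(k, K, n, N)))
    frame = pd.DataFrame(rows, columns=["term_id", "category", "k", "K", "n", "N", "p_value"])
    frame["bh_fdr"] = benjamini_hochberg(frame["p_value"].to_numpy()) if len(frame) else []
    frame["significant"] = frame["p_value"] < alpha
    frame = frame.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return EnrichmentTable(frame=frame, alpha=alpha, method=method)


def filter_uninformative(
    table: EnrichmentTable,
    blocklist: Sequence[str] = DEFAULT_BLOCKLIST,
) -> EnrichmentTable:
    """Remove rows whose term name exactly matches a blocklist entry.

    The default blocklist holds annotation names that flag a gene as
    disease-associated without saying anything about its molecular role.
    Row order is preserved; an empty blocklist is a no-op.
    """
    if not blocklist:
        return table
    block = set(blocklist)
    kept = table.frame[~table.frame["term_id"].isin(block)].reset_index(drop=True)
    return EnrichmentTable(frame=kept, alpha=table.alpha, method=table.method)
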