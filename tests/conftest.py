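import numpy as np
import pytest

from hairnet import (
    AnnotationCatalog,
    AnnotationTerm,
    GeneUniverse,
    enrich_catalog,
)


@pytest.fixture
def small_universe() -> GeneUniverse:
    """Twenty-gene background universe for the worked enrichment example."""
    return GeneUniverse.from_iterable(f"G{i:02d}" for i in range(1, 21))


@pytest.fixture
def small_catalog(small_universe) -> AnnotationCatalog:
    """One four-gene term overlapping the five-gene query in three genes."""
    return AnnotationCatalog(
        terms=[AnnotationTerm("termA", "GO", frozenset({"G01", "G02", "G03", "G10"}))],
        universe=small_universe,
    )


@pytest.fixture
def small_query() -> list[str]:
    return ["G01", "G02", "G03", "G04", "G05"]


@pytest.fixture
def toy_matrix():
    """Three genes x two terms: memberships {g1,g2} and {g2,g3}."""
    from hairnet import AnnotationMatrix

    return AnnotationMatrix(
        genes=["GA", "GB", "GC"],
        terms=["t1", "t2"],
        values=np.array([[1, 0], [1, 1], [0, 1]]),
    )
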