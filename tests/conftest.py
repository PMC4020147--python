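import itertools

import pytest

from qmnet import FilterList, compute_network, reduce_table
from qmnet import fixtures


def network_for(table, flt, **kw):
    """Full pipeline: filter -> reduce -> condense -> closure -> graph."""
    condensed = reduce_table(list(table), flt)
    return compute_network(condensed, filter_name=flt.name, **kw)


EMPTY_FILTER = FilterList("empty", frozenset())


@pytest.fixture(scope="session")
def fig1b_run():
    return fixtures.generate(fixtures.preset_spec("fig1b", seed=11))


@pytest.fixture(scope="session")
def datasetA_run():
    return fixtures.generate(fixtures.preset_spec("datasetA_like", seed=11))


@pytest.fixture(scope="session")
def datasetB_run():
    return fixtures.generate(fixtures.preset_spec("datasetB_like", seed=11))


def naive_quasi_median_closure(vectors):
    """Independent oracle: all-triples fixpoint with the majority rule spelled
    out inline (triples with repeated members add nothing — the quasi-median
    of (u, u, w) is {u} by the majority rule)."""
    closed = set(vectors)
    while True:
        new = set()
        for u, v, w in itertools.combinations(sorted(closed), 3):
            per_char = []
            for a, b, c in zip(u, v, w):
                if a == b or a == c:
                    per_char.append((a,))
                elif b == c:
                    per_char.append((b,))
                else:
                    per_char.append((a, b, c))
            for q in itertools.product(*per_char):
                if q not in closed:
                    new.add(q)
        if not new:
            return closed
        closed |= new
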