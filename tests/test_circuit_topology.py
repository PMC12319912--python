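"""Circuit-topology relation classification against an independent oracle.

The oracle classifies a contact pair by the left-to-right pattern of its
endpoints along the chain (AABB -> series, ABBA -> parallel, ABAB -> cross,
with shared endpoints merged), a formulation independent of the interval
comparisons used by the implementation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctfold.circuit_topology import (
    CROSS,
    PARALLEL,
    SERIES,
    build_ct_matrix,
    classify_pair,
    count_relations,
    count_relations_for_sets,
    topology_matrix,
)
from ctfold.contacts import ContactSet
from ctfold.foldscore import StateLabels
from ctfold.synthetic_data import generate_arc_diagram


def oracle_classify(c1, c2):
    """Endpoint-pattern oracle: merge coincident endpoints, read the A/B
    pattern along the chain."""
    points = sorted(set(c1) | set(c2))
    pattern = ["".join(["A" * (p in c1), "B" * (p in c2)]) for p in points]
    if len(points) == 4:
        return {
            "AABB": SERIES,
            "BBAA": SERIES,
            "ABBA": PARALLEL,
            "BAAB": PARALLEL,
            "ABAB": CROSS,
            "BABA": CROSS,
        }["".join(pattern)]
    assert len(points) == 3  # exactly one shared endpoint
    return SERIES if pattern[1] == "AB" else PARALLEL


def random_contact(rng, n_res=30):
    i = int(rng.integers(1, n_res))
    j = int(rng.integers(i + 1, n_res + 1))
    return (i, j)


@pytest.mark.parametrize(
    "c1, c2, expected, concerted",
    [
        ((2, 10), (12, 20), SERIES, False),
        ((2, 20), (5, 10), PARALLEL, False),
        ((2, 10), (5, 15), CROSS, False),
        ((2, 10), (10, 15), SERIES, True),  # shared junction endpoint
        ((1, 4), (1, 9), PARALLEL, True),  # shared left endpoint, nesting
        ((2, 9), (5, 9), PARALLEL, True),  # shared right endpoint, nesting
    ],
)
def test_classify_pair_examples(c1, c2, expected, concerted):
    rel = classify_pair(c1, c2)
    assert rel.value == expected
    assert rel.concerted is concerted


def test_classify_pair_rejects_identical_and_unordered():
    with pytest.raises(ValueError):
        classify_pair((2, 5), (2, 5))
    with pytest.raises(ValueError):
        classify_pair((5, 2), (1, 3))


def test_classify_matches_oracle_on_random_pairs(rng):
    """Exhaustive agreement with the endpoint-pattern oracle on 10^4 pairs."""
    n_checked = 0
    while n_checked < 10_000:
        c1, c2 = random_contact(rng), random_contact(rng)
        if c1 == c2:
            continue
        assert classify_pair(c1, c2).value == oracle_classify(c1, c2), (c1, c2)
        n_checked += 1


@given(
    i1=st.integers(1, 40),
    l1=st.integers(1, 20),
    i2=st.integers(1, 40),
    l2=st.integers(1, 20),
    shift=st.integers(-500, 500),
)
@settings(max_examples=300, derandomize=True)
def test_classification_is_symmetric_and_translation_invariant(i1, l1, i2, l2, shift):
    c1, c2 = (i1, i1 + l1), (i2, i2 + l2)
    if c1 == c2:
        return
    rel = classify_pair(c1, c2)
    assert classify_pair(c2, c1) == rel
    shifted = classify_pair(
        (c1[0] + shift, c1[1] + shift), (c2[0] + shift, c2[1] + shift)
    )
    assert shifted == rel


def test_ct_matrix_worked_example():
    cs = ContactSet(6, frozenset({(1, 4), (2, 3), (5, 6)}))
    m = build_ct_matrix(cs)
    rel = {
        (m.contacts[a], m.contacts[b]): m.relations[a, b]
        for a, b in itertools.combinations(range(3), 2)
    }
    assert rel == {
        ((1, 4), (2, 3)): PARALLEL,
        ((1, 4), (5, 6)): SERIES,
        ((2, 3), (5, 6)): SERIES,
    }
    assert count_relations(m) == count_relations(m)  # stable
    c = count_relations(m)
    assert (c.P, c.S, c.X) == (1, 2, 0)


def test_ct_matrix_degenerate_sizes():
    empty = build_ct_matrix(ContactSet(10, frozenset()))
    assert empty.n_contacts == 0
    c = count_relations(empty)
    assert (c.P, c.S, c.X) == (0, 0, 0)
    single = build_ct_matrix(ContactSet(10, frozenset({(1, 5)})))
    assert count_relations(single).total == 0


def test_count_relations_interleaved_example():
    m = build_ct_matrix(ContactSet(8, frozenset({(1, 3), (2, 4), (5, 7), (6, 8)})))
    c = count_relations(m)
    assert (c.P, c.S, c.X) == (0, 4, 2)


def test_relation_counts_complete_on_random_diagrams():
    """P + S + X = C(n, 2) for every frame, and the vectorized per-frame
    counter agrees with the explicit CT-matrix route."""
    sets = [
        generate_arc_diagram(20, int(3 + seed % 15), min_seq_sep=1, seed=seed)
        for seed in range(1000)
    ]
    fast = count_relations_for_sets(sets)
    for cs, counts in zip(sets, fast):
        n = len(cs)
        assert counts.total == n * (n - 1) // 2
    for cs, counts in zip(sets[:50], fast[:50]):
        assert count_relations(build_ct_matrix(cs)) == counts


def test_exclude_concerted_drops_shared_endpoint_pairs():
    cs = ContactSet(10, frozenset({(1, 5), (5, 9), (2, 8)}))
    m = build_ct_matrix(cs)
    assert count_relations(m).total == 3
    # (1,5)-(5,9) shares residue 5; the other two pairs share nothing
    assert count_relations(m, include_concerted=False).total == 2


def test_topology_matrix_series_partners():
    sets = [ContactSet(6, frozenset({(1, 4), (2, 3), (5, 6)}))]
    t = topology_matrix(sets, SERIES)
    assert t[4, 5] == 2  # (5,6) is in series with both other contacts
    assert t[0, 3] == 1
    assert t[1, 2] == 1
    assert np.allclose(t, t.T)
    x = topology_matrix(sets, CROSS)
    assert np.count_nonzero(x) == 0


def test_topology_matrix_averages_over_frames():
    with_contact = ContactSet(10, frozenset({(1, 5), (6, 9)}))
    without = ContactSet(10, frozenset())
    t = topology_matrix([with_contact, without], SERIES)
    assert t[0, 4] == pytest.approx(0.5)


def test_topology_matrix_state_selection_errors():
    sets = [ContactSet(6, frozenset({(1, 4)}))]
    labels = StateLabels(labels=np.array(["exposed"]))
    with pytest.raises(ValueError, match="compact"):
        topology_matrix(sets, SERIES, labels=labels, state="compact")
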