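"""Circuit-topology classification of intrachain contact pairs.

Two contacts (loops) along a chain, viewed as closed intervals on the
residue index, stand in exactly one of three relations:

* **series (S)** — the intervals are disjoint,
* **parallel (P)** — one interval is nested inside the other,
* **cross (X)** — the intervals partially overlap (entangled loops).

Contact pairs sharing one residue endpoint are *concerted*; they are mapped
to a base class (junction sharing -> S, same-side nesting -> P) and carry a
flag so they can be excluded from tallies if desired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .contacts import ContactSet, pairs_array

SERIES = "S"
PARALLEL = "P"
CROSS = "X"

__all__ = [
    "Relation",
    "CTMatrix",
    "RelationCounts",
    "classify_pair",
    "build_ct_matrix",
    "count_relations",
    "count_relations_for_sets",
    "topology_matrix",
    "SERIES",
    "PARALLEL",
    "CROSS",
]


@dataclass(frozen=True)
class Relation:
    """Relation between two contacts: value in {S, P, X}, plus a flag
    marking concerted pairs (one shared residue endpoint)."""

    value: str
    concerted: bool = False

    def __post_init__(self) -> None:
        if self.value not in (SERIES, PARALLEL, CROSS):
            raise ValueError(f"invalid relation value {self.value!r}")


@dataclass
class CTMatrix:
    """Symmetric table of pairwise relations between a frame's contacts.

    ``relations[a, b]`` is the relation code for contacts ``contacts[a]``
    and ``contacts[b]`` (``a != b``); the diagonal holds ``""``.
    ``concerted[a, b]`` marks shared-endpoint pairs.
    """

    contacts: list[tuple[int, int]]
    relations: np.ndarray  # (n, n) of "S"/"P"/"X", "" on the diagonal
    concerted: np.ndarray  # (n, n) bool

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class RelationCounts:
    """Tallies of unordered contact pairs by relation class."""

    P: int
    S: int
    X: int

    def __post_init__(self) -> None:
        if min(self.P, self.S, self.X) < 0:
            raise ValueError("relation counts must be non-negative")

    @property
    def total(self) -> int:
        return self.P + self.S + self.X

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.S, self.X], dtype=float)


def classify_pair(c1: tuple[int, int], c2: tuple[int, int]) -> Relation:
    """Classify the relation between two contacts ``(i1, j1)``, ``(i2, j2)``.

    Both contacts must be ordered ``i < j``. Identical contacts are a
    precondition error. With disjoint endpoint sets the classification is
    pure interval logic; with one shared endpoint the concerted variant is
    mapped to its base class: shared junction endpoint (``j1 == i2`` or
    ``j2 == i1``) -> S, shared left/right endpoint (nesting) -> P.
    """
    i1, j1 = c1
    i2, j2 = c2
    if not (i1 < j1 and i2 < j2):
        raise ValueError(f"contacts must be ordered i < j: {c1}, {c2}")
    if c1 == c2:
        raise ValueError(f"cannot classify a contact against itself: {c1}")

    shared = len({i1, j1} & {i2, j2}) > 0
    # Closed-interval convention: a shared junction endpoint counts as
    # series; a shared same-side endpoint counts as nesting (parallel).
    if j1 <= i2 or j2 <= i1:
        return Relation(SERIES, concerted=shared)
    if (i1 <= i2 and j2 <= j1) or (i2 <= i1 and j1 <= j2):
        return Relation(PARALLEL, concerted=shared)
    return Relation(CROSS, concerted=shared)


def build_ct_matrix(cs: ContactSet) -> CTMatrix:
    """Build the full pairwise relation table for one frame's contacts.

    Contacts are ordered lexicographically; the result is symmetric because
    the relation itself is symmetric in its arguments.
    """
    contacts = sorted(cs.contacts)
    n = len(contacts)
    relations = np.full((n, n), "", dtype="<U1")
    concerted = np.zeros((n, n), dtype=bool)
    for a, b in itertools.combinations(range(n), 2):
        rel = classify_pair(contacts[a], contacts[b])
        relations[a, b] = relations[b, a] = rel.value
        concerted[a, b] = concerted[b, a] = rel.concerted
    return CTMatrix(contacts=contacts, relations=relations, concerted=concerted)


def count_relations(m: CTMatrix, include_concerted: bool = True) -> RelationCounts:
    """Tally each unordered contact pair of a CT matrix once.

    Concerted (shared-endpoint) pairs are counted under their mapped base
    class by default; ``include_concerted=False`` drops them entirely.
    """
    upper = np.triu_indices(m.n_contacts, k=1)
    codes = m.relations[upper]
    if not include_concerted:
        codes = codes[~m.concerted[upper]]
    return RelationCounts(
        P=int(np.count_nonzero(codes == PARALLEL)),
        S=int(np.count_nonzero(codes == SERIES)),
        X=int(np.count_nonzero(codes == CROSS)),
    )


def _pairwise_codes(pairs: np.ndarray, include_concerted: bool = True):
    """Vectorized S/P/X classification over all unordered pairs of a frame's
    contact array; returns (P, S, X) counts. Hot path of the pipeline."""
    n = len(pairs)
    if n < 2:
        return 0, 0, 0
    i = pairs[:, 0]
    j = pairs[:, 1]
    a, b = np.triu_indices(n, k=1)
    i1, j1, i2, j2 = i[a], j[a], i[b], j[b]
    series = (j1 <= i2) | (j2 <= i1)
    parallel = ~series & (((i1 <= i2) & (j2 <= j1)) | ((i2 <= i1) & (j1 <= j2)))
    cross = ~series & ~parallel
    if not include_concerted:
        keep = ~((i1 == i2) | (i1 == j2) | (j1 == i2) | (j1 == j2))
        series &= keep
        parallel &= keep
        cross &= keep
    return (
        int(parallel.sum()),
        int(series.sum()),
        int(cross.sum()),
    )


def count_relations_for_sets(
    contact_sets: list[ContactSet], include_concerted: bool = True
) -> list[RelationCounts]:
    """Per-frame relation counts for a contact-set trajectory.

    Equivalent to ``count_relations(build_ct_matrix(cs))`` per frame but
    without materializing the relation tables.
    """
    out = []
    for cs in contact_sets:
        p, s, x = _pairwise_codes(pairs_array(cs), include_concerted)
        out.append(RelationCounts(P=p, S=s, X=x))
    return out


def topology_matrix(
    contact_sets: list[ContactSet],
    relation_type: str,
    labels=None,
    state: str | None = None,
) -> np.ndarray:
    """Residue-pair matrix of mean relation participation.

    Entry ``(i, j)`` (0-based on the residue index minus one) is the average
    over selected frames of the number of ``relation_type`` relations in
    which contact ``(i, j)`` participates; frames lacking the contact
    contribute 0. ``labels``/``state`` restrict the average to one
    conformational state.
    """
    if relation_type not in (SERIES, PARALLEL, CROSS):
        raise ValueError(f"unknown relation type {relation_type!r}")
    if not contact_sets:
        raise ValueError("empty contact-set selection")
    n_res = contact_sets[0].n_residues
    if any(cs.n_residues != n_res for cs in contact_sets):
        raise ValueError("all frames must share n_residues")

    selected = contact_sets
    if state is not None:
        if labels is None:
            raise ValueError("state-resolved matrix requires labels")
        mask = np.asarray(labels.labels) == state
        if len(mask) != len(contact_sets):
            raise ValueError("labels not aligned with contact sets")
        selected = [cs for cs, m in zip(contact_sets, mask) if m]
        if not selected:
            raise ValueError(f"no frame carries label {state!r}")

    acc = np.zeros((n_res, n_res), dtype=float)
    for cs in selected:
        pairs = pairs_array(cs)
        n = len(pairs)
        if n < 2:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        a, b = np.triu_indices(n, k=1)
        i1, j1, i2, j2 = i[a], j[a], i[b], j[b]
        series = (j1 <= i2) | (j2 <= i1)
        parallel = ~series & (((i1 <= i2) & (j2 <= j1)) | ((i2 <= i1) & (j1 <= j2)))
        if relation_type == SERIES:
            hit = series
        elif relation_type == PARALLEL:
            hit = parallel
        else:
            hit = ~series & ~parallel
        per_contact = np.zeros(n, dtype=float)
        np.add.at(per_contact, a[hit], 1.0)
        np.add.at(per_contact, b[hit], 1.0)
        acc[i - 1, j - 1] += per_contact
    acc /= len(selected)
    return acc + acc.T
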