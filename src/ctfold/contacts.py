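"""Residue–residue contact extraction and contact-map statistics.

A frame's contacts are the residue pairs (i, j), i < j, whose minimum
inter-atomic distance over a chosen atom selection falls at or below a
cutoff (default 0.5 nm), subject to a minimum sequence separation that
removes trivially close chain neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ContactSet",
    "ContactMap",
    "pairs_array",
    "extract_contacts",
    "contact_vector",
    "contact_universe",
    "mean_contact_map",
    "write_contacts_csv",
    "read_contacts_csv",
]


@dataclass(frozen=True)
class ContactSet:
    """The set of residue-pair contacts of one frame.

    Contacts are ordered pairs ``(i, j)`` with ``1 <= i < j <= n_residues``
    on 1-based residue indices.
    """

    n_residues: int
    contacts: frozenset

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not (1 <= i < j <= self.n_residues):
                raise ValueError(
                    f"contact ({i}, {j}) outside chain of {self.n_residues} residues"
                )

    def __len__(self) -> int:
        return len(self.contacts)

    def __contains__(self, pair) -> bool:
        return pair in self.contacts


@dataclass
class ContactMap:
    """Per-pair contact frequencies in [0, 1]; symmetric, zero diagonal."""

    n_residues: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.n_residues, self.n_residues):
            raise ValueError("matrix shape must be (n_residues, n_residues)")
        if not np.allclose(m, m.T):
            raise ValueError("contact map must be symmetric")


def pairs_array(cs: ContactSet) -> np.ndarray:
    """Sorted ``(n_contacts, 2)`` int array view of a ContactSet."""
    if not cs.contacts:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(sorted(cs.contacts), dtype=np.int64)


def extract_contacts(
    frame,
    cutoff_nm: float = 0.5,
    min_seq_sep: int = 3,
    atom_mode: str = "heavy",
) -> ContactSet:
    """Extract the residue contacts of one conformation.

    Residues i, j are in contact iff the minimum distance over the selected
    atoms (all non-hydrogens for ``heavy``, alpha-carbons for ``ca``) is
    <= ``cutoff_nm`` and ``j - i >= min_seq_sep``.
    """
    if atom_mode not in ("heavy", "ca"):
        raise ValueError(f"unknown atom_mode {atom_mode!r} (expected 'heavy' or 'ca')")
    res_idx = np.asarray(frame.residue_index)
    n_res = int(res_idx.max())
    if n_res < 2:
        raise ValueError("contact extraction needs at least 2 residues")

    if atom_mode == "heavy":
        sel = np.asarray(frame.element) != "H"
    else:
        names = getattr(frame, "atom_name", None)
        if names is None:
            raise ValueError("atom_mode='ca' requires atom names on the frame")
        sel = np.asarray(names) == "CA"

    missing = set(range(1, n_res + 1)) - set(res_idx[sel].tolist())
    if missing:
        warnings.warn(
            f"residues {sorted(missing)} have no atoms in selection "
            f"'{atom_mode}'; they form no contacts",
            stacklevel=2,
        )

    coords = np.asarray(frame.atom_coords, dtype=float)[sel]
    residues = res_idx[sel]
    tree = cKDTree(coords)
    contacts = set()
    for a, b in tree.query_pairs(cutoff_nm):
        ri, rj = int(residues[a]), int(residues[b])
        if ri == rj:
            continue
        i, j = (ri, rj) if ri < rj else (rj, ri)
        if j - i >= min_seq_sep:
            contacts.add((i, j))
    return ContactSet(n_residues=n_res, contacts=frozenset(contacts))


def contact_universe(contact_sets) -> list:
    """Sorted union of all contacts observed across frames — the shared
    feature space for contact vectors and PCA."""
    universe = set()
    for cs in contact_sets:
        universe |= cs.contacts
    return sorted(universe)


def contact_vector(cs: ContactSet, universe) -> np.ndarray:
    """Binary vector of length ``len(universe)``: 1 where the pair is in cs."""
    index = {pair: k for k, pair in enumerate(universe)}
    vec = np.zeros(len(universe), dtype=np.int8)
    for pair in cs.contacts:
        if pair not in index:
            raise ValueError(f"contact {pair} absent from the supplied universe")
        vec[index[pair]] = 1
    return vec


def mean_contact_map(
    contact_sets,
    labels=None,
    state: str | None = None,
) -> ContactMap:
    """State-resolved mean contact map.

    Entry (i, j) is the fraction of selected frames containing contact
    (i, j). With ``state`` given, only frames carrying that label are
    averaged.
    """
    contact_sets = list(contact_sets)
    if not contact_sets:
        raise ValueError("no frames supplied")
    n_res = contact_sets[0].n_residues
    if any(cs.n_residues != n_res for cs in contact_sets):
        raise ValueError("all frames must share n_residues")

    selected = contact_sets
    if state is not None:
        if labels is None:
            raise ValueError("state selection requires labels")
        mask = np.asarray(labels.labels) == state
        selected = [cs for cs, m in zip(contact_sets, mask) if m]
        if not selected:
            raise ValueError(f"no frame carries label {state!r}")

    counts = np.zeros((n_res, n_res), dtype=float)
    for cs in selected:
        for i, j in cs.contacts:
            counts[i - 1, j - 1] += 1.0
    counts /= len(selected)
    return ContactMap(n_residues=n_res, matrix=counts + counts.T)


def write_contacts_csv(path, contact_sets, n_residues: int | None = None) -> None:
    """Write a contact-set trajectory as CSV (frame_index, res_i, res_j).

    Frames without contacts are still recorded (res_i = res_j = 0 sentinel
    rows are avoided by writing an explicit n_frames/n_residues header
    comment instead).
    """
    if n_residues is None:
        n_residues = contact_sets[0].n_residues if contact_sets else 0
    rows = []
    for k, cs in enumerate(contact_sets):
        for i, j in sorted(cs.contacts):
            rows.append((k, i, j))
    df = pd.DataFrame(rows, columns=["frame_index", "res_i", "res_j"])
    with open(path, "w") as fh:
        fh.write(f"# n_frames={len(contact_sets)} n_residues={n_residues}\n")
        df.to_csv(fh, index=False)


def read_contacts_csv(path) -> list:
    """Read a contact-set trajectory written by :func:`write_contacts_csv`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# n_frames=... n_residues=...' header")
        meta = dict(item.split("=") for item in header.lstrip("# ").split())
        n_frames = int(meta["n_frames"])
        n_residues = int(meta["n_residues"])
        df = pd.read_csv(fh)
    per_frame = [set() for _ in range(n_frames)]
    for k, i, j in df.itertuples(index=False):
        per_frame[int(k)].add((int(i), int(j)))
    return [
        ContactSet(n_residues=n_residues, contacts=frozenset(s)) for s in per_frame
    ]
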