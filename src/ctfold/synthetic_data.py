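"""Synthetic contact trajectories and bead polymers with known ground truth.

Three generators cover the pipeline without any MD input:

* random arc diagrams (contact sets) for topology-level tests,
* a two-state (exposed <-> compact) hidden Markov contact process for a
  ~58-residue chain — exposed frames draw only short-range "coil" contacts,
  compact frames additionally include a fixed set of nonlocal contacts —
  with known switching rates, so state classification and dwell kinetics
  can be scored against truth,
* bead-polymer conformations (random-walk coil / collapsed globule) for the
  geometric observables.

All generators are seeded and emit identical output for identical seeds.
The random stream order per operation is documented in its docstring and is
part of the API: fixtures are bit-stable across releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactSet
from .foldscore import COMPACT, EXPOSED, StateLabels

__all__ = [
    "TwoStateParams",
    "generate_arc_diagram",
    "generate_two_state_trajectory",
    "simulate_state_chain",
    "generate_bead_polymer",
    "BeadConformation",
]


def _admissible_pairs(n_residues: int, min_seq_sep: int, max_seq_sep: int | None = None):
    pairs = []
    for i in range(1, n_residues + 1):
        for j in range(i + min_seq_sep, n_residues + 1):
            if max_seq_sep is None or j - i <= max_seq_sep:
                pairs.append((i, j))
    return pairs


def generate_arc_diagram(
    n_residues: int, n_contacts: int, min_seq_sep: int = 3, seed: int = 0
) -> ContactSet:
    """Uniform random contact set: ``n_contacts`` pairs sampled without
    replacement from all pairs with ``j - i >= min_seq_sep``.

    Random stream: one ``rng.choice`` call on the lexicographically sorted
    admissible-pair list.
    """
    pairs = _admissible_pairs(n_residues, min_seq_sep)
    if n_contacts > len(pairs):
        raise ValueError(
            f"requested {n_contacts} contacts but only {len(pairs)} admissible "
            f"pairs exist (n_residues={n_residues}, min_seq_sep={min_seq_sep})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n_contacts, replace=False)
    return ContactSet(
        n_residues=n_residues, contacts=frozenset(pairs[k] for k in idx)
    )


@dataclass
class TwoStateParams:
    """Parameters of the two-state hidden Markov contact process.

    Rates are in 1/ns; the per-step switching probability over a time step
    dt is 1 - exp(-k * dt). ``coil_pool`` maps short-range contacts to their
    per-frame inclusion probability (always active); ``compact_extra`` maps
    nonlocal contacts to their inclusion probability in the compact state
    only. The defaults emulate a ~58-residue disordered chain with compact
    dwells of ~50 ns and exposed dwells of ~100 ns sampled every 0.5 ns.
    """

    n_residues: int = 58
    dt_ns: float = 0.5
    n_frames: int = 20_000
    k_compaction: float = 0.01  # exposed -> compact, 1/ns
    k_decompaction: float = 0.02  # compact -> exposed, 1/ns
    coil_pool: dict = field(default_factory=dict)
    compact_extra: dict = field(default_factory=dict)
    min_seq_sep: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_compaction < 0 or self.k_decompaction < 0:
            raise ValueError("rates must be >= 0")
        if not self.coil_pool:
            self.coil_pool = {
                p: 0.12
                for p in _admissible_pairs(self.n_residues, self.min_seq_sep, 6)
            }
        if not self.compact_extra:
            rng = np.random.default_rng(self.seed + 10_007)
            nonlocal_pairs = _admissible_pairs(self.n_residues, 12)
            idx = rng.choice(len(nonlocal_pairs), size=10, replace=False)
            self.compact_extra = {nonlocal_pairs[k]: 0.8 for k in idx}
        for pool in (self.coil_pool, self.compact_extra):
            for (i, j), p in pool.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"inclusion probability {p} for {(i, j)}")
                if j - i < self.min_seq_sep:
                    raise ValueError(
                        f"pool contact {(i, j)} violates min_seq_sep={self.min_seq_sep}"
                    )


def simulate_state_chain(p: TwoStateParams, rng=None) -> np.ndarray:
    """Hidden-state trace of the two-state chain (True = compact).

    Discrete-time Markov chain starting exposed; per-step switch
    probabilities 1 - exp(-k * dt). Random stream: one uniform draw per
    step, consumed in frame order.
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    p_up = 1.0 - np.exp(-p.k_compaction * p.dt_ns)
    p_down = 1.0 - np.exp(-p.k_decompaction * p.dt_ns)
    u = rng.random(p.n_frames)
    states = np.zeros(p.n_frames, dtype=bool)
    current = False
    for t in range(p.n_frames):
        if current:
            if u[t] < p_down:
                current = False
        else:
            if u[t] < p_up:
                current = True
        states[t] = current
    return states


def generate_two_state_trajectory(p: TwoStateParams):
    """Two-state contact-set trajectory with ground-truth labels.

    Exposed frames sample each coil-pool contact independently with its
    probability; compact frames additionally sample each compact-extra
    contact. Random stream: the state chain first (one uniform per frame),
    then one (n_frames, n_pool) uniform block for the coil pool, then one
    (n_frames, n_extra) block for the compact extras.

    Returns ``(contact_sets, labels)`` with labels aligned per frame.
    """
    rng = np.random.default_rng(p.seed)
    states = simulate_state_chain(p, rng)

    coil_pairs = sorted(p.coil_pool)
    coil_probs = np.array([p.coil_pool[c] for c in coil_pairs])
    extra_pairs = sorted(p.compact_extra)
    extra_probs = np.array([p.compact_extra[c] for c in extra_pairs])

    coil_on = rng.random((p.n_frames, len(coil_pairs))) < coil_probs
    extra_on = rng.random((p.n_frames, len(extra_pairs))) < extra_probs
    extra_on &= states[:, None]

    contact_sets = []
    for t in range(p.n_frames):
        contacts = {coil_pairs[k] for k in np.flatnonzero(coil_on[t])}
        contacts.update(extra_pairs[k] for k in np.flatnonzero(extra_on[t]))
        contact_sets.append(
            ContactSet(n_residues=p.n_residues, contacts=frozenset(contacts))
        )
    labels = StateLabels(labels=np.where(states, COMPACT, EXPOSED))
    return contact_sets, labels


@dataclass
class BeadConformation:
    """One-bead-per-residue pseudo-structure (carbon beads), duck-typed to
    the Conformation interface consumed by the geometric observables."""

    atom_coords: np.ndarray
    residue_index: np.ndarray
    element: np.ndarray
    atom_mass: np.ndarray
    frame_time: float = 0.0
    box: np.ndarray | None = None

    @property
    def atom_name(self) -> np.ndarray:
        return np.array(["CA"] * len(self.residue_index))


def generate_bead_polymer(
    n_residues: int, state: str = "coil", seed: int = 0, step_nm: float = 0.38
) -> BeadConformation:
    """Bead polymer: 3-D random walk (coil) or the same walk compacted into
    a sphere (globule).

    The coil takes isotropic steps of fixed length ``step_nm``. The globule
    rescales the walk radially so all beads fit a sphere of radius
    ``0.8 * N**(1/3) * 0.2`` nm. Random stream: one (n-1, 3) normal block.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if state not in ("coil", "globule"):
        raise ValueError(f"unknown state {state!r}")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues - 1, 3))
    steps *= step_nm / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    coords -= coords.mean(axis=0)
    if state == "globule":
        r_target = 0.8 * n_residues ** (1.0 / 3.0) * 0.2
        r = np.linalg.norm(coords, axis=1)
        r_max = r.max()
        if r_max > r_target:
            coords *= r_target / r_max
    n = n_residues
    return BeadConformation(
        atom_coords=coords,
        residue_index=np.arange(1, n + 1),
        element=np.array(["C"] * n),
        atom_mass=np.full(n, 12.011),
    )
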