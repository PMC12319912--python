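"""Structure and ensemble I/O with trajectory preprocessing filters.

Multi-model PDB files are read into :class:`Ensemble` objects (one frame
per MODEL, coordinates in nm), then filtered the way equilibrated MD
analyses are prepared: an initial transient is discarded, frames are
subsampled to a fixed stride, and frames whose protein sits too close to
its own periodic image are removed.

Binary trajectory formats (XTC/DCD) are supported through the adapter
contract :func:`ensemble_from_frames`: any iterator yielding objects with
the Conformation fields can be wrapped; the package never parses binary
formats itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Conformation",
    "Ensemble",
    "read_structure",
    "write_structure",
    "ensemble_from_frames",
    "filter_equilibrated",
    "filter_periodic_image",
]


@dataclass
class Conformation:
    """One frame: coordinates in nm with per-atom residue/element/mass."""

    frame_time: float  # ns
    atom_coords: np.ndarray  # (n_atoms, 3) nm
    residue_index: np.ndarray  # 1-based, contiguous within the chain
    element: np.ndarray
    atom_mass: np.ndarray
    atom_name: np.ndarray | None = None
    box: np.ndarray | None = None  # (3, 3) box vectors, nm

    def __post_init__(self) -> None:
        coords = np.asarray(self.atom_coords, dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        if np.any(np.diff(np.asarray(self.residue_index)) < 0):
            raise ValueError("residue indices must be non-decreasing")
        if np.any(np.asarray(self.atom_mass) <= 0):
            raise ValueError("atomic masses must be > 0")

    @property
    def n_residues(self) -> int:
        return int(np.max(self.residue_index))


@dataclass
class Ensemble:
    """Ordered frames sharing one atom table, with replicate/variant labels."""

    frames: list
    replicate_id: list = field(default_factory=list)
    variant_id: list = field(default_factory=list)
    residue_offset: int = 0  # original numbering of internal residue 1, minus 1

    def __post_init__(self) -> None:
        n = len(self.frames)
        if not self.replicate_id:
            self.replicate_id = ["0"] * n
        if not self.variant_id:
            self.variant_id = ["NP"] * n
        for rep in set(self.replicate_id):
            t = [f.frame_time for f, r in zip(self.frames, self.replicate_id) if r == rep]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"frame times not strictly increasing in replicate {rep}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.frame_time for f in self.frames])


_NAME_ELEMENTS = {"CL": "CL", "BR": "BR", "NA": "NA", "MG": "MG", "ZN": "ZN", "SE": "SE"}


def _element_from_name(name: str) -> str:
    name = name.strip()
    if name[:2].upper() in _NAME_ELEMENTS:
        return _NAME_ELEMENTS[name[:2].upper()]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def read_structure(path, model_index="all", dt_ns: float = 1.0) -> Ensemble:
    """Read a (multi-model) PDB file into an Ensemble.

    Coordinates are converted from Angstrom to nm. Elements come from the
    element column when present, otherwise from atom-name heuristics, and
    masses from a built-in element table. PDB files carry no time axis, so
    frame times are assigned as ``model_index * dt_ns``.
    """
    try:
        pdb = pdbio.PDBFile.read(str(path))
    except OSError as exc:
        raise ValueError(f"cannot read structure file {path}: {exc}") from exc
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        raise ValueError(f"{path}: no parsable ATOM/HETATM records") from exc
    if stack.array_length() == 0:
        raise ValueError(f"{path}: structure contains no atoms")

    elements = []
    for el, name in zip(stack.element, stack.atom_name):
        elements.append(el.upper() if el.strip() else _element_from_name(name))
    elements = np.array(elements)
    masses = np.array([struc_info.mass(e.capitalize()) for e in elements])

    res_ids = np.asarray(stack.res_id)
    unique_ids, internal = np.unique(res_ids, return_inverse=True)
    residue_index = internal + 1
    offset = int(unique_ids[0]) - 1

    box = None
    if stack.box is not None:
        box = np.asarray(stack.box[0], dtype=float) / 10.0

    if model_index == "all":
        model_range = range(stack.stack_depth())
    else:
        model_range = [int(model_index)]

    frames = [
        Conformation(
            frame_time=m * dt_ns,
            atom_coords=np.asarray(stack.coord[m], dtype=float) / 10.0,
            residue_index=residue_index,
            element=elements,
            atom_mass=masses,
            atom_name=np.asarray(stack.atom_name),
            box=box,
        )
        for m in model_range
    ]
    return Ensemble(frames=frames, residue_offset=offset)


def write_structure(path, ensemble: Ensemble) -> None:
    """Write an Ensemble as a multi-model PDB (nm converted back to Å)."""
    n_atoms = len(ensemble.frames[0].atom_coords)
    coord = np.stack([np.asarray(f.atom_coords) * 10.0 for f in ensemble.frames])
    ref = ensemble.frames[0]
    atoms = struc.AtomArrayStack(len(ensemble.frames), n_atoms)
    atoms.coord = coord
    atoms.res_id = np.asarray(ref.residue_index) + ensemble.residue_offset
    atoms.res_name = np.array(["GLY"] * n_atoms)
    atoms.chain_id = np.array(["A"] * n_atoms)
    atoms.element = np.array([e.capitalize() for e in ref.element])
    names = ref.atom_name if ref.atom_name is not None else ref.element
    atoms.atom_name = np.asarray(names)
    atoms.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = pdbio.PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def ensemble_from_frames(frames, replicate_id=None, variant_id=None) -> Ensemble:
    """Adapter entry point: wrap any iterator of Conformation-like frames
    (e.g. from an mdtraj/MDAnalysis XTC reader) into an Ensemble."""
    frames = list(frames)
    return Ensemble(
        frames=frames,
        replicate_id=list(replicate_id) if replicate_id is not None else [],
        variant_id=list(variant_id) if variant_id is not None else [],
    )


def _native_step(times: np.ndarray) -> float:
    if len(times) < 2:
        return 0.0
    return float(np.median(np.diff(times)))


def filter_equilibrated(
    ensemble: Ensemble, discard_ns: float, stride_ns: float
) -> Ensemble:
    """Drop the initial transient and subsample to a fixed stride.

    Per replicate, frames with time < ``discard_ns`` are removed; a
    remaining frame is kept iff (t - discard_ns) is an integer multiple of
    ``stride_ns`` to within half the native time step. Idempotent.
    """
    keep = np.zeros(len(ensemble), dtype=bool)
    for rep in sorted(set(ensemble.replicate_id)):
        idx = np.array([k for k, r in enumerate(ensemble.replicate_id) if r == rep])
        t = np.array([ensemble.frames[k].frame_time for k in idx])
        step = _native_step(t)
        if step > 0 and stride_ns < step - 1e-9:
            raise ValueError(
                f"stride {stride_ns} ns is smaller than the native step {step} ns"
            )
        tol = step / 2 if step > 0 else 1e-9
        rel = t - discard_ns
        on_grid = np.abs(rel - stride_ns * np.round(rel / stride_ns)) < tol
        keep[idx] = (rel > -tol / 2) & on_grid
    if not keep.any():
        warnings.warn("all frames removed by equilibration filter", stacklevel=2)
    return _subset(ensemble, keep)


def filter_periodic_image(
    ensemble: Ensemble, min_dist_nm: float = 2.0
) -> Ensemble:
    """Remove frames whose protein approaches its own periodic image.

    The minimum distance between any atom and any of the 26 neighbouring
    image translations of any atom is computed exactly (valid for boxes
    larger than the molecule); frames below ``min_dist_nm`` are dropped.
    """
    keep = np.ones(len(ensemble), dtype=bool)
    for k, frame in enumerate(ensemble.frames):
        if frame.box is None:
            raise ValueError(
                f"frame {k} has no box vectors; disable the periodic-image "
                "filter explicitly if the system is not periodic"
            )
        keep[k] = _min_image_distance(frame) >= min_dist_nm
    return _subset(ensemble, keep)


def _min_image_distance(frame: Conformation) -> float:
    from scipy.spatial import cKDTree

    coords = np.asarray(frame.atom_coords, dtype=float)
    box = np.asarray(frame.box, dtype=float)
    tree = cKDTree(coords)
    best = np.inf
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                if a == b == c == 0:
                    continue
                shift = a * box[0] + b * box[1] + c * box[2]
                d, _ = tree.query(coords + shift, k=1)
                best = min(best, float(d.min()))
    return best


def _subset(ensemble: Ensemble, keep: np.ndarray) -> Ensemble:
    return Ensemble(
        frames=[f for f, k in zip(ensemble.frames, keep) if k],
        replicate_id=[r for r, k in zip(ensemble.replicate_id, keep) if k],
        variant_id=[v for v, k in zip(ensemble.variant_id, keep) if k],
        residue_offset=ensemble.residue_offset,
    )
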