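"""Geometric observables, contact-space PCA and free-energy landscapes.

Covers the per-frame chain geometry (radius of gyration, Shrake–Rupley
solvent-accessible surface area), the Flory excluded-volume estimate of Rg
for a disordered chain, PCA of binary contact vectors pooled across
variants, and 2-D free-energy surfaces of the leading projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

__all__ = [
    "FloryParams",
    "PcaModel",
    "EnergyLandscape",
    "radius_of_gyration",
    "flory_rg",
    "sasa",
    "contact_pca",
    "residue_loadings",
    "free_energy_landscape",
    "VDW_RADII_NM",
]

# Bondi-style van der Waals radii, nm
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "SE": 0.190,
}


@dataclass(frozen=True)
class FloryParams:
    """Flory scaling parameters: Rg ~ b * N**nu for an N-residue chain."""

    N: int
    nu: float = 0.6
    b: float = 0.22  # nm per residue

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.nu < 1:
            raise ValueError("nu must lie in (0, 1)")
        if self.b <= 0:
            raise ValueError("b must be > 0")


@dataclass
class PcaModel:
    """PCA of binary contact vectors on a shared contact universe."""

    universe: list
    mean_vector: np.ndarray
    eigenvectors: np.ndarray  # (n_components, n_features)
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return (np.asarray(vectors, dtype=float) - self.mean_vector) @ self.eigenvectors.T


@dataclass
class EnergyLandscape:
    """Free energy per 2-D bin in kT units, minimum shifted to zero.

    Empty bins are masked (``mask`` True) and hold NaN, not zero.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray


def radius_of_gyration(frame, mass_weighted: bool = True) -> float:
    """Mass-weighted RMS distance of atoms from the center of mass, nm."""
    coords = np.asarray(frame.atom_coords, dtype=float)
    if coords.size == 0:
        raise ValueError("frame has no atoms")
    if mass_weighted:
        m = np.asarray(frame.atom_mass, dtype=float)
    else:
        m = np.ones(len(coords))
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def flory_rg(p: FloryParams) -> float:
    """Excluded-volume estimate Rg = b * N**nu, nm."""
    return p.b * p.N**p.nu


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points by the golden-spiral construction
    (deterministic)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def sasa(frame, probe_nm: float = 0.14, n_sphere_points: int = 960):
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's accessible area is the fraction of quasi-uniform test points
    on its solvent-inflated sphere (radius r_vdw + probe) lying outside every
    other atom's inflated sphere, times 4*pi*(r_vdw + probe)**2. Returns
    ``(per_residue, total)`` in nm^2.
    """
    coords = np.asarray(frame.atom_coords, dtype=float)
    elements = np.asarray(frame.element)
    unknown = sorted(set(elements) - set(VDW_RADII_NM))
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    radii = np.array([VDW_RADII_NM[e] for e in elements]) + probe_nm
    res_idx = np.asarray(frame.residue_index)

    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    r_max = radii.max()
    per_atom = np.zeros(len(coords))
    for a in range(len(coords)):
        pts = coords[a] + radii[a] * unit
        neighbors = [b for b in tree.query_ball_point(coords[a], radii[a] + r_max) if b != a]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[a] = frac * 4.0 * np.pi * radii[a] ** 2

    n_res = int(res_idx.max())
    per_residue = np.zeros(n_res)
    np.add.at(per_residue, res_idx - 1, per_atom)
    return per_residue, float(per_atom.sum())


def contact_pca(vectors: np.ndarray, universe) -> PcaModel:
    """PCA of pooled contact vectors from all variants on a shared universe.

    Mean-centered covariance eigendecomposition of the raw binary vectors;
    components sorted by descending eigenvalue. Sign convention: the
    largest-magnitude loading of each component is made positive.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("contact PCA needs >= 2 frames")
    if X.shape[1] != len(universe):
        raise ValueError("vector length does not match universe size")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate input: zero variance in every contact")
    n_components = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for k in range(components.shape[0]):
        lead = np.argmax(np.abs(components[k]))
        if components[k, lead] < 0:
            components[k] = -components[k]
    return PcaModel(
        universe=list(universe),
        mean_vector=pca.mean_,
        eigenvectors=components,
        eigenvalues=pca.explained_variance_,
        variance_fractions=pca.explained_variance_ratio_,
    )


def residue_loadings(model: PcaModel, component: int) -> np.ndarray:
    """Per-residue contribution of one eigenvector.

    A residue's contribution is the sum of absolute loadings over all
    universe contacts that touch it.
    """
    if not 0 <= component < model.eigenvectors.shape[0]:
        raise ValueError(f"component {component} out of range")
    loadings = model.eigenvectors[component]
    n_res = max(j for _, j in model.universe) if model.universe else 0
    out = np.zeros(n_res)
    for (i, j), w in zip(model.universe, loadings):
        out[i - 1] += abs(w)
        out[j - 1] += abs(w)
    return out


def free_energy_landscape(
    projections: np.ndarray,
    n_bins: int = 50,
    kT: float = 1.0,
    ranges=None,
) -> EnergyLandscape:
    """2-D free-energy surface of (PC1, PC2) projections.

    F = -kT * ln(count), shifted so the occupied minimum is zero; empty bins
    are masked. ``ranges`` fixes the bin edges so panels for different
    variants share one grid.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2 or pts.shape[0] < 1:
        raise ValueError("projections must be an (n_frames, >=2) array")
    counts, x_edges, y_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=n_bins, range=ranges
    )
    mask = counts == 0
    with np.errstate(divide="ignore"):
        F = -kT * np.log(counts)
    F[mask] = np.nan
    F -= np.nanmin(F)
    return EnergyLandscape(x_edges=x_edges, y_edges=y_edges, free_energy=F, mask=mask)
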