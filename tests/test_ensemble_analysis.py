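"""Geometric observables, Flory estimate, SASA, contact PCA, landscapes."""

import numpy as np
import pytest

from conftest import make_frame
from ctfold.contacts import ContactSet, contact_universe, contact_vector
from ctfold.ensemble_analysis import (
    FloryParams,
    contact_pca,
    flory_rg,
    free_energy_landscape,
    radius_of_gyration,
    residue_loadings,
    sasa,
)


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        frame = make_frame([[0, 0, 0], [1, 0, 0]])
        assert radius_of_gyration(frame) == pytest.approx(0.5)

    def test_unit_square(self):
        frame = make_frame([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert radius_of_gyration(frame) == pytest.approx(1 / np.sqrt(2))

    def test_single_atom(self):
        assert radius_of_gyration(make_frame([[3, 2, 1]])) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(40, 3))
        frame = make_frame(coords)
        ref = radius_of_gyration(frame)
        for _ in range(5):
            q = rng.normal(size=(3, 3))
            u, _, vt = np.linalg.svd(q)
            rot = u @ vt
            moved = make_frame(coords @ rot.T + rng.normal(size=3))
            assert radius_of_gyration(moved) == pytest.approx(ref, abs=1e-9)

    def test_mass_weighting_matters(self):
        frame = make_frame([[0, 0, 0], [1, 0, 0]], elements=["C", "H"])
        weighted = radius_of_gyration(frame, mass_weighted=True)
        unweighted = radius_of_gyration(frame, mass_weighted=False)
        assert weighted < unweighted  # heavy atom pulls the COM towards itself


class TestFlory:
    def test_disordered_chain_estimate(self):
        # 58-residue chain, excluded-volume exponent 0.6, 0.22 nm per residue
        assert flory_rg(FloryParams(N=58, nu=0.6, b=0.22)) == pytest.approx(2.5, abs=0.05)

    def test_single_residue_returns_prefactor(self):
        assert flory_rg(FloryParams(N=1, nu=0.5, b=0.22)) == pytest.approx(0.22)

    def test_ideal_chain(self):
        assert flory_rg(FloryParams(N=100, nu=0.5, b=0.1)) == pytest.approx(1.0)

    def test_monotone_in_parameters(self):
        base = flory_rg(FloryParams(N=58, nu=0.6, b=0.22))
        assert flory_rg(FloryParams(N=80, nu=0.6, b=0.22)) > base
        assert flory_rg(FloryParams(N=58, nu=0.7, b=0.22)) > base
        assert flory_rg(FloryParams(N=58, nu=0.6, b=0.3)) > base

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FloryParams(N=0)
        with pytest.raises(ValueError):
            FloryParams(N=10, nu=1.5)


class TestSasa:
    def test_isolated_atom_is_full_sphere(self):
        frame = make_frame([[0, 0, 0]], elements=["C"])
        per_res, total = sasa(frame, probe_nm=0.14)
        r = 0.170 + 0.14
        assert total == pytest.approx(4 * np.pi * r**2, rel=1e-6)
        assert per_res[0] == pytest.approx(total)

    def test_distant_atoms_do_not_occlude(self):
        frame = make_frame([[0, 0, 0], [100.0, 0, 0]], elements=["C", "O"])
        _, total = sasa(frame)
        rc, ro = 0.170 + 0.14, 0.152 + 0.14
        assert total == pytest.approx(4 * np.pi * (rc**2 + ro**2), rel=1e-6)

    def test_quadrature_convergence(self, rng):
        coords = rng.uniform(0, 0.8, size=(10, 3))
        frame = make_frame(coords)
        _, coarse = sasa(frame, n_sphere_points=960)
        _, fine = sasa(frame, n_sphere_points=1920)
        assert abs(fine - coarse) / fine < 0.02

    def test_burial_monotone_with_separation(self):
        areas = []
        for d in (0.2, 0.4, 0.8, 2.0):
            frame = make_frame([[0, 0, 0], [d, 0, 0]])
            areas.append(sasa(frame)[1])
        assert areas == sorted(areas)

    def test_unknown_element(self):
        frame = make_frame([[0, 0, 0]], elements=["XX"])
        with pytest.raises(ValueError, match="XX"):
            sasa(frame)

    def test_agrees_with_mdtraj_reference(self, rng):
        """Cross-check against an independent Shrake–Rupley implementation
        (different sphere-point construction) on a random 12-atom cluster."""
        md = pytest.importorskip("mdtraj")
        coords = rng.uniform(0, 0.9, size=(12, 3))
        elements = list("CNOCSCNOCOCC")
        frame = make_frame(coords, elements=elements)
        _, total = sasa(frame, probe_nm=0.14, n_sphere_points=960)

        top = md.Topology()
        chain = top.add_chain()
        for k, el in enumerate(elements):
            res = top.add_residue("GLY", chain)
            top.add_atom(f"A{k}", md.element.get_by_symbol(el), res)
        traj = md.Trajectory(coords[None], top)
        ref = md.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum()
        assert total == pytest.approx(float(ref), rel=0.03)


class TestContactPca:
    def test_two_cluster_data_has_single_component(self):
        universe = [(1, 5), (2, 8), (3, 9)]
        a = contact_vector(ContactSet(10, frozenset({(1, 5)})), universe)
        b = contact_vector(ContactSet(10, frozenset({(2, 8), (3, 9)})), universe)
        X = np.array([a] * 50 + [b] * 50)
        model = contact_pca(X, universe)
        assert model.variance_fractions[0] == pytest.approx(1.0)

    def test_degenerate_identical_frames(self):
        universe = [(1, 5)]
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="degenerate"):
            contact_pca(X, universe)

    def test_full_basis_reconstruction(self, rng):
        universe = [(1, k) for k in range(4, 12)]
        X = (rng.random((40, len(universe))) < 0.4).astype(float)
        model = contact_pca(X, universe)
        proj = model.transform(X)
        recon = proj @ model.eigenvectors + model.mean_vector
        assert np.abs(recon - X).max() < 1e-10
        assert model.variance_fractions.sum() <= 1.0 + 1e-12
        # Parseval: full-basis projection preserves pairwise distances
        d_orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_proj = np.linalg.norm(proj[:, None] - proj[None, :], axis=2)
        assert np.allclose(d_orig, d_proj)

    def test_sign_convention(self, rng):
        universe = [(1, 5), (2, 8)]
        X = (rng.random((30, 2)) < 0.5).astype(float)
        model = contact_pca(X, universe)
        for comp in model.eigenvectors:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestResidueLoadings:
    def test_single_contact(self):
        model = _model_with_loadings([(1, 5)], [[1.0]])
        prof = residue_loadings(model, 0)
        assert prof[0] == 1.0 and prof[4] == 1.0
        assert prof[1:4].sum() == 0

    def test_absolute_values_accumulate(self):
        model = _model_with_loadings([(1, 5), (1, 9)], [[0.6, -0.8]])
        prof = residue_loadings(model, 0)
        assert prof[0] == pytest.approx(1.4)
        assert prof[4] == pytest.approx(0.6)
        assert prof[8] == pytest.approx(0.8)

    def test_bad_component_index(self):
        model = _model_with_loadings([(1, 5)], [[1.0]])
        with pytest.raises(ValueError):
            residue_loadings(model, 3)


def _model_with_loadings(universe, eigenvectors):
    from ctfold.ensemble_analysis import PcaModel

    ev = np.asarray(eigenvectors, dtype=float)
    return PcaModel(
        universe=universe,
        mean_vector=np.zeros(len(universe)),
        eigenvectors=ev,
        eigenvalues=np.ones(len(ev)),
        variance_fractions=np.ones(len(ev)) / len(ev),
    )


class TestEnergyLandscape:
    def test_single_bin(self):
        land = free_energy_landscape(np.zeros((100, 2)), n_bins=10)
        occupied = ~land.mask
        assert occupied.sum() == 1
        assert land.free_energy[occupied][0] == 0.0
        assert np.isnan(land.free_energy[land.mask]).all()

    def test_one_kt_between_e_ratio_bins(self):
        n_hi, n_lo = 2718, 1000  # counts in ratio e
        pts = np.concatenate(
            [np.tile([0.5, 0.5], (n_hi, 1)), np.tile([4.5, 4.5], (n_lo, 1))]
        )
        land = free_energy_landscape(pts, n_bins=5, ranges=[[0, 5], [0, 5]])
        vals = np.sort(land.free_energy[~land.mask])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(1.0, abs=1e-3)

    def test_uniform_occupancy_is_flat(self, rng):
        pts = rng.uniform(0, 1, size=(200_00, 2))
        land = free_energy_landscape(pts, n_bins=5)
        assert np.nanmax(land.free_energy) < 0.25  # ln-count sampling noise
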