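"""Promolecular NCI fields: closed forms, derivative oracles, classification."""

import warnings

import numpy as np
import pytest

from xenbkit import struct_io, synthetic_data
from xenbkit.nci_grid import (
    ProatomModel,
    classify_nci,
    grid_from_box,
    interfacial_nci,
    nci_fields,
    promolecular_fields,
    reduced_gradient,
)
from xenbkit.struct_io import BOHR_PER_ANGSTROM, Atom, Structure, VolumetricGrid

RDG_PREFACTOR = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)


def single_h(model=None):
    return Structure([Atom("H", "H1", "MOL", 1, "A", np.zeros(3))])


def h_pair(separation):
    return Structure(
        [
            Atom("H", "H1", "MOL", 1, "A", np.array([0.0, 0.0, 0.0])),
            Atom("H", "H2", "MOL", 1, "A", np.array([separation, 0.0, 0.0])),
        ]
    )


@pytest.fixture(scope="module")
def exp_model():
    """Single-term exponential proatom: everything about it is closed form."""
    return ProatomModel({"H": [(0.3, 0.8)]})


def fields_at_points(structure, model, points_ang):
    """Evaluate NCI fields at arbitrary points via degenerate 1-point grids."""
    rho, grad, hess = [], [], []
    for p in np.atleast_2d(points_ang):
        grid = VolumetricGrid(p, np.eye(3) * 0.1, (1, 1, 1), np.zeros(1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = promolecular_fields(structure, model, grid)
        rho.append(g.rho[0])
        grad.append(g.grad[0])
        hess.append(g.hessian[0])
    return np.array(rho), np.array(grad), np.array(hess)


class TestPromolecularFields:
    def test_single_proatom_closed_form_density(self, exp_model):
        r_bohr = 0.5
        r_ang = r_bohr / BOHR_PER_ANGSTROM
        rho, _, _ = fields_at_points(
            single_h(), exp_model, np.array([[r_ang, 0.0, 0.0]])
        )
        assert rho[0] == pytest.approx(0.3 * np.exp(-0.5 / 0.8), rel=1e-12)

    def test_density_superposition(self, exp_model):
        points = np.random.default_rng(0).uniform(-1.5, 1.5, (20, 3))
        rho_pair, _, _ = fields_at_points(h_pair(1.2), exp_model, points)
        rho_a, _, _ = fields_at_points(single_h(), exp_model, points)
        shifted = Structure(
            [Atom("H", "H1", "MOL", 1, "A", np.array([1.2, 0.0, 0.0]))]
        )
        rho_b, _, _ = fields_at_points(shifted, exp_model, points)
        np.testing.assert_allclose(rho_pair, rho_a + rho_b, rtol=1e-12)

    def test_analytic_gradient_matches_finite_differences(self, exp_model):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1.2, 1.2, (30, 3))
        pts = pts[np.linalg.norm(pts, axis=1) > 0.3]
        structure = h_pair(1.0)
        _, grad, _ = fields_at_points(structure, exp_model, pts)
        h_bohr = 5e-5
        h_ang = h_bohr / BOHR_PER_ANGSTROM
        for i, p in enumerate(pts):
            num = np.zeros(3)
            for d in range(3):
                for sgn in (1.0, -1.0):
                    q = p.copy()
                    q[d] += sgn * h_ang
                    rho_q, _, _ = fields_at_points(structure, exp_model, q[None])
                    num[d] += sgn * rho_q[0]
                num[d] /= 2 * h_bohr
            np.testing.assert_allclose(grad[i], num, atol=1e-6)

    def test_analytic_hessian_matches_gradient_differences(self, exp_model):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1.2, 1.2, (10, 3))
        pts = pts[np.linalg.norm(pts, axis=1) > 0.4]
        structure = single_h()
        _, _, hess = fields_at_points(structure, exp_model, pts)
        h_bohr = 5e-5
        h_ang = h_bohr / BOHR_PER_ANGSTROM
        for i, p in enumerate(pts):
            num = np.zeros((3, 3))
            for d in range(3):
                for sgn in (1.0, -1.0):
                    q = p.copy()
                    q[d] += sgn * h_ang
                    _, grad_q, _ = fields_at_points(structure, exp_model, q[None])
                    num[d] += sgn * grad_q[0]
                num[d] /= 2 * h_bohr
            np.testing.assert_allclose(hess[i], 0.5 * (num + num.T), atol=1e-6)

    def test_missing_element_named(self):
        structure = Structure([Atom("P", "P1", "MOL", 1, "A", np.zeros(3))])
        model = ProatomModel({"H": [(0.3, 0.8)]})
        with pytest.raises(KeyError, match="P"):
            promolecular_fields(structure, model, spacing=0.5)

    def test_heavy_atom_only_structure_warns(self):
        ring = synthetic_data.make_ring()
        with pytest.warns(UserWarning, match="no hydrogens"):
            promolecular_fields(ring, spacing=0.5, padding=1.0)


class TestReducedGradient:
    def test_zero_gradient_gives_zero_s(self):
        s = reduced_gradient(np.array([0.1, 0.2]), np.zeros((2, 3)))
        np.testing.assert_array_equal(s, 0.0)

    def test_single_proatom_closed_form(self, exp_model):
        """For rho = c exp(-r/zeta): s(r) = 1 / (2 (3 pi^2)^(1/3) zeta rho^(1/3))."""
        g = nci_fields(single_h(), model=exp_model, spacing=0.2, padding=2.0)
        pts = g.points() * BOHR_PER_ANGSTROM
        r = np.linalg.norm(pts, axis=1)
        mask = r > 0.2
        rho = 0.3 * np.exp(-r / 0.8)
        want = 1.0 / (RDG_PREFACTOR * 0.8 * rho ** (1.0 / 3.0))
        np.testing.assert_allclose(g.s[mask], want[mask], atol=1e-8)

    def test_midpoint_of_homonuclear_pair_has_zero_s(self, exp_model):
        pair = h_pair(2.0)
        # grid node exactly at the bond midpoint
        grid = VolumetricGrid(
            np.array([1.0, 0.0, 0.0]), np.eye(3) * 0.1, (1, 1, 1), np.zeros(1)
        )
        g = promolecular_fields(pair, exp_model, grid)
        s = reduced_gradient(g.rho, g.grad)
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        # attractive signature: middle Hessian eigenvalue < 0 at the saddle
        assert g.lambda2[0] < 0

    def test_scaling_law(self, exp_model):
        """rho -> k rho with grad -> k grad sends s -> k^(-1/3) s."""
        rho = np.array([0.05, 0.2, 0.7])
        grad = np.array([[0.01, 0.0, 0.0], [0.0, 0.1, 0.0], [0.02, 0.03, 0.0]])
        k = 3.7
        s1 = reduced_gradient(rho, grad)
        s2 = reduced_gradient(k * rho, k * grad)
        np.testing.assert_allclose(s2, k ** (-1.0 / 3.0) * s1, rtol=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            reduced_gradient(np.array([0.0]), np.zeros((1, 3)))


class TestClassification:
    def test_isolated_atom_has_no_low_s_interaction_region(self, exp_model):
        """s grows monotonically outward for one exponential proatom, so the
        retained region is confined to a ball around the nucleus whose radius
        follows from the closed form s(r) = 1/(pref * zeta * rho(r)^(1/3))."""
        c, zeta, s_max = 0.3, 0.8, 0.5
        # solve s(r_cross) = s_max for the single-exponential closed form
        rho_cross = (1.0 / (RDG_PREFACTOR * zeta * s_max)) ** 3
        r_cross = -zeta * np.log(rho_cross / c)
        g = nci_fields(single_h(), model=exp_model, spacing=0.25, padding=2.0)
        pts = g.points() * BOHR_PER_ANGSTROM
        away = np.linalg.norm(pts, axis=1) > r_cross + 1e-9
        assert away.any()
        assert np.all(g.s[away] > s_max)

    def test_pair_produces_interaction_region_near_midpoint(self, exp_model):
        pair = h_pair(2.0)
        g = nci_fields(pair, model=exp_model, spacing=0.15, padding=1.5)
        cls = classify_nci(g, s_max=0.5, signed_rho_cut=0.01)
        low_s_region = np.concatenate(
            [cls.attractive, cls.van_der_waals, cls.repulsive]
        )
        pts = g.points()[low_s_region]
        # some retained point lies in the bonding region between the nuclei
        mid_mask = np.abs(pts[:, 0] - 1.0) < 0.5
        near_axis = np.linalg.norm(pts[:, 1:], axis=1) < 0.5
        assert np.any(mid_mask & near_axis)

    def test_partition_property(self, exp_model):
        g = nci_fields(h_pair(1.6), model=exp_model, spacing=0.2, padding=1.0)
        cls = classify_nci(g)
        assert cls.n_retained == int(np.sum(g.s < cls.s_max))
        together = np.concatenate([cls.attractive, cls.van_der_waals, cls.repulsive])
        assert len(np.unique(together)) == together.size

    def test_empty_retention_warns(self, exp_model):
        # padding chosen so no grid node sits exactly on the nucleus (where
        # the gradient, hence s, is identically zero by symmetry)
        g = nci_fields(single_h(), model=exp_model, spacing=0.5, padding=1.9)
        assert np.all(g.s > 0)
        with pytest.warns(UserWarning, match="empty"):
            cls = classify_nci(g, s_max=1e-9)
        assert cls.n_retained == 0


class TestInterfacialNci:
    def test_stacked_rings_have_vdw_region(self):
        ring = synthetic_data.make_ring()
        upper = [
            Atom(a.element, a.name, "RNG", 2, "A", a.position + np.array([0, 0, 3.4]))
            for a in ring.atoms
        ]
        stack = Structure(ring.atoms + upper)
        ligand = struct_io.select_atoms(stack, "resid 2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid, cls = interfacial_nci(stack, ligand, margin=1.0, spacing=0.3)
        assert cls.van_der_waals.size + cls.attractive.size > 0
        centroid = cls.centroids["van_der_waals"]
        if centroid is not None:
            assert 0.5 < centroid[2] < 3.0  # between the ring planes

    def test_single_atom_zero_margin_box_still_has_a_cell(self):
        structure = single_h()
        ligand = struct_io.select_atoms(structure, "element H")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid, _ = interfacial_nci(structure, ligand, margin=0.0, spacing=0.2)
        assert all(n >= 1 for n in grid.shape)

    def test_cube_round_trip(self, tmp_path, exp_model):
        g = nci_fields(h_pair(1.5), model=exp_model, spacing=0.3, padding=1.0)
        path = tmp_path / "s.cube"
        struct_io.write_grid(g.s_grid(), h_pair(1.5), path)
        back, _ = struct_io.read_grid(path)
        np.testing.assert_allclose(back.values, g.s, rtol=1e-5, atol=1e-9)
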