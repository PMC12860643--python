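"""Geometric primitives: angles, hydrogen placement, SASA, triad metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import biotite.structure as struc

from triadscan.geometry import (
    Thresholds,
    angle,
    coplanarity_collinearity,
    dihedral,
    evaluate_triad_geometry,
    fibonacci_sphere,
    fit_plane,
    is_competent,
    place_atom,
    place_polar_hydrogens,
    sasa,
    stage_thresholds,
)
from triadscan.io import _structure_to_atom_array
from triadscan.model import (
    Atom,
    GeometryMetrics,
    Residue,
    Structure,
    TriadSpec,
    TriadscanError,
)


def _rigid_transform(structure, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    res = []
    for r in structure.residues:
        atoms = [Atom(a.name, a.element, rot @ a.coords + shift) for a in r.atoms]
        res.append(Residue(r.chain_id, r.number, r.aa, atoms, r.hetero))
    return Structure(res)


class TestAnglePrimitives:
    @pytest.mark.parametrize(
        "a,b,c,expected",
        [
            ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (0, 0, 0), (-2, 0, 0), 180.0),
            ((1, 0, 0), (0, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_angle_examples(self, a, b, c, expected):
        assert angle(a, b, c) == pytest.approx(expected, abs=1e-9)

    def test_angle_symmetric_and_rotation_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3))
            ref = angle(a, b, c)
            assert angle(c, b, a) == pytest.approx(ref, abs=1e-9)
            rot = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3)
            assert angle(rot @ a + t, rot @ b + t, rot @ c + t) == pytest.approx(
                ref, abs=1e-7
            )

    def test_angle_rejects_coincident_points(self):
        with pytest.raises(ValueError):
            angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_place_atom_realises_internal_coordinates(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b, c = rng.normal(size=(3, 3)) * 3
            bond, ang, dih = 1.5, 109.0, float(rng.uniform(-180, 180))
            d = place_atom(a, b, c, bond, ang, dih)
            assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-9)
            assert angle(b, c, d) == pytest.approx(ang, abs=1e-7)
            assert dihedral(a, b, c, d) == pytest.approx(dih, abs=1e-7)


class TestPlaneFit:
    def test_coplanar_points_have_zero_rms(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0], [0, 3, 0]], float)
        _, _, rms = fit_plane(pts)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_rms_matches_brute_force_plane_search(self):
        # 5 points in a plane, one lifted by 1 A
        pts = np.array(
            [[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0], [1, 0.5, 0], [1, 1, 1.0]], float
        )
        _, _, rms = fit_plane(pts)

        def cost(x):
            theta, phi, d = x
            n = np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
            return np.mean((pts @ n - d) ** 2)

        best = np.inf
        for theta in np.linspace(0, np.pi, 25):
            for phi in np.linspace(0, 2 * np.pi, 50):
                res = minimize(cost, [theta, phi, 0.0], method="Nelder-Mead")
                best = min(best, res.fun)
        assert rms == pytest.approx(np.sqrt(best), abs=1e-4)


class TestPolarHydrogens:
    def test_his_ring_h_lies_in_ring_plane(self, planted8):
        structure, spec = planted8
        hyd = place_polar_hydrogens(structure, spec)
        his = structure.residue(spec.his_pos)
        ring = his.coords(("CG", "ND1", "CD2", "CE1", "NE2"))
        centroid, normal, _ = fit_plane(ring)
        out_of_plane = abs((hyd.his_h.coords - centroid) @ normal)
        assert out_of_plane < 0.01

    def test_grid_step_20_gives_18_hg_candidates(self, planted8):
        structure, spec = planted8
        hyd = place_polar_hydrogens(structure, spec, grid_step=20.0)
        assert len(hyd.hg_candidates) == 18
        for a in hyd.hg_candidates:
            og = structure.residue(spec.ser_pos).atom("OG").coords
            assert np.linalg.norm(a.coords - og) == pytest.approx(0.96, abs=1e-6)

    def test_missing_og_is_an_error(self, helix8):
        spec = TriadSpec(1, 5, 8)
        with pytest.raises(TriadscanError, match="OG"):
            place_polar_hydrogens(helix8, spec)  # position 1 is still Ala


class TestTriadGeometry:
    def test_planted_geometry_reproduced(self, planted8):
        structure, spec = planted8
        m = evaluate_triad_geometry(structure, spec)
        assert m.d_ser_his == pytest.approx(3.0, abs=0.05)
        assert m.d_his_acid == pytest.approx(3.0, abs=0.05)
        assert 98.0 <= m.ang_ser <= 180.0
        assert 98.0 <= m.ang_his <= 180.0

    def test_d_his_acid_uses_nearest_carboxylate_oxygen(self, planted8):
        structure, spec = planted8
        m = evaluate_triad_geometry(structure, spec)
        hyd = place_polar_hydrogens(structure, spec)
        acid = structure.residue(spec.acid_pos)
        d = [
            np.linalg.norm(acid.atom(n).coords - hyd.his_h.coords)
            for n in ("OD1", "OD2")
        ]
        assert m.d_his_acid == pytest.approx(min(d), abs=1e-9)

    def test_wrong_residue_identity_raises(self, planted8):
        structure, spec = planted8
        bad = TriadSpec(2, spec.his_pos, spec.acid_pos)  # position 2 is Ala
        with pytest.raises(TriadscanError, match="SER"):
            evaluate_triad_geometry(structure, bad)

    def test_metrics_invariant_under_rigid_transform(self, planted8):
        structure, spec = planted8
        m0 = evaluate_triad_geometry(structure, spec)
        m1 = evaluate_triad_geometry(_rigid_transform(structure, seed=4), spec)
        for field in ("d_ser_his", "d_his_acid", "ang_ser", "ang_his",
                      "coplanarity", "collinearity"):
            assert getattr(m1, field) == pytest.approx(getattr(m0, field), abs=1e-6)

    def test_collinear_centroids_give_180(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert angle(pts[0], pts[1], pts[2]) == pytest.approx(180.0)

    def test_coplanarity_collinearity_wrapper(self, planted8):
        structure, spec = planted8
        cop, col = coplanarity_collinearity(structure, spec)
        m = evaluate_triad_geometry(structure, spec)
        assert cop == pytest.approx(m.coplanarity)
        assert col == pytest.approx(m.collinearity)


class TestCompetence:
    def _metrics(self, d_sh, d_ha, ang_s=150.0, ang_h=150.0, d_lig=None):
        return GeometryMetrics(d_sh, d_ha, ang_s, ang_h, d_ser_lig=d_lig)

    def test_stage_windows(self):
        m = self._metrics(3.8, 3.8)
        assert is_competent(m, stage_thresholds("relax"))
        assert not is_competent(m, stage_thresholds("md"))
        tight = self._metrics(3.4, 3.4, d_lig=4.9)
        assert is_competent(tight, stage_thresholds("pele_md"))

    def test_angle_window_boundary(self):
        thr = Thresholds(4.0, 4.0, ang_min=100.0, ang_max=180.0, apply_angles=True)
        assert not is_competent(self._metrics(3.0, 3.0, ang_s=95.0), thr)
        assert is_competent(self._metrics(3.0, 3.0, ang_s=100.0), thr)

    def test_ligand_distance_checked_only_when_present(self):
        thr = stage_thresholds("md")
        assert is_competent(self._metrics(3.0, 3.0, d_lig=None), thr)
        assert not is_competent(self._metrics(3.0, 3.0, d_lig=5.5), thr)


class TestSasa:
    def test_isolated_carbon_matches_sphere_area(self):
        s = Structure([Residue("A", 1, "GLY", [Atom("CA", "C", [0, 0, 0])])])
        result = sasa(s, probe_radius=1.4, n_points=960)
        expected = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert result.per_atom[(1, "CA")] == pytest.approx(expected, rel=0.01)

    def test_fully_enclosed_atom_has_zero_sasa(self, cage):
        result = sasa(cage)
        assert result.per_residue[1] == pytest.approx(0.0, abs=1e-9)
        assert result.relative[1] == pytest.approx(0.0, abs=1e-9)

    def test_sasa_monotone_under_added_neighbour(self):
        lone = Structure([Residue("A", 1, "GLY", [Atom("CA", "C", [0, 0, 0])])])
        paired = Structure(
            [
                Residue("A", 1, "GLY", [Atom("CA", "C", [0, 0, 0])]),
                Residue("A", 2, "GLY", [Atom("CA", "C", [2.5, 0, 0])]),
            ]
        )
        a0 = sasa(lone).per_atom[(1, "CA")]
        a1 = sasa(paired).per_atom[(1, "CA")]
        assert a1 < a0

    def test_far_separated_atoms_are_additive(self):
        s = Structure(
            [
                Residue("A", 1, "GLY", [Atom("CA", "C", [0, 0, 0])]),
                Residue("A", 2, "GLY", [Atom("CA", "C", [50.0, 0, 0])]),
            ]
        )
        result = sasa(s)
        iso = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert result.per_atom[(1, "CA")] + result.per_atom[(2, "CA")] == pytest.approx(
            2 * iso, rel=0.01
        )

    def test_point_density_convergence(self, helix8):
        lo = sasa(helix8, n_points=960)
        hi = sasa(helix8, n_points=3840)
        for key, v_hi in hi.per_residue.items():
            assert lo.per_residue[key] == pytest.approx(v_hi, abs=2.0, rel=0.02)

    def test_against_independent_shrake_rupley(self, helix12):
        """Cross-check per-residue totals against biotite's implementation."""
        ours = sasa(helix12, probe_radius=1.4, n_points=1920)
        arr = _structure_to_atom_array(helix12)
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=1000, vdw_radii="Single")
        per_res = {}
        for atom_sasa, res_id in zip(theirs, arr.res_id):
            per_res[int(res_id)] = per_res.get(int(res_id), 0.0) + float(atom_sasa)
        for res_id, ref in per_res.items():
            assert ours.per_residue[res_id] == pytest.approx(ref, rel=0.10)

    def test_unknown_element_radius_is_an_error(self):
        s = Structure([Residue("A", 1, "UNK", [Atom("X1", "Xx", [0, 0, 0])], hetero=True)])
        s.residues = [Residue("A", 1, "GLY", [Atom("X1", "Xx", [0, 0, 0])])]
        with pytest.raises(TriadscanError, match="Xx"):
            sasa(s)

    def test_fibonacci_lattice_is_unit_and_deterministic(self):
        pts = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, fibonacci_sphere(960))
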