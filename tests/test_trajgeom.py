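"""Geometry engines: superposition, fluctuations, dihedrals, SASA, spheres.

Independent oracles: a quaternion eigen-decomposition for Kabsch RMSD,
MDAnalysis for dihedral angles, Bio.PDB's Shrake-Rupley for SASA, and
closed-form spheres/triangles for the enclosing-sphere volume.
"""

import numpy as np
import pytest

from trajmech.structure_io import AtomRecord, Frame, Trajectory
from trajmech.trajgeom import (
    DihedralStateModel,
    SasaParams,
    assign_states,
    bfactor_to_rmsf,
    circular_distance,
    dihedral,
    enclosing_sphere_volume,
    kabsch_superpose,
    rmsd_series,
    rmsf,
    rmsf_to_bfactor,
    sasa_frame,
    sasa_series,
)


def _rotation(axis, deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.radians(deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _quaternion_rmsd(a, b):
    """Independent minimum RMSD via the quaternion (Kearsley) eigenproblem."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k).max()
    e0 = (a**2).sum() + (b**2).sum()
    return np.sqrt(max(0.0, e0 - 2 * lam) / len(a))


def _traj_from_frames(coord_list):
    n = coord_list[0].shape[0]
    topo = [
        AtomRecord(serial=i + 1, name=f"C{i}", element="C", res_name="GLY",
                   res_seq=i + 1, chain_id="A")
        for i in range(n)
    ]
    frames = [Frame(c, time=float(t)) for t, c in enumerate(coord_list)]
    return Trajectory(topology=topo, frames=frames)


class TestKabsch:
    def test_identical_structures_rmsd_zero(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        rot, trans, r = kabsch_superpose(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_rigid_motion_invariance(self):
        pts = np.random.default_rng(1).normal(size=(12, 3))
        moved = pts @ _rotation([0, 0, 1], 90).T + np.array([5.0, -2.0, 7.0])
        rot, trans, r = kabsch_superpose(moved, pts)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(size=(8, 3)) * 2
            b = a + rng.normal(size=(8, 3)) * 0.5
            _, _, r = kabsch_superpose(a, b)
            assert r == pytest.approx(_quaternion_rmsd(a, b), abs=1e-9)

    def test_single_displaced_atom(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(20, 3)) * 3
        b = a.copy()
        b[0] += [1.0, 0.0, 0.0]
        _, _, r = kabsch_superpose(a, b)
        assert r == pytest.approx(_quaternion_rmsd(a, b), abs=1e-9)

    def test_rejects_degenerate_input(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_proper_rotation_for_reflected_cloud(self):
        pts = np.random.default_rng(4).normal(size=(9, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0)


class TestRmsdSeries:
    def test_reference_frame_is_zero(self):
        rng = np.random.default_rng(5)
        frames = [rng.normal(size=(10, 3)) * 2 for _ in range(4)]
        traj = _traj_from_frames(frames)
        series = rmsd_series(traj, traj.frames[0])
        assert series[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigidly_rotating_trajectory_is_all_zero(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(10, 3)) * 2
        frames = [base @ _rotation([1, 1, 0], 30 * t).T + t for t in range(5)]
        traj = _traj_from_frames(frames)
        np.testing.assert_allclose(rmsd_series(traj, traj.frames[0]), 0.0,
                                   atol=1e-9)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        base = np.random.default_rng(7).normal(size=(8, 3))
        traj = _traj_from_frames([base.copy() for _ in range(5)])
        per_atom, _ = rmsf(traj)
        np.testing.assert_allclose(per_atom, 0.0, atol=1e-12)

    def test_alternating_unit_displacement(self):
        base = np.random.default_rng(8).normal(size=(6, 3)) * 5
        plus, minus = base.copy(), base.copy()
        plus[0, 0] += 1.0
        minus[0, 0] -= 1.0
        traj = _traj_from_frames([plus, minus] * 10)
        per_atom, _ = rmsf(traj, fit=False)
        assert per_atom[0] == pytest.approx(1.0)
        np.testing.assert_allclose(per_atom[1:], 0.0, atol=1e-12)

    def test_isotropic_jitter_limit(self):
        # RMSF -> sigma * sqrt(3) for i.i.d. Gaussian displacement
        sigma, n_frames = 0.3, 4000
        rng = np.random.default_rng(9)
        base = rng.normal(size=(4, 3)) * 10
        frames = [base + rng.normal(scale=sigma, size=base.shape)
                  for _ in range(n_frames)]
        traj = _traj_from_frames(frames)
        per_atom, _ = rmsf(traj, fit=False)
        expect = sigma * np.sqrt(3)
        se = expect / np.sqrt(2 * n_frames)  # delta-method scale
        assert np.all(np.abs(per_atom - expect) < 5 * se)

    def test_single_frame_rejected(self):
        traj = _traj_from_frames([np.zeros((4, 3)) + np.arange(12).reshape(4, 3)])
        with pytest.raises(ValueError):
            rmsf(traj)


class TestBfactorConversion:
    def test_analytic_point(self):
        assert bfactor_to_rmsf(8 * np.pi**2 / 3) == pytest.approx(1.0)
        assert bfactor_to_rmsf(0.0) == 0.0

    def test_round_trip_identity(self):
        vals = np.linspace(0, 3, 7)
        np.testing.assert_allclose(bfactor_to_rmsf(rmsf_to_bfactor(vals)), vals,
                                   atol=1e-14)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bfactor_to_rmsf(-1.0)


class TestDihedral:
    def test_planar_trans_and_cis(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0, abs=1e-10)

    def test_matches_mdanalysis(self):
        MDAmod = pytest.importorskip("MDAnalysis.lib.distances")
        rng = np.random.default_rng(10)
        for _ in range(30):
            p = rng.normal(size=(4, 3)) * 3
            ref = np.degrees(
                MDAmod.calc_dihedrals(p[0][None], p[1][None], p[2][None], p[3][None])
            )[0]
            assert circular_distance(dihedral(*p), ref) < 1e-3

    def test_order_reversal_invariant_and_mirror_negates(self):
        rng = np.random.default_rng(11)
        p = rng.normal(size=(4, 3)) * 2
        fwd = dihedral(*p)
        assert dihedral(*p[::-1]) == pytest.approx(fwd)
        mirrored = p * np.array([1.0, 1.0, -1.0])
        assert dihedral(*mirrored) == pytest.approx(-fwd)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestAssignStates:
    @pytest.mark.parametrize(
        "angle,label",
        [
            (-85.0, "native"),      # 5 deg from the native center
            (175.0, "altered"),     # 6 deg from -179 across the wrap
            (-130.0, "unassigned"),  # 50 and 49 deg away, both > 45
        ],
    )
    def test_examples(self, angle, label):
        series = assign_states([angle])
        assert series.labels[0] == label

    def test_fraction_and_switch_events(self):
        angles = [-80, -80, -179, -179, -179, -80]
        series = assign_states(angles)
        assert series.altered_fraction == pytest.approx(0.5)
        assert series.switch_events == [2, 5]

    def test_state_separation_is_99_degrees(self):
        assert DihedralStateModel().separation == pytest.approx(99.0)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            DihedralStateModel(tolerance=95.0)
        with pytest.raises(ValueError):
            DihedralStateModel(native_center=200.0)


def _lone_atoms(coord_list, element="C"):
    topo = [
        AtomRecord(serial=i + 1, name=f"X{i}", element=element, res_name="GLY",
                   res_seq=i + 1, chain_id="A")
        for i in range(len(coord_list))
    ]
    return Trajectory(topology=topo, frames=[Frame(np.array(coord_list, float))])


class TestSasa:
    def test_isolated_atom_is_analytic_sphere(self):
        traj = _lone_atoms([[0, 0, 0]])
        per_atom, _ = sasa_frame(traj, 0)
        expect = 4 * np.pi * (1.7 + 1.4) ** 2  # 120.76
        assert per_atom[0] == pytest.approx(expect, rel=0.01)

    def test_distant_atoms_do_not_occlude(self):
        traj = _lone_atoms([[0, 0, 0], [100, 0, 0]])
        per_atom, _ = sasa_frame(traj, 0)
        expect = 4 * np.pi * 3.1**2
        assert sum(per_atom.values()) == pytest.approx(2 * expect, rel=0.01)

    def test_fully_enclosed_atom_is_zero(self):
        from trajmech.synthetic_data import _fibonacci_sphere

        shell = 2.5 * _fibonacci_sphere(100)
        traj = _lone_atoms([[0, 0, 0]] + shell.tolist())
        per_atom, _ = sasa_frame(traj, 0, subset=[0])
        assert per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_quadrature_convergence(self):
        # doubling the point count moves any atom by < 0.5% of its expanded
        # sphere area (the scale on which the quadrature discretizes)
        rng = np.random.default_rng(12)
        traj = _lone_atoms((rng.normal(size=(8, 3)) * 4.0).tolist())
        lo, _ = sasa_frame(traj, 0, SasaParams(n_sphere_points=960))
        hi, _ = sasa_frame(traj, 0, SasaParams(n_sphere_points=1920))
        sphere_area = 4 * np.pi * (1.7 + 1.4) ** 2
        for i in lo:
            assert abs(lo[i] - hi[i]) <= 0.005 * sphere_area

    def test_matches_biopython_shrake_rupley(self):
        bp = pytest.importorskip("Bio.PDB")
        from Bio.PDB.SASA import ShrakeRupley

        rng = np.random.default_rng(13)
        coords = rng.normal(size=(15, 3)) * 3.0
        traj = _lone_atoms(coords.tolist())
        mine, _ = sasa_frame(traj, 0, SasaParams(n_sphere_points=960))

        struct = bp.Structure.Structure("s")
        model = bp.Model.Model(0)
        chain = bp.Chain.Chain("A")
        struct.add(model)
        model.add(chain)
        for i, xyz in enumerate(coords):
            res = bp.Residue.Residue((" ", i + 1, " "), "GLY", "")
            atom = bp.Atom.Atom(f"X{i}", xyz, 0.0, 1.0, " ", f"X{i}", i + 1, "C")
            res.add(atom)
            chain.add(res)
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(struct, level="A")
        ref = [a.sasa for a in struct.get_atoms()]
        for i, r in enumerate(ref):
            assert mine[i] == pytest.approx(r, rel=0.03, abs=0.5)

    def test_series_windows_static_open_state(self):
        from trajmech.synthetic_data import generate, scenario_defaults

        traj, _ = generate(scenario_defaults("WT", n_frames=8, seed=0))
        series = sasa_series(traj, subset="resid 31-33", window_ns=0.05)
        assert len(series.windows) == 4
        for w in series.window_means:
            np.testing.assert_allclose(w, series.window_means[0], atol=1e-9)
        assert series.final_window_total == pytest.approx(
            float(series.window_means[-1].sum())
        )

    def test_window_longer_than_trajectory_degrades_to_one(self):
        from trajmech.synthetic_data import generate, scenario_defaults

        traj, _ = generate(scenario_defaults("WT", n_frames=4, seed=0))
        series = sasa_series(traj, subset="resid 31-33", window_ns=10.0)
        assert len(series.windows) == 1


class TestEnclosingSphere:
    def test_two_atoms_closed_form(self):
        vol = enclosing_sphere_volume(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert vol == pytest.approx(4.0 / 3.0 * np.pi, rel=1e-12)

    def test_equilateral_triangle_diameter_vs_welzl(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]], float)
        diam = enclosing_sphere_volume(pts, mode="diameter")
        assert diam == pytest.approx(4.0 / 3.0 * np.pi)
        welzl = enclosing_sphere_volume(pts, mode="welzl")
        r_exact = 2.0 / np.sqrt(3.0)  # circumradius > 1: documented gap
        assert welzl == pytest.approx(4.0 / 3.0 * np.pi * r_exact**3, rel=1e-6)
        assert welzl > diam

    def test_single_atom_rejected(self):
        with pytest.raises(ValueError):
            enclosing_sphere_volume(np.array([[0.0, 0, 0]]))

    def test_jung_bound_on_random_point_sets(self):
        # diameter-mode radius >= welzl radius / (sqrt(3/2)) in 3D
        rng = np.random.default_rng(14)
        for _ in range(20):
            pts = rng.normal(size=(rng.integers(3, 12), 3)) * 4
            v_d = enclosing_sphere_volume(pts, mode="diameter")
            v_w = enclosing_sphere_volume(pts, mode="welzl")
            assert v_w <= v_d * np.sqrt(1.5) ** 3 * (1 + 1e-9)
            # and welzl truly encloses: every point inside its radius
            r_w = (v_w / (4 * np.pi / 3)) ** (1 / 3)
            from trajmech.trajgeom import _welzl

            c, r = _welzl(pts)
            assert np.all(np.linalg.norm(pts - c, axis=1) <= r + 1e-6)
            assert r == pytest.approx(r_w, rel=1e-9)
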