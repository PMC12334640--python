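"""Solvation-shell geometry, trajectory I/O, maps and the V(N) estimator."""

import math

import numpy as np
import pytest

from ionvol import (SolvationSnapshot, density_map, fit_vn_global, min_image,
                    orientation_records, read_snapshots, vn_curve, write_xyz)
from ionvol.synth import SolvationDesign, gen_solvation_snapshots

from conftest import make_snapshot


class TestOrientationGeometry:
    def test_collinear_water_theta_180(self, collinear_water_snapshot):
        rec = orientation_records(collinear_water_snapshot, r_max=12.5)
        assert len(rec) == 1
        assert rec["d"][0] == pytest.approx(3.0)
        assert rec["theta"][0] == pytest.approx(180.0, abs=1e-9)

    def test_mirrored_hydrogens_theta_0(self):
        snap = make_snapshot(
            [((3.0, 0, 0), (2.414, 0.757, 0), (2.414, -0.757, 0))])
        rec = orientation_records(snap)
        assert rec["theta"][0] == pytest.approx(0.0, abs=1e-9)

    def test_law_of_cosines_oracle(self):
        # independent evaluation from raw side lengths
        ion = np.array([0.5, -0.2, 1.0])
        O = np.array([2.5, 1.1, -0.7])
        q = np.array([2.9, 1.6, -0.2])
        hh = np.array([0.3, -0.5, -0.4])
        hh = 0.757 * hh / np.linalg.norm(hh)
        # place Q at distance 0.586 from O along (q - O)
        qdir = (q - O) / np.linalg.norm(q - O)
        Q = O + 0.586 * qdir
        snap = make_snapshot([(O, Q + hh, Q - hh)], ion=ion)
        rec = orientation_records(snap)
        a = np.linalg.norm(ion - O)
        b = np.linalg.norm(Q - O)
        c = np.linalg.norm(ion - Q)
        theta = math.degrees(math.acos((a * a + b * b - c * c) / (2 * a * b)))
        assert rec["theta"][0] == pytest.approx(theta, abs=1e-9)
        assert rec["d"][0] == pytest.approx(a)

    def test_r_max_beyond_half_box_rejected(self, collinear_water_snapshot):
        with pytest.raises(ValueError, match="half the box"):
            orientation_records(collinear_water_snapshot, r_max=13.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        base = next(iter(gen_solvation_snapshots(
            SolvationDesign(mode="isotropic", n_waters=40, n_frames=1, seed=8))))
        rec0 = orientation_records(base, r_max=5.0)
        for _ in range(5):
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            shift = rng.uniform(-2, 2, 3)
            center = base.ion_position
            rot = SolvationSnapshot(
                box_edge=base.box_edge,
                ion_position=center + shift,
                O=(base.O - center) @ Q.T + center + shift,
                H1=(base.H1 - center) @ Q.T + center + shift,
                H2=(base.H2 - center) @ Q.T + center + shift)
            rec = orientation_records(rot, r_max=5.0)
            assert np.allclose(np.sort(rec["d"]), np.sort(rec0["d"]), atol=1e-9)
            assert np.allclose(np.sort(rec["theta"]), np.sort(rec0["theta"]),
                               atol=1e-7)

    def test_minimum_image_shift_invariance(self, collinear_water_snapshot):
        snap = collinear_water_snapshot
        rec0 = orientation_records(snap)
        L = snap.box_edge
        for axis in range(3):
            for sign in (-1, 1):
                shift = np.zeros(3)
                shift[axis] = sign * L
                moved = SolvationSnapshot(
                    box_edge=L, ion_position=snap.ion_position,
                    O=snap.O + shift, H1=snap.H1 + shift, H2=snap.H2 + shift)
                rec = orientation_records(moved)
                assert rec["d"][0] == pytest.approx(rec0["d"][0], abs=1e-9)
                assert rec["theta"][0] == pytest.approx(rec0["theta"][0],
                                                        abs=1e-9)

    def test_straddling_water_valid_after_unwrap(self):
        # hydrogen wrapped to the far side of the box
        L = 25.0
        snap = make_snapshot(
            [((0.2, 0, 0), (-0.386 + L, 0.757, 0), (-0.386 + L, -0.757, 0))],
            box_edge=L, ion=(3.0, 0.0, 0.0))
        snap.validate()  # O-H ~0.96 Å after minimum image
        rec = orientation_records(snap)
        assert rec["theta"][0] == pytest.approx(180.0, abs=1e-6)


class TestTrajectoryIO:
    def _two_frames(self):
        design = SolvationDesign(mode="isotropic", n_waters=3, n_frames=2,
                                 seed=3)
        return list(gen_solvation_snapshots(design))

    def test_xyz_round_trip(self, tmp_path):
        frames = self._two_frames()
        path = tmp_path / "traj.xyz"
        write_xyz(frames, path)
        back = list(read_snapshots(path))
        assert len(back) == 2
        for a, b in zip(frames, back):
            assert b.n_waters == 3
            assert np.allclose(a.O, b.O, atol=1e-6)
            assert np.allclose(a.H2, b.H2, atol=1e-6)

    def test_missing_box_is_format_error(self, tmp_path):
        path = tmp_path / "nobox.xyz"
        path.write_text("1\nno box here\nION 0 0 0\n")
        with pytest.raises(ValueError, match="box"):
            list(read_snapshots(path))

    def test_unpaired_hydrogens_reported_with_frame(self, tmp_path):
        path = tmp_path / "badh.xyz"
        path.write_text("3\nbox=25\nION 0 0 0\nOW 3 0 0\nHW1 3.5 0.7 0\n")
        with pytest.raises(ValueError, match="frame 0"):
            list(read_snapshots(path))

    def test_pdb_multimodel_reader(self, tmp_path):
        frames = self._two_frames()
        path = tmp_path / "traj.pdb"
        with open(path, "w") as fh:
            fh.write(f"CRYST1{frames[0].box_edge:9.3f}\n")
            for i, snap in enumerate(frames, 1):
                fh.write(f"MODEL {i:8d}\n")
                serial = 1

                def atom(name, xyz):
                    nonlocal serial
                    fh.write(f"ATOM  {serial:5d} {name:<4s}SOL A   1    "
                             f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}\n")
                    serial += 1

                atom("NA", snap.ion_position)
                for o, h1, h2 in zip(snap.O, snap.H1, snap.H2):
                    atom("OW", o); atom("HW1", h1); atom("HW2", h2)
                fh.write("ENDMDL\n")
        back = list(read_snapshots(path, fmt="pdb-multimodel"))
        assert len(back) == 2
        assert np.allclose(back[0].O, frames[0].O, atol=1e-3)


class TestDensityMap:
    def test_single_point_single_bin(self):
        rec = np.array([(3.0, 90.0)] * 10, dtype=[("d", float), ("theta", float)])
        grid = density_map(rec, np.array([0, 2, 4.0]), np.array([0, 60, 120, 180.0]))
        assert grid.sum() == 10
        assert grid[1, 1] == 10

    def test_empty_records_rejected(self):
        rec = np.empty(0, dtype=[("d", float), ("theta", float)])
        with pytest.raises(ValueError, match="no orientation"):
            density_map(rec, np.array([0, 1.0]), np.array([0, 180.0]))

    def test_non_increasing_bins_rejected(self):
        rec = np.array([(1.0, 1.0)], dtype=[("d", float), ("theta", float)])
        with pytest.raises(ValueError, match="increasing"):
            density_map(rec, np.array([1.0, 0.5]), np.array([0, 180.0]))

    def test_isotropic_corrected_flat_uncorrected_jacobian(self):
        from scipy.stats import chi2

        design = SolvationDesign(mode="isotropic", n_frames=150, seed=12)
        recs = [orientation_records(s, r_max=12.0)
                for s in gen_solvation_snapshots(design)]
        records = np.concatenate(recs)
        d_bins = np.linspace(2.0, 12.0, 9)
        t_bins = np.linspace(0.0, 180.0, 10)
        counts = density_map(records, d_bins, t_bins, corrected=False)
        dvol = np.diff(d_bins**3) / 3.0
        avol = np.cos(np.radians(t_bins[:-1])) - np.cos(np.radians(t_bins[1:]))
        jac = np.outer(dvol, avol)
        expected = jac / jac.sum() * counts.sum()
        use = expected >= 20
        stat = float(np.sum((counts[use] - expected[use]) ** 2 / expected[use]))
        dof = use.sum() - 1
        assert stat < chi2.ppf(0.99, dof)
        # corrected map is flat at unity over the far field
        corr = density_map(records, d_bins, t_bins, corrected=True)
        far = corr[d_bins[:-1] >= 8.0]
        assert np.nanmean(far) == pytest.approx(1.0, abs=0.05)

    def test_shell_modes_match_qualitative_orientation(self):
        def first_shell_theta(mode, d_max, lo, hi):
            design = SolvationDesign(mode=mode, n_frames=30, seed=6)
            recs = np.concatenate([
                orientation_records(s) for s in gen_solvation_snapshots(design)])
            first = recs[recs["d"] < d_max]
            return np.mean((first["theta"] >= lo) & (first["theta"] <= hi))

        assert first_shell_theta("cation-like", 2.8, 120, 180) > 0.8
        assert first_shell_theta("anion-like", 4.0, 30, 90) > 0.8
        # bulk-like: split between donor (>120) and acceptor (<60) peaks
        design = SolvationDesign(mode="bulk-like", n_frames=30, seed=6)
        recs = np.concatenate([
            orientation_records(s) for s in gen_solvation_snapshots(design)])
        first = recs[recs["d"] < 3.3]
        donors = np.mean(first["theta"] > 120)
        acceptors = np.mean(first["theta"] < 60)
        assert donors > 0.25 and acceptors > 0.25


class TestVNCurve:
    def test_direct_formula_small_frame(self):
        snap = make_snapshot(
            [((1.0, 0, 0), (1.586, 0.757, 0), (1.586, -0.757, 0)),
             ((0, 2.0, 0), (0.757, 2.586, 0), (-0.757, 2.586, 0)),
             ((0, 0, 3.0), (0.757, 0, 3.586), (-0.757, 0, 3.586))])
        curve = vn_curve([snap], N_max=3)
        assert curve.V_mean[1] == pytest.approx(4 / 3 * math.pi * 8.0)
        assert np.all(np.diff(curve.V_mean) > 0)

    def test_n_max_too_large_names_admissible_maximum(self):
        design = SolvationDesign(mode="isotropic", n_waters=50, n_frames=2,
                                 seed=1)
        with pytest.raises(ValueError, match="admissible|waters"):
            vn_curve(gen_solvation_snapshots(design), N_max=400)

    def test_poisson_fluid_expectation(self):
        # E[V(N)] = N/rho + core volume for the hard-core Poisson fluid
        rho = 0.0334
        r_ex = 2.0
        design = SolvationDesign(mode="hard-core", r_ex=r_ex,
                                 target_density=rho, n_frames=600,
                                 count_distribution="poisson", seed=42)
        curve = vn_curve(gen_solvation_snapshots(design))
        v0 = 4 / 3 * math.pi * r_ex**3
        for N in (50, 100, 150):
            expected = N / rho + v0
            z = (curve.V_mean[N - 1] - expected) / curve.V_se[N - 1]
            assert abs(z) < 4.0


class TestFitVnGlobal:
    def test_zero_core_zero_intercept(self):
        design = SolvationDesign(mode="hard-core", r_ex=0.0,
                                 target_density=0.0334, n_frames=800,
                                 count_distribution="poisson", seed=17)
        curve = vn_curve(gen_solvation_snapshots(design))
        fit = fit_vn_global({"none": curve})
        # honest scatter of the intercept is a few Å³ at this frame count
        assert abs(fit["intercepts"]["none"]) < 6.0
        assert fit["slope"] == pytest.approx(1 / 0.0334, rel=0.01)

    def test_too_few_points_rejected(self):
        design = SolvationDesign(mode="isotropic", n_frames=2, seed=2)
        curve = vn_curve(gen_solvation_snapshots(design))
        with pytest.raises(ValueError, match="usable points"):
            fit_vn_global({"x": curve}, N_skip=len(curve.N) - 2)
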