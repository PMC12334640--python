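"""Density model: Debye-Hückel term, closed-form inversion, global fit."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ionvol import (SALTS, DensityRecord, ThermalVolumeModel, apparent_rhs,
                    dh_term, extremum_temperature, fit_salt, predict_density,
                    read_density_csv, write_density_csv)
from ionvol.reference import d0_ref
from ionvol.synth import DensityDesign, gen_density_dataset


class TestDhTerm:
    def test_zero_at_zero_molality(self, ctx):
        assert dh_term(0.0, 1, 25.0, ctx) == 0.0

    def test_small_molality_limiting_law(self, ctx):
        # dh -> Av * omega^{3/2} * sqrt(m) as m -> 0
        m = 1e-6
        for omega in (1, 3, 4):
            expected = ctx.av(25.0) * omega**1.5 * np.sqrt(m)
            # first-order agreement; next order is b*sqrt(omega*m)/2 ~ 1e-3
            assert dh_term(m, omega, 25.0, ctx) == pytest.approx(expected, rel=5e-3)

    def test_monotone_in_m_and_omega(self, ctx):
        m = np.geomspace(1e-4, 3e-2, 30)
        vals = dh_term(m, 3, 25.0, ctx)
        assert np.all(np.diff(vals) > 0)
        assert dh_term(0.01, 4, 25.0, ctx) > dh_term(0.01, 3, 25.0, ctx)

    def test_negative_molality_rejected(self, ctx):
        with pytest.raises(ValueError):
            dh_term(-1e-3, 1, 25.0, ctx)


class TestApparentRhs:
    def test_reduces_to_M_over_d0_when_d_equals_d0(self):
        assert apparent_rhs(0.9971, 0.9971, 0.01, 58.44) == pytest.approx(
            58.44 / 0.9971)

    def test_singular_at_zero_molality(self):
        with pytest.raises(ZeroDivisionError):
            apparent_rhs(0.998, 0.997, 0.0, 58.44)

    def test_against_bisection_inversion(self, sctx, nacl):
        # independent oracle: numerically invert the working equation on d
        V0, m, T = 16.43, 0.03, 25.0
        d0 = d0_ref(T)
        target = V0 + dh_term(m, nacl.omega, T, sctx)

        def f(d):
            return apparent_rhs(d, d0, m, nacl.M) - target

        d_star = brentq(f, d0, d0 * 1.01, xtol=1e-14)
        assert apparent_rhs(d_star, d0, m, nacl.M) == pytest.approx(16.69, abs=0.01)
        model = ThermalVolumeModel(V_ref=V0)
        assert predict_density(m, T, model, nacl, 0.0, sctx) == pytest.approx(
            d_star, abs=1e-12)


class TestPredictDensity:
    def test_returns_offset_solvent_density_at_zero_m(self, ctx, nacl, nacl_truth):
        dd0 = 1.5e-5
        assert predict_density(0.0, 25.0, nacl_truth, nacl, dd0, ctx) == \
            pytest.approx(d0_ref(25.0) + dd0, abs=1e-15)

    def test_nacl_printed_scale(self, ctx, nacl, nacl_truth):
        d = predict_density(0.03, 25.0, nacl_truth, nacl, 0.0, ctx)
        assert d == pytest.approx(0.99830, abs=2e-5)

    def test_round_trip_all_solutes(self, ctx):
        # exact closed-form inverse across the studied molality range
        m = np.geomspace(1e-3, 3e-2, 12)
        for name, salt in SALTS.items():
            model = ThermalVolumeModel(V_ref=15.0, alpha=0.05, beta=-2e-3)
            for T in (20.0, 30.0, 40.0):
                d = predict_density(m, T, model, salt, 5e-6, ctx)
                vpsi = apparent_rhs(d, d0_ref(T) + 5e-6, m, salt.M)
                back = vpsi - dh_term(m, salt.omega, T, ctx)
                assert np.max(np.abs(back - model.value_at(T))) < 1e-9

    def test_denser_than_water_for_positive_M_minus_dV(self, ctx):
        for name in ("NaCl", "MgSO4", "KI"):
            salt = SALTS[name]
            from ionvol.literature import SALT_VOLUMES_25C
            v, *_ = SALT_VOLUMES_25C[name]
            model = ThermalVolumeModel(V_ref=v)
            d = predict_density(0.01, 25.0, model, salt, 0.0, ctx)
            assert d > d0_ref(25.0)

    def test_mgso4_rises_faster_than_nacl(self, ctx):
        m = 0.02
        d_na = predict_density(m, 25.0, ThermalVolumeModel(16.43),
                               SALTS["NaCl"], 0.0, ctx)
        d_mg = predict_density(m, 25.0, ThermalVolumeModel(-4.71),
                               SALTS["MgSO4"], 0.0, ctx)
        assert d_mg - d0_ref(25.0) > d_na - d0_ref(25.0)

    def test_near_linear_in_molality(self, ctx, nacl, nacl_truth):
        # chord deviation below 1% of the total density rise over the range
        m = np.linspace(1e-3, 3e-2, 50)
        d = predict_density(m, 25.0, nacl_truth, nacl, 0.0, ctx)
        chord = d[0] + (d[-1] - d[0]) * (m - m[0]) / (m[-1] - m[0])
        assert np.max(np.abs(d - chord)) < 0.01 * (d[-1] - d[0])


class TestExtremumTemperature:
    def test_marcus_parameterization(self):
        model = ThermalVolumeModel(V_ref=-5.1, alpha=-0.008, beta=-1.7e-4,
                                   T_ref=0.0)
        T, extrapolated = extremum_temperature(model)
        assert T == pytest.approx(-23.5, abs=0.1)
        assert extrapolated

    def test_linear_model_has_no_extremum(self):
        assert extremum_temperature(ThermalVolumeModel(10.0, 0.05, 0.0)) is None

    def test_vertex_at_reference_when_alpha_zero(self):
        T, _ = extremum_temperature(ThermalVolumeModel(10.0, 0.0, -1e-3))
        assert T == 25.0


class TestFitSalt:
    def test_noise_free_round_trip(self, ctx, nacl, nacl_truth):
        design = DensityDesign(noise_sd=0.0, delta_d0_sd=0.0, seed=1)
        records, _ = gen_density_dataset(nacl, nacl_truth, design, ctx)
        res = fit_salt(records, nacl, ctx, "quadratic")
        assert res.model.V_ref == pytest.approx(nacl_truth.V_ref, abs=1e-6)
        assert res.model.alpha == pytest.approx(nacl_truth.alpha, abs=1e-6)
        assert res.model.beta == pytest.approx(nacl_truth.beta, abs=1e-6)
        assert res.residual_sd < 1e-10

    def test_offsets_recovered_and_flagged_below_ceiling(self, ctx, nacl,
                                                         nacl_truth):
        design = DensityDesign(noise_sd=0.0, delta_d0_sd=1e-5, seed=7)
        records, side = gen_density_dataset(nacl, nacl_truth, design, ctx)
        res = fit_salt(records, nacl, ctx, "quadratic")
        for key, injected in side["delta_d0"].items():
            sid, tpart = key.split("@")
            fitted = res.delta_d0[(sid, float(tpart[:-1]))]
            assert fitted == pytest.approx(injected, abs=1e-9)
        assert res.delta_d0_flags == []

    def test_monte_carlo_se_and_bias(self, ctx, nacl, nacl_truth):
        # study-design noise: V_ref SE near 0.1 cm³/mol, negligible bias
        rng = np.random.default_rng(11)
        n_rep = 120
        vrefs, ses = [], []
        for _ in range(n_rep):
            design = DensityDesign(seed=int(rng.integers(2**31)))
            records, _ = gen_density_dataset(nacl, nacl_truth, design, ctx)
            res = fit_salt(records, nacl, ctx, "quadratic")
            vrefs.append(res.model.V_ref)
            ses.append(res.model.se()[0])
        vrefs = np.asarray(vrefs)
        assert np.mean(ses) == pytest.approx(0.1, abs=0.05)
        assert abs(np.mean(vrefs) - nacl_truth.V_ref) < 0.02

    def test_f_test_size_under_null(self, ctx, nacl):
        # with beta = 0 truth, auto mode picks the quadratic rarely
        truth = ThermalVolumeModel(V_ref=16.43, alpha=87e-3, beta=0.0)
        rng = np.random.default_rng(5)
        picks = 0
        n_rep = 60
        for _ in range(n_rep):
            design = DensityDesign(seed=int(rng.integers(2**31)))
            records, _ = gen_density_dataset(nacl, truth, design, ctx)
            res = fit_salt(records, nacl, ctx, "auto")
            picks += res.selected_order == "quadratic"
        assert picks / n_rep <= 0.12  # ~5% nominal size, binomial slack

    def test_single_temperature_quadratic_unidentifiable(self, ctx, nacl,
                                                         nacl_truth):
        design = DensityDesign(temperatures=np.array([25.0]), seed=3)
        records, _ = gen_density_dataset(nacl, nacl_truth, design, ctx)
        with pytest.raises(ValueError, match="beta|alpha"):
            fit_salt(records, nacl, ctx, "quadratic")

    def test_model_choice_barely_moves_v_ref(self, ctx, nacl, nacl_truth):
        design = DensityDesign(seed=21)
        records, _ = gen_density_dataset(nacl, nacl_truth, design, ctx)
        res = fit_salt(records, nacl, ctx, "quadratic")
        assert abs(res.model.V_ref - res.model_linear.V_ref) < 0.1


class TestCsvRoundTrip:
    def test_write_read(self, tmp_path, ctx, nacl, nacl_truth):
        design = DensityDesign(seed=9)
        records, _ = gen_density_dataset(nacl, nacl_truth, design, ctx)
        path = tmp_path / "dens.csv"
        write_density_csv(records, path)
        back = read_density_csv(path)
        assert len(back) == len(records)
        assert back[0] == records[0]

    def test_negative_molality_named_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "solute,series_id,temperature_C,molality_mol_kg,density_g_cm3\n"
            "NaCl,s1,25,-0.01,0.9975\n")
        with pytest.raises(ValueError, match="row 0"):
            read_density_csv(path)
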