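"""Modulus fitting, plasticity index, cycle analysis, per-cell aggregation."""

import numpy as np
import pytest

from cellmech import (
    ForceIndentation,
    IndentConfig,
    IndentSimParams,
    InvalidParameterError,
    StageError,
    TipModel,
    analyze_indentation_cycle,
    fit_young_modulus,
    plasticity_index,
    simulate_indentation_cycle,
    summarize_cell,
)
from cellmech.forcecurve import (
    ContactPoint,
    detect_contact_point,
    estimate_baseline,
    to_force_indentation,
)


def _fi_power_law(B, m, delta_max=1e-6, n=500):
    delta = np.linspace(0, delta_max, n)
    return ForceIndentation(delta, B * delta**m, ContactPoint(0, 0.0, 0.0))


class TestYoungFit:
    @pytest.mark.parametrize("geometry", ["cone", "paraboloid"])
    def test_noise_free_recovery_within_1pct(self, geometry):
        tip = (
            TipModel(geometry="cone", half_angle_rad=np.deg2rad(35), radius_m=None)
            if geometry == "cone"
            else TipModel()
        )
        for e_true in (300.0, 1500.0, 5000.0):
            c, _ = simulate_indentation_cycle(
                IndentSimParams(young_modulus_Pa=e_true, tip=tip, noise_sigma_N=0.0)
            )
            res = analyze_indentation_cycle(c, IndentConfig(tip=tip))
            assert res.young.E_Pa == pytest.approx(e_true, rel=0.01)

    def test_force_scaling_doubles_modulus(self, cone_tip):
        fi = _fi_power_law(500.0, 2.0)
        fi2 = ForceIndentation(fi.indentation_m, 2 * fi.force_N, fi.contact)
        e1 = fit_young_modulus(fi, cone_tip).E_Pa
        e2 = fit_young_modulus(fi2, cone_tip).E_Pa
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    def test_default_fit_fraction_is_10pct_of_depth(self, cone_tip):
        fi = _fi_power_law(500.0, 2.0, delta_max=1e-6)
        fit = fit_young_modulus(fi, cone_tip)
        assert fit.fit_range_m[1] <= 0.10 * 1e-6 + 1e-12

    def test_cell_height_caps_fit_depth(self, cone_tip):
        fi = _fi_power_law(500.0, 2.0, delta_max=1e-6)
        fit = fit_young_modulus(fi, cone_tip, cell_height_m=5e-6)
        assert fit.fit_range_m[1] <= 0.5e-6 + 1e-12

    def test_resampling_invariance(self, cone_tip):
        e = [
            fit_young_modulus(_fi_power_law(500.0, 2.0, n=n), cone_tip).E_Pa
            for n in (500, 1000)
        ]
        assert e[0] == pytest.approx(e[1], rel=0.005)


class TestPlasticityIndex:
    def test_identical_withdraw_gives_zero(self):
        fi = _fi_power_law(500.0, 2.0)
        wd = ForceIndentation(
            fi.indentation_m[::-1].copy(), fi.force_N[::-1].copy(), fi.contact
        )
        assert plasticity_index(fi, wd).eta == 0.0

    def test_zero_withdraw_force_gives_one(self):
        fi = _fi_power_law(500.0, 2.0)
        wd = ForceIndentation(
            fi.indentation_m[::-1].copy(), np.zeros(fi.force_N.size), fi.contact
        )
        assert plasticity_index(fi, wd).eta == 1.0

    def test_closed_form_power_pair(self):
        # loading m = 2, unloading p = 5 -> eta = 1 - (m+1)/(p+1) = 0.5
        delta = np.linspace(0, 1e-6, 500)
        f_max = 500.0 * (1e-6) ** 2
        app = ForceIndentation(delta, 500.0 * delta**2, ContactPoint(0, 0, 0))
        wd = ForceIndentation(
            delta[::-1].copy(),
            (f_max * (delta / 1e-6) ** 5)[::-1].copy(),
            ContactPoint(0, 0, 0),
        )
        assert plasticity_index(app, wd).eta == pytest.approx(0.5, abs=0.005)

    def test_negative_area_rejected(self):
        delta = np.linspace(0, 1e-6, 100)
        app = ForceIndentation(delta, -np.ones(100) * 1e-10, ContactPoint(0, 0, 0))
        with pytest.raises(InvalidParameterError):
            plasticity_index(app, app)

    def test_eta_monotone_in_unloading_exponent(self):
        delta = np.linspace(0, 1e-6, 500)
        app = ForceIndentation(delta, 500.0 * delta**2, ContactPoint(0, 0, 0))
        f_max = 500.0 * (1e-6) ** 2
        etas = []
        for p_exp in (3.0, 5.0, 9.0, 17.0):
            wd = ForceIndentation(
                delta[::-1].copy(),
                (f_max * (delta / 1e-6) ** p_exp)[::-1].copy(),
                ContactPoint(0, 0, 0),
            )
            etas.append(plasticity_index(app, wd).eta)
        assert all(b > a for a, b in zip(etas, etas[1:]))

    def test_trapezoid_matches_fine_rectangle_rule(self):
        delta = np.linspace(0, 1e-6, 500)
        app = ForceIndentation(delta, 500.0 * delta**2, ContactPoint(0, 0, 0))
        a1 = plasticity_index(
            app,
            ForceIndentation(delta[::-1].copy(), np.zeros(500), ContactPoint(0, 0, 0)),
        ).A1_J
        fine = np.linspace(0, 1e-6, 5000)
        riemann = float(np.sum(500.0 * ((fine[:-1] + fine[1:]) / 2) ** 2) * np.diff(fine)[0])
        assert a1 == pytest.approx(riemann, rel=0.002)


class TestCycleAnalysis:
    def test_noisy_cycle_recovery(self, cone_tip):
        c, _ = simulate_indentation_cycle(
            IndentSimParams(
                young_modulus_Pa=1000.0, target_eta=0.3, tip=cone_tip,
                relative_noise=0.01, noise_sigma_N=1e-12, seed=12,
            )
        )
        res = analyze_indentation_cycle(c, IndentConfig(tip=cone_tip))
        assert res.young.E_Pa == pytest.approx(1000.0, rel=0.05)
        assert res.plasticity.eta == pytest.approx(0.3, abs=0.02)

    def test_determinism(self, clean_cycle, cone_config):
        c, _ = clean_cycle
        r1 = analyze_indentation_cycle(c, cone_config)
        r2 = analyze_indentation_cycle(c, cone_config)
        assert r1.young.E_Pa == r2.young.E_Pa
        assert r1.plasticity.eta == r2.plasticity.eta

    def test_missing_withdraw_names_stage(self, cone_config):
        c, _ = simulate_indentation_cycle(IndentSimParams())
        c.segments = [c.segment("approach")]
        with pytest.raises(StageError) as err:
            analyze_indentation_cycle(c, cone_config)
        assert err.value.stage == "plasticity"


class TestCellSummary:
    def test_mean_of_repeats(self, clean_cycle, cone_config):
        c, _ = clean_cycle
        r = analyze_indentation_cycle(c, cone_config)
        reps = [r, r, r]
        for i, scale in enumerate((1.0, 2.0, 3.0)):
            reps[i] = type(r)(
                young=type(r.young)(
                    E_Pa=scale * 1000.0, fit_range_m=r.young.fit_range_m,
                    rms_residual_N=0.0, r_squared=1.0,
                ),
                plasticity=r.plasticity, contact=r.contact,
            )
        s = summarize_cell(reps, "c1", "WT")
        assert s.mean_E_Pa == pytest.approx(2000.0)
        assert s.n_repeats == 3

    def test_single_repeat_identity(self, clean_cycle, cone_config):
        c, _ = clean_cycle
        r = analyze_indentation_cycle(c, cone_config)
        s = summarize_cell([r], "c1", "WT")
        assert s.mean_E_Pa == r.young.E_Pa
        assert s.mean_eta == r.plasticity.eta

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            summarize_cell([], "c1", "WT")
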