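import numpy as np
import pytest

from nampod.chemistry import ChemicalRecord
from nampod.toxicokinetics import (Physiology, TKParameters, apply_css_floor,
                                   apply_fup_floor, convert_hlm_clint, css_analytic,
                                   css_population, hepatic_clearance_well_stirred,
                                   tk_eligibility_filter)


class TestUnitConversion:
    def test_standard_scaling_constants(self):
        # 99 μL/min/mg x 32 mg/g / 99e6 cells/g = 32 μL/min/10^6 cells
        assert convert_hlm_clint(99.0) == pytest.approx(32.0, abs=1e-12)

    def test_zero_maps_to_zero(self):
        assert convert_hlm_clint(0.0) == 0.0

    def test_arbitrary_value(self):
        assert convert_hlm_clint(10.0) == pytest.approx(10 * 32 / 99, rel=1e-12)

    def test_linear(self):
        assert convert_hlm_clint(7 * 3.5) == pytest.approx(7 * convert_hlm_clint(3.5), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            convert_hlm_clint(-1.0)


class TestFupFloor:
    def test_exact_zero_floored_to_lod(self):
        assert apply_fup_floor(0.0) == 0.005

    def test_above_floor_unchanged(self):
        assert apply_fup_floor(0.5) == 0.5

    def test_below_lod_only_floored_in_floor_all_mode(self):
        assert apply_fup_floor(0.001) == 0.001
        assert apply_fup_floor(0.001, floor_all_below=True) == 0.005

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_fup_floor(1.5)


class TestCssAnalytic:
    def test_renal_only_closed_form(self):
        # clint 0, fup 1, gfr chosen so renal clearance is 10 L/day/kg,
        # mw 100 -> dose 10 μmol/kg/day -> Css exactly 1 μM
        phys = Physiology(gfr=10 / 24)
        tk = TKParameters("x", fup=1.0, clint_hep=0.0)
        assert css_analytic(tk, phys, mw=100.0) == pytest.approx(1.0, rel=1e-9)

    def test_zero_dose_rate_gives_zero(self):
        tk = TKParameters("x", fup=0.5, clint_hep=10.0)
        assert css_analytic(tk, mw=200.0, dose_rate=0.0) == 0.0

    def test_dose_linearity(self):
        tk = TKParameters("x", fup=0.5, clint_hep=10.0)
        c1 = css_analytic(tk, mw=200.0, dose_rate=1.0)
        c2 = css_analytic(tk, mw=200.0, dose_rate=2.0)
        assert c2 == pytest.approx(2 * c1, rel=1e-9)

    def test_nonpositive_mw_rejected(self):
        tk = TKParameters("x", fup=0.5, clint_hep=10.0)
        with pytest.raises(ValueError):
            css_analytic(tk, mw=0.0)

    def test_css_decreases_with_clearance(self):
        tk_grid = [TKParameters("x", fup=0.5, clint_hep=c) for c in (0.0, 1.0, 10.0, 100.0)]
        css = [css_analytic(tk, mw=300.0) for tk in tk_grid]
        assert all(a > b for a, b in zip(css, css[1:]))

    def test_wellstirred_bounded_by_blood_flow(self):
        q = 1.3
        for clint in (0.0, 1.0, 10.0, 1e3, 1e6, 1e9):
            assert hepatic_clearance_well_stirred(0.8, clint, q) <= q + 1e-12
        # perfusion limit: clearance approaches Q as clint grows
        assert hepatic_clearance_well_stirred(0.8, 1e12, q) == pytest.approx(q, rel=1e-9)


class TestCssPopulation:
    TK = TKParameters("x", fup=0.5, clint_hep=10.0)

    def test_cv_zero_collapses_to_analytic(self):
        phys = Physiology(cv=0.0, n_draws=100)
        res = css_population(self.TK, phys, mw=300.0, seed=1)
        assert res.css_p95 == css_analytic(self.TK, phys, mw=300.0)

    def test_seed_reproducibility(self):
        a = css_population(self.TK, mw=300.0, seed=42)
        b = css_population(self.TK, mw=300.0, seed=42)
        c = css_population(self.TK, mw=300.0, seed=43)
        assert a.css_p95 == b.css_p95
        assert a.css_p95 != c.css_p95

    def test_sampled_clearance_cv_matches_nominal(self):
        res = css_population(self.TK, mw=300.0, seed=5, keep_draws=True)
        cv = res.clint_draws.std(ddof=1) / res.clint_draws.mean()
        assert cv == pytest.approx(0.30, abs=0.02)
        assert (res.clint_draws >= 0).all()

    def test_p95_above_median(self):
        res = css_population(self.TK, mw=300.0, seed=6, keep_draws=True)
        assert res.css_p95 >= np.median(res.css_draws)

    def test_standard_error_shrinks_with_draws(self):
        # Monte-Carlo convergence: p95 spread over seeds ~ 1/sqrt(n)
        def spread(n_draws):
            phys = Physiology(n_draws=n_draws)
            vals = [css_population(self.TK, phys, mw=300.0, seed=s).css_p95
                    for s in range(20)]
            return np.std(vals)

        s_small, s_big = spread(50), spread(1600)
        ratio = s_small / s_big
        # expect ~ sqrt(32) ~ 5.7; allow generous slack for 20-seed noise
        assert ratio > 2.5

    def test_invalid_draw_count_rejected(self):
        with pytest.raises(ValueError):
            css_population(self.TK, Physiology(n_draws=0), mw=300.0, seed=1)


class TestCssFloor:
    @pytest.mark.parametrize("css,expected,floored", [
        (0.001, 0.1, True),
        (5.0, 5.0, False),
        (0.1, 0.1, False),
    ])
    def test_floor_behaviour(self, css, expected, floored):
        value, flag = apply_css_floor(css)
        assert value == expected and flag is floored

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_css_floor(-0.1)


class TestEligibility:
    def base_record(self, **kw):
        defaults = dict(chem_id="c", mw=300.0, logp=2.0, hbd=1, hba=2,
                        fraction_absorbed=0.5, fraction_bioavailable=0.5,
                        in_applicability_domain=True)
        defaults.update(kw)
        return ChemicalRecord(**defaults)

    def test_predicted_low_bioavailability_fails(self):
        ok, reasons = tk_eligibility_filter(self.base_record(fraction_bioavailable=0.05),
                                            "predicted")
        assert not ok and reasons == ["fbio<0.1"]

    def test_predicted_boundary_values_pass(self):
        rec = self.base_record(mw=500, logp=5, hbd=5, hba=10,
                               fraction_absorbed=0.1, fraction_bioavailable=0.1)
        ok, reasons = tk_eligibility_filter(rec, "predicted")
        assert ok and reasons == []

    def test_measured_bypasses_all_filters(self):
        rec = self.base_record(mw=800.0, fraction_bioavailable=0.01,
                               in_applicability_domain=False)
        ok, reasons = tk_eligibility_filter(rec, "measured")
        assert ok and reasons == []

    def test_overlapping_reasons_all_reported(self):
        rec = self.base_record(mw=600, logp=6, fraction_absorbed=0.05,
                               in_applicability_domain=False)
        ok, reasons = tk_eligibility_filter(rec, "predicted")
        assert not ok
        assert {"ro5:MW>500", "ro5:logP>5", "fabs<0.1", "out_of_applicability_domain"} <= set(reasons)

    def test_missing_field_reported_for_predicted(self):
        rec = self.base_record()
        rec.fraction_absorbed = None
        ok, reasons = tk_eligibility_filter(rec, "predicted")
        assert not ok and "missing_field:fraction_absorbed" in reasons

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            tk_eligibility_filter(self.base_record(), "guessed")
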