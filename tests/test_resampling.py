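"""Leave-one-site-out sensitivity and sample-size resampling."""

import math

import numpy as np
import pytest

from sealpup.aggregate import overall_mean_survival
from sealpup.data import SurvivalDataset
from sealpup.resampling import (
    NOT_REACHED,
    SampleSizeCurve,
    loo_site_sensitivity,
    required_n,
    sample_size_curve,
    sensitivity_models,
)

from conftest import rec


def constant_dataset(survival=0.7, n_sites=4, n_years=3):
    records = []
    for a, site in [("A", f"s{i}") for i in range(n_sites)]:
        area = "A" if site < "s2" else "B"
        for y in range(2000, 2000 + n_years):
            n = 10
            records.append(rec(area, site, y, n, round(n * survival)))
    return SurvivalDataset(records=records)


class TestLooSensitivity:
    def test_constant_data_all_deltas_zero(self):
        out = loo_site_sensitivity(constant_dataset())
        assert all(r.delta == pytest.approx(0.0, abs=1e-15) for r in out)

    def test_removing_lowest_site_raises_mean(self, toy_dataset):
        out = {r.site_id: r for r in loo_site_sensitivity(toy_dataset)}
        # b1 has the lowest weighted survival; omitting it raises the mean
        assert out["b1"].delta > 0

    def test_hand_computed_deltas(self):
        ds = SurvivalDataset(
            records=[
                rec("A", "s1", 2000, 10, 8),   # 0.8
                rec("A", "s2", 2000, 30, 15),  # 0.5
                rec("B", "s3", 2000, 10, 9),   # 0.9
            ]
        )
        base = (8 + 15 + 9) / 50  # 0.64
        out = {r.site_id: r for r in loo_site_sensitivity(ds)}
        assert out["s1"].delta == pytest.approx((15 + 9) / 40 - base)
        assert out["s2"].delta == pytest.approx((8 + 9) / 20 - base)
        assert out["s3"].delta == pytest.approx((8 + 15) / 40 - base)
        assert out["s2"].mean_pups == 30

    def test_site_at_overall_mean_has_zero_delta(self):
        ds = SurvivalDataset(
            records=[
                rec("A", "s1", 2000, 10, 4),
                rec("A", "s2", 2000, 10, 8),
                rec("B", "s3", 2000, 20, 12),  # survival 0.6 = overall mean
            ]
        )
        assert overall_mean_survival(ds) == pytest.approx(0.6)
        out = {r.site_id: r for r in loo_site_sensitivity(ds)}
        assert out["s3"].delta == pytest.approx(0.0, abs=1e-15)


def _sens(site, area, delta, pups):
    from sealpup.resampling import SensitivityResult

    return SensitivityResult(site_id=site, area_id=area, delta=delta, mean_pups=pups)


class TestSensitivityModels:
    def test_zero_within_group_variance_gives_infinite_f(self):
        results = [
            _sens("s1", "A", 0.01, 10), _sens("s2", "A", 0.01, 12),
            _sens("s3", "B", -0.02, 9), _sens("s4", "B", -0.02, 11),
        ]
        fits = sensitivity_models(results)
        assert math.isinf(fits["delta_by_area"].F)
        assert fits["delta_by_area"].p_value == 0.0

    def test_constant_deltas_give_zero_slope(self):
        results = [_sens(f"s{i}", "A" if i < 2 else "B", 0.005, 5 + i) for i in range(5)]
        fits = sensitivity_models(results)
        assert fits["delta_by_pups"].slope == pytest.approx(0.0)
        assert fits["delta_by_pups"].F == 0.0

    def test_against_statsmodels_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        import pandas as pd

        rng = np.random.default_rng(11)
        areas = ["A"] * 18 + ["B"] * 9 + ["C"] * 14  # 41 sites
        results = [
            _sens(f"s{i:02d}", a, rng.normal(0, 0.01), rng.uniform(2, 60))
            for i, a in enumerate(areas)
        ]
        fits = sensitivity_models(results)
        df = pd.DataFrame(
            {
                "delta": [r.delta for r in results],
                "area": [r.area_id for r in results],
                "pups": [r.mean_pups for r in results],
            }
        )
        aov = smf.ols("delta ~ C(area)", data=df).fit()
        assert fits["delta_by_area"].F == pytest.approx(aov.fvalue, rel=1e-10)
        assert fits["delta_by_area"].p_value == pytest.approx(aov.f_pvalue, rel=1e-10)
        assert (fits["delta_by_area"].df1, fits["delta_by_area"].df2) == (2, 38)
        reg = smf.ols("delta ~ pups", data=df).fit()
        assert fits["delta_by_pups"].F == pytest.approx(reg.fvalue, rel=1e-10)
        assert fits["delta_by_pups"].p_value == pytest.approx(reg.f_pvalue, rel=1e-10)

    def test_single_area_skips_area_model(self):
        results = [_sens(f"s{i}", "A", 0.001 * i, 5 + i) for i in range(4)]
        with pytest.warns(UserWarning, match="single sampling area"):
            fits = sensitivity_models(results)
        assert "delta_by_area" not in fits and "delta_by_pups" in fits


class TestSampleSizeCurve:
    def test_zero_variance_data_always_within(self):
        ds = constant_dataset(survival=0.7, n_sites=6, n_years=10)
        curve = sample_size_curve(ds, n_range=range(5, 31, 5), reps=50, seed=1)
        assert all(p == 1.0 for p in curve.proportion_within)

    def test_full_tolerance_always_within(self, design_dataset):
        curve = sample_size_curve(
            design_dataset, n_range=[5, 10], reps=50, tolerance=1.0, seed=1
        )
        assert overall_mean_survival(design_dataset) >= 0.5
        assert all(p == 1.0 for p in curve.proportion_within)

    def test_exhaustive_draw_is_degenerate(self, toy_dataset):
        n = len(toy_dataset)
        curve = sample_size_curve(toy_dataset, n_range=[n], reps=100, seed=3)
        assert curve.proportion_within[0] in (0.0, 1.0)

    def test_same_seed_bit_identical(self, design_dataset):
        kw = dict(n_range=range(5, 16, 5), reps=200, seed=99)
        c1 = sample_size_curve(design_dataset, **kw)
        c2 = sample_size_curve(design_dataset, **kw)
        assert c1.proportion_within == c2.proportion_within

    def test_substreams_independent_of_n_range(self, design_dataset):
        # adding an n value must not perturb results for other n
        c_small = sample_size_curve(design_dataset, n_range=[10, 20], reps=100, seed=5)
        c_large = sample_size_curve(
            design_dataset, n_range=[5, 10, 15, 20], reps=100, seed=5
        )
        d_small = dict(zip(c_small.n_values, c_small.proportion_within))
        d_large = dict(zip(c_large.n_values, c_large.proportion_within))
        assert d_small[10] == d_large[10] and d_small[20] == d_large[20]

    def test_oversized_n_skipped_with_warning(self, toy_dataset):
        with pytest.warns(UserWarning, match="skipped"):
            curve = sample_size_curve(toy_dataset, n_range=[3, 100], reps=10, seed=0)
        assert curve.n_values == (3,)

    def test_monotone_in_expectation(self, design_dataset):
        # Monte-Carlo average over seeds; small slack for simulation error
        ns = [5, 15, 30, 45]
        mean_props = np.zeros(len(ns))
        for seed in range(10):
            c = sample_size_curve(design_dataset, n_range=ns, reps=200, seed=seed)
            mean_props += np.array(c.proportion_within)
        mean_props /= 10
        assert all(np.diff(mean_props) > -0.03)


class TestRequiredN:
    def _curve(self, ns, props):
        return SampleSizeCurve(
            scope="pooled", n_values=tuple(ns), proportion_within=tuple(props),
            tolerance=0.1, reps=10, target_mean=0.7, seed=0,
        )

    def test_first_crossing(self):
        assert required_n(self._curve([5, 10, 15], [0.5, 0.7, 0.9]), 0.8) == 15

    def test_all_above_threshold(self):
        assert required_n(self._curve([5, 10], [0.9, 0.95]), 0.8) == 5

    def test_never_reached(self):
        assert required_n(self._curve([5, 10], [0.1, 0.2]), 0.8) == NOT_REACHED
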