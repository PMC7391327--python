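"""Matrix construction, growth rates and the matrix-set assembly."""

import numpy as np
import pytest
from scipy.optimize import brentq

from sealpup.data import SurvivalDataset
from sealpup.mpm import (
    DemographyParams,
    build_matrix_sets,
    build_mpm,
    estimate_late_survival,
    growth_rate,
    rank_sites,
    stable_stage_distribution,
)

from conftest import rec

# lambda of the reference archetype (S_P equal to the published low-density
# birth-to-age-1 survival of 0.48), computed once by the scalar root oracle
ARCHETYPE_LAMBDA = 1.064723235508988


def charpoly_dominant_root(A):
    """Dominant root of det(A - xI) via Faddeev-LeVerrier + np.roots.

    Builds the characteristic polynomial from matrix traces, independent of
    any eigendecomposition of A itself.
    """
    n = A.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    M = np.zeros_like(A)
    I = np.eye(n)
    for k in range(1, n + 1):
        M = A @ M + coeffs[k - 1] * I
        coeffs[k] = -np.trace(A @ M) / k
    roots = np.roots(coeffs)
    return roots[np.argmax(np.abs(roots))]


def euler_lotka_lambda(s_e, params: DemographyParams):
    """Scalar growth-rate equation for the default (single 6+ class) preset:
    F * S_P * s_pre^5 = lambda^6 (lambda - s_breed)."""
    s_p = s_e * params.s_late
    rhs = params.f_entry * s_p * params.s_pre**5

    def f(lam):
        return lam**6 * (lam - params.s_breed) - rhs

    return brentq(f, params.s_breed + 1e-12, 2.0, xtol=1e-14, rtol=8.9e-16)


class TestLateSurvival:
    def test_published_calibration(self):
        # 0.48 / 0.69 is approximately 0.70
        assert estimate_late_survival(0.48, 0.69) == pytest.approx(0.6957, abs=5e-4)

    def test_boundary(self):
        assert estimate_late_survival(0.48, 0.48) == 1.0

    def test_impossible_probability(self):
        with pytest.raises(ValueError, match="impossible"):
            estimate_late_survival(0.48, 0.40)


class TestBuildMpm:
    def test_pup_entry_is_product_of_early_and_late(self):
        m = build_mpm(1.0)
        assert m.matrix[1, 0] == pytest.approx(0.70)
        m2 = build_mpm(0.69)
        assert m2.matrix[1, 0] == pytest.approx(0.483)

    def test_default_structure_entries(self):
        p = DemographyParams()
        m = build_mpm(0.69, p).matrix
        assert m[0, 6] == pytest.approx(0.45)  # fecundity x sex ratio
        for j in range(1, 6):
            assert m[j + 1, j] == p.s_pre
        assert m[6, 6] == p.s_breed
        assert np.count_nonzero(m) == 8

    def test_two_breeding_stages_structure(self):
        p = DemographyParams()
        m = build_mpm(0.69, p, structure="two_breeding_stages").matrix
        assert m[0, 5] == m[0, 6] == pytest.approx(0.45)
        assert m[6, 5] == m[6, 6] == p.s_breed
        assert np.count_nonzero(m) == 9

    def test_zero_early_survival_limit(self):
        # with no pup recruitment the long-run rate is adult survival
        m = build_mpm(0.0)
        assert growth_rate(m) == pytest.approx(0.95, abs=1e-10)

    def test_invalid_s_e_rejected(self):
        with pytest.raises(ValueError):
            build_mpm(1.2)


class TestGrowthRate:
    def test_diagonal_spectrum(self):
        A = np.diag(np.arange(0.1, 0.75, 0.1))
        assert growth_rate(A) == pytest.approx(0.7)

    def test_two_by_two_closed_form(self):
        assert growth_rate(np.array([[0.0, 2.0], [0.5, 0.0]])) == pytest.approx(1.0)

    def test_against_charpoly_oracle_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            A = rng.uniform(0, 1, size=(7, 7))
            dom = charpoly_dominant_root(A)
            assert abs(dom.imag) < 1e-10
            assert growth_rate(A) == pytest.approx(dom.real, abs=1e-10)

    def test_against_euler_lotka_oracle(self):
        p = DemographyParams()
        for s_e in (0.3, 0.5, 0.69, 0.9):
            m = build_mpm(s_e, p)
            assert growth_rate(m) == pytest.approx(
                euler_lotka_lambda(s_e, p), abs=1e-10
            )

    def test_archetype_regression_value(self):
        p = DemographyParams()
        m = build_mpm(p.s01_ref / p.s_late, p)  # S_P = 0.48 exactly
        assert m.matrix[1, 0] == pytest.approx(0.48)
        assert growth_rate(m) == pytest.approx(ARCHETYPE_LAMBDA, abs=1e-10)

    def test_lambda_monotone_in_early_survival(self):
        lams = [growth_rate(build_mpm(s)) for s in np.linspace(0.0, 1.0, 21)]
        assert all(b > a for a, b in zip(lams, lams[1:]))

    def test_stable_stage_distribution(self):
        m = build_mpm(0.69)
        v = stable_stage_distribution(m)
        assert v.sum() == pytest.approx(1.0)
        assert (v >= 0).all()
        lam = growth_rate(m)
        assert m.matrix @ v == pytest.approx(lam * v, abs=1e-12)


def _graded_dataset(n_sites=4, base=0.2, step=0.2):
    records = []
    for i in range(n_sites):
        p = base + step * i
        for y in (2000, 2001):
            records.append(rec("A" if i % 2 == 0 else "B", f"s{i}", y, 10,
                               round(10 * p)))
    return SurvivalDataset(records=records)


class TestRankSites:
    def test_partition_of_four_sites(self):
        ds = _graded_dataset()  # site means 0.2, 0.4, 0.6, 0.8
        worst, best = rank_sites(ds, k=2)
        assert set(worst) == {"s0", "s1"} and set(best) == {"s2", "s3"}

    def test_weighted_ranking_hand_case(self):
        ds = SurvivalDataset(
            records=[
                rec("A", "s1", 2000, 90, 9),   # weighted mean (9+9)/(90+10)=0.18
                rec("A", "s1", 2001, 10, 9),
                rec("A", "s2", 2000, 10, 2),   # (2+18)/(10+90) = 0.20
                rec("A", "s2", 2001, 90, 18),
                rec("B", "s3", 2000, 10, 9),
                rec("B", "s4", 2000, 10, 8),
            ]
        )
        worst, _ = rank_sites(ds, k=1)
        assert worst == ["s1"]

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            rank_sites(_graded_dataset(), k=3)


class TestBuildMatrixSets:
    def test_design_counts(self, design_dataset):
        sets = build_matrix_sets(design_dataset)
        assert len(sets["per_site"]) == 46
        assert len(sets["per_area"]) == 3
        assert len(sets["worst_best_pooled"]) == 2
        assert len(sets["worst_best_per_site"]) == 20
        n_extreme_records = len(sets["worst_site_years"]) + len(
            sets["best_site_years"]
        )
        extreme_sites = {
            m.label.split(":")[0]
            for s in ("worst_site_years", "best_site_years")
            for m in sets[s].matrices
        }
        assert len(extreme_sites) == 20
        assert n_extreme_records == sum(
            1 for r in design_dataset if r.site_id in extreme_sites
        )

    def test_toy_counts(self):
        sets = build_matrix_sets(_graded_dataset(), k=2)
        assert len(sets["per_site"]) == 4
        assert len(sets["per_area"]) == 2
        assert len(sets["worst_best_pooled"]) == 2
        assert len(sets["worst_best_per_site"]) == 4

    def test_identical_survival_gives_identical_lambda(self):
        ds = SurvivalDataset(
            records=[
                rec("A", f"s{i}", y, 10, 7)
                for i in range(4)
                for y in (2000, 2001)
            ]
        )
        sets = build_matrix_sets(ds, k=2)
        lams = [growth_rate(m) for m in sets["per_site"].matrices]
        assert np.ptp(lams) < 1e-12
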