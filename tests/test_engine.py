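"""Sensitivity estimation, NORSE scoring, 2D scores, ranking arithmetic."""

import numpy as np
import pandas as pd
import pytest

from norse.engine import (
    age_stratified_norse,
    estimate_sensitivity,
    norse_2d,
    norse_score,
    rank_1d,
    round_half_away,
    summarize_1d,
)
from norse.maps import BinGrid, InsufficientSupportError, PMap, build_pmap
from norse.registry import zscore
from norse.synthetic import PrevalenceModel, SyntheticConfig, generate_population

from conftest import vector_from


def linear_pmap(slope=2.0, intercept=5.0, sigma=10.0, n_cell=100):
    """Hand-built 1D p-map whose prevalence is exactly linear in the center.

    Centers 2.5, 7.5, 12.5, 17.5 with prevalence intercept + slope*center,
    chosen so n_cond is a whole number of the 100 participants per cell.
    """
    edges = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
    grid = BinGrid(axes=("B",), mus=(0.0,), sigmas=(sigma,), edges=(edges,))
    centers = grid.centers(0)
    prev = intercept + slope * centers
    counts = np.full(4, n_cell)
    n_cond = np.round(prev / 100.0 * n_cell).astype(int)
    assert np.allclose(100.0 * n_cond / n_cell, prev)  # integers by design
    return PMap(grid=grid, condition="c", n_cell=counts, n_cond=n_cond,
                n_tot=int(counts.sum()))


class TestSensitivity:
    def test_exactly_linear_prevalence_recovers_slope_exactly(self):
        fit = estimate_sensitivity(linear_pmap(slope=2.0, intercept=5.0))
        assert fit.sensitivity == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0, abs=1e-12)

    def test_constant_prevalence_gives_zero_slope(self):
        fit = estimate_sensitivity(linear_pmap(slope=0.0, intercept=30.0))
        assert fit.sensitivity == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_wls(self):
        """Independent route: statsmodels WLS on the same cells."""
        import statsmodels.api as sm

        gen = np.random.default_rng(5)
        pm = linear_pmap(slope=2.0)
        # perturb counts so weights differ per cell
        counts = np.array([80, 150, 260, 120])
        prev = 5.0 + 2.0 * pm.grid.centers(0) + gen.normal(0, 1.5, 4)
        n_cond = np.round(prev / 100 * counts).astype(int)
        pm2 = PMap(grid=pm.grid, condition="c", n_cell=counts, n_cond=n_cond,
                   n_tot=int(counts.sum()))
        fit = estimate_sensitivity(pm2)
        X = sm.add_constant(pm2.grid.centers(0))
        ref = sm.WLS(pm2.prevalence, X, weights=counts).fit().params[1]
        assert fit.sensitivity == pytest.approx(ref, rel=1e-10)

    def test_slope_recovery_under_binomial_noise(self, linear_cohort):
        """B ~ N(0,1), P(%) = 10 + 4B at n=2e5: slope back within ±0.3."""
        b, flags = linear_cohort
        pm = build_pmap(zscore(vector_from(b)), flags)
        fit = estimate_sensitivity(pm)
        assert fit.sensitivity == pytest.approx(4.0, abs=0.3)

    def test_too_few_usable_cells_raises(self):
        pm = linear_pmap()
        tiny = PMap(grid=pm.grid, condition="c",
                    n_cell=np.array([100, 5, 5, 5]),
                    n_cond=np.array([10, 1, 1, 1]), n_tot=115)
        with pytest.raises(InsufficientSupportError):
            estimate_sensitivity(tiny)


class TestNorseScore:
    def test_norse_is_sigma_times_sensitivity(self):
        res = norse_score(linear_pmap(slope=2.0, sigma=10.0))
        assert res.norse == res.sensitivity * 10.0
        assert res.norse == pytest.approx(20.0, abs=1e-10)

    def test_norse_recovery_matches_generating_product(self, linear_cohort):
        """True b*sigma = 4 with sigma = 1; estimate within ±0.6."""
        b, flags = linear_cohort
        v = zscore(vector_from(b))
        res = norse_score(build_pmap(v, flags), v.sigma)
        assert res.norse == pytest.approx(4.0, abs=0.6)

    def test_affine_invariance_bit_identical_power_of_two(self, rng):
        vals = rng.normal(50.0, 8.0, 20_000)
        flags = pd.Series((rng.random(20_000) < (0.1 + 0.004 * (vals - 50))).astype(float))
        v1 = zscore(vector_from(vals))
        v2 = zscore(vector_from(vals * 128.0))  # exact float scaling
        r1 = norse_score(build_pmap(v1, flags), v1.sigma)
        r2 = norse_score(build_pmap(v2, flags), v2.sigma)
        assert r1.norse == r2.norse  # bit identical

    def test_affine_invariance_general_units(self, rng):
        """cm -> m plus an offset: NORSE agrees to float precision."""
        vals = rng.normal(100.0, 10.0, 20_000)
        flags = pd.Series((rng.random(20_000) < 0.2 + 0.003 * (vals - 100)).astype(float))
        v1 = zscore(vector_from(vals))
        v2 = zscore(vector_from(vals * 0.01 + 5.0))
        r1 = norse_score(build_pmap(v1, flags), v1.sigma)
        r2 = norse_score(build_pmap(v2, flags), v2.sigma)
        assert r2.norse == pytest.approx(r1.norse, rel=1e-9)

    def test_sign_antisymmetry(self, rng):
        vals = rng.normal(0.0, 1.0, 20_000)
        flags = pd.Series((rng.random(20_000) < 0.2 + 0.05 * vals).astype(float))
        v1 = zscore(vector_from(vals))
        v2 = zscore(vector_from(-vals))
        r1 = norse_score(build_pmap(v1, flags), v1.sigma)
        r2 = norse_score(build_pmap(v2, flags), v2.sigma)
        assert r2.norse == pytest.approx(-r1.norse, rel=1e-9)


class TestNorse2D:
    @staticmethod
    def planar_pmap():
        """Prevalence exactly planar over a 4x4 grid, equal counts."""
        ex = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        ey = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        grid = BinGrid(axes=("X", "Y"), mus=(0.0, 0.0), sigmas=(2.0, 4.0),
                       edges=(ex, ey))
        cx, cy = np.meshgrid(grid.centers(0), grid.centers(1), indexing="ij")
        prev = 10.0 - 2.0 * cx + 1.5 * cy  # percent
        n_cell = np.full((4, 4), 200)
        n_cond = np.round(prev / 100.0 * 200).astype(int)
        assert np.allclose(100.0 * n_cond / 200, prev)
        return PMap(grid=grid, condition="c", n_cell=n_cell, n_cond=n_cond,
                    n_tot=3200)

    def test_planar_map_recovers_row_and_column_slopes_exactly(self):
        res = norse_2d(self.planar_pmap())
        assert np.allclose(res.row_norse, -2.0 * 2.0, atol=1e-10)  # sigma_x=2
        assert np.allclose(res.col_norse, 1.5 * 4.0, atol=1e-10)  # sigma_y=4
        assert res.x_norse == pytest.approx(-4.0, abs=1e-9)
        assert res.y_norse == pytest.approx(6.0, abs=1e-9)
        assert res.separation == pytest.approx(10.0, abs=1e-9)

    def test_rowmean_and_gradient_agree_on_uncorrelated_planar_map(self):
        r_grad = norse_2d(self.planar_pmap(), aggregate="gradient")
        r_mean = norse_2d(self.planar_pmap(), aggregate="rowmean")
        assert r_grad.x_norse == pytest.approx(r_mean.x_norse, abs=1e-9)
        assert r_grad.y_norse == pytest.approx(r_mean.y_norse, abs=1e-9)

    def test_display_mask_hides_but_never_deletes(self):
        res = norse_2d(self.planar_pmap())
        shown = res.displayed("row", threshold=100.0)
        assert np.all(np.isnan(shown))  # everything hidden at a huge threshold
        assert np.all(np.isfinite(res.row_norse))  # raw scores intact

    def test_prevalence_independent_of_axes_gives_near_zero_separation(self, rng):
        x = zscore(vector_from(rng.normal(0, 1, 50_000), "x"))
        y = zscore(vector_from(rng.normal(0, 1, 50_000), "y"))
        flags = pd.Series((rng.random(50_000) < 0.25).astype(float))
        res = norse_2d(build_pmap((x, y), flags))
        assert abs(res.separation) < 1.0

    def test_fully_suppressed_map_raises(self):
        pm = self.planar_pmap()
        starved = PMap(grid=pm.grid, condition="c",
                       n_cell=np.full((4, 4), 10), n_cond=np.full((4, 4), 2),
                       n_tot=160)
        with pytest.raises(InsufficientSupportError):
            norse_2d(starved)


class TestRankingArithmetic:
    def test_row_average_of_equal_values_is_that_value(self):
        rows = [
            {"sex": s, "biomarker": "B", "condition": c, "norse": 3.7}
            for s in ("male", "female")
            for c in ("c1", "c2", "c3")
        ]
        rt = summarize_1d(pd.DataFrame(rows), conditions=("c1", "c2", "c3"))
        assert rt.per_sex_average.loc["B", "male"] == pytest.approx(3.7)
        assert rt.key.loc["B"] == pytest.approx(3.7)

    def test_rows_sorted_descending_by_cross_gender_key(self):
        rows = []
        for name, val in [("lo", 1.0), ("hi", 9.0), ("mid", 5.0)]:
            for s in ("male", "female"):
                rows.append({"sex": s, "biomarker": name, "condition": "c1",
                             "norse": val})
        rt = summarize_1d(pd.DataFrame(rows), conditions=("c1",))
        assert list(rt.key.index) == ["hi", "mid", "lo"]

    @pytest.mark.parametrize("x,expected", [(7.65, 7.7), (-7.65, -7.7),
                                            (9.1667, 9.2), (28.35, 28.4),
                                            (0.04, 0.0)])
    def test_round_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_ranking_invariant_under_unit_change(self):
        """Rescaling one biomarker's unit must not move it in the table."""
        from norse.registry import BiomarkerDefinition, default_registry

        cfg = SyntheticConfig(n=4000, seed=11)
        df = generate_population(cfg)
        names = ["WHR", "BMI", "Waist circ"]
        rt1 = rank_1d(df, biomarkers=names)
        reg = default_registry()
        reg.register(BiomarkerDefinition(
            "WHR", "regional", ("waist_circ", "hip_circ"),
            lambda d: 128.0 * d["waist_circ"] / d["hip_circ"],
        ))
        rt2 = rank_1d(df, biomarkers=names, registry=reg)
        assert list(rt1.key.index) == list(rt2.key.index)
        assert rt1.key.to_numpy() == pytest.approx(rt2.key.to_numpy(), rel=1e-12)


class TestAgeStratification:
    def test_single_bracket_equals_unstratified_score(self):
        cfg = SyntheticConfig(n=6000, seed=21)
        df = generate_population(cfg)
        curve = age_stratified_norse(df, "WHR", "diabetes",
                                     brackets=[(20.0, 110.0)], sexes=("male",))
        sub = df[df.sex == "male"]
        v = zscore(vector_from(sub["waist_circ"] / sub["hip_circ"], "WHR"))
        pm = build_pmap(v, sub["diabetes"])
        direct = norse_score(pm, v.sigma)
        assert curve.loc[0, "norse"] == pytest.approx(direct.norse, rel=1e-9)

    def test_starved_bracket_is_unavailable_not_an_error(self):
        cfg = SyntheticConfig(n=2000, seed=22, age_range=(20.0, 50.0))
        df = generate_population(cfg)
        curve = age_stratified_norse(df, "BMI", "arthritis",
                                     brackets=[(20.0, 50.0), (50.0, 110.0)])
        old = curve[(curve.age_lo == 50.0)]
        assert (~old["available"]).all()
        assert old["norse"].isna().all()
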