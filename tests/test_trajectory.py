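"""Tests for deficit-accumulation trajectory statistics."""

import numpy as np
import pandas as pd
import pytest
from patsy import dmatrix
from scipy import stats

from mcfi.cohort_sim import simulate_fi_values
from mcfi.fi_core import ConfigurationError, ValidationError
from mcfi.trajectory import (
    DEFAULT_BANDS,
    assign_band,
    band_means,
    compare_slopes,
    factorial_anova,
    fit_loglinear,
)


def frame(groups_ages_fis):
    rows = []
    for g, ages, fis in groups_ages_fis:
        for a, f in zip(ages, fis):
            rows.append({"group": g, "age_at_fi": a, "fi": f})
    return pd.DataFrame(rows)


class TestFitLoglinear:
    def test_noiseless_exponential_recovered_exactly(self):
        ages = np.arange(50, 650, 25)
        fis = 0.05 * np.exp(0.03 * ages / 10)
        fit = fit_loglinear(ages, fis, group="exact")
        assert fit.slope == pytest.approx(0.03, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log(0.05), abs=1e-10)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_constant_fi_gives_zero_slope(self):
        fit = fit_loglinear([100, 200, 300, 400], [0.1, 0.1, 0.1, 0.1])
        assert fit.slope == 0.0
        assert fit.pearson_r == 0.0
        assert fit.p_value == 1.0

    def test_slope_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(1)
        ages = rng.integers(100, 800, 60)
        fis = 0.05 * np.exp(0.025 * ages / 10) * rng.lognormal(0, 0.2, 60)
        fis = np.clip(fis, 0.02, 1.0)
        f1 = fit_loglinear(ages, fis)
        f2 = fit_loglinear(ages, np.clip(2.0 * fis, None, 1.0))
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)
        assert f2.intercept == pytest.approx(f1.intercept + np.log(2), abs=1e-10)

    def test_floor_applied_before_log(self):
        fit = fit_loglinear([100, 200, 300], [0.0, 0.1, 0.2], fi_floor=1 / 62)
        assert np.isfinite(fit.slope)

    def test_preconditions(self):
        with pytest.raises(ValidationError, match=">= 3"):
            fit_loglinear([100, 200], [0.1, 0.2])
        with pytest.raises(ValidationError, match="positive"):
            fit_loglinear([0, 100, 200], [0.1, 0.1, 0.2])
        with pytest.raises(ValidationError, match="age variance"):
            fit_loglinear([100, 100, 100], [0.1, 0.2, 0.3])

    def test_recovers_generator_rate_at_cohort_scale(self, groups):
        p = groups["male_tg"]
        rng = np.random.default_rng(11)
        ages = rng.integers(p.age_range[0], p.age_range[1] + 1, 500)
        fit = fit_loglinear(ages, simulate_fi_values(ages, p, rng), "male_tg")
        lo, hi = fit.ci95()
        assert lo <= p.targets.slope <= hi

    def test_recovery_unbiased_with_nominal_ci_coverage(self, groups):
        # mean estimated slope within 2% of the calibration target per group;
        # pooled 95% CI coverage within 95 +/- 3 points
        rng = np.random.default_rng(77)
        reps = 150
        covered = 0
        for label, p in groups.items():
            slopes = np.empty(reps)
            for r in range(reps):
                ages = rng.integers(p.age_range[0], p.age_range[1] + 1, 500)
                fit = fit_loglinear(ages, simulate_fi_values(ages, p, rng), label)
                slopes[r] = fit.slope
                lo, hi = fit.ci95()
                covered += lo <= p.targets.slope <= hi
            assert slopes.mean() == pytest.approx(p.targets.slope, rel=0.02)
        coverage = covered / (reps * len(groups))
        assert 0.92 <= coverage <= 0.98


class TestBandMeans:
    def test_single_mouse(self):
        out = band_means(frame([("g", [100], [0.2])]))
        first = next(s for s in out if s.band == (0, 300))
        assert first.n == 1 and first.mean_fi == pytest.approx(0.2)
        assert first.sem is None

    def test_two_mouse_hand_values(self):
        out = band_means(frame([("g", [350, 400], [0.1, 0.3])]))
        mid = next(s for s in out if s.band == (300, 600))
        assert mid.mean_fi == pytest.approx(0.2)
        assert mid.sem == pytest.approx(0.1)

    def test_empty_band_reported_absent(self):
        out = band_means(frame([("short_lived", [100, 400], [0.1, 0.2])]))
        old = next(s for s in out if s.band[0] == 600)
        assert old.n == 0 and old.mean_fi is None

    def test_counts_conserve_cohort_size(self, groups):
        rng = np.random.default_rng(8)
        rows = []
        for label, p in groups.items():
            ages = rng.integers(p.age_range[0], p.age_range[1] + 1, 137)
            fis = simulate_fi_values(ages, p, rng)
            rows.append((label, ages, fis))
        out = band_means(frame(rows))
        per_group = {}
        for s in out:
            per_group[s.group] = per_group.get(s.group, 0) + s.n
        assert all(v == 137 for v in per_group.values())

    def test_band_edges_half_open(self):
        labels = assign_band([299, 300, 599, 600]).tolist()
        assert labels == ["0-300", "300-600", "300-600", "600+"]

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            band_means(frame([("g", [100], [0.1])]),
                       bands=((0, 400), (300, 600)))


class TestCompareSlopes:
    def _sim_group(self, rng, slope, n=200):
        ages = rng.integers(50, 900, n)
        lnfi = np.log(0.05) + slope * ages / 10 + rng.normal(0, 0.35, n)
        return ages, np.clip(np.exp(lnfi), None, 1.0)

    def test_duplicated_group_has_zero_slope_difference(self):
        rng = np.random.default_rng(2)
        ages, fis = self._sim_group(rng, 0.025)
        df = frame([("a", ages, fis), ("b", ages, fis)])
        comp = compare_slopes(df)
        pair = comp.pairwise[0]
        assert pair.estimate == pytest.approx(0.0, abs=1e-12)
        assert comp.interaction_F == pytest.approx(0.0, abs=1e-9)

    def test_interaction_model_slopes_match_separate_fits(self):
        rng = np.random.default_rng(3)
        data = [(g, *self._sim_group(rng, s))
                for g, s in [("a", 0.02), ("b", 0.03), ("c", 0.025)]]
        df = frame(data)
        comp = compare_slopes(df)
        for g, ages, fis in data:
            separate = fit_loglinear(ages, fis, g)
            assert comp.slopes[g] == pytest.approx(separate.slope, abs=1e-10)

    def test_null_case_rejection_rate_nominal(self):
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            df = frame([("a", *self._sim_group(rng, 0.025)),
                        ("b", *self._sim_group(rng, 0.025))])
            rejections += compare_slopes(df).p_value < 0.05
        assert rejections / n_seeds <= 0.15

    def test_distinct_rates_detected_with_high_power(self):
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            df = frame([("slow", *self._sim_group(rng, 0.020, 500)),
                        ("fast", *self._sim_group(rng, 0.035, 500))])
            rejections += compare_slopes(df).p_value < 0.05
        assert rejections / n_seeds >= 0.95

    def test_needs_two_groups(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValidationError):
            compare_slopes(frame([("only", *self._sim_group(rng, 0.02))]))


def _type3_oracle(df, response, factors):
    """Brute-force Type III F-tests: extra sum of squares in sum coding."""
    import itertools

    terms = []
    for order in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, order):
            terms.append(":".join(f"C({f}, Sum)" for f in subset))
    X = dmatrix(" + ".join(terms), df, return_type="dataframe")
    y = df[response].to_numpy(dtype=float)

    def rss(cols):
        A = X[cols].to_numpy()
        resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        return resid @ resid

    full = rss(list(X.columns))
    df_res = len(df) - X.shape[1]
    out = {}
    di = X.design_info
    for term in di.term_names:
        if term == "Intercept":
            continue
        sl = di.term_name_slices[term]
        keep = [c for i, c in enumerate(X.columns) if not sl.start <= i < sl.stop]
        q = sl.stop - sl.start
        F = ((rss(keep) - full) / q) / (full / df_res)
        out[term.replace("C(", "").replace(", Sum)", "")] = F
    return out


class TestFactorialAnova:
    def _random_design(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for s in ["m", "f"]:
            for g in ["tg", "wt"]:
                for b in ["young", "mid", "old"]:
                    n = int(rng.integers(3, 9))
                    mu = 0.1 + 0.04 * (s == "m") + 0.02 * (b == "old")
                    for _ in range(n):
                        rows.append(
                            {"sex": s, "genotype": g, "age_band": b,
                             "fi": float(rng.normal(mu, 0.05))}
                        )
        return pd.DataFrame(rows)

    def test_constant_response_gives_zero_f(self):
        df = self._random_design(0).assign(fi=0.2)
        terms, _ = factorial_anova(df)
        assert all(t.F == 0.0 for t in terms)

    def test_balanced_two_group_f_is_squared_t(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "sex": ["m"] * 20 + ["f"] * 20,
                "fi": np.concatenate(
                    [rng.normal(0.15, 0.05, 20), rng.normal(0.11, 0.05, 20)]
                ),
            }
        )
        terms, _ = factorial_anova(df, factors=("sex",))
        t_stat, _ = stats.ttest_ind(
            df.loc[df.sex == "m", "fi"], df.loc[df.sex == "f", "fi"]
        )
        assert terms[0].F == pytest.approx(t_stat**2, rel=1e-10)

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_type3_matches_extra_sum_of_squares_oracle(self, seed):
        df = self._random_design(seed)
        terms, _ = factorial_anova(df)
        oracle = _type3_oracle(df, "fi", ["sex", "genotype", "age_band"])
        assert set(oracle) == {t.term for t in terms}
        for t in terms:
            assert t.F == pytest.approx(oracle[t.term], abs=1e-8)

    def test_empty_cell_drops_interaction_term(self, caplog):
        df = self._random_design(2)
        df = df[~((df.sex == "m") & (df.genotype == "tg") & (df.age_band == "old"))]
        terms, _ = factorial_anova(df)
        names = {t.term for t in terms}
        assert "sex:genotype:age_band" not in names
        assert {"sex", "genotype", "age_band"} <= names

    def test_sex_linked_frailty_detected_genotype_not(self, groups):
        # generator where only sex moves the trajectory: sex main effect
        # should reject, genotype should not, at n = 200 per cell
        from mcfi.cohort_sim import GroupParams

        hits_sex = 0
        hits_geno = 0
        n_seeds = 20
        base = dict(m=0.025, lambda0=2e-4, gamma=0.0, beta=0.0,
                    age_range=(50, 800), p_cens=0.0)
        for seed in range(n_seeds):
            rng = np.random.default_rng(900 + seed)
            rows = []
            for sex, f0 in [("M", 0.06), ("F", 0.04)]:
                for geno in ["TG", "WT"]:
                    p = GroupParams(sex=sex, genotype=geno, f0=f0, **base)
                    ages = rng.integers(50, 800, 200)
                    fis = simulate_fi_values(ages, p, rng)
                    for a, f in zip(ages, fis):
                        rows.append({"sex": sex, "genotype": geno,
                                     "age_band": assign_band([a])[0], "fi": f})
            terms, _ = factorial_anova(pd.DataFrame(rows))
            by = {t.term: t.p_value for t in terms}
            hits_sex += by["sex"] < 0.05
            hits_geno += by["genotype"] < 0.05
        assert hits_sex / n_seeds >= 0.95
        assert hits_geno / n_seeds <= 0.3

    def test_posthoc_contrasts_bonferroni_capped(self):
        df = self._random_design(3)
        _, contrasts = factorial_anova(df, factors=("sex", "genotype"),
                                       posthoc=True)
        assert len(contrasts) == 6  # C(4, 2) cells
        for c in contrasts:
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted <= 1.0
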