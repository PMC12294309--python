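"""Reliability statistics against closed forms, brute-force sums-of-squares
oracles, and pingouin as an independent implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abit.model import Source, Stage
from abit.reliability import (
    UndefinedStatisticError,
    cronbach_alpha,
    icc_single,
    lin_ccc,
    reliability_report,
)
from abit.simulate import SimulationParams, simulate_cohort

from conftest import make_record, triplet


# ---------------------------------------------------------------- oracles


def alpha_covariance_oracle(m: np.ndarray) -> float:
    """Alpha from the item covariance matrix: k/(k-1) * (1 - tr(C)/sum(C))."""
    c = np.cov(m, rowvar=False, ddof=1)
    k = m.shape[1]
    return k / (k - 1) * (1 - np.trace(c) / c.sum())


def icc_anova_oracle(m: np.ndarray, form: str) -> float:
    """ICC from an explicitly looped two-way ANOVA table."""
    n, k = m.shape
    grand = m.mean()
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if form == "consistency":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


def ccc_pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """CCC as Pearson's r times the bias-correction factor C_b."""
    r = stats.pearsonr(x, y).statistic
    sx, sy = x.std(), y.std()  # n denominator
    v = sx / sy
    u = (x.mean() - y.mean()) / np.sqrt(sx * sy)
    c_b = 2 / (v + 1 / v + u**2)
    return r * c_b


# ---------------------------------------------------------------- alpha


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        col = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        m = np.column_stack([col, col, col])
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_hand_computed_perfectly_correlated_pair(self):
        m = np.array([[1, 2], [2, 3], [3, 4], [4, 5]], dtype=float)
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_uncorrelated_items_give_zero_in_expectation(self):
        rng = np.random.default_rng(42)
        m = rng.standard_normal((10_000, 3))
        assert cronbach_alpha(m) == pytest.approx(0.0, abs=0.05)

    def test_zero_total_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cronbach_alpha(np.ones((5, 3)))

    def test_matches_covariance_oracle_and_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.integers(0, 5, size=(8, 3)).astype(float)
            if m.sum(axis=1).var(ddof=1) == 0:
                continue
            ours = cronbach_alpha(m)
            assert ours == pytest.approx(alpha_covariance_oracle(m), abs=1e-10)
            theirs = pg.cronbach_alpha(data=pd.DataFrame(m))[0]
            assert ours == pytest.approx(theirs, abs=1e-8)

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((20, 3))
        assert cronbach_alpha(m + 17.3) == pytest.approx(cronbach_alpha(m), abs=1e-10)


# ---------------------------------------------------------------- ICC


class TestICC:
    def test_identical_administrations_give_one(self):
        col = np.array([3.0, 7.0, 1.0, 9.0])
        m = np.column_stack([col, col])
        assert icc_single(m, "consistency") == pytest.approx(1.0)
        assert icc_single(m, "agreement") == pytest.approx(1.0)

    def test_location_shift_splits_the_forms(self):
        col = np.array([3.0, 7.0, 1.0, 9.0])
        m = np.column_stack([col, col + 2.0])
        assert icc_single(m, "consistency") == pytest.approx(1.0)
        assert icc_single(m, "agreement") < 1.0

    def test_small_hand_dataset_matches_anova_oracle(self):
        m = np.array([[9, 2], [4, 5], [6, 7], [8, 3]], dtype=float)
        for form in ("consistency", "agreement"):
            assert icc_single(m, form) == pytest.approx(
                icc_anova_oracle(m, form), abs=1e-12
            )

    def test_random_matrices_match_oracle_and_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(1)
        for _ in range(20):
            m = rng.integers(0, 10, size=(5, 2)).astype(float)
            if np.allclose(m.var(axis=0), 0):
                continue
            cons = icc_single(m, "consistency")
            agree = icc_single(m, "agreement")
            assert cons == pytest.approx(icc_anova_oracle(m, "consistency"), abs=1e-10)
            assert agree == pytest.approx(icc_anova_oracle(m, "agreement"), abs=1e-10)
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(5), 2),
                    "rater": np.tile(["a", "b"], 5),
                    "score": m.ravel(),
                }
            )
            icc = pg.intraclass_corr(
                data=long, targets="subject", raters="rater", ratings="score"
            ).set_index("Type")

            def pg_icc(*labels):
                for label in labels:
                    if label in icc.index:
                        return icc.loc[label, "ICC"]
                raise KeyError(labels)

            assert cons == pytest.approx(pg_icc("ICC3", "ICC(C,1)"), abs=1e-8)
            assert agree == pytest.approx(pg_icc("ICC2", "ICC(A,1)"), abs=1e-8)

    def test_agreement_never_exceeds_consistency_when_columns_differ(self):
        # Holds whenever MS_C >= MS_E and the numerator MS_R - MS_E is
        # non-negative (a negative ICC flips the denominator ordering).
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(200):
            m = rng.standard_normal((6, 2)) + [0.0, 0.5]
            m[:, 1] += 0.8 * m[:, 0]  # induce positive subject variance
            cons = icc_single(m, "consistency")
            agree = icc_single(m, "agreement")
            n, k = m.shape
            grand = m.mean()
            ms_c = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
            ss_tot = ((m - grand) ** 2).sum()
            ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
            ms_r = ss_rows / (n - 1)
            ms_e = (ss_tot - ss_rows - ms_c * (k - 1)) / ((n - 1) * (k - 1))
            if ms_c >= ms_e and ms_r >= ms_e:
                assert agree <= cons + 1e-12
                checked += 1
        assert checked > 50

    def test_forms_coincide_when_column_and_error_mean_squares_match(self):
        # Construct MS_C == MS_E exactly: with k=2 and column offset d,
        # MS_C = n d^2 / 2, so choose d accordingly.
        rng = np.random.default_rng(3)
        m = rng.standard_normal((8, 2))
        m -= m.mean(axis=0)
        n, k = m.shape
        grand = m.mean()
        ss_tot = ((m - grand) ** 2).sum()
        ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
        ms_e = (ss_tot - ss_rows) / ((n - 1) * (k - 1))
        d = np.sqrt(2 * ms_e / n)
        m[:, 1] += d
        assert icc_single(m, "agreement") == pytest.approx(
            icc_single(m, "consistency"), abs=1e-10
        )

    def test_degenerate_matrix_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_single(np.full((4, 2), 3.0), "consistency")


# ---------------------------------------------------------------- CCC


class TestLinCCC:
    def test_identity_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert lin_ccc(x, x) == (1.0, 1.0, 1.0)

    def test_negation_gives_minus_one(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        ccc, lo, hi = lin_ccc(x, -x)
        assert ccc == pytest.approx(-1.0)

    def test_magnitude_bounded_by_pearson(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.standard_normal(12)
            y = 0.6 * x + rng.standard_normal(12) + rng.normal(0, 1)
            ccc, _, _ = lin_ccc(x, y)
            r = stats.pearsonr(x, y).statistic
            assert abs(ccc) <= abs(r) + 1e-12
            assert ccc == pytest.approx(ccc_pearson_oracle(x, y), abs=1e-10)

    def test_location_shift_strictly_reduces_concordance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        y = x + 0.1 * rng.standard_normal(30)
        base, _, _ = lin_ccc(x, y)
        for shift in (0.5, 1.0, 2.0):
            shifted, _, _ = lin_ccc(x, y + shift)
            assert shifted < base

    def test_ci_brackets_estimate_and_widens_with_level(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        y = 0.8 * x + 0.4 * rng.standard_normal(40)
        ccc, lo95, hi95 = lin_ccc(x, y, ci_level=0.95)
        _, lo99, hi99 = lin_ccc(x, y, ci_level=0.99)
        assert lo95 <= ccc <= hi95
        assert lo99 <= lo95 and hi99 >= hi95

    def test_both_constant_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            lin_ccc(np.ones(5), np.ones(5))

    def test_parameter_recovery_at_latent_correlation(self):
        """Mean CCC over seeded replicates recovers rho=0.9 under matched moments."""
        rho, n, reps = 0.9, 200, 100
        rng = np.random.default_rng(123)
        cov = [[1.0, rho], [rho, 1.0]]
        estimates = [
            lin_ccc(*rng.multivariate_normal([0, 0], cov, size=n).T)[0]
            for _ in range(reps)
        ]
        se = np.std(estimates, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(estimates) - rho) < 3 * se


# ---------------------------------------------------------------- report


class TestReliabilityReport:
    def test_identical_cohorts_give_perfect_agreement(self):
        params = SimulationParams(n_participants=12, seed=11)
        test, _, _ = simulate_cohort(params)
        retest = [
            make_record(
                participant_id=r.participant_id,
                age_years=r.age_years,
                stage=Stage.RETEST,
                r1=r.r1,
                sr=r.sr,
                r2=r.r2,
                ema=r.ema,
                exam=r.exam,
            )
            for r in test
        ]
        report = reliability_report(test, retest)
        assert report.icc_consistency == pytest.approx(1.0)
        assert report.icc_agreement == pytest.approx(1.0)
        assert report.ccc == pytest.approx(1.0)
        assert report.ccc_ci_low <= report.ccc <= report.ccc_ci_high

    def test_unmatched_ids_listed(self):
        test, retest, _ = simulate_cohort(SimulationParams(n_participants=5, seed=2))
        with pytest.raises(ValueError, match="P005"):
            reliability_report(test, retest[:-1])

    def test_single_overlap_rejected(self):
        test, retest, _ = simulate_cohort(SimulationParams(n_participants=1, seed=2))
        with pytest.raises(ValueError):
            reliability_report(test, retest)

    def test_alpha_computed_over_questions(self):
        # Three participants with distinct answer profiles; R1 alpha from the
        # test stage must equal alpha of the 3x3 question-score matrix.
        rows = [(0, 1, 2), (2, 3, 4), (1, 1, 0), (4, 2, 1)]
        test = [
            make_record(
                participant_id=f"P{i}", r1=triplet(Source.R1, *row)
            )
            for i, row in enumerate(rows)
        ]
        retest = [
            make_record(
                participant_id=f"P{i}",
                stage=Stage.RETEST,
                r2=triplet(Source.R2, *row),
            )
            for i, row in enumerate(rows)
        ]
        report = reliability_report(test, retest)
        expected = cronbach_alpha(np.array(rows, dtype=float))
        assert report.alpha_r1 == pytest.approx(expected, abs=1e-12)
        assert report.alpha_r2 == pytest.approx(expected, abs=1e-12)
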