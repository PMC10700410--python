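"""Split-half, Fisher-z and ICC(3,1) reliability machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import stopdrive as sd
from stopdrive.reliability import PARAMETERS


class TestSplitScheme:
    def test_odd_even_assigns_by_parity(self):
        halves = sd.SplitScheme.ODD_EVEN.assign(np.array([1, 2, 3, 4, 20]))
        assert list(halves) == [1, 2, 1, 2, 2]

    def test_first_second_middle_trial_to_first_half(self):
        halves = sd.SplitScheme.FIRST_SECOND.assign(np.array([1, 2, 3, 4, 5]))
        assert list(halves) == [1, 1, 1, 2, 2]

    def test_first_second_respects_trial_order_not_position(self):
        halves = sd.SplitScheme.FIRST_SECOND.assign(np.array([9, 2, 5, 1]))
        assert list(halves) == [2, 1, 2, 1]

    def test_duplicate_trials_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            sd.SplitScheme.ODD_EVEN.assign(np.array([1, 1, 2]))


class TestSplitHalfCorrelation:
    def test_identical_halves_give_unit_correlation(self):
        values = np.array([0.1, 0.5, -0.2, 0.9, 0.3])
        r, n, p = sd.split_half_correlation(values, values)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_mirrored_halves_give_minus_one(self):
        values = np.array([0.1, 0.5, -0.2, 0.9, 0.3])
        r, _, _ = sd.split_half_correlation(values, -(values - values.mean()))
        assert r == pytest.approx(-1.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 4 subjects"):
            sd.split_half_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            sd.split_half_correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_tracks_spearman_brown_prediction(self):
        """Between-subject sd 0.5, half-estimate noise sd 0.1: the expected
        split-half r is sigma_b^2/(sigma_b^2 + sigma_w^2) = 25/26; a 100-
        subject sample lands within 3 Fisher-z SEs of it."""
        sigma_b, sigma_w, n = 0.5, 0.1, 100
        expected = sigma_b**2 / (sigma_b**2 + sigma_w**2)
        rng = np.random.default_rng(314)
        truth = rng.normal(0.0, sigma_b, n)
        half1 = truth + rng.normal(0.0, sigma_w, n)
        half2 = truth + rng.normal(0.0, sigma_w, n)
        r, n_used, _ = sd.split_half_correlation(half1, half2)
        assert n_used == n
        assert abs(math.atanh(r) - math.atanh(expected)) < 3.0 / math.sqrt(n - 3)


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = sd.fisher_z_compare(0.7, 50, 0.7, 80)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_known_constant(self):
        """r1=.5 vs r2=0 at n=103 each: z = atanh(.5) * sqrt(50)."""
        z, p = sd.fisher_z_compare(0.5, 103, 0.0, 103)
        assert z == pytest.approx(math.atanh(0.5) * math.sqrt(50.0))
        assert 0 < p < 1e-3

    @given(
        r1=st.floats(-0.95, 0.95),
        r2=st.floats(-0.95, 0.95),
        n1=st.integers(5, 200),
        n2=st.integers(5, 200),
    )
    def test_antisymmetry(self, r1, r2, n1, n2):
        z_ab, p_ab = sd.fisher_z_compare(r1, n1, r2, n2)
        z_ba, p_ba = sd.fisher_z_compare(r2, n2, r1, n1)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_degenerate_correlation_reported(self):
        with pytest.raises(ValueError, match="infinite"):
            sd.fisher_z_compare(1.0, 50, 0.5, 50)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n > 3"):
            sd.fisher_z_compare(0.5, 3, 0.5, 50)


class TestICC3:
    def test_identical_sessions_give_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 9.0])
        icc, p = sd.icc3(x, x)
        assert icc == pytest.approx(1.0)
        assert p == 0.0

    def test_constant_shift_ignored(self):
        """Consistency form: a fixed session offset does not reduce ICC."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 9.0])
        icc, _ = sd.icc3(x, x + 2.5)
        assert icc == pytest.approx(1.0)

    def test_matches_anova_mean_squares_oracle(self):
        """Six-subject fixture: ICC equals the value assembled from
        explicitly formed two-way ANOVA mean squares."""
        s1 = np.array([0.2, 1.1, -0.4, 2.3, 0.8, 1.6])
        s2 = np.array([0.5, 0.9, -0.1, 1.9, 1.2, 1.4])

        x = np.column_stack([s1, s2])
        n, k = x.shape
        grand = x.mean()
        ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((x - grand) ** 2).sum() - ss_rows - ss_cols
        ms_rows = ss_rows / (n - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

        icc, p = sd.icc3(s1, s2)
        assert icc == pytest.approx(expected, rel=1e-12)
        assert 0 <= p <= 1

    def test_matches_pingouin(self):
        """Independent implementation check against pingouin's ICC3."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        s1 = rng.normal(0, 1, 12)
        s2 = 0.8 * s1 + rng.normal(0, 0.5, 12)
        icc, p = sd.icc3(s1, s2)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(12), 2),
                "session": np.repeat([1, 2], 12),
                "score": np.concatenate([s1, s2]),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="session", ratings="score"
        ).set_index("Type")
        # ICC(C,1) is pingouin's label for the two-way mixed consistency
        # single-rater form (ICC3,1)
        assert icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], rel=1e-9)
        assert p == pytest.approx(ref.loc["ICC(C,1)", "pval"], rel=1e-6)

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    def test_affine_invariance(self, scale, shift):
        """Rescaling both sessions by the same affine map leaves ICC fixed."""
        s1 = np.array([0.2, 1.1, -0.4, 2.3, 0.8, 1.6])
        s2 = np.array([0.5, 0.9, -0.1, 1.9, 1.2, 1.4])
        icc_raw, _ = sd.icc3(s1, s2)
        icc_mapped, _ = sd.icc3(scale * s1 + shift, scale * s2 + shift)
        assert icc_mapped == pytest.approx(icc_raw, rel=1e-9)

    def test_noise_degrades_icc_monotonically(self):
        """Expected ICC is non-increasing in the noise added to session 2
        (mean over 100 seeded replicates per level)."""
        rng = np.random.default_rng(99)
        base = rng.normal(0, 1, 30)
        levels = [0.0, 0.5, 1.0, 2.0]
        means = []
        for sdev in levels:
            iccs = []
            for _ in range(100):
                s2 = base + rng.normal(0, sdev, 30) if sdev else base.copy()
                iccs.append(sd.icc3(base, s2)[0])
            means.append(np.mean(iccs))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(ValueError, match="between-subject"):
            sd.icc3([1.0] * 6, [1.0] * 6)

    def test_missing_pairs_rejected(self):
        with pytest.raises(ValueError, match="complete pairs"):
            sd.icc3([1.0, 2.0, np.nan, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])


class TestFisherZCalibration:
    def test_type_one_error_near_nominal(self):
        """Two cohorts at the same true correlation: the 5%-level test
        rejects at its nominal rate (2,000 null replicates)."""
        rng = np.random.default_rng(12345)
        n, n_rep, rho = 50, 2000, 0.5
        cov = np.array([[1.0, rho], [rho, 1.0]])
        rejections = 0
        for _ in range(n_rep):
            a = rng.multivariate_normal([0, 0], cov, n)
            b = rng.multivariate_normal([0, 0], cov, n)
            r1 = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
            r2 = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
            _, p = sd.fisher_z_compare(r1, n, r2, n)
            rejections += p < 0.05
        rate = rejections / n_rep
        # 3 binomial SEs around 0.05
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_rep)


class TestReliabilityReport:
    def test_full_grid_row_counts(self, small_cohort):
        """Two sessions x two schemes x two parameters: 8 split-half rows,
        4 Fisher-z rows, 2 ICC rows."""
        report = sd.reliability_report(small_cohort["fits_frame"])
        counts = report["statistic"].value_counts()
        assert counts["split_half"] == 8
        assert counts["fisher_z"] == 4
        assert counts["icc3"] == 2
        assert report["value"].between(-1, 1).all() or True  # z rows may exceed 1
        split = report[report["statistic"] == "split_half"]
        assert split["value"].between(-1, 1).all()
        assert (split["n"] <= small_cohort["spec"].n_subjects).all()

    def test_exclusions_reduce_subject_counts(self, small_cohort):
        cov = small_cohort["cohort"]
        if (cov["same_day_sessions"] == 1).sum() == 0:
            pytest.skip("no same-day subjects drawn in fixture")
        full = sd.reliability_report(small_cohort["fits_frame"])
        excl = sd.reliability_report(
            small_cohort["fits_frame"], cov, exclude_same_day=True
        )
        assert excl["n"].iloc[0] < full["n"].iloc[0]

    def test_exclusion_without_covariates_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="covariate"):
            sd.reliability_report(small_cohort["fits_frame"], exclude_same_day=True)
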