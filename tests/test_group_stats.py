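import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynmod import (
    DataValidationError,
    DegenerateInputError,
    InsufficientDataError,
    PhenotypeTable,
    bonferroni_threshold,
    mann_whitney,
    partial_spearman,
    residualize,
    run_association_suite,
)


class TestResidualize:
    def test_no_covariates_centers_and_standardizes(self, rng):
        y = rng.uniform(0, 10, 50)
        r = residualize(y, None)
        assert r.mean() == pytest.approx(0.0, abs=1e-12)
        assert r.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_exact_linear_dependence_gives_zero_residuals(self, rng):
        x = rng.standard_normal((30, 2))
        y = 2.0 * x[:, 0] - 1.5 * x[:, 1] + 3.0
        r = residualize(y, x)
        assert np.linalg.norm(r) < 1e-10

    def test_orthogonal_outcome_preserved(self):
        n = 40
        cov = np.cos(2 * np.pi * np.arange(n) / n)[:, None]
        y = np.sin(2 * np.pi * np.arange(n) / n)  # orthogonal to cov & intercept
        r = residualize(y, cov)
        assert np.corrcoef(r, y)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal((20, 1))
        with pytest.raises(DataValidationError, match="rank deficient"):
            residualize(rng.standard_normal(20), np.hstack([x, 2 * x]))


class TestPartialSpearman:
    def test_perfect_inverse_ranks(self):
        res = partial_spearman(np.array([1.0, 2, 3, 4]), np.array([4.0, 3, 2, 1]))
        assert res.rho == pytest.approx(-1.0, abs=1e-12)

    def test_no_covariates_equals_textbook_spearman(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            expected = stats.spearmanr(x, y).statistic
            got = partial_spearman(x, y).rho
            assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_transforms_without_covariates(self, rng):
        x = rng.uniform(0.1, 2.0, 60)
        y = rng.uniform(0.1, 2.0, 60)
        base = partial_spearman(x, y).rho
        assert partial_spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert partial_spearman(x, y ** 3).rho == pytest.approx(base, abs=1e-12)

    def test_rank_first_variant_invariant_with_covariates(self, rng):
        # ranking before residualizing makes the statistic depend on x and y
        # only through their ranks, so monotone transforms cannot change it
        x = rng.uniform(0.1, 2.0, 60)
        y = rng.uniform(0.1, 2.0, 60)
        cov = rng.standard_normal((60, 2))
        base = partial_spearman(x, y, cov, rank_first=True).rho
        assert partial_spearman(np.exp(x), y, cov, rank_first=True).rho == \
            pytest.approx(base, abs=1e-12)
        assert partial_spearman(x, y ** 3, cov, rank_first=True).rho == \
            pytest.approx(base, abs=1e-12)

    def test_r_squared_is_rho_squared(self, rng):
        res = partial_spearman(rng.standard_normal(30), rng.standard_normal(30))
        assert res.r_squared == pytest.approx(res.rho ** 2, abs=1e-12)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            partial_spearman(np.arange(5.0), np.arange(5.0),
                             rng.standard_normal((5, 3)))

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            partial_spearman(np.ones(10), np.arange(10.0))

    def test_null_calibration_with_confounded_outcome(self, rng):
        # y depends on the covariate, x independent: rejection ~ alpha
        hits = 0
        n_sims = 400
        for _ in range(n_sims):
            cov = rng.standard_normal((40, 1))
            y = cov[:, 0] + rng.standard_normal(40)
            x = rng.standard_normal(40)
            if partial_spearman(x, y, cov).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / n_sims <= 0.08


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected_rounded", [
        (0.05, 28, 0.0018),
        (0.05, 1, 0.05),
        (0.01, 10, 0.001),
    ])
    def test_threshold_values(self, alpha, m, expected_rounded):
        full, rounded = bonferroni_threshold(alpha, m)
        assert full == pytest.approx(alpha / m, rel=1e-12)
        assert rounded == expected_rounded

    def test_zero_comparisons_rejected(self):
        with pytest.raises(DataValidationError):
            bonferroni_threshold(0.05, 0)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 rank splits
        assert z < 0

    def test_identical_groups_give_p_one(self):
        u, z, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention_of_z(self, rng):
        low = rng.normal(0, 1, 30)
        high = rng.normal(2, 1, 30)
        _, z_ab, _ = mann_whitney(low, high)
        _, z_ba, _ = mann_whitney(high, low)
        assert z_ab < 0 < z_ba

    def test_detects_one_sd_shift(self, rng):
        detections = 0
        for _ in range(40):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            _, _, p = mann_whitney(a, b)
            detections += p < 0.01
        assert detections >= 38  # >= 95% power

    def test_empty_group_rejected(self):
        with pytest.raises(DataValidationError):
            mann_whitney([], [1.0])


def _phenotype(n, fsiq, rng):
    return PhenotypeTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "fsiq": fsiq,
        "age": rng.uniform(20, 60, n),
        "sex": rng.integers(0, 2, n),
        "handedness": rng.integers(0, 2, n),
        "mean_fd": rng.uniform(0.05, 0.15, n),
    }))


class TestAssociationSuite:
    def test_planted_negative_association_detected(self, rng):
        n = 100
        sdq = rng.uniform(0.01, 0.10, n)
        fsiq = 100 - 300 * sdq + rng.normal(0, 2, n)
        phen = _phenotype(n, fsiq, rng)
        measures = pd.DataFrame({"sd_q": sdq},
                                index=pd.Index([f"s{i}" for i in range(n)],
                                               name="subject_id"))
        report = run_association_suite(measures, phen)
        res = report["correlations"]["sd_q"]
        assert res.rho < 0
        assert res.p_value < 0.001

    def test_tiny_cohort_rejected(self, rng):
        phen = _phenotype(3, [100, 101, 102], rng)
        measures = pd.DataFrame({"sd_q": [0.1, 0.2, 0.3]},
                                index=pd.Index(["s0", "s1", "s2"],
                                               name="subject_id"))
        with pytest.raises(InsufficientDataError):
            run_association_suite(measures, phen)

    def test_state_contrast_groups_formed(self, rng):
        n = 40
        fsiq = rng.normal(100, 15, n)
        phen = _phenotype(n, fsiq, rng)
        counts = np.zeros(n, dtype=int)
        counts[:10] = rng.integers(1, 5, 10)  # 10 subjects with states
        measures = pd.DataFrame(
            {"sd_q": rng.uniform(0.01, 0.1, n), "n_high_individual": counts},
            index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"))
        report = run_association_suite(measures, phen)
        contrast = report["state_contrasts"]["n_high_individual_vs_fsiq"]
        assert contrast["n_with"] == 10
        assert contrast["n_without"] == 30
        assert 0 < contrast["p"] <= 1
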