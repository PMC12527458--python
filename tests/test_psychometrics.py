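"""Factorability diagnostics, EFA, internal consistency, reliability,
responsiveness, and convergent-validity hypotheses."""

import numpy as np
import pandas as pd
import pytest

from mc_activity.psychometrics import (
    CorrelationHypothesis,
    bartlett_sphericity,
    cronbach_alpha,
    efa,
    icc2k,
    kmo,
    parallel_analysis,
    promax,
    responsiveness_battery,
    validity_correlations,
)


def _factor_data(loadings, n, noise_sd=None, seed=0):
    """Sample data from a factor model with unit-variance factors."""
    rng = np.random.default_rng(seed)
    L = np.asarray(loadings, dtype=float)
    p = L.shape[0]
    uniq = np.sqrt(np.clip(1 - (L**2).sum(axis=1), 0.05, 1)) if noise_sd is None \
        else np.full(p, noise_sd)
    f = rng.normal(0, 1, (n, L.shape[1]))
    return f @ L.T + rng.normal(0, 1, (n, p)) * uniq


class TestBartlett:
    def test_identity_matrix_gives_zero_statistic(self):
        chi2, df, p = bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_two_item_closed_form(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2, df, p = bartlett_sphericity(r, n=100)
        assert chi2 == pytest.approx(-(99 - 9 / 6) * np.log(0.75), rel=1e-12)
        assert df == 1

    def test_equicorrelated_matrix_is_significant(self):
        r = np.full((6, 6), 0.3)
        np.fill_diagonal(r, 1.0)
        _, _, p = bartlett_sphericity(r, n=131)
        assert p < 0.05

    def test_singular_matrix_raises(self):
        r = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            bartlett_sphericity(r, n=50)


class TestKMO:
    def test_two_item_matrix_is_exactly_half(self):
        overall, msa = kmo(np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert overall == pytest.approx(0.5, abs=1e-12)

    def test_single_common_factor_data_is_adequate(self):
        x = _factor_data(np.full((6, 1), 0.8), n=2000, seed=1)
        overall, _ = kmo(np.corrcoef(x, rowvar=False))
        assert overall > 0.8

    def test_independent_blocks_lower_msa_than_one_block(self):
        one = _factor_data(np.full((6, 1), 0.8), n=4000, seed=2)
        L2 = np.zeros((6, 2)); L2[:3, 0] = 0.8; L2[3:, 1] = 0.8
        two = _factor_data(L2, n=4000, seed=2)
        _, msa_one = kmo(np.corrcoef(one, rowvar=False))
        _, msa_two = kmo(np.corrcoef(two, rowvar=False))
        assert msa_two.mean() < msa_one.mean()


class TestParallelAnalysis:
    def test_deterministic_given_seed(self):
        x = np.random.default_rng(0).normal(0, 1, (200, 8))
        assert parallel_analysis(x, n_reps=150, seed=7) == \
            parallel_analysis(x, n_reps=150, seed=7)

    def test_pure_noise_suggests_at_most_one_factor(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(0, 1, (200, 8))
            hits += parallel_analysis(x, n_reps=150, seed=seed) <= 1
        assert hits >= 9

    def test_three_factor_structure_detected(self):
        L = np.zeros((9, 3))
        for j in range(3):
            L[3 * j:3 * (j + 1), j] = 0.8
        x = _factor_data(L, n=500, seed=3)
        assert parallel_analysis(x, n_reps=200, seed=1) == 3

    def test_rejects_too_few_reps(self):
        with pytest.raises(ValueError):
            parallel_analysis(np.zeros((10, 3)), n_reps=10)


class TestEFA:
    def test_one_factor_loading_recovery(self):
        x = _factor_data(np.full((6, 1), 0.7), n=2000, seed=4)
        m = efa(x, n_factors=1, rotation="none")
        assert np.all(np.abs(m.loadings.to_numpy().ravel() - 0.7) < 0.1)

    def test_three_factor_simple_structure_recovery(self):
        L = np.zeros((9, 3))
        for j in range(3):
            L[3 * j:3 * (j + 1), j] = 0.8
        x = _factor_data(L, n=2000, seed=5)
        m = efa(x, n_factors=3, rotation="promax")
        lam = np.abs(m.loadings.to_numpy())
        top = lam.argmax(axis=1)
        # items generated by the same factor share their top loading
        assert len({tuple(top[3 * j:3 * (j + 1)]) for j in range(3)}) == 3
        for j in range(3):
            assert len(set(top[3 * j:3 * (j + 1)])) == 1
        # factor congruence with the generating pattern
        for j in range(3):
            col = lam[:, top[3 * j]]
            tgt = L[:, j]
            congruence = col @ tgt / np.sqrt((col**2).sum() * (tgt**2).sum())
            assert congruence >= 0.95

    def test_promax_phi_near_identity_for_orthogonal_factors(self):
        L = np.zeros((9, 3))
        for j in range(3):
            L[3 * j:3 * (j + 1), j] = 0.8
        x = _factor_data(L, n=2000, seed=6)
        m = efa(x, n_factors=3, rotation="promax")
        assert np.abs(m.phi - np.eye(3)).max() < 0.15

    def test_communality_plus_uniqueness_is_one(self):
        x = _factor_data(np.full((6, 1), 0.7), n=500, seed=7)
        m = efa(x, n_factors=1, rotation="none")
        assert np.allclose(m.communalities + m.uniquenesses, 1.0, atol=1e-12)
        assert np.all((m.communalities >= 0) & (m.communalities <= 1))

    def test_eigenvalues_sum_to_item_count(self):
        x = _factor_data(np.full((6, 1), 0.7), n=500, seed=8)
        m = efa(x, n_factors=1, rotation="none")
        assert m.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)

    def test_invalid_factor_count_rejected(self):
        with pytest.raises(ValueError):
            efa(np.random.default_rng(0).normal(size=(50, 4)), n_factors=4)


class TestCronbachAlpha:
    def test_duplicated_column_gives_one(self):
        col = np.random.default_rng(0).normal(0, 1, 50)
        assert cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_independent_items_give_near_zero(self):
        x = np.random.default_rng(1).normal(0, 1, (5000, 6))
        assert abs(cronbach_alpha(x)) < 0.05

    def test_spearman_brown_identity_for_equicorrelated_items(self):
        # population alpha for k=3 items with pairwise r=0.5 is
        # k*r / (1 + (k-1)*r) = 0.75
        rng = np.random.default_rng(2)
        f = rng.normal(0, np.sqrt(0.5), (20000, 1))
        x = f + rng.normal(0, np.sqrt(0.5), (20000, 3))
        assert cronbach_alpha(x) == pytest.approx(0.75, abs=0.02)

    def test_item_order_invariance(self):
        x = np.random.default_rng(3).normal(0, 1, (100, 4)).cumsum(axis=1)
        assert cronbach_alpha(x) == pytest.approx(cronbach_alpha(x[:, ::-1]))

    def test_zero_total_variance_is_error(self):
        with pytest.raises(ZeroDivisionError):
            cronbach_alpha(np.column_stack([np.arange(10.0), -np.arange(10.0)]))


class TestICC2k:
    def test_identical_occasions_give_one(self):
        x = np.random.default_rng(0).normal(0, 1, 12)
        r = icc2k(np.column_stack([x, x]))
        assert r.icc == pytest.approx(1.0)

    def test_constant_shift_penalized_below_one(self):
        # absolute agreement penalizes systematic occasion shifts; verify
        # against the explicit ANOVA algebra on a 6-subject fixture
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        m = np.column_stack([x, x + 2.0])
        r = icc2k(m)
        assert r.icc < 1.0
        n, k = 6, 2
        msr = k * np.var(m.mean(axis=1), ddof=1)
        msc = n * np.var(m.mean(axis=0), ddof=1)
        mse = 0.0  # after removing row and column effects the residual is exactly 0
        expected = (msr - mse) / (msr + (msc - mse) / n)
        assert r.icc == pytest.approx(expected, abs=1e-12)
        assert r.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.normal(0, 1, (20, 2)) + rng.normal(0, 2, (20, 1))
        a = icc2k(m)
        b = icc2k(m[rng.permutation(20)])
        assert a.icc == pytest.approx(b.icc, abs=1e-12)

    def test_listwise_deletion(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(0, 1, (20, 2)) + rng.normal(0, 2, (20, 1)))
        m_with_nan = m.copy()
        m_with_nan.iloc[0, 0] = np.nan
        assert icc2k(m_with_nan).n_subjects == 19

    def test_insufficient_data_raises(self):
        with pytest.raises(ValueError):
            icc2k(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            icc2k(np.random.default_rng(0).normal(size=(10, 1)))

    def test_ci_brackets_estimate(self):
        from mc_activity.synthetic_cohort import generate_retest_data
        r = icc2k(generate_retest_data(40, 0.85, seed=9))
        assert r.ci_low <= r.icc <= r.ci_high


class TestResponsiveness:
    def _items(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"a": rng.integers(0, 5, n).astype(float),
                             "b": rng.integers(0, 5, n).astype(float)},
                            index=[f"P{i}" for i in range(n)])

    def test_identical_timepoints_give_p_one(self):
        base = self._items()
        res = responsiveness_battery(base, base.copy())
        assert (res.table["p_raw"] == 1.0).all()
        assert (res.table["flag"] == "no_change").all()

    def test_uniform_improvement_is_highly_significant(self):
        base = self._items(n=40, seed=1)
        fup = base - 2.0
        res = responsiveness_battery(base, fup)
        assert (res.table["p_adjusted"] < 5e-4).all()
        assert (res.table["direction"] == "decrease").all()

    def test_bonferroni_multiplication_and_cap(self):
        base = self._items(n=20, seed=2)
        fup = base + np.random.default_rng(3).normal(0, 1, base.shape)
        res = responsiveness_battery(base, fup, m_comparisons=8)
        assert np.allclose(res.table["p_adjusted"],
                           np.minimum(1.0, 8 * res.table["p_raw"]))
        assert (res.table["p_adjusted"] >= res.table["p_raw"]).all()

    def test_only_shared_patients_enter(self):
        base = self._items(n=20, seed=4)
        fup = self._items(n=20, seed=5).iloc[:12]
        res = responsiveness_battery(base, fup)
        assert (res.table["n_pairs"] == 12).all()


class TestValidityCorrelations:
    def _cohort(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        sev = rng.uniform(0, 15, n)
        return pd.DataFrame({
            "mcs": sev,
            "mcs_copy": sev,
            "ibdq_total": 200 - 6 * sev + rng.normal(0, 10, n),
            "noise": rng.normal(0, 1, n),
            "constant": np.ones(n),
        })

    def test_variable_against_itself_is_one(self):
        res = validity_correlations(self._cohort(), [
            CorrelationHypothesis("mcs", "mcs_copy", +1)])
        assert res.loc[0, "r"] == pytest.approx(1.0)
        assert bool(res.loc[0, "met"])

    def test_anchored_ibdq_hypothesis_met(self):
        res = validity_correlations(self._cohort(), [
            CorrelationHypothesis("mcs", "ibdq_total", -1)])
        assert bool(res.loc[0, "met"]) and res.loc[0, "r"] < -0.4

    def test_noise_hypothesis_unmet(self):
        res = validity_correlations(self._cohort(), [
            CorrelationHypothesis("mcs", "noise", +1)])
        assert not bool(res.loc[0, "met"])

    def test_constant_column_flagged_not_raised(self):
        res = validity_correlations(self._cohort(), [
            CorrelationHypothesis("mcs", "constant", +1)])
        assert res.loc[0, "flag"] == "constant" and np.isnan(res.loc[0, "r"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            validity_correlations(self._cohort(n=5), [
                CorrelationHypothesis("mcs", "ibdq_total", -1)])
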