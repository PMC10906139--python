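"""Model-based biomarkers, exact Wilcoxon tests, logistic risk classifier
and ROC analysis."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from fkgrowth.biomarkers import (BiomarkerPanel, GsObservation,
                                 biomarker_panel, fit_logistic,
                                 prostate_volume, risk_trajectory,
                                 roc_analysis, wilcoxon_rank_sum,
                                 wilcoxon_signed_rank)
from fkgrowth.solver import DensityState, GrowthParams, SimulationGrid


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def rank_sum_p_oracle(x, y, alternative):
    """Brute-force permutation p-value of the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = [sum(ranks[list(c)])
          for c in itertools.combinations(range(len(pooled)), n1)]
    ws = np.array(ws)
    p_less = np.mean(ws <= w_obs + 1e-9)
    p_greater = np.mean(ws >= w_obs - 1e-9)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def signed_rank_p_oracle(x, y, alternative):
    """Brute-force sign-flip p-value of the signed-rank statistic."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(d))]
    ws = np.array(ws)
    p_less = np.mean(ws <= w_obs + 1e-9)
    p_greater = np.mean(ws >= w_obs - 1e-9)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def auc_concordance_oracle(scores, labels):
    """AUC as the Mann-Whitney pairwise concordance probability."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# biomarker panel
# ---------------------------------------------------------------------------

class TestBiomarkerPanel:
    def _grid(self, shape=(10, 10, 10), spacing=1.0):
        return SimulationGrid(np.ones(shape, bool), spacing, 1.0)

    def test_prostate_volume_hand_conversion(self):
        # 36,400 voxels at 1 mm^3 -> 36.4 cc (the cohort's median V_P)
        mask = np.zeros((40, 40, 40), bool)
        mask.flat[:36400] = True
        assert prostate_volume(SimulationGrid(mask, 1.0, 1.0)) == \
            pytest.approx(36.4)
        single = np.zeros((3, 3, 3), bool); single[1, 1, 1] = True
        assert prostate_volume(SimulationGrid(single, 1.0, 1.0)) == \
            pytest.approx(1e-3)

    def test_volume_scales_with_spacing_cubed(self):
        mask = np.ones((5, 5, 5), bool)
        v1 = prostate_volume(SimulationGrid(mask, 1.0, 1.0))
        v2 = prostate_volume(SimulationGrid(mask, 2.0, 1.0))
        assert v2 == pytest.approx(8 * v1)

    def test_uniform_half_density_activity(self):
        grid = self._grid()
        nbar = np.full((10, 10, 10), 0.5)
        panel = biomarker_panel(DensityState(nbar, 0.0), grid,
                                GrowthParams(1e-3, 2e-3))
        assert panel.a_p == pytest.approx(2e-3 * 0.25)  # rho * n(1-n)
        assert panel.nbar_mean == pytest.approx(0.5)

    def test_saturated_density_has_zero_activity(self):
        grid = self._grid()
        panel = biomarker_panel(DensityState(np.ones((10, 10, 10)), 0.0),
                                grid, GrowthParams(1e-3, 2e-3))
        assert panel.a_p == 0.0
        assert panel.nbar_mean == pytest.approx(1.0)

    def test_hand_arithmetic_small_tumor(self):
        # 1 cc tumor at nbar = 0.4 in a 40 cc prostate
        mask = np.zeros((40, 40, 40), bool)
        mask.flat[:40000] = True
        grid = SimulationGrid(mask, 1.0, 1.0)
        nbar = np.zeros((40, 40, 40))
        nbar[mask] = 0.0
        nbar.flat[:1000] = 0.4
        panel = biomarker_panel(DensityState(nbar, 0.0), grid,
                                GrowthParams(1e-3, 2e-3))
        assert panel.v_t == pytest.approx(1.0)
        assert panel.v_n == pytest.approx(0.4)
        assert panel.nbar_mean == pytest.approx(0.4)
        assert panel.n_t == pytest.approx(0.01)

    def test_empty_tumor_region_zeroes_markers(self):
        grid = self._grid()
        panel = biomarker_panel(DensityState(np.zeros((10, 10, 10)), 0.0),
                                grid, GrowthParams(1e-3, 2e-3))
        assert (panel.v_t, panel.v_n, panel.nbar_mean, panel.n_t,
                panel.a_p) == (0, 0, 0, 0, 0)

    def test_activity_maximal_at_half_density(self):
        rho = 3e-3
        vals = [rho * n * (1 - n) for n in np.linspace(0.15, 1.0, 50)]
        assert np.argmax(vals) == np.argmin(np.abs(
            np.linspace(0.15, 1.0, 50) - 0.5))

    def test_gs_risk_rule(self):
        assert GsObservation(0.0, 3, 3).risk == "lower_risk"
        assert GsObservation(0.0, 3, 4).risk == "higher_risk"
        assert GsObservation(0.0, 4, 3).risk == "higher_risk"
        with pytest.raises(ValueError):
            GsObservation(0.0, 2, 3)


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

class TestWilcoxonRankSum:
    def test_fully_separated_one_sided(self):
        # 1/C(6,3) = 0.05: the most extreme of the 20 assignments
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less") == \
            pytest.approx(0.05)

    def test_identical_groups_two_sided(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two_sided") == 1.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
    def test_matches_enumeration_oracle(self, seed, alternative):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5, size=2)
        x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
        y = rng.integers(0, 6, size=n2).astype(float)
        assert wilcoxon_rank_sum(x, y, alternative) == \
            pytest.approx(rank_sum_p_oracle(x, y, alternative))

    def test_exact_agrees_with_scipy_when_tie_free(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        p = wilcoxon_rank_sum(x, y, "two_sided")
        p_sp = sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="exact").pvalue
        assert p == pytest.approx(p_sp)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.0, 1.0, size=30)
        y = rng.normal(0.8, 1.0, size=25)
        p = wilcoxon_rank_sum(x, y, "less")
        p_sp = sps.mannwhitneyu(x, y, alternative="less",
                                method="asymptotic").pvalue
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestWilcoxonSignedRank:
    def test_all_positive_differences(self):
        # one-sided: only 1 of 2^5 sign patterns is as extreme
        x = [2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert wilcoxon_signed_rank(x, y, "greater") == \
            pytest.approx(1 / 32)

    def test_identical_pairs_degenerate(self):
        assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
    def test_matches_enumeration_oracle(self, seed, alternative):
        rng = np.random.default_rng(seed + 100)
        n = int(rng.integers(3, 7))
        x = rng.integers(0, 8, size=n).astype(float)
        y = rng.integers(0, 8, size=n).astype(float)
        if np.all(x == y):
            x[0] += 1
        assert wilcoxon_signed_rank(x, y, alternative) == \
            pytest.approx(signed_rank_p_oracle(x, y, alternative))

    def test_exact_agrees_with_scipy_when_tie_free(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        p = wilcoxon_signed_rank(x, y, "two_sided")
        p_sp = sps.wilcoxon(x, y, alternative="two-sided",
                            mode="exact").pvalue
        assert p == pytest.approx(p_sp)


# ---------------------------------------------------------------------------
# logistic classifier and ROC
# ---------------------------------------------------------------------------

def _panels_from_feature(values, labels):
    return [BiomarkerPanel(v_p=30.0, v_t=1.0, v_n=0.5, nbar_mean=0.5,
                           n_t=0.02, a_p=v, gs_label=lab)
            for v, lab in zip(values, labels)]


class TestLogistic:
    def test_symmetric_data_boundary_at_center(self):
        vals = [1.0, 2.0, 3.0, 5.0, 6.0, 7.0]
        labels = ["lower_risk"] * 3 + ["higher_risk"] * 3
        clf = fit_logistic(_panels_from_feature(vals, labels),
                           features=("a_p",))
        boundary = -clf.coef[0] / clf.coef[1]
        assert boundary == pytest.approx(4.0, abs=1e-3)

    def test_uninformative_feature_gives_zero_slope(self):
        vals = [2.0] * 6
        labels = ["lower_risk", "higher_risk"] * 3
        clf = fit_logistic(_panels_from_feature(vals, labels),
                           features=("a_p",))
        assert abs(clf.coef[1]) < 1e-8

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        p = 1 / (1 + np.exp(-(0.5 + 1.5 * x)))
        y = (rng.random(40) < p).astype(float)
        labels = ["higher_risk" if yi else "lower_risk" for yi in y]
        clf = fit_logistic(_panels_from_feature(x, labels), features=("a_p",))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert not clf.separated
        np.testing.assert_allclose(clf.coef, ref.params, rtol=1e-4)

    def test_separation_flagged_and_capped(self):
        vals = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        labels = ["lower_risk"] * 3 + ["higher_risk"] * 3
        clf = fit_logistic(_panels_from_feature(vals, labels),
                           features=("a_p",))
        assert clf.separated
        assert np.all(np.isfinite(clf.predict_proba(np.array([[5.0]]))))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(_panels_from_feature([1, 2, 3],
                                              ["lower_risk"] * 3),
                         features=("a_p",))
        with pytest.raises(ValueError):
            fit_logistic(_panels_from_feature([1, 2], ["lower_risk",
                                                       "higher_risk"]),
                         features=("a_p", "n_t", "v_t"))


class TestRoc:
    def test_perfect_separation(self):
        fpr, tpr, auc, opt = roc_analysis([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert opt[0] == 1.0 and opt[1] == 1.0
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0

    def test_hand_pairwise_example(self):
        # 3 of 4 (pos, neg) pairs concordant -> AUC = 0.75
        _, _, auc, _ = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)
        assert auc_concordance_oracle([0.1, 0.4, 0.35, 0.8],
                                      np.array([0, 0, 1, 1])) == 0.75

    @pytest.mark.parametrize("seed", range(8))
    def test_trapezoid_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        scores = rng.permutation(n).astype(float)  # tie-free
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        _, _, auc, _ = roc_analysis(scores, labels)
        assert auc == pytest.approx(auc_concordance_oracle(scores, labels))

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 4, size=25).astype(float)
        labels = rng.integers(0, 2, size=25)
        labels[0], labels[1] = 0, 1
        _, _, auc, _ = roc_analysis(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.9], [1, 1])


class TestRiskTrajectory:
    def _setup(self):
        grid = SimulationGrid(np.ones((8, 8, 8), bool), 1.0, 1.0)
        params = GrowthParams(1e-3, 2e-3)
        vals = [1.0, 2.0, 3.0, 5.0, 6.0, 7.0]
        labels = ["lower_risk"] * 3 + ["higher_risk"] * 3
        clf = fit_logistic(_panels_from_feature(np.array(vals) * 1e-4,
                                                labels), features=("a_p",))
        return grid, params, clf

    def test_constant_density_constant_risk(self):
        grid, params, clf = self._setup()
        nbar = np.full((8, 8, 8), 0.4)
        states = [DensityState(nbar, t) for t in (0.0, 100.0, 200.0)]
        _, probs, _ = risk_trajectory(states, grid, params, clf)
        assert np.ptp(probs) == 0.0

    def test_monotone_density_monotone_risk_and_crossing(self):
        grid, params, clf = self._setup()
        states = [DensityState(np.full((8, 8, 8), v), t)
                  for t, v in zip((0.0, 100.0, 200.0, 300.0),
                                  (0.2, 0.3, 0.4, 0.5))]
        times, probs, crossing = risk_trajectory(states, grid, params, clf)
        assert np.all(np.diff(probs) >= 0)
        thr = clf.optimal_point[2]
        brute = next((t for t, p in zip(times, probs) if p >= thr), None)
        assert crossing == brute
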