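"""Metric closed forms, Kendall pair-enumeration oracle, stratified
diagnostics, anti-symmetry reporting and permutation importance."""

import numpy as np
import pytest
from scipy import stats

from mutstab.evaluation import (
    antisymmetry_diagnostics,
    compute_metrics,
    permutation_importance,
    stratified_report,
)


def kendall_tau_b_oracle(x, y):
    """Tie-corrected Kendall tau via explicit enumeration of all pairs."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_s == pytest.approx(1.0)
        assert rep.kendall_k == pytest.approx(1.0)
        assert rep.rmse == rep.mae == rep.mse_signed == 0.0
        assert rep.n == 3

    def test_anti_correlated_two_points(self):
        rep = compute_metrics([1.0, 2.0], [2.0, 1.0])
        assert rep.pearson_r == pytest.approx(-1.0)
        assert rep.mse_signed == 0.0
        assert rep.mae == 1.0
        assert rep.rmse == 1.0

    def test_rmse_dominates_mae_dominates_bias(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=50), rng.normal(size=50)
        rep = compute_metrics(p, t)
        assert rep.rmse >= rep.mae >= abs(rep.mse_signed)

    @pytest.mark.parametrize("seed", range(3))
    def test_kendall_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(0, 8, size=20).astype(float)  # ties included
        t = rng.integers(0, 8, size=20).astype(float)
        rep = compute_metrics(p, t)
        assert rep.kendall_k == pytest.approx(kendall_tau_b_oracle(p, t), abs=1e-12)

    def test_constant_input_reports_nan_correlations_but_errors(self):
        rep = compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rep.pearson_r)
        assert rep.rmse > 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0])


class TestStratifiedReport:
    def test_all_positive_truth_omits_destabilising(self):
        pred = np.arange(6.0)
        true = np.arange(6.0) + 0.5
        out = stratified_report(pred, true, {})
        assert "stabilising" in out
        assert "destabilising" not in out

    def test_exact_antisymmetry_equalises_forward_reverse_rmse(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        pred_f = y + rng.normal(0, 0.3, size=30)
        pred = np.concatenate([pred_f, -pred_f])
        true = np.concatenate([y, -y])
        meta = {"direction": np.array(["forward"] * 30 + ["reverse"] * 30)}
        out = stratified_report(pred, true, meta)
        assert out["forward"].rmse == pytest.approx(out["reverse"].rmse)

    def test_toy_strata_sizes_match_hand_count(self):
        true = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 3.0, -3.0])
        pred = true * 0.9
        meta = {"direction": np.array(["forward"] * 4 + ["reverse"] * 4),
                "multiplicity": np.array([2, 2, 3, 3, 2, 2, 3, 3])}
        out = stratified_report(pred, true, meta)
        assert out["forward"].n == 4
        assert out["stabilising"].n == 4
        assert out["double"].n == 4
        assert out["triple"].n == 4
        assert out["forward_stabilising"].n == 2


class TestAntisymmetryDiagnostics:
    def test_structurally_antisymmetric_model(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=40)
        rep = antisymmetry_diagnostics(f, -f)
        assert rep["pearson_fwd_rev"] == pytest.approx(-1.0)
        assert rep["bias"] == pytest.approx(0.0)

    def test_identical_vectors_fully_correlated(self):
        f = np.arange(10.0)
        assert antisymmetry_diagnostics(f, f)["pearson_fwd_rev"] == pytest.approx(1.0)

    def test_random_pair_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        f, r = rng.normal(size=25), rng.normal(size=25)
        rep = antisymmetry_diagnostics(f, r)
        assert rep["pearson_fwd_rev"] == pytest.approx(stats.pearsonr(f, r)[0])
        assert rep["bias"] == pytest.approx(float(np.mean(f + r)))


class _LinearModel:
    """predict = X @ w; a stand-in regressor for importance tests."""

    def __init__(self, w):
        self.w = np.asarray(w)

    def predict(self, X):
        return X @ self.w


class TestPermutationImportance:
    def test_irrelevant_feature_has_near_zero_importance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 3))
        y = X[:, 0] + rng.normal(0, 0.1, size=2000)
        model = _LinearModel([1.0, 0.0, 0.5])  # feature 1 unused
        out = permutation_importance(model, X, y, 1, n_repeats=10, seed=0)
        assert abs(out["importance"]) <= 0.02

    def test_dominant_feature_importance_approaches_baseline(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 2))
        y = X[:, 0] + rng.normal(0, 0.1, size=2000)
        model = _LinearModel([1.0, 0.0])
        out = permutation_importance(model, X, y, 0, n_repeats=10, seed=0)
        assert out["importance"] == pytest.approx(out["baseline_pearson"], abs=0.05)

    def test_collinear_copy_masks_importance(self):
        """A duplicated feature read by the model through both copies drops
        less under single-column permutation than the lone feature does."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2000, 1))
        noise = rng.normal(0, 0.1, size=2000)
        y = x[:, 0] + noise
        X_dup = np.hstack([x, x])
        dup_model = _LinearModel([0.5, 0.5])
        solo_model = _LinearModel([1.0, 0.0])
        imp_dup = permutation_importance(dup_model, X_dup, y, 0, 10, seed=3)
        imp_solo = permutation_importance(solo_model, X_dup, y, 0, 10, seed=3)
        assert imp_dup["importance"] < imp_solo["importance"]

    def test_unknown_feature_raises(self):
        model = _LinearModel([1.0])
        with pytest.raises(KeyError):
            permutation_importance(model, np.zeros((5, 1)), np.zeros(5), 3)
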