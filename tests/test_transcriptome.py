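"""Noise-model fitting, filtration, ANOVA/Tukey-Kramer and directional BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amlmo import (
    ExpressionMatrix,
    anova_tukey,
    benjamini_hochberg,
    directional_calls,
    filter_features,
    fit_noise_model,
)
from amlmo.transcriptome import PairwiseComparisons

from conftest import build_dataset


def _matrix_from_values(x: np.ndarray, ncol: int = 10) -> ExpressionMatrix:
    x = x[: (len(x) // ncol) * ncol].reshape(-1, ncol)
    return ExpressionMatrix(
        pd.DataFrame(x, index=[f"f{i}" for i in range(x.shape[0])],
                     columns=[f"s{j}" for j in range(ncol)])
    )


class TestNoiseModel:
    def test_single_component_marks_nothing(self):
        rng = np.random.default_rng(2)
        m = _matrix_from_values(rng.normal(8, 1, 5000))
        model = fit_noise_model(m, seed=0)
        assert model.n_components == 1
        assert model.noise_threshold == -np.inf
        _, kept = filter_features(m, model, variance_quantile=0.0)
        assert len(kept) == m.shape[0]  # nothing removed by noise

    def test_two_component_recovery(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(3, 0.5, 5000), rng.normal(9, 1, 5000)])
        model = fit_noise_model(_matrix_from_values(x), seed=1)
        assert model.n_components >= 2
        assert model.component_means[0] == pytest.approx(3, abs=0.1)
        assert model.component_means[-1] == pytest.approx(9, abs=0.1)
        assert 4 < model.noise_threshold < 8

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(3, 0.5, 3000), rng.normal(9, 1, 3000)])
        m = _matrix_from_values(x)
        a, b = fit_noise_model(m, seed=5), fit_noise_model(m, seed=5)
        assert np.array_equal(a.component_means, b.component_means)
        assert a.noise_threshold == b.noise_threshold

    def test_too_few_values_rejected(self):
        m = _matrix_from_values(np.arange(50, dtype=float), ncol=5)
        with pytest.raises(ValueError, match="100"):
            fit_noise_model(m)


class TestFilter:
    def _model(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(3, 0.5, 4000), rng.normal(9, 1, 4000)])
        return fit_noise_model(_matrix_from_values(x), seed=0)

    def test_below_threshold_feature_removed(self):
        model = self._model()
        vals = np.vstack([np.full(6, model.noise_threshold - 2.0),
                          np.random.default_rng(1).normal(9, 1, 6)])
        m = ExpressionMatrix(pd.DataFrame(vals, index=["low", "high"], columns=list("abcdef")))
        _, kept = filter_features(m, model, variance_quantile=0.0)
        assert kept == ["high"]

    def test_constant_feature_removed_by_variance_rule(self):
        model = self._model()
        rng = np.random.default_rng(2)
        vals = np.vstack([np.full(6, 9.0), rng.normal(9, 1, (5, 6))])
        m = ExpressionMatrix(pd.DataFrame(vals, index=[f"f{i}" for i in range(6)], columns=list("abcdef")))
        _, kept = filter_features(m, model, variance_quantile=0.1)
        assert "f0" not in kept

    def test_invalid_quantile(self):
        with pytest.raises(ValueError, match="variance_quantile"):
            filter_features(
                _matrix_from_values(np.random.default_rng(0).normal(9, 1, 100)),
                self._model(), variance_quantile=1.0,
            )

    def test_planted_noise_features_removed(self, small_multiomic):
        matrix, design, _, _, truth = small_multiomic
        model = fit_noise_model(matrix, seed=7)
        _, kept = filter_features(matrix, model, design=design)
        removed = truth.noise_features - set(kept)
        assert len(removed) / len(truth.noise_features) >= 0.95


class TestAnovaTukey:
    def test_pairwise_p_against_statsmodels(self):
        m, d = build_dataset({
            "control": np.array([[1.0, 2, 3]]),
            "MLP3-cl": np.array([[2.0, 3, 4]]),
            "RF12-cl": np.array([[10.0, 11, 12]]),
        })
        pw = anova_tukey(m, d)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        y = np.array([1, 2, 3, 2, 3, 4, 10, 11, 12], dtype=float)
        g = np.repeat(["control", "MLP3-cl", "RF12-cl"], 3)
        res = pairwise_tukeyhsd(y, g)
        ref = {tuple(sorted((a, b))): p for (a, b), p in
               zip([(res.groupsunique[i], res.groupsunique[j])
                    for i in range(3) for j in range(i + 1, 3)], res.pvalues)}
        for (a, b), p in zip(pw.pairs, pw.p_two[0]):
            assert p == pytest.approx(ref[tuple(sorted((a, b)))], rel=1e-4, abs=1e-6)
        lookup = {tuple(sorted(p)): pv for p, pv in zip(pw.pairs, pw.p_two[0])}
        assert lookup[("RF12-cl", "control")] < 0.01
        # the adjacent groups are clearly not separable (oracle p = 0.4827)
        assert lookup[("MLP3-cl", "control")] > 0.4

    def test_two_groups_reduce_to_pooled_t_test(self):
        a, b = [1.0, 2.2, 3.1, 4.0], [2.5, 3.3, 4.8, 5.1]
        m, d = build_dataset({"control": np.array([a]), "MLP3-cl": np.array([b])})
        pw = anova_tukey(m, d)
        _, p_t = stats.ttest_ind(a, b)
        assert pw.p_two[0, 0] == pytest.approx(p_t, rel=1e-6)

    def test_null_calibration_two_groups(self):
        rng = np.random.default_rng(11)
        n = 2000
        m, d = build_dataset({
            "control": rng.normal(8, 1, (n, 5)),
            "MLP3-cl": rng.normal(8, 1, (n, 5)),
        }, feature_ids=[f"f{i}" for i in range(n)])
        pw = anova_tukey(m, d)
        frac = (pw.p_two[:, 0] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 2 * se + 1e-9

    def test_invariance_to_column_order_and_location_shift(self):
        rng = np.random.default_rng(4)
        m, d = build_dataset({
            "control": rng.normal(8, 1, (10, 3)),
            "MLP3-cl": rng.normal(9, 1, (10, 3)),
            "RF12-p": rng.normal(7, 1, (10, 3)),
        }, feature_ids=[f"f{i}" for i in range(10)])
        pw = anova_tukey(m, d)
        perm = list(rng.permutation(m.sample_ids))
        m2 = ExpressionMatrix(m.values[perm] + 5.0)
        pw2 = anova_tukey(m2, d)
        assert np.allclose(pw.p_two, pw2.p_two, equal_nan=True)
        assert np.allclose(pw.mean_diff, pw2.mean_diff)

    def test_zero_variance_feature_flagged_untested(self):
        m, d = build_dataset({
            "control": np.array([[1.0, 1, 1], [1.0, 2, 3]]),
            "MLP3-cl": np.array([[2.0, 2, 2], [4.0, 5, 6]]),
        })
        pw = anova_tukey(m, d)
        assert not pw.tested[0] and pw.tested[1]
        assert np.isnan(pw.p_two[0, 0])

    def test_single_replicate_group_rejected(self):
        m, d = build_dataset({
            "control": np.array([[1.0, 2, 3]]),
            "MLP3-cl": np.array([[2.0]]),
        })
        with pytest.raises(ValueError, match="replicates"):
            anova_tukey(m, d)


def _toy_pairwise(p_two, diffs):
    p = np.array([[p_two]])
    return PairwiseComparisons(
        feature_ids=["f1"], groups=["MLP3-cl", "control"],
        group_sizes={"MLP3-cl": 3, "control": 3},
        pairs=[("MLP3-cl", "control")],
        mean_diff=np.array([[diffs]]), p_two=p, tested=np.array([True]),
    )


class TestDirectionalCalls:
    def test_one_sided_construction(self):
        de = directional_calls(_toy_pairwise(0.04, +1.0), alpha=0.05)
        row = de.table.iloc[0]
        assert row["p_up"] == pytest.approx(0.02)
        assert row["p_down"] == pytest.approx(0.98)

    def test_bh_step_up_hand_example(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_bh_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]))

    def test_up_down_sets_disjoint_and_directional(self, small_multiomic):
        matrix, design, *_ = small_multiomic
        de = directional_calls(anova_tukey(matrix, design), alpha=0.05)
        for s in de.sets().values():
            assert s.up.isdisjoint(s.down)
        up_rows = de.table[de.table["direction"] == "up"]
        assert (up_rows["mean_log2_diff"] > 0).all()
        assert (de.table["q_up"].dropna() >= de.table["p_up"].dropna() - 1e-12).all()

    def test_alpha_bounds(self):
        with pytest.raises(ValueError, match="alpha"):
            directional_calls(_toy_pairwise(0.04, 1.0), alpha=1.5)

    def test_planted_recovery(self, small_multiomic):
        matrix, design, _, _, truth = small_multiomic
        model = fit_noise_model(matrix, seed=7)
        filtered, _ = filter_features(matrix, model, design=design)
        de = directional_calls(anova_tukey(filtered, design), alpha=0.05)
        sets = de.sets()
        kept = set(filtered.feature_ids)
        sens, fdp = [], []
        for m_lbl, s in sets.items():
            planted = (truth.planted_up[m_lbl] | truth.planted_down[m_lbl]) & kept
            called = s.all
            sens.append(len(called & planted) / len(planted))
            fdp.append(len(called - planted) / max(len(called), 1))
        assert min(sens) >= 0.95
        assert max(fdp) <= 0.10
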