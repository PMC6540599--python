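"""Repeatability (RSD), PCA and Fisher LDA."""

import logging
from dataclasses import replace

import numpy as np
import pytest

from enosekit import (
    DegenerateInputError,
    FeatureMatrix,
    SampleRecord,
    SampleSet,
    compute_rsd,
    extract_features,
    generate_dataset,
    lda_fit,
    pca_fit,
)
from enosekit.chemometrics import FisherDiscriminant
from enosekit.synthetic import SyntheticConfig, _separable_amplitudes
from conftest import make_trace


def replicate_set(values_per_replicate, grade=1):
    records = [
        SampleRecord(f"R{i}", grade, (make_trace([0.0] * 30 + [v] * 9),))
        for i, v in enumerate(values_per_replicate)
    ]
    return SampleSet(records)


def toy_matrix(values, grades):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        sample_ids=[f"r{i}" for i in range(values.shape[0])],
        grades=np.asarray(grades, dtype=int),
        columns=[f"S{i + 1}__RSAV" for i in range(values.shape[1])],
        values=values,
    )


class TestRSD:
    def test_hand_computed_example(self):
        # replicate steady-state means 9, 10, 11: sd 1, mean 10 -> 10 %
        table = compute_rsd(replicate_set([9.0, 10.0, 11.0]), grade=1, t0=30.0)
        assert table.rsd["S1"] == pytest.approx(10.0)

    def test_identical_replicates_give_zero(self):
        table = compute_rsd(replicate_set([5.0, 5.0, 5.0]), grade=1, t0=30.0)
        assert table.rsd["S1"] == 0.0

    def test_scale_invariance(self):
        a = compute_rsd(replicate_set([9.0, 10.0, 11.0]), 1, t0=30.0)
        b = compute_rsd(replicate_set([27.0, 30.0, 33.0]), 1, t0=30.0)
        assert a.rsd["S1"] == pytest.approx(b.rsd["S1"])

    def test_too_few_replicates_raise(self):
        with pytest.raises(ValueError, match="replicate"):
            compute_rsd(replicate_set([5.0]), grade=1)

    def test_zero_mean_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_rsd(replicate_set([1.0, -1.0]), grade=1, t0=30.0)

    def test_default_preset_repeatability_below_five_percent(self, paper_like_set):
        """Replicate RSD < 5 % per sensor at the default noise level."""
        for grade in (1, 6):
            table = compute_rsd(paper_like_set, grade)
            assert table.max() < 5.0


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self, rng):
        direction = rng.normal(size=4)
        values = np.outer(rng.normal(size=10), direction)
        result = pca_fit(toy_matrix(values, np.ones(10)), n_components=2)
        assert result.all_ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_ratios_sum_to_one(self, paper_like_features):
        result = pca_fit(paper_like_features, n_components=2)
        assert result.all_ratios.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(result.all_ratios) <= 1e-12)

    def test_matches_covariance_eigendecomposition_oracle(self):
        values = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.0, 0.0], [3.0, 4.0, 1.5], [0.0, 1.0, 2.0]]
        )
        result = pca_fit(toy_matrix(values, np.ones(4)), n_components=3)
        # independent oracle: min-max normalize, center, eigendecompose the
        # sample covariance
        span = values.max(0) - values.min(0)
        normalized = (values - values.min(0)) / span
        centered = normalized - normalized.mean(0)
        cov = centered.T @ centered / (values.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eigvals / eigvals.sum()
        assert np.allclose(result.all_ratios[: expected.size], expected, atol=1e-9)

    def test_requesting_beyond_rank_pads_with_zero(self):
        values = np.outer(np.arange(3.0), np.ones(3))
        result = pca_fit(toy_matrix(values, np.ones(3)), n_components=3)
        assert result.explained_variance_ratio.size == 3
        assert result.explained_variance_ratio[-1] == pytest.approx(0.0, abs=1e-9)

    def test_scores_invariant_to_sample_order(self, rng, paper_like_features):
        fm = paper_like_features
        base = pca_fit(fm, n_components=2)
        perm = rng.permutation(fm.n_samples)
        shuffled = pca_fit(fm.take(perm), n_components=2)
        assert np.allclose(shuffled.scores, base.scores[perm], atol=1e-8)
        assert np.allclose(shuffled.loadings, base.loadings, atol=1e-8)


class TestLDA:
    def test_two_separable_classes_resubstitution_perfect(self):
        values = np.vstack([np.zeros((5, 2)), np.ones((5, 2))])
        values += np.random.default_rng(0).normal(0, 0.01, values.shape)
        result = lda_fit(toy_matrix(values, [1] * 5 + [2] * 5))
        assert result.accuracy == 1.0
        assert result.n_functions == 1

    def test_six_classes_give_five_discriminant_functions(self, paper_like_features):
        result = lda_fit(paper_like_features)
        assert result.n_functions == 5
        assert result.confusion_matrix.sum() == 180
        counts = result.confusion_matrix.sum(axis=1)
        assert np.all(counts == 30)  # row sums = class counts

    def test_permuted_labels_score_at_chance(self, rng):
        """LOO accuracy under the permutation null stays within 3 se of 1/6."""
        cfg = SyntheticConfig(
            amplitude_matrix=_separable_amplitudes(2, 6),
            n_sensors=2, replicates_per_grade=5, seed=3,
        )
        fm = extract_features(generate_dataset(cfg), codes=["RSAV"])
        accs = []
        for _ in range(80):
            permuted = replace(fm, grades=rng.permutation(fm.grades))
            accs.append(lda_fit(permuted, protocol="loo_cv").accuracy)
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(accs.size)
        assert abs(accs.mean() - 1.0 / 6.0) <= 3 * se

    def test_separable_rsav_accuracy_high(self, separable_features):
        block = separable_features.select_feature("RSAV")
        assert lda_fit(block).accuracy >= 0.95

    def test_loo_not_better_than_resubstitution_on_average(self):
        resub, loo = [], []
        for seed in range(20):
            cfg = SyntheticConfig(replicates_per_grade=6, seed=seed)
            fm = extract_features(generate_dataset(cfg), codes=["MGV"])
            resub.append(lda_fit(fm, "resubstitution").accuracy)
            loo.append(lda_fit(fm, "loo_cv").accuracy)
        assert np.mean(loo) <= np.mean(resub)

    def test_unknown_protocol_raises(self, separable_features):
        with pytest.raises(ValueError, match="protocol"):
            lda_fit(separable_features, protocol="bootstrap")

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="two classes"):
            FisherDiscriminant().fit(np.random.default_rng(0).normal(size=(6, 2)),
                                     np.ones(6))

    def test_singular_within_scatter_gets_ridge_warning(self, caplog):
        rng = np.random.default_rng(0)
        col = rng.normal(size=(20, 1))
        values = np.hstack([col, col, col])  # rank-deficient within-class scatter
        labels = np.repeat([1, 2], 10)
        with caplog.at_level(logging.WARNING, logger="enosekit.chemometrics"):
            clf = FisherDiscriminant().fit(values, labels)
        assert clf.functions_.shape == (1, 3)
        assert any("singular" in rec.message for rec in caplog.records)
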