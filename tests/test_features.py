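"""The six characteristic parameters and the assembled feature matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enosekit import (
    FEATURE_CODES,
    CurveFeaturizer,
    FeatureConfig,
    average_differential,
    extract_features,
    integral_value,
    max_gradient,
    steady_state_mean,
    variance_value,
    wavelet_energy,
)
from enosekit.features import level4_approximation
from conftest import make_trace

# Orthonormal Daubechies-3 decomposition low-pass filter, frozen for the
# independent cascade oracle below.
DB3_DEC_LO = np.array(
    [
        0.03522629188570953,
        -0.08544127388202666,
        -0.13501102001025458,
        0.45987750211849154,
        0.8068915093110925,
        0.33267055295008263,
    ]
)


def cascade_approximation(x, levels=4):
    """Brute-force multilevel DWT approximation: half-point symmetric
    extension, full convolution with the low-pass filter, dyadic decimation."""
    a = np.asarray(x, dtype=float)
    L = DB3_DEC_LO.size
    for _ in range(levels):
        pad = L - 1
        ext = np.concatenate([a[:pad][::-1], a, a[-pad:][::-1]])
        full = np.convolve(ext, DB3_DEC_LO)
        a = full[L::2][: (a.size + L - 1) // 2]
    return a


class TestScalarFeatures:
    def test_integral_is_sum_times_dt(self):
        assert integral_value(make_trace([1.0, 2.0, 3.0])) == pytest.approx(6.0)
        assert integral_value(make_trace([0.0, 0.0, 0.0])) == 0.0

    def test_integral_is_linear(self, rng):
        x = rng.normal(size=10)
        assert integral_value(make_trace(2 * x)) == pytest.approx(
            2 * integral_value(make_trace(x))
        )

    def test_max_gradient_chord_slope(self):
        assert max_gradient(make_trace([1.0, 2.0, 5.0, 4.0])) == pytest.approx(2.0)
        assert max_gradient(make_trace([0.0, 1.0, 2.0, 3.0])) == pytest.approx(1.0)

    def test_max_gradient_non_increasing_convention(self):
        assert max_gradient(make_trace([5.0, 4.0, 3.0])) == 0.0

    def test_average_differential(self):
        assert average_differential(make_trace([0.0, 1.0, 3.0])) == pytest.approx(1.5)
        assert average_differential(make_trace([2.0, 2.0, 2.0])) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-100.0, 100.0), min_size=2, max_size=40),
        st.floats(0.1, 10.0),
    )
    def test_average_differential_telescopes(self, values, dt):
        """ADV equals (last - first) / ((T-1) * dt) for any trace."""
        tr = make_trace(values, dt=dt)
        expected = (values[-1] - values[0]) / ((len(values) - 1) * dt)
        assert average_differential(tr) == pytest.approx(expected, abs=1e-10)

    def test_steady_state_mean_window(self):
        tr = make_trace([1.0, 2.0, 5.0, 4.0])
        assert steady_state_mean(tr, t0=2.0) == pytest.approx(4.5)
        assert steady_state_mean(tr, t0=0.0) == pytest.approx(3.0)

    def test_steady_state_mean_constant(self):
        assert steady_state_mean(make_trace([7.0] * 5), t0=3.0) == 7.0

    def test_steady_state_mean_bad_window_raises(self):
        with pytest.raises(ValueError, match="t0"):
            steady_state_mean(make_trace([1.0, 2.0]), t0=1.0)

    def test_variance_is_population_variance(self):
        assert variance_value(make_trace([1.0, 2.0, 3.0])) == pytest.approx(2.0 / 3.0)
        assert variance_value(make_trace([4.0] * 5)) == 0.0

    def test_variance_shift_invariant_scale_quadratic(self, rng):
        x = rng.normal(size=15)
        base = variance_value(make_trace(x))
        assert variance_value(make_trace(x + 3.7)) == pytest.approx(base)
        assert variance_value(make_trace(3.0 * x)) == pytest.approx(9.0 * base)


class TestWaveletEnergy:
    def test_zero_trace_has_zero_energy(self):
        assert wavelet_energy(make_trace(np.zeros(39))) == 0.0

    def test_39_point_trace_gives_seven_coefficients(self):
        approx = level4_approximation(make_trace(np.zeros(39)))
        assert approx.size == 7

    def test_constant_trace_energy_closed_form(self):
        # each level scales a constant by sqrt(2): 7 coefficients of 2**2 = 4
        assert wavelet_energy(make_trace(np.ones(39))) == pytest.approx(112.0)

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError, match="at least"):
            wavelet_energy(make_trace([1.0, 2.0, 3.0]))

    def test_matches_cascade_oracle_on_random_traces(self, rng):
        for _ in range(200):
            n = int(rng.integers(39, 81))
            x = rng.normal(size=n)
            expected = float(np.sum(cascade_approximation(x) ** 2))
            got = wavelet_energy(make_trace(x))
            assert got == pytest.approx(expected, rel=1e-9)


class TestExtractFeatures:
    def test_sixty_column_matrix(self, paper_like_features):
        assert len(paper_like_features.columns) == 60
        assert paper_like_features.values.shape == (180, 60)

    def test_column_order_sensor_major_canonical(self, paper_like_features):
        assert paper_like_features.columns[:6] == [f"S1__{c}" for c in FEATURE_CODES]
        assert paper_like_features.columns[-6:] == [f"S10__{c}" for c in FEATURE_CODES]

    def test_single_code_gives_one_column_per_sensor(self, paper_like_set):
        fm = extract_features(paper_like_set, codes=["RSAV"])
        assert fm.columns == [f"S{i + 1}__RSAV" for i in range(10)]

    def test_code_order_is_canonical_regardless_of_request(self, paper_like_set):
        fm = extract_features(paper_like_set, codes=["VARV", "INV"])
        assert fm.columns[:2] == ["S1__INV", "S1__VARV"]

    def test_unknown_code_raises(self, paper_like_set):
        with pytest.raises(ValueError, match="unknown feature"):
            extract_features(paper_like_set, codes=["INV", "XXX"])

    def test_all_features_finite_on_generator_output(self, paper_like_features):
        assert np.all(np.isfinite(paper_like_features.values))

    def test_select_feature_block(self, paper_like_features):
        block = paper_like_features.select_feature("MGV")
        assert block.columns == [f"S{i + 1}__MGV" for i in range(10)]
        assert np.array_equal(block.grades, paper_like_features.grades)

    def test_featurizer_transformer_roundtrip(self, paper_like_set, paper_like_features):
        fm = CurveFeaturizer().fit_transform(paper_like_set)
        assert np.allclose(fm.values, paper_like_features.values)
        assert CurveFeaturizer(codes=["INV"]).get_params()["codes"] == ["INV"]

    def test_smoothing_changes_noisy_features(self, paper_like_set):
        raw = extract_features(paper_like_set, codes=["VARV"],
                               cfg=FeatureConfig(smooth=False))
        smoothed = extract_features(paper_like_set, codes=["VARV"])
        assert not np.allclose(raw.values, smoothed.values)
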