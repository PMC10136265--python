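"""MSE scoring, Silverman bandwidth, KDE, interval inversion and decisions."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from aptanomaly.autoencoders import TrainingConfig, train_autoencoder
from aptanomaly.errors import DegenerateSampleError, ValidationError
from aptanomaly.signal_model import Quality, Segment, SegmentDataset
from aptanomaly.thresholding import (
    DetectorModel,
    ErrorDensityModel,
    ErrorSample,
    decide,
    fit_detector,
    kde_cdf,
    kde_density,
    kde_interval,
    load_detector,
    mse,
    save_detector,
    silverman_bandwidth,
    silverman_bandwidth_formula,
)


class TestMSE:
    @pytest.mark.parametrize("x, x_hat, expected", [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
        ([0.0, 0.0], [1.0, 1.0], 1.0),
        ([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], 5.0 / 3.0),
    ])
    def test_values(self, x, x_hat, expected):
        assert mse(x, x_hat) == pytest.approx(expected, abs=1e-15)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            mse([1.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            mse([], [])


class TestBandwidth:
    def test_unit_sd_power_of_two(self):
        # m = 32 means m^(1/5) = 2 exactly, so H = 1.06 / 2
        assert silverman_bandwidth_formula(1.0, 32) == pytest.approx(0.53,
                                                                     abs=1e-15)

    def test_one_two_three(self):
        H = silverman_bandwidth(ErrorSample([1.0, 2.0, 3.0]))
        assert H == pytest.approx(1.06 * 3 ** (-0.2), abs=1e-12)

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateSampleError):
            silverman_bandwidth(ErrorSample([2.0, 2.0, 2.0]))

    def test_sample_too_small(self):
        with pytest.raises(ValidationError):
            ErrorSample([1.0])

    def test_negative_errors_rejected(self):
        with pytest.raises(ValidationError):
            ErrorSample([0.5, -0.1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 2**16))
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        errs = rng.gamma(2.0, 1.0, size=20)
        H1 = silverman_bandwidth(ErrorSample(errs))
        H2 = silverman_bandwidth(ErrorSample(errs * scale))
        assert H2 == pytest.approx(H1 * scale, rel=1e-9)


class TestDensity:
    def test_single_point_gaussian_peak(self):
        assert kde_density(np.array([0.0]), 0.0, bandwidth=1.0) == \
            pytest.approx(1.0 / np.sqrt(2 * np.pi), abs=1e-12)

    def test_symmetry(self):
        pts = np.array([-1.3, 1.3])
        for r in (0.2, 0.9, 2.5):
            assert kde_density(pts, r, bandwidth=0.7) == \
                pytest.approx(kde_density(pts, -r, bandwidth=0.7), abs=1e-14)

    def test_unit_integral_by_quadrature(self, rng):
        pts = rng.gamma(2.0, 0.5, size=15)
        H = silverman_bandwidth(ErrorSample(pts))
        total, _ = quad(lambda r: kde_density(pts, r, bandwidth=H),
                        pts.min() - 12 * H, pts.max() + 12 * H, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonnegative(self, rng):
        pts = rng.gamma(2.0, 0.5, size=10)
        grid = np.linspace(-5, 10, 200)
        assert np.all(kde_density(pts, grid, bandwidth=0.3) >= 0)


class TestInterval:
    def test_symmetric_sample_gives_symmetric_interval(self):
        pts = np.array([-2.0, -1.0, 1.0, 2.0])
        tau_l, tau_u = kde_interval(pts, level=0.9)
        assert tau_l == pytest.approx(-tau_u, abs=1e-9)

    def test_endpoints_invert_the_cdf(self, rng):
        pts = rng.gamma(2.0, 0.5, size=40)
        H = silverman_bandwidth(ErrorSample(pts))
        tau_l, tau_u = kde_interval(pts, level=0.9, bandwidth=H)
        assert kde_cdf(pts, H, tau_l) == pytest.approx(0.05, abs=1e-10)
        assert kde_cdf(pts, H, tau_u) == pytest.approx(0.95, abs=1e-10)

    def test_interval_widens_with_level(self, rng):
        pts = rng.gamma(2.0, 0.5, size=30)
        _, u90 = kde_interval(pts, level=0.90)
        _, u95 = kde_interval(pts, level=0.95)
        assert u95 > u90

    def test_large_sample_converges_to_population_quantile(self):
        rng = np.random.default_rng(77)
        pts = rng.standard_normal(10_000)
        tau_l, tau_u = kde_interval(pts, level=0.90)
        # fresh-draw empirical quantile as the independent oracle
        fresh = np.quantile(np.random.default_rng(78).standard_normal(200_000),
                            0.95)
        assert tau_u == pytest.approx(fresh, abs=0.05)
        assert tau_l == pytest.approx(-fresh, abs=0.05)

    def test_one_sided_option(self, rng):
        pts = rng.gamma(2.0, 0.5, size=30)
        H = silverman_bandwidth(ErrorSample(pts))
        tau_l, tau_u = kde_interval(pts, level=0.90, two_sided=False)
        assert tau_l == float("-inf")
        assert kde_cdf(pts, H, tau_u) == pytest.approx(0.90, abs=1e-10)

    def test_bad_level(self, rng):
        with pytest.raises(ValidationError):
            kde_interval(rng.gamma(2.0, 0.5, size=5), level=1.0)


class TestDecide:
    def test_boundary_is_normal(self):
        assert decide(0.5, 0.5) == 1
        assert decide(0.5 + 1e-12, 0.5) == 0
        assert decide(0.0, 0.5) == 1

    def test_below_lower_bound_is_still_normal(self):
        # the lower endpoint plays no role: a tiny error is a good fit
        assert decide(1e-9, 0.5) == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(tau=st.floats(0.01, 10.0), seed=st.integers(0, 2**16))
    def test_monotone_in_error(self, tau, seed):
        rs = np.sort(np.random.default_rng(seed).uniform(0, 20, size=25))
        zs = [decide(float(r), tau) for r in rs]
        assert np.all(np.diff(zs) <= 0)  # never flips anomaly -> normal


def small_trained_detector(rng, level=0.90):
    segs = [Segment(f"s{i}", "c",
                    np.sin(np.linspace(0, 3, 24) + rng.uniform(0, 2)) +
                    0.05 * rng.standard_normal(24), Quality.NORMAL)
            for i in range(30)]
    ds = SegmentDataset(segs, segment_length=24, role="train")
    net = train_autoencoder("vanilla", ds, TrainingConfig(max_epochs=30, seed=4))
    return fit_detector(net, ds, level=level), ds


class TestDetector:
    def test_train_errors_mostly_below_threshold(self, rng):
        det, ds = small_trained_detector(rng)
        errs = det.errors(ds)
        frac = np.mean(errs <= det.tau_u)
        # tau_u is the 0.95 quantile of the KDE; the KDE smooths, so allow MC slack
        assert frac == pytest.approx(0.95, abs=0.10)

    def test_degenerate_errors_propagate(self):
        segs = [Segment(f"s{i}", "c", np.zeros(8), Quality.NORMAL)
                for i in range(5)]
        ds = SegmentDataset(segs, segment_length=8, role="train")
        net = train_autoencoder("vanilla", ds,
                                TrainingConfig(max_epochs=300, seed=0,
                                               learning_rate=1e-2))

        class Perfect:
            kind = "vanilla"
            input_length = 8

            def forward_batch(self, X):
                return X.copy()

        with pytest.raises(DegenerateSampleError):
            fit_detector(Perfect(), ds)

    def test_round_trip_bit_exact(self, rng, tmp_path):
        det, ds = small_trained_detector(rng)
        save_detector(det, tmp_path / "det.h5")
        back = load_detector(tmp_path / "det.h5")
        assert back.density.tau_u == det.density.tau_u
        assert back.density.tau_l == det.density.tau_l
        assert back.density.bandwidth == det.density.bandwidth
        assert back.density.level == det.density.level
        np.testing.assert_array_equal(back.density.sample.errors,
                                      det.density.sample.errors)
        np.testing.assert_array_equal(back.predict(ds), det.predict(ds))

    def test_predict_matches_decide(self, rng):
        det, ds = small_trained_detector(rng)
        errs = det.errors(ds)
        np.testing.assert_array_equal(
            det.predict(ds), [decide(float(e), det.tau_u) for e in errs])
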