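import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import osteonlo as o
from osteonlo.errors import ParameterError
from osteonlo.fibre_model import (
    REFERENCE_ORIENTATION_FITS,
    gaussian_area,
    round_half_up,
)
from osteonlo.orientation import OrientationHistogram

BIN_CENTERS = np.arange(180) + 0.5


def hist_from_params(A, theta0, sigma, B):
    y = o.eval_model(A, theta0, sigma, B, BIN_CENTERS)
    return OrientationHistogram(BIN_CENTERS, y, n_analyzable=10000)


def grid_search_oracle(theta, y):
    """Coarse brute-force fit: 2-deg grid over (theta0, sigma), linear
    least squares for (A, B) clipped to be nonnegative.  Returns best SS."""
    best = np.inf
    for t0 in np.arange(0.0, 180.1, 2.0):
        for s in np.arange(1.0, 89.1, 2.0):
            g = np.exp(-(((theta - t0) / (2 * s)) ** 2))
            X = np.column_stack([g, np.ones_like(theta)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            coef = np.clip(coef, 0.0, None)
            ss = float(np.sum((y - X @ coef) ** 2))
            best = min(best, ss)
    return best


class TestEvalModel:
    def test_peak_value(self):
        assert o.eval_model(2.0, 90.0, 10.0, 0.5, 90.0) == pytest.approx(2.5)

    def test_zero_amplitude_is_baseline(self):
        th = np.linspace(0, 180, 50)
        np.testing.assert_allclose(o.eval_model(0.0, 90, 10, 0.7, th), 0.7)

    def test_printed_exponent_form(self):
        # exponent ((theta-theta0)/(2 sigma))^2 = 1 at offset 2 sigma
        assert o.eval_model(1.0, 90.0, 10.0, 0.0, 110.0) == pytest.approx(
            np.exp(-1.0))

    def test_invalid_sigma(self):
        with pytest.raises(ParameterError):
            o.eval_model(1.0, 90.0, 0.0, 0.0, 90.0)


class TestFitRecovery:
    @pytest.mark.parametrize("polarization", sorted(REFERENCE_ORIENTATION_FITS))
    @pytest.mark.parametrize("genotype,roi",
                             [("WT", "cortical"), ("WT", "trabecular"),
                              ("KO", "cortical"), ("KO", "trabecular")])
    def test_reference_rows_refit_exactly(self, polarization, genotype, roi):
        """Noiseless histograms built from published parameter rows refit to
        the generating values (<1%) with near-perfect R^2."""
        p = REFERENCE_ORIENTATION_FITS[polarization][(genotype, roi)]
        fit = o.fit_orientation_model(hist_from_params(
            p["A"], p["theta0"], p["sigma"], p["B"]))
        assert fit.A == pytest.approx(p["A"], rel=0.01)
        assert fit.theta0 == pytest.approx(p["theta0"], rel=0.01)
        assert fit.sigma == pytest.approx(p["sigma"], rel=0.01)
        assert fit.B == pytest.approx(p["B"], rel=0.01)
        assert fit.r_squared >= 0.99

    def test_flat_histogram_fits_pure_baseline(self):
        flat = OrientationHistogram(BIN_CENTERS,
                                    np.full(180, 100.0 / 180), 10000)
        fit = o.fit_orientation_model(flat)
        assert fit.A == pytest.approx(0.0, abs=1e-6)
        assert fit.B == pytest.approx(100.0 / 180, abs=1e-6)

    @given(A=st.floats(0.1, 2.0), theta0=st.floats(20.0, 160.0),
           sigma=st.floats(5.0, 45.0), B=st.floats(0.05, 1.0))
    @settings(max_examples=30)
    def test_noiseless_recovery_sweep(self, A, theta0, sigma, B):
        fit = o.fit_orientation_model(hist_from_params(A, theta0, sigma, B))
        assert fit.A == pytest.approx(A, rel=0.01)
        assert fit.theta0 == pytest.approx(theta0, rel=0.01)
        assert fit.sigma == pytest.approx(sigma, rel=0.01)
        assert fit.B == pytest.approx(B, rel=0.01)

    def test_sampled_mixture_centre_recovered(self, rng):
        """Histogram of 10^4 mixture draws refits theta0 within 3 deg."""
        n = 10_000
        al = rng.random(n) < 0.5
        th = np.where(al,
                      np.mod(90 + np.sqrt(2) * 20 * rng.standard_normal(n), 180),
                      rng.uniform(0, 180, n))
        counts, _ = np.histogram(th, bins=np.arange(181))
        hist = OrientationHistogram(BIN_CENTERS, 100 * counts / n, n)
        fit = o.fit_orientation_model(hist)
        assert abs(fit.theta0 - 90.0) <= 3.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_never_worse_than_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = o.eval_model(1.0, 70.0, 20.0, 0.4, BIN_CENTERS)
        y = np.clip(y + rng.normal(0, 0.1, y.shape), 0, None)
        hist = OrientationHistogram(BIN_CENTERS, y, 10000)
        fit = o.fit_orientation_model(hist)
        ss_fit = float(np.sum(
            (y - o.eval_model(fit.A, fit.theta0, fit.sigma, fit.B,
                              BIN_CENTERS)) ** 2))
        assert ss_fit <= grid_search_oracle(BIN_CENTERS, y) + 1e-9

    def test_scene_parameter_recovery_over_seeds(self):
        """Full-pipeline recovery on 20 stochastic synthetic vertebrae:
        median theta0 error <= 3 deg, median sigma relative error <= 20%."""
        th_err, sg_err = [], []
        for seed in range(20):
            spec = o.SceneSpec(seed=seed, aligned_fraction=0.5,
                               theta0_true=90.0, sigma_true=25.0)
            labels = o.make_region_labels(spec)
            img, _ = o.render_shg_channel(spec, labels)
            angles, valid = o.fibre_angle_map(o.sobel_gradients(img))
            hist = o.orientation_histogram(angles, valid, labels,
                                           o.BONE_CLASSES)
            fit = o.fit_orientation_model(hist)
            th_err.append(abs(fit.theta0 - 90.0))
            sg_err.append(abs(fit.sigma - 25.0) / 25.0)
        assert np.median(th_err) <= 3.0
        assert np.median(sg_err) <= 0.20


class TestAlignmentRatio:
    def test_zero_amplitude_gives_zero(self):
        fit = o.FibreFit(A=0.0, theta0=90, sigma=20, B=0.5,
                         r_squared=1.0, alignment_ratio=0.0)
        assert o.alignment_ratio(fit) == pytest.approx(0.0)

    def test_zero_baseline_gives_hundred(self):
        fit = o.FibreFit(A=1.0, theta0=90, sigma=20, B=0.0,
                         r_squared=1.0, alignment_ratio=100.0)
        assert o.alignment_ratio(fit) == pytest.approx(100.0)

    def test_balanced_areas_give_fifty(self):
        # baseline area == Gaussian area when B = 2 sigma sqrt(pi) / 180
        B = 2 * 20 * np.sqrt(np.pi) / 180
        fit = o.FibreFit(A=1.0, theta0=90.0, sigma=20.0, B=B,
                         r_squared=1.0, alignment_ratio=50.0)
        assert o.alignment_ratio(fit) == pytest.approx(49.963405, abs=1e-3)

    @given(A=st.floats(0.05, 3.0), theta0=st.floats(10.0, 170.0),
           sigma=st.floats(2.0, 45.0))
    @settings(max_examples=30)
    def test_gaussian_area_matches_trapezoid_oracle(self, A, theta0, sigma):
        th = np.linspace(0.0, 180.0, 20001)
        oracle = np.trapezoid(o.eval_model(A, theta0, sigma, 0.0, th), th)
        assert gaussian_area(A, theta0, sigma) == pytest.approx(oracle,
                                                                rel=1e-6)

    @given(a1=st.floats(0.05, 1.0), da=st.floats(0.05, 2.0),
           b1=st.floats(0.05, 1.0), db=st.floats(0.05, 2.0))
    def test_monotone_in_amplitude_and_baseline(self, a1, da, b1, db):
        def ar(A, B):
            return o.alignment_ratio(
                o.FibreFit(A=A, theta0=90, sigma=20, B=B,
                           r_squared=1.0, alignment_ratio=0.0))
        assert ar(a1 + da, b1) > ar(a1, b1)
        assert ar(a1, b1 + db) < ar(a1, b1)


class TestSummaries:
    def test_round_half_up_at_printed_precision(self):
        assert round_half_up(0.385, 2) == 0.39
        assert round_half_up(27.575, 2) == 27.58
        assert round_half_up(0.384, 2) == 0.38

    def _fits(self, polarization):
        out = []
        for (gen, roi), p in REFERENCE_ORIENTATION_FITS[polarization].items():
            fit = o.FibreFit(A=p["A"], theta0=p["theta0"], sigma=p["sigma"],
                             B=p["B"], r_squared=0.99, alignment_ratio=0.0,
                             genotype=gen, roi_class=roi,
                             polarization=polarization)
            fit.alignment_ratio = o.alignment_ratio(fit)
            out.append(fit)
        return out

    def test_parallel_condition_averages(self):
        """Cross-condition means of the parallel-polarization reference rows:
        baseline 0.39 and width 27.58 deg."""
        table = o.summarize_fits(self._fits("parallel"))
        means = table.means["parallel"]
        assert means["B"] == 0.39
        assert means["sigma"] == 27.58

    def test_single_fit_summary_is_identity(self):
        fit = self._fits("parallel")[0]
        table = o.summarize_fits([fit])
        row = table.frame.iloc[0]
        assert row["A"] == pytest.approx(fit.A)
        assert row["sigma"] == pytest.approx(fit.sigma)
        assert table.means["parallel"]["A"] == round_half_up(fit.A, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            o.summarize_fits([])
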