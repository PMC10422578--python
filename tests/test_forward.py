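"""Forward model: exact values, grid shape, canonical ordering, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotau import (
    ExponentialSpectrum,
    ScalingTransform,
    TimeGrid,
    evaluate_curve,
    make_time_grid,
    normalize_spectrum,
    rescale_spectrum,
    sort_components,
)
from thermotau.forward import evaluate_curves

# Reference recovery parameters of a healthy-skin recording (seconds, degC).
HEALTHY_TAU = np.array([1.9486818, 18.936752, 113.21907, 230.25365])
HEALTHY_AMP = np.array([1.354312, 1.1490566, 0.9453574, 0.8074841])


def spectra(n=4, normalized=True):
    """Hypothesis strategy for valid spectra."""
    pos = st.floats(0.01, 1.0, allow_nan=False)
    amp = st.floats(0.0, 1.0, allow_nan=False)
    return st.builds(
        lambda tau, a: ExponentialSpectrum(tau=np.array(tau), amp=np.array(a), normalized=normalized),
        st.lists(pos, min_size=n, max_size=n),
        st.lists(amp, min_size=n, max_size=n),
    )


class TestEvaluateCurve:
    def test_identical_components_analytic(self):
        s = ExponentialSpectrum(tau=[1, 1, 1, 1], amp=[0.25] * 4, normalized=True)
        curve = evaluate_curve(s, TimeGrid(np.array([0.5, 1.0])))
        assert curve.values[1] == pytest.approx(1 - np.exp(-1), rel=1e-12)

    def test_vanishes_at_early_time(self):
        s = ExponentialSpectrum(tau=[0.1, 0.2, 0.5, 0.9], amp=[0.3, 0.2, 0.6, 0.1])
        tiny = evaluate_curve(s, TimeGrid(np.array([1e-12, 1.0]))).values[0]
        assert tiny == pytest.approx(0.0, abs=1e-9)

    def test_healthy_skin_asymptote(self):
        """At t = 3600 s the rise equals the sum of amplitudes (~4.2562 degC)."""
        s = ExponentialSpectrum(tau=HEALTHY_TAU, amp=HEALTHY_AMP)
        curve = evaluate_curve(s, TimeGrid(np.array([1.0, 3600.0])))
        assert curve.values[1] == pytest.approx(4.2562101, rel=1e-6)
        assert s.asymptote == pytest.approx(4.2562101, rel=1e-8)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError, match="strictly positive"):
            ExponentialSpectrum(tau=[0.0, 0.1, 0.2, 0.3], amp=[1, 1, 1, 1])
        with pytest.raises(ValueError, match="strictly positive"):
            ExponentialSpectrum(tau=[-0.5, 0.1, 0.2, 0.3], amp=[1, 1, 1, 1])

    def test_batch_matches_single(self, grid):
        s = ExponentialSpectrum(tau=[0.05, 0.1, 0.4, 0.8], amp=[0.2, 0.4, 0.1, 0.9])
        batch = evaluate_curves(s.to_vector()[None, :], grid)
        single = evaluate_curve(s, grid)
        np.testing.assert_allclose(batch[0], single.values, rtol=1e-13)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(spectra())
    def test_asymptote_conservation(self, s):
        """Curve value at t >> max(tau) equals the amplitude sum."""
        t = 100.0 * s.tau.max()
        v = evaluate_curve(s, TimeGrid(np.array([t / 2, t]))).values[1]
        assert v == pytest.approx(s.asymptote, rel=1e-6, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(spectra())
    def test_monotone_nondecreasing(self, s):
        curve = evaluate_curve(s, make_time_grid(256))
        assert np.all(np.diff(curve.values) >= -1e-15)
        assert curve.values.max() <= s.asymptote + 1e-12


class TestTimeGrid:
    def test_basic_contract(self):
        g = make_time_grid(1024, 1.0)
        assert g.n == 1024
        assert g.t_end == 1.0
        assert g.samples[0] > 0
        assert np.all(np.diff(g.samples) > 0)

    def test_dense_at_early_times(self):
        g = make_time_grid(1024, 1.0)
        assert np.sum(g.samples <= 0.1) >= 512

    def test_spacing_grows(self):
        g = make_time_grid(1024, 1.0)
        assert np.all(np.diff(np.diff(g.samples)) > -1e-15)

    def test_degenerate_two_samples(self):
        g = make_time_grid(2, 5.0)
        assert g.n == 2
        assert g.samples[-1] == 5.0

    @pytest.mark.parametrize("n,t_end", [(1, 1.0), (0, 1.0), (10, 0.0), (10, -1.0)])
    def test_invalid_arguments(self, n, t_end):
        with pytest.raises(ValueError):
            make_time_grid(n, t_end)

    def test_rejects_nonincreasing_samples(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.1, 0.1, 0.3]))
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 0.1, 0.3]))


class TestSortComponents:
    def test_permutation_bookkeeping(self):
        s = ExponentialSpectrum(tau=[0.5, 0.1, 0.9, 0.3], amp=[10, 20, 30, 40])
        np.testing.assert_array_equal(s.tau, [0.1, 0.3, 0.5, 0.9])
        np.testing.assert_array_equal(s.amp, [20, 40, 10, 30])

    def test_idempotent(self):
        s = ExponentialSpectrum(tau=[0.1, 0.3, 0.5, 0.9], amp=[1, 2, 3, 4])
        s2 = sort_components(s)
        np.testing.assert_array_equal(s.tau, s2.tau)
        np.testing.assert_array_equal(s.amp, s2.amp)

    def test_curve_invariant_under_reordering(self, grid):
        a = ExponentialSpectrum(tau=[0.5, 0.1, 0.9, 0.3], amp=[0.4, 0.3, 0.2, 0.1])
        b = ExponentialSpectrum(tau=[0.9, 0.5, 0.3, 0.1], amp=[0.2, 0.4, 0.1, 0.3])
        np.testing.assert_allclose(
            evaluate_curve(a, grid).values, evaluate_curve(b, grid).values, rtol=1e-12
        )


class TestScaling:
    def test_normalize_divides(self):
        s = ExponentialSpectrum(tau=[180.0], amp=[2.0])
        n = normalize_spectrum(s, ScalingTransform(t_scale=360.0, temp_scale=4.0))
        assert n.tau[0] == pytest.approx(0.5)
        assert n.amp[0] == pytest.approx(0.5)
        assert n.normalized

    def test_healthy_skin_tau4_normalizes(self):
        s = ExponentialSpectrum(tau=HEALTHY_TAU, amp=HEALTHY_AMP)
        n = normalize_spectrum(s, ScalingTransform(t_scale=360.0, temp_scale=HEALTHY_AMP.sum()))
        assert n.tau[-1] == pytest.approx(230.25365 / 360.0, rel=1e-9)

    def test_round_trip(self):
        s = ExponentialSpectrum(tau=[1.5, 20.0, 110.0, 230.0], amp=[1.3, 1.1, 0.9, 0.8])
        tr = ScalingTransform(t_scale=360.0, temp_scale=5.0)
        back = rescale_spectrum(normalize_spectrum(s, tr), tr)
        np.testing.assert_allclose(back.tau, s.tau, rtol=1e-12)
        np.testing.assert_allclose(back.amp, s.amp, rtol=1e-12)
        assert not back.normalized

    def test_identity_transform(self):
        s = ExponentialSpectrum(tau=[0.1, 0.2, 0.3, 0.4], amp=[0.1, 0.2, 0.3, 0.4], normalized=True)
        r = rescale_spectrum(s, ScalingTransform.identity())
        np.testing.assert_array_equal(r.tau, s.tau)

    def test_out_of_range_warns_not_raises(self):
        s = ExponentialSpectrum(tau=[500.0], amp=[1.0])
        with pytest.warns(UserWarning, match="outside"):
            normalize_spectrum(s, ScalingTransform(t_scale=360.0, temp_scale=2.0))

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError):
            ScalingTransform(t_scale=0.0, temp_scale=1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(spectra(), st.floats(1.0, 1000.0), st.floats(0.1, 10.0))
    def test_scaling_covariance(self, s_norm, t_scale, temp_scale):
        """Evaluating normalized on normalized time then rescaling equals
        evaluating the physical spectrum on physical time."""
        tr = ScalingTransform(t_scale=t_scale, temp_scale=temp_scale)
        s_phys = rescale_spectrum(s_norm, tr)
        g_norm = make_time_grid(64, 1.0)
        g_phys = g_norm.scaled(t_scale)
        v_norm = evaluate_curve(s_norm, g_norm).values * temp_scale
        v_phys = evaluate_curve(s_phys, g_phys).values
        np.testing.assert_allclose(v_norm, v_phys, rtol=1e-9)


class TestSerialization:
    def test_spectrum_json_round_trip(self, tmp_path):
        s = ExponentialSpectrum(tau=[0.1, 0.2, 0.3, 0.4], amp=[0.4, 0.3, 0.2, 0.1], normalized=True)
        p = tmp_path / "spec.json"
        s.save(p)
        s2 = ExponentialSpectrum.load(p)
        np.testing.assert_array_equal(s.tau, s2.tau)
        assert s2.normalized

    def test_curve_csv_round_trip(self, tmp_path, grid):
        s = ExponentialSpectrum(tau=[0.05, 0.1, 0.4, 0.8], amp=[0.2, 0.4, 0.1, 0.9])
        curve = evaluate_curve(s, grid)
        p = tmp_path / "curve.csv"
        curve.to_csv(p)
        from thermotau import TemperatureCurve

        c2 = TemperatureCurve.from_csv(p)
        np.testing.assert_allclose(c2.values, curve.values, rtol=1e-6)
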