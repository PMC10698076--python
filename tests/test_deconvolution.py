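import numpy as np
import pytest

from ctpcal.deconvolution import (
    DegenerateInputError,
    JWLParams,
    PlugFlowGrid,
    deconvolve_fourier,
    deconvolve_jwl,
    deconvolve_plugflow,
    jwl_bases,
    jwl_irf,
    plugflow_basis,
    plugflow_sse_surface,
)
from ctpcal.phantom import (
    FlowScaledIRF,
    GroundTruthParams,
    TimeCurve,
    make_arterial_tdc,
    make_gamma_variate_irf,
    simulate_tissue_tdc,
)


def circulant_forward(ca: TimeCurve, rf_per_s: np.ndarray) -> TimeCurve:
    """Circulant convolution of the AIF with an IRF given in 1/s on a 1 s grid."""
    t = np.arange(len(rf_per_s), dtype=float)
    c = ca.interp(t)
    m = 2 * len(t)
    q = np.fft.irfft(np.fft.rfft(c, m) * np.fft.rfft(rf_per_s, m), m)[: len(t)]
    return TimeCurve(t, q)


def smooth_rf(n: int, t0: float, mtt: float, cbf: float) -> np.ndarray:
    """A smooth gamma-shaped flow-scaled IRF sampled at 1 s, in 1/s units."""
    gt = GroundTruthParams.from_cbv_mtt(cbf * mtt / 60.0, mtt, t0)
    irf = make_gamma_variate_irf(gt)
    return np.interp(np.arange(n, dtype=float), irf.t, irf.r, right=0.0) / 6000.0


@pytest.fixture(scope="module")
def aif_long():
    # recirculation-free, long scan: curves settle before the end so
    # circulant wrap-around is negligible
    return make_arterial_tdc(duration_s=150.0, recirc_frac=0.0)


class TestFourier:

    def test_recovers_peak_with_tiny_regularization(self, aif_long):
        rf = smooth_rf(150, 2.0, 6.0, 40.0)
        q = circulant_forward(aif_long, rf)
        _, est = deconvolve_fourier(q, aif_long, reg_frac=1e-3)
        assert est.cbf == pytest.approx(6000.0 * rf.max(), rel=0.02)

    def test_scaled_copy_gives_exact_cbv(self, aif):
        q = TimeCurve(aif.t, 0.03 * aif.v)
        _, est = deconvolve_fourier(q, aif)
        assert est.cbv == pytest.approx(3.0, rel=1e-12)

    def test_delay_insensitivity(self, aif_long):
        rf = smooth_rf(150, 1.0, 6.0, 40.0)
        q0 = circulant_forward(aif_long, rf)
        _, est0 = deconvolve_fourier(q0, aif_long, reg_frac=0.05)
        for d in (3, 7):
            rf_d = np.roll(rf, d)
            qd = circulant_forward(aif_long, rf_d)
            _, est_d = deconvolve_fourier(qd, aif_long, reg_frac=0.05)
            assert abs((est_d.tmax - est0.tmax) - d) <= 1.0
            assert est_d.cbf == pytest.approx(est0.cbf, rel=0.01)

    def test_zero_arterial_area_rejected(self, aif):
        flat = TimeCurve(aif.t, np.zeros_like(aif.v))
        with pytest.raises(DegenerateInputError):
            deconvolve_fourier(aif, flat)

    @pytest.mark.parametrize("reg", [0.0, 1.0, -0.5])
    def test_reg_frac_domain(self, aif, reg):
        with pytest.raises(ValueError):
            deconvolve_fourier(aif, aif, reg_frac=reg)


class TestPlugFlowBasis:
    def test_matches_direct_boxcar_convolution(self, aif):
        t0, mtt = 3.0, 8.0
        b = plugflow_basis(aif, t0, mtt)
        # direct oracle: fine-grid convolution with a unit boxcar
        dt = 0.01
        tf = np.arange(0.0, aif.duration + dt / 2, dt)
        ca = aif.interp(tf)
        box = ((tf >= t0) & (tf < t0 + mtt)).astype(float)
        conv = np.convolve(ca, box)[: len(tf)] * dt
        expect = np.interp(b.t, tf, conv)
        scale = np.abs(expect).max()
        assert np.all(b.v >= -1e-9)
        assert np.abs(b.v - expect).max() <= 0.005 * scale

    def test_large_mtt_reduces_to_running_integral(self, aif):
        t0 = 2.0
        b = plugflow_basis(aif, t0, 1000.0)
        from scipy.integrate import cumulative_trapezoid

        shifted = np.interp(b.t - t0, aif.t, aif.v, left=0.0)
        expect = cumulative_trapezoid(shifted, dx=1.0, initial=0.0)
        assert np.allclose(b.v, expect)

    def test_unit_rectangle_ramp_and_plateau(self):
        # Ca = unit rectangle on [0, 20); basis ramps over MTT then plateaus
        t = np.arange(0.0, 40.0, 1.0)
        ca = TimeCurve(t, ((t >= 0) & (t < 20)).astype(float))
        mtt = 5.0
        b = plugflow_basis(ca, 0.0, mtt)
        plateau = b.v[(b.t >= mtt + 1) & (b.t <= 19)]
        assert np.allclose(plateau, mtt, atol=0.51)  # trapezoid edge effects
        ramp = b.v[b.t <= mtt]
        assert np.all(np.diff(ramp) > 0)


class TestPlugFlowDeconvolution:
    def test_default_grid_counts_575_pairs(self):
        assert PlugFlowGrid().n_pairs == 575

    def test_selfconsistency_on_grid(self, aif):
        t = np.arange(0.0, 40.0, 0.01)
        r = np.where((t >= 3.0) & (t < 11.0), 30.0, 0.0)
        q = simulate_tissue_tdc(aif, FlowScaledIRF(t, r))
        est = deconvolve_plugflow(q, aif)
        assert est.t0 == 3.0
        assert est.mtt == 8.0
        assert est.cbf == pytest.approx(30.0, rel=0.01)
        assert est.tmax == pytest.approx(7.0)
        assert est.cbv == pytest.approx(est.cbf * est.mtt / 60.0, rel=1e-12)

    def test_winner_is_global_minimum(self, aif, rng):
        gt = GroundTruthParams.from_cbv_mtt(2.0, 8.0, 2.0)
        q = simulate_tissue_tdc(aif, make_gamma_variate_irf(gt))
        q = TimeCurve(q.t, q.v + rng.normal(0, 1.5, len(q.v)))
        est = deconvolve_plugflow(q, aif)
        pairs, sse = plugflow_sse_surface(q, aif)
        assert len(sse) == 575
        assert est.sse == pytest.approx(sse.min())
        winner = pairs[np.argmin(sse)]
        assert (est.t0, est.mtt) == (winner[0], winner[1])

    def test_all_zero_curve_flagged_degenerate(self, aif):
        q = TimeCurve(aif.t, np.zeros_like(aif.v))
        est = deconvolve_plugflow(q, aif)
        assert est.cbf == 0.0
        assert est.degenerate

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            PlugFlowGrid(t0_values=(3.0, 1.0))
        with pytest.raises(ValueError):
            PlugFlowGrid(mtt_values=())


class TestJwlIrf:
    def test_large_k_approaches_plugflow_boxcar(self):
        p = JWLParams(t0=2.0, w=6.0, e=1.0, k=50.0, f=30.0)
        irf = jwl_irf(p)
        box = (irf.t >= 2.0) & (irf.t < 8.0)
        assert np.allclose(irf.r[box], 30.0)
        assert irf.cbv() == pytest.approx(30.0 * 6.0 / 60.0, rel=0.01)

    def test_area_equals_w_plus_e_over_k(self):
        p = JWLParams(t0=0.0, w=4.0, e=0.5, k=0.25, f=10.0)
        irf = jwl_irf(p)
        assert p.mtt == pytest.approx(6.0)
        assert irf.cbv() * 60.0 / p.f == pytest.approx(6.0, rel=1e-3)

    def test_tmax_convention(self):
        p = JWLParams(t0=3.0, w=4.0, e=0.5, k=0.25, f=10.0)
        assert p.tmax == pytest.approx(3.0 + 0.5 * 6.0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            JWLParams(t0=0.0, w=2.0, e=0.5, k=0.0, f=10.0)
        with pytest.raises(ValueError):
            JWLParams(t0=0.0, w=2.0, e=1.5, k=0.5, f=10.0)


class TestJwlDeconvolution:
    def test_exact_recovery_from_own_bases(self, aif):
        b1, b2 = jwl_bases(aif, 3.0, 4.0, 0.2)
        q = TimeCurve(b1.t, (20.0 / 6000.0) * (b1.v + 0.5 * b2.v))
        est = deconvolve_jwl(q, aif)
        assert (est.jwl.t0, est.jwl.w, est.jwl.k) == (3.0, 4.0, 0.2)
        assert est.jwl.e == pytest.approx(0.5, rel=1e-9)
        assert est.cbf == pytest.approx(20.0, rel=1e-9)
        assert est.mtt == pytest.approx(4.0 + 0.5 / 0.2, rel=1e-9)

    def test_recovery_from_simulated_curve(self, aif):
        p = JWLParams(t0=3.0, w=4.0, e=0.5, k=0.2, f=20.0)
        q = simulate_tissue_tdc(aif, jwl_irf(p), dt_out=1.0)
        est = deconvolve_jwl(q, aif)
        assert (est.jwl.t0, est.jwl.w, est.jwl.k) == (3.0, 4.0, 0.2)
        assert est.jwl.e == pytest.approx(0.5, rel=0.02)
        assert est.cbf == pytest.approx(20.0, rel=0.02)

    def test_e_always_in_unit_interval(self, aif, rng):
        for _ in range(5):
            gt = GroundTruthParams.from_cbv_mtt(2.0, 8.0, 1.0)
            q = simulate_tissue_tdc(aif, make_gamma_variate_irf(gt))
            q = TimeCurve(q.t, q.v + rng.normal(0, 1.5, len(q.v)))
            est = deconvolve_jwl(q, aif)
            assert 0.0 <= est.jwl.e <= 1.0

    def test_nests_plugflow_model(self, aif):
        # boxcar-generated curve: fitted tail should contribute ~nothing
        t = np.arange(0.0, 40.0, 0.01)
        r = np.where((t >= 2.0) & (t < 10.0), 25.0, 0.0)
        q = simulate_tissue_tdc(aif, FlowScaledIRF(t, r), dt_out=1.0)
        est = deconvolve_jwl(q, aif)
        assert est.jwl.e / est.jwl.k <= 0.1 * 8.0  # tail transit time small
        assert est.mtt == pytest.approx(8.0, rel=0.10)


class TestEngineInvariants:
    def engines(self, q, aif):
        _, mi = deconvolve_fourier(q, aif)
        md = deconvolve_plugflow(q, aif)
        jw = deconvolve_jwl(q, aif)
        return mi, md, jw

    def test_nonnegativity_on_noisy_curves(self, aif, rng):
        gt = GroundTruthParams.from_cbv_mtt(0.5, 16.0, 8.0)  # lowest SNR corner
        q0 = simulate_tissue_tdc(aif, make_gamma_variate_irf(gt))
        for _ in range(3):
            q = TimeCurve(q0.t, q0.v + rng.normal(0, 1.5, len(q0.v)))
            for est in self.engines(q, aif):
                assert est.cbf >= 0.0
                assert est.cbv >= 0.0

    def test_central_volume_consistency(self, aif, rng):
        gt = GroundTruthParams.from_cbv_mtt(2.0, 6.0, 1.0)
        q0 = simulate_tissue_tdc(aif, make_gamma_variate_irf(gt))
        q = TimeCurve(q0.t, q0.v + rng.normal(0, 1.0, len(q0.v)))
        mi, md, jw = self.engines(q, aif)
        for est in (md, jw):
            assert est.cbv == pytest.approx(est.cbf * est.mtt / 60.0, rel=1e-12)
            assert est.tmax == pytest.approx(est.t0 + 0.5 * est.mtt, rel=1e-12)
        assert mi.mtt == pytest.approx(60.0 * mi.cbv / mi.cbf, rel=1e-12)

    def test_doubling_curve_doubles_cbf(self, aif):
        gt = GroundTruthParams.from_cbv_mtt(2.0, 6.0, 1.0)
        q = simulate_tissue_tdc(aif, make_gamma_variate_irf(gt))
        q2 = TimeCurve(q.t, 2.0 * q.v)
        for one, two in zip(self.engines(q, aif), self.engines(q2, aif)):
            assert two.cbf == pytest.approx(2.0 * one.cbf, rel=1e-6)
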