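"""Perfusion estimation from (tissue, arterial) curve pairs.

Three engines:

``mi``
    Model-independent Fourier deconvolution with Wiener-like
    regularization (20% of the peak arterial spectrum magnitude).
``md``
    Model-dependent plug-flow (boxcar IRF) grid search with
    single-coefficient non-negative least squares.
``jwl``
    Model-based fit of a boxcar-plus-exponential-tail IRF
    (minimum transit time W, extraction-like fraction E, rate k),
    emulating a commercial model-based method.

All engines work on a 1 s virtual sampling grid internally and return
CBF in ml/min/100 g, CBV in ml/100 g, and MTT/T0/Tmax in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .phantom import FLOW_TO_PER_S, FlowScaledIRF, TimeCurve

__all__ = [
    "PerfusionEstimate",
    "PlugFlowGrid",
    "JWLParams",
    "DegenerateInputError",
    "deconvolve_fourier",
    "deconvolve_fourier_batch",
    "plugflow_basis",
    "deconvolve_plugflow",
    "deconvolve_plugflow_batch",
    "plugflow_sse_surface",
    "jwl_irf",
    "jwl_bases",
    "deconvolve_jwl",
    "deconvolve_jwl_batch",
    "DEFAULT_JWL_K_VALUES",
]

PER_S_TO_FLOW = 1.0 / FLOW_TO_PER_S  # 6000: (1/s) -> ml/min/100 g

DEFAULT_JWL_K_VALUES = (0.1, 0.2, 0.4, 0.8, 1.6)


class DegenerateInputError(ValueError):
    """Raised when an input curve cannot support deconvolution."""


@dataclass(frozen=True)
class PerfusionEstimate:
    """One engine's perfusion read-out for a single tissue curve."""

    cbf: float
    cbv: float
    mtt: float
    tmax: float
    t0: float | None = None  # model-based engines only
    sse: float | None = None  # model-based engines only
    degenerate: bool = False
    jwl: "JWLParams | None" = None


@dataclass(frozen=True)
class PlugFlowGrid:
    """Search grid of candidate (T0, MTT) pairs for the plug-flow engine."""

    t0_values: tuple = tuple(range(0, 25))
    mtt_values: tuple = tuple(range(2, 25))

    def __post_init__(self):
        for name, vals in (("t0_values", self.t0_values),
                           ("mtt_values", self.mtt_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0 or np.any(arr < 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be non-empty, non-negative, sorted")
        if min(self.mtt_values) <= 0:
            raise ValueError("mtt_values must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.t0_values) * len(self.mtt_values)

    def pairs(self) -> np.ndarray:
        """(n_pairs, 2) array of (T0, MTT), T0-major (tie-break order)."""
        t0, mtt = np.meshgrid(self.t0_values, self.mtt_values, indexing="ij")
        return np.column_stack([t0.ravel(), mtt.ravel()]).astype(float)


@dataclass(frozen=True)
class JWLParams:
    """Boxcar-plus-exponential-tail IRF parameters."""

    t0: float
    w: float
    e: float
    k: float
    f: float

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("decay rate k must be positive")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("fraction e must lie in [0, 1]")
        if self.w < 0 or self.t0 < 0 or self.f < 0:
            raise ValueError("t0, w and f must be non-negative")

    @property
    def mtt(self) -> float:
        """Area under the unit-height IRF: W + E/k."""
        return self.w + self.e / self.k

    @property
    def tmax(self) -> float:
        return self.t0 + 0.5 * self.mtt


# ---------------------------------------------------------------------------
# shared working-grid helpers

def _working_times(*curves: TimeCurve, dt: float = 1.0) -> np.ndarray:
    t_end = min(c.duration for c in curves)
    return np.arange(0.0, np.floor(t_end / dt) * dt + dt / 2, dt)


def _resample_rows(times: np.ndarray, rows: np.ndarray, new_t: np.ndarray) -> np.ndarray:
    """Row-wise linear interpolation of `rows` sampled at `times`."""
    idx = np.clip(np.searchsorted(times, new_t, side="right") - 1, 0, len(times) - 2)
    frac = np.clip((new_t - times[idx]) / (times[idx + 1] - times[idx]), 0.0, 1.0)
    return rows[..., idx] * (1.0 - frac) + rows[..., idx + 1] * frac


# ---------------------------------------------------------------------------
# model-independent (Fourier) engine

def deconvolve_fourier_batch(
    q_rows: np.ndarray,
    times: np.ndarray,
    ca: TimeCurve,
    reg_frac: float = 0.2,
) -> dict:
    """Fourier deconvolution of many tissue curves against one AIF.

    Curves are interpolated to 1 s and zero-padded to twice their length
    (circulant convolution, delay-insensitive). The flow-scaled IRF is the
    inverse transform of ``F{Q} conj(F{Ca}) / (|F{Ca}|^2 + lam^2)`` with
    ``lam = reg_frac * max|F{Ca}|``. CBF is the IRF peak, Tmax its argmax
    time; CBV is the raw-curve trapezoidal area ratio times 100 and
    MTT = 60*CBV/CBF.
    """
    if not 0.0 < reg_frac < 1.0:
        raise ValueError("reg_frac must lie in (0, 1)")
    q_rows = np.atleast_2d(np.asarray(q_rows, dtype=float))
    times = np.asarray(times, dtype=float)
    ca_area = ca.area()
    if ca_area <= 0:
        raise DegenerateInputError("arterial curve has non-positive area")

    t_w = _working_times(TimeCurve(times, times), ca)
    n = len(t_w)
    q = _resample_rows(times, q_rows, t_w)
    c = ca.interp(t_w)
    m = 2 * n  # zero-pad to avoid time aliasing

    fq = np.fft.rfft(q, m, axis=-1)
    fc = np.fft.rfft(c, m)
    lam = reg_frac * np.abs(fc).max()
    irf = np.fft.irfft(fq * np.conj(fc) / (np.abs(fc) ** 2 + lam**2), m, axis=-1)
    rf = irf[..., :n] * PER_S_TO_FLOW

    peak_idx = np.argmax(rf, axis=-1)
    cbf = np.maximum(np.take_along_axis(rf, peak_idx[..., None], -1)[..., 0], 0.0)
    tmax = t_w[peak_idx]
    cbv = np.maximum(100.0 * np.trapezoid(q_rows, times, axis=-1) / ca_area, 0.0)
    mtt = np.divide(60.0 * cbv, cbf, out=np.zeros_like(cbf), where=cbf > 0)
    return {"cbf": cbf, "cbv": cbv, "mtt": mtt, "tmax": tmax,
            "irf": rf, "irf_times": t_w}


def deconvolve_fourier(
    q: TimeCurve, ca: TimeCurve, reg_frac: float = 0.2
) -> tuple[FlowScaledIRF, PerfusionEstimate]:
    res = deconvolve_fourier_batch(q.v[None, :], q.t, ca, reg_frac)
    est = PerfusionEstimate(
        cbf=float(res["cbf"][0]),
        cbv=float(res["cbv"][0]),
        mtt=float(res["mtt"][0]),
        tmax=float(res["tmax"][0]),
    )
    return FlowScaledIRF(res["irf_times"], res["irf"][0]), est


# ---------------------------------------------------------------------------
# model-dependent (plug-flow) engine

def plugflow_basis(
    ca: TimeCurve,
    t0: float,
    mtt: float,
    dt: float = 1.0,
    t_end: float | None = None,
) -> TimeCurve:
    """Closed-form plug-flow tissue basis for one (T0, MTT) pair.

    ``b(t) = int_0^t Ca(u - T0) du - int_0^t Ca(u - T0 - MTT) du`` with the
    AIF treated as 0 before its first sample; equivalently the convolution
    of the AIF with a unit boxcar on [T0, T0 + MTT). Trapezoidal
    integration on a `dt` working grid.
    """
    if t0 < 0 or mtt <= 0:
        raise ValueError("t0 must be >= 0 and mtt > 0")
    t_end = ca.duration if t_end is None else t_end
    t_w = np.arange(0.0, np.floor(t_end / dt) * dt + dt / 2, dt)
    lead = np.interp(t_w - t0, ca.t, ca.v, left=0.0, right=float(ca.v[-1]))
    lag = np.interp(t_w - t0 - mtt, ca.t, ca.v, left=0.0, right=float(ca.v[-1]))
    b = cumulative_trapezoid(lead - lag, dx=dt, initial=0.0)
    return TimeCurve(t_w, b)


def _plugflow_design(ca: TimeCurve, grid: PlugFlowGrid, t_w: np.ndarray) -> np.ndarray:
    pairs = grid.pairs()
    basis = np.empty((len(pairs), len(t_w)))
    for i, (t0, mtt) in enumerate(pairs):
        basis[i] = plugflow_basis(ca, t0, mtt, t_end=t_w[-1]).v
    return basis


def deconvolve_plugflow_batch(
    q_rows: np.ndarray,
    times: np.ndarray,
    ca: TimeCurve,
    grid: PlugFlowGrid | None = None,
    chunk: int = 4096,
) -> dict:
    """Plug-flow grid-search deconvolution of many tissue curves.

    For every candidate (T0, MTT) pair the flow coefficient is solved by
    single-coefficient non-negative least squares; the pair with minimal
    SSE wins (ties broken by smallest T0 then smallest MTT through the
    T0-major candidate ordering).
    """
    grid = grid or PlugFlowGrid()
    q_rows = np.atleast_2d(np.asarray(q_rows, dtype=float))
    times = np.asarray(times, dtype=float)
    t_w = _working_times(TimeCurve(times, times), ca)
    q = _resample_rows(times, q_rows, t_w)

    basis = _plugflow_design(ca, grid, t_w)
    bb = np.einsum("pt,pt->p", basis, basis)
    if np.any(bb <= 0):
        raise DegenerateInputError("a plug-flow basis function is all-zero")
    pairs = grid.pairs()

    m = q.shape[0]
    best_idx = np.empty(m, dtype=int)
    best_coef = np.empty(m)
    best_sse = np.empty(m)
    for lo in range(0, m, chunk):
        sl = slice(lo, min(lo + chunk, m))
        qb = q[sl] @ basis.T
        coef = np.maximum(qb / bb, 0.0)
        qq = np.einsum("mt,mt->m", q[sl], q[sl])
        sse = qq[:, None] - 2.0 * coef * qb + coef**2 * bb
        j = np.argmin(sse, axis=1)  # first minimum = smallest T0 then MTT
        best_idx[sl] = j
        rows = np.arange(sse.shape[0])
        best_coef[sl] = coef[rows, j]
        best_sse[sl] = sse[rows, j]

    cbf = PER_S_TO_FLOW * best_coef
    t0 = pairs[best_idx, 0]
    mtt = pairs[best_idx, 1]
    degenerate = ~np.any(q_rows != 0.0, axis=-1)
    return {
        "cbf": cbf,
        "cbv": cbf * mtt / 60.0,
        "mtt": mtt,
        "t0": t0,
        "tmax": t0 + 0.5 * mtt,
        "sse": best_sse,
        "degenerate": degenerate,
        "n_candidates": basis.shape[0],
    }


def plugflow_sse_surface(
    q: TimeCurve, ca: TimeCurve, grid: PlugFlowGrid | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Full (pairs, SSE) surface for one curve — the exhaustiveness oracle."""
    grid = grid or PlugFlowGrid()
    t_w = _working_times(q, ca)
    qv = np.interp(t_w, q.t, q.v)
    basis = _plugflow_design(ca, grid, t_w)
    bb = np.einsum("pt,pt->p", basis, basis)
    qb = basis @ qv
    coef = np.maximum(qb / bb, 0.0)
    sse = qv @ qv - 2.0 * coef * qb + coef**2 * bb
    return grid.pairs(), sse


def deconvolve_plugflow(
    q: TimeCurve, ca: TimeCurve, grid: PlugFlowGrid | None = None
) -> PerfusionEstimate:
    res = deconvolve_plugflow_batch(q.v[None, :], q.t, ca, grid)
    return PerfusionEstimate(
        cbf=float(res["cbf"][0]),
        cbv=float(res["cbv"][0]),
        mtt=float(res["mtt"][0]),
        tmax=float(res["tmax"][0]),
        t0=float(res["t0"][0]),
        sse=float(res["sse"][0]),
        degenerate=bool(res["degenerate"][0]),
    )


# ---------------------------------------------------------------------------
# JWL (boxcar + exponential tail) engine

def jwl_irf(p: JWLParams, dt_s: float = 0.01) -> FlowScaledIRF:
    """Flow-scaled boxcar-plus-exponential-tail IRF.

    Height F on [T0, T0+W), then ``F*E*exp(-k*(t - T0 - W))``; the area
    divided by 60 equals ``F*(W + E/k)/60``.
    """
    t_end = p.t0 + p.w + max(30.0 / p.k, 1.0)
    t = np.arange(0.0, t_end + dt_s / 2, dt_s)
    r = np.zeros_like(t)
    box = (t >= p.t0) & (t < p.t0 + p.w)
    tail = t >= p.t0 + p.w
    r[box] = p.f
    r[tail] = p.f * p.e * np.exp(-p.k * (t[tail] - p.t0 - p.w))
    return FlowScaledIRF(t, r)


def _shift_rows(base: np.ndarray, shift_steps: int) -> np.ndarray:
    if shift_steps == 0:
        return base
    out = np.zeros_like(base)
    out[shift_steps:] = base[: len(base) - shift_steps]
    return out


def jwl_bases(
    ca: TimeCurve, t0: float, w: float, k: float, t_end: float | None = None
) -> tuple[TimeCurve, TimeCurve]:
    """Unit-coefficient boxcar and exponential-tail tissue bases (1 s grid)."""
    box = plugflow_basis(ca, t0, w, t_end=t_end)
    t_w = box.t
    c = ca.interp(t_w)
    g = _tail_conv(c, k, t_w)
    shift = int(round(t0 + w))
    return box, TimeCurve(t_w, _shift_rows(g, shift))


def _tail_conv(c: np.ndarray, k: float, t_w: np.ndarray) -> np.ndarray:
    """Trapezoidal convolution of the AIF with a unit exponential tail."""
    n = len(t_w)
    g = np.convolve(c, np.exp(-k * t_w))[:n]
    # trapezoid end-point correction (dt = 1 s): halve the boundary terms
    return g - 0.5 * (c[0] * np.exp(-k * t_w) + c)


def deconvolve_jwl_batch(
    q_rows: np.ndarray,
    times: np.ndarray,
    ca: TimeCurve,
    t0_values: tuple | None = None,
    w_values: tuple | None = None,
    k_values: tuple | None = None,
) -> dict:
    """Grid-search fit of the boxcar-plus-tail model to many curves.

    For each (T0, W, k) triple the tissue curve is modelled as
    ``F*b_box + (F*E)*b_tail`` with both bases built by convolving the
    AIF on the 1 s grid; the two coefficients are solved by non-negative
    least squares in closed form, with a post-hoc clamp E <= 1 (refit of
    F on the combined basis when violated). The minimal-SSE triple wins.
    """
    t0_values = tuple(range(0, 25)) if t0_values is None else tuple(t0_values)
    w_values = tuple(range(2, 25)) if w_values is None else tuple(w_values)
    k_values = DEFAULT_JWL_K_VALUES if k_values is None else tuple(k_values)
    if min(k_values) <= 0:
        raise ValueError("k values must be positive")

    q_rows = np.atleast_2d(np.asarray(q_rows, dtype=float))
    times = np.asarray(times, dtype=float)
    t_w = _working_times(TimeCurve(times, times), ca)
    n = len(t_w)
    q = _resample_rows(times, q_rows, t_w)
    qq = np.einsum("mt,mt->m", q, q)
    c = ca.interp(t_w)

    # boxcar bases at T0 = 0, one per W (then integer-shifted per T0)
    box0 = {w: plugflow_basis(ca, 0.0, w, t_end=t_w[-1]).v for w in w_values}
    # tail bases at T0 + W = 0, one per k
    tail0 = {k: _tail_conv(c, k, t_w) for k in k_values}

    m = q.shape[0]
    best = {
        "sse": np.full(m, np.inf),
        "c1": np.zeros(m),
        "e": np.zeros(m),
        "t0": np.zeros(m),
        "w": np.full(m, float(w_values[0])),
        "k": np.full(m, float(k_values[0])),
    }

    for t0 in t0_values:
        s0 = int(round(t0))
        if s0 >= n:
            continue
        for w in w_values:
            b1 = _shift_rows(box0[w], s0)
            g11 = b1 @ b1
            if g11 <= 0:
                continue
            q1 = q @ b1
            s1 = int(round(t0 + w))
            for k in k_values:
                if s1 >= n:
                    continue
                b2 = _shift_rows(tail0[k], s1)
                g22 = b2 @ b2
                if g22 <= 0:
                    continue
                g12 = b1 @ b2
                q2 = q @ b2
                det = g11 * g22 - g12 * g12

                if det > 0:
                    c1 = (g22 * q1 - g12 * q2) / det
                    c2 = (g11 * q2 - g12 * q1) / det
                else:
                    c1 = np.full(m, -1.0)
                    c2 = np.full(m, -1.0)
                neg = (c1 < 0) | (c2 < 0)
                if np.any(neg):
                    a1 = np.maximum(q1 / g11, 0.0)
                    a2 = np.maximum(q2 / g22, 0.0)
                    sse1 = qq - 2 * a1 * q1 + a1**2 * g11
                    sse2 = qq - 2 * a2 * q2 + a2**2 * g22
                    use1 = sse1 <= sse2
                    c1 = np.where(neg, np.where(use1, a1, 0.0), c1)
                    c2 = np.where(neg, np.where(use1, 0.0, a2), c2)

                # post-hoc physiological constraint: E = c2/c1 <= 1
                over = c2 > c1
                if np.any(over):
                    bc = b1 + b2
                    gc = bc @ bc
                    cc = np.maximum((q1 + q2) / gc, 0.0)
                    c1 = np.where(over, cc, c1)
                    c2 = np.where(over, cc, c2)

                sse = (qq - 2 * (c1 * q1 + c2 * q2) + c1**2 * g11
                       + 2 * c1 * c2 * g12 + c2**2 * g22)
                better = sse < best["sse"]
                if np.any(better):
                    e = np.divide(c2, c1, out=np.zeros(m), where=c1 > 0)
                    for key, val in (("sse", sse), ("c1", c1),
                                     ("e", np.clip(e, 0.0, 1.0)),
                                     ("t0", float(t0)), ("w", float(w)),
                                     ("k", float(k))):
                        best[key] = np.where(better, val, best[key])

    cbf = PER_S_TO_FLOW * best["c1"]
    mtt = best["w"] + best["e"] / best["k"]
    return {
        "cbf": cbf,
        "cbv": cbf * mtt / 60.0,
        "mtt": mtt,
        "t0": best["t0"],
        "tmax": best["t0"] + 0.5 * mtt,
        "e": best["e"],
        "w": best["w"],
        "k": best["k"],
        "sse": best["sse"],
        "degenerate": ~np.any(q_rows != 0.0, axis=-1),
    }


def deconvolve_jwl(
    q: TimeCurve,
    ca: TimeCurve,
    t0_values: tuple | None = None,
    w_values: tuple | None = None,
    k_values: tuple | None = None,
) -> PerfusionEstimate:
    res = deconvolve_jwl_batch(
        q.v[None, :], q.t, ca, t0_values, w_values, k_values
    )
    params = JWLParams(
        t0=float(res["t0"][0]),
        w=float(res["w"][0]),
        e=float(res["e"][0]),
        k=float(res["k"][0]),
        f=float(res["cbf"][0]),
    )
    return PerfusionEstimate(
        cbf=float(res["cbf"][0]),
        cbv=float(res["cbv"][0]),
        mtt=float(res["mtt"][0]),
        tmax=float(res["tmax"][0]),
        t0=float(res["t0"][0]),
        sse=float(res["sse"][0]),
        degenerate=bool(res["degenerate"][0]),
        jwl=params,
    )
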