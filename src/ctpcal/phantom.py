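"""Digital perfusion phantom.

Tissue time-density curves (TDCs) are simulated by convolving an analytic
arterial input with gamma-variate flow-scaled impulse residue functions
(IRFs) of known ground-truth perfusion, resampling to the scanner frame
interval, and adding zero-mean Gaussian noise.

Unit conventions
----------------
CBF is in ml/min/100 g, CBV in ml/100 g, times in seconds, and curve
values in Hounsfield units of contrast enhancement (baseline subtracted).
A flow-scaled IRF carries CBF units; dividing by 6000 converts it to the
fractional rate (1/s) that maps arterial HU to tissue HU, assuming unit
tissue density (1 g/ml).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import fftconvolve
from scipy.special import gammaln

__all__ = [
    "TimeCurve",
    "GroundTruthParams",
    "FlowScaledIRF",
    "PhantomConfig",
    "PhantomDataset",
    "FLOW_TO_PER_S",
    "gamma_shape_exponent",
    "make_arterial_tdc",
    "make_gamma_variate_irf",
    "simulate_tissue_tdc",
    "add_noise",
    "build_phantom",
]

#: (ml/min/100 g) -> fractional clearance rate in 1/s at unit density.
FLOW_TO_PER_S = 1.0 / 6000.0


@dataclass(frozen=True)
class TimeCurve:
    """A sampled contrast-enhancement curve: times (s) and values (HU)."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("t and v must be 1-D arrays of equal length")
        if len(t) < 2:
            raise ValueError("a curve needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def area(self) -> float:
        """Trapezoidal area under the curve (HU*s)."""
        return float(np.trapezoid(self.v, self.t))

    def interp(self, new_t: np.ndarray, left: float = 0.0) -> np.ndarray:
        """Linear interpolation; values before the first sample are `left`."""
        return np.interp(np.asarray(new_t, dtype=float), self.t, self.v,
                         left=left, right=float(self.v[-1]))


@dataclass(frozen=True)
class GroundTruthParams:
    """Self-consistent perfusion ground truth for one phantom combination.

    Invariants: cbf == 60*cbv/mtt (Central Volume Principle with the
    s -> min conversion) and tmax == t0 + mtt/2.
    """

    cbf: float
    cbv: float
    mtt: float
    t0: float
    tmax: float

    def __post_init__(self):
        if self.mtt <= 0:
            raise ValueError("MTT must be positive")
        if min(self.cbf, self.cbv, self.t0, self.tmax) < 0:
            raise ValueError("perfusion parameters must be non-negative")
        if not np.isclose(self.cbf, 60.0 * self.cbv / self.mtt, rtol=1e-9):
            raise ValueError("cbf must equal 60*cbv/mtt")
        if not np.isclose(self.tmax, self.t0 + 0.5 * self.mtt, rtol=0, atol=1e-9):
            raise ValueError("tmax must equal t0 + mtt/2")

    @classmethod
    def from_cbv_mtt(cls, cbv: float, mtt: float, t0: float) -> "GroundTruthParams":
        return cls(cbf=60.0 * cbv / mtt, cbv=cbv, mtt=mtt, t0=t0,
                   tmax=t0 + 0.5 * mtt)


@dataclass(frozen=True)
class FlowScaledIRF:
    """Flow-scaled impulse residue function R_F(t) = F*R(t).

    `r` is in ml/min/100 g; its trapezoidal area divided by 60 is CBV in
    ml/100 g.
    """

    t: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("t and r must be 1-D arrays of equal length")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "r", r)

    def cbv(self) -> float:
        """Area under the flow-scaled IRF, converted to ml/100 g."""
        return float(np.trapezoid(self.r, self.t)) / 60.0


@lru_cache(maxsize=1)
def gamma_shape_exponent() -> float:
    """Shape exponent of the phantom gamma-variate IRF.

    The exponent ``a`` is the root of ``a * a**a * exp(-a) / Gamma(a+1)
    = 1/2``, which simultaneously pins the mode of the gamma shape at
    half its (peak-normalized) area so the three IRF constraints
    (peak = CBF, area = 60*CBV, mode = T0 + MTT/2) are jointly solvable.
    The root is independent of the perfusion parameters.
    """
    def f(a: float) -> float:
        return (a + 1.0) * np.log(a) - a - gammaln(a + 1.0) - np.log(0.5)

    return float(brentq(f, 1e-2, 20.0, xtol=1e-13))


def make_arterial_tdc(
    duration_s: float = 60.0,
    dt_s: float = 0.5,
    *,
    arrival_s: float = 8.0,
    peak_hu: float = 300.0,
    shape: float = 3.0,
    time_to_peak_s: float = 11.0,
    recirc_frac: float = 0.25,
    recirc_delay_s: float = 10.0,
    recirc_dispersion: float = 2.0,
) -> TimeCurve:
    """Synthetic arterial TDC: gamma-variate bolus plus recirculation bump.

    A stand-in for a patient-measured arterial curve: a first-pass
    gamma-variate peaking at `peak_hu`, plus a smaller, delayed and
    dispersed recirculation component. Baseline is 0 HU.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration_s and dt_s must be positive")
    if duration_s < 40:
        raise ValueError("duration_s must be at least 40 s to contain a bolus")

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)

    def bump(t0: float, tp: float) -> np.ndarray:
        x = np.maximum(t - t0, 0.0) / tp
        return np.where(t > t0, x**shape * np.exp(shape * (1.0 - x)), 0.0)

    v = bump(arrival_s, time_to_peak_s)
    if recirc_frac > 0:
        v = v + recirc_frac * bump(
            arrival_s + recirc_delay_s, time_to_peak_s * recirc_dispersion
        )
    return TimeCurve(t, v * (peak_hu / v.max()))


def make_gamma_variate_irf(
    gt: GroundTruthParams, dt_s: float = 0.01
) -> FlowScaledIRF:
    """Gamma-variate flow-scaled IRF matching a perfusion ground truth.

    Returns ``R_F(t) = K*(t-T0)**a * exp(-(t-T0)/b)`` for ``t >= T0``
    (0 before), with ``(K, a, b)`` solved so that peak height equals CBF,
    trapezoidal area equals 60*CBV, and the peak occurs at T0 + MTT/2.
    All three constraints are verified to 0.1% relative error.
    """
    a = gamma_shape_exponent()
    b = 0.5 * gt.mtt / a
    # exp(-30) tail truncation keeps the omitted area ~1e-11 of the total
    t_end = gt.t0 + 0.5 * gt.mtt + 30.0 * b
    t = np.arange(0.0, t_end + dt_s / 2, dt_s)
    x = np.maximum(t - gt.t0, 0.0)
    k_amp = gt.cbf * np.exp(a) / (0.5 * gt.mtt) ** a
    r = np.where(t >= gt.t0, k_amp * x**a * np.exp(-x / b), 0.0)
    irf = FlowScaledIRF(t, r)

    peak = float(r.max())
    area_cbv = irf.cbv()
    mode = float(t[np.argmax(r)])
    if abs(peak - gt.cbf) > 1e-3 * gt.cbf or abs(area_cbv - gt.cbv) > 1e-3 * gt.cbv:
        raise ArithmeticError(
            f"gamma-variate IRF constraints not met: peak={peak:.4f} "
            f"(want {gt.cbf:.4f}), area={area_cbv:.4f} (want {gt.cbv:.4f})"
        )
    if abs(mode - gt.tmax) > dt_s + 1e-12:
        raise ArithmeticError(
            f"gamma-variate IRF mode {mode:.4f} != Tmax {gt.tmax:.4f}"
        )
    return irf


def simulate_tissue_tdc(
    aif: TimeCurve,
    irf: FlowScaledIRF,
    dt_sim: float = 0.01,
    dt_out: float = 2.0,
    duration_s: float | None = None,
) -> TimeCurve:
    """Noise-free tissue TDC: fine-grid convolution of AIF and IRF.

    The AIF is linearly interpolated to `dt_sim`, discretely convolved
    with the IRF (scaled by dt_sim/6000 for the min -> s and per-100 g
    conversions), and sampled at `dt_out` intervals.
    """
    duration = aif.duration if duration_s is None else float(duration_s)
    if duration <= 0 or duration > aif.duration + 1e-9:
        raise ValueError("requested duration not covered by the arterial curve")
    tf = np.arange(0.0, duration + dt_sim / 2, dt_sim)
    ca = aif.interp(tf)
    tr = np.arange(0.0, irf.t[-1] + dt_sim / 2, dt_sim)
    r = np.interp(tr, irf.t, irf.r, left=0.0, right=0.0)
    q = fftconvolve(ca, r)[: len(tf)] * dt_sim * FLOW_TO_PER_S
    t_out = np.arange(0.0, duration + 1e-9, dt_out)
    return TimeCurve(t_out, np.interp(t_out, tf, q))


def add_noise(tdc: TimeCurve, sigma_hu: float, rng) -> TimeCurve:
    """Add independent zero-mean Gaussian noise to every sample."""
    if sigma_hu < 0:
        raise ValueError("sigma_hu must be non-negative")
    if sigma_hu == 0:
        return TimeCurve(tdc.t, tdc.v.copy())
    rng = np.random.default_rng(rng)
    return TimeCurve(tdc.t, tdc.v + rng.normal(0.0, sigma_hu, size=len(tdc.v)))


@dataclass
class PhantomConfig:
    """Parameter grids and acquisition settings of the digital phantom."""

    t0_grid: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 8.0)
    mtt_grid: tuple = (3.4, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0)
    cbv_grid: tuple = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0)
    n_real: int = 1024
    sigma_hu: float = 1.5
    duration_s: float = 60.0
    dt_sim: float = 0.01
    dt_sample: float = 2.0
    noisy_aif: bool = False
    aif_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.t0_grid and self.mtt_grid and self.cbv_grid):
            raise ValueError("parameter grids must be non-empty")
        if self.n_real < 1:
            raise ValueError("n_real must be >= 1")

    def combos(self) -> list[GroundTruthParams]:
        """Full Cartesian product of the grids, T0-major ordering."""
        return [
            GroundTruthParams.from_cbv_mtt(cbv, mtt, t0)
            for t0, mtt, cbv in itertools.product(
                self.t0_grid, self.mtt_grid, self.cbv_grid
            )
        ]


@dataclass
class PhantomDataset:
    """Ground-truth-labelled tissue TDCs plus the shared arterial TDC.

    `clean` has shape (n_combos, n_times); `tissue` has shape
    (n_combos, n_real, n_times). Every curve shares `times`.
    """

    aif: TimeCurve
    combos: list[GroundTruthParams]
    times: np.ndarray
    clean: np.ndarray
    tissue: np.ndarray
    sigma_hu: float
    seed: int

    @property
    def n_combos(self) -> int:
        return len(self.combos)

    @property
    def n_real(self) -> int:
        return self.tissue.shape[1]

    def tissue_curve(self, combo: int, realization: int) -> TimeCurve:
        return TimeCurve(self.times, self.tissue[combo, realization])

    def gt_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "combo": np.arange(self.n_combos),
                "t0": [g.t0 for g in self.combos],
                "mtt": [g.mtt for g in self.combos],
                "cbv": [g.cbv for g in self.combos],
                "cbf": [g.cbf for g in self.combos],
                "tmax": [g.tmax for g in self.combos],
            }
        )

    def curves_frame(self) -> pd.DataFrame:
        """Long-format table of every noisy realization (one row each)."""
        nc, nr, nt = self.tissue.shape
        gt = self.gt_frame().loc[np.repeat(np.arange(nc), nr)].reset_index(drop=True)
        gt["real"] = np.tile(np.arange(nr), nc)
        vals = pd.DataFrame(
            self.tissue.reshape(nc * nr, nt),
            columns=[f"v{t:g}" for t in self.times],
        )
        return pd.concat([gt, vals], axis=1)


def build_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomDataset:
    """Generate the full phantom: grid product x noise realizations.

    Reproducible for a fixed seed; each combination draws its noise from
    an independent child stream of the master seed so realizations do not
    depend on combo ordering.
    """
    config = config or PhantomConfig()
    aif = make_arterial_tdc(config.duration_s, 0.5, **config.aif_kwargs)
    combos = config.combos()
    times = np.arange(0.0, config.duration_s + 1e-9, config.dt_sample)

    master = np.random.SeedSequence(seed)
    if config.noisy_aif:
        aif_rng = np.random.default_rng(master.spawn(1)[0])
        aif = add_noise(aif, config.sigma_hu, aif_rng)
    streams = master.spawn(len(combos))

    # Curves scale linearly with CBF, so convolve once per (T0, MTT) shape.
    unit_clean: dict[tuple[float, float], np.ndarray] = {}
    clean = np.empty((len(combos), len(times)))
    for i, gt in enumerate(combos):
        key = (gt.t0, gt.mtt)
        if key not in unit_clean:
            unit = GroundTruthParams.from_cbv_mtt(gt.mtt / 60.0, gt.mtt, gt.t0)
            irf = make_gamma_variate_irf(unit, config.dt_sim)
            unit_clean[key] = simulate_tissue_tdc(
                aif, irf, config.dt_sim, config.dt_sample, config.duration_s
            ).v
        clean[i] = gt.cbf * unit_clean[key]

    tissue = np.empty((len(combos), config.n_real, len(times)))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        tissue[i] = clean[i] + rng.normal(
            0.0, config.sigma_hu, size=(config.n_real, len(times))
        )

    return PhantomDataset(
        aif=aif,
        combos=combos,
        times=times,
        clean=clean,
        tissue=tissue,
        sigma_hu=config.sigma_hu,
        seed=seed,
    )
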