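"""Threshold calibration between deconvolution engines.

Engine estimates on the digital phantom are regressed against ground
truth; the regression coefficients feed closed-form calibration of the
relative-CBF (ischemic core) and Tmax (penumbra) thresholds so that a
model-based engine segments the same tissue as the model-independent
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .deconvolution import (
    deconvolve_fourier_batch,
    deconvolve_jwl_batch,
    deconvolve_plugflow_batch,
)
from .phantom import PhantomDataset

__all__ = [
    "RegressionFit",
    "CalibrationResult",
    "estimate_phantom",
    "summarize_estimates",
    "fit_regression",
    "calibrate_cbf_threshold",
    "calibrate_tmax_threshold",
    "run_phantom_calibration",
]

REFERENCE_RCBF = 0.30
REFERENCE_TMAX_S = 6.0
NORMAL_CBF_GT = 50.0  # assumed ground-truth CBF of normally perfused brain


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of engine estimates against ground truth (est on gt)."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, gt: float) -> float:
        return self.slope * gt + self.intercept


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated thresholds; CBF part and/or Tmax part may be present."""

    r_mb: float | None = None
    r_mb_rounded: float | None = None
    tmax_mb: float | None = None
    tmax_rounded: float | None = None
    r_mi: float | None = None
    tmax_mi: float | None = None
    n_gt: float | None = None
    fit_mi: RegressionFit | None = None
    fit_mb: RegressionFit | None = None


def _round_half_up(x: float) -> float:
    return float(np.floor(x + 0.5))


def round_rcbf(fraction: float) -> float:
    """Round a relative-CBF fraction to the nearest 5 percentage points."""
    return _round_half_up(100.0 * fraction / 5.0) * 5.0 / 100.0


def round_tmax(seconds: float) -> float:
    """Round a Tmax threshold to the nearest integer second."""
    return _round_half_up(seconds)


def estimate_phantom(phantom: PhantomDataset, engine: str = "mi", **kwargs) -> dict:
    """Run one engine over every phantom realization.

    Returns ``{"cbf": (n_combos, n_real), "tmax": (n_combos, n_real)}``.
    """
    nc, nr, nt = phantom.tissue.shape
    q = phantom.tissue.reshape(nc * nr, nt)
    if engine == "mi":
        res = deconvolve_fourier_batch(q, phantom.times, phantom.aif, **kwargs)
    elif engine == "md":
        res = deconvolve_plugflow_batch(q, phantom.times, phantom.aif, **kwargs)
    elif engine == "jwl":
        res = deconvolve_jwl_batch(q, phantom.times, phantom.aif, **kwargs)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return {"cbf": res["cbf"].reshape(nc, nr), "tmax": res["tmax"].reshape(nc, nr)}


def summarize_estimates(phantom: PhantomDataset, results: dict) -> pd.DataFrame:
    """Per-combo means of the estimated parameters, joined to ground truth."""
    for key in ("cbf", "tmax"):
        arr = np.asarray(results[key])
        if arr.shape[0] != phantom.n_combos:
            raise ValueError("estimates do not cover every phantom combination")
        if arr.ndim != 2 or arr.shape[1] < 1:
            raise ValueError("need at least one estimate per combination")
    out = phantom.gt_frame()
    out["cbf_est"] = np.mean(results["cbf"], axis=1)
    out["tmax_est"] = np.mean(results["tmax"], axis=1)
    return out


def fit_regression(gt_values, est_means, exclude=None) -> RegressionFit:
    """Ordinary least squares of estimates on ground truth.

    `exclude` is an optional boolean mask (True = drop) or a predicate
    applied to the ground-truth values. The intercept is free.
    """
    gt = np.asarray(gt_values, dtype=float)
    est = np.asarray(est_means, dtype=float)
    if exclude is not None:
        mask = exclude(gt) if callable(exclude) else np.asarray(exclude, bool)
        gt, est = gt[~mask], est[~mask]
    if len(gt) < 2:
        raise ValueError("need at least two points after exclusion")
    if np.ptp(gt) == 0:
        raise ValueError("degenerate ground-truth variance")
    fit = sps.linregress(gt, est)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(gt),
    )


def calibrate_cbf_threshold(
    fit_mi: RegressionFit,
    fit_mb: RegressionFit,
    r_mi: float = REFERENCE_RCBF,
    n_gt: float = NORMAL_CBF_GT,
) -> CalibrationResult:
    """Closed-form relative-CBF threshold mapping between two engines.

    With (alpha, beta) the CBF regression slope/intercept of the reference
    (MI) and calibrated (MB) engines,

    ``R_MB = [a_MB(a_MI N + b_MI) R_MI + a_MI b_MB - a_MB b_MI]
             / [a_MI (a_MB N + b_MB)]``

    where N is the assumed ground-truth CBF of normal brain. Relative CBF
    of each engine is absolute CBF over that engine's regression-line
    value at N.
    """
    a_mi, b_mi = fit_mi.slope, fit_mi.intercept
    a_mb, b_mb = fit_mb.slope, fit_mb.intercept
    if a_mi <= 0 or a_mb <= 0:
        raise ValueError("regression slopes must be positive")
    denom = a_mi * (a_mb * n_gt + b_mb)
    if denom == 0:
        raise ZeroDivisionError("degenerate calibration: zero denominator")
    r_mb = (a_mb * (a_mi * n_gt + b_mi) * r_mi + a_mi * b_mb - a_mb * b_mi) / denom
    return CalibrationResult(
        r_mb=float(r_mb),
        r_mb_rounded=round_rcbf(r_mb),
        r_mi=r_mi,
        n_gt=n_gt,
        fit_mi=fit_mi,
        fit_mb=fit_mb,
    )


def calibrate_tmax_threshold(
    fit_mi: RegressionFit,
    fit_mb: RegressionFit,
    t_mi: float = REFERENCE_TMAX_S,
) -> CalibrationResult:
    """Closed-form Tmax threshold mapping between two engines.

    With (gamma, delta) the Tmax regression slope/intercept,

    ``T_MB = (g_MB / g_MI) T_MI + (g_MI d_MB - g_MB d_MI) / g_MI``.
    """
    g_mi, d_mi = fit_mi.slope, fit_mi.intercept
    g_mb, d_mb = fit_mb.slope, fit_mb.intercept
    if g_mi == 0:
        raise ZeroDivisionError("degenerate calibration: zero reference slope")
    t_mb = (g_mb / g_mi) * t_mi + (g_mi * d_mb - g_mb * d_mi) / g_mi
    return CalibrationResult(
        tmax_mb=float(t_mb),
        tmax_rounded=round_tmax(t_mb),
        tmax_mi=t_mi,
        fit_mi=fit_mi,
        fit_mb=fit_mb,
    )


def run_phantom_calibration(
    phantom: PhantomDataset,
    engines: tuple = ("mi", "md"),
    r_mi: float = REFERENCE_RCBF,
    t_mi: float = REFERENCE_TMAX_S,
    n_gt: float = NORMAL_CBF_GT,
    exclude_cbv: float | None = 0.5,
) -> dict:
    """Full phantom calibration workflow.

    Runs each engine over the phantom, regresses per-combo mean CBF and
    Tmax on ground truth (Tmax fits drop combos at the excluded CBV,
    where low SNR makes the model-independent Tmax deviate), and
    calibrates the model-based engines' thresholds against the
    model-independent reference.
    """
    if "mi" not in engines:
        raise ValueError("the 'mi' reference engine is required")
    summaries: dict[str, pd.DataFrame] = {}
    cbf_fits: dict[str, RegressionFit] = {}
    tmax_fits: dict[str, RegressionFit] = {}
    for engine in engines:
        summary = summarize_estimates(phantom, estimate_phantom(phantom, engine))
        summaries[engine] = summary
        cbf_fits[engine] = fit_regression(summary["cbf"], summary["cbf_est"])
        drop = (
            np.isclose(summary["cbv"].to_numpy(), exclude_cbv)
            if exclude_cbv is not None
            else None
        )
        tmax_fits[engine] = fit_regression(
            summary["tmax"], summary["tmax_est"], exclude=drop
        )

    thresholds = {}
    for engine in engines:
        if engine == "mi":
            continue
        thresholds[engine] = {
            "cbf": calibrate_cbf_threshold(
                cbf_fits["mi"], cbf_fits[engine], r_mi=r_mi, n_gt=n_gt
            ),
            "tmax": calibrate_tmax_threshold(
                tmax_fits["mi"], tmax_fits[engine], t_mi=t_mi
            ),
        }
    return {
        "summaries": summaries,
        "cbf_fits": cbf_fits,
        "tmax_fits": tmax_fits,
        "thresholds": thresholds,
    }
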