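"""Summary statistics for homeostat trajectories.

Implements the running (cumulative) time average

    <X>(t) = 1/(t - t0) * integral_{t0}^{t} X(t') dt'

used to express homeostasis of oscillatory variables, per-cycle period and
frequency series (frequency = inverse period, measured peak-to-peak on the
plotted species), the maximum post-step frequency, and the response
amplitude ``delta_A`` of non-oscillatory step responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .errors import AnalysisError, ConvergenceWarning
from .simulate import Trajectory

__all__ = [
    "RunningAverage",
    "CycleSeries",
    "StepResponseSummary",
    "running_average",
    "detect_cycles",
    "max_post_step_frequency",
    "delta_A",
    "harmonic_average_check",
]


# --------------------------------------------------------------------------
# running time average
# --------------------------------------------------------------------------

@dataclass
class RunningAverage:
    """Cumulative time average of one species from an origin ``t0``."""

    t: np.ndarray
    values: np.ndarray
    t0: float
    species: str = ""

    def final(self) -> float:
        return float(self.values[-1])

    def convergence(self, tail_fraction: float = 0.1) -> float:
        """Relative change of the average over the trailing ``tail_fraction``
        of the (t - t0) span."""
        span = self.t[-1] - self.t0
        mask = self.t >= self.t[-1] - tail_fraction * span
        seg = self.values[mask]
        denom = abs(seg[-1]) if seg[-1] != 0 else 1.0
        return float(abs(seg[-1] - seg[0]) / denom)

    def asymptote(self, method: str = "extrapolate",
                  tail_fraction: float = 0.5,
                  convergence_tol: float = 1e-3) -> float:
        """Long-time limit of the running average.

        A running average whose underlying signal has settled onto an
        attractor approaches its limit as ``a + b/t``; ``method='extrapolate'``
        (default) fits that form over the trailing ``tail_fraction`` of the
        span and returns ``a``.  ``method='final'`` returns the last value and
        warns if the plain convergence criterion (< ``convergence_tol``
        relative change over the final 10 %) is not met.
        """
        if method == "final":
            if self.convergence() > convergence_tol:
                warnings.warn(
                    f"running average of {self.species!r} changed by "
                    f"{self.convergence():.2e} over the final 10% "
                    f"(tolerance {convergence_tol:g})",
                    ConvergenceWarning, stacklevel=2,
                )
            return self.final()
        if method != "extrapolate":
            raise ValueError(f"unknown method {method!r}")
        span = self.t[-1] - self.t0
        mask = self.t >= self.t[-1] - tail_fraction * span
        tt = self.t[mask] - self.t0
        tt = np.where(tt <= 0, np.nan, tt)
        good = np.isfinite(tt)
        design = np.column_stack([np.ones(good.sum()), 1.0 / tt[good]])
        coef, *_ = np.linalg.lstsq(design, self.values[mask][good], rcond=None)
        return float(coef[0])


def running_average(trajectory: Trajectory, species: str,
                    t0: float | None = None) -> RunningAverage:
    """Cumulative trapezoid average of ``species`` from ``t0`` (default: run start).

    The value at ``t0`` itself is defined as ``X(t0)``.
    """
    x = trajectory[species]
    t = trajectory.t
    if t0 is None:
        t0 = float(t[0])
    if not (t[0] <= t0 <= t[-1]):
        raise AnalysisError(f"t0={t0} outside trajectory span {trajectory.t_span}")
    i0 = int(np.searchsorted(t, t0))
    tt, xx = t[i0:], x[i0:]
    integral = cumulative_trapezoid(xx, tt, initial=0.0)
    elapsed = tt - tt[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(elapsed > 0, integral / np.where(elapsed > 0, elapsed, 1.0), xx)
    avg[0] = xx[0]
    return RunningAverage(t=tt, values=avg, t0=float(tt[0]), species=species)


# --------------------------------------------------------------------------
# cycle detection
# --------------------------------------------------------------------------

@dataclass
class CycleSeries:
    """Ordered per-cycle records of an oscillatory signal.

    A cycle is the interval between two successive qualifying peaks; its
    period is the peak-time difference and its frequency the inverse period.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cycle_index", "t_peak", "t_next_peak", "period",
                 "frequency", "peak_value", "trough_value"]))
    species: str = ""

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def peak_times(self) -> np.ndarray:
        if len(self.frame) == 0:
            return np.array([])
        return np.append(self.frame["t_peak"].to_numpy(),
                         self.frame["t_next_peak"].iloc[-1])

    @property
    def periods(self) -> np.ndarray:
        return self.frame["period"].to_numpy()

    @property
    def frequencies(self) -> np.ndarray:
        return self.frame["frequency"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _parabolic_refine(t: np.ndarray, x: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak location/height by a parabola through 3 points."""
    if i <= 0 or i >= len(x) - 1:
        return float(t[i]), float(x[i])
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom == 0:
        return float(t[i]), float(x[i])
    d = 0.5 * (x[i - 1] - x[i + 1]) / denom
    d = float(np.clip(d, -1.0, 1.0))
    dt = t[i + 1] - t[i] if d >= 0 else t[i] - t[i - 1]
    height = x[i] - 0.25 * (x[i - 1] - x[i + 1]) * d
    return float(t[i] + d * abs(dt)), float(height)


def detect_cycles(trajectory: Trajectory, species: str = "A",
                  prominence_fraction: float = 0.01) -> CycleSeries:
    """Locate oscillation cycles of ``species`` by peak detection.

    Local maxima are refined by parabolic interpolation; a candidate peak
    qualifies only if its prominence exceeds ``prominence_fraction`` of the
    signal's running peak-to-trough range (so early small-amplitude cycles
    are kept even when the signal later grows).  Samples at schedule
    breakpoints are excluded — a parameter jump produces a kink, not an
    oscillation maximum.  Fewer than two qualifying peaks yield an empty
    series (non-oscillatory regime).
    """
    x = trajectory[species]
    t = trajectory.t
    idx, props = find_peaks(x, prominence=0.0)
    if idx.size == 0:
        return CycleSeries(species=species)

    run_max = np.maximum.accumulate(x)
    run_min = np.minimum.accumulate(x)
    rng = run_max[idx] - run_min[idx]
    keep = props["prominences"] >= prominence_fraction * rng
    idx = idx[keep]

    if trajectory.breakpoints:
        bps = np.asarray(trajectory.breakpoints)
        dt_local = np.median(np.diff(t))
        near_bp = np.array([
            bool(np.any(np.abs(t[i] - bps) <= 1.5 * dt_local)) for i in idx
        ])
        idx = idx[~near_bp]

    if idx.size < 2:
        return CycleSeries(species=species)

    refined = [_parabolic_refine(t, x, i) for i in idx]
    t_pk = np.array([r[0] for r in refined])
    h_pk = np.array([r[1] for r in refined])

    rows = []
    for k in range(len(idx) - 1):
        i0, i1 = idx[k], idx[k + 1]
        period = t_pk[k + 1] - t_pk[k]
        if period <= 0:
            continue
        trough = float(x[i0:i1 + 1].min())
        rows.append({
            "cycle_index": k,
            "t_peak": t_pk[k],
            "t_next_peak": t_pk[k + 1],
            "period": period,
            "frequency": 1.0 / period,
            "peak_value": h_pk[k],
            "trough_value": trough,
        })
    return CycleSeries(frame=pd.DataFrame(rows), species=species)


# --------------------------------------------------------------------------
# step-response statistics
# --------------------------------------------------------------------------

@dataclass
class StepResponseSummary:
    """Summary of one step-perturbation response."""

    t_step: float
    pre_step_reference: float
    max_frequency: float = float("nan")
    delta_A: float = float("nan")
    diagnostics: dict = field(default_factory=dict)


def max_post_step_frequency(cycles: CycleSeries, t_step: float) -> float:
    """Maximum per-cycle frequency over cycles starting at or after ``t_step``.

    The maximum occurs directly after the step in these homeostats; ties are
    broken toward the earliest cycle (np.max on an ordered series).
    """
    if len(cycles) == 0:
        raise AnalysisError("empty cycle series: non-oscillatory regime")
    f = cycles.frame
    post = f[f["t_peak"] >= t_step]
    if len(post) == 0:
        raise AnalysisError(
            f"no cycles start at or after t_step={t_step} "
            "(overdamped or too-short post-step horizon)"
        )
    return float(post["frequency"].max())


def delta_A(trajectory: Trajectory, t_step: float,
            pre_step_reference: float | None = None,
            species: str = "A",
            settle_tol: float = 1e-4) -> float:
    """Maximum post-step excursion ``max_{t>=t_step} |X(t) - X_ref|``.

    ``X_ref`` defaults to the value just before the step, which must be a
    settled steady state; an unsettled pre-step signal triggers a warning
    but the excursion is still computed.
    """
    x = trajectory[species]
    t = trajectory.t
    if not (t[0] <= t_step <= t[-1]):
        raise AnalysisError(f"t_step={t_step} outside trajectory span")
    pre = x[t < t_step]
    if pre_step_reference is None:
        if pre.size == 0:
            raise AnalysisError("no pre-step samples to take a reference from")
        pre_step_reference = float(pre[-1])
        tail = pre[-min(50, pre.size):]
        scale = abs(pre_step_reference) if pre_step_reference else 1.0
        if (tail.max() - tail.min()) / scale > settle_tol:
            warnings.warn(
                f"pre-step signal not settled (relative wobble "
                f"{(tail.max()-tail.min())/scale:.2e} > {settle_tol:g}); "
                "delta_A computed against the last pre-step value",
                ConvergenceWarning, stacklevel=2,
            )
    post = x[t >= t_step]
    return float(np.max(np.abs(post - pre_step_reference)))


def harmonic_average_check(trajectory: Trajectory, params) -> dict[str, float]:
    """Empirical vs analytic long-time average of ``1/(k10 + A)`` (motif-8).

    The motif-8 steady-state argument predicts
    ``<1/(k10+A)> -> k7/(k6*k10)`` at long times.  Returns the empirical
    asymptote, the prediction, and their relative deviation; warns when the
    running average has not flattened (< 0.1 % change over the last 10 %).
    """
    k10 = params.k10
    shifted = 1.0 / (k10 + trajectory["A"])
    shadow = Trajectory(
        t=trajectory.t, y=shifted[:, None], species=("inv_shifted_A",),
        model_name=trajectory.model_name,
    )
    avg = running_average(shadow, "inv_shifted_A")
    if avg.convergence() > 1e-3:
        warnings.warn(
            f"running average of 1/(k10+A) changed by {avg.convergence():.2e} "
            "over the final 10% — extend the horizon",
            ConvergenceWarning, stacklevel=2,
        )
    empirical = avg.asymptote()
    predicted = params.k7 / (params.k6 * params.k10)
    return {
        "empirical": empirical,
        "predicted": predicted,
        "relative_deviation": abs(empirical - predicted) / predicted,
    }
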