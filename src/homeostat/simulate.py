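"""Stiff integration of homeostat models under piecewise-constant schedules.

The networks combine rate constants spanning nine orders of magnitude
(Michaelis constants of 1e-6 against concentrations of 1e4+), so every
integration uses the LSODA stiff/non-stiff switching solver (via
``scipy.integrate.odeint``) at tight tolerances.  Perturbations and
backgrounds are piecewise-constant *schedules* on named parameters; the
integration is segmented at every schedule breakpoint and the solver
restarted, because multistep solvers interpolate poorly across parameter
jumps.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .errors import (
    ConfigError,
    ConvergenceWarning,
    IntegrationError,
    InvalidStateError,
)
from .models import ModelDefinition

__all__ = [
    "PerturbationSchedule",
    "SimulationConfig",
    "Trajectory",
    "integrate",
    "pre_equilibrate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationSchedule:
    """Piecewise-constant time course for one named parameter.

    ``breakpoints`` is an ordered sequence of ``(time, value)`` pairs; the
    first pair applies from the simulation start, each later pair from its
    time onward.
    """

    parameter: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self):
        bps = tuple((float(t), float(v)) for t, v in self.breakpoints)
        if not bps:
            raise ConfigError("schedule needs at least one breakpoint")
        times = [t for t, _ in bps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigError(f"breakpoint times must strictly increase: {times}")
        if any(v < 0 for _, v in bps):
            raise ConfigError("schedule values must be >= 0")
        object.__setattr__(self, "breakpoints", bps)

    @classmethod
    def step(cls, parameter: str, t_step: float, phase1: float, phase2: float,
             t_start: float = 0.0) -> "PerturbationSchedule":
        """Two-phase step: ``phase1`` before ``t_step``, ``phase2`` after."""
        return cls(parameter, ((t_start, phase1), (t_step, phase2)))

    @classmethod
    def constant(cls, parameter: str, value: float,
                 t_start: float = 0.0) -> "PerturbationSchedule":
        """Constant background level."""
        return cls(parameter, ((t_start, value),))

    def value_at(self, t: float) -> float:
        times = [bt for bt, _ in self.breakpoints]
        i = bisect.bisect_right(times, t) - 1
        return self.breakpoints[max(i, 0)][1]

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.breakpoints)


@dataclass(frozen=True)
class SimulationConfig:
    """Solver and output-grid settings.

    ``dt`` is the output grid spacing (solver-interpolated, not the internal
    step).  Defaults suit the oscillatory networks; non-oscillatory runs can
    use a coarser ``dt=0.1``.
    """

    t_start: float = 0.0
    t_end: float = 100.0
    dt: float = 0.01
    rtol: float = 1e-8
    atol: float = 1e-10
    max_internal_steps: int = 10_000_000
    restart_at_breakpoints: bool = True

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ConfigError(f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")
        if self.dt <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ConfigError("dt, rtol and atol must be > 0")


@dataclass
class Trajectory:
    """Time grid + state matrix from one integration, with run metadata."""

    t: np.ndarray                     # (n,)
    y: np.ndarray                     # (n, n_species)
    species: tuple[str, ...]
    model_name: str = ""
    phases: list[dict] = field(default_factory=list)  # per-segment parameter snapshots
    breakpoints: tuple[float, ...] = ()
    config: SimulationConfig | None = None
    diagnostics: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)  # set by synthetic fixtures

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.shape != (self.t.size, len(self.species)):
            raise InvalidStateError(
                f"state matrix shape {self.y.shape} does not match "
                f"{self.t.size} times x {len(self.species)} species"
            )
        if np.any(np.diff(self.t) <= 0):
            raise InvalidStateError("trajectory times must strictly increase")

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            j = self.species.index(species)
        except ValueError:
            raise KeyError(
                f"unknown species {species!r}; have {self.species}"
            ) from None
        return self.y[:, j]

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def final_state(self) -> np.ndarray:
        return self.y[-1].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, **{s: self[s] for s in self.species}})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def metadata(self) -> dict:
        cfg = None
        if self.config is not None:
            cfg = {
                "t_start": self.config.t_start,
                "t_end": self.config.t_end,
                "dt": self.config.dt,
                "rtol": self.config.rtol,
                "atol": self.config.atol,
            }
        return {
            "model": self.model_name,
            "species": list(self.species),
            "phases": self.phases,
            "breakpoints": list(self.breakpoints),
            "solver": cfg,
            "diagnostics": self.diagnostics,
        }


def _grid(t0: float, t1: float, dt: float) -> np.ndarray:
    n = int(round((t1 - t0) / dt))
    g = t0 + dt * np.arange(n + 1)
    if g[-1] < t1 - 1e-12:
        g = np.append(g, t1)
    g[-1] = t1
    return g


def integrate(
    model: ModelDefinition,
    params,
    state0,
    schedules: Sequence[PerturbationSchedule] = (),
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Integrate ``model`` from ``state0`` under the given schedules.

    The run is split into segments at every schedule breakpoint; within a
    segment all parameters are constant and LSODA restarts fresh at each
    segment boundary.  Output is sampled on the uniform ``config.dt`` grid
    (plus the exact breakpoint times).
    """
    config = config or SimulationConfig()
    pset = model.make_params(params)
    y0 = model.validate_state(state0)

    names = set(pset.param_names())
    for s in schedules:
        if s.parameter not in names:
            raise ConfigError(
                f"schedule references unknown parameter {s.parameter!r} "
                f"for model {model.name}"
            )

    cut_times = sorted(
        {t for s in schedules for t in s.times
         if config.t_start < t < config.t_end}
    )
    seg_edges = [config.t_start, *cut_times, config.t_end]
    if not config.restart_at_breakpoints:
        seg_edges = [config.t_start, config.t_end]

    ts, ys, phases = [], [], []
    y = y0
    n_clipped = 0
    for t0, t1 in zip(seg_edges, seg_edges[1:]):
        vals = {s.parameter: s.value_at(t0) for s in schedules}
        pseg = pset.replace(**vals) if vals else pset
        pvec = pseg.to_vector()
        grid = _grid(t0, t1, config.dt)
        out, info = odeint(
            model.rhs, y, grid, args=(pvec,), tfirst=True,
            rtol=config.rtol, atol=config.atol,
            mxstep=config.max_internal_steps, full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"{model.name}: solver failed in segment [{t0}, {t1}]: "
                f"{info['message']}",
                t_fail=float(info["tcur"][-1]) if len(info["tcur"]) else t0,
            )
        # concentrations may undershoot zero by up to ~atol; clip and count
        neg = out < 0
        if neg.any():
            worst = out[neg].min()
            if worst < -100 * config.atol:
                raise IntegrationError(
                    f"{model.name}: negative concentration {worst:.3e} "
                    f"(beyond -100*atol) in segment [{t0}, {t1}]", t_fail=t0
                )
            n_clipped += int(neg.sum())
            out = np.clip(out, 0.0, None)
        y = out[-1]
        if ts:
            out = out[1:]
            grid = grid[1:]
        ts.append(grid)
        ys.append(out)
        phases.append({"t_start": t0, "t_end": t1, "params": pseg.to_dict()})

    t = np.concatenate(ts)
    yy = np.vstack(ys)
    if n_clipped:
        log.info("clipped %d negative output values to 0", n_clipped)
    return Trajectory(
        t=t, y=yy, species=model.species, model_name=model.name,
        phases=phases, breakpoints=tuple(cut_times), config=config,
        diagnostics={"n_clipped_negative": n_clipped,
                     "n_segments": len(seg_edges) - 1},
    )


def _rhs_scale(model, y, pvec) -> float:
    dy = model.rhs(0.0, np.asarray(y, float), pvec)
    return float(np.max(np.abs(dy) / (1.0 + np.abs(y))))


def pre_equilibrate(
    model: ModelDefinition,
    params,
    state0_guess,
    config: SimulationConfig | None = None,
    *,
    residual_tol: float = 1e-5,
    period_tol: float = 1e-3,
    chunk: float = 200.0,
    max_chunks: int = 50,
) -> tuple[np.ndarray, dict]:
    """Relax ``state0_guess`` onto the attractor of the (fixed) parameter set.

    Non-oscillatory models: integrates in chunks until the scaled residual
    ``max |dy_i/dt| / (1+|y_i|)`` drops below ``residual_tol``.

    Oscillatory models: integrates until the per-cycle period of ``A`` varies
    by less than ``period_tol`` (0.1 %) between consecutive cycles, then
    returns the state *at a cycle peak* of ``A``, so that callers start from
    a well-defined oscillation phase.  Returns ``(state, info)`` where info
    carries the final residual or period.
    """
    from .analysis import detect_cycles  # deferred: avoids an import cycle

    config = config or SimulationConfig(
        t_end=chunk, dt=0.01 if model.oscillatory else 0.1
    )
    pset = model.make_params(params)
    pvec = pset.to_vector()
    y = model.validate_state(state0_guess)

    if not model.oscillatory:
        span = chunk
        for i in range(max_chunks):
            res = _rhs_scale(model, y, pvec)
            if res < residual_tol:
                return y, {"residual": res, "chunks": i, "mode": "steady"}
            traj = integrate(model, pset, y,
                            config=SimulationConfig(
                                t_end=span, dt=config.dt,
                                rtol=config.rtol, atol=config.atol))
            y = traj.final_state()
            span = min(span * 1.5, 2000.0)  # slow controller modes
        res = _rhs_scale(model, y, pvec)
        raise IntegrationError(
            f"{model.name}: pre-equilibration did not reach residual "
            f"{residual_tol:g} within {max_chunks} chunks (final {res:.3e})"
        )

    # oscillatory: look for a stable cycle in successive chunks; a damped
    # regime that reaches a fixed point instead is returned in steady mode
    for i in range(max_chunks):
        traj = integrate(model, pset, y,
                        config=SimulationConfig(
                            t_end=chunk, dt=config.dt,
                            rtol=config.rtol, atol=config.atol))
        y = traj.final_state()
        cycles = detect_cycles(traj, "A")
        if len(cycles) >= 3:
            per = cycles.periods
            drift = abs(per[-1] - per[-2]) / per[-1]
            if drift < period_tol:
                # re-land exactly on the last interpolated peak
                t_pk = cycles.peak_times[-1]
                j = int(np.searchsorted(traj.t, t_pk)) - 1
                seg = odeint(
                    model.rhs, traj.y[j], [traj.t[j], t_pk], args=(pvec,),
                    tfirst=True, rtol=min(config.rtol, 1e-10),
                    atol=min(config.atol, 1e-12),
                    mxstep=config.max_internal_steps,
                )
                return np.clip(seg[-1], 0.0, None), {
                    "period": float(per[-1]),
                    "period_drift": float(drift),
                    "chunks": i + 1,
                    "mode": "limit_cycle",
                }
        else:
            res = _rhs_scale(model, y, pvec)
            if res < residual_tol:
                return y, {"residual": res, "chunks": i + 1, "mode": "steady"}
    raise IntegrationError(
        f"{model.name}: no stable cycle (or fixed point) found within "
        f"{max_chunks} chunks of {chunk} time units "
        f"(period drift tolerance {period_tol:g})"
    )
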