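"""Synthetic trajectories and sweep tables with known ground truth.

These generators exercise the analysis operators (running averages, cycle
detection, response amplitudes, compensation verdicts) independently of the
ODE engine: every signal carries its programmed period, excursion and mean
as a ``ground_truth`` record.  The homeostat pipeline itself is noise-free;
the optional additive Gaussian noise exists purely to stress-test the
detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .simulate import Trajectory

__all__ = ["SyntheticSignalSpec", "make_signal", "make_sweep_fixture"]

_KINDS = ("constant", "ramp", "sinusoid", "damped_sinusoid", "step_relaxation")


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """Closed-form waveform description.

    ``kind`` selects the waveform; ``offset`` is the baseline, ``amplitude``
    the oscillation amplitude (or ramp slope, or step excursion), ``period``
    the oscillation period, ``decay`` an exponential amplitude decay rate,
    ``t_step`` the onset of the step-relaxation excursion.  ``noise``
    (standard deviation, default 0) adds seeded Gaussian noise.
    """

    kind: str = "sinusoid"
    amplitude: float = 1.0
    period: float = 5.0
    decay: float = 0.0
    offset: float = 0.0
    t_step: float = 0.0
    dt: float = 0.01
    horizon: float = 100.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown waveform {self.kind!r}; have {_KINDS}")
        if self.dt <= 0 or self.horizon <= self.dt:
            raise ConfigError("need dt > 0 and horizon > dt")
        if self.kind in ("sinusoid", "damped_sinusoid"):
            if self.period <= 0:
                raise ConfigError("oscillatory signals need period > 0")
            if self.dt >= self.period / 20:
                raise ConfigError(
                    f"sampling interval {self.dt} too coarse for period "
                    f"{self.period}: need >= 20 samples per period"
                )


def make_signal(spec: SyntheticSignalSpec) -> Trajectory:
    """Generate the waveform as a single-species trajectory named ``A``.

    The returned trajectory's ``ground_truth`` dict records the programmed
    period, mean, and (for step-relaxation) the excursion ``delta_A``.
    """
    t = np.arange(0.0, spec.horizon + spec.dt / 2, spec.dt)
    truth: dict = {"kind": spec.kind, "offset": spec.offset}
    if spec.kind == "constant":
        x = np.full_like(t, spec.offset)
        truth["mean"] = spec.offset
    elif spec.kind == "ramp":
        x = spec.offset + spec.amplitude * t
        truth["mean_at_end"] = spec.offset + spec.amplitude * spec.horizon / 2
    elif spec.kind == "sinusoid":
        x = spec.offset + spec.amplitude * np.sin(2 * np.pi * t / spec.period)
        truth.update(period=spec.period, frequency=1.0 / spec.period,
                     mean=spec.offset)
    elif spec.kind == "damped_sinusoid":
        envelope = spec.amplitude * np.exp(-spec.decay * t)
        x = spec.offset + envelope * np.sin(2 * np.pi * t / spec.period)
        truth.update(period=spec.period, frequency=1.0 / spec.period,
                     decay=spec.decay, mean=spec.offset)
    elif spec.kind == "step_relaxation":
        x = np.full_like(t, spec.offset)
        post = t >= spec.t_step
        x[post] = spec.offset - spec.amplitude * np.exp(
            -spec.decay * (t[post] - spec.t_step))
        truth.update(delta_A=abs(spec.amplitude), t_step=spec.t_step,
                     pre_step_value=spec.offset)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise, size=t.shape)
    traj = Trajectory(t=t, y=x[:, None], species=("A",),
                      model_name=f"synthetic:{spec.kind}")
    traj.ground_truth = truth
    return traj


def make_sweep_fixture(compensated: bool, n_backgrounds: int = 4,
                       n_steps: int = 5, spread: float = 0.1,
                       base_frequency: float = 0.2,
                       slope: float = 0.05):
    """Synthetic sweep table for testing the compensation verdict both ways.

    ``compensated=True`` produces background-invariant max frequencies
    (spread exactly 0); otherwise the statistic degrades linearly with the
    background index so the fractional spread within each step column equals
    ``spread`` and decreases monotonically with background.  Returns a table
    in the ``run_sweep`` column layout.
    """
    if n_backgrounds < 2 or n_steps < 2:
        raise ConfigError("need at least 2 backgrounds and 2 steps")
    from .experiments import SweepTable

    rows = []
    backgrounds = [float(2 ** i) for i in range(n_backgrounds)]
    for j in range(n_steps):
        step = 2.0 + j
        base = base_frequency + slope * j
        for i, bg in enumerate(backgrounds):
            f = base if compensated else base * (1.0 - spread * i / (n_backgrounds - 1))
            rows.append({"background": bg, "phase2_value": step,
                         "abscissa": step + bg, "max_frequency": f,
                         "delta_A": np.nan, "status": "ok"})
    return SweepTable(frame=pd.DataFrame(rows))
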