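"""Trapezoidal diffusion-encoding waveforms (effective gradient after the
refocusing pulse) and their integral properties.

Two encoding shapes are supported, both filling the diffusion time ``T``:

* ``beta = 0`` (bipolar / velocity-sensitive): a positive trapezoidal lobe on
  ``[0, T/2]`` followed by a negative lobe on ``[T/2, T]``.  The spin-phase
  moment ``q(t)`` rises and returns to zero; the first moment is non-zero, so
  the waveform is sensitive to constant-velocity flow.
* ``beta = 1`` (flow-compensated): four lobes ``+, -, -, +`` of duration
  ``T/4`` each.  The pattern is symmetric under ``t -> T - t`` which nulls the
  first gradient moment exactly, removing sensitivity to constant velocity.

Ramps use the full slew rate (ramp time ``g / slew_max``).  Waveform samples
are stored as exact cell averages of the ideal piecewise-linear gradient, so
cumulative sums reproduce ``q`` exactly at cell edges and moment cancellations
hold to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hardware import (
    DEFAULT_HARDWARE,
    HardwareLimits,
    InfeasibleWaveformError,
)

#: Default waveform time step, ms (10 us).
DT_MS = 0.01


def _lobe_breakpoints(t0: float, dur: float, amp: float, ramp: float):
    """Breakpoints of one trapezoidal lobe starting at ``t0`` (ms, mT/m)."""
    if 2.0 * ramp > dur:
        # triangle lobe: slew-limited, peak reduced
        peak = np.sign(amp) * (dur / 2.0) * abs(amp) / ramp if ramp > 0 else amp
        return [(t0, 0.0), (t0 + dur / 2.0, peak), (t0 + dur, 0.0)]
    return [
        (t0, 0.0),
        (t0 + ramp, amp),
        (t0 + dur - ramp, amp),
        (t0 + dur, 0.0),
    ]


def _breakpoints(beta: int, T: float, g: float, slew: float):
    """Piecewise-linear breakpoints of the full waveform."""
    ramp = g / slew
    if beta == 0:
        lobes = [(0.0, T / 2.0, g), (T / 2.0, T / 2.0, -g)]
    elif beta == 1:
        q = T / 4.0
        lobes = [(0.0, q, g), (q, q, -g), (2 * q, q, -g), (3 * q, q, g)]
    else:
        raise ValueError("beta must be 0 (bipolar) or 1 (flow-compensated)")
    ts, gs = [], []
    for t0, dur, amp in lobes:
        for t, val in _lobe_breakpoints(t0, dur, amp, ramp):
            ts.append(t)
            gs.append(val)
    return np.asarray(ts), np.asarray(gs)


def _antiderivative_at(ts, gs, t):
    """Evaluate P(t) = int_0^t G dt' for piecewise-linear G, exactly.

    ``ts``/``gs`` are breakpoints (G linear between them); ``t`` may be an
    array.  Units: ms and mT/m in -> mT/m*ms out.
    """
    seg_areas = 0.5 * (gs[1:] + gs[:-1]) * np.diff(ts)
    P_break = np.concatenate([[0.0], np.cumsum(seg_areas)])
    idx = np.clip(np.searchsorted(ts, t, side="right") - 1, 0, len(ts) - 2)
    h = t - ts[idx]
    dt_seg = ts[idx + 1] - ts[idx]
    slope = np.where(dt_seg > 0, (gs[idx + 1] - gs[idx]) / np.where(dt_seg > 0, dt_seg, 1.0), 0.0)
    return P_break[idx] + gs[idx] * h + 0.5 * slope * h * h


@dataclass
class Waveform:
    """Discretized effective diffusion gradient.

    Attributes
    ----------
    beta : int
        Gradient shape flag: 0 bipolar, 1 flow-compensated.
    T : float
        Diffusion time, ms.
    dt : float
        Sample spacing, ms.
    samples : np.ndarray
        Cell-average gradient amplitude per time step, mT/m.
    g_amp : float
        Peak lobe amplitude, mT/m.
    b : float
        Diffusion weighting, s/mm^2 (gamma^2 * int q^2 dt).
    m1 : float
        First-moment phase sensitivity int_0^T q(t) dt in SI (s/m, times
        gamma's rad): the phase accrued by a spin at constant unit velocity
        (1 m/s) is ``-m1`` rad.
    """

    beta: int
    T: float
    dt: float
    samples: np.ndarray
    g_amp: float
    gamma: float
    b: float = field(init=False)
    m1: float = field(init=False)

    def __post_init__(self) -> None:
        self.t_edges_s, self.q_edges, self.Iq = _q_of_samples(
            self.samples, self.dt, self.gamma
        )
        self.b = b_from_samples(self.samples, self.dt, self.gamma)
        self.m1 = m1_from_samples(self.samples, self.dt, self.gamma)

    @property
    def times(self) -> np.ndarray:
        """Sample-center times, ms."""
        return (np.arange(self.samples.size) + 0.5) * self.dt

    def to_csv(self, path) -> None:
        """Write two-column CSV (time_ms, g_mT_per_m)."""
        import pandas as pd

        pd.DataFrame({"time_ms": self.times, "g_mT_per_m": self.samples}).to_csv(
            path, index=False
        )


def _q_of_samples(samples: np.ndarray, dt: float, gamma: float):
    """q(t) = gamma * int G dt' at cell edges (rad/m), plus its running integral.

    Returns (edge times s, q at edges rad/m, Iq(t)=int_0^t q dt' at edges rad*s/m).
    """
    dt_s = dt * 1e-3
    g_si = samples * 1e-3  # mT/m -> T/m
    q = gamma * np.concatenate([[0.0], np.cumsum(g_si)]) * dt_s
    t_edges = np.arange(q.size) * dt_s
    Iq = np.concatenate([[0.0], np.cumsum(0.5 * (q[1:] + q[:-1]) * dt_s)])
    return t_edges, q, Iq


def b_from_samples(samples: np.ndarray, dt: float, gamma: float = DEFAULT_HARDWARE.gamma) -> float:
    """Recompute b = int q(t)^2 dt from gradient samples; returns s/mm^2."""
    _, q, _ = _q_of_samples(samples, dt, gamma)
    b_si = np.trapezoid(q * q, dx=dt * 1e-3)  # s/m^2
    return b_si * 1e-6


def m1_from_samples(samples: np.ndarray, dt: float, gamma: float = DEFAULT_HARDWARE.gamma) -> float:
    """Recompute m1 = int q(t) dt (SI, rad*s/m) from gradient samples."""
    _, q, _ = _q_of_samples(samples, dt, gamma)
    return float(np.trapezoid(q, dx=dt * 1e-3))


def _samples_for(beta: int, T: float, g: float, hw: HardwareLimits, dt: float) -> np.ndarray:
    ts, gs = _breakpoints(beta, T, g, hw.slew_max)
    n = int(round(T / dt))
    edges = np.arange(n + 1) * dt
    P = _antiderivative_at(ts, gs, edges)
    return np.diff(P) / dt


def _b_at_amplitude(beta: int, T: float, g: float, hw: HardwareLimits, dt: float) -> float:
    return b_from_samples(_samples_for(beta, T, g, hw, dt), dt, hw.gamma)


def max_b(
    beta: int,
    T: float,
    hw: HardwareLimits = DEFAULT_HARDWARE,
    dt: float = DT_MS,
) -> float:
    """Largest achievable b-value (s/mm^2) at full gradient amplitude."""
    hw.check_T(T)
    return _b_at_amplitude(beta, T, hw.g_max, hw, dt)


def build_waveform(
    beta: int,
    T: float,
    target_b: float,
    hw: HardwareLimits = DEFAULT_HARDWARE,
    dt: float = DT_MS,
) -> Waveform:
    """Construct a waveform hitting ``target_b`` (s/mm^2) at diffusion time ``T``.

    The lobe amplitude is solved so the recomputed b matches ``target_b`` to
    well within 0.1%.  Raises :class:`InfeasibleWaveformError` if the target
    exceeds what full amplitude achieves, and
    :class:`DiffusionTimeRangeError` for T outside the hardware range.
    """
    hw.check_T(T)
    if target_b < 0:
        raise ValueError("target_b must be non-negative")
    n = int(round(T / dt))
    if target_b == 0:
        return Waveform(beta, T, dt, np.zeros(n), 0.0, hw.gamma)
    bmax = _b_at_amplitude(beta, T, hw.g_max, hw, dt)
    if target_b > bmax * (1.0 + 1e-9):
        raise InfeasibleWaveformError(
            f"target b={target_b} s/mm^2 exceeds max_b={bmax:.1f} at "
            f"beta={beta}, T={T} ms"
        )
    if abs(target_b - bmax) <= 1e-9 * bmax:
        g = hw.g_max
    else:
        g = brentq(
            lambda gg: _b_at_amplitude(beta, T, gg, hw, dt) - target_b,
            1e-9 * hw.g_max,
            hw.g_max,
            xtol=1e-12 * hw.g_max,
            rtol=8.9e-16,
        )
    return Waveform(beta, T, dt, _samples_for(beta, T, g, hw, dt), g, hw.gamma)
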