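"""Simplified sinoatrial membrane model, pulse energetics and pacing actuator.

The sinoatrial cell membrane is reduced to a parallel RC circuit,
``Cm * dV/dt + V/Rm = Iapp``, advanced with the exact exponential update (the
closed-form solution of the linear ODE, so the step size only limits temporal
resolution, not accuracy).  The pacing pulse dissipates
``E = d * Vpulse^2 / Rpulse`` per pulse of duration ``d``.

The actuation convention: the controller's command variable is the pacing
*period* ``d`` (s) — the printed duration/rate pairs (0.49 s <-> 122 bpm,
0.79 s <-> 76 bpm, ...) all satisfy ``rate = 60 / d`` to rounding, so the
paced heart rate is ``60 / d`` and the fixed 0.094 s recovery delay is the
intra-beat stimulus width.  The controller output ``u`` acts in velocity
form: each update decrements the commanded period by
``slew_ms_per_unit * u`` milliseconds, clipped to the actuator range, giving
the loop integral action (zero steady-state tracking error).  The rate
sensor optionally relaxes toward ``60 / d`` with a first-order lag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("ifpace")

__all__ = [
    "MembraneParams",
    "PulseParams",
    "HeartState",
    "membrane_step",
    "pulse_energy",
    "rate_from_duration",
    "duration_from_rate",
    "apply_command",
    "generate_pulse_train",
    "plant_waveform",
]


@dataclass(frozen=True)
class MembraneParams:
    """RC membrane: capacitance ``cm`` (uF/cm^2) and resistance ``rm`` (Ohm)."""

    cm: float = 1.0
    rm: float = 20.0

    def __post_init__(self) -> None:
        if self.cm <= 0 or self.rm <= 0:
            raise ValueError(
                f"membrane parameters must be positive: cm={self.cm}, rm={self.rm}"
            )


@dataclass(frozen=True)
class PulseParams:
    """Stimulus-path electrical constants and actuator limits.

    ``r_pulse`` (Ohm) and ``v_pulse`` (mV) set the per-pulse energy;
    ``amplitude`` (mA) is the constant stimulus current; ``beat_delay`` (s)
    is the per-beat recovery delay, used as the intra-beat pulse width;
    ``d_min``/``d_max`` (s) bound the commanded pacing period
    (0.3–1.2 s <-> 200–50 bpm); ``slew_ms_per_unit`` converts one unit of
    controller output into milliseconds of period change per update.
    """

    r_pulse: float = 601.0
    v_pulse: float = 197.8
    amplitude: float = 0.165
    beat_delay: float = 0.094
    d_min: float = 0.3
    d_max: float = 1.2
    slew_ms_per_unit: float = 20.0

    def __post_init__(self) -> None:
        if self.r_pulse <= 0:
            raise ValueError(f"r_pulse must be positive, got {self.r_pulse}")
        if not 0 < self.d_min < self.d_max:
            raise ValueError(
                f"need 0 < d_min < d_max, got {self.d_min}, {self.d_max}"
            )
        if self.slew_ms_per_unit <= 0:
            raise ValueError("slew_ms_per_unit must be positive")


@dataclass(frozen=True)
class HeartState:
    """Paced-heart state: membrane potential ``v`` (mV, diagnostic only),
    measured heart rate ``hr`` (bpm) and commanded pacing period ``d`` (s)."""

    hr: float
    d: float
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError(f"heart rate must be positive, got {self.hr}")


def membrane_step(v: float, i_app: float, p: MembraneParams, dt: float) -> float:
    """Advance the RC membrane one step under constant applied current.

    Uses the exact exponential solution
    ``V' = Iapp*Rm + (V - Iapp*Rm) * exp(-dt / (Rm*Cm))``, so a single step
    of size T equals any refinement into sub-steps.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    v_inf = i_app * p.rm
    return v_inf + (v - v_inf) * math.exp(-dt / (p.rm * p.cm))


def pulse_energy(d: float, p: PulseParams = PulseParams()) -> float:
    """Energy (J) delivered by one pulse of duration ``d`` s:
    ``E = d * Vpulse^2 / Rpulse`` with ``Vpulse`` in volts."""
    if d < 0:
        raise ValueError(f"pulse duration must be non-negative, got {d}")
    v_volts = p.v_pulse / 1000.0
    return d * v_volts * v_volts / p.r_pulse


def rate_from_duration(d: float, p: PulseParams = PulseParams()) -> float:
    """Paced heart rate (bpm) for a commanded period ``d`` s: ``60 / d``,
    strictly decreasing on the actuator range.  Out-of-range commands are
    clipped and logged."""
    if not p.d_min <= d <= p.d_max:
        logger.warning(
            "pulse duration %.4f s outside [%.2f, %.2f]; clipped",
            d, p.d_min, p.d_max,
        )
        d = max(p.d_min, min(p.d_max, d))
    return 60.0 / d


def duration_from_rate(hr: float, p: PulseParams = PulseParams()) -> float:
    """Inverse of :func:`rate_from_duration`, clipped to the actuator range."""
    if hr <= 0:
        raise ValueError(f"heart rate must be positive, got {hr}")
    return max(p.d_min, min(p.d_max, 60.0 / hr))


def apply_command(
    state: HeartState,
    u: float,
    p: PulseParams = PulseParams(),
    sensor_tau: float = 0.0,
    dt: float = 0.05,
) -> HeartState:
    """One actuation update for controller output ``u``.

    Velocity form: ``d' = clip(d - slew_ms_per_unit * u / 1000, d_min, d_max)``
    — positive error gives positive ``u``, a shorter period and a higher
    paced rate.  The measured rate then relaxes toward ``60 / d'`` with the
    exact first-order lag ``sensor_tau`` (0 disables the lag).
    """
    d_new = state.d - p.slew_ms_per_unit * u / 1000.0
    d_new = max(p.d_min, min(p.d_max, d_new))
    target = 60.0 / d_new
    if sensor_tau > 0.0:
        hr_new = target + (state.hr - target) * math.exp(-dt / sensor_tau)
    else:
        hr_new = target
    return replace(state, hr=hr_new, d=d_new)


def generate_pulse_train(
    d: float,
    p: PulseParams = PulseParams(),
    horizon: float = 2.0,
    dt: float = 0.001,
) -> pd.DataFrame:
    """Sampled rectangular stimulus train at pacing period ``d``.

    Each beat delivers one pulse of width ``beat_delay`` with constant
    current amplitude, alternating polarity beat to beat (charge-balanced
    pacing); the pulse voltage follows the same pattern.  Duty cycle is
    ``beat_delay / d``.  Columns: ``time`` (s), ``current_ma``, ``voltage_mv``.
    """
    if horizon < d:
        raise ValueError(f"horizon {horizon} must cover the period {d}")
    t = np.arange(int(round(horizon / dt))) * dt
    phase = np.mod(t, d)
    beat = np.floor(t / d).astype(int)
    on = phase < p.beat_delay
    sign = np.where(beat % 2 == 0, 1.0, -1.0)
    current = np.where(on, sign * p.amplitude, 0.0)
    voltage = np.where(on, sign * p.v_pulse, 0.0)
    return pd.DataFrame({"time": t, "current_ma": current, "voltage_mv": voltage})


def plant_waveform(
    d: float,
    mp: MembraneParams = MembraneParams(),
    pp: PulseParams = PulseParams(),
    horizon: float = 2.0,
    dt: float = 0.001,
) -> pd.DataFrame:
    """Diagnostic membrane trace under a constant-period pulse train.

    Drives :func:`membrane_step` with the stimulus current and returns
    columns ``time, V, Iapp, hr, d`` (CSV-exportable).  The membrane trace
    is illustrative only; it does not feed back into the paced rate.
    """
    train = generate_pulse_train(d, pp, horizon, dt)
    v = 0.0
    vs = np.empty(len(train))
    for i, i_app in enumerate(train["current_ma"].to_numpy()):
        v = membrane_step(v, i_app, mp, dt)
        vs[i] = v
    return pd.DataFrame({
        "time": train["time"],
        "V": vs,
        "Iapp": train["current_ma"],
        "hr": np.full(len(train), 60.0 / d),
        "d": np.full(len(train), d),
    })
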