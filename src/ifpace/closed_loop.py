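"""Closed-loop pacing simulation, patient scenarios and tracking metrics.

Six built-in patient scenarios give the preset (desired) heart rates, with
tolerance bands, for three daily activities — rest, walking, jogging.  The
simulation driver closes the loop: at every control update the normalized
tracking error ``(ref - measured) / hr_span`` (clipped to [-1, 1]) feeds the
intuitionistic fuzzy controller, whose output moves the commanded pacing
period; the paced rate is read back through the rate sensor.

Tracking quality is summarized by the RMSE (bpm) and the maximum error as a
percentage of the preset, both over a configurable evaluation window.  The
default window is the steady-state window — the final half of each activity
segment — because the transient entry into the tolerance band is dominated
by the (arbitrary) initial condition, while steady behaviour is what the
pacing metrics are meant to grade.  Band-entry ("settled") and full-trace
windows are also available, and the settle time (first sustained entry into
the tolerance band) is always reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .iflc import ControllerConfig, ControllerState, RuleBase, controller_step
from .ifs_core import TermSet
from .pacemaker_plant import (
    HeartState,
    MembraneParams,
    PulseParams,
    apply_command,
    duration_from_rate,
    pulse_energy,
)

logger = logging.getLogger("ifpace")

__all__ = [
    "ACTIVITIES",
    "PatientScenario",
    "ActivityProfile",
    "SimulationTrace",
    "Metrics",
    "DivergenceError",
    "builtin_scenarios",
    "random_scenario",
    "run_simulation",
    "compute_rmse",
    "compute_max_error_pct",
    "compute_metrics",
    "evaluate_all",
    "reference_results",
]

ACTIVITIES = ("rest", "walking", "jogging")

TRACE_COLUMNS = (
    "time", "ref_hr", "measured_hr", "error_norm", "u", "d", "pulse_energy_j",
)

#: default evaluation-window conventions
STEADY_FRACTION = 0.5


class DivergenceError(RuntimeError):
    """Raised when the tracking error stays saturated for too long."""


@dataclass(frozen=True)
class PatientScenario:
    """Preset heart rates, with tolerance bands, per activity."""

    label: str
    sex: str
    age: int
    preset: Mapping[str, Tuple[float, float]]  # activity -> (target bpm, +/- bpm)

    def __post_init__(self) -> None:
        for act, (target, tol) in self.preset.items():
            if not 40.0 <= target <= 220.0:
                raise ValueError(
                    f"{self.label}/{act}: target {target} bpm outside [40, 220]"
                )
            if tol <= 0:
                raise ValueError(f"{self.label}/{act}: tolerance must be positive")

    def target(self, activity: str) -> float:
        return self.preset[activity][0]

    def tolerance(self, activity: str) -> float:
        return self.preset[activity][1]


@dataclass(frozen=True)
class ActivityProfile:
    """Piecewise-constant reference schedule: (activity, duration s) pairs."""

    schedule: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must not be empty")
        for act, dur in self.schedule:
            if dur <= 0:
                raise ValueError(f"segment {act!r} has non-positive duration {dur}")

    @classmethod
    def single(cls, activity: str, duration: float = 60.0) -> "ActivityProfile":
        return cls(schedule=((activity, duration),))

    @classmethod
    def daily(cls, duration: float = 60.0) -> "ActivityProfile":
        """Rest -> walking -> jogging, equal segment lengths."""
        return cls(schedule=tuple((a, duration) for a in ACTIVITIES))

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.schedule)


@dataclass(frozen=True)
class SimulationTrace:
    """Time-indexed closed-loop record, one row per control update.

    Columns: ``time`` (s), ``ref_hr`` and ``measured_hr`` (bpm), the
    normalized error fed to the controller, the controller output ``u``, the
    commanded pacing period ``d`` (s) and the per-pulse energy (J).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trace is missing columns {missing}")
        t = self.frame["time"].to_numpy()
        if len(t) == 0:
            raise ValueError("trace must contain at least one row")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.frame[column].to_numpy()


@dataclass(frozen=True)
class Metrics:
    """Tracking summary: RMSE (bpm), maximum error (% of preset), settle
    time (s; inf if the band is never held) and mean steady pacing period (s)."""

    rmse: float
    max_error_pct: float
    settle_time: float
    steady_duration: float

    def __post_init__(self) -> None:
        for name in ("rmse", "max_error_pct", "settle_time", "steady_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

_TABLE2 = (
    ("case1", "F", 66, (81, 5), (94, 5), (107, 5)),
    ("case2", "M", 54, (89, 5), (98, 5), (113, 5)),
    ("case3", "M", 48, (90, 5), (100, 5), (120, 5)),
    ("case4", "F", 45, (92, 5), (103, 5), (122, 5)),
    ("case5", "F", 58, (85, 6), (92, 4), (103, 3)),
    ("case6", "M", 62, (80, 5), (94, 5), (108, 4)),
)


def builtin_scenarios() -> List[PatientScenario]:
    """The six built-in patient scenarios (preset rates per activity)."""
    return [
        PatientScenario(
            label=label, sex=sex, age=age,
            preset={
                "rest": (float(r[0]), float(r[1])),
                "walking": (float(w[0]), float(w[1])),
                "jogging": (float(j[0]), float(j[1])),
            },
        )
        for label, sex, age, r, w, j in _TABLE2
    ]


DEFAULT_BANDS: Dict[str, Tuple[float, float]] = {
    "rest": (70.0, 95.0),
    "walking": (90.0, 110.0),
    "jogging": (100.0, 130.0),
}


def random_scenario(
    seed: int,
    bands: Mapping[str, Tuple[float, float]] = None,
    tolerance: float = 5.0,
) -> PatientScenario:
    """Draw a synthetic scenario with uniform presets inside physiological
    bands (reproducible from ``seed``)."""
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    lows = [bands[a][0] for a in ACTIVITIES]
    highs = [bands[a][1] for a in ACTIVITIES]
    if not (all(a < b for a, b in zip(lows, lows[1:]))
            and all(a < b for a, b in zip(highs, highs[1:]))):
        raise ValueError(f"bands must be ordered rest < walking < jogging: {bands}")
    rng = np.random.default_rng(seed)
    preset = {
        act: (float(np.round(rng.uniform(*bands[act]))), tolerance)
        for act in ACTIVITIES
    }
    return PatientScenario(
        label=f"random-{seed}", sex="?", age=0, preset=preset,
    )


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def run_simulation(
    scn: PatientScenario,
    prof: ActivityProfile,
    cfg: ControllerConfig = ControllerConfig(),
    mp: MembraneParams = MembraneParams(),
    pp: PulseParams = PulseParams(),
    dt: float = 0.05,
    sensor_tau: float = 1.5,
    noise_std: float = 0.0,
    hr_span: float = 60.0,
    initial_hr_offset: float = -15.0,
    seed: int = 0,
    rb: RuleBase = None,
    terms: TermSet = None,
    saturation_limit_s: float = 30.0,
) -> SimulationTrace:
    """Run the closed loop over an activity profile.

    Initial condition: the measured rate starts ``initial_hr_offset`` bpm
    away from the first segment's preset (bradycardic onset by default) and
    the commanded period starts consistent with that rate.  Deterministic
    for a given seed (the seed only drives optional sensor noise).

    Raises :class:`DivergenceError` if the normalized error stays saturated
    at the universe edge for longer than ``saturation_limit_s``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    for act, _ in prof.schedule:
        if act not in scn.preset:
            raise ValueError(f"profile activity {act!r} not in scenario presets")
    rb = RuleBase() if rb is None else rb
    terms = TermSet.default() if terms is None else terms
    rng = np.random.default_rng(seed)

    hr0 = scn.target(prof.schedule[0][0]) + initial_hr_offset
    heart = HeartState(hr=hr0, d=duration_from_rate(hr0, pp))
    state = ControllerState()

    rows = []
    t = 0.0
    saturated_for = 0.0
    for activity, duration in prof.schedule:
        ref = scn.target(activity)
        n_steps = int(round(duration / dt))
        for _ in range(n_steps):
            measured = heart.hr
            if noise_std > 0.0:
                measured += rng.normal(0.0, noise_std)
            e = (ref - measured) / hr_span
            e = max(-1.0, min(1.0, e))
            saturated_for = saturated_for + dt if abs(e) >= 1.0 else 0.0
            if saturated_for > saturation_limit_s:
                raise DivergenceError(
                    f"tracking error saturated for {saturated_for:.1f} s at "
                    f"t={t:.1f} s ({scn.label}/{activity}, ref {ref} bpm, "
                    f"measured {measured:.1f} bpm)"
                )
            u, state = controller_step(e, state, cfg, rb, terms)
            heart = apply_command(heart, u, pp, sensor_tau, dt)
            rows.append(
                (t, ref, measured, e, u, heart.d, pulse_energy(heart.d, pp))
            )
            t += dt
    frame = pd.DataFrame(rows, columns=list(TRACE_COLUMNS))
    return SimulationTrace(frame=frame)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _window_mask(
    trace: SimulationTrace,
    window: str,
    tol: Optional[float] = None,
    steady_fraction: float = STEADY_FRACTION,
) -> np.ndarray:
    """Boolean evaluation-window mask over the trace rows.

    ``"full"`` — every row; ``"steady"`` — the final ``steady_fraction`` of
    the trace; ``"settled"`` — from the first row after which the response
    remains inside the ± ``tol`` band for the rest of the trace.
    """
    n = len(trace)
    if isinstance(window, np.ndarray):
        return window
    if window == "full":
        return np.ones(n, dtype=bool)
    if window == "steady":
        mask = np.zeros(n, dtype=bool)
        mask[int(math.floor(n * (1.0 - steady_fraction))):] = True
        return mask
    if window == "settled":
        if tol is None:
            raise ValueError("the 'settled' window needs a tolerance")
        idx = settle_index(trace, tol)
        mask = np.zeros(n, dtype=bool)
        if idx is not None:
            mask[idx:] = True
        return mask
    raise ValueError(f"unknown window {window!r}")


def settle_index(trace: SimulationTrace, tol: float) -> Optional[int]:
    """First row index after which |ref - measured| stays within ``tol``."""
    err = np.abs(trace["ref_hr"] - trace["measured_hr"])
    inside = err <= tol
    if not inside[-1]:
        return None
    # last index that is outside the band, +1
    outside = np.nonzero(~inside)[0]
    return 0 if len(outside) == 0 else int(outside[-1]) + 1


def compute_rmse(
    trace: SimulationTrace,
    window: str = "steady",
    tol: Optional[float] = None,
) -> float:
    """Root-mean-square tracking error (bpm) over the evaluation window."""
    mask = _window_mask(trace, window, tol)
    if not mask.any():
        raise ValueError("evaluation window is empty")
    err = trace["ref_hr"][mask] - trace["measured_hr"][mask]
    return float(np.sqrt(np.mean(err * err)))


def compute_max_error_pct(
    trace: SimulationTrace,
    preset: float,
    window: str = "steady",
    tol: Optional[float] = None,
) -> float:
    """Maximum |ref - measured| over the window, as a percent of ``preset``."""
    if preset <= 0:
        raise ValueError(f"preset must be positive, got {preset}")
    mask = _window_mask(trace, window, tol)
    if not mask.any():
        raise ValueError("evaluation window is empty")
    err = np.abs(trace["ref_hr"][mask] - trace["measured_hr"][mask])
    return float(np.max(err) / preset * 100.0)


def compute_metrics(
    trace: SimulationTrace,
    preset: float,
    tol: float,
    window: str = "steady",
) -> Metrics:
    """Summary metrics for one activity segment."""
    idx = settle_index(trace, tol)
    time = trace["time"]
    dt = time[1] - time[0] if len(time) > 1 else 0.0
    settle_time = math.inf if idx is None else float(time[idx] - time[0])
    mask = _window_mask(trace, window, tol)
    steady_d = float(np.mean(trace["d"][mask])) if mask.any() else math.nan
    return Metrics(
        rmse=compute_rmse(trace, window, tol),
        max_error_pct=compute_max_error_pct(trace, preset, window, tol),
        settle_time=settle_time,
        steady_duration=steady_d,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def evaluate_all(
    scenarios: Sequence[PatientScenario] = None,
    variants: Mapping[str, ControllerConfig] = None,
    activities: Sequence[str] = ACTIVITIES,
    segment_s: float = 60.0,
    window: str = "steady",
    **sim_kwargs,
) -> pd.DataFrame:
    """Per scenario x activity x controller-variant tracking report.

    Default variants: the intuitionistic controller with its default
    hesitancy weight, and the ``sigma_c = 0`` classical-fuzzy degenerate
    baseline.  Returns a DataFrame with columns
    ``controller, case, activity, rmse_bpm, max_error_pct``.
    """
    scenarios = builtin_scenarios() if scenarios is None else scenarios
    if variants is None:
        variants = {
            "IFLC": ControllerConfig(),
            "classical_fuzzy_sigma0": ControllerConfig(sigma_c=0.0),
        }
    rows = []
    for name, cfg in variants.items():
        for scn in scenarios:
            for act in activities:
                trace = run_simulation(
                    scn, ActivityProfile.single(act, segment_s), cfg,
                    **sim_kwargs,
                )
                m = compute_metrics(
                    trace, scn.target(act), scn.tolerance(act), window
                )
                rows.append((name, scn.label, act, m.rmse, m.max_error_pct))
    return pd.DataFrame(
        rows,
        columns=["controller", "case", "activity", "rmse_bpm", "max_error_pct"],
    )


def reference_results() -> pd.DataFrame:
    """Published tracking results of previously reported pacemaker
    controllers (classical fuzzy, fuzzy PID, RBF network), shipped as a
    static transcription for report context only — not recomputed here."""
    with resources.files("ifpace.data").joinpath(
        "reference_controllers.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)
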