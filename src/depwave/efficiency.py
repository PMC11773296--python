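"""Trapping and separation metrics, plus a synthetic outlet-trace generator.

Two experimental figures of merit:

* **Failure rate** FR = 100 * escaped / entered — the percentage of
  particles entering an electrode region that escape trapping (0% is
  ideal pDEP trapping).

* **Separation efficiency** eta = 1 - I_DEP / I_c0 — one minus the
  ratio of mean outlet fluorescence while the field traps particles to
  the mean baseline fluorescence before the field is switched on. With
  intensity proportional to particle concentration, eta is the
  retained fraction. Negative eta (outlet brighter than baseline, e.g.
  during release) is physically meaningful and passed through with a
  warning rather than clamped.

The synthetic generator emulates the canonical three-phase filter
trace: a 60 s baseline, 180 s of field-on during which the outlet
intensity settles exponentially to ``trap_fraction`` of baseline, and
a 120 s recovery with a release peak after switch-off. The outlet sees
each phase ~10 s late (transport from filter to detector), which is
why the standard 225-245 s evaluation window — straddling the 240 s
switch-off of the *field* schedule — still samples the trapping
plateau at the detector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "CountPair",
    "IntensityTrace",
    "EfficiencySummary",
    "failure_rate",
    "separation_efficiency",
    "replicate_efficiency",
    "synth_trace",
    "trace_to_csv",
    "trace_from_csv",
    "DEFAULT_BASELINE_WINDOW",
    "DEFAULT_EVAL_WINDOW",
    "DEFAULT_SCHEDULE",
]

#: Evaluation window (s) for the trapping-phase mean, per the standard
#: filter protocol; baseline window trims the edges of the 0-70 s
#: baseline phase as seen at the outlet.
DEFAULT_EVAL_WINDOW = (225.0, 245.0)
DEFAULT_BASELINE_WINDOW = (10.0, 55.0)
#: Outlet-referred phase boundaries (baseline end, field off), s: the
#: 60 s / 240 s field schedule shifted by the 10 s transport delay.
DEFAULT_SCHEDULE = (70.0, 250.0)


@dataclass(frozen=True)
class CountPair:
    """Particle counts for the failure rate: escaped (red) / entered (green)."""

    escaped: int
    entered: int

    def __post_init__(self) -> None:
        if self.entered <= 0:
            raise DomainError(f"entered must be a positive count, got {self.entered}")
        if not (0 <= self.escaped <= self.entered):
            raise DomainError(
                f"escaped must satisfy 0 <= escaped <= entered, got {self.escaped}/{self.entered}"
            )


def failure_rate(counts: CountPair) -> float:
    """Trapping failure rate in percent: 100 * escaped / entered, in [0, 100]."""
    return 100.0 * counts.escaped / counts.entered


@dataclass(frozen=True)
class IntensityTrace:
    """Time-stamped outlet fluorescence with its phase schedule and windows.

    ``schedule`` holds the outlet-referred phase boundaries
    (baseline end, field off) in seconds; ``eval_window`` must lie in
    the field-on phase and ``baseline_window`` in the baseline phase.
    ``true_eta`` records the generator's ground truth when the trace is
    synthetic (None for measured data).
    """

    times: np.ndarray
    intensities: np.ndarray
    schedule: tuple[float, float] = DEFAULT_SCHEDULE
    eval_window: tuple[float, float] = DEFAULT_EVAL_WINDOW
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW
    true_eta: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        if t.ndim != 1 or t.size < 2 or i.shape != t.shape:
            raise DomainError("times/intensities must be matching 1-D arrays with >= 2 samples")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(i < 0) or not np.all(np.isfinite(i)):
            raise DomainError("intensities must be finite and >= 0")
        t_on, t_off = self.schedule
        if not (0.0 < t_on < t_off):
            raise DomainError(f"schedule must satisfy 0 < baseline_end < field_off, got {self.schedule}")
        b0, b1 = self.baseline_window
        if not (0.0 <= b0 < b1 <= t_on):
            raise DomainError(
                f"baseline_window {self.baseline_window} must lie inside the baseline phase [0, {t_on}]"
            )
        e0, e1 = self.eval_window
        if not (t_on <= e0 < e1 <= t_off):
            raise DomainError(
                f"eval_window {self.eval_window} must lie inside the field-on phase [{t_on}, {t_off}]"
            )

    def window_mean(self, window: tuple[float, float]) -> float:
        lo, hi = window
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise DomainError(f"no samples in window [{lo}, {hi}] s")
        return float(self.intensities[mask].mean())


def separation_efficiency(trace: IntensityTrace) -> float:
    """eta = 1 - mean(eval window) / mean(baseline window).

    In-window averaging is the plain arithmetic mean of the samples (no
    resampling). Scale-invariant: rescaling all intensities by a
    positive constant leaves eta unchanged.
    """
    i_c0 = trace.window_mean(trace.baseline_window)
    if i_c0 <= 0:
        raise DomainError("baseline mean intensity must be > 0")
    eta = 1.0 - trace.window_mean(trace.eval_window) / i_c0
    if eta < 0:
        warnings.warn(
            f"negative separation efficiency ({eta:.3f}): outlet brighter than baseline "
            "(release or enrichment); value passed through unclamped",
            stacklevel=2,
        )
    return eta


class EfficiencySummary(NamedTuple):
    """Replicate aggregation of eta: per-trace values, mean, SD (n-1), SEM."""

    values: tuple[float, ...]
    mean: float
    sd: float
    sem: float


def replicate_efficiency(traces: Sequence[IntensityTrace]) -> EfficiencySummary:
    """Mean +- spread of eta over replicate traces.

    Reports both sample standard deviation (ddof=1) and the standard
    error of the mean, since a bare "+-" is ambiguous between the two.
    SD/SEM are nan for a single replicate.
    """
    if len(traces) == 0:
        raise DomainError("need at least one trace")
    vals = tuple(separation_efficiency(tr) for tr in traces)
    arr = np.array(vals)
    sd = float(arr.std(ddof=1)) if len(vals) > 1 else float("nan")
    return EfficiencySummary(
        values=vals,
        mean=float(arr.mean()),
        sd=sd,
        sem=sd / math.sqrt(len(vals)) if len(vals) > 1 else float("nan"),
    )


def synth_trace(
    baseline_level: float = 1.0,
    trap_fraction: float = 0.3,
    release_peak: float = 0.5,
    noise_sd: float = 0.01,
    seed: int | None = None,
    *,
    dt: float = 1.0,
    duration: float = 360.0,
    transport_delay: float = 10.0,
    settle_tau: float = 5.0,
) -> IntensityTrace:
    """Deterministic synthetic outlet trace of one filter run.

    Phases (field schedule 0-60 s baseline, 60-240 s field on,
    240-360 s recovery, all shifted by ``transport_delay`` at the
    outlet): constant ``baseline_level``; exponential settle (time
    constant ``settle_tau``) to ``trap_fraction * baseline_level``;
    recovery back to baseline with a Gaussian release peak of height
    ``release_peak * baseline_level``. Additive white noise of
    standard deviation ``noise_sd`` (intensity units) is applied with
    the given ``seed`` and the result clipped at 0. Ground-truth
    efficiency 1 - trap_fraction is recorded on the trace.
    """
    if not (0.0 <= trap_fraction <= 1.0):
        raise DomainError(f"trap_fraction must be in [0, 1], got {trap_fraction!r}")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd!r}")
    if baseline_level <= 0:
        raise DomainError(f"baseline_level must be > 0, got {baseline_level!r}")
    if release_peak < 0:
        raise DomainError(f"release_peak must be >= 0, got {release_peak!r}")

    t = np.arange(0.0, duration + 0.5 * dt, dt)
    t_on = 60.0 + transport_delay
    t_off = 240.0 + transport_delay
    trap_level = trap_fraction * baseline_level

    i = np.full_like(t, baseline_level)
    on = (t >= t_on) & (t < t_off)
    i[on] = trap_level + (baseline_level - trap_level) * np.exp(-(t[on] - t_on) / settle_tau)
    rec = t >= t_off
    i[rec] = baseline_level + (trap_level - baseline_level) * np.exp(-(t[rec] - t_off) / settle_tau)
    # release peak ~10 s after switch-off, as trapped particles wash out
    i[rec] += (
        release_peak
        * baseline_level
        * np.exp(-0.5 * ((t[rec] - (t_off + 10.0)) / 6.0) ** 2)
    )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=i.shape)
    i = np.clip(i, 0.0, None)

    return IntensityTrace(
        times=t,
        intensities=i,
        schedule=(t_on, t_off),
        eval_window=DEFAULT_EVAL_WINDOW,
        baseline_window=DEFAULT_BASELINE_WINDOW,
        true_eta=1.0 - trap_fraction,
    )


def trace_to_csv(trace: IntensityTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "intensity": trace.intensities}).to_csv(
        path, index=False, float_format="%.17g"
    )


def trace_from_csv(
    path,
    schedule: tuple[float, float] = DEFAULT_SCHEDULE,
    eval_window: tuple[float, float] = DEFAULT_EVAL_WINDOW,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> IntensityTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time_s", "intensity"} - set(df.columns)
    if missing:
        raise DomainError(f"trace CSV {path} missing columns: {sorted(missing)}")
    return IntensityTrace(
        times=df["time_s"].to_numpy(dtype=float),
        intensities=df["intensity"].to_numpy(dtype=float),
        schedule=schedule,
        eval_window=eval_window,
        baseline_window=baseline_window,
    )
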