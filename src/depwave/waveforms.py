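"""Fourier representation of rectangular and sinusoidal excitation.

An ideal 50%-duty rectangular wave of peak amplitude V0 and fundamental
frequency f0 is the odd-harmonic sine series

    v(t) = (4/pi) V0 sum_k sin(2 pi (2k-1) f0 t) / (2k-1),

i.e. a line at every odd order n = 2k-1 with peak amplitude
A_n = (4/pi) V0 / n and zero at even orders. Spectral line energies use
the convention P_n = A_n^2 (peak amplitude squared, no 1/2 factor), so
that a unit-amplitude sine carries energy 1 and the full rectangular
series carries energy (16/pi^2) * pi^2/8 = 2 — the "twice the energy"
of a square wave at equal peak amplitude. ``time_domain_energy`` is
scaled by the same factor 2 over the mean square so Parseval holds
against these spectral totals.

Harmonics are indexed by harmonic order n (frequency n*f0); the series
expansion index k maps to n = 2k-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "WaveformSpec",
    "HarmonicLine",
    "HarmonicSpectrum",
    "harmonic_spectrum",
    "rms_amplitude",
    "spectral_energy",
    "SpectralEnergy",
    "odd_harmonic_sum",
    "synthesize",
    "time_domain_energy",
    "spectrum_to_csv",
    "spectrum_from_csv",
    "DEFAULT_MAX_ORDER",
]

#: Default truncation: first 100 odd harmonics. By the tail bound
#: sum_{k>N} 1/(2k-1)^2 < 1/(4N) this captures > 99.7% of the
#: harmonic energy.
DEFAULT_MAX_ORDER = 199

Shape = Literal["sine", "rectangular"]


@dataclass(frozen=True)
class WaveformSpec:
    """Periodic drive signal: shape, peak amplitude V0 (V), fundamental f0 (Hz)."""

    shape: Shape
    v0: float
    f0: float

    def __post_init__(self) -> None:
        if self.shape not in ("sine", "rectangular"):
            raise DomainError(f"shape must be 'sine' or 'rectangular', got {self.shape!r}")
        if not (math.isfinite(self.v0) and self.v0 > 0):
            raise DomainError(f"v0 must be finite and > 0 V, got {self.v0!r}")
        if not (math.isfinite(self.f0) and self.f0 > 0):
            raise DomainError(f"f0 must be finite and > 0 Hz, got {self.f0!r}")


class HarmonicLine(NamedTuple):
    order: int
    frequency: float
    amplitude: float


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Ordered spectral lines (order n, frequency n*f0, peak amplitude)."""

    lines: tuple[HarmonicLine, ...]
    source: WaveformSpec
    truncation: int
    bandwidth_limit: float | None = None
    rolloff: Literal["brickwall", "first_order"] = "brickwall"

    def __post_init__(self) -> None:
        freqs = [ln.frequency for ln in self.lines]
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise DomainError("line frequencies must be strictly increasing")

    @property
    def orders(self) -> np.ndarray:
        return np.array([ln.order for ln in self.lines], dtype=int)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([ln.frequency for ln in self.lines], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([ln.amplitude for ln in self.lines], dtype=float)

    def nonzero(self) -> "HarmonicSpectrum":
        """Spectrum restricted to lines with nonzero amplitude."""
        kept = tuple(ln for ln in self.lines if ln.amplitude != 0.0)
        return HarmonicSpectrum(kept, self.source, self.truncation, self.bandwidth_limit, self.rolloff)


def harmonic_spectrum(
    spec: WaveformSpec,
    max_order: int = DEFAULT_MAX_ORDER,
    bandwidth_limit: float | None = None,
    rolloff: Literal["brickwall", "first_order"] = "brickwall",
) -> HarmonicSpectrum:
    """Spectral lines of the drive up to harmonic order ``max_order``.

    Rectangular: A_n = (4/pi) V0 / n at odd n, exactly 0 at even n.
    Sine: a single line of amplitude V0 at f0.

    ``bandwidth_limit`` models a bandwidth-limited drive chain:
    ``rolloff="brickwall"`` zeroes lines above the cutoff;
    ``rolloff="first_order"`` attenuates each line by
    1/sqrt(1 + (f/fc)^2), the simplest physical low-pass.
    """
    if max_order < 1:
        raise DomainError(f"max_order must be >= 1, got {max_order}")
    if bandwidth_limit is not None and bandwidth_limit <= 0:
        raise DomainError("bandwidth_limit must be > 0 Hz")
    if rolloff not in ("brickwall", "first_order"):
        raise DomainError(f"unknown rolloff {rolloff!r}")

    lines: list[HarmonicLine] = []
    if spec.shape == "sine":
        amp = spec.v0
        if bandwidth_limit is not None:
            if rolloff == "brickwall":
                amp = amp if spec.f0 <= bandwidth_limit else 0.0
            else:
                amp = amp / math.sqrt(1.0 + (spec.f0 / bandwidth_limit) ** 2)
        lines.append(HarmonicLine(1, spec.f0, amp))
    else:
        for n in range(1, max_order + 1):
            fn = n * spec.f0
            amp = (4.0 / math.pi) * spec.v0 / n if n % 2 == 1 else 0.0
            if amp != 0.0 and bandwidth_limit is not None:
                if rolloff == "brickwall":
                    amp = amp if fn <= bandwidth_limit else 0.0
                else:
                    amp = amp / math.sqrt(1.0 + (fn / bandwidth_limit) ** 2)
            lines.append(HarmonicLine(n, fn, amp))
    return HarmonicSpectrum(tuple(lines), spec, max_order, bandwidth_limit, rolloff)


def rms_amplitude(spec: WaveformSpec) -> float:
    """Root-mean-square amplitude: V0/sqrt(2) for sine, V0 for rectangular."""
    return spec.v0 / math.sqrt(2.0) if spec.shape == "sine" else spec.v0


class SpectralEnergy(NamedTuple):
    per_line: np.ndarray  # P_n = A_n^2 per included line, V^2
    total: float


def spectral_energy(spectrum: HarmonicSpectrum) -> SpectralEnergy:
    """Per-line energies P_n = A_n^2 and their sum over included lines.

    Note the convention P_n = A_n^2 on *peak* amplitudes (no 1/2
    factor): a unit sine has total 1, the full unit square wave 2.
    """
    per = spectrum.amplitudes**2
    return SpectralEnergy(per_line=per, total=float(per.sum()))


def odd_harmonic_sum(max_n: float = math.inf) -> float:
    """Partial (or full) sum of 1/(2k-1)^2 over k = 1..max_n.

    ``max_n = inf`` returns the closed form pi^2/8 ~ 1.2337: the total
    spectral weight of a square wave relative to its fundamental. The
    harmonics-only share is odd_harmonic_sum(inf) - 1 ~ 0.2337.
    """
    if math.isinf(max_n):
        return math.pi**2 / 8.0
    n = int(max_n)
    if n < 1 or n != max_n:
        raise DomainError(f"max_n must be a positive integer or inf, got {max_n!r}")
    k = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / (2.0 * k - 1.0) ** 2))


def synthesize(spectrum: HarmonicSpectrum, times) -> np.ndarray:
    """Time-domain samples sum_n A_n sin(2 pi f_n t) at the given times (s).

    Converges pointwise to the ideal +-V0 square wave away from the
    transitions as the truncation grows (Gibbs overshoot persists at
    the edges).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size == 0:
        raise DomainError("times must be nonempty")
    nz = spectrum.nonzero()
    if len(nz.lines) == 0:
        return np.zeros_like(t)
    phases = 2.0 * math.pi * np.outer(t, nz.frequencies)
    return np.sin(phases) @ nz.amplitudes


def time_domain_energy(spec: WaveformSpec) -> float:
    """Signal energy over one period, as 2x the mean square of v(t).

    The factor 2 matches the spectral convention P_n = A_n^2 (Parseval:
    mean square of sum A_n sin = sum A_n^2 / 2), so sine V0=1 -> 1 and
    rectangular V0=1 -> 2.
    """
    ms = 0.5 * spec.v0**2 if spec.shape == "sine" else spec.v0**2
    return 2.0 * ms


# -- CSV export/import (columns: order, frequency_hz, amplitude_v, energy_v2)


def spectrum_to_csv(spectrum: HarmonicSpectrum, path) -> None:
    df = pd.DataFrame(
        {
            "order": spectrum.orders,
            "frequency_hz": spectrum.frequencies,
            "amplitude_v": spectrum.amplitudes,
            "energy_v2": spectrum.amplitudes**2,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def spectrum_from_csv(path, source: WaveformSpec | None = None) -> HarmonicSpectrum:
    """Rebuild a spectrum from its CSV table.

    ``source`` may be supplied to re-attach the generating waveform; if
    omitted a sine spec matching the first line is synthesized as a
    placeholder carrier (the lines themselves are authoritative).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    lines = tuple(
        HarmonicLine(int(r.order), float(r.frequency_hz), float(r.amplitude_v))
        for r in df.itertuples()
    )
    if not lines:
        raise DomainError(f"no spectral lines in {path}")
    if source is None:
        amp0 = abs(lines[0].amplitude) or 1.0
        source = WaveformSpec("sine", amp0, lines[0].frequency)
    return HarmonicSpectrum(lines, source, truncation=lines[-1].order)
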