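"""Per-harmonic DEP force summation and the waveform-choice advisor.

Because the DEP force is quadratic in the field and cross-frequency
terms of a multi-tone drive time-average to zero, each spectral line
contributes independently with weight proportional to its peak
amplitude squared:

    F_n = K * G * A_n^2 * Re{CM}(n f0),   K = 2 pi Rp^3 eps_m,

where G = grad|E_rms|^2 collapses the (frequency-independent) electrode
geometry into one positive scalar. Harmonic contributions above the
fundamental are split by sign into A (same direction as an increase of
the net force, >= 0) and B (opposing, <= 0); a rectangular drive beats
an equal-peak sinusoid exactly when the signed total exceeds the
single-line sine baseline.

The energy rule is the conservative shortcut: the 3rd and 5th harmonic
together carry just over half of all harmonic energy (1/9 + 1/25 =
0.1511 of 0.2337), so if both lie below the cross-over frequency —
i.e. f0 < fco/5 — the rectangular drive is guaranteed beneficial even
if every higher harmonic opposes; above fco every harmonic shares the
fundamental's sign and the drive always helps. In between the outcome
depends on the actual dispersion, which the exact decomposition
resolves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

from .dielectrics import ParticleSystem, crossover_frequency, re_cm
from .errors import DomainError, MultiCrossoverError
from .waveforms import (
    DEFAULT_MAX_ORDER,
    HarmonicSpectrum,
    WaveformSpec,
    harmonic_spectrum,
    rms_amplitude,
)

__all__ = [
    "ForceContribution",
    "ForceDecomposition",
    "BenefitRule",
    "BenefitReport",
    "decompose_force",
    "advise",
    "smallest_safe_divisor",
]


class ForceContribution(NamedTuple):
    order: int
    frequency: float
    re_cm: float
    force: float  # N, signed


@dataclass(frozen=True)
class ForceDecomposition:
    """Sign-separated per-harmonic force budget of one spectrum.

    ``fundamental`` is the order-1 line's force; ``positive_sum`` (A)
    and ``negative_sum`` (B) partition the harmonic (n > 1)
    contributions by sign, so total = fundamental + A + B.
    ``sine_baseline`` is the force of the comparison sinusoid at f0.
    """

    contributions: tuple[ForceContribution, ...]
    fundamental: float
    positive_sum: float  # A >= 0
    negative_sum: float  # B <= 0
    total: float
    sine_baseline: float

    @property
    def gain_ratio(self) -> float:
        """total / sine_baseline; > 1 means the harmonics help."""
        return self.total / self.sine_baseline

    @property
    def beneficial_exact(self) -> bool:
        """True iff |total| > |baseline| with matching force direction."""
        return (
            self.total * self.sine_baseline > 0
            and abs(self.total) > abs(self.sine_baseline)
        )


def decompose_force(
    system: ParticleSystem,
    spectrum: HarmonicSpectrum,
    field_gradient: float,
    comparison: str = "equal-peak",
) -> ForceDecomposition:
    """Per-line DEP forces, their sign-separated sums, and the sine baseline.

    ``comparison`` selects the baseline sinusoid: ``"equal-peak"``
    (same V0 as the source waveform — the experimental same-Vpp
    comparison, default) or ``"equal-rms"`` (same RMS amplitude, i.e.
    peak sqrt(2)*Vrms).
    """
    if not (math.isfinite(field_gradient) and field_gradient > 0):
        raise DomainError(f"field_gradient must be finite and > 0, got {field_gradient!r}")
    if comparison not in ("equal-peak", "equal-rms"):
        raise DomainError(f"comparison must be 'equal-peak' or 'equal-rms', got {comparison!r}")
    if len(spectrum.lines) == 0:
        raise DomainError("spectrum has no lines")

    k_geom = 2.0 * math.pi * system.radius**3 * system.medium.eps_abs
    scale = k_geom * field_gradient

    orders = spectrum.orders
    freqs = spectrum.frequencies
    amps = spectrum.amplitudes
    cms = np.where(amps != 0.0, np.atleast_1d(re_cm(system, freqs)), 0.0)
    forces = scale * amps**2 * cms
    contribs = tuple(
        ForceContribution(int(n), float(f), float(c), float(fr))
        for n, f, c, fr in zip(orders, freqs, cms, forces)
    )

    fund_mask = orders == 1
    harm = forces[~fund_mask]
    fundamental = float(forces[fund_mask].sum())
    a = float(harm[harm > 0].sum())
    b = float(harm[harm < 0].sum())
    total = fundamental + a + b

    src = spectrum.source
    if comparison == "equal-peak":
        base_amp = src.v0
    else:
        base_amp = math.sqrt(2.0) * rms_amplitude(src)
    baseline = scale * base_amp**2 * re_cm(system, src.f0)

    return ForceDecomposition(
        contributions=tuple(contribs),
        fundamental=fundamental,
        positive_sum=a,
        negative_sum=b,
        total=total,
        sine_baseline=baseline,
    )


class BenefitRule(str, Enum):
    """Tri-state verdict of the conservative spectral-energy rule."""

    BENEFICIAL = "beneficial"  # f0 < fco/5: guaranteed gain
    NOT_GUARANTEED = "not guaranteed"  # fco/5 <= f0 <= fco: dispersion decides
    ALWAYS_BENEFICIAL = "always beneficial"  # f0 > fco or no crossover


@dataclass(frozen=True)
class BenefitReport:
    """Advisor output: energy rule, exact decomposition, and gain ratio."""

    beneficial_energy_rule: BenefitRule
    boundary_frequency: float | None  # fco/5, Hz, when a crossover exists
    fco: float | None
    f0: float
    beneficial_exact: bool
    gain_ratio: float
    decomposition: ForceDecomposition

    @property
    def rules_disagree(self) -> bool:
        """True when the conservative rule withholds a gain the exact sum finds
        (or vice versa); the energy rule is sufficient, not necessary."""
        rule_says_gain = self.beneficial_energy_rule in (
            BenefitRule.BENEFICIAL,
            BenefitRule.ALWAYS_BENEFICIAL,
        )
        return rule_says_gain != self.beneficial_exact


def advise(
    system: ParticleSystem,
    f0: float,
    *,
    v0: float = 1.0,
    max_order: int = DEFAULT_MAX_ORDER,
    bandwidth_limit: float | None = None,
    rolloff: str = "brickwall",
    field_gradient: float = 1.0,
    comparison: str = "equal-peak",
) -> BenefitReport:
    """Should a rectangular drive replace the sinusoid at this f0?

    Applies both the conservative energy rule (f0 vs fco/5) and the
    exact CM-weighted decomposition of the rectangular spectrum against
    the equal-amplitude sine baseline. Raises
    :class:`~depwave.errors.MultiCrossoverError` if Re{CM} changes sign
    more than once across the harmonic range (multishell dispersion;
    the fco/5 rule assumes a single cross-over).
    """
    if not (math.isfinite(f0) and f0 > 0):
        raise DomainError(f"f0 must be finite and > 0 Hz, got {f0!r}")

    spec = WaveformSpec("rectangular", v0, f0)
    spectrum = harmonic_spectrum(spec, max_order, bandwidth_limit, rolloff)  # type: ignore[arg-type]

    # Defensive multishell check: at most one sign change across lines.
    freqs = spectrum.nonzero().frequencies
    signs = np.sign(re_cm(system, freqs))
    nz = signs[signs != 0]
    flips = int(np.count_nonzero(np.diff(nz) != 0))
    if flips > 1:
        raise MultiCrossoverError(
            f"Re{{CM}} changes sign {flips} times over the harmonic range; "
            "the fco/5 rule assumes a single cross-over — use decompose_force directly"
        )

    co = crossover_frequency(system)
    if not co.exists or f0 > co.fco:
        rule = BenefitRule.ALWAYS_BENEFICIAL
    elif f0 < co.fco / 5.0:
        rule = BenefitRule.BENEFICIAL
    else:
        rule = BenefitRule.NOT_GUARANTEED

    dec = decompose_force(system, spectrum, field_gradient, comparison)
    return BenefitReport(
        beneficial_energy_rule=rule,
        boundary_frequency=(co.fco / 5.0) if co.exists else None,
        fco=co.fco if co.exists else None,
        f0=f0,
        beneficial_exact=dec.beneficial_exact,
        gain_ratio=dec.gain_ratio,
        decomposition=dec,
    )


def smallest_safe_divisor(energy_threshold: float = 0.5) -> int:
    """Smallest odd order m whose harmonics 3..m carry >= the given
    fraction of all harmonic energy.

    Scans odd orders accumulating 1/m^2 against
    ``energy_threshold * (pi^2/8 - 1)``. At threshold 0.5 the answer is
    5 (the 3rd and 5th harmonic hold just over half the harmonic
    energy), which is the divisor in the f0 < fco/5 rule.
    """
    if not (0.0 < energy_threshold < 1.0):
        raise DomainError(f"energy_threshold must be in (0, 1), got {energy_threshold!r}")
    target = energy_threshold * (math.pi**2 / 8.0 - 1.0)
    acc = 0.0
    m = 1
    while True:
        m += 2
        acc += 1.0 / (m * m)
        if acc >= target:
            return m
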