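"""Dielectric dispersion of a homogeneous sphere in a lossy medium.

The force on a polarizable sphere in a non-uniform AC field is

    F_DEP = 2 pi Rp^3 eps_m Re{CM(omega)} grad|E_rms|^2,

where the Clausius-Mossotti (CM) factor

    CM(omega) = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*),
    eps_i*    = eps_i eps0 - j sigma_i / omega,

sets both sign (pDEP vs nDEP) and magnitude of the frequency response.
This module computes the complex permittivities, the real part of the
CM factor (closed form and via the complex quotient), the force
prefactor, and the cross-over frequency where Re{CM} changes sign.

All permittivities are handled as absolute values (eps_r * eps0) so the
omega^2 term and the conductivity term of the closed form carry
commensurate units. Frequencies are ordinary frequencies f in Hz at
every interface; omega = 2 pi f internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import epsilon_0 as EPS0

from .errors import DomainError

__all__ = [
    "EPS0",
    "DielectricMaterial",
    "ParticleSystem",
    "CrossoverResult",
    "complex_permittivity",
    "cm_factor",
    "re_cm",
    "crossover_frequency",
    "dep_force_prefactor",
    "particle_system_with_crossover",
]


@dataclass(frozen=True)
class DielectricMaterial:
    """One phase (particle or medium): relative permittivity + conductivity.

    Parameters
    ----------
    eps_r
        Relative permittivity, dimensionless, >= 1.
    sigma
        Electrical conductivity in S/m, >= 0.
    """

    eps_r: float
    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eps_r) and self.eps_r >= 1.0):
            raise DomainError(f"eps_r must be finite and >= 1, got {self.eps_r!r}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0.0):
            raise DomainError(f"sigma must be finite and >= 0 S/m, got {self.sigma!r}")

    @property
    def eps_abs(self) -> float:
        """Absolute permittivity eps_r * eps0 in F/m."""
        return self.eps_r * EPS0


@dataclass(frozen=True)
class ParticleSystem:
    """A spherical particle suspended in a medium.

    ``surface_conductance`` (Ks, in S) models conduction along the
    particle's double layer, which dominates the effective conductivity
    of small latex spheres:

        sigma_p_eff = sigma_p_bulk + 2 Ks / Rp.

    It defaults to 0 because it is a fitted, particle-lot-specific
    quantity; the dispersion then uses the bulk conductivity alone.
    """

    particle: DielectricMaterial
    medium: DielectricMaterial
    radius: float
    surface_conductance: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0.0):
            raise DomainError(f"radius must be finite and > 0 m, got {self.radius!r}")
        if not (math.isfinite(self.surface_conductance) and self.surface_conductance >= 0.0):
            raise DomainError(
                f"surface_conductance must be finite and >= 0 S, got {self.surface_conductance!r}"
            )

    @property
    def sigma_p_eff(self) -> float:
        """Effective particle conductivity including surface conductance, S/m."""
        return self.particle.sigma + 2.0 * self.surface_conductance / self.radius


@dataclass(frozen=True)
class CrossoverResult:
    """Outcome of the cross-over search.

    ``exists`` is True iff Re{CM} changes sign between its DC and
    high-frequency plateaus; ``fco`` then solves Re{CM}(fco) = 0 and
    ``sign_below`` is the sign of Re{CM} for f < fco (+1 pDEP, -1 nDEP).
    """

    exists: bool
    fco: float | None = None
    sign_below: int | None = None


def _check_frequency(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or not np.all(np.isfinite(f)):
        raise DomainError("frequency must be finite and > 0 Hz")
    return f


def complex_permittivity(material: DielectricMaterial, f):
    """Absolute complex permittivity eps* = eps_r eps0 - j sigma/omega, F/m.

    ``f`` may be a scalar or array of frequencies in Hz (> 0).
    """
    f = _check_frequency(f)
    omega = 2.0 * math.pi * f
    out = material.eps_abs - 1j * material.sigma / omega
    return complex(out) if np.ndim(out) == 0 else out


def _effective_particle_material(system: ParticleSystem) -> DielectricMaterial:
    if system.surface_conductance == 0.0:
        return system.particle
    return DielectricMaterial(system.particle.eps_r, system.sigma_p_eff)


def cm_factor(system: ParticleSystem, f):
    """Full complex CM factor (eps_p* - eps_m*)/(eps_p* + 2 eps_m*)."""
    part = _effective_particle_material(system)
    ep = complex_permittivity(part, f)
    em = complex_permittivity(system.medium, f)
    return (ep - em) / (ep + 2.0 * em)


def re_cm(system: ParticleSystem, f):
    """Real part of the CM factor, closed form.

    Re{CM} = [w^2 (ep-em)(ep+2em) + (sp-sm)(sp+2sm)]
             / [w^2 (ep+2em)^2 + (sp+2sm)^2]

    with absolute permittivities and the effective particle
    conductivity. Bounded in [-0.5, 1.0] for a homogeneous sphere.
    """
    f = _check_frequency(f)
    omega2 = (2.0 * math.pi * f) ** 2
    ep = _effective_particle_material(system).eps_abs
    em = system.medium.eps_abs
    sp = system.sigma_p_eff
    sm = system.medium.sigma
    num = omega2 * (ep - em) * (ep + 2.0 * em) + (sp - sm) * (sp + 2.0 * sm)
    den = omega2 * (ep + 2.0 * em) ** 2 + (sp + 2.0 * sm) ** 2
    out = num / den
    return float(out) if np.ndim(out) == 0 else out


def crossover_frequency(system: ParticleSystem) -> CrossoverResult:
    """Cross-over frequency of Re{CM}, if one exists.

    The single-relaxation dispersion is monotone between its DC limit
    (sp-sm)/(sp+2sm) and high-frequency limit (ep-em)/(ep+2em), so a
    sign change exists iff the two limits have strictly opposite signs;
    the zero then has the closed form

        (2 pi fco)^2 = -(sp-sm)(sp+2sm) / [(ep-em)(ep+2em)].

    Degenerate particle == medium systems (CM identically 0) and
    same-sign plateaus report ``exists=False``.
    """
    ep = _effective_particle_material(system).eps_abs
    em = system.medium.eps_abs
    sp = system.sigma_p_eff
    sm = system.medium.sigma
    num_dc = (sp - sm) * (sp + 2.0 * sm)  # sign of DC plateau
    num_hf = (ep - em) * (ep + 2.0 * em)  # sign of HF plateau
    if num_dc == 0.0 or num_hf == 0.0 or math.copysign(1.0, num_dc) == math.copysign(1.0, num_hf):
        return CrossoverResult(exists=False)
    omega_co = math.sqrt(-num_dc / num_hf)
    fco = omega_co / (2.0 * math.pi)
    return CrossoverResult(exists=True, fco=fco, sign_below=1 if num_dc > 0 else -1)


def dep_force_prefactor(system: ParticleSystem, f):
    """DEP force per unit field-gradient scalar, 2 pi Rp^3 eps_m Re{CM}(f).

    Units N m^3/V^2: multiply by a user-supplied field-gradient scalar
    G = grad|E_rms|^2 (V^2/m^3) to obtain a force in N. The spatial
    field geometry is deliberately not modelled here.
    """
    base = 2.0 * math.pi * system.radius**3 * system.medium.eps_abs
    return base * re_cm(system, f)


def particle_system_with_crossover(
    fco: float,
    *,
    eps_r_particle: float = 2.55,
    eps_r_medium: float = 78.5,
    sigma_medium: float = 1e-4,
    radius: float = 1.25e-6,
) -> ParticleSystem:
    """Construct a pDEP->nDEP system with a prescribed cross-over frequency.

    Solves the closed form for the particle conductivity that places the
    zero of Re{CM} at ``fco``, holding the other parameters fixed.
    Requires eps_r_particle < eps_r_medium (nDEP plateau at high f, the
    polystyrene-in-water situation). Useful for building test systems
    and documentation examples with a known fco.
    """
    if fco <= 0:
        raise DomainError("fco must be > 0 Hz")
    if eps_r_particle >= eps_r_medium:
        raise DomainError("requires eps_r_particle < eps_r_medium (nDEP high-frequency plateau)")
    epa = eps_r_particle * EPS0
    ema = eps_r_medium * EPS0
    sm = sigma_medium
    # (sp-sm)(sp+2sm) = C > 0  =>  sp^2 + sp*sm - 2 sm^2 - C = 0
    c = -((2.0 * math.pi * fco) ** 2) * (epa - ema) * (epa + 2.0 * ema)
    sp = 0.5 * (-sm + math.sqrt(9.0 * sm * sm + 4.0 * c))
    return ParticleSystem(
        particle=DielectricMaterial(eps_r_particle, sp),
        medium=DielectricMaterial(eps_r_medium, sm),
        radius=radius,
    )
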