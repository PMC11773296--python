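import numpy as np
import pytest
from hypothesis import strategies as st

from depwave import DielectricMaterial, ParticleSystem


@pytest.fixture
def ps_in_water() -> ParticleSystem:
    """Polystyrene-like bead in low-conductivity water: pDEP at DC
    (sigma_p > sigma_m), nDEP plateau at high frequency (eps_p << eps_m),
    hence a single cross-over."""
    return ParticleSystem(
        particle=DielectricMaterial(eps_r=2.55, sigma=2e-4),
        medium=DielectricMaterial(eps_r=78.5, sigma=1e-4),
        radius=1.24e-6,
    )


@pytest.fixture
def flat_system() -> ParticleSystem:
    """eps_p = 2 eps_m and sigma_p = 2 sigma_m make the closed-form
    numerator exactly 0.25x the denominator term-by-term, so
    Re{CM} == 0.25 at every frequency (dispersionless)."""
    return ParticleSystem(
        particle=DielectricMaterial(eps_r=40.0, sigma=2e-3),
        medium=DielectricMaterial(eps_r=20.0, sigma=1e-3),
        radius=1e-6,
    )


def materials() -> st.SearchStrategy[DielectricMaterial]:
    """Physically plausible single phases: eps_r within common liquids
    and solids, sigma from deionized water to saline."""
    return st.builds(
        DielectricMaterial,
        eps_r=st.floats(1.0, 100.0),
        sigma=st.floats(1e-6, 1.0),
    )


def particle_systems() -> st.SearchStrategy[ParticleSystem]:
    return st.builds(
        ParticleSystem,
        particle=materials(),
        medium=materials(),
        radius=st.floats(1e-7, 1e-4),
    )


def random_physical_systems(rng: np.random.Generator, n: int) -> list[ParticleSystem]:
    """Seeded bulk draws for the oracle-equivalence sweeps (log-uniform
    conductivities, uniform permittivities)."""
    eps_p = rng.uniform(1.0, 100.0, n)
    eps_m = rng.uniform(1.0, 100.0, n)
    sig_p = 10 ** rng.uniform(-6, 0, n)
    sig_m = 10 ** rng.uniform(-6, 0, n)
    rad = 10 ** rng.uniform(-7, -4, n)
    return [
        ParticleSystem(
            DielectricMaterial(float(ep), float(sp)),
            DielectricMaterial(float(em), float(sm)),
            float(r),
        )
        for ep, em, sp, sm, r in zip(eps_p, eps_m, sig_p, sig_m, rad)
    ]
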