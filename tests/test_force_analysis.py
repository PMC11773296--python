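"""Sign-separated force summation and the waveform-choice advisor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import depwave.force_analysis as fa
from depwave import (
    BenefitRule,
    DielectricMaterial,
    DomainError,
    MultiCrossoverError,
    ParticleSystem,
    WaveformSpec,
    advise,
    crossover_frequency,
    decompose_force,
    harmonic_spectrum,
    particle_system_with_crossover,
    re_cm,
    smallest_safe_divisor,
)

from conftest import particle_systems


def _rect(f0, v0=1.0, max_order=199):
    return harmonic_spectrum(WaveformSpec("rectangular", v0, f0), max_order)


class TestDecomposeForce:
    def test_flat_dispersion_ratio_equals_truncated_energy_ratio(self, flat_system):
        """With Re{CM} constant, the rectangular/sine force ratio is the
        spectral energy ratio (16/pi^2) * partial odd sum."""
        assert np.allclose(re_cm(flat_system, np.logspace(1, 11, 30)), 0.25)
        dec = decompose_force(flat_system, _rect(1e4, max_order=199), field_gradient=1e12)
        k = np.arange(1, 101)
        expected = (16 / math.pi**2) * np.sum(1.0 / (2 * k - 1) ** 2)
        assert dec.gain_ratio == pytest.approx(expected, rel=1e-12)
        assert dec.gain_ratio == pytest.approx(2.0, abs=5e-3)  # truncation tail

    def test_sine_spectrum_total_equals_baseline(self, ps_in_water):
        spect = harmonic_spectrum(WaveformSpec("sine", 2.0, 5e3))
        dec = decompose_force(ps_in_water, spect, field_gradient=1e13)
        assert dec.total == pytest.approx(dec.sine_baseline, rel=1e-14)
        assert dec.positive_sum == 0.0 and dec.negative_sum == 0.0

    def test_all_negative_above_crossover(self):
        sys = particle_system_with_crossover(40e3)
        dec = decompose_force(sys, _rect(350e3), field_gradient=1e13)
        forces = [c.force for c in dec.contributions if c.force != 0]
        assert all(f < 0 for f in forces)
        assert dec.positive_sum == 0.0 and dec.negative_sum < 0
        assert abs(dec.total) > abs(dec.sine_baseline)

    def test_mixed_signs_when_fco_is_four_f0(self):
        """fco = 4 f0 (the 10 kHz drive vs ~40 kHz cross-over situation):
        fundamental and order 3 push pDEP, orders >= 5 oppose."""
        sys = particle_system_with_crossover(40e3)
        dec = decompose_force(sys, _rect(10e3), field_gradient=1e13)
        by_order = {c.order: c.force for c in dec.contributions if c.order % 2 == 1}
        assert by_order[1] > 0 and by_order[3] > 0
        assert all(by_order[n] < 0 for n in range(5, 30, 2))
        assert dec.positive_sum > 0 and dec.negative_sum < 0

    def test_sign_partition_and_total(self, ps_in_water):
        dec = decompose_force(ps_in_water, _rect(5e3), field_gradient=1e13)
        assert dec.positive_sum >= 0 >= dec.negative_sum
        assert dec.total == pytest.approx(
            dec.fundamental + dec.positive_sum + dec.negative_sum, rel=1e-12
        )
        assert dec.total == pytest.approx(sum(c.force for c in dec.contributions), rel=1e-9)

    def test_equal_rms_baseline_doubles_for_rect_source(self, flat_system):
        peak = decompose_force(flat_system, _rect(1e4), 1e12, comparison="equal-peak")
        rms = decompose_force(flat_system, _rect(1e4), 1e12, comparison="equal-rms")
        assert rms.sine_baseline == pytest.approx(2 * peak.sine_baseline, rel=1e-12)
        assert rms.total == peak.total

    def test_rejects_nonpositive_gradient(self, ps_in_water):
        with pytest.raises(DomainError):
            decompose_force(ps_in_water, _rect(1e4), 0.0)

    @settings(derandomize=True, max_examples=150)
    @given(system=particle_systems(), f0=st.floats(1e2, 1e8))
    def test_total_is_fundamental_plus_a_plus_b(self, system, f0):
        dec = decompose_force(system, _rect(f0, max_order=49), field_gradient=1e10)
        assert dec.positive_sum >= 0 >= dec.negative_sum
        assert dec.total == pytest.approx(
            dec.fundamental + dec.positive_sum + dec.negative_sum, rel=1e-9, abs=1e-40
        )

    def test_gain_ratio_tends_to_two_as_dispersion_flattens(self):
        """Shrinking the conductivity contrast toward the permittivity
        contrast flattens Re{CM}; the force ratio then approaches the
        pure energy ratio 2."""
        deviations = []
        for contrast in (4.0, 2.5, 2.1, 2.01):
            sys = ParticleSystem(
                DielectricMaterial(40.0, contrast * 1e-3),
                DielectricMaterial(20.0, 1e-3),
                1e-6,
            )
            dec = decompose_force(sys, _rect(1e5, max_order=9999), field_gradient=1e12)
            deviations.append(abs(dec.gain_ratio - 2.0))
        assert all(b < a for a, b in zip(deviations, deviations[1:]))
        assert deviations[-1] < 2e-3

    def test_monotone_truncation_same_sign_regime(self):
        """Above fco every harmonic shares the fundamental's sign, so
        adding harmonics never decreases |total|."""
        sys = particle_system_with_crossover(40e3)
        mags = [
            abs(decompose_force(sys, _rect(350e3, max_order=m), 1e13).total)
            for m in (1, 3, 9, 49, 199)
        ]
        assert all(b >= a for a, b in zip(mags, mags[1:]))


class TestAdvise:
    def test_beneficial_when_f0_below_fco_over_five(self):
        sys = particle_system_with_crossover(260e3)
        rep = advise(sys, 15e3, field_gradient=1e13)
        assert rep.beneficial_energy_rule is BenefitRule.BENEFICIAL
        assert rep.boundary_frequency == pytest.approx(52e3)
        assert rep.beneficial_exact and rep.gain_ratio > 1

    def test_not_guaranteed_between_boundary_and_fco(self):
        sys = particle_system_with_crossover(40e3)
        rep = advise(sys, 10e3, field_gradient=1e13)
        assert rep.beneficial_energy_rule is BenefitRule.NOT_GUARANTEED
        dec = rep.decomposition
        assert dec.positive_sum > 0 and dec.negative_sum < 0  # mixed signs

    def test_always_beneficial_above_fco(self):
        sys = particle_system_with_crossover(40e3)
        rep = advise(sys, 350e3, field_gradient=1e13)
        assert rep.beneficial_energy_rule is BenefitRule.ALWAYS_BENEFICIAL
        assert rep.beneficial_exact and rep.gain_ratio > 1
        assert not rep.rules_disagree

    def test_always_beneficial_without_crossover(self, flat_system):
        rep = advise(flat_system, 1e4, field_gradient=1e12)
        assert rep.beneficial_energy_rule is BenefitRule.ALWAYS_BENEFICIAL
        assert rep.fco is None and rep.boundary_frequency is None
        assert rep.beneficial_exact

    def test_rejects_nonpositive_f0(self, ps_in_water):
        with pytest.raises(DomainError):
            advise(ps_in_water, 0.0)

    def test_energy_rule_soundness_on_random_crossover_systems(self):
        """Whenever the conservative rule promises a gain (f0 < fco/5) on a
        single-crossover monotone dispersion AND the opposing harmonics
        see no larger |Re{CM}| than the fundamental (the worst-case
        assumption behind the half-energy accounting), the exact
        decomposition agrees."""
        rng = np.random.default_rng(7)
        checked = attempts = 0
        while checked < 50 and attempts < 2000:
            attempts += 1
            fco = 10 ** rng.uniform(3.5, 6.5)
            sys = particle_system_with_crossover(
                fco,
                sigma_medium=10 ** rng.uniform(-5, -3),
                radius=10 ** rng.uniform(-6.5, -5.5),
            )
            f0 = fco / 5.0 * rng.uniform(0.05, 0.98)
            rep = advise(sys, f0, field_gradient=1e13)
            assert rep.beneficial_energy_rule is BenefitRule.BENEFICIAL
            opposing = [
                abs(c.re_cm) for c in rep.decomposition.contributions if c.force < 0
            ]
            if opposing and max(opposing) > abs(re_cm(sys, f0)):
                continue  # worst-case assumption violated; rule not applicable
            assert rep.beneficial_exact, (fco, f0)
            checked += 1
        assert checked == 50

    def test_multishell_dispersion_rejected(self, ps_in_water, monkeypatch):
        """A dispersion with two sign changes on the harmonic range must be
        refused: the fco/5 rule assumes a single cross-over."""

        def two_crossings(system, f):
            f = np.asarray(f, dtype=float)
            out = np.where((f > 3e4) & (f < 3e5), -1.0, 1.0) * 0.3
            return float(out) if out.ndim == 0 else out

        monkeypatch.setattr(fa, "re_cm", two_crossings)
        with pytest.raises(MultiCrossoverError):
            advise(ps_in_water, 1e4)


class TestSmallestSafeDivisor:
    @staticmethod
    def _oracle(threshold):
        target = threshold * (math.pi**2 / 8 - 1)
        acc, m = 0.0, 1
        while acc < target:
            m += 2
            acc += 1 / m**2
        return m

    @pytest.mark.parametrize("threshold, expected", [(0.5, 5), (0.47, 3)])
    def test_known_thresholds(self, threshold, expected):
        assert smallest_safe_divisor(threshold) == expected

    @pytest.mark.parametrize("threshold", [0.1, 0.3, 0.5, 0.7, 0.9, 0.99, 0.999])
    def test_matches_brute_force_scan(self, threshold):
        assert smallest_safe_divisor(threshold) == self._oracle(threshold)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_out_of_range(self, threshold):
        with pytest.raises(DomainError):
            smallest_safe_divisor(threshold)
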