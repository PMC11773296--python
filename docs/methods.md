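# Methods

## Model

A homogeneous dielectric sphere (radius Rp, relative permittivity
eps_p, conductivity sigma_p) in a lossy medium (eps_m, sigma_m)
experiences the time-averaged DEP force
`F = 2 pi Rp^3 eps_m Re{CM(w)} grad|E_rms|^2`. All permittivities enter
as absolute values (eps_r * eps0) so the closed form

```
Re{CM} = [w^2 (ep-em)(ep+2em) + (sp-sm)(sp+2sm)]
         / [w^2 (ep+2em)^2 + (sp+2sm)^2]
```

is dimensionally consistent; it is a single-relaxation dispersion,
monotone in w^2 between its DC plateau `(sp-sm)/(sp+2sm)` and
high-frequency plateau `(ep-em)/(ep+2em)`, bounded in [-0.5, 1], with
at most one zero crossing. The cross-over frequency is the closed form
`(2 pi fco)^2 = -(sp-sm)(sp+2sm) / [(ep-em)(ep+2em)]`, reported only
when the plateau signs differ; the test suite verifies it against a
bracketing Brent root finder on 1000 random physical systems.
Degenerate particle==medium systems yield CM = 0 and "no crossover"
rather than an error.

**Surface conductance.** Micron-scale latex spheres conduct mainly
along their double layer; `ParticleSystem.surface_conductance` (Ks, S)
adds `2 Ks / Rp` to the bulk particle conductivity. Default 0, because
Ks is a fitted, lot-specific quantity no one should get silently.
Plausible sets that place the cross-over where typical experiments see
it — documentation only, not asserted by tests, since Ks is never
measured independently here:

* 4.5 µm carboxyl PS in DI water (sigma_m = 2e-4 S/m): Ks ~ 0.33 nS
  gives fco ~ 40 kHz.
* 2.48 µm plain PS in 1 µS/cm water: Ks ~ 1 nS gives fco ~ 260 kHz
  (equivalently, effective sigma_p ~ 1.55 mS/m, as in the README
  example).

## Waveform spectra and energy convention

An ideal 50%-duty square wave of peak V0 has odd-harmonic lines
`A_n = (4/pi) V0 / n` (even orders exactly zero; harmonic order n =
2k-1 in the series index k). Line energies use the convention
**P_n = A_n^2 on peak amplitudes** — no 1/2 factor — so a unit sine
has total energy 1 and the full square-wave series
`(16/pi^2) * pi^2/8 = 2`: the "twice the energy at equal peak"
statement. `time_domain_energy` is scaled to the same convention
(2x the mean square over one period); a literal period integral of
v(t) would vanish for any AC signal, so the mean-square reading is the
only one consistent with the spectral totals (Parseval). The tests
check Parseval two ways: closed form, and uniform-sampling integration
of the truncated synthesis (exact for trig polynomials by discrete
orthogonality).

Defaults: truncation max_order = 199 (first 100 odd harmonics —
captures > 99.7% of harmonic energy by the tail bound
`sum_{k>N} 1/(2k-1)^2 < 1/(4N)`); all lines carry the sine phase of
the series; duty cycle fixed at 50%. Bandwidth limiting of a real
drive chain is modelled as an ideal brick-wall by default (lines above
the cutoff removed) with an optional first-order low-pass
(`amplitude / sqrt(1+(f/fc)^2)`) — the simplest physical alternative;
no measured amplifier response is modelled.

## Force decomposition and the advisor

Each line contributes `K G A_n^2 Re{CM}(n f0)` with `K = 2 pi Rp^3
eps_m`; the force is quadratic in the field, and cross-frequency beat
terms average to zero over a period, so lines add independently. The
spatial factor grad|E_rms|^2 is collapsed into one positive scalar G
identical for all harmonics (electrode geometry treated as
frequency-independent; anything else would require an electrode
model). Harmonic (n > 1) contributions are split by sign into A >= 0
and B <= 0; `total = fundamental + A + B`.

The comparison baseline is an **equal peak amplitude** sinusoid at f0
(the same-Vpp comparison used in practice when swapping generator
waveforms); an equal-RMS mode is available, which for a square-wave
source doubles the baseline energy.

The advisor reports two verdicts side by side:

* **Energy rule (tri-state, conservative).** `beneficial` if
  f0 < fco/5 — the 3rd+5th harmonics (0.1511) exceed half of all
  harmonic energy (0.5 x 0.2337 = 0.1168), so even if every higher
  harmonic opposes at the worst-case weight the net force grows;
  `always beneficial` if f0 > fco or no crossover exists (all
  harmonics share the fundamental's sign); `not guaranteed` in
  between. The divisor 5 is itself computed
  (`smallest_safe_divisor(0.5)`), and generalizes to other energy
  thresholds. The rule is sufficient, not necessary, and assumes
  |Re{CM}| at opposing harmonics does not exceed its value at the
  fundamental; the property test enforces exactly that scope.
* **Exact rule.** `beneficial_exact` = the CM-weighted total exceeds
  the sine baseline in magnitude with the same sign; `gain_ratio` =
  total/baseline (→ 2 as the dispersion flattens; an exactly flat
  test system uses eps_p = 2 eps_m, sigma_p = 2 sigma_m, which makes
  Re{CM} ≡ 0.25 identically).

Dispersions with more than one sign change across the harmonic range
(multishell particles, membrane-covered cells) are outside the rule's
validity; `advise` refuses them with `MultiCrossoverError` while
`decompose_force` still works line-by-line. The homogeneous-sphere
model here cannot produce them; the check guards future dispersion
models.

## Efficiency metrics and the synthetic trace

`failure_rate` = 100 x escaped/entered (%, counts from video analysis
of an electrode region). `separation_efficiency` eta = 1 - (mean
outlet intensity in the evaluation window) / (mean in the baseline
window); plain arithmetic means of the in-window samples, no
resampling. Negative eta (outlet brighter than baseline — release or
enrichment) is physically meaningful and passed through with a
warning, never clamped. Replicates are aggregated as mean with both
sample SD (ddof = 1) and SEM, since a bare "±" does not distinguish
them; with n = 3 replicates SD is the conservative choice.

The generator emulates the canonical mesh-filter run: 60 s baseline,
180 s field-on, 120 s recovery, sampled at 1 Hz. The outlet sees each
phase ~10 s late (transport from filter to detector; visible in real
traces as the intensity drop starting near 70 s and the release peak
after 250 s), which is why the standard 225–245 s evaluation window —
nominally straddling the 240 s switch-off — still samples the trapping
plateau at the detector. Trace objects therefore store
*outlet-referred* phase boundaries, default (70 s, 250 s), and
validate that the evaluation window lies inside the field-on phase and
the baseline window (default 10–55 s, edges trimmed) inside the
baseline phase. Field-on intensity settles exponentially (tau = 5 s,
so the plateau is reached to ~1e-13 by 225 s and noiseless recovery is
exact) to `trap_fraction x baseline`; recovery returns to baseline
with a Gaussian release peak (default height 0.5 x baseline, centre
10 s after switch-off, width 6 s). Additive white noise (default SD
0.01 x the unit baseline, about the relative noise of a spectrometer
trace) is seeded and the result clipped at zero. Ground truth
eta = 1 - trap_fraction is recorded on the trace.

What a green test establishes: the estimator recovers the generator's
plateau ratio under iid Gaussian noise (mean absolute error < 0.02
over a trap-fraction grid). What it does not: real traces have drift,
bleaching, pump pulsation, non-proportionality between intensity and
concentration, and saturation of the filter — none of which are
emulated, so agreement here says nothing about instrument systematics.

## Numerical choices

* Frequencies in Hz everywhere at the interface; omega = 2 pi f
  internally. Root bracket for the oracle: [1e-2, 1e14] Hz; closed
  form vs oracle agreement required to < 1e-4 relative.
* CSV I/O writes floats with %.17g and reads with round-trip
  precision, so write→read→write is byte-idempotent.
* JSON advisor reports are schema-versioned (`schema_version: 1`) and
  round-trip every numeric field at full double precision.
* The gain-ratio → 2 limit is demonstrated at the truncation the tail
  bound requires (~1e6 lines, still < 1 s vectorized); at the default
  truncation 199 the ratio is 1.99595..., matching its analytic
  partial-sum value to 1e-9 — the 2.5e-3 gap *is* the harmonic tail,
  not numerical error.

## Limitations

Homogeneous-sphere CM only (no multishell/membrane models, no
electrorotation/imaginary part, no temperature dependence); ideal
symmetric square waves only (no ramp/triangle, no duty-cycle control,
no measured-waveform ingestion); the field-gradient scalar G is the
user's responsibility (no electrode/CFD modelling); efficiency metrics
assume intensity proportional to concentration.
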