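# Methods

This note documents the models, conventions and design choices behind
`cochlenv`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and where the genuinely open choices
were made.

## Stimulus and exact-bin convention

The three-tone complex is synthesized directly from its defining sum; the
phase φ (degrees at the interface, radians internally) applies to the
center tone only. Derived frequencies f₂ = f₁ + f_e and f₃ = f₁ + 2 f_e
are always recomputed from f₁ and f_e, never stored.

All spectral quantities in the package follow an **exact-bin convention**:
analysis records span an integer number of 1/f_e periods and are analysed
with a rectangular window. Because f₁ is an integer multiple of f_e in
every configuration used here, *all* components of interest — primaries,
f_e, 2 f_e, 3 f_e and the integer-combination distortion products — fall
exactly on Fourier bins and are leakage-free. This makes component
extraction testable against a single-frequency projection oracle at
10⁻⁹ relative accuracy. Welch/multitaper averaging is deliberately out of
scope: single exact-bin records suffice for every quantity computed.

Amplitude spectra use the peak convention (a sinusoid of amplitude A gives
a bin value A); DC is reported separately; the Nyquist bin is not doubled.
Component lookups that miss a bin center by half a bin width or more raise
an error rather than silently reading a neighbouring bin.

Defaults: 100-ms records (50 envelope periods at f_e = 500 Hz), sample
rate 16 × f₃ with a 64-kHz floor — an 8× oversampling of the highest
primary that keeps third-order distortion products far from Nyquist.
Ramps default to a 5-ms cos² gate (animal protocol); a 30-ms/1-ms human
protocol preset is provided. Component analysis is always performed on the
unramped plateau.

## Envelope analysis

The envelope is the magnitude of the analytic signal (Hilbert transform).
For the three-tone complex it has the closed form
A·√(4 cos²(2π f_e t) + 4 cos φ · cos(2π f_e t) + 1), which the
implementation reproduces to quadrature accuracy. Two conventions, chosen
where the procedure itself is underdetermined:

* **Edge exclusion.** The analytic signal is distorted near record edges,
  so at least 5 % of the samples at each end are excluded, rounded up to
  whole f_e periods to preserve exact bins.
* **DC removal and normalization.** The envelope mean is removed before
  the Fourier step, so the f_e and 2 f_e values are pure modulation
  amplitudes; phase-sweep tables are optionally normalized by each
  component's own maximum over the sweep (recorded in the table).

A quadratic (Taylor) nonlinearity applied to the stimulus predicts
envelope-side components in the ratio 2·|cos φ| at f_e to 1 at 2 f_e. The
exact envelope's f_e Fourier coefficient follows |cos φ| closely but not
perfectly: the deviation reaches ≈ 0.07 of full scale near 45°, because
the |cos φ| law is exact only for the purely quadratic term. The package
therefore treats |cos φ| as the regression predictor it is, and verifies
1 %-level agreement only in the small-signal receptor-current regime,
where the quadratic term genuinely dominates.

## MET channel model

The Boltzmann activation curve is evaluated sample-wise — no kinetics, no
adaptation state; this is the model's central assumption (infinitely fast
channels), and its consequences (all distortion orders generated
instantaneously) are exactly what the analysis quantifies. Parameters with
defaults: I_max = 2.5 nA, X₀ = 5.5 nm (resting open probability 0.206),
Z = 1.05 pN, T = 310.15 K, k_B = 1.381 × 10⁻²³ J/K; the activation-curve
width k_B T / Z is then 4.08 nm. Exponent clipping at ±700 makes extreme
displacements saturate to 0 or I_max instead of overflowing. Component
amplitudes below 10⁻¹² × I_max are treated as floor values so dB
differences stay finite.

The X₀ sweep uses a 0–20 nm grid in 0.05-nm steps, ties at the maximum
resolving to the smaller X₀. With the default drive (1 nm per component)
the f_e-maximizing offset computes to 5.5 nm. This is consistent with
small-signal theory: the quadratic-distortion coefficient of a logistic of
width s is proportional to its second derivative, maximal at open
probability (3 − √3)/6, i.e. at an offset s·ln((3 + √3)/(3 − √3)) ≈ 1.32 s
≈ 5.4 nm, with mild saturation at the 3-nm peak drive nudging it to 5.5.

## Electrode filter

A glass microelectrode acts as a first-order low-pass,
H(f) = 1/(1 + i f/f_c), with f_c typically 1–5 kHz. The forward model and
the correction are both applied in the frequency domain (exact for the
periodic records used here); time-domain corrected traces come from the
inverse FFT. The correction gain |1/H| is capped at its value at 10 × f_c
(≈ 20 dB) so it cannot amplify high-frequency noise without bound — the
cap level is a package choice, as is the frequency-domain (rather than
IIR) forward implementation, which buys exact round-trip testability.

## Synthetic recordings

The generators emulate the *statistical structure* of the three recording
sites, not their physiology:

* **BM**: primaries plus requested high-frequency distortion products
  (levels in dB re f₁, random phases) plus noise. The deterministic part
  has exactly zero energy at f_e/2 f_e by construction, and requesting an
  envelope-frequency component is a contract violation. No traveling-wave
  mechanics, compressive nonlinearity or tuning is modelled.
* **OoC**: Boltzmann current → electrode low-pass → noise, labelled µV
  with a nominal 1 nA → 1 µV calibration (far-field electrical calibration
  is arbitrary in this emulation).
* **RW**: a sum over cells with X₀ ~ Normal(x0_mean, x0_sd) and log-normal
  gain jitter, plus an optional neural surrogate and noise. The surrogate
  — a half-wave-rectified, low-pass-filtered (6 f_e) copy of the stimulus
  envelope, scaled relative to the summed saturating current — is a
  minimal envelope-locked waveform that exists solely so the TTX flag has
  something to remove; it is explicitly not a model of auditory-nerve
  physiology.

Noise is white Gaussian shaped in the frequency domain: flat amplitude
density above a corner frequency, rising at a configurable dB/octave below
it (default 6 dB/oct below 200 Hz), emulating the low-frequency noise rise
of interferometric recordings. Seeds are mandatory inputs and are recorded
in output metadata; identical seeds give bit-identical records.

Sweep averaging rejects records whose 0–50 Hz band RMS (breathing-rate
scale) exceeds 3× the median across sweeps — band and factor are package
choices, since the acquisition systems being emulated publish no
threshold — then averages the survivors in the time domain.

Passing tests on these generators shows the *analysis chain* is correct
under the assumed structure (stationary shaped noise, memoryless
transduction, linear electrode). It does not validate the generators
against real cochlear data: real recordings add compressive mechanics,
adaptation, and nonstationary noise that are deliberately absent here.

## Statistics

* **Permutation test vs noise.** Statistic: difference of group means,
  one-sided (signal > noise), add-one p-value over label permutations
  drawn with replacement. Minimum 99 permutations; p ∈ [1/(n+1), 1].
* **Phase-effect fit.** log(level) = intercept_prep + slope·|cos φ|, by
  least squares with per-preparation fixed intercepts; the slope p-value
  comes from permuting phase labels within each preparation (one-sided,
  slope > 0). This is a fixed-effects approximation of a random-intercept
  mixed model: point estimates coincide on balanced designs, and
  inference is permutation-based rather than likelihood-based, so no REML
  machinery is required. Levels must be positive; a constant |cos φ|
  design raises an error.

Both procedures are calibrated in the test suite (type-I error 5 % ± 1 %
at α = 0.05 over 2000 null replicates; exact slope recovery on noiseless
data).

## Problem sizes and determinism

The standard experiment uses 100-ms records at 248 kHz (24 800 samples)
and a 401-point X₀ grid; unit tests use 20-ms records (10 envelope
periods), which keep every exact-bin property intact. The receptor-current
experiment is fully deterministic; every stochastic routine takes an
explicit seed and derives per-sweep seeds from it below 2³¹.

## Known limitations

* The Boltzmann model underpredicts measured in-vivo envelope levels
  (−17 dB re f₁ versus around −7 dB measured); additional nonlinearities
  in bundle mechanics and organ-of-Corti feedback are out of scope.
* Tip-to-tail uses the mean of the 0°/180° dB levels as the tip (falling
  back to 0° alone); whether experimental practice uses one or both
  phases is a convention, and both are computable.
* The envelope |cos φ| comparison is approximate by nature (see above);
  sub-percent agreement should not be expected of the exact envelope.
* WAV export uses IEEE-float samples with a JSON sidecar for rate, units
  and provenance; integer-PCM WAV files are readable but lose the unit
  metadata unless a sidecar is present.
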