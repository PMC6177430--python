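"""Three-tone complex synthesis with controllable center-tone phase.

The stimulus is the sum of three equal-amplitude sinusoids with constant
frequency separation ``f_e``::

    x(t) = A sin(2π f1 t) + A sin(2π f2 t + φ) + A sin(2π f3 t)
    f2 = f1 + f_e,   f3 = f1 + 2 f_e

Shifting the phase φ of the center tone reshapes the waveform envelope —
from alternating large/small peaks recurring at f_e (φ = 0°) to a flatter
outline dominated by 2 f_e periodicity (φ = 90°) — while leaving the
magnitude spectrum untouched.  Crucially the stimulus itself carries no
spectral component at f_e or 2 f_e, which is what makes it a clean probe of
envelope extraction by downstream nonlinearities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError, RampError, SamplingRateError
from .timeseries import TimeSeries

__all__ = [
    "ThreeToneParams",
    "IN_VIVO_PROTOCOL",
    "HUMAN_PROTOCOL",
    "default_sample_rate",
    "synthesize_three_tone",
    "apply_ramp",
    "assert_no_envelope_component",
    "EnvelopeComponentReport",
]

#: Minimum default sample rate (Hz): even low-frequency complexes are
#: rendered with generous headroom for distortion analysis.
MIN_SAMPLE_RATE = 64_000.0


@dataclass(frozen=True)
class ThreeToneParams:
    """Definition of a three-tone complex.

    Parameters
    ----------
    A
        Per-component amplitude (nm for bundle displacement, Pa or
        normalized for acoustic use).
    f1
        Lowest component frequency (Hz).
    f_e
        Component spacing (Hz); equals the repetition rate of the large
        envelope peaks.
    phi
        Center-tone phase in degrees.
    duration
        Signal length (s).
    ramp
        Rise/fall time (s) of the cos² gate.
    ramp_shape
        ``"cos2"`` or ``"none"``.
    exact_bins
        When set, ``duration`` must be an integer number of 1/f_e periods so
        that f_e, 2 f_e, the primaries and all integer-combination
        distortion products fall exactly on Fourier bins of a rectangular
        analysis window.
    """

    A: float
    f1: float
    f_e: float
    phi: float = 0.0
    duration: float = 0.1
    ramp: float = 0.005
    ramp_shape: str = "cos2"
    exact_bins: bool = True

    def __post_init__(self) -> None:
        for name in ("A", "f1", "f_e", "phi", "duration", "ramp"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if self.f1 <= 0 or self.f_e <= 0:
            raise InvalidParameterError("f1 and f_e must be positive")
        if self.A < 0:
            raise InvalidParameterError("A must be non-negative")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be positive")
        if self.ramp < 0 or 2 * self.ramp > self.duration:
            raise RampError("need 0 <= 2*ramp <= duration")
        if self.ramp_shape not in ("cos2", "none"):
            raise InvalidParameterError(f"unknown ramp_shape {self.ramp_shape!r}")
        if self.exact_bins:
            n_periods = self.duration * self.f_e
            if abs(n_periods - round(n_periods)) > 1e-9 * max(1.0, n_periods):
                raise InvalidParameterError(
                    "exact_bins requires duration to be an integer multiple "
                    f"of 1/f_e; got {n_periods} periods")

    @property
    def f2(self) -> float:
        """Center-tone frequency, f1 + f_e (always derived, never stored)."""
        return self.f1 + self.f_e

    @property
    def f3(self) -> float:
        """Highest-tone frequency, f1 + 2 f_e."""
        return self.f1 + 2 * self.f_e

    def with_phi(self, phi: float) -> "ThreeToneParams":
        return replace(self, phi=phi)


#: Animal protocol: 100-ms bursts with 5-ms cos² rise/fall.
IN_VIVO_PROTOCOL = dict(duration=0.1, ramp=0.005)
#: Human protocol: 30-ms bursts with 1-ms cos² rise/fall.
HUMAN_PROTOCOL = dict(duration=0.03, ramp=0.001)


def default_sample_rate(params: ThreeToneParams) -> float:
    """16 × f3, floored at 64 kHz — clean headroom for 3rd-order products."""
    return max(16.0 * params.f3, MIN_SAMPLE_RATE)


def synthesize_three_tone(
    params: ThreeToneParams,
    sample_rate: float | None = None,
    units: str = "nm",
    two_speaker: bool = False,
):
    """Render the three-tone complex as a :class:`TimeSeries`.

    Parameters
    ----------
    params
        Stimulus definition; φ applies to the center tone only.
    sample_rate
        Hz; defaults to :func:`default_sample_rate`.  Must be at least
        16 × f3 (8× the Nyquist rate of the highest primary) so that
        high-order distortion products of downstream nonlinearities remain
        cleanly representable.
    units
        Unit label for the output, default displacement in nm.
    two_speaker
        When set, return a pair ``(side_tones, center_tone)`` of TimeSeries
        that sum sample-wise to the standard stimulus (emulating delivery of
        the phase-varying center tone through a second speaker).
    """
    if sample_rate is None:
        sample_rate = default_sample_rate(params)
    if sample_rate < 16.0 * params.f3 * (1 - 1e-12):
        raise SamplingRateError(
            f"sample_rate {sample_rate} Hz < 16*f3 = {16 * params.f3} Hz")
    n = int(round(sample_rate * params.duration))
    if n < 2:
        raise InvalidParameterError("duration too short for this sample rate")
    t = np.arange(n) / sample_rate
    phi = np.deg2rad(params.phi)
    side = params.A * (np.sin(2 * np.pi * params.f1 * t)
                       + np.sin(2 * np.pi * params.f3 * t))
    center = params.A * np.sin(2 * np.pi * params.f2 * t + phi)
    meta = {
        "generator": "synthesize_three_tone",
        "A": params.A, "f1": params.f1, "f_e": params.f_e,
        "phi_deg": params.phi, "duration": params.duration,
        "ramp": params.ramp, "ramp_shape": params.ramp_shape,
    }

    def _finish(x: np.ndarray, which: str) -> TimeSeries:
        ts = TimeSeries(x, sample_rate, units, meta=dict(meta, channel=which))
        if params.ramp_shape == "cos2" and params.ramp > 0:
            ts = apply_ramp(ts, params.ramp, "cos2")
        return ts

    if two_speaker:
        return _finish(side, "side_tones"), _finish(center, "center_tone")
    return _finish(side + center, "sum")


def apply_ramp(x: TimeSeries, ramp: float, shape: str = "cos2") -> TimeSeries:
    """Gate a waveform with a cos²-shaped rise/plateau/fall envelope.

    The gate rises as sin²(π t / (2 ramp)) over [0, ramp] (0 at onset, 1 at
    the plateau), holds unity, and falls as the mirror image.  ``ramp = 0``
    or ``shape = "none"`` returns the input unchanged.
    """
    if shape == "none" or ramp == 0:
        return x
    if shape != "cos2":
        raise InvalidParameterError(f"unknown ramp shape {shape!r}")
    if ramp < 0 or 2 * ramp > x.duration:
        raise RampError(f"2*ramp = {2 * ramp} s exceeds duration {x.duration} s")
    t = np.arange(x.n) / x.sample_rate
    gate = np.ones(x.n)
    rising = t < ramp
    gate[rising] = np.sin(np.pi * t[rising] / (2 * ramp)) ** 2
    t_end = (x.n - 1) / x.sample_rate
    falling = t > t_end - ramp
    gate[falling] = np.sin(np.pi * (t_end - t[falling]) / (2 * ramp)) ** 2
    return x.with_samples(x.samples * gate, ramped=ramp)


@dataclass(frozen=True)
class EnvelopeComponentReport:
    """Outcome of the stimulus-purity check at the envelope frequency."""

    passed: bool
    level_db: float  # level at f_e re the f1 component; -inf for silence


def assert_no_envelope_component(
    x: TimeSeries, f_e: float, tol_db: float = -60.0,
) -> EnvelopeComponentReport:
    """Verify a stimulus carries no energy at the envelope frequency.

    Analyses an integer number of f_e periods (the longest that fits, taken
    from the start of ``x``, which should be an unramped plateau) and
    reports the f_e level relative to the f1 component in dB.  A stimulus
    passes when that level is below ``tol_db``.  All-zero input passes with
    a −inf sentinel.
    """
    from .spectral import amplitude_spectrum, component_amplitude

    period = x.sample_rate / f_e
    n_periods = int(np.floor(x.n / period))
    if n_periods < 1:
        raise InvalidParameterError("record shorter than one f_e period")
    n_use = int(round(n_periods * period))
    seg = TimeSeries(x.samples[:n_use], x.sample_rate, x.units, meta=x.meta)
    if not np.any(seg.samples):
        return EnvelopeComponentReport(True, -np.inf)
    spec = amplitude_spectrum(seg)
    amp_fe = component_amplitude(spec, f_e)
    ref = float(np.max(spec.amps))  # strongest component = primary reference
    if amp_fe == 0.0:
        return EnvelopeComponentReport(True, -np.inf)
    level = 20.0 * np.log10(amp_fe / ref)
    return EnvelopeComponentReport(bool(level < tol_db), float(level))
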