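"""Amplitude spectra, distortion bookkeeping, dB ratios, electrode correction.

All component extraction in the package follows the exact-bin convention:
records span an integer number of 1/f_e periods and are analysed with a
rectangular window, so every quantity of interest — f_e, 2 f_e, the
primaries and the integer-combination distortion products — falls exactly
on a Fourier bin and suffers no leakage.  Amplitudes use the peak
convention: a pure sinusoid of amplitude A yields a bin value of A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BinAlignmentError, InvalidParameterError, MissingPhaseError
from .sweeps import PhaseSweepResult
from .timeseries import TimeSeries

__all__ = [
    "Spectrum",
    "DistortionSet",
    "amplitude_spectrum",
    "component_amplitude",
    "distortion_frequencies",
    "db_ratio",
    "estimate_noise_floor",
    "tip_to_tail",
    "first_order_lowpass",
    "correct_electrode_filter",
    "correct_electrode_filter_time",
    "spectrum_to_csv",
]


@dataclass
class Spectrum:
    """Single-sided amplitude spectrum with exact-bin lookup.

    ``amps[k]`` is the peak amplitude of the component at ``freqs[k]``; the
    DC (mean) value is kept apart in ``dc`` so component tables never mix it
    with oscillatory content.
    """

    freqs: np.ndarray
    amps: np.ndarray
    df: float
    dc: float = 0.0
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.amps = np.asarray(self.amps, dtype=float)
        if self.freqs.shape != self.amps.shape:
            raise InvalidParameterError("freqs and amps must align")


def amplitude_spectrum(x: TimeSeries) -> Spectrum:
    """Single-sided amplitude spectrum of a real record.

    Positive-frequency bins are scaled by 2/N (peak convention); the DC bin
    is reported separately and the Nyquist bin, when present, is not
    doubled.  Rectangular window — pair with exact-bin records.
    """
    n = x.n
    if n < 16:
        raise InvalidParameterError("need at least 16 samples")
    spec = np.fft.rfft(x.samples)
    amps = np.abs(spec) * (2.0 / n)
    dc = float(np.abs(spec[0]) / n)
    amps[0] = 0.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / x.sample_rate)
    return Spectrum(freqs, amps, df=x.sample_rate / n, dc=dc,
                    source_meta=dict(x.meta, units=x.units, n=n,
                                     sample_rate=x.sample_rate))


def component_amplitude(s: Spectrum, f: float) -> float:
    """Amplitude at the bin nearest ``f``.

    Raises :class:`BinAlignmentError` when ``f`` sits half a bin (or more)
    from every bin center — a misaligned lookup would silently read
    leakage.
    """
    k = int(round(f / s.df))
    if k < 0 or k >= s.freqs.size:
        raise BinAlignmentError(f"{f} Hz outside the spectrum")
    if abs(f - s.freqs[k]) >= 0.5 * s.df * (1 - 1e-9):
        raise BinAlignmentError(
            f"{f} Hz falls between bins (df = {s.df} Hz)")
    return float(s.amps[k])


@dataclass(frozen=True)
class DistortionSet:
    """Frequencies of the distortion products of a three-tone complex.

    Low-frequency (envelope-side) products at f_e, 2 f_e, 3 f_e, and the
    labelled high-frequency intermodulation products near the primaries.
    """

    f_e: float
    two_f_e: float
    three_f_e: float
    hf_products: dict

    def all_frequencies(self) -> dict:
        out = {"fe": self.f_e, "2fe": self.two_f_e, "3fe": self.three_f_e}
        out.update(self.hf_products)
        return out


#: Labels of the high-frequency intermodulation products tracked here.
HF_LABELS = ("2f1-f2", "3f1-2f2", "2f3-f2")


def distortion_frequencies(f1: float, f_e: float) -> DistortionSet:
    """Distortion-product frequencies for primaries f1, f1+f_e, f1+2 f_e."""
    if f1 <= 0 or f_e <= 0:
        raise InvalidParameterError("f1 and f_e must be positive")
    f2 = f1 + f_e
    f3 = f1 + 2 * f_e
    hf = {
        "2f1-f2": 2 * f1 - f2,
        "3f1-2f2": 3 * f1 - 2 * f2,
        "2f3-f2": 2 * f3 - f2,
    }
    return DistortionSet(f_e, 2 * f_e, 3 * f_e, hf)


def db_ratio(a: float, b: float, floor: float | None = None) -> float:
    """20·log10(a/b) with optional floor for dead-silent numerators.

    ``floor`` replaces a numerator below it, keeping dB arithmetic finite
    for components at the numerical floor; ``b`` must be positive.
    """
    if b == 0:
        raise ZeroDivisionError("reference amplitude is zero")
    if b < 0 or a < 0:
        raise InvalidParameterError("amplitudes must be non-negative")
    if floor is not None:
        a = max(a, floor)
    if a == 0:
        return -np.inf
    return float(20.0 * np.log10(a / b))


def estimate_noise_floor(s: Spectrum, f: float, half_window: int = 20,
                         exclude: tuple = ()) -> float:
    """Median amplitude of the ±``half_window`` bins around ``f``.

    Bins within half a bin of any frequency in ``exclude`` (plus the target
    itself) are left out so deterministic components do not inflate the
    floor estimate.
    """
    k = int(round(f / s.df))
    lo, hi = max(1, k - half_window), min(s.amps.size, k + half_window + 1)
    idx = np.arange(lo, hi)
    keep = np.ones(idx.size, dtype=bool)
    for fx in tuple(exclude) + (f,):
        keep &= np.abs(idx - fx / s.df) > 0.5
    if not np.any(keep):
        raise InvalidParameterError("no noise bins left in the window")
    return float(np.median(s.amps[idx[keep]]))


def tip_to_tail(sweep: PhaseSweepResult, component: str) -> float:
    """Tip-to-tail ratio (dB) of one component over a center-tone phase sweep.

    Tip = level at the peaked-envelope phases, the mean of the dB levels at
    0° and 180° when both are present, else the 0° level alone; tail = level
    at the flat-envelope phase 90°.  Invariant under any global gain.
    """
    amps = sweep.component(component)

    def _at(phase: float) -> float | None:
        hit = np.isclose(sweep.phases, phase, atol=1e-6)
        if not np.any(hit):
            return None
        return float(amps[np.argmax(hit)])

    a0, a90, a180 = _at(0.0), _at(90.0), _at(180.0)
    if a0 is None or a90 is None:
        raise MissingPhaseError("sweep must include phases 0° and 90°")
    if a0 <= 0 or a90 <= 0 or (a180 is not None and a180 <= 0):
        raise InvalidParameterError("levels must be positive for dB ratios")
    tip_db = 20 * np.log10(a0)
    if a180 is not None:
        tip_db = 0.5 * (tip_db + 20 * np.log10(a180))
    return float(tip_db - 20 * np.log10(a90))


# --- electrode filter -------------------------------------------------------
#
# A glass microelectrode behaves as a first-order low-pass filter
# H(f) = 1 / (1 + i f / f_c).  Recordings are corrected by dividing each
# complex bin by H(f); the inverse gain |1/H| is capped at its value at
# 10 × f_c (≈ 20 dB) so the correction cannot amplify high-frequency noise
# without bound.

def _inverse_gain(freqs: np.ndarray, cutoff: float, cap_at: float = 10.0):
    """Complex 1/H(f) with magnitude clipped at |1/H(cap_at · f_c)|."""
    h_inv = 1.0 + 1j * freqs / cutoff
    cap = np.sqrt(1.0 + cap_at ** 2)
    mag = np.abs(h_inv)
    over = mag > cap
    h_inv[over] *= cap / mag[over]
    return h_inv


def first_order_lowpass(x: TimeSeries, cutoff: float) -> TimeSeries:
    """Forward electrode model: multiply each bin by H(f) = 1/(1 + i f/f_c).

    Applied in the frequency domain (circular), matching the exact-bin
    analysis convention; on periodic records this is the exact steady-state
    response.
    """
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    spec = np.fft.rfft(x.samples)
    freqs = np.fft.rfftfreq(x.n, d=1.0 / x.sample_rate)
    spec /= (1.0 + 1j * freqs / cutoff)
    return x.with_samples(np.fft.irfft(spec, n=x.n),
                          electrode_cutoff=cutoff)


def correct_electrode_filter(s: Spectrum, cutoff: float,
                             cap_at: float = 10.0) -> Spectrum:
    """Undo the electrode low-pass on an amplitude spectrum.

    Each amplitude is multiplied by |1/H(f)| = sqrt(1 + (f/f_c)²), clipped
    at the boost attained at ``cap_at`` × cutoff.
    """
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    gain = np.abs(_inverse_gain(s.freqs.astype(complex), cutoff, cap_at))
    return Spectrum(s.freqs.copy(), s.amps * gain, s.df, s.dc,
                    dict(s.source_meta, electrode_corrected=cutoff))


def correct_electrode_filter_time(x: TimeSeries, cutoff: float,
                                  cap_at: float = 10.0) -> TimeSeries:
    """Electrode correction of a time trace via the inverse Fourier transform."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    spec = np.fft.rfft(x.samples)
    freqs = np.fft.rfftfreq(x.n, d=1.0 / x.sample_rate)
    spec *= _inverse_gain(freqs, cutoff, cap_at)
    return x.with_samples(np.fft.irfft(spec, n=x.n),
                          electrode_corrected=cutoff)


def spectrum_to_csv(s: Spectrum, path) -> None:
    """Write ``freq_hz, amplitude, units`` rows for a spectrum."""
    import pandas as pd

    units = s.source_meta.get("units", "arb")
    pd.DataFrame({"freq_hz": s.freqs, "amplitude": s.amps,
                  "units": units}).to_csv(path, index=False)
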