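"""Envelope extraction via the analytic signal and its spectral components.

The envelope of a waveform is the magnitude of its analytic (Hilbert)
signal.  For the three-tone complex the envelope has the closed form

    env(t) = A · sqrt(4 cos²(2π f_e t) + 4 cos φ · cos(2π f_e t) + 1),

so its f_e component vanishes at φ = 90° while the 2 f_e component barely
moves — the signature this package exists to quantify.  A quadratic
(Taylor-series) nonlinearity applied to the stimulus predicts relative
envelope-side components 2·cos φ at f_e and 1 at 2 f_e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .errors import BinAlignmentError, InvalidParameterError
from .spectral import amplitude_spectrum, component_amplitude
from .stimulus import ThreeToneParams, synthesize_three_tone
from .timeseries import TimeSeries

__all__ = [
    "EnvelopeSpectrumResult",
    "hilbert_envelope",
    "envelope_component_amplitudes",
    "quadratic_prediction",
    "phase_sweep",
    "phase_sweep_to_csv",
]

#: Fraction of samples excluded at each edge before envelope statistics, to
#: keep analytic-signal edge transients out of the analysis window.
EDGE_FRACTION = 0.05


@dataclass(frozen=True)
class EnvelopeSpectrumResult:
    """Envelope components of one record at one center-tone phase."""

    phi: float          # degrees
    amp_fe: float       # envelope amplitude at f_e (input units)
    amp_2fe: float      # envelope amplitude at 2 f_e
    dc: float           # envelope mean over the analysis window
    normalization: str = "none"


def hilbert_envelope(x: TimeSeries) -> TimeSeries:
    """Magnitude of the analytic signal of ``x`` (same length, rate, units)."""
    if x.n < 16:
        raise InvalidParameterError("need at least 16 samples")
    env = np.abs(hilbert(x.samples))
    return x.with_samples(env, envelope="hilbert-magnitude")


def envelope_component_amplitudes(x: TimeSeries, f_e: float,
                                  phi: float = np.nan) -> EnvelopeSpectrumResult:
    """Envelope amplitudes at the exact f_e and 2 f_e bins.

    The Hilbert envelope is computed on the full record; the analysis
    window then drops at least :data:`EDGE_FRACTION` of the samples at each
    edge, rounded up to whole f_e periods so both components stay on exact
    bins.  The envelope mean (DC) is removed before the Fourier step, so
    ``amp_fe`` is a pure modulation amplitude.
    """
    period = x.sample_rate / f_e
    if abs(period - round(period)) > 1e-9 * period:
        raise BinAlignmentError(
            "sample_rate must be an integer multiple of f_e for exact-bin "
            "envelope analysis")
    period = int(round(period))
    env = hilbert_envelope(x).samples
    skip = int(np.ceil(EDGE_FRACTION * x.n / period)) * period
    n_keep = ((x.n - 2 * skip) // period) * period
    if n_keep < period:
        raise InvalidParameterError("record too short after edge exclusion")
    seg = env[skip:skip + n_keep]
    dc = float(np.mean(seg))
    spec = amplitude_spectrum(
        TimeSeries(seg - dc, x.sample_rate, x.units, meta=x.meta))
    return EnvelopeSpectrumResult(
        phi=float(phi),
        amp_fe=component_amplitude(spec, f_e),
        amp_2fe=component_amplitude(spec, 2 * f_e),
        dc=dc,
    )


def quadratic_prediction(phi: float) -> dict:
    """Envelope-side coefficients of a quadratic nonlinearity.

    For the three-tone input, the squared term contributes components in
    relative amplitude 2·|cos φ| at f_e and 1 at 2 f_e.
    """
    return {"c_fe": float(2.0 * np.abs(np.cos(np.deg2rad(phi)))),
            "c_2fe": 1.0}


def phase_sweep(
    params: ThreeToneParams,
    phis=np.arange(0.0, 181.0, 15.0),
    sample_rate: float | None = None,
    normalization: str = "max-over-sweep",
) -> pd.DataFrame:
    """Envelope components across a center-tone phase sweep.

    Synthesizes the unramped plateau at each phase, extracts the envelope
    components, and optionally normalizes each component trace by its own
    maximum over the sweep (the convention used for relative-amplitude
    plots).  Returns a DataFrame with columns ``phi_deg, amp_fe, amp_2fe,
    dc, normalization``.
    """
    if normalization not in ("none", "max-over-sweep"):
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    from dataclasses import replace

    plateau = replace(params, ramp=0.0, ramp_shape="none")
    rows = []
    for phi in np.asarray(phis, dtype=float):
        x = synthesize_three_tone(plateau.with_phi(phi), sample_rate)
        r = envelope_component_amplitudes(x, params.f_e, phi=phi)
        rows.append((phi, r.amp_fe, r.amp_2fe, r.dc))
    df = pd.DataFrame(rows, columns=["phi_deg", "amp_fe", "amp_2fe", "dc"])
    if normalization == "max-over-sweep":
        for col in ("amp_fe", "amp_2fe"):
            peak = df[col].max()
            if peak > 0:
                df[col] = df[col] / peak
    df["normalization"] = normalization
    return df


def phase_sweep_to_csv(df: pd.DataFrame, path) -> None:
    """Write a phase-sweep table (phi_deg, amp_fe, amp_2fe, dc, normalization)."""
    df.to_csv(path, index=False)
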