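"""Synthetic recordings with the statistical structure the analysis assumes.

Three families of traces are generated, mirroring the measurement sites of
the envelope-detection experiments:

* **Basilar-membrane-like (BM)** — the three primaries plus optional
  high-frequency intermodulation products, with a noise floor that rises at
  low frequencies (as in interferometric recordings).  By construction the
  deterministic part carries *zero* energy at f_e and 2 f_e: the mechanical
  input contains no envelope-frequency component.
* **Organ-of-Corti-like (OoC)** — a Boltzmann receptor current low-pass
  filtered by a first-order electrode model, plus noise: the electrical
  signal in which envelope tracking first appears.
* **Round-window-like (RW)** — a population sum of MET currents with
  per-cell operating-point and gain jitter, a removable envelope-locked
  neural surrogate (TTX emulation), and noise.

A sweep-averaging routine with low-frequency artifact rejection emulates
the acquisition protocol (repeated 100-ms presentations, records
contaminated by breathing movements rejected automatically).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import hilbert

from .errors import (AllSweepsRejectedError, ContractError,
                     InvalidParameterError)
from .met_model import BoltzmannParams, boltzmann_current, simulate_receptor_current
from .spectral import HF_LABELS, distortion_frequencies, first_order_lowpass
from .stimulus import ThreeToneParams, synthesize_three_tone
from .timeseries import TimeSeries

__all__ = [
    "NoiseModel",
    "PopulationConfig",
    "SweepSet",
    "synthesize_noise",
    "generate_bm_recording",
    "generate_ooc_recording",
    "generate_rw_recording",
    "generate_sweep_set",
    "average_with_artifact_rejection",
    "apply_electrode_filter",
]

# Forward electrode model (first-order low-pass), re-exported here because
# the synthetic OoC chain owns the forward direction; the spectral module
# owns the correction.
apply_electrode_filter = first_order_lowpass


@dataclass(frozen=True)
class NoiseModel:
    """Parametric recording-noise model.

    White Gaussian noise shaped in the frequency domain: amplitude spectral
    density ``floor`` (units/√Hz) above ``lf_corner`` and rising at
    ``lf_slope`` dB/octave below it — the low-frequency rise typical of in
    vivo interferometric recordings.
    """

    floor: float = 0.0          # units/sqrt(Hz)
    lf_corner: float = 200.0    # Hz
    lf_slope: float = 6.0       # dB/octave below the corner
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.floor < 0 or self.lf_corner <= 0 or self.lf_slope < 0:
            raise InvalidParameterError(
                "need floor >= 0, lf_corner > 0, lf_slope >= 0")

    def density(self, freqs: np.ndarray) -> np.ndarray:
        """Amplitude spectral density (units/√Hz) at ``freqs``."""
        freqs = np.asarray(freqs, dtype=float)
        safe = np.where(freqs > 0, freqs, self.lf_corner)
        octaves_below = np.log2(np.maximum(self.lf_corner / safe, 1.0))
        out = self.floor * 10.0 ** (self.lf_slope * octaves_below / 20.0)
        return np.where(freqs > 0, out, 0.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Round-window population: cell count, operating-point/gain jitter,
    and the neural surrogate amplitude (zeroed by the ``ttx`` flag)."""

    n_cells: int = 50
    x0_mean: float = 5.5       # nm
    x0_sd: float = 1.0         # nm
    gain_sd: float = 0.2       # sd of log-normal gain jitter
    neural_gain: float = 0.0   # relative to the summed hair-cell current
    ttx: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if self.x0_sd < 0 or self.gain_sd < 0 or self.neural_gain < 0:
            raise InvalidParameterError(
                "x0_sd, gain_sd and neural_gain must be non-negative")


@dataclass
class SweepSet:
    """Repeated presentations of one stimulus, with ground-truth artifact
    flags for testing the rejection logic."""

    sweeps: list                      # list[TimeSeries], equal rate/length
    artifact_flags: np.ndarray        # bool per sweep (ground truth)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sweeps) < 1:
            raise InvalidParameterError("need at least one sweep")
        n = self.sweeps[0].n
        sr = self.sweeps[0].sample_rate
        for s in self.sweeps:
            if s.n != n or s.sample_rate != sr:
                raise InvalidParameterError(
                    "all sweeps must share length and sample rate")
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.artifact_flags.size != len(self.sweeps):
            raise InvalidParameterError("one artifact flag per sweep")


def _rng(noise_seed, override) -> np.random.Generator:
    seed = override if override is not None else noise_seed
    return np.random.default_rng(seed)


def synthesize_noise(n: int, sample_rate: float, noise: NoiseModel,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw one shaped-noise record of ``n`` samples.

    Complex Gaussian bins scaled so the expected single-sided bin amplitude
    matches the model's density: a bin of width df carries RMS amplitude
    ``density(f)·sqrt(2·df)`` (power density²·df per bin).
    """
    if noise.floor == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    df = sample_rate / n
    sigma = n * noise.density(freqs) * np.sqrt(df) / 2.0
    coef = sigma * (rng.standard_normal(freqs.size)
                    + 1j * rng.standard_normal(freqs.size))
    coef[0] = 0.0
    if n % 2 == 0:
        coef[-1] = coef[-1].real
    return np.fft.irfft(coef, n=n)


def _plateau(stim_params: ThreeToneParams) -> ThreeToneParams:
    return replace(stim_params, ramp=0.0, ramp_shape="none")


def generate_bm_recording(
    stim_params: ThreeToneParams,
    dp_levels_db: dict | None = None,
    noise: NoiseModel = NoiseModel(),
    sample_rate: float | None = None,
    units: str = "nm",
    seed: int | None = None,
) -> TimeSeries:
    """Basilar-membrane-like trace: primaries + HF distortion + shaped noise.

    ``dp_levels_db`` maps high-frequency product labels (``"2f1-f2"``,
    ``"3f1-2f2"``, ``"2f3-f2"``) to levels in dB re the f1 component.
    Envelope-frequency components cannot be requested: the deterministic
    part of a BM trace carries exactly zero energy at f_e and 2 f_e.
    ``units`` may be ``"nm"`` (displacement, interferometric emulation) or
    ``"um/s"`` (velocity, vibrometry emulation).
    """
    dp_levels_db = dict(dp_levels_db or {})
    bad = set(dp_levels_db) - set(HF_LABELS)
    if bad:
        raise ContractError(
            f"only high-frequency products {HF_LABELS} may be requested; "
            f"got {sorted(bad)} (envelope-frequency components are "
            "excluded by construction)")
    if units not in ("nm", "um/s"):
        raise InvalidParameterError("units must be 'nm' or 'um/s'")
    x = synthesize_three_tone(_plateau(stim_params), sample_rate, units=units)
    rng = _rng(noise.seed, seed)
    dset = distortion_frequencies(stim_params.f1, stim_params.f_e)
    t = np.arange(x.n) / x.sample_rate
    det = x.samples.copy()
    for label, level_db in dp_levels_db.items():
        amp = stim_params.A * 10.0 ** (level_db / 20.0)
        det += amp * np.sin(2 * np.pi * dset.hf_products[label] * t
                            + rng.uniform(0, 2 * np.pi))
    out = det + synthesize_noise(x.n, x.sample_rate, noise, rng)
    return TimeSeries(out, x.sample_rate, units, meta=dict(
        x.meta, generator="generate_bm_recording", seed=seed,
        dp_levels_db=dp_levels_db, noise_floor=noise.floor))


def generate_ooc_recording(
    stim_params: ThreeToneParams,
    met: BoltzmannParams = BoltzmannParams(),
    electrode_cutoff: float = 3000.0,
    noise: NoiseModel = NoiseModel(),
    sample_rate: float | None = None,
    seed: int | None = None,
) -> TimeSeries:
    """Organ-of-Corti-like electrical trace.

    Chain: three-tone displacement → Boltzmann receptor current →
    first-order electrode low-pass → additive shaped noise.  The trace is
    labelled µV with a nominal 1 nA → 1 µV calibration (the absolute
    electrical calibration is arbitrary in this emulation).
    ``electrode_cutoff`` must lie in [500, 20000] Hz; measured electrodes
    typically fall between 1 and 5 kHz.
    """
    if not 500.0 <= electrode_cutoff <= 20000.0:
        raise InvalidParameterError(
            "electrode_cutoff must lie within [500, 20000] Hz")
    x = synthesize_three_tone(_plateau(stim_params), sample_rate, units="nm")
    current = simulate_receptor_current(x, met)
    filtered = first_order_lowpass(current, electrode_cutoff)
    rng = _rng(noise.seed, seed)
    out = filtered.samples + synthesize_noise(x.n, x.sample_rate, noise, rng)
    return TimeSeries(out, x.sample_rate, "uV", meta=dict(
        filtered.meta, generator="generate_ooc_recording", seed=seed,
        electrode_cutoff=electrode_cutoff, noise_floor=noise.floor))


def _neural_surrogate(stim: TimeSeries, f_e: float) -> np.ndarray:
    """Envelope-locked neural waveform, unit peak amplitude.

    A minimal stand-in for the auditory-nerve contribution: the stimulus
    envelope, mean-subtracted, half-wave rectified and low-pass filtered at
    6 f_e.  It exists solely so the TTX flag has something to remove; it is
    not a physiological model.
    """
    env = np.abs(hilbert(stim.samples))
    rect = np.maximum(env - env.mean(), 0.0)
    spec = np.fft.rfft(rect)
    freqs = np.fft.rfftfreq(stim.n, d=1.0 / stim.sample_rate)
    spec /= (1.0 + 1j * freqs / (6.0 * f_e))
    wave = np.fft.irfft(spec, n=stim.n)
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def generate_rw_recording(
    stim_params: ThreeToneParams,
    pop: PopulationConfig = PopulationConfig(),
    met_base: BoltzmannParams = BoltzmannParams(),
    noise: NoiseModel = NoiseModel(),
    sample_rate: float | None = None,
    seed: int | None = None,
) -> TimeSeries:
    """Round-window-like population signal.

    Sum over ``pop.n_cells`` of Boltzmann currents with per-cell operating
    point X0 ~ Normal(x0_mean, x0_sd) and log-normal gain jitter, plus
    ``pop.neural_gain`` × an envelope-locked neural surrogate scaled to the
    summed saturating current (zeroed when ``pop.ttx`` is set), plus noise.
    Labelled µV (arbitrary far-field calibration).
    """
    x = synthesize_three_tone(_plateau(stim_params), sample_rate, units="nm")
    rng = _rng(pop.seed, seed)
    x0s = rng.normal(pop.x0_mean, pop.x0_sd, size=pop.n_cells)
    gains = np.exp(rng.normal(0.0, pop.gain_sd, size=pop.n_cells))
    total = np.zeros(x.n)
    for x0, gain in zip(x0s, gains):
        total += gain * boltzmann_current(x.samples, met_base.with_x0(x0))
    if pop.neural_gain > 0 and not pop.ttx:
        total += (pop.neural_gain * pop.n_cells * met_base.i_max
                  * _neural_surrogate(x, stim_params.f_e))
    total += synthesize_noise(x.n, x.sample_rate, noise, rng)
    return TimeSeries(total, x.sample_rate, "uV", meta=dict(
        x.meta, generator="generate_rw_recording", seed=seed,
        n_cells=pop.n_cells, ttx=pop.ttx, neural_gain=pop.neural_gain))


def generate_sweep_set(
    stim_params: ThreeToneParams,
    n_sweeps: int = 60,
    generator=generate_ooc_recording,
    artifact_sweeps: tuple = (),
    artifact_amp: float = 0.0,
    artifact_freq: float = 1.0,
    seed: int | None = 0,
    **generator_kwargs,
) -> SweepSet:
    """Repeated presentations with optional injected breathing artifacts.

    Each sweep gets an independent seed derived from ``seed``.  Sweeps
    listed in ``artifact_sweeps`` receive an additive low-frequency drift
    (sinusoid at ``artifact_freq`` Hz, amplitude ``artifact_amp``, random
    phase) emulating breathing contamination; the returned
    ``artifact_flags`` record the ground truth.
    """
    master = np.random.default_rng(seed)
    sweeps, flags = [], np.zeros(n_sweeps, dtype=bool)
    artifact_sweeps = set(artifact_sweeps)
    for i in range(n_sweeps):
        sub = int(master.integers(2 ** 31))
        ts = generator(stim_params, seed=sub, **generator_kwargs)
        if i in artifact_sweeps and artifact_amp > 0:
            t = np.arange(ts.n) / ts.sample_rate
            drift = artifact_amp * np.sin(
                2 * np.pi * artifact_freq * t + master.uniform(0, 2 * np.pi))
            ts = ts.with_samples(ts.samples + drift, artifact=True)
            flags[i] = True
        sweeps.append(ts)
    return SweepSet(sweeps, flags, meta={"seed": seed, "n_sweeps": n_sweeps})


def average_with_artifact_rejection(
    sweeps: SweepSet,
    reject_k: float = 3.0,
    artifact_band: tuple = (0.0, 50.0),
):
    """Average sweeps in the time domain, dropping artifact-contaminated ones.

    A sweep is rejected when its RMS within ``artifact_band`` (default
    0–50 Hz, the breathing-rate scale; DC excluded) exceeds ``reject_k`` ×
    the median band-RMS across sweeps.  Returns ``(average, report)`` with
    ``report = {"n_used", "n_rejected", "rejected_indices"}``.
    """
    if len(sweeps.sweeps) < 2:
        raise InvalidParameterError("need at least 2 sweeps")
    ref = sweeps.sweeps[0]
    freqs = np.fft.rfftfreq(ref.n, d=1.0 / ref.sample_rate)
    band = (freqs > max(artifact_band[0], 0.0)) & (freqs <= artifact_band[1])
    band[0] = False
    rms = np.empty(len(sweeps.sweeps))
    for i, s in enumerate(sweeps.sweeps):
        coef = np.fft.rfft(s.samples)[band]
        rms[i] = np.sqrt(np.sum(np.abs(coef) ** 2)) / ref.n
    median = np.median(rms)
    keep = rms <= reject_k * median if median > 0 else np.ones_like(rms, bool)
    if not np.any(keep):
        raise AllSweepsRejectedError("every sweep exceeded the artifact bound")
    stack = np.stack([s.samples for s, k in zip(sweeps.sweeps, keep) if k])
    avg = TimeSeries(stack.mean(axis=0), ref.sample_rate, ref.units,
                     meta=dict(ref.meta, averaged=int(keep.sum()),
                               reject_k=reject_k))
    report = {"n_used": int(keep.sum()),
              "n_rejected": int((~keep).sum()),
              "rejected_indices": np.flatnonzero(~keep).tolist()}
    return avg, report
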