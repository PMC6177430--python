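"""Uniformly sampled time series and float-WAV round-tripping.

The :class:`TimeSeries` container carries every waveform in the package:
acoustic or hair-bundle displacement stimuli, model receptor currents, and
synthetic recordings.  It stores a unit label and a free-form ``meta`` dict
(seed, generator name, parameters) so that any derived result can state its
provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InvalidParameterError

__all__ = ["TimeSeries", "write_wav", "read_wav"]


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        Ordered sample values; coerced to a float64 array.
    sample_rate
        Sampling rate in Hz; must be positive.
    units
        Non-empty unit label, e.g. ``"nm"``, ``"nA"``, ``"uV"``, ``"Pa"``.
    t0
        Time of the first sample in seconds.
    meta
        Provenance: seed, generator name, parameter values.
    """

    samples: np.ndarray
    sample_rate: float
    units: str
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidParameterError("samples must be 1-D with at least 2 values")
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive and finite")
        if not self.units:
            raise InvalidParameterError("units must be a non-empty string")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / sample_rate)."""
        return self.n / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sample_rate

    def with_samples(self, samples: np.ndarray, units: str | None = None,
                     **meta) -> "TimeSeries":
        """Copy carrying new samples (and optionally new units / extra meta)."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return TimeSeries(np.asarray(samples, dtype=float), self.sample_rate,
                          units if units is not None else self.units,
                          self.t0, new_meta)


def write_wav(ts: TimeSeries, path: str | Path) -> None:
    """Write a TimeSeries as an IEEE-float WAV plus a JSON sidecar.

    The sidecar (``<path>.json``) records sample rate, units, t0 and meta so
    the WAV round-trips losslessly through :func:`read_wav`.
    """
    path = Path(path)
    wavfile.write(path, int(round(ts.sample_rate)),
                  ts.samples.astype(np.float64))
    sidecar = {
        "sample_rate": ts.sample_rate,
        "units": ts.units,
        "t0": ts.t0,
        "meta": _jsonable(ts.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_wav(path: str | Path, units: str = "arb") -> TimeSeries:
    """Read a float WAV written by :func:`write_wav`.

    If the JSON sidecar is present its sample rate, units and meta take
    precedence; otherwise ``units`` is used and meta is empty.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    ts = TimeSeries(np.asarray(data, dtype=float), float(rate), units)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        ts = TimeSeries(ts.samples, float(info["sample_rate"]),
                        info["units"], float(info.get("t0", 0.0)),
                        dict(info.get("meta", {})))
    return ts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
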