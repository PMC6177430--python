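"""Phase-sweep result container shared by the spectral and stats layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = ["PhaseSweepResult"]


@dataclass
class PhaseSweepResult:
    """Component amplitudes as a function of center-tone phase.

    One sweep belongs to one preparation/recording site: ``levels`` maps a
    component label (``"fe"``, ``"2fe"``, ``"2f3-f2"``, ...) to the
    per-phase amplitudes, in the order of ``phases``.
    """

    phases: np.ndarray                   # degrees, ascending within [0, 180]
    levels: dict                         # label -> amplitudes (input units)
    prep_id: str = "prep0"
    stimulus_level_db: float | None = None
    site: str = "model"                  # one of BM, OoC, RW, model
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if np.any(np.diff(self.phases) < 0):
            raise InvalidParameterError("phases must be sorted ascending")
        if np.any(self.phases < 0) or np.any(self.phases > 180):
            raise InvalidParameterError("phases must lie within [0°, 180°]")
        for label, amps in self.levels.items():
            amps = np.asarray(amps, dtype=float)
            if amps.shape != self.phases.shape:
                raise InvalidParameterError(
                    f"levels[{label!r}] must align with phases")
            if np.any(amps < 0):
                raise InvalidParameterError("levels must be non-negative")
            self.levels[label] = amps

    def component(self, label: str) -> np.ndarray:
        try:
            return self.levels[label]
        except KeyError:
            raise InvalidParameterError(
                f"sweep has no component {label!r}; "
                f"available: {sorted(self.levels)}") from None
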