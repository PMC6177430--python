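"""Memoryless Boltzmann model of MET-channel activation.

Mechanoelectrical transduction (MET) channels in hair-cell stereocilia have
a sigmoidal activation curve.  The receptor current evoked by a bundle
displacement X (nm) is modelled as a first-order Boltzmann function

    I(X) = I_max / (1 + exp(−Z (X − X0) / (k_B T))),

where Z is the single-channel gating force (pN), X0 the horizontal offset
of the curve (nm) set by adaptation, T the absolute temperature and k_B
Boltzmann's constant.  The model has no temporal parameters — channels are
treated as infinitely fast — so simulation is a pure sample-wise map.  The
asymmetry of the curve about the operating point rectifies a three-tone
stimulus and thereby writes the stimulus envelope into the current
spectrum; at X0 = 0 (resting open probability 0.5) the curve is odd-symmetric
about rest and no envelope-frequency component is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError, UnitError
from .spectral import amplitude_spectrum, component_amplitude
from .stimulus import ThreeToneParams, synthesize_three_tone
from .timeseries import TimeSeries

__all__ = [
    "BOLTZMANN_CONSTANT",
    "BoltzmannParams",
    "X0SweepResult",
    "boltzmann_current",
    "resting_open_probability",
    "simulate_receptor_current",
    "sweep_x0",
    "fe_component_amplitudes",
]

#: Boltzmann's constant (J/K).
BOLTZMANN_CONSTANT = 1.381e-23

#: Relative numerical floor: component amplitudes below this fraction of
#: I_max are treated as floor values so dB arithmetic stays finite.
FLOOR_REL = 1e-12

_DISPLACEMENT_UNITS = ("nm",)


@dataclass(frozen=True)
class BoltzmannParams:
    """MET activation-curve parameters.

    Parameters
    ----------
    i_max
        Saturating current (nA); must be positive.
    x0
        Activation-curve offset (nm).  Any sign: it sets which direction of
        bundle motion the resting asymmetry favours.
    z
        Single-channel gating force (pN); must be positive.
    temperature
        Absolute temperature (K).
    k_b
        Boltzmann constant (J/K); fixed physical constant, overridable only
        for unit experiments.
    """

    i_max: float = 2.5
    x0: float = 5.5
    z: float = 1.05
    temperature: float = 310.15
    k_b: float = BOLTZMANN_CONSTANT

    def __post_init__(self) -> None:
        if self.i_max <= 0 or self.z <= 0 or self.temperature <= 0:
            raise InvalidParameterError("i_max, z and temperature must be positive")
        if not all(np.isfinite([self.i_max, self.x0, self.z,
                                self.temperature, self.k_b])):
            raise InvalidParameterError("all parameters must be finite")

    @property
    def slope_scale_nm(self) -> float:
        """k_B·T/Z expressed in nm — the width of the activation curve."""
        return self.k_b * self.temperature / (self.z * 1e-12) * 1e9

    def with_x0(self, x0: float) -> "BoltzmannParams":
        return replace(self, x0=x0)


def boltzmann_current(X, p: BoltzmannParams):
    """Receptor current (nA) for bundle displacement ``X`` (nm).

    Vectorized; strictly increasing in X and bounded in (0, I_max).  The
    exponent is clipped so extreme displacements saturate cleanly instead
    of overflowing.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("displacement must be finite")
    z = -(X - p.x0) / p.slope_scale_nm
    out = p.i_max / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return out if out.ndim else float(out)


def resting_open_probability(p: BoltzmannParams) -> float:
    """Open probability at rest (X = 0): 1 / (1 + exp(Z·X0 / k_B T))."""
    return float(boltzmann_current(0.0, p) / p.i_max)


def simulate_receptor_current(stim: TimeSeries, p: BoltzmannParams) -> TimeSeries:
    """Map a displacement waveform through the Boltzmann curve, sample-wise.

    No filtering and no state: the model treats MET gating as infinitely
    fast.  ``stim`` must be in displacement units (nm).
    """
    if stim.units not in _DISPLACEMENT_UNITS:
        raise UnitError(
            f"expected displacement units {_DISPLACEMENT_UNITS}, got "
            f"{stim.units!r}")
    current = boltzmann_current(stim.samples, p)
    return stim.with_samples(current, units="nA", model="boltzmann",
                             i_max=p.i_max, x0=p.x0, z=p.z,
                             temperature=p.temperature)


def fe_component_amplitudes(stim_params: ThreeToneParams, p: BoltzmannParams,
                            sample_rate: float | None = None) -> dict:
    """Simulate the unramped plateau and extract key current components.

    Returns amplitudes (nA) at f_e, 2 f_e and f1 for the given phase.  The
    record is the unramped plateau with integer f_e periods, so all three
    lookups are exact-bin.
    """
    plateau = replace(stim_params, ramp=0.0, ramp_shape="none")
    x = synthesize_three_tone(plateau, sample_rate, units="nm")
    current = simulate_receptor_current(x, p)
    spec = amplitude_spectrum(current)
    return {
        "fe": component_amplitude(spec, stim_params.f_e),
        "2fe": component_amplitude(spec, 2 * stim_params.f_e),
        "f1": component_amplitude(spec, stim_params.f1),
    }


@dataclass
class X0SweepResult:
    """f_e / 2 f_e current amplitudes as a function of the operating point."""

    grid: np.ndarray       # X0 values (nm), strictly increasing
    amp_fe: np.ndarray     # nA
    amp_2fe: np.ndarray    # nA
    argmax_fe: float       # grid point maximizing amp_fe (smallest on ties)


def sweep_x0(
    stim_params: ThreeToneParams,
    p_base: BoltzmannParams,
    grid=None,
    sample_rate: float | None = None,
) -> X0SweepResult:
    """Sweep the activation-curve offset X0 and track envelope-side currents.

    For each X0 on the grid the receptor current is simulated for the
    phase in ``stim_params`` and the exact-bin f_e and 2 f_e amplitudes are
    extracted.  Ties at the maximum resolve to the smallest X0.  The default
    grid spans 0–20 nm in 0.05-nm steps.
    """
    if grid is None:
        grid = np.arange(0.0, 20.0 + 1e-9, 0.05)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("grid must be non-empty, strictly increasing")

    plateau = replace(stim_params, ramp=0.0, ramp_shape="none")
    x = synthesize_three_tone(plateau, sample_rate, units="nm")
    n = x.n
    k_fe = int(round(stim_params.f_e * x.duration))
    amp_fe = np.empty(grid.size)
    amp_2fe = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        current = boltzmann_current(x.samples, p_base.with_x0(x0))
        spec = np.fft.rfft(current)
        amp_fe[i] = 2.0 * np.abs(spec[k_fe]) / n
        amp_2fe[i] = 2.0 * np.abs(spec[2 * k_fe]) / n
    return X0SweepResult(grid, amp_fe, amp_2fe,
                         argmax_fe=float(grid[int(np.argmax(amp_fe))]))
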