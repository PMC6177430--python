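"""Synthetic recordings at the three measurement sites.

Generates basilar-membrane-like, organ-of-Corti-like and round-window-like
traces for peaked (phi = 0) and flat (phi = 90 deg) envelopes and compares
their f_e content; then shows that removing the neural surrogate (TTX
emulation) leaves the round-window tip-to-tail ratio unchanged.
"""

import numpy as np

from cochlenv import (BoltzmannParams, NoiseModel, PhaseSweepResult,
                      PopulationConfig, ThreeToneParams, amplitude_spectrum,
                      component_amplitude, estimate_noise_floor,
                      generate_bm_recording, generate_ooc_recording,
                      generate_rw_recording, tip_to_tail)

stim = ThreeToneParams(A=1.0, f1=14_500.0, f_e=500.0, duration=0.1,
                       ramp=0.0, ramp_shape="none")
met = BoltzmannParams()
noise = NoiseModel(floor=1e-4, lf_corner=2000.0, lf_slope=6.0)

print("f_e amplitude by site (phi = 0 vs 90 deg):")
for phi in (0.0, 90.0):
    p = stim.with_phi(phi)
    bm = generate_bm_recording(p, {"2f3-f2": -13.0}, noise, seed=1)
    ooc = generate_ooc_recording(p, met, 3000.0, noise, seed=2)
    spec_bm, spec_ooc = amplitude_spectrum(bm), amplitude_spectrum(ooc)
    floor = estimate_noise_floor(spec_bm, stim.f_e)
    print(f"  phi={phi:3.0f}:  BM {component_amplitude(spec_bm, stim.f_e):.2e}"
          f" (noise floor {floor:.2e})   "
          f"OoC {component_amplitude(spec_ooc, stim.f_e):.2e}")
# BM: the f_e bin stays at the noise floor at both phases -- the mechanical
# input carries no envelope component.  OoC: the electrical trace shows a
# strong f_e peak at phi = 0 that collapses at phi = 90.

phases = np.array([0.0, 90.0, 180.0])
for ttx in (False, True):
    pop = PopulationConfig(n_cells=20, neural_gain=0.001, ttx=ttx, seed=None)
    amps = [component_amplitude(
        amplitude_spectrum(generate_rw_recording(stim.with_phi(phi), pop,
                                                 met, noise, seed=3)),
        stim.f_e) for phi in phases]
    sweep = PhaseSweepResult(phases, {"fe": np.array(amps)})
    label = "TTX (neural silenced)" if ttx else "control"
    print(f"round-window tip-to-tail, {label}: "
          f"{tip_to_tail(sweep, 'fe'):.1f} dB")
# the ratios agree to well under 1 dB: the envelope-tracking potential is
# generated by the hair cells, not by auditory-nerve activity.
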