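"""Three-tone stimuli and how the center-tone phase reshapes the envelope.

Builds the standard three-tone complex (14.5/15/15.5 kHz, 1 nm per
component), verifies the stimulus itself carries no energy at the envelope
frequency, and sweeps the center-tone phase to show the envelope's f_e
component collapsing at 90 degrees while 2 f_e barely moves.
"""

import numpy as np

from cochlenv import (ThreeToneParams, assert_no_envelope_component,
                      phase_sweep, quadratic_prediction,
                      synthesize_three_tone)

params = ThreeToneParams(A=1.0, f1=14_500.0, f_e=500.0, phi=0.0,
                         duration=0.1, ramp=0.0, ramp_shape="none")
stim = synthesize_three_tone(params)
purity = assert_no_envelope_component(stim, params.f_e)
print(f"components: {params.f1:.0f}, {params.f2:.0f}, {params.f3:.0f} Hz")
print(f"stimulus energy at f_e re f1: {purity.level_db:.1f} dB "
      f"(pass={purity.passed})")
# the f_e level sits at the numerical floor: phase shifts change the
# envelope without introducing any envelope-frequency component.

df = phase_sweep(params, np.arange(0.0, 181.0, 15.0))
print("\nphi_deg  amp_fe  amp_2fe  2|cos phi|/2")
for _, row in df.iterrows():
    pred = quadratic_prediction(row.phi_deg)["c_fe"] / 2.0
    print(f"{row.phi_deg:7.0f}  {row.amp_fe:6.3f}  {row.amp_2fe:7.3f}  "
          f"{pred:6.3f}")
# amp_fe falls to zero at 90 degrees and tracks |cos phi| closely (the
# residual few-percent deviation is the exact Hilbert envelope departing
# from the purely quadratic prediction); amp_2fe stays nearly constant.
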