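"""Envelope extraction by the Boltzmann MET nonlinearity.

Runs the receptor-current experiment at the standard parameters and prints
the quantities that characterise envelope coding: the f_e component's level
relative to the first primary, its collapse when the envelope flattens, the
stability of 2 f_e, and the operating-point (X0) sweep.
"""

from cochlenv import MetExperimentConfig, run_receptor_current_experiment

report = run_receptor_current_experiment(MetExperimentConfig())

print(f"resting open probability (X0 = 5.5 nm): "
      f"{report['resting_open_probability']:.3f}")
print(f"f_e component re f1 at phi = 0:         "
      f"{report['fe_re_f1_db']:.1f} dB")
print(f"f_e drop from phi = 0 to 90 deg:        "
      f"{report['fe_drop_db']:.0f} dB")
print(f"2 f_e change between the two phases:    "
      f"{report['two_fe_change_db']:.2f} dB")
print(f"X0 maximizing the f_e current:          "
      f"{report['x0_argmax_fe_nm']:.2f} nm")
# Reading: the sigmoidal channel curve rectifies the stimulus, writing the
# envelope into the current at f_e about 17 dB below the primaries.  A flat
# envelope (phi = 90 deg) removes that component entirely (the dB drop is
# limited only by floating-point precision), while the 2 f_e component --
# set by the envelope periodicity present at every phase -- is untouched.
# The f_e current vanishes at X0 = 0 (symmetric operating point, open
# probability 0.5) and peaks a few nm away, where the curvature of the
# activation function is largest.
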