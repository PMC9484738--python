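"""Simulate an ultrasound acquisition and track strains from RF data.

Synthesises RF frames for a uniformly compressed speckle phantom with
the convolution point-spread-function model (6.6 MHz array, 40 MHz
sampling, 40 dB SNR), then recovers the displacement and strain with
the two-step tracker (dynamic-programming integer search + Horn-Schunck
optical-flow refinement).
"""

import numpy as np

from stpe import TransducerSpec, make_scatterer_field, synthesize_rf
from stpe.strain_estimation import strain_from_displacement, track_pair

spec = TransducerSpec()
applied_strain = 0.01

field = make_scatterer_field((20.0, 20.0), density_per_cell=10, seed=1, spec=spec)
pre = synthesize_rf(field, spec, snr_db=40.0, seed=2)
post_field = field.copy()
post_field.positions[:, 1] *= 1 - applied_strain  # 1% compression
post = synthesize_rf(post_field, spec, snr_db=40.0, seed=3)
print(f"frames: {pre.shape[0]} lines x {pre.shape[1]} samples "
      f"({spec.line_pitch_mm:.3f} mm pitch, {spec.sample_pitch_mm * 1e3:.1f} um axially)")

disp = track_pair(pre, post, spec, search_range=(14, 0))
eps_ax, eps_lat = strain_from_displacement(disp)
centre = eps_ax[6:-6, 100:-100]
print(f"applied axial strain : {applied_strain:.4f}")
print(f"tracked axial strain : {centre.mean():.4f} +- {centre.std():.4f}")
print(f"mean |error|         : {np.abs(centre - applied_strain).mean():.2e}")
print()
print("The tracker recovers the compression to a fraction of a percent;")
print("the residual spatial spread is speckle-induced estimation noise.")
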