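"""Fit the creep exponential on shrinking windows of observation.

Adds 40 dB measurement noise to a phantom strain movie, then fits
s(t) = eta + (alpha - eta) exp(-t/tau) on the full hour-glass record
and on windows of 2, 1 and 0.5 time constants, showing how the
steady-state and time-constant estimates degrade as the window shrinks.
"""

import numpy as np

from stpe import add_strain_noise, generate_strain_series
from stpe.evaluation import SCENARIOS
from stpe.temporal_fit import eof_denoise, fit_field

series = generate_strain_series(SCENARIOS["A"])
noisy = eof_denoise(add_strain_noise(series, snr_db=40.0, seed=0), n_modes=3)
mask = series.inclusion_mask
tau_true = series.meta["tau_inclusion_s"]
eta_true = series.meta["eta"]["zz_in"]

print(f"true inclusion: eta = {eta_true:.5f}, tau = {tau_true:.1f} s")
for window in (60.0, 2 * tau_true, tau_true, 0.5 * tau_true):
    maps = fit_field(noisy, window, mask=mask, which="axial")
    eta = np.nanmedian(maps.eta_map[mask])
    tau = np.nanmedian(maps.tau_map[mask])
    print(
        f"window {window:5.1f} s ({window / tau_true:.1f} TC): "
        f"median eta {eta:.5f} ({100 * abs(eta - eta_true) / eta_true:.2f}% off), "
        f"median tau {tau:6.2f} s ({100 * abs(tau - tau_true) / tau_true:.2f}% off)"
    )
print()
print("The steady state stays accurate down to ~1 TC of data, while the")
print("time constant (which the permeability estimate needs) degrades")
print("faster -- the reason transport imaging needs longer windows.")
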