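"""Short-time poroelastography: error versus window of observation.

Runs the full noise-free pipeline on one spherical phantom: fit the
creep model on the complete record (the steady-state reference), then
on windows of 0.5, 1 and 2 time constants; invert Young's modulus,
Poisson's ratio and vascular permeability for each window and print the
percent relative error (PRE) against the full-record estimates.
"""

from stpe.evaluation import ExperimentConfig, run_stpe_experiment

cfg = ExperimentConfig(
    scenario="A", noise_mode="ideal", woo_multiples=(0.5, 1.0, 2.0), seed=0
)
report = run_stpe_experiment(cfg)

ref = report.reference
print(f"scenario A: sphere, 2x stiffness contrast, tau = {report.pilot_tau_s:.1f} s")
print(f"full-record estimates: E_i {ref['E_i_pa'] / 1e3:.2f} kPa, "
      f"nu_i {ref['nu_i']:.3f}, Lp {ref['Lp_m_per_pa_s']:.3g} m/(Pa s)")
print()
print("window   YM PRE%    PR PRE%    VP PRE%")
for m in (0.5, 1.0, 2.0):
    r = report.results[str(m)]
    print(f"{m:4.1f} TC  {r['YM']['pre_pct']:8.5f}  {r['PR']['pre_pct']:8.5f}"
          f"  {r['VP']['pre_pct']:8.5f}")
print()
print("On model-exact data the short-window fits reproduce the steady")
print("state almost perfectly, so all PREs are tiny; with measurement")
print("noise the same numbers grow as the window shrinks (see the")
print("noise_mode='strain' and 'rf' configurations).")
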