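# stpe — short-time poroelastography

Tools for estimating the mechanical and transport properties of a
tumour-like inclusion — Young's modulus (YM, *E*), Poisson's ratio
(PR, *ν*) and vascular permeability (VP, *L<sub>p</sub>*) — from time
series of ultrasound strain images acquired under sustained (creep)
compression, and for quantifying how those estimates degrade when the
temporal **window of observation (WoO)** is cut down to a small
multiple of the underlying strain time constant.

Poroelastography experiments are long (a minute or more) because the
tissue must relax toward its drained steady state.  The premise of
*short-time* poroelastography is that the creep strain at every pixel
follows a first-order relaxation

&nbsp;&nbsp;&nbsp;&nbsp; s(t) = η + (α − η) e^(−t/τ)

with α the strain just after loading (undrained, effective ν ≈ 0.5),
η the steady-state strain and τ the strain time constant.  After two
time constants only e^(−2) ≈ 0.135 of the transient remains, so the
steady state — and everything derived from it — can be *predicted* from
a short record by fitting the exponential.  The derived quantities are:

- **Background moduli**: E_b = σ₀/ε_zz, ν_b = ε_rr/ε_zz from steady
  background strains under the applied stress σ₀;
- **Inclusion moduli**: Eshelby's equivalent-inclusion relation — the
  uniform strain inside an ellipsoidal inhomogeneity determines
  (E_i, ν_i) by minimising the mismatch between two expressions of the
  same eigenstrain, one geometric and one material;
- **Vascular permeability**: τ = 1/(H_A · χ) with the aggregate modulus
  H_A = E(1−ν)/((1−2ν)(1+ν)) and the microfiltration coefficient
  χ = L_p·S/V, so L_p = 1/(τ · H_A · S/V).

The package is a library first (the `stpe` Python API plus the short
narrative scripts in `examples/`), with a thin `stpe` command-line
wrapper for the common pipeline stages.

## What's inside

| module | role |
| --- | --- |
| `stpe.phantom_forward` | analytic ground-truth creep strain movies (Eshelby steady states + exponential transients) |
| `stpe.rf_simulation` | convolution-model ultrasound RF synthesis (PSF, speckle, SNR control) |
| `stpe.strain_estimation` | DP + Horn–Schunck speckle tracking, least-squares/Kalman strain images |
| `stpe.temporal_fit` | EOF (truncated SVD) denoising, variable-projection exponential fitting, TC outlier rule |
| `stpe.inversion` | Eshelby tensors (sphere/spheroid), equivalent-inclusion modulus inversion, best-fit ellipsoid |
| `stpe.transport` | τ → L_p conversion, tumour-volume → S/V regression, force-sensor → stress |
| `stpe.evaluation` | scenario library, window-of-observation experiments, percent-relative-error reports |

## Worked example

```sh
python examples/invert_moduli.py
```

```
measured steady-state strains (axial, lateral):
  inclusion : 0.06621, 0.02611
  background: 0.10000, 0.03000
background: E = 10.00 kPa, nu = 0.300
inclusion : E = 20.00 kPa, nu = 0.400 (cost 1.01e-16)
S/V from the 7.5 mm best-fit sphere: 1.84e+04 1/m
vascular permeability Lp = 1.27e-10 m/(Pa s)
```

A 1 kPa compression of a 10 kPa / ν = 0.3 background produces 10%
axial strain far from the inclusion; the stiffer (20 kPa, ν = 0.4)
sphere strains less (6.6%).  Feeding those steady-state strains back
through the inversion recovers the generating moduli essentially
exactly (the cost is the squared eigenstrain mismatch), and combining
the fitted time constant with the capillary surface-to-volume ratio of
the best-fit ellipsoid turns it into a permeability.

The other examples show the forward phantom (`forward_phantom.py`),
window-dependent exponential fitting under noise
(`fit_time_constant.py`), RF simulation + speckle tracking
(`rf_pipeline.py`) and a complete window-of-observation experiment
(`woo_experiment.py`).

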