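# turbodyn

Turbulent whole-brain dynamics on parcellated resting-state BOLD: model-free
Kuramoto-based turbulence measures, a coupled Stuart–Landau (Hopf) whole-brain
model fitted by distance-resolved functional connectivity, in silico
perturbation metrics, and simulated lesion attacks on structural connectivity.

The package is aimed at computational neuroscientists studying how injury or
disease alters large-scale brain dynamics — for example, comparing patient and
control resting-state fMRI cohorts — and ships a synthetic-data generator so
every stage runs and is tested without any imaging downloads.

## The measures

All model-free measures derive from the **Kuramoto local order parameter**.
Given band-passed (0.008–0.08 Hz, second-order zero-phase Butterworth) BOLD
phases φ_p(t) obtained by the Hilbert transform, and centroid distances r_np
in mm:

```
R_n(t) e^{iν_n(t)} = Σ_p C_np e^{iφ_p(t)} / Σ_q C_nq,     C_np = e^{−λ r_np}
```

The spatial scale λ (mm⁻¹) runs over 0.01 (~100 mm) to 0.30 (~3 mm) in steps
of 0.03. From the modulus field R:

- **Amplitude turbulence** `D = std_{n,t}(R)` — pooled population std across
  nodes and time.
- **Node-level metastability** `NLM_n = std_t(R_n)`.
- **Information cascade flow** `F(λ) = ⟨corr_t(R_λ(n, t+Δt), R_{λ−Δλ}(n, t))⟩_n`
  and the **information cascade**, its average over scale transitions.
- **Information transfer** `A^λ`: the slope of log corr_t(R_n, R_p) against
  log r_np inside the inertial subrange (10–100 mm by default).

The **Hopf whole-brain model** couples Stuart–Landau oscillators on an
exponential-distance-rule connectome `C_np = e^{−0.18 r_np}` (optionally with
long-range exceptions from an empirical SC):

```
dx_n = [a_n x_n − (x_n²+y_n²)x_n − ω_n y_n + G Σ_p C_np (x_p − x_n)] dt + ν dW
```

with ν = 0.01, a_n = −0.02 at rest, and ω_n from each node's spectral peak.
The global coupling G is fitted by grid search: the working point G* minimises
the Euclidean distance between simulated and group-averaged empirical FC(r)
profiles within the inertial subrange. At G*, **susceptibility** χ and
**information-encoding capability** I summarise the response to random
perturbations of a_n in [−0.02, 0]: χ is the node- and trial-averaged
perturbed-minus-unperturbed time-mean of R, and I the across-trial dispersion
of that difference.

**Simulated attack**: lesion–node overlap fractions are thresholded at
mean + k·SD of the pooled positive overlaps; attacked nodes are disconnected
fully (binary) or down-weighted by 1 − lesion frequency (weighted), and the
mask multiplies the connectome before modelling.

## Worked example

```python
import numpy as np
import turbodyn as td
from turbodyn import fitting, phases, turbulence as turb

geom = td.make_geometry(60, seed=1)
cohort = td.make_cohort(geom, n_per_group=6, G_control=1.6, G_injury=0.9,
                        T=145, TR=2.0, seed=1)

for group in ("control-like", "injury-like"):
    D = []
    for bold in cohort.by_group(group):
        ph = phases.extract_phases(phases.bandpass(bold))
        D.append(turb.amplitude_turbulence(turb.local_order(ph, geom.distances, 0.01)))
    print(f"{group}: amplitude turbulence D(lambda=0.01) = {np.mean(D):.4f}")

grid = np.round(np.arange(0, 2.01, 0.1), 10)
for group, conn in (("control-like", cohort.connectome),
                    ("injury-like", cohort.attacked_connectome)):
    emp = fitting.group_fc_profile(cohort.by_group(group), geom.distances)
    cfg = td.HopfConfig(omega=cohort.omega, duration=290.0, tr=2.0)
    sw = fitting.sweep_G(conn, cfg, emp, grid, reps=5, seed=1)
    print(f"{group}: working point G* = {sw.G_star:.1f} (min error {sw.mean_error.min():.3f})")
```

prints

```
control-like: amplitude turbulence D(lambda=0.01) = 0.1696
injury-like: amplitude turbulence D(lambda=0.01) = 0.1388
control-like: working point G* = 1.4 (min error 0.537)
injury-like: working point G* = 0.8 (min error 0.365)
```

The injury-like group — generated at lower coupling on a lesion-attacked
connectome — shows reduced amplitude turbulence at the largest spatial scale,
and the model fit recovers a lower working point, the directional signature
the pipeline is built to detect.

A command-line interface mirrors the library:
`turbodyn turbulence`, `simulate`, `fit`, `attack`, `perturb`, `stats`
(see `turbodyn --help`).

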