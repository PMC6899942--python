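# fcivim

Flow-compensated intravoxel incoherent motion (FC-IVIM) diffusion MRI:
forward signal model, constrained model fitting, simulation-driven
acquisition-protocol optimization, and test-retest repeatability statistics.
Everything runs from synthetic inputs — no scanner data required.

## Who this is for

Quantitative-MRI researchers who want to (a) fit the FC-IVIM model to
ROI-median diffusion decay curves acquired with bipolar and flow-compensated
gradients at several diffusion times, (b) decide *which* (b-value, diffusion
time, gradient shape) acquisitions are worth scan time before going to the
scanner, and (c) quantify test-retest precision (wCV, ICC) of the resulting
parameter estimates.

## The model

IVIM splits the diffusion-weighted signal into tissue and microvascular
compartments. FC-IVIM avoids the pseudo-diffusion assumption (invalid in
abdominal organs, where blood traverses few capillary segments per encoding)
by modelling the perfusion attenuation explicitly:

    S(b,T,β) = S0 [ (1−f) e^{−bD} + f · F(b,T,β,τ,v) · e^{−b·D_blood(β)} ]

* `D` — tissue diffusivity (mm²/s), `f` — perfusion signal fraction,
* `v` — blood speed (mm/s), `τ` — capillary segment traversal time (ms),
* `β` — gradient shape (0 bipolar, 1 flow-compensated),
* `F` — ensemble average of cos(spin phase) for flow through randomly
  oriented straight segments, computed by Monte-Carlo phase simulation under
  the actual gradient waveform (cached as a deterministic table over
  `T/τ` and `x = v√(bT)`).

In the diffusive limit `T/τ → ∞` this reduces to conventional IVIM with
`D* = τv²/6`; in the ballistic limit bipolar encoding gives `F = sinc(v·m1)`
while flow compensation gives `F = 1`.

## Worked example

```python
import numpy as np
from fcivim import (FcIvim, FitBounds, TissueParams, add_rician,
                    default_tables, forward_signal, reference_scheme_50)

tables = default_tables()            # ~4 s, cached per process
scheme = reference_scheme_50()       # built-in 50-point two-shape protocol

truth = TissueParams(D=1.61e-3, f=0.45, tau=171.0, v=8.4)   # liver-like
clean = forward_signal(scheme, truth, tables=tables)
noisy = add_rician(clean, snr_eff=20.0, rng=np.random.default_rng(0))

res = FcIvim(noisy, bounds=FitBounds.for_organ("liver"), tables=tables).fit()
print(res.summary())
```

This prints:

```
FC-IVIM least-squares fit
  n points: 50   converged: True   residual norm: 0.3452   nfev: 17
   param     estimate      std err  unit
      S0       0.9781      0.01868
       D        1.569       0.2346  1e-3 mm^2/s
       f        42.21        1.738  %
     tau        201.5         30.9  ms
       v        7.033       0.3969  mm/s
```

i.e. from one noisy 50-point curve at effective SNR 20 the fit recovers
D = 1.57×10⁻³ mm²/s (truth 1.61), f = 42.2% (truth 45%), τ = 201 ms
(truth 171) and v = 7.0 mm/s (truth 8.4), with Gauss-Newton standard errors.

Protocol design and repeatability run the same way from Python
(`greedy_optimize`, `evaluate_scheme`, `generate_study`, `wcv`, `icc_a_k`,
`t2_adjust_f`) or from the CLI:

```bash
fcivim optimize --n-add 20 --n-rep 500 --seed 0 --out-dir out/opt
fcivim evaluate --organ liver --snr 20 --n-rep 500 --seed 0 --out out/liver.csv
fcivim make-fixtures --n-subjects 7 --seed 0 --out-dir out/study
fcivim repeatability --series out/study/roi_series.csv --out-dir out/rep
```

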