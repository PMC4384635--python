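# btkact

Quantitative models of Bruton's tyrosine kinase (Btk) activation by
transient PH-TH-module dimerization, for researchers studying Tec-family
kinase regulation who want the published mechanistic arguments as running,
tested code rather than prose.

Btk activates by trans-autophosphorylation: two kinase molecules form a
transient encounter complex and one phosphorylates the other's activation
loop. This package implements the four models that together make that
mechanism quantitative:

* **Kinetics** — the autocatalytic mass-action scheme

  ```
  Btk + Btk   <=[k1, k-1]=>  Btk·Btk   --[k2]-->  pBtk + Btk
  pBtk + Btk  <=[k3, k-3]=>  pBtk·Btk  --[k4]-->  pBtk + pBtk
  ```

  with k4 ≫ k2 (phosphorylated Btk is the better kinase, hence
  autocatalysis and sigmoidal progress curves) and IP6 binding at a
  peripheral PH-domain site raising the on-rates k1 = k3 ten-fold
  (dimer Kd = k-1/k1: 2 mM → 200 μM). Deterministic LSODA integration,
  plus an exact Gillespie simulator in a femtoliter volume as a
  stochastic cross-check.
* **Membrane recruitment** — the geometric estimate C = f/(A0·L·Na) of the
  effective Btk concentration in the membrane-proximal shell of a
  PIP3-containing vesicle (~14 mM at 5% PIP3 — millimolar, i.e. above the
  dimer Kd, which is why membranes activate).
* **ITC binding** — the one-site Wiseman forward model for a fixed-volume
  cell under the published injection schedule, nonlinear fitting of
  (N, Ka, ΔH) with curvature standard errors, and the identities
  Kd = 1/Ka and ΔS = (ΔH + RT ln Ka)/T.
* **Assay estimators** — initial rate over the first 150 s, activation
  slope with a non-linearity caveat, Michaelis–Menten (Km, Vmax), and
  four-parameter-logistic EC50 on log dose.

Seeded synthetic-data generators emulate each assay (progress curves, ITC
isotherms, dose–response via peripheral-site occupancy scaling the
on-rate) so the whole pipeline is testable end to end without downloads.
See `docs/methods.md` for the models, conventions and known limitations.

## Worked example

```python
import numpy as np
from btkact import kinetics

t = np.linspace(0, 1e4, 501)
for scenario in ("no_IP6", "with_IP6"):
    p = kinetics.make_rate_parameters(scenario)
    curve = kinetics.simulate_progress(p, total0=1e-6, t_grid=t)
    print(scenario, f"dimer Kd = {kinetics.dimer_kd(p)*1e3:.1f} mM,",
          f"t50 = {kinetics.time_to_half(curve):.0f} s")
```

prints

```
no_IP6 dimer Kd = 2.0 mM, t50 = 4959 s
with_IP6 dimer Kd = 0.2 mM, t50 = 503 s
```

— at 1 μM Btk both dissociation constants leave the dimer a trace species,
yet the 10-fold on-rate enhancement cuts the half-activation time from
~83 min to ~8 min: transient, sub-Kd dimerization is enough to switch the
kinase on. The numbered scripts under `analysis/` run the full set of
analyses (kinetics scenarios, membrane concentration, binding-table
reproduction and ITC refit, Km/EC50 recovery) and write their tables under
`results/`; for instance

```sh
python analysis/03_itc_binding.py
```

recomputes the derived Kd and ΔS columns of the binding-thermodynamics
table from the printed fit parameters (wild-type/IP6: Kd 238.1 nM,
ΔS 26.6 cal/mol/K) and flags the one row that rounded inputs cannot
reproduce.

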