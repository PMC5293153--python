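# eposignal

Cell-type-parametrized kinetic modeling of erythropoietin (Epo)-driven
proliferation in hematopoietic cells.

Primary erythroid progenitors (CFU-E) and the Epo-responsive cell lines
BaF3-EpoR and 32D-EpoR share the same pro-proliferative network topology —
EpoR activating the PI3K/AKT and Ras/MEK/ERK pathways, both converging on
ribosomal protein S6 — yet proliferate very differently. `eposignal`
implements the modeling strategy that explains this: a mass-action ODE model
whose kinetic rate constants are *global* (shared across cell types, with
every enzymatic rate decomposed as k_cat × [enzyme] × [substrate]) while all
cell-type specificity enters through measured protein abundances, cell
volume and surface area. On top of the kinetic layer sit:

* **calibration** — weighted least squares under the blot error model
  σ = 0.10·y + 0.05·max(condition), multi-start Latin-hypercube fitting on
  log10 parameters, and profile-likelihood identifiability (95% pointwise
  intervals at the χ² threshold 3.84);
* **sensitivity** — response coefficients S_p^X = (∂X/∂p)·(p/X) of the
  1-h-integrated pS6 response with respect to protein abundances, grouped by
  network module, quantifying how signal flow to S6 distributes between the
  AKT and ERK arms in each cell type;
* **phenotype link** — the cell cycle indicator
  CCI = cyclinD2 / (cyclinG2 · p27) (qPCR fold changes), linear regression of
  log CCI on integrated pAKT/ppERK, AIC-selected regression of proliferation
  on integrated pS6 and/or CCI, four-parameter Hill dose–response fits
  (y = y0 + a·x^b/(c^b + x^b), EC50 = c) and exponential doubling-time fits;
* **synthetic data** — a declared ground truth that generates every input
  (time courses, qPCR triples, proliferation readouts) under the study's
  design, so the whole pipeline is testable end to end;
* **I/O and CLI** — SBML import/export, tidy CSV schemas, YAML contexts,
  and `eposignal` subcommands (`synth`, `simulate`, `fit`, `profile`,
  `sensitivity`, `link`, `predict`).

The intended users are systems biologists who want to transplant a
calibrated signaling model to a new cellular context from protein-abundance
measurements alone and predict the anti-proliferative effect of targeted
kinase inhibitors (AKT VIII, U0126, BI-D1870, rapamycin), singly or in
combination.

## Worked example

```python
import numpy as np
from eposignal.network import Perturbation, simulate
from eposignal.phenotype import predict_proliferation
from eposignal.synth import (DesignSpec, default_ground_truth, fit_links,
                             generate_cci_dataset,
                             generate_proliferation_dataset)

truth = default_ground_truth(seed=1)

# anchored mCFU-E simulation at saturating Epo
inst = truth.instance("mCFU-E")
t = np.linspace(0.0, 60.0, 121)
traj = simulate(inst, 50.0, t)
print(f"max pEpoR degree : {100*traj.observables['pEpoR'].max()/inst.total('EpoR'):5.1f} %")
print(f"max ppERK degree : {100*traj.observables['ppERK'].max()/inst.total('ERK'):5.1f} %")

# synthetic inhibitor study, link fitting, prediction
design = DesignSpec()
cci = generate_cci_dataset(truth, design, noise=False)
prolif = generate_proliferation_dataset(truth, design, noise=False)
pipeline, tables = fit_links(truth, cci, prolif, use_aicc=True)
for ct in ("mCFU-E", "BaF3-EpoR"):
    lm = pipeline.stage2[ct]
    print(f"{ct:10s} proliferation ~ {lm.predictors}  R^2 = {lm.r_squared:.2f}")

akt = Perturbation("inhibitor", "AKTVIII", 5.0)
mek = Perturbation("inhibitor", "U0126", 5.0)
for ct in ("mCFU-E", "BaF3-EpoR"):
    p_a = predict_proliferation(pipeline, ct, 5.0, [akt])
    p_m = predict_proliferation(pipeline, ct, 5.0, [mek])
    p_b = predict_proliferation(pipeline, ct, 5.0, [akt, mek])
    print(f"{ct:10s} scaled proliferation: AKTi {p_a:.2f}  MEKi {p_m:.2f}  both {p_b:.2f}")
```

prints

```
max pEpoR degree :  75.0 %
max ppERK degree :  10.0 %
mCFU-E     proliferation ~ ['I_pS6']  R^2 = 1.00
BaF3-EpoR  proliferation ~ ['cci']  R^2 = 1.00
mCFU-E     scaled proliferation: AKTi 0.17  MEKi 0.88  both 0.05
BaF3-EpoR  scaled proliferation: AKTi 0.35  MEKi 0.19  both 0.07
```

Reading the output: the anchored simulation respects the phospho-degree
constraints (receptor phosphorylation capped at 75%, double-phosphorylated
ERK at 10% of total ERK in primary cells). AIC model selection recovers the
class structure — proliferation of the fast-cycling primary cells follows
integrated pS6 (growth-limited), while the cell line follows the cell cycle
indicator (cycle-limited). The predictions (scaled so the Epo-only
condition equals 1) show the cell-type-specific drug pattern: AKT inhibition
dominates in mCFU-E with little added effect of MEK inhibition, whereas in
BaF3-EpoR both drugs bite and the combination is strongest.

The same steps run from the shell:

```bash
eposignal synth --seed 1 --out synth_out
eposignal link --cci synth_out/cci.csv --prolif synth_out/proliferation.csv --out link_out
eposignal predict --links link_out/links.json --context BaF3-EpoR --epo 5 \
    --akt-dose 5 --mek-dose 5
```

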