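# permqspr

A toolkit for analysing membrane-permeation experiments in which the
properties of the **vehicle** and the **membrane** matter as much as the
permeant. It targets the classic factorial design — small-molecule
permeants (caffeine, methyl/butyl paraben) applied in oily vehicles
(isohexadecane, hexadecane, oleic acid, isopropyl myristate) to
synthetic barrier membranes (silicone, HDPE, polyurethane) — and covers
the full analytical chain:

* **Topological molecular descriptors** computed on heavy-atom graphs:
  connectivity indices chi0, chi1 (and carbon-restricted and valence
  variants), Kier shape indices κ1–κ3 and flexibility Φ = κ1κ2/A,
  Balaban J, Lipinski acceptor/donor counts, simple and Oprea
  rotatable/rigid bond counts, molecular weight.
* **Hansen solubility parameter arithmetic**, including the
  vehicle–membrane interaction distance
  Ra = √(4ΔδD² + ΔδP² + ΔδH²) (MPa^0.5) — the smaller Ra, the more
  alike solvent and polymer.
* **Franz diffusion cell analysis**: sampling-corrected cumulative
  permeation Qₙ = (V_r·Cₙ + V_s·Σ_{i<n}Cᵢ)/A, steady-state flux J as
  the slope of the best linear window of Q(t), permeability coefficient
  Kp = J/C_donor.
* **PCA with iterative loadings-based descriptor elimination** (drop
  the lowest |PC1 loading|, stop on explained-variance drop or loss of
  component orthogonality) plus a Hotelling T² outlier screen.
* **Linear QSPR construction**: |r| > 0.70 cross-correlation pruning,
  zero-mean/unit-variance scaling, OLS with leave-one-out
  q² = 1 − PRESS/TSS, backward refinement until r² and q² converge, and
  a representative 30/6 train/test split of the 36-combination design.
  The two published fixed-coefficient models for Kp and
  thickness-normalized flux ship as frozen predictors (`eq2`, `eq3`).
* **Seeded synthetic-data generators** for every stage — factorial
  descriptor tables with planted sparse responses and correlated
  blocks, and a forward Franz-cell simulator with lag, sampling
  withdrawal and measurement noise — so the whole pipeline is testable
  without any external data.

See `docs/methods.md` for the models, conventions, defaults and
limitations.

## Worked example

```python
from permqspr import estimate_flux, hsp_distance, predict_published
from permqspr.synth import generate_franz_series, default_hsp

# a Franz-cell run: true flux 36.6 ug/cm2/h, 1 h lag, noisy sampling
series = generate_franz_series(36.6, lag=1.0, noise_sd=0.8,
                               donor_concentration=1000.0, seed=42)
res = estimate_flux(series)
print(f"flux J = {res.flux:.2f} ug/cm2/h   Kp = {res.kp:.5f} cm/h")
print(f"window = {res.window}, r2 = {res.r2_fit:.4f}, lag = {res.lag_time:.2f} h")

hsp = default_hsp()   # synthetic default HSP table
for m in ("silicone", "HDPE", "PU"):
    print(f"Ra(IHD, {m}) = {hsp_distance(hsp['IHD'], hsp[m]):.2f} MPa^0.5")

kp = predict_published("eq2", {"solubility": 1.2, "lip_acc_vehicle": 0.0,
                               "dH_exp_drug": -0.3})
print(f"eq2 prediction: {kp:.4f}")
```

prints

```
flux J = 35.32 ug/cm2/h   Kp = 0.03532 cm/h
window = (6, 10), r2 = 0.9992, lag = 0.84 h
Ra(IHD, silicone) = 4.72 MPa^0.5
Ra(IHD, HDPE) = 3.77 MPa^0.5
Ra(IHD, PU) = 11.39 MPa^0.5
eq2 prediction: 1.0081
```

The estimated flux sits within the noise of the planted 36.6 (the
estimator chose the late, post-lag window and reports its fit r² and
the fitted lag); Kp is the flux divided by the 1000 µg/mL donor
concentration. The Hansen distances say isohexadecane is a closer
solubility match to HDPE and silicone than to polyurethane, i.e. the
alkane is predicted to swell the nonpolar membranes more. The `eq2`
prediction is an affine evaluation of the frozen published permeability
model at standardized inputs.

The same stages are scriptable from the shell:

```bash
permqspr simulate franz --flux 36.6 --lag 1 --out series.csv
permqspr flux --in series.csv --donor-conc 1000
permqspr descriptors --in molecules.smi --out desc.csv
permqspr simulate dataset --seed 3 --out data.csv --truth truth.json
permqspr pca-select --in desc_only.csv --out trace.json
permqspr qspr-fit --in data.csv --response response --out model.json
permqspr predict --model eq2 --in newdata.csv
```

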