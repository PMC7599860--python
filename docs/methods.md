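# Methods

This note documents the models and procedures implemented in `permqspr`,
the choices made where the workflow was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Problem setting

The package analyses membrane-permeation experiments in which three
small-molecule permeants (caffeine CF, methyl paraben MP, butyl paraben
BP) are applied in four oily vehicles (isohexadecane IHD, hexadecane HD,
oleic acid OA, isopropyl myristate IPM) to three synthetic barrier
membranes (silicone, HDPE, polyurethane) — a 3 × 4 × 3 factorial of 36
permeant/vehicle/membrane combinations — plus a smaller permeant × vehicle
series through human epidermis. The analytical chain is: compute or
collect molecular descriptors for each entity; quantify vehicle–membrane
likeness with the Hansen solubility parameter distance; turn Franz-cell
receptor time series into fluxes and permeability coefficients; find
which descriptors explain the variance in the responses by iterative
PCA-based elimination; and build sparse linear QSPR models validated by
leave-one-out cross-validation.

## Molecular descriptors

Descriptors are computed on the heavy-atom graph with implicit
hydrogens.

* **Connectivity indices.** chi0 = Σ_atoms δ⁻¹ᐟ², chi1 = Σ_bonds
  (δᵢδⱼ)⁻¹ᐟ² with δ the heavy-atom degree. The carbon-restricted
  variants (chi0_C, chi1_C) restrict the sums to carbon atoms / C–C
  bonds but keep the full-graph degrees; this matches common
  descriptor-software convention and is what the brute-force oracles in
  the test suite verify. chi0v uses the valence delta δᵛ = Zᵛ − h for
  second-period atoms and the (Zᵛ − h)/(Z − Zᵛ − 1) correction beyond.
  An isolated heavy atom is assigned δ = 1 so chi0 stays defined; chi1
  is then 0.
* **Kier shape indices.** κ1 = A(A−1)²/P1², κ2 = (A−1)(A−2)²/P2², κ3
  with the odd/even-A forms, Pk = number of simple k-bond paths
  (counted by exhaustive DFS — molecules are small), flexibility
  Φ = κ1κ2/A. The α heteroatom/hybridization correction is off by
  default because the provenance of the original values does not pin
  down which variant was used; `alpha=True` enables a covalent-radius
  based correction table. Indices undefined at a molecule size (κ2
  below 3 atoms, κ3 below 4) are reported as missing, never as 0.
* **Counts.** lip_acc = #N + #O; lip_don = number of H on N/O.
  A simple rotatable bond (b_rotN) is an acyclic single bond between
  two non-terminal heavy atoms; the Oprea variant (opr_nrot) also
  excludes amide C–N bonds; opr_brigid counts bonds that are neither
  Oprea-rotatable nor attached to a terminal atom. Aromatic bonds are
  ring bonds and count as order 1 where an order is needed.
* **Balaban J.** J = B/(μ+1) Σ_bonds (sᵢsⱼ)⁻¹ᐟ² over topological
  distance-matrix row sums (unweighted shortest paths).

SMILES parsing is delegated to RDKit behind a thin adapter; molecules
can also be supplied as explicit graph mappings so graph-only workflows
carry no chemistry dependency. No attempt is made to reproduce any
specific commercial package's numeric conventions bit-for-bit; the
ground truth for this implementation is the set of defining formulas,
enforced by independent brute-force oracles in the tests.

## Hansen solubility parameters

The interaction distance between materials A and B is
Ra = √(4(δD_A−δD_B)² + (δP_A−δP_B)² + (δH_A−δH_B)²), in MPa^0.5: a
scaled Euclidean metric, so nonnegativity, symmetry and the triangle
inequality hold exactly and are property-tested. The packaged HSP table
(`data/hsp_defaults_synthetic.csv`) contains plausible synthetic values
so the pipeline runs end to end; it is labelled synthetic because the
measured HSP values for the study's oils and membranes are not publicly
printed.

## Franz-cell analysis

Receptor sampling with fluid replacement dilutes the receptor, so the
cumulative amount permeated per area is reconstructed as
Qₙ = (V_r·Cₙ + V_s·Σ_{i<n} Cᵢ)/A. The replacement fluid is assumed
permeant-free and equal in volume to the sample; under that assumption
the correction inverts the dilution bookkeeping exactly, which the
forward simulator verifies to 1e-9.

"The linear portion" of Q(t) is operationalized as the contiguous
window of ≥ 4 timepoints maximizing the OLS r² (ties prefer the longer,
then the later window; a zero-variance window is assigned r² = 0 so
flat lag stretches never win). A fixed window can be passed to
reproduce any published choice. Flux J is the window slope; lag time is
the t-intercept (informational only); Kp = J / C_donor.

The noisy-recovery check compares |Ĵ − J_true| against three standard
errors computed by exact linear propagation of the known measurement
noise through the sampling correction and the window weights — the
simulator knows σ, so no plug-in residual estimate is needed, and
coverage at 3 SE is expected near 99.7 % against the 95 % bar.

## PCA and iterative descriptor elimination

Descriptors are autoscaled to zero mean and unit sample variance
(constant columns are an error, named). PCA is exact SVD by default,
with a deterministic sign convention (largest-|loading| entry of each
component positive) and explained variance reported as a percentage of
the total variance. A NIPALS back end (capped iterations, configurable
tolerance) is provided because the elimination loop's
orthogonality-loss stop is only meaningful when components can actually
drift from orthogonality; under exact SVD scores are orthogonal by
construction and that stop provably never fires (asserted in tests).

The elimination loop: fit PCA, tentatively remove the descriptor with
the lowest |PC1 loading| (ties break lexicographically, with a 1e-12
numerical-tie band), refit; if PC1's explained variance drops by more
than `tol_var` (default 0.1 percentage points) or the score
orthogonality metric (max pairwise |cos|) exceeds `tol_orth` (default
0.01), restore the descriptor and stop; otherwise commit. A floor
(default 2 descriptors) bounds the loop, so it always terminates within
p − floor removals. The full removal trace is serializable so every
final descriptor set is auditable.

A structural property of this criterion worth knowing: for an
equicorrelated signal block, removing one member *raises* the EV1
percentage (EV1 % of a k-column block at correlation r is
(1+(k−1)r)/k, which grows as k shrinks), so once all noise columns are
gone the variance-drop stop cannot protect the last signal columns.
The recovery simulations therefore run with the floor set at the
planted support size; what they measure is the ordering property —
that |PC1 loading| ranks every noise descriptor below every signal
descriptor, so all noise columns are removed first. Across 100 seeded
replicates of the 36-row, 3-signal + 5-noise design (column noise
σ = 0.1) the signal set is recovered in ≥ 90 % of runs (100 % observed).

Hotelling's T² screen: T²ᵢ = Σ_k t²ᵢₖ/var(t_k) over the retained
components against the limit k(n−1)/(n−k)·F₁₋α(k, n−k). On clean
multivariate-normal data the empirical flag rate sits near α.

## QSPR workflow

1. **Correlation pruning.** Descriptor pairs with |r| > 0.70 are
   processed in descending |r|; in each still-intact pair the member
   less correlated with the response is removed (ties remove the
   lexicographically later name). No surviving pair exceeds the
   threshold.
2. **Rank pruning.** Level-based factorial tables are often
   rank-deficient even after correlation pruning (many columns constant
   within a 4-level factor span at most 3 centered dimensions); a
   deterministic greedy left-to-right scan keeps a full-rank column
   subset before fitting. `fit_linear` itself refuses rank-deficient
   designs and names the collinear terms.
3. **Fitting.** OLS on z-scored predictors, i.e. coefficients on the
   standardized ("normalized") scale; the response is left on its own
   scale, so a single standardized predictor's slope equals
   corr(x, y)·sd(y).
4. **Validation.** q² = 1 − PRESS/TSS with leave-one-out refits;
   scaling is re-estimated inside each fold so the held-out row never
   leaks into the transform. The implementation is an explicit refit
   loop and is tested for exact agreement with an independent
   scikit-learn fold loop.
5. **Refinement.** Repeatedly drop the term with the smallest
   |standardized coefficient| ("contributing least"); stop when
   |r² − q²| ≤ `prox_tol` (default 0.15, bracketing typical
   training-gap magnitudes for models of this size) and the next
   removal would cost more than `max_r2_drop` (default 0.02) of r².
   An alternative importance ordering by p-value is deliberately not
   the default; the standardized-coefficient rule is simpler and
   deterministic.
6. **Split.** The 36-row factorial is divided 30/6 by a seeded greedy
   procedure that picks test rows maximizing new factor-level coverage,
   guaranteeing all permeants and membranes (and ≥ 3 of 4 vehicles)
   appear in the test set while every level stays in training. Test-set
   quality is the squared Pearson correlation between predicted and
   observed (a predictive-R² variant about the train mean is available
   behind a flag).

The two published fixed-coefficient models are frozen verbatim:

* `eq2` (permeability coefficient):
  Kp = 0.41902·solubility − 0.85524·lip_acc_vehicle +
  0.64106·δH_drug + 0.6976
* `eq3` (thickness-normalized flux):
  Flux = 1.08083 + 0.23534·weight_ratio − 0.36141·logKow_vehicle −
  0.24036·MPt_permeant − 1.01839·δH_membrane + 0.47908·δP_membrane −
  0.34680·opr_brigid_vehicle

Their inputs are treated as already on the models' own standardized
scale. Flux normalization by membrane thickness is interpreted as
J × thickness (µg cm⁻¹ h⁻¹), with thickness supplied via membrane
metadata. The r²/q² statistics behind these equations derive from a
raw dataset that is not publicly printed, so they cannot be recomputed
here; only the frozen equations themselves are reproduced.

## Synthetic-data generators

Every generator is a pure function of (configuration, seed).

* **Factorial dataset.** The 36-row design with computed descriptors
  from the seven fixture molecules (suffixed `_vehicle`/`_permeant`),
  synthetic membrane HSP components, the vehicle–membrane HSP distance,
  and supplied-type descriptors (solubility 1–120 µg-scale units,
  melting point 50–250 °C, log Ko/w 3–9, density 0.75–0.95 g/mL,
  weight ratio 1–2) drawn per factor level from uniform ranges chosen
  to be physically plausible for oily vehicles and small-molecule
  permeants. Responses follow y = Σ βⱼ·zⱼ + ε with z the standardized
  planted columns and ε ~ N(0, σ²), default σ = 0.1 — a
  moderate-noise regime for standardized effects of order 1.
  Correlated "supplied" blocks are drawn from an equicorrelated
  Gaussian. The truth record (β, σ, seed, roles) makes recovery tests
  self-validating.
* **Planted designs.** `planted_factor_matrix` (one latent factor,
  3 signal + 5 noise columns, n = 36, σ = 0.1) and
  `sparse_linear_dataset` (independent predictors, 3 true terms with
  β = 1.0/0.8/0.6 among 7 decoys, n = 30, σ = 0.1) mirror the study's
  dataset sizes.
* **Franz simulator.** Mass enters the receptor at J·A after a lag;
  each scheduled sample records the concentration (with optional
  N(0, σ) measurement noise on the record only, truncated at zero) and
  then withdraws/replaces the aliquot. Default geometry: 12 mL
  receptor, 200 µL samples, 2 cm² area, ten timepoints over 8 h —
  typical bench values.

What the generators do **not** emulate: nonlinear (non-steady-state)
permeation kinetics, membrane saturation or vehicle depletion,
inter-replicate biological variability of excised skin,
non-Gaussian assay error, and real correlation structure among
measured physicochemical descriptors. Passing the recovery suites
therefore demonstrates that the estimators invert their own stated
data-generating assumptions — not that those assumptions hold for any
particular laboratory dataset.

## Fixtures

The epidermal permeation table (mean ± sd flux, µg cm⁻² h⁻¹, and
permeability coefficient, 10⁻² cm h⁻¹, for CF/MP/BP from buffer and
five oily vehicles) ships as a CSV guarded by a SHA-256 checksum so it
cannot drift silently. Donor concentrations behind the Kp values are
not part of the table, so only per-pair J/Kp consistency and the
within-vehicle flux ordering MP > BP > CF are asserted, never absolute
Kp reconstruction.

## Problem sizes

The simulation suites use 100-seed replication for the two recovery
rates, 500 replicates for flux-coverage in the test suite (200 in the
acceptance script), and n = 200 for the Hotelling false-alarm rate;
these sizes give binomial standard errors of 1–3 percentage points on
the reported rates.

## Known limitations

* Descriptor values are not expected to match any specific commercial
  software release numerically (conventions differ in the carbon
  restriction, α-corrections and aromatic handling); the defining
  formulas above are the contract.
* The elimination stop criteria are heuristics; under exact SVD only
  the variance-drop stop is active, and as noted it is structurally
  permissive for correlated blocks once noise is gone — use the floor.
* `refine` assumes the proximity condition |r² − q²| ≤ prox_tol is
  reachable; with very noisy data it will keep removing terms down to
  one rather than stop early.
* The greedy representative split maximizes coverage, not balance; it
  is not a stratified randomization.
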