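# Methods

This note records the model, its assumptions, the parameterization, the
synthetic data generator, the numerical choices, and the known limitations
of `etcfit`.

## 1. Model

### 1.1 Enzyme-constrained FBA

An `ECModel` is a stoichiometric network with explicit enzymes.  For each
temperature and particle we build one linear program:

* **Variables.** A forward flux per reaction, a backward flux per reversible
  reaction (net flux v = v⁺ − v⁻), and an enzyme-usage variable u_e
  (mmol·gDW⁻¹) per enzyme.
* **Steady state.** S·v = 0 for every metabolite.
* **Capacity.** For every (enzyme, reaction) pair:
  v⁺ + v⁻ ≤ kcat_e(T) · 3600 · u_e, with kcat in s⁻¹ and fluxes in h⁻¹.
* **Pool.** Σ_e MW_e · u_e ≤ P, the total available protein mass.
* **Maintenance.** The non-growth-associated maintenance (NGAM) reaction's
  net flux is fixed at a temperature-dependent value given by a
  piecewise-linear table in °C.
* **Regimes.** `aerobic-batch` maximizes growth; `anaerobic-batch`
  additionally closes the oxygen uptake exchange (upper bound 0);
  `chemostat` solves a three-stage lexicographic program (§1.3).

All LPs are solved with `scipy.optimize.linprog(method="highs")`.  Reported
fluxes are net fluxes rounded to 1e−10 (with −0.0 normalized to 0.0), which
makes degenerate-solution bookkeeping such as "the growth reaction's FVA
range is exactly zero" hold exactly.

### 1.2 Temperature dependence of kcat

Each enzyme carries three thermal parameters — melting temperature **Tm**
(K), catalytic optimum **Topt** (K) and activation heat-capacity change
**ΔC‡p** (J·mol⁻¹·K⁻¹) — subject to the admissibility constraint
Tm > Topt > 0.  The effective turnover is

  kcat(T) = kcat_ref · f_folded(T) · g(T)

with a two-state denaturation sigmoid

  f_folded(T) = 1 / (1 + exp(−ΔH_u (1 − T/Tm) / (R T))),  ΔH_u = 3·10⁵ J/mol

(equal to exactly ½ at T = Tm, monotonically decreasing in T), and a
macromolecular-rate-theory-style catalytic factor normalized to 1 at Topt:

  g(T) = exp[(ΔC‡p / R) · (ln(T/Topt) − (T − Topt)/T)].

For ΔC‡p < 0, g peaks at Topt and |ΔC‡p| controls the curvature; ΔC‡p = 0
(no temperature dependence) is rejected as outside the model class.  The
rate law is validated on 260–380 K; temperatures outside that window raise.

**Assumption.** This rate law is a self-contained substitute for published
temperature-correction procedures that depend on additional per-enzyme
quantities (ΔG of unfolding curves, reference assay temperatures).  It keeps
the three-parameter-per-enzyme structure, the Tm/Topt semantics (folded
fraction ½ at Tm; rate peak at Topt), and the qualitative
rise-peak-collapse shape, which is what the inference machinery exercises.

### 1.3 Chemostat simulation

Given dilution rate D, the chemostat solve is lexicographic:

1. feasibility of growth = D (growth net flux locked to D within a relative
   band of 1e−9);
2. minimize glucose uptake; then cap it at its minimum + 1e−9;
3. minimize total protein mass Σ MW_e·u_e.

Exchange fluxes of the final solution are the observables.  Stage-1 or
stage-3 infeasibility is reported with the failing stage.  Uptake exchanges
are written uptake-positive in all user-facing files.

### 1.4 Fitness

For each dataset, predictions are generated at the dataset's temperatures
(°C converted to K at exactly +273.15) and compared to observations by
R² = 1 − SS_res/SS_tot.  An infeasible LP predicts 0 for its observables.
The chemostat dataset pools its three observables into one R².  The overall
fitness is the arithmetic mean of per-dataset R² (≤ 1, unbounded below).
`withhold_chemostat=True` averages only the two batch datasets.

## 2. Inference engines

A *particle* is the flat vector (Tm, Topt, ΔC‡p) × n_enzymes.  Priors are
independent normals per coordinate.  Draws violating admissibility are
repaired by re-drawing the offending coordinates (the (Tm, Topt) pair
jointly for ordering violations, Topt alone for positivity) with a budget of
1000 attempts before a hard error.

### 2.1 SMC-ABC with truncation selection

Each iteration: fit an independent normal to the current population (mean
and population standard deviation, ddof = 0), draw a fixed number of
proposals, repair, evaluate, pool incumbents and proposals, and keep the
top-N by fitness (stable sort; ties keep creation order).  Selection is
elitist, so the population's minimum fitness is non-decreasing — and
population diversity collapses on multimodal problems (the documented
pathology this package exists to demonstrate and avoid).

### 2.2 CrowdingDE

Per child: draw three distinct parents P1, P2, P3; copy P1; starting from a
random parameter index and wrapping, update coordinate k ←
P1_k + F·(P2_k − P3_k) while successive uniform draws stay below CR
(the random draw is taken before the stop check); an update that breaks its
enzyme's admissibility triple is reverted individually.  The child then
competes against its *nearest* population member — Euclidean distance in
σ-standardized coordinates, with σ frozen at the previous generation's end —
and replaces it only if strictly fitter (ties keep the incumbent).
Replacement is sequential on the live population.  Crowding preserves
multiple modes where truncation selection collapses them.

Both engines are driven by `numpy.random.default_rng(seed)` exclusively;
identical seed + configuration gives bit-identical histories.  Histories
(every evaluated individual plus per-generation population membership)
round-trip losslessly through CSV (`float_format="%.17g"` on write,
`float_precision="round_trip"` on read) with row counts checked against a
JSON sidecar.

## 3. Synthetic data generator

The study system (`make_scenario`) is a six-enzyme network: glucose uptake →
lumped glycolysis (pyruvate + ATP) → fermentation (ethanol + CO₂) or
respiration (O₂-consuming, 12 ATP), biomass consuming pyruvate + ATP, and an
NGAM drain whose demand rises with temperature (0.6 at 5 °C, 1.0 at 30 °C,
1.8 at 42 °C).  All enzymes share MW = 100 g/mmol on a pool of 0.02
gProt/gDW.  A `redundant` flag duplicates the first glycolysis step with its
own enzyme, creating a deliberately non-identifiable parallel pathway.

The ground truth draws Topt ~ U(300, 320) K, Tm = Topt + U(5, 20) K,
ΔC‡p ~ U(−8000, −500) J·mol⁻¹·K⁻¹.  Datasets are simulated from the truth:
growth rates at 8 temperatures in 16–42 °C (aerobic) and 5–40 °C
(anaerobic), and chemostat exchange fluxes at 6 temperatures in 30–38.5 °C
at D = 0.1 h⁻¹, with multiplicative Gaussian noise (σ = 2 %).  A truth draw
that cannot grow under every condition (e.g. too cold-sensitive to cover
maintenance at 5 °C) is discarded and redrawn from the same stream, keeping
the scenario a pure function of the seed.  The default inference prior is
N(325, 5²) for Tm, N(310, 5²) for Topt, N(−3000, 1500²) for ΔC‡p,
identical across enzymes and deliberately broader than the truth's ranges.

A two-parameter bimodal toy landscape,
f(x, y) = 1 / (1 + ((x−1)² + (y−1)²)·((x+1)² + (y+1)²)), with optima at
±(1, 1), a saddle of value 0.2 at the origin, and prior N(0, 0.2²), serves
as the analytic benchmark for the mode-retention/mode-collapse contrast.

## 4. Post-hoc diagnostics

* **FVA over the posterior** (all evaluated particles with overall
  R² above a threshold; a seeded uniform subsample): growth is maximized,
  its lower bound locked at the optimum, and each reaction's net flux
  minimized/maximized.  Failed subproblems yield NaN and are dropped.
  Per-reaction (min, max) become midpoint (mean) and range (absolute
  difference), aggregated per simulation × dataset × temperature × reaction.
* **PCA ordination** (scikit-learn, full SVD) of the parameter matrix
  standardized by population standard deviation, with constant columns
  dropped under a warning; standardization statistics come from all
  particles in the ordination so panels share axes.
* **Single-linkage clustering** (scipy) on pairwise Euclidean distances of
  the same standardized matrix; inputs are sorted by particle id first so
  tie-prone merge orders are reproducible.

## 5. Numerical choices

* LP backend: HiGHS via scipy; no commercial solver dependency.
* kcat unit bridge: s⁻¹ × 3600 inside capacity rows (fluxes are per hour).
* Temperature conversion: °C + 273.15 exactly, at the I/O boundary only.
* Flux rounding to 1e−10 (+0.0) for stable degenerate-solution reporting.
* Population statistics use ddof = 0 everywhere (ABC proposals, crowding
  distances, ordination, clustering).
* All stochastic code takes an explicit `numpy.random.Generator`; seeds are
  mandatory in run configurations.

## 6. Limitations

* The thermal rate law is a normalized stand-in (§1.2); fitted Tm/Topt/ΔC‡p
  values are comparable within this framework, not directly against
  calorimetric measurements.
* The synthetic network is desk-scale (6+ enzymes).  Genome-scale inference
  (hundreds of enzymes, thousands of parameters) is supported by the same
  code paths — SBML import via cobra included — but requires cluster-scale
  compute and real datasets not shipped here.
* Fitness equals mean R² across datasets; no measurement-error weighting or
  formal likelihood.  The "posterior" (particles above an R² threshold) is
  an approximate-Bayesian convention, not a calibrated posterior.
* The chemostat solve assumes glucose-limited steady state and fixes NGAM
  by table lookup; no dynamic or batch-phase modelling.
* Single-process execution; the engines are deliberately sequential so that
  results are bit-reproducible.
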