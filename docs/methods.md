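# Methods

This note documents the models and numerical choices behind the package, in
the spirit of a methods appendix: what is computed, under which assumptions,
and where the design was genuinely open.

## Network preparation

**Positive-only fluxes.** The learning architecture represents fluxes as a
nonnegative vector, so models are rewritten before use. Every reversible
internal reaction becomes a `_for`/`_rev` pair (the reverse column is the
negated forward column); every exchange reaction — a reaction whose
metabolites all sit on one side — becomes an inflow `_i` (oriented to add
matter to the system) and an outflow `_o`, even when the original was
one-sided. The biomass pseudo-reaction is exempt from exchange treatment: it
is one-sided in toy models but is a sink, not a boundary reaction. For the
E. coli core model this yields 154 reactions over 72 metabolites
(2×20 exchanges + 36 irreversible + 2×39 reversible internals), matching the
published unidirectional model. Any feasible signed flux maps to a
nonnegative flux of the split model with identical mass balance, and the FBA
optimum is invariant (tested on random networks and on the core model).

One nuance: a positive *lower* bound (the ATP maintenance flux, lb = 8.39 in
the core model) is preserved as-is rather than zeroed. Dropping it would
change the split model's FBA optimum; keeping it preserves the equivalence.
The differentiable solvers themselves only see `[0, upper]` boxes — positive
lower bounds and non-uptake upper bounds are honored by the simplex oracle
only, so oracle-equivalence tests compare against the simplex solution of
the same relaxed problem.

**Reduction.** Reactions whose flux stays ≤ 1e-9 across a supplied
collection of FBA solutions (by default the full training-media set) are
removed, together with metabolites left without any reaction; the objective
and all uptake inflow reactions are always retained so the input projection
stays well-defined. Reduction preserves the FBA optimum on every medium used
to build it (tested).

**Projections.** `P_in`, `P_ref`, `P_KO` are 0/1 row selectors for the
uptake, reference and knockout reactions. `S_int` is S with the uptake
inflow columns zeroed. For the Wt solver, `P_v2m = ReLU(S)` maps fluxes to
metabolite production and `P_m2v[k, j] = ReLU(−1/(z_j · S[j, k]))`
distributes metabolite j's production uniformly over its z_j consumers. The
source material prints both matrices with the same symbol and indexes z
ambiguously; we resolved the orientation from the worked example (a
metabolite consumed by two reactions with coefficient −1 gives entries 0.5),
i.e. z counts the strictly negative entries of the metabolite's *row*.

## Loss function

For a flux vector V, uptake bounds V_in, reference fluxes V_ref and binary
knockout vector R_KO (0 = knocked out):

- L1 = ‖P_ref V − V_ref‖² / n_ref — fit to reference data;
- L2 = ‖S V‖² / m — mass balance;
- L3 = ‖ReLU(P_in V − V_in)‖² / n_in — uptake upper bounds;
- L4 = ‖ReLU(−V)‖² / n — flux positivity;
- L5 = ‖ReLU(P_KO V − R_KO)‖² / n_KO — knocked-out fluxes.

The five terms are summed unweighted (weights are exposed but default to 1).
L5 is replicated as printed in its source, including the quirk that an entry
of 1 (reaction *not* knocked out) grants a flux allowance of 1 rather than
being inactive; with growth rates ≤ ~1 h⁻¹ this is harmless, but it is a
semantic oddity worth knowing about. The rectifier uses subgradient 0 at
exactly 0, which makes tie-breaking deterministic. The analytic gradient of
every term is verified against central finite differences to 1e-5.

## The three differentiable solvers

**Wt.** Alternates M = P_v2m V and V = (P_m2v ⊙ W_r) M + V⁰. W_r rescales
the uniform consumer split into actual branching ratios; with W_r derived
from a reference distribution the fixed point reproduces that distribution
(closed-form check on the branch network). The scheme cannot represent two
exactly-bounded flux distributions that split a node differently with one
W_r — this documented limitation is asserted as a test, and the estimator
refuses the Wt solver in exact-bounds mode.

**LP.** Solves max c᷀ᵀV s.t. S_int V = −b, V ≥ 0, where b carries the uptake
supply per medium metabolite row, by primal–dual gradient iterations:
diagonal-preconditioned Chambolle–Pock steps (τ_j = 1/Σ_i|K_ij|,
σ_i = 1/Σ_j|K_ij|) with primal extrapolation, initialized at
V⁰ = P_inᵀ V_in, U⁰ = 0. U converges to the metabolite shadow prices. With
upper (rather than exact) bounds, slack variables on the uptake-fed rows
let the network consume less than the supplied bound. Plain saddle-point
dynamics on the augmented Lagrangian were tried first and satisfy
feasibility quickly but approach the optimum far too slowly on the core
model; the extrapolated, preconditioned form reaches the simplex optimum to
~1e-4 relative in 5×10⁴ iterations there, and to 1e-3 within 2×10⁴
iterations on the random toy networks used in the acceptance property.
Divergence (non-finite or > 1e9 iterates) raises with the iteration index.

**QP.** Plain gradient descent V ← V − dt ∇L with the analytic gradient
above. `dt="auto"` sets dt = 0.9/Lip from the largest singular value of S,
guaranteeing monotone descent on the smooth part (the loss trace is
asserted non-increasing after the first 10 iterations). In exact-bounds
mode the uptake components of V are overwritten with V_in at every step —
bit-identical, not approximately. Terminal losses below 1e-5 on
FBA-consistent references need up to ~1.5×10⁵ iterations on ill-conditioned
random instances; convergence is declared when the loss improves by < 1e-9
over 100 iterations, and the state reports which criterion ended the run.

## Hybrid estimators

`AMNRegressor` composes a dense network (He-initialized, rectified hidden
layers, inverted dropout) with an unrolled mechanistic layer. Defaults
follow the benchmark settings: one hidden layer of 500 (toy tests use 16),
dropout 0.25, batch size 5, Adam at 1e-3, and 4 unrolled solver iterations —
the neural warm start is what lets the mechanistic layer be shallow. Inside
the layers, the QP form uses the same auto step as the standalone solver;
the LP form scales its diagonal steps by 0.1 by default, because the layer's
job is to nudge V⁰ toward optimality, not to re-solve the LP in four steps
(full-strength steps dominated the forward pass and broke training).

**V⁰ activation.** The source architecture does not state an output
activation for the neural layer. A rectified output was tried and reliably
*dies* under Adam on small problems (all pre-activations go negative, the
gradient vanishes, training stalls at Q² < 0). The default is therefore a
linear V⁰ output; flux positivity is enforced by L4 and by the projection
steps inside the LP layer. `output_activation="relu"` remains available.

**Inputs.** With `input_kind="V_in"` the bound loss L3 uses the supplied
bounds. With binary compositions (`C_med`, optionally `+R_KO`) there are no
numeric bounds; L3 then uses the neural layer's own uptake predictions as
bounds, which ties the internal fluxes to the predicted uptakes without
fixing them. In exact-bounds mode the uptake components of every V iterate
are clamped to the input and receive no updates from either layer.

`ANNFluxRegressor` is the black-box baseline: a dense map from uptake bounds
to *all* fluxes, trained on the mean squared error over every reaction (so a
1000-row training set carries 154,000 labels on the core model instead of
1000). Constraint losses are computed post hoc on its predictions; the
paired tests show the hybrid keeps constraints orders of magnitude tighter
at equal row counts — the dimensionality argument for hybrid models.

## Reservoir scheme

`build_reservoir` deep-copies a trained AMN and freezes its parameters
(fit refuses to run; a parameter checksum is asserted unchanged after
downstream training), while gradients still flow *through* it.
`UptakeNetwork` prepends a trainable network mapping C_med → V_in and trains
it at Adam 1e-4–1e-3 for ~400–1000 epochs so that the composite prediction
matches measured growth; the fitted V_in table is exported as a
tab-separated bounds file (reaction id, upper bound) that any
constraint-based tool can apply directly.

Two numerical choices matter here, both found the hard way and verified by
gradient checks and loss-landscape scans:

1. the pre-network's final layer is initialized small (weights ×0.01, bias
   1.0) so every inferred bound starts near 1 mmol gDW⁻¹ h⁻¹. He
   initialization with few inputs gives output SD > 1, which can land the
   initial V_in in a spurious basin of the frozen reservoir — outside its
   training range the reservoir extrapolates (roughly |V_in|), creating a
   mirror-image local minimum at negative V_in that traps training.
2. an explicit positivity penalty ‖ReLU(−V_in)‖²/n_in is added to the
   composite loss, and exported bounds are rectified at 0: an uptake bound
   is a flux and must be nonnegative.

The end-to-end acceptance property runs the whole loop — simulate FBA data,
train an AMN-QP, freeze it, fit the pre-network on a synthetic "measured"
dataset, export V_in, re-score with the independent simplex oracle — and
requires R² ≥ 0.95 against the world's growth rates; a control with a
random-weight (untrained) reservoir must do worse, confirming the trained
surrogate is load-bearing.

## Classical-FBA side

`solve_fba` delegates the LP to scipy's HiGHS; cobra (GLPK) re-solves the
same instances in tests as an independent oracle. Infeasible media are
reported distinctly from feasible zero growth, and training-set generation
keeps them as growth-0 rows with a log entry. Degenerate alternate optima
are accepted: only the objective value is contractually unique, and
flux-level assertions use networks with unique optima. The knockout baseline
clamps knocked-out reactions to zero flux and gives present substrates a
common upper bound (default 11 mmol gDW⁻¹ h⁻¹, the calibrated value for the
knockout benchmark); the scaler search scans bounds in [1, 10] at a 0.1
resolution for the value maximizing R² against measured growth.

**Obligate uptakes.** A candidate uptake is obligate when closing it (upper
bound 0) abolishes growth although every other candidate is open at a high
bound (1000). On toy networks this behaves as expected (a sole carbon source
is obligate; alternative carbon sources are not). On the E. coli core model
the scan flags only uptakes with no metabolic alternative — phosphate when
all 20 exchanges are candidates; glucose, ammonium and phosphate when
restricted to the 7 default-medium exchanges — because CO2, H⁺, H2O are
net-excreted and anaerobic routes bypass O2. The conventional 7-uptake
"obligate" list for that model equals its default-medium exchange set and is
shipped as the preset `ECOLI_CORE_OBLIGATE` rather than derived from the
scan.

## Media and designs

Simulated media select each variable uptake independently with probability p
(so the selected count is Binomial(n_var, p); a chi-square goodness-of-fit
test guards the sampler) and draw the bound of each selected uptake
uniformly with the lower edge excluded by rejection; obligate uptakes are
fixed at 10 mmol gDW⁻¹ h⁻¹. Presets mirror the benchmark recipes: bounds in
(2, 10] for the core model, (0, 2.2] for iML1515-style media, (0, 10] for
iJN1463-style. All-zero selection rows are kept (the medium is then
obligates only). The experimental design enumerates all single carbon
sources and samples 20 pairs, 40 triples and 40 quadruples without
replacement per size — 110 media over 10 sources.

## Growth rates from OD600

µmax is the maximum slope of an ordinary least-squares fit of ln(OD600)
within a 1 h window sliding one sampling point (10 min in the emulated plate
format) at a time; only full-width windows with ≥ 2 points count, windows
containing nonpositive OD are skipped with a warning, and `t_max` restricts
scoring to the first growth phase. Natural log is used; a base-10 fit would
scale slopes by ln 10. On noiseless exponentials the recovery is exact to
1e-9. Note that max-over-windows is an extreme-value statistic: on long pure
exponentials with multiplicative noise it is biased upward by window
selection, while on realistic lag/saturation curves (few windows at maximal
slope) the bias stays below 5% at 2% OD noise — the property is asserted on
the realistic fixture.

Replicates are aggregated per medium after an automated outlier rule
replacing manual curation: a replicate is dropped when its robust z-score —
deviation from the replicate median over max(1.4826·MAD, 10% of the median
rate) — exceeds 3. A plain z-score cannot exceed (n−1)/√n ≈ 2.5 at n = 8,
so a plain-z cutoff of 3 would never fire; the MAD scale needs the 10%
relative floor so that tight replicate sets do not lose healthy members. A
manual exclusion list is supported for exact reproduction of curated
datasets.

## Evaluation

Q² = 1 − SS_res/SS_tot on held-out predictions (R², same formula, on fitted
data). Repeated stratified k-fold cross-validation stratifies on balanced
rank bins of the growth rate (or on caller-supplied groups), predicts every
point exactly once per repeat, and pools validation predictions across
repeats; per-point prediction mean/SD over repeats feed the
box-intersection analysis. Growth/no-growth classification binarizes
measured rates at 5% of the dataset maximum (0.165 h⁻¹ for a 3.3 h⁻¹
maximum) and uses continuous predictions as ROC scores. The variability
ceiling resamples each point from Normal(mean, sd) and reports the mean ± sd
of Q² over 1000 draws; negative resampled rates are kept by default
(clipping is an option). The box-intersection fraction counts points whose
measurement and prediction ±1 SD intervals overlap — the exact condition for
the error box to touch the identity line.

## Synthetic worlds: what a green test establishes

The fixture generators emulate the *statistical structure* of the real
pipelines — binomial media, binary designs with replicate noise, lag +
logistic OD curves with multiplicative lognormal noise, affine (default) or
saturating medium→uptake maps with FBA-computed growth — and emit the same
file formats the real-data path reads. They do not emulate transporter
kinetics, regulation, batch effects or plate artifacts. A green end-to-end
test therefore establishes that the machinery (splitting, sampling,
solvers, backpropagation, freezing, export, re-scoring) is correct and
self-consistent at toy scale, not that any particular organism-level
accuracy will be reached; the headline experimental reproductions require
the original measured datasets and genome-scale models, which are
download-gated and out of the offline test surface.

## Known limitations

- The differentiable solvers ignore positive lower bounds and non-uptake
  upper bounds (see above); models whose phenotype depends on such bounds
  are only faithfully handled by the simplex oracle.
- The LP surrogate needs tens of thousands of iterations for tight optima
  at genome scale; inside an AMN this is mitigated by the neural warm start,
  standalone use should budget iterations accordingly.
- Training runs on CPU via the numpy autodiff engine; it is sized for
  reduced models (hundreds of reactions), not for unreduced genome-scale
  networks with thousands.
- `repeated_stratified_cv` retrains one model per fold per repeat; with
  expensive estimators the caller controls cost through k, repeats and the
  estimator's own epochs.
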