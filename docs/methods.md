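# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the test suite demonstrates.

## Physiological models

Biomass follows the closed-form logistic curve

    X(t) = X0 * exp(mu_max t) / (1 - (X0/X_max)(1 - exp(mu_max t)))

with X0 (g/L) fitted (lower-bounded at 0.01 g/L) rather than fixed, since
inoculum carry-over varies between runs.  Glucose and shikimate follow the
integrated two-rate recursions

    S(t) = S(t-dt) - q_exp X dt (1 - X/X_max) - q_sta X dt (X/X_max)
    P(t) = P(t-dt) + q_exp X dt (1 - X/X_max) + q_sta X dt (X/X_max)

stepped on a fine grid (default dt = 0.01 h; halving dt moves the
trajectory endpoints by well under 0.5 % at the central-point parameters)
and clipped at zero for the substrate.  The q's are specific rates in
g·gX⁻¹·h⁻¹: the parameter-table convention of printing q in g/(L·h) is
dimensionally inconsistent with multiplying by X(t) inside the recursion,
so the specific-rate reading is used throughout and values are comparable
after dividing volumetric rates by biomass.

Fitting is two-stage, matching the sequential description of the method:
the logistic triple first (multi-start Nelder–Mead on log parameters, five
seeded starts, ties broken by SSE then by parameter norm), then each
two-rate pair by linear least squares on the phase-integral design matrix
(the recursion is linear in the two rates) with a simplex polish against
the zero-clipped model.  Substrate samples at the zero floor are censored
from the linear solve — they carry no rate information and would otherwise
bias both rates.  Zero-noise round trips recover all rate parameters to
better than 0.1 % relative.

Acetate is not described by these recursions (it is produced, consumed and
produced again); it is summarized by the approximated rates q_ac_exp =
mu_max · Y_ac/x (AC-vs-biomass regression slope over the first three
exponential-phase samples) and q_ac_sta = Q_sta / X_max (AC-vs-time slope
over the first three stationary samples).  Window sizes are configurable.

Yields: Y_ps = ΔP/ΔS on the model curves, evaluated at substrate
exhaustion when that precedes the end of the run (the decoupled production
model would otherwise keep producing without substrate).  Y_px has no
reconstruction that reproduces the historically printed value from the
printed totals, so it is a configurable definition (default ΔP/X_max) and
its printed value is never asserted.

Model adequacy per channel: error % = 100·SSE/SSEP, the squared Pearson
coefficient of the model-vs-data regression, the slope percent deviation
SPD = 100·|slope − 1|, and the regression p value (t statistic, n − 2 df).

## Response surfaces

One ordinary-least-squares quadratic f(G,Y) = b0 + b1 G + b2 Y + b3 G² +
b4 Y² + b5 GY per parameter, in natural units (not coded levels) so
critical-point coordinates read directly in g/L.  Critical points solve
∇f = 0 and classify by the Hessian eigenvalue signs; |det H| below 1e-10
(scaled) reports "degenerate".  Out-of-domain critical points are reported
with an `in_domain` flag rather than suppressed.  Held-out validation uses
a two-tailed t test with statistic (pred − obs)/(σ·√(1 + 1/n)), df = n − 1,
where σ is the central-replicate standard deviation and n = 3; the exact
denominator of the historical test is not recorded, and this form (a
prediction-vs-single-observation comparison scaled by replicate spread) is
the package's choice.  Zone maps z-score each surface over the evaluation
grid before taking the per-cell argmax, so units do not dominate; z-scores
are rounded to 9 decimals so exact ties break deterministically by
insertion order.

## Synthetic data

The generator emulates the study conditions: the 3×3 design (GLC
75/100/125 × YE 15/30/45 g/L) with the central point in triplicate,
sampling every 2 h to 12 h then every 4 h to 36 h, and multiplicative
Gaussian measurement noise (default cv = 0.05 per channel, clipped at
zero).  The truth parameter field is quadratic in (GLC₀, YE₀), anchored
exactly at the central-point means (X_max 12.80 g/L, μ_max 0.58 h⁻¹,
q_glc^exp 1.24, q_sa^exp 0.35, q_glc^sta 0.45, q_sa^sta 0.13, q_ac^exp
0.52, q_ac^sta 0.50 g/gX/h) and encoding the reported geometry: the
q_glc^exp saddle at (96, 37) g/L, the μ_max minimum at (105, 21), the
final-SA maximum at (110, 40), and X_max increasing with YE.  Off-center
coefficients are package fixture constants.

Acetate is built piecewise to mimic the observed profile: biomass-tracking
production (yield q_ac_exp/μ_max) until the biomass-acceleration maximum,
linear consumption to 5 % of the peak at stationary onset (X ≥ 0.95
X_max), then linear production with volumetric slope q_ac_sta·X_max — so
the early-window regressions recover the construction exactly.

What the generator does **not** model: batch-to-batch biological
variation.  At cv = 0.05 the Monte-Carlo spread of refitted X_max across
replicates is 0.25 g/L, about a third of the study's central-point σ
(0.77), which included three different yeast-extract lots.  Passing tests
therefore demonstrate estimator correctness under measurement noise, not
robustness to biological lot effects.  The per-parameter truth fields are
also mutually independent quadratics; emergent quantities (final SA,
consumed GLC, Y_ps) follow from the rate fields and differ from the
metadata anchor fields by design.

## Metabolic network fixture

`data/ar36_synthetic_network.tsv` is a synthetic reconstruction of the
strain's central carbon metabolism sized to exactly 60 reactions, 44
internal metabolites and 6 external species (GLC, YE, SA, AC, BIOMASS,
MAINT): EMP glycolysis (GalP lumped with glucokinase; Fba with triose
isomerase; GapA with Pgk; Pgm with enolase), oxidative and non-oxidative
PPP with the transketolase split (TktA1/TktA2), Entner–Doudoroff, TCA,
glyoxylate shunt, anaplerosis (Ppc, PckA, both malic enzymes), acetate
metabolism (PoxB, Pta/AckA, Acs, ActP import/export), the terminal
shikimate branch (aroK/aroL absent, so shikimate is exported), a
three-route carbon-consistent yeast-extract decomposition into BIOMp, AAA,
ALA and GLU, lumped biomass formation, and respiration/maintenance.  The
strain lacks pykF, so PykA is the only pyruvate kinase.  CO₂ is tracked as
an internal metabolite vented into the MAINT sink, which makes the whole
network carbon-balanced (cofactor moieties carry no carbon) and lets the
tests audit carbon closure through the mode yields.  Biomass and YE are
pseudo-species with fixture molar masses 130 and 150 g/mol; GLC/SA/AC use
180.16/174.15/60.05 g/mol.

## Elementary modes and yield reduction

Enumeration is the double-description (Schuster tableau) algorithm on the
split-reversible network with the support-based adjacency test (a
candidate from a positive/negative ray pair survives only if no third ray's
support is contained in the union of the parents' supports).  Two lossless
pre-processing steps keep the tableau small: flux-forced-zero columns are
dropped and single-producer/single-consumer internal metabolites are
merged, with modes re-expanded to original reactions afterwards.  Supports
are bit-packed; the adjacency loop compiles with numba when available.
Spurious two-cycles from the reversible split, and modes using both
directions of one reaction, are removed.  Modes are normalized to unit
glucose uptake when glucose is in the support (unit L1 norm otherwise).
The fixture enumerates to 27 944 modes in well under a minute on one CPU;
enumeration equals an exhaustive support-search oracle on all toy networks
the suite generates.

Family selection follows the phase sign patterns: exponential modes
consume both GLC and YE and produce SA; stationary modes consume GLC,
produce SA and have zero YE uptake.  Reduction seeks the smallest subset
whose convex hull in yield space (default dimensions: biomass, SA, AC per
mmol GLC) contains the observed yield point, with ties broken by smaller
hull volume then lexicographic mode index.  The search is exhaustive up to
12 family modes; beyond that the support of a basic (vertex) LP solution —
a Carathéodory subset of at most dim+1 modes — seeds an exhaustive
minimization within that support (the family sizes here, ~19 000 modes,
make per-removal elimination sweeps impractical; this path is flagged as a
heuristic).

Two structural facts shape the reduced counts.  First, Carathéodory bounds
any minimal containing subset at dim+1 (4 in the default 3-D yield space),
so large published family sizes cannot be reproduced by minimal-subset
reduction alone; the pipeline therefore expands the reduced families
deterministically (greedy hull-volume maximization) to the 6 + 3 model
structure of the study design, and reports both the minimal and the model
counts.  Second, support-minimality gives every glucose-only SA-producing
mode an SA yield of at least ~0.5 mol/mol in this network, while the
observed stationary yields (q_ac_sta exceeding q_glc_sta in carbon) are
infeasible for any glucose-only stoichiometry; infeasible targets are
projected onto the nearest hull point (L1, by LP) with a provenance flag.

## Cybernetic model

State: GLC, AC, SA (mM), YE (pseudo-mM), biomass (g/L) and one relative
enzyme level per mode.  Mode kinetics r_i = k_max,i [GLC]/(K_m,i+[GLC]) ·
(1+[AC]/K_I)⁻¹ · w_i with w = 1 − X/X_max for exponential-family and
X/X_max for stationary-family modes (w clipped into [0,1]).  The realized
uptake is q_i = e_i v_i r_i; external balances are the yield-weighted sums
dC/dt = Σ y_C,i q_i X.  The matching law sets u_i = p_i/Σp and
v_i = p_i/max p from returns p_i = e_i r_i · (carbon uptake of mode i per
mmol GLC), implementing carbon-uptake maximization; biomass- and
SA-weighted objectives are selectable.  Enzyme dynamics follow the
standard cybernetic form de_i/dt = α + k_e u_i·Monod − (β + μ) e_i with
defaults α = 0.001 h⁻¹, β = 0.05 h⁻¹, k_e = 1 h⁻¹ and the dilution term
toggleable.  Initial enzyme levels are 0.95 for the first
exponential-family mode, 0.5 for the remaining exponential modes and 0.1
for stationary modes.  Mixed-substrate modes stall when YE is exhausted.

Integration uses LSODA (halving its tolerances moves final concentrations
by far less than 0.1 %); a fixed-step RK4 with nonnegativity clipping
(numba-compiled) serves the fitting loops, where truth and candidate
trajectories share the same integrator and step (dt = 0.1–0.125 h; the
step-refinement study shows sub-0.1 % trajectory changes below dt = 0.05).
Flux snapshots reconstruct reaction fluxes as mode-weighted sums and
normalize to glucose uptake; snapshot times are IEx = MEx/2, MEx = the
biomass-acceleration maximum (for a logistic, at X/X_max = 1/2 − √3/6),
and MSt = the midpoint of stationary onset (X ≥ 0.95 of the trajectory's
own plateau) and the end of the run.

## Genetic algorithm

From k_max = 1, K_m = 10 for every mode: each cycle perturbs one parameter
at a time by a log-uniform factor in [0.5, 2] (2m candidates; 18 for nine
modes), refines each candidate by Nelder–Mead in log space capped at 200
objective evaluations, crosses the best with the runner-up by copying the
runner-up's perturbed coordinate, and keeps the incumbent when it is still
best.  Channels are normalized by their experimental sum of squares so mM
and g/L channels weigh comparably.  Cycling stops at a relative
best-SSE change below 1e-3 over consecutive cycles — or when the
normalized SSE falls below 1e-6, since on noise-free self-generated data
the SSE tends to zero and relative change alone never settles — followed
by a final 400-evaluation polish.  On self-generated nine-mode data the
plateau arrives in about 9–14 cycles across seeds.

A known limitation: the model is *sloppy* in absolute k_max — enzyme-level
scaling and K_m trade off against it — so fits reproduce every channel to
error percentages far below 1 % while individual k_max values can sit far
from the generating ones.  Recovery claims are therefore made about the
trajectories, not about per-mode kinetic constants.

## Fed-batch feed design

Open-loop, model-based pseudo-exponential feeding with a 15-min zero-order
hold: per substrate, F_s = q_s X V/(C_feed,s − C_set,s), with q_s X
evaluated as the model's average consumption over the upcoming hold so the
tank returns to the setpoint at hold boundaries under model-perfect
operation.  YE demand is approximated as 2.3 g YE per g of new biomass.
Pure open-loop operation accumulates the pre-window deficit (feeding
starts at 3 h) and the cross-dilution of each substrate by the other feed,
drifting ~7 g/L below an 80 g/L glucose setpoint over the window; the
optional measurement-feedback mode adds a proportional correction (1-h
time constant) at each hold and keeps |GLC − 80| within ~2.5 g/L.
Simulated mass balance closes to machine precision.  Volume dynamics exist
only in the fed-batch simulator; batch modules assume constant volume.

## Problem sizes used by the test suite

The suite runs the full physiological pipeline on the 9-condition design
(11 experiments) but exercises the GA-based flux stage on two design
points and one shared nine-mode recovery experiment; the acceptance script
runs five GA fits on the full nine-mode model.  These sizes were chosen as
the smallest that still exercise every code path end to end.
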