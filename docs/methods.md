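# Methods

## Model and assumptions

The circuit couples active YAP/TAZ (`YT_up`) to three feedbacks: a negative
loop through LATS1/2 (YAP/TAZ induces LATS transcription; LATS
phosphorylates and thereby inactivates YAP/TAZ), and two positive loops
through SIRT1 and NOTCH (each induced by YAP/TAZ and each inducing YAP/TAZ
production).  Transcriptional regulation is modelled with Hill functions
sharing a single exponent `n`; phosphorylation and dephosphorylation with
Michaelis–Menten kinetics; basal production is constant and degradation
first-order.  Concentrations and time carry arbitrary units throughout —
no unit-conversion layer is provided, and 720 time units is used as the
"long-run" horizon at which every trajectory has reached its attractor.

Because SIRT1, NOTCH and phosphorylated YAP/TAZ are fast relative to
`(L, YT_up)`, they are eliminated by quasi-steady state.  `S*` and `N*`
are simple rational functions of `YT_up`; `YTp*` is the positive root of a
quadratic in `YT_p`.  All equilibrium, nullcline and bifurcation analysis
uses the resulting two-variable system; the five-variable system is kept
for time courses and as the substrate of the stochastic scheme.  The
package asserts (in tests) that the two representations have identical
equilibria.

## Standard parameter set and its calibration

The standard parameter set shipped in
`src/yaptaz/data/standard_parameters.yaml` is this package's own
calibration, constructed so that the circuit exhibits the canonical
coupled-bidirectional-switch structure with the conventional standard
operating point `kYTup0 = 0.007`:

* four saddle-nodes with SN1 (0.0035) < SN2 (0.0055) < SN4 (0.0105) <
  SN3 (0.0155), so 0.007 is monostable homeostatic;
* tristability (SN4 < SN2) when the negative-feedback strength `kYTup3`
  is reduced to 85%, and a widened monostable window at 115%;
* SN4 < 0 (irreversible tumorigenic state) when `JN` is reduced by 15%;
* all four folds persist under every single-parameter ±15% perturbation;
* the lower switch most sensitive to SIRT1-loop parameters and the upper
  switch to NOTCH-loop parameters;
* visible noise-driven state transitions at Ω = 100 for `kYTup0` in
  {0.004, 0.005, 0.012, 0.014}.

Calibration proceeded in two stages.  First, the structure was designed
analytically: the scalar equilibrium residual along the L-nullcline
decomposes into a production ladder (basal rate plus two sigmoidal steps
from the SIRT1 and NOTCH loops) against a loss curve (linear degradation
plus the LATS-mediated phosphorylation flux, whose own Hill dependence on
`YT_up` forms a loss shoulder).  The SIRT1 step is placed below the
homeostatic level and the NOTCH step inside the LATS loss shoulder — the
latter is what lets a 15% change of `JN` move SN4 across zero, because the
composed (double-Hill) production step is locally steeper than the
single-Hill loss shoulder.  Second, nine structural knobs were tuned by
Nelder–Mead against penalty terms encoding the bullet list above, and the
result rounded to three significant figures and re-verified.  `n = 4` is
used for every Hill term: a single shared exponent keeps the model
minimal, and the effective cooperativity of the two-Hill compositions then
suffices for all switches.  Half-saturation constants place SIRT1
activation (`JS = 0.336`) below, and NOTCH (`JN = 1.382`) and LATS
(`JL = 1.461`) activation above, the homeostatic YAP/TAZ level 0.67.

Saddle-node *coordinates* under this set are properties of the
calibration, not externally fixed quantities; the structural and counting
statements above are the meaningful outputs.

## Equilibria and continuation

Equilibria of the reduced system always satisfy the explicit L-nullcline
`L = (kL1 + kL2·H(YT_up))/kL3`, so the census reduces to root-finding a
scalar residual in `YT_up`: a dense grid scan (2000 points by default)
plus Brent refinement to 1e-14.  Stability comes from the eigenvalues of
the central-difference Jacobian of the two-variable field, with thresholds
±1e-8 on the largest real part ("marginal" in between, expected only at
folds).  An independent brute-force oracle — 2-D sign-change cells on a
400×400 grid refined by damped Newton iteration, never using the
L-nullcline reduction — must agree with the census on the standard set and
on randomly perturbed suites; this dual route is asserted in tests and in
the acceptance script.

Bifurcation diagrams use a dense parameter sweep (300–400 steps) rather
than pseudo-arclength continuation: the system is two-dimensional and each
census costs a millisecond, and a sweep composes naturally with the
brute-force oracle.  Censuses at successive parameter values are linked
into branches by an order-preserving minimum-cost alignment (roots of a
scalar residual cannot cross in `YT_up`; folds create or destroy adjacent
stable/unstable pairs), which is robust where greedy nearest-neighbour
matching mislinks distant branches.  Branch endpoints interior to the
sweep range are folds and are refined by bisection on the swept parameter
to ~1e-9.  Stable branches are labelled degenerative / homeostatic /
tumorigenic by their `YT_up` ordering; SN1/SN3 are the homeostatic
branch's endpoints, SN2 the degenerative branch's right endpoint, SN4 the
tumorigenic branch's left endpoint.  Sweep ranges extend to negative
`kYTup0` so that folds pushed below zero (the irreversibility signature)
are recorded rather than lost.  A generic scalar fold detector
(`detect_folds_1d`) exposes the same count-and-bisect core and is
validated against the cusp normal form `dx/dt = a + b·x − x³`, whose folds
sit at `a = ±2(b/3)^{3/2}` exactly (matched to 1e-5).

## Sensitivity scan

Each parameter except the swept `kYTup0` (a CLI/API flag can include it)
is multiplied by 0.85 and 1.15 one at a time — including the Hill exponent
`n`, whose perturbation is logged separately since it changes term shapes
rather than scales.  Each perturbed diagram is fully retraced and each
fold reported as `perturbed position / baseline position`; a fold at ≤ 0
sets the irreversibility flag (the ratio is still reported with its sign).
Rankings use the larger |log fold change| of the two directions, ties
broken alphabetically for determinism.

## Stochastic scheme

The five ODEs decompose into 16 reaction channels — one per additive rate
term, with phosphorylation/dephosphorylation moving a molecule between the
`YT_up` and `YT_p` pools.  The scheme is hybrid (not mass-action): Hill
and Michaelis–Menten propensities are evaluated at concentrations `X/Ω`
and scaled by Ω, which reproduces the deterministic right-hand side
exactly in the large-Ω limit (asserted at machine precision in tests).
Tau-leaping fires each channel Poisson(propensity·τ) times per leap.

Numerical choices: Ω = 100 molecules per concentration unit for
population experiments; τ = 0.01 time units — a package choice validated
two ways (clamp rate, see below, and agreement of tau-leap moments with an
exact-SSA oracle on a birth–death toy in the tests); horizon 720 time
units; initial copy numbers `round(Ω × homeostatic concentration)`.
Species driven negative in a leap are clamped to zero and counted; the
clamp rate is reported per run and a warning is raised above 10% of leaps
(at the defaults it is ~0).  Extrinsic noise draws one Latin-hypercube
parameter set per cell — every parameter stratified uniformly within ±5% —
fixed for that cell's whole trajectory.  One global seed expands through
`numpy.random.SeedSequence` spawning into per-stage, per-condition
streams, so ensembles are reproducible and individually re-runnable.

Cells are classified by their terminal `YT_up` against the stable branches
of a reference bifurcation diagram at the experiment's `kYTup0`: thresholds
are the unstable-branch values separating adjacent stable branches
(monostable regimes label unconditionally; a value exactly on a threshold
goes to the lower state and is logged).  This is an approximation to the
true basin boundary that ignores the `L` coordinate; it is validated
against labelled mixture fixtures in the tests.

## Synthetic fixtures and what passing tests show

The fixture module generates every test input: the analytic cusp toy (fold
oracle), multiplicative ±15% parameter suites (oracle-equivalence
regression), and labelled Gaussian-mixture populations (classifier test
bed).  All are pure functions of their seeds.  The mixture fixture
emulates well-separated terminal-state clusters; it does not emulate the
correlated, heavy-tailed excursions of real tau-leap trajectories near a
fold, so classifier accuracy guarantees apply to separated populations
only.  Likewise, the parameter suites probe a ±15% box around one
calibrated point, not the global parameter space.

## Problem sizes used in the shipped runs

Default analysis sizes were chosen so that each stage completes in seconds
to a few minutes on one core: 300-step sweeps with 1200-point censuses for
diagrams, 5-point grids for two-parameter fold curves, 50-set oracle
suites, and stochastic ensembles of 200 cells per condition (the examples
use 60).  Fold positions change by < 1e-4 between 300- and 400-step
sweeps; fractions at 200 cells carry binomial error of a few percent.

## Known limitations

* Saddle-node coordinates are calibration-dependent (see above).
* No Hopf or limit-cycle continuation: none arises in this circuit's
  explored range, and the stability classifier only distinguishes
  node/saddle behaviour by eigenvalue real parts.
* The basin classifier thresholds on `YT_up` alone.
* Tau-leaping uses a fixed τ with clamping; no adaptive step selection.
* No spatial or population-level (division/death) extensions; parameters
  are not fitted to experimental data.
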