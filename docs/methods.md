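# Methods

This note documents the models, numerical choices and limitations behind
`mfa2s`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The system is a stoichiometric model (metabolites I, reactions J, matrix
S) at metabolic and isotopic steady state: S·v = 0 for all non-boundary
metabolites, and labeling patterns are time-invariant. Carbon labeling is
tracked only over the core reaction set; every core reaction carries one
or more letter-coded atom maps (multiple equiprobable maps encode
molecular symmetry, e.g. a two-fold symmetric intermediate contributes its
two orientations at weight ½ each). Reversible core reactions are split
into nonnegative forward/backward fluxes (`j_f`, `j_b`); the net flux is
v_j = glucupt·(V_f − V_b) with V normalized to the substrate uptake rate
*glucupt* (taken as the midpoint of the measured uptake interval). Isotope
effects, natural-abundance corrections and isotopically nonstationary
dynamics are out of scope; measured MDVs are assumed already corrected.

**Two-scale approximation.** Non-core reactions are assumed not to
contribute directly to core labeling. It is enforced by the limiting
procedure: for each non-core reaction with a core product (or, for
reversible reactions, a core reactant reachable by the backward
direction), the corresponding bound is clamped to the smallest of
{0, 0.05, 0.2}·glucupt that leaves the model feasible with growth
constrained to its measured interval (growth is never maximized).
Reactions still infeasible at 0.2·glucupt are left there and flagged.
Clamps are applied cumulatively in model order; because feasibility is
rechecked after each clamp the order can matter in principle, so the order
and every trial are recorded in the `LimitReport`.

**EMU balances under residual inflow.** The published balance equations
couple Σ_m f_em = 1 with core-only production/consumption terms; taken
literally they force core-only mass balance for every tracked metabolite,
which contradicts the nonzero (≤ 0.05·glucupt) inflows the limiting step
deliberately allows. `mfa2s` therefore uses *production-weighted*
balances: the MDV of each tracked EMU is the flux-weighted mixture of the
MDVs delivered by its tracked producers. When tracked production equals
tracked consumption this is exactly the standard steady-state EMU balance;
when part of the turnover is untracked it is equivalent to assuming the
untracked inflow carries the same labeling as the tracked production mix —
a neutral, zero-information assumption whose worst-case error is precisely
what ELVA bounds. MDVs are solved size level by size level as dense linear
systems (one iterative-refinement step if the residual exceeds 1e-10);
condensations enter as discrete convolutions of lower-level MDVs.

## The fit

The fit minimizes OF = mean_e mean_m ((f_exp − f)/Δ)² (the average
squared data–model deviation in units of the experimental error; SSR is
reported alongside). Rather than carrying the labeling balances as
explicit NLP equality constraints, the problem is solved in reduced form:
decision variables are the split core fluxes plus non-core net fluxes; the
EMU cascade is solved exactly inside the objective; stoichiometry, bounds
(including measured extracellular fluxes and growth applied as bound
pairs, not equalities) and split-net coupling remain linear constraints.
SLSQP handles the smooth reduced problem with finite-difference objective
gradients and exact constraint Jacobians; the balance matrix is passed as
an orthonormal row-space basis so the equality system is full-rank.

Nonconvexity is addressed by multistart: restart k draws a starting point
seeded by (master seed, k) as a Dirichlet mixture of random LP vertices
blended 50/50 with a max-slack interior point of the flux polytope.
Interior starts matter twice over: they keep every carbon route active (a
zero-production EMU makes the balance singular; such trial points are
penalized with a large objective value), and they leave
labeling-indifferent directions — futile cycles — at interior values
rather than parked at ±bounds. Default restarts: 10 for the library
(configurable; the underlying multistart need is the reason restart counts
in the upstream literature plateau around 15); the bundled study runs use
3–4 on the small fixtures. Convergence tolerances: 1e-10 on the SLSQP
objective step, 1e-6 on constraint violation for accepting a restart.
Exchange (split) fluxes are capped at 10·glucupt above the net bound to
keep the problem bounded; exchange magnitude is not penalized.

## ELVA

At the fitted solution the aggregated non-core *net* flux at each core
metabolite is computed (its consistency with S·v = 0 is asserted to
1e-6). Net inflow becomes a dummy reaction `RI<met>` from species
`OUT<met>` with an identity atom map, the same carbon count, and free
labeling; net outflow becomes `RO<met>` (no labeling effect). Each
measured MDV element is then minimized and maximized over the dummy
labelings with all fluxes fixed. Free labelings are parameterized as full
positional-isotopomer distributions per dummy (so all of a dummy's EMUs
stay mutually consistent). Because the objective is linear in each
dummy's distribution separately, the optimum over the product of
simplices lies at vertices; it is found by alternating exact
single-dummy vertex sweeps from several starts (unlabeled, fully labeled,
two random). With a single dummy one sweep is exact. The fitted value is
always included in the interval (it corresponds to the neutral-inflow
assumption of the fit). The run passes when every interval half-width is
at most `factor`·Δ (default factor 1.0, i.e. comparable to the
experimental error; inclusive at the boundary). On failure, dummies are
ranked by one-at-a-time interval impact — an automated stand-in for the
by-inspection attribution in the original procedure — and the non-core
reactions feeding the offending dummies become expansion candidates. The
recursive driver re-limits, refits and re-tests after each expansion (5
rounds maximum by default; the reference application needed one).

## ¹³C FVA

Per-element tolerances follow δ_em = Δ_em if Δ_em > ε_em else
1.1·ε_em, with ε_em = |f_fit − f_exp|; worse fits widen intervals
instead of making them infeasible. The 1.1 multiplier is kept as given in
the method's definition and exposed as a configuration knob. Each
reaction's net flux is then minimized/maximized subject to the same
linear constraints plus (f_em − f_exp)² ≤ δ_em² per measured element
(deliberately per element, not as an aggregate objective budget),
warm-started at the fit optimum with one perturbed retry before flagging
a reaction. Intervals are reported in three nested modes — measured
extracellular bounds only, plus core limits, plus labeling — and the
labeling interval is trimmed into the core-limits interval to remove
solver-tolerance overshoot (the mathematics guarantees nesting; the trim
is numerical hygiene). Split-flux (exchange) intervals are available
separately.

A statistical caveat computed directly by the test suite's Monte-Carlo of
the δ rule: for a flux that is *sharply* determined by labeling, a
corridor of max(Δ, 1.1ε) centered on noisy measurements covers the true
value only ~35–50% of the time when the noise scale equals Δ, because the
fit partially absorbs noise (ε < |noise|) on exactly the elements that
bind. Coverage is excellent for fluxes that are pinned by stoichiometry
and measured exchanges (the fit cannot drift, so ε tracks the noise and
δ ≥ |noise| automatically) and for loosely constrained fluxes (wide
intervals). Realistic networks — and the bundled study fixtures — sit in
the regime where exchange fluxes and network slack leave nuisance freedom,
and there measured coverage is high (the acceptance script reports it).

## Knockout prediction

`knockout` zeroes reaction bounds (gene names are matched against stored
gene-rule strings). Methods: FBA maximizing growth or a designated
ATP-yielding reaction (LP); MOMA as the convex QP min ‖v − v_ref‖²
(SLSQP with analytic gradient); ROOM as a MILP minimizing the number of
fluxes outside [v_ref ± 0.03·|v_ref| ± 0.001] (the published ROOM
defaults, configurable), solved by HiGHS with a 60 s limit and the gap
reported. The ¹³C variants are the same programs with the two-scale fit
of the reference strain as v_ref (their exact published formulation was
not available to this implementation; the plain MOMA/ROOM objectives with
the ¹³C reference are used and documented as an interpretation). In full
prediction mode no target-experiment data are used: the substrate uptake
bound is carried over from the reference condition and growth is left
free. Predicted labeling is simulated with zero exchange on reversible
core reactions (LP/QP predictions carry no exchange information) and
scored with the same OF against the target dataset.

## Synthetic study conditions

All study data are generated, never shipped. Defaults, chosen once:
measurement error Δ = 0.01 per MDV element with Gaussian N(0, Δ²) noise
(clipped to [0,1], renormalized) for fit-time datasets; uniform-in-±Δ
resampling (30 sets in the robustness protocol, 100 in the Monte-Carlo
comparison) for perturbation studies; extracellular-flux and growth
intervals of ±1% around truth; substrate uptake 10 mmol/gdw/h.

- `exemplary_network` — the 20-reaction illustrative network: a core box
  (uptake, A→B→D→C→E chain, NADPH-producing A→F, F→G⇌E, NADPH-consuming
  E→I), peripheral drains to T/U/Y/Z with measured fluxes, a reversible
  transhydrogenase-like NADPH/NADH shuttle, and the growth-essential
  non-core F → D + M. Carbon skeletons (1–4 carbons) are invented for the
  fixture; they are chosen so the F→D backflow measurably perturbs the
  labeling of the measured metabolite C (both routes deliver the same
  atoms of A, so the *fit* is unbiased while ELVA still sees the inflow as
  unknown — the storyline the recursive procedure exists to resolve).
  True fluxes put 60% of uptake through the NADPH branch with growth at
  0.3 (well under the 0.05·glucupt allowance the limiting step grants the
  essential reaction).
- `recovery_scenario(seed)` — a branch network (direct route vs
  cleave-and-recombine through a shared one-carbon pool) whose split,
  drawn from U(0.2, 0.8)·uptake per seed, is identifiable only through
  labeling. The recombination step is reversible (aldolase-like), so its
  exchange flux is a nuisance degree of freedom as in real networks; an
  irreversible variant (`reversible_join=False`) gives a sharply
  determined split for tests that need one.
- `futile_cycle_scenario` — a labeled pass-through chain plus the
  NDPK1/ADK1/ADK2 nucleotide cycle at ±500 bounds, which labeling cannot
  constrain at all.
- `knockout_pair_scenario` — three routes to the biomass precursor with
  distinct carbon fates and yields; the true wild type is deliberately
  not FBA-optimal, and the "true" knockout is constructed as the minimal
  adjustment from the true wild type.

What passing tests on these fixtures do *not* show about real data:
CE-TOFMS artifacts, natural-abundance effects, model-reconstruction
mismatch beyond the single simulated cofactor swap, and genome-scale
problem dimensions (the NLP sizes here are tens of variables; scaling the
SLSQP-based solver to thousands of reactions is untested and would likely
need an exact-gradient NLP engine). The Fig-8-style robustness comparison
against FBA is reproduced only in the form the toy can express — the
fitted carbon fluxes barely move under a cofactor swap and the
transhydrogenase-analogue reverses to compensate — because the toy has no
ATP economy for FBA to be cofactor-sensitive about.

## Numerical conventions and degenerate inputs

Carbon positions are 1-based everywhere. MDV inputs with sums within 5%
of 1 are renormalized (logged), beyond that rejected. Bounds missing from
a model file default to ±500 mmol/gdw/h (cobra's |1000| placeholder is
mapped onto this). Zero-Δ measurements are rejected. Atom maps must
source every product carbon; reactant carbons absent from all products
flow to untracked sinks. A measured EMU with no tracked producer is a
decomposition error naming the EMU; a tracked EMU whose production is
zero at a trial flux point is a simulation error (penalized during
fitting). The exhaustive validation oracle solves the full positional
state space exactly in cumomer coordinates (linear per weight level,
Möbius-inverted to isotopomers); plain fixed-point iteration is avoided
because condensations inside strong recycling loops make the physical
fixed point locally unstable. LP/MILP run on HiGHS via SciPy behind a
minimal solve contract. Alternate LP optima: only objective values and
intervals are consumed downstream, never a particular vertex.
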