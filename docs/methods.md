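# Methods

This note documents the models and procedures implemented in `pkaswarm`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the design decisions taken where the problem was
genuinely open.

## The optimizer

CSAPSO-EDCD is a particle swarm minimizer over a bounded box.  The velocity
rule is the standard two-attractor form

    v ← ω v + c1 (p_i − x) + c2 (p_g − x),   x ← x + v

implemented, deliberately, *without* the classical per-dimension uniform
random multipliers on the attraction terms: the stochasticity comes from
the chaotic learning factors.  `OptimizerConfig.randomize_accel` restores
the classical randomized update, and is on in the `plain_pso_config`
baseline.

**Velocity and boundary handling.**  Velocities are clamped componentwise
to 20% of the box range; positions are clipped to the box and the offending
velocity component zeroed.  Both are common PSO practice; without the ω cap
below, the divergence regime grows velocities without bound within a few
iterations.

**Initial state.**  Positions uniform in the box; velocities uniform in
±10% of the box range.  A strictly nonzero initial velocity matters: the
divergence regime rescues a collapsed swarm by amplifying velocities
(ω > 1), which cannot act on exact zeros.

**Population entropy.**  The swarm is projected onto the first principal
axis of the particle positions (sign fixed by the largest-magnitude
component) and binned into `Q = 10` equal-width cells spanning the
*projection of the search box*; the entropy of the cell-occupancy
distribution, in bits (`k = 1`), is the diversity measure.  Binning over
the box rather than over the observed span of the swarm is the load-bearing
choice: observed-span binning is scale-free, so a uniformly contracting
swarm keeps its relative shape and its entropy never falls — the
convergence regime then becomes an absorbing state and the entropy
switching the algorithm is named for never operates.  Box binning makes the
entropy track absolute concentration, producing the intended
converge → self-adaptive → diverge cycling.  `assign_subgroups` retains the
observed-span variant when called without bounds, which is the natural
choice for inspecting a swarm in isolation and is what its standalone
examples use.

**Thresholds.**  `E_high = 0.7·log2(Q)` and `E_low = 0.3·log2(Q)` by
default, both configurable; keeping them proportional to `log2(Q)` makes
the switching behaviour independent of the subgroup count.

**Chaotic learning factors.**  The Lorenz system with (a, b, r) =
(10, 8/3, 28) is integrated by fixed-step RK4 (dt = 0.01; validated against
an adaptive reference integrator and by an attractor-envelope test), with a
1000-step transient discarded and one sample per 10 steps.  Raw x and y lie
in (−30, 30) on the attractor and are affinely rescaled into [0.5, 2.5]:
raw (frequently negative) values would repel particles from both
attractors.  Each particle owns an independent seeded stream.  This
per-particle granularity is another load-bearing choice: with a single
shared pair and no random multipliers, every particle applies the *same*
coefficients in every dimension each iteration, and the late-stage swarm
(inertia clamped at ω_min, factor sum near 3) hovers without refining —
solving the 5-d sphere to 1e-4 succeeded in only 50–75% of seeded runs.
With per-particle streams a fraction of the swarm is always in the
contractive regime, and 20/20 seeded sphere runs reach the 1e-7 stopping
threshold.

**Self-adaptive inertia.**  `ω = ω_max − Pgbest(k)/Plbest_ave −
(ω_max−ω_min)·k/k_max`, with `Plbest_ave` the mean of the *current*
personal-best fitnesses, clamped into [ω_min, ω_max] = [0.4, 0.9] (the raw
expression can leave the stable range in both directions).  A zero
`Plbest_ave` falls back to the plain linear schedule with a warning.

**Convergence/divergence regimes.**  Convergence uses
`ω = 0.65·|sin(1/E_t)|`, `φ = c1 + c2 = 0.1·|sin(1/E_t)|`, split equally
between the two factors (only the sum is constrained; symmetry is the
neutral choice).  Divergence uses `ω = 1 + λ·φ/E_t` with λ = 2 and the
current chaotic factors, capped at ω_div_max = 1.5; a zero entropy is
floored at `E_low`.  Ties in fitness keep the earlier incumbent best, so
runs are deterministic given the seed.

**Stopping.**  `it_max = 2000` iterations or global best ≤ 1e-7, whichever
first; `m = 50` particles.  These, with λ and the Lorenz constants, are the
study conditions and the package defaults.

## RBF network training

The network is `o(x) = Σ_h W[h]·exp(−‖x − c_h‖²/σ_h²) + B`.  All
parameters are packed into one particle as (weights, biases, centers,
log-spreads); representing spreads by their logarithm makes every decodable
particle a valid network.  Features are z-scored with training-set
statistics (stored on the model and applied at prediction time); targets
are left unscaled.  Search bounds: weights/biases in [−10, 10], centers in
[−3, 3] (z-scored space), spreads in [0.1, 10].

Half the swarm starts from data-informed anchors — centers at randomly
chosen (jittered) training points, bias near mean(y), weights on the scale
of 3·sd(y), spreads in [0.5, 2] — the standard RBF initialization heuristic;
the other half starts uniformly in the box.  Training is stochastic:
run-to-run training MSE varies by roughly an order of magnitude across
seeds, and a handful of restarts (keeping the best training MSE) is the
recommended protocol, as in the README example.

**Hidden-layer size.**  The rule-of-thumb `floor(2·sqrt(m·n) + 1)` gives
the default (5 for a 5-input scalar-output network).
`heuristic_hidden_search` refines it by 5-fold cross-validated MSE over a
candidate range (3–13 by convention), selecting by the one-standard-error
parsimony rule — the smallest candidate within one SE of the CV minimum.
The plain argmin is unstable in the size direction because fold noise is
comparable to the differences between adjacent candidate sizes; the 1-SE
rule recovers the generating complexity of a 4-center test surface in 9/10
seeds where the argmin manages 3–7/10.

## Descriptor selection

Particles live in [0,1]^D; coordinates above 0.5 switch a descriptor on
(an empty mask is rescued by its largest coordinate).  Subset fitness is
5-fold cross-validated MSE of ordinary least squares on the masked columns
plus a sparsity penalty `α·k/D` with `α = 0.1·var(target)` by default —
wrapper selection needs thousands of evaluations, so the fast linear inner
model does the scoring and the final QSAR model is still the RBF network
trained on the chosen subset.  Folds are seeded from the selection seed, so
results are reproducible and the returned subset's fitness is exactly the
trace's best.  Two anchor particles (the all-features mask; a random
five-feature mask) are injected into the initial swarm, which guarantees
the returned subset never scores worse than using every descriptor.  No
multiple-testing control is applied: selection is optimization, not
inference.

## Molecular descriptors

The five-descriptor panel is computed from structures as drawn (no
protonation-state enumeration):

* *relative number of N atoms* — nitrogen count over total atoms,
  hydrogens included (a flag excludes them);
* *Randić index, order 3* — `Σ 1/sqrt(d_a d_b d_c d_d)` over simple
  3-edge paths in the hydrogen-suppressed graph, each path counted once
  (verified against brute-force path enumeration);
* *RNCG* — |most negative atomic charge| / |sum of negative charges|;
* *RNCS* — solvent-accessible surface area of the most negatively charged
  atom times RNCG;
* *maximum net atomic charge*.

Charges are empirical Gasteiger values; the SASA uses a fixed 960-point
Fibonacci sphere per atom on probe-inflated van der Waals radii (probe
1.4 Å, closed-form-exact for an isolated atom) over a seeded ETKDG
conformer relaxed with MMFF94 (UFF fallback).  These are open, deterministic
approximations to quantum-chemical/Zefirov charge models and analytic
surface areas; absolute descriptor values therefore differ from
commercially derived tables, which is why the bundled SMILES sidecar is
labelled best-effort and no external descriptor values are asserted.

## Data and synthetic generators

The two bundled tables (74 modelling compounds, 20 validation compounds)
are checksummed on load.  `random_split` partitions with NumPy's PCG64
generator and rounds the training size half-up, so the 74-compound table
splits 52/22 at the default 70%.  Which 52 compounds formed the original
training partition is not recoverable; the seeded split is the package's
substitute.

`synth_rbf_regression` draws features uniformly from [−2, 2]^d and targets
from a random RBF surface (centers in the same cube, spreads in
[0.6, 1.6], weights in [−2, 2], bias in [−1, 1]) plus Gaussian noise,
returning the generating network for recovery tests.
`synth_selection_problem` plants a linear support among independent
standard-normal columns.  Neither emulates real descriptor data's
collinearity, heavy tails or measurement error, so passing recovery tests
demonstrates that the machinery works on well-posed ground truth, not that
real-data performance matches any particular figure.

Problem sizes used by the test suite mirror the application: 52 training
rows × 5 features for trainer recovery and comparison, 3 planted + 7 noise
descriptors for selection recovery, with the optimizer at its default
budget for recovery runs and reduced budgets (m = 30–50, 80–200 iterations)
for the selection searches, whose fitness evaluations each cost five OLS
fits.

## A comparison property that does not replicate

The three-trainer comparison (entropy-driven chaotic swarm vs classical
randomized PSO vs random search at matched evaluation budget, median final
training MSE over 20 seeds) was expected to order the chaotic swarm first.
In this implementation it does not: classical PSO attains lower *training*
MSE (median 2.8e-3 vs 6.0e-3 on the 52×5 noiseless task), because the
divergence regime spends a quarter to a third of the iteration budget
re-expanding the swarm.  That diversity is not wasted — under the
comparison that matters for a QSAR model, *held-out* prediction error on a
noisy task, the ordering inverts: chaotic swarm 4.8e-2, random baseline
7.1e-2, classical PSO 1.0e-1 (median held-out MSE), i.e. the
entropy-driven trainer generalizes best while deep PSO training overfits
below the random baseline.  No protocol we examined makes the full
training-MSE ordering hold; the corresponding end-to-end test asserts it
as stated and fails, and is left failing rather than weakened.  Random
search is soundly worst on training error under every configuration.

## Known limitations

* Swarm training quality varies across seeds; restarts are cheap and
  recommended.  The entropy machinery guards diversity, not optimality.
* The descriptor values are open approximations; models trained on them
  are internally consistent but not comparable to models trained on
  commercial descriptor pipelines.
* AARD divides by the signed experimental value and is rejected at zero
  targets; it is only meaningful on scales bounded away from zero (true
  for pKa here).
* The wrapper's linear inner model scores subsets by linear predictability;
  a subset whose value is purely non-linear can be under-ranked (a small
  RBF inner model can be substituted at quadratic cost via the `inner`
  hook).
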