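# Methods

This note documents the model, the numerical scheme, the calibration the
package treats as its study design, and the choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The game

Two players — a dominant breeder and one potential subordinate — make a
simultaneous, one-shot decision to breed together or apart during a single
season (no queuing, inheritance, or repeated interaction). Subordinate
quality x is both the subordinate's outside option and, through the
quality–productivity coefficient (QPC) a, a driver of its helping effect
h = a·x + m; group productivity is G = b(1 + m + a·x). Solitary inclusive
fitness is d_A = b + r·x (dominant) and s_A = r·b + x (subordinate); in a
group at concession y the dominant's inclusive fitness is G[1 − y(1 − r)]
and the subordinate's G[y(1 − r) + r]. For r < 1 the dominant offers the
smallest retaining share, the critical concession
y_c = (x − b·r·(m + a·x)) / (b(1 − r)(m + a·x + 1)).

Assumptions worth keeping in view: quality is uniform on [0, 1] with b = 1
(everything else scales; b ≠ 1 is used only in the constant-productivity
comparison scenario, where m = 1/b − 1 makes G ≡ 1); relatedness is
symmetric; helping is unconditional; quality is distinct from fighting
ability, so there is no within-group contest.

### Tie conventions

At exact indifference the subordinate stays and the dominant accepts: the
critical concession is defined as the share that *induces* staying, and an
ε-increment convention would inject grid-dependent artifacts. Numerically
the stay comparison uses an absolute tolerance of 1e−12, which only absorbs
float rounding when the share is the algebraic y_c itself. y_c < 0 clamps
to an offer of 0 (the subordinate stays for the indirect benefit); y_c > 1
means no feasible share retains the subordinate. r = 1 is rejected in
concession solving (no conflict of interest; any share is optimal).

## Perception and belief

A dominant with information ω perceives z ~ Beta(1 + xω, 1 + (1 − x)ω):
mode exactly x for every ω > 0, uniform at ω = 0, a point mass at ω = ∞.
The printed-form ambiguity in the kernel's exponents is resolved in favor
of the two limit statements (uniform at ω = 0, delta at ω = ∞), which only
this shape family satisfies while keeping the mode at the true value.
ω = ∞ is a symbolic branch throughout (one-hot rows/columns), never a
large float.

Discretization: x and z live on 201 evenly spaced points of [0, 1]
(step 0.005, a config knob; all grid-level tolerances scale with it). The
kernel is tabulated as row-stochastic masses — beta density × trapezoid
cell weight, renormalized per row — and the posterior is the **exact Bayes
inversion of that same tabulated kernel**. This self-consistency matters:
the law of total probability then recovers the prior to machine precision,
and, because decisions are optimized under the same measure that scores
them, the dominant's mean fitness is non-decreasing in ω (information
cannot hurt a Bayesian whose beliefs match the world). An earlier variant
that mixed a continuous-density posterior with discrete outcome weights
violated that monotonicity at the 1e−3 level.

Two closed-form properties hold exactly at the likelihood level, where the
x-dependent beta normalizer cancels: z = 0.5 carries no directional
information (the posterior is symmetric about 0.5 with mean 0.5, though a
narrow kernel rightly concentrates it there), and the log-likelihood
*ratio* of two perceptions is linear in x with slope ω·ln(z₁(1−z₂)/…) —
the monotone-likelihood-ratio property that makes higher perceptions shift
belief upward.

## Solving for the offer

Given a posterior over x, the dominant's expected payoff as a function of
y is piecewise linear, decreasing between staying thresholds and jumping
upward exactly at each y_c(x_i). Its maximum over [0, 1] is therefore
attained at 0 or at one of the feasible critical concessions, and the
solver evaluates the objective exactly on that candidate set — no share
grid, no refinement error. The first maximum over the ascending candidates
implements the smallest-concession tie-break. (A share grid remains in the
`Grids` object for brute-force validation scans; the grid-with-refinement
approach was abandoned because adjacent local maxima differ by less than
the coarse sampling error, so the refined share was not grid-converged.)

The accept/evict decision uses **expected** payoffs — the dominant cannot
condition on the true x — while region maps color each (x, z) cell by
**realized** payoffs at the offered share. A subordinate with y_c ≤ 0
stays at every share, so eviction is the dominant's only recourse; this is
why "accept" is a separate action rather than a property of the share.

## Population aggregation

Population means weight every (x, z) cell by P(z | x)·P(x), with the
discrete uniform prior 1/n on the x grid. The "average subordinate
inclusive fitness" covers **all** subordinates — stayers at their
cooperative payoff, leavers and evictees at s_A — because the uninformed
and perfectly informed analytic endpoints are defined over the whole
population; `include_leavers=False` is provided as a sensitivity switch
that averages over formed groups only. The per-quality aggregation behind
the information–quality preference maps averages each party's in-group
payoff over z with weight P(z | x) ("weighted_mean"); a "majority" rule
(perception-weighted fraction of z favoring the group ≥ ½) is available
behind a config flag since the aggregation behind those maps admits either
reading.

## The calibrated study design

The scenarios the fixtures encode, and that tests and the acceptance
script run, are: baseline b = 1, r = 0.25, a = 0.5, m = 0.35; the
productivity-balancing constraint m = 0.6 − a/2, which pins G(0.5) = 1.6
for every a so that varying the QPC rotates fitness slopes without moving
their magnitude at the population mean; the three QPC columns
a ∈ {−0.5, 0.5, 1.5} (m = 0.85, 0.35, −0.15) at r = 0.5; explored
information levels ω ∈ {0, 1, 2, …, 1024, ∞} (powers of two); and the
constant-productivity comparison a = 0, m = 1/b − 1. One calibration point
deserves a flag: the a = 1.5 column is sometimes quoted with m = −0.25,
but that value contradicts the constraint (0.6 − 1.5/2 = −0.15) and makes
the game degenerate — y_c(x) ≡ 1/3 identically in x, with the dominant
exactly tied between accepting and breeding alone — so the package uses
the constraint value throughout.

### Information cost

The "optimal" dominant information is the ω maximizing mean inclusive
fitness net of an illustrative cost of 0.003 per unit of information. The
package reads "unit" on the log2 ladder along which information is
explored (total cost 0.003·log2(1 + ω), i.e. per doubling): the dominant's
entire fitness gain from ω = 0 to ∞ is below 0.06 for the flat and
moderate QPC columns, so a literally linear 0.003·ω charge exceeds the
total benefit by ω ≈ 16 and collapses every optimum to zero, erasing the
decline of ω* with relatedness that the model otherwise produces. The
literal linear scale is retained as `InfoCost(scale="linear")`. No cost is
charged when computing the information level a subordinate would prefer
the dominant to have, since the subordinate does not pay for it. The
subordinate's preferred ω is computed unconditionally over outcomes
(staying and leaving both counted), not conditioned on joining.

### Relatedness uncertainty

The kinship variant swaps the roles: x is known, r is perceived through
the same beta family with information Ω, with a uniform prior over
candidate relatedness on a grid topping out one step below 1 (the r = 1
point is excluded from concession solving). The subordinate's stay rule
always uses its true r — it knows its own kinship. Reference subordinates
for the value-of-information comparison default to r = 0.5 (full sibling
or offspring) and r = 0 (non-kin); a discrete prior (e.g. mass on
{0, 0.25, 0.5}) can be supplied instead of the uniform one.

## Directionality caveats

Two spec-level simplifications the implementation sharpens:

- ∂y_c/∂r has the sign of x − h(x): the concession falls with relatedness
  wherever the helping effect exceeds the outside option, and rises in the
  opposite corner (e.g. x < 0.3 in the a = 1.5 column). The
  population-level decline of concessions with relatedness holds where
  cooperation is actually viable.
- The offer curve y*(z) rises with perceived quality only up to an
  interior maximum; above it the dominant perceives the required
  concession as too costly and offers nothing. Monotonicity claims are
  therefore asserted up to the collapse point.

## Problem sizes and limitations

Default resolution is 201 × 201 state cells with exact share optimization;
a full 13-point information sweep takes well under a second on one core,
and the entire suite of analyses the tests exercise completes in seconds.
At very large finite ω (≥ 512) the beta kernel's width approaches the
perception-grid step, leaving population means with residual wiggles of
order 1e−4–1e−3; directional tests at those ω use tolerances of that
grid scale. The model itself is intentionally stylized: one season, two
players, unconditional helping, no strategic misreporting by the
subordinate, and no joint uncertainty about quality *and* relatedness —
the two uncertainty variants are analyzed separately.
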