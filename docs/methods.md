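# Methods

`mutualism` analyzes two-species mutualism population models of the form

    dN1/dt = f1(N1, N2; p),    dN2/dt = f2(N1, N2; p),

where `N1, N2 >= 0` are population densities and all quantities are
dimensionless (the models in this literature are abstract rate/density
systems; no unit registry is kept). This note records the model conventions,
the numerical procedures and their tolerances, the design choices that were
genuinely open, and the limitations of what the test suite can show.

## The model registry

Every model is defined once, symbolically (sympy); right-hand sides,
analytic Jacobians and per-capita growth rates `g_i = f_i / N_i` are
compiled from that single definition to vectorized numpy callables. The
registry covers two families:

**Classical pairwise models.** Lotka–Volterra-style linear-benefit models
(Gause–Witt, Whittaker, Vandermeer–Boucher, Addicott), saturating-benefit
models (Wolin–Lawlor, Wright, Graves, Thompson), cost–benefit and
consumer–resource models (Zhang's competition form, Neuhauser–Fargione,
Holland–DeAngelis bidirectional and unidirectional, Fishman–Hadany, Kang,
Martignoni, and the pollination/seed-dispersal pair with emergent Allee
structure). Parameter symbols follow the original citations with subscripts
flattened to ASCII (`alpha12`, `beta21`, `d1min`, ...). Where published
typography is ambiguous, the algebraic structure was reconstructed from the
models' stated mechanisms: for example, the competition-form model is
registered as `R_i N_i (c_i − N_i − a_i (N_j − b_i)^2)`, the unique reading
that produces the parabolic nullclines (mutualistic at low, competitive at
high partner density) this model is known for; the pollination model's
plant growth is built so that its per-capita value at the origin is
`bP·f·g − dP`, matching the obligacy condition attached to it.

**Generic cases.** Nine canonical ways benefits enter a logistic-style
backbone: linear benefit with power-law self-limitation `s_i N_i^theta_i`
(theta = 1, < 1, > 1 as three registered variants); benefit saturating in
partner, recipient, or total density; benefit raising carrying capacity
linearly; and benefit relieving self-limitation linearly or saturatingly.
Besides the nine symmetric pairs, mixed pairs (species 1 of one form,
species 2 of the linear or partner-saturating form) are registered as
`case_<row>_vs_<partner>` — these realize the pairings under which the
qualitative outcomes of each form are tabulated.

**Conventions.**

* *Obligacy.* A species is obligate iff the limit of its per-capita growth
  rate as its own density tends to 0+ with the partner absent is ≤ 0
  (evaluated numerically at densities 1e-3…1e-7 with symbolic ±inf
  handling). The carrying-capacity form (`r N (1 − N/(K+N_j))`) keeps the
  deprecated historical convention: obligate iff `K ≤ 0`. A uniform rule
  was preferred over per-model notes because the latter are not mutually
  consistent across the historical literature.
* *Axis invariance.* Decided symbolically (`f_i` at `N_i = 0`); the
  habitat-provisioning model with immigration `I_i > 0` is the one
  registered family whose axes are not invariant, and its closed-system
  defaults (`I_i = 0`, `rho_i = 1`) restore invariance.
* *Validity domains.* Denominators that can vanish in the closed positive
  quadrant (`K_i + N_j` in the carrying-capacity form; the symbiont terms
  of the host–symbiont models on their axes) are guarded by validity
  predicates; violations raise a domain error rather than being clamped.
* The phenomenological competition-form model is registered with
  sign-unconstrained `b_i` and no ecological range interpretation.

## Phase-plane machinery

**Equilibria.** The origin and axis equilibria come from 1-D root scans of
the per-capita growth along each axis (400-point bracketing + Brent).
Interior candidates are cells of a 64×64 grid (default) in which both rhs
components change sign; each candidate is polished by a Jacobian-based
Powell/Newton hybrid, accepted at relative residual 1e-10, and deduplicated
within 1e-5·L (L = box size). Non-convergent candidates are dropped.
Local types come from the analytic Jacobian's eigenvalues: both real parts
negative → stable (node/spiral by the imaginary part), both positive →
unstable, mixed → saddle; any |Re| below 1e-6·max(1, |λ|) → nonhyperbolic,
which is never silently promoted to stable/unstable — flow evidence decides
(see oscillations).

**Analysis box.** `[0, L]^2` with `L = 10 × max(single-species equilibria,
half-saturation/shelter constants, 1)`. Saturating benefits are bounded by
their `beta` coefficients, so all finite structure falls well inside; the
linear unbounded-growth models are the exception and are handled by the
blow-up event below.

**Nullclines.** Zero-contours of `g_i` on a 401-point grid (contour
extraction via contourpy), clipped to the validity domain. Each polyline is
summarized as (monotonicity × curvature) by sign votes on slopes and slope
differences of a 30-point resample (the resampling keeps contour jitter
from flipping votes; a 95 % vote is required). Closed or back-bending
curves are tagged `lobe` — the signature of saturating costs.

**Integration.** Single trajectories use scipy RK45 (rtol 1e-8, atol
1e-10·L) with an LSODA stiff fallback, with terminal events: *unbounded*
(any density above 1e3·L — the finite-time surrogate for divergence),
*extinct* (density below 1e-6·L while declining; transient dips with
non-negative growth are not extinctions), *converged* (|rhs| below 1e-5·
max(1, L) sustained for 5 time units; an orbit creeping onto an axis or
the origin is recorded as extinction, not coexistence). Basin maps
integrate the whole grid of initial conditions at once with a vectorized
Cash–Karp RK45 whose step size adapts per trajectory; finished
trajectories freeze in place. The convergence floor is set an order above
the batch solver's error floor so that the event can actually fire.

**Basins, cycles, separatrices.** Grids are row-major with inclusive
endpoints and origin at (0, 0). Converged endpoints are matched to known
equilibria within 5e-3·L; endpoints that never settle are probed for
bounded recurrence (Poincaré-style return within 1e-3·L after leaving a
reference point) and registered as cycle attractors when found — this
deliberately reports recurrence evidence instead of deciding analytically
whether a nearly-neutral spiral is a true center or a weak limit cycle,
a question the eigenvalues cannot settle. Separatrices are stable
manifolds of saddles, seeded 1e-6·L along the stable eigenvector and
integrated in reversed time until box exit, a backward-time rest point, or
the horizon; a consistency check asks that ≥ 95 % of probe pairs
straddling the polyline fall into different basins.

## Outcome classification

The classifier synthesizes a label from which basins are present among
*strictly interior* initial conditions (the axes are invariant and answer a
single-species question): an interior attractor (point or cycle) with
neither unbounded nor extinction basins is `SC`; attractor + extinction is
`SC/E threshold`, upgraded to `HD SC & SC/E threshold` when the attractor
exceeds both single-species equilibria componentwise; unbounded +
extinction without an attractor is `UC/E threshold`; unbounded alone `UC`;
extinction alone `E`; attractor + unbounded is `HD UC & UC/SC threshold`;
all three together `HD UC & SC/E threshold`; two or more interior
attractors `multi-attractor`. Classifications with more than 10 % of cells
unresolved at the horizon carry a low-confidence flag.

Coexistence at an interior attractor is *mutualistic* iff both species
exceed their single-species equilibria, or both off-diagonal Jacobian
entries at the attractor are positive; otherwise *parasitic*.

**Threshold taxonomy.** The three collapse mechanisms are defined
operationally (probe initial conditions integrated to their fate), since
the distinction is pictorial in the literature:

* *partner threshold* — with the focal species anchored at 0.8·L, collapse
  of the focal species occurs exactly when the partner starts below a
  critical density;
* *overexploitation* — collapse instead occurs when the partner (consumer)
  starts above a critical density;
* *own-density Allee effect* — with the partner anchored near its own
  zero-growth density, the focal species collapses below a critical density
  of its own.

A collapse counts only if the probing species itself goes extinct, which
keeps a partner-driven collapse from masquerading as the partner's Allee
effect. Probes co-fire by construction (partner thresholds induce Allee
effects in both species); all fired probes are listed in the evidence and
the headline label follows the precedence overexploitation >
own-density-Allee > partner-threshold, surfacing the most
management-relevant cause.

**Critical interaction strength.** Bisection (40 iterations) on a benefit
coefficient for the boundary of "a feasible interior attractor exists".
Near the linear models' boundary the interior equilibrium recedes to
infinity, so the feasibility predicate grows its search box (×10 up to
1e8·L) until the equilibrium set stabilizes; this is what lets the
empirical boundary match the closed form `beta12·beta21 = s1·s2` to 1e-3.

**Oscillations.** After discarding the first half of the horizon, the peak
sequence of `N1` decides: shrinking peaks (or convergence onto a stable
spiral) → damped; stabilized peak amplitude above 1e-4·L → sustained, with
the period estimated from peak spacing; otherwise none. Orbits ending
extinct or unbounded report `none` with the terminal event noted.

## Fixtures

The figure-panel parameter values behind the regimes this package
reproduces were never published, so the committed fixtures are
implementer-derived stand-ins: found once by seeded random search (seed 0),
verified at two basin resolutions, and frozen with their expected labels as
the package's regression surface. Hand-derived closed-form fixtures are
preferred where available (e.g. the golden-ratio equilibrium of the
symmetric partner-saturating pair, the (0.5, 0.5) saddle of the obligate
linear pair). Two findings from assembling the audit registry are worth
recording as results in their own right:

* For the decelerating-self-limitation form (`theta < 1`) paired with a
  *saturating* partner, the unbounded-growth labels sometimes quoted for
  it are unreachable: the partner is self-bounded
  (`N2 ≤ (r2 + beta21)/s2`), and `s·N^theta` with any `theta > 0`
  eventually exceeds a bounded benefit, so no orbit diverges. A property
  test asserts this boundedness.
* For the same form paired with a *linear* partner, the combination
  "interior attractor + unbounded basin + extinction basin" is also
  unattainable: writing `u = sqrt(N1)`, interior crossings solve
  `a·u² − u + c = 0` (`a = beta12·beta21`, `c = r1 + beta12·r2`), and the
  no-invasion condition that creates an asymptotic extinction basin
  (`beta21·r1² < |r2|`) places `r1` strictly between the roots, so the
  lower (stable) crossing has negative partner density. Only the saddle
  survives — the regime is a plain unbounded/extinction threshold.

The corresponding label stays in the classifier vocabulary (its synthesis
rule is well-defined and other model families could in principle reach it),
but carries no fixture.

## What the tests do and do not show

The suite verifies the machinery against closed forms (linear 2×2 solves,
the golden-ratio root, hand Jacobians), against independent numerics
(central-difference Jacobians to 1e-5, resolution and horizon doubling,
separatrix/basin consistency), and against the committed qualitative
regression labels. All of this concerns the registered ODE families under
deterministic, well-mixed, two-species assumptions: no demographic noise,
no stage/age or spatial structure, no third state variable for rewards
dynamics, and no fitting to empirical data. Passing tests therefore show
that the *models'* documented dynamics are reproduced faithfully — not that
any particular natural mutualism follows them. Problem sizes used by the
default analyses (64×64 root scans, 61×61 basins, horizon 400 time units,
100-draw safety sweeps at 31×31) were chosen so the full regression surface
re-runs in a few minutes on one core while staying comfortably inside the
resolution-robustness margins verified by the doubling tests.

## Known limitations

* Basin labels are event-based with finite floors; collapse slivers
  thinner than the grid spacing are invisible at coarse resolutions (the
  resolution-doubling tests bound, but do not eliminate, this).
* The extinction event (density < 1e-6·L while declining) treats a
  transiently rescued species as extinct if the rescue arrives only below
  that floor; this is the intended reading of a demographic threshold, but
  it makes near-marginal invasion parameterizations (where an obligate
  partner's invasion condition is exactly balanced) horizon-dominated and
  flagged low-confidence rather than resolved.
* The center-vs-limit-cycle question for the nearly neutral
  consumer-resource spirals is reported as recurrence evidence, not
  decided.
* Rigorous root certification and global bifurcation continuation are out
  of scope; the completeness of the equilibrium set is supported by
  resolution doubling, not proof.
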