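# Methods

## The question the package answers

Controller motifs are two- or three-species biomolecular reaction networks
with negative feedback that hold a controlled species `A` at a homeostatic
setpoint.  Before fitting such a model to data one wants to know, from the
model structure alone, whether the chosen measurements can determine the
parameters at all.  This package decides that question — *local structural
identifiability* — for the complete library of basic and antithetic
controller motifs, for every combination of one or two concentration
and/or flow measurements.

## Model library

**Basic motifs** (two species, `A` and `E`).  Eight wirings: motifs 1–4 are
inflow controllers (the compensatory flow `j_c` adds `A`), motifs 5–8
outflow controllers (`j_c = k_c·f(E)·A` removes `A`, first order in `A`).
The controller either activates (odd motifs) or inhibits (even motifs)
`j_c`, and `A` signals back through either the synthesis flow `j_s` or the
degradation flow `j_d` of `E`; the two link signs always close a negative
loop.  The wiring table is

| motif | type | actuation E→j_c | sensing A→ |
|---|---|---|---|
| 1 | inflow | activating | j_d, activating |
| 2 | inflow | inhibiting | j_s, activating |
| 3 | inflow | activating | j_s, inhibiting |
| 4 | inflow | inhibiting | j_d, inhibiting |
| 5 | outflow | activating | j_s, activating |
| 6 | outflow | inhibiting | j_d, activating |
| 7 | outflow | activating | j_d, inhibiting |
| 8 | outflow | inhibiting | j_s, inhibiting |

Motifs 6 and 8 deserve a note: this motif family is usually presented
graphically, and the two inhibiting outflow wirings are easy to
transpose.  The assignment above is pinned by two independent numerical
fingerprints of the family's reference tabulations — the per-motif
identifiability scores under first-order controller degradation with two
disturbances (10/11 for motif 6, 11/11 for motif 8) and the per-motif
parameter-count ranges (7–9 for motif 6, 8–9 for motif 8 with one
disturbance) — which discriminate the two assignments and agree with
each other.

Twelve kinetic cases per motif grade model complexity: one disturbance
(the inflow `d_i = k_i` for outflow controllers, the outflow `d_o = k_o·A`
for inflow controllers) versus both; first-order (`f_a(X) = X`) versus
saturable (`X/(K_aX+X)`) activation kinetics; and zero-order (`k_d`),
first-order (`k_d·E`) or Michaelis–Menten (`k_d·E/(K_ME+E)`) degradation
of `E`.  Inhibition is always `K_iX/(K_iX+X)`.  Cases B1–B6 have one
disturbance, B7–B12 two; within each block the three degradation laws ×
two activation laws give the six cases.  Motifs whose links are both
inhibiting (4 and 8) are unchanged by the saturable cases, so for them
B1≡B4 and so on; the library still enumerates all 96 = 8×12 entries.

**Antithetic motifs** (three species, `A`, `E1`, `E2`).  The controller
pair is produced by `j_s1 = k_s1` (constant reference) and
`j_s2 = k_s2·f(A)` (sensing) and removed jointly by the annihilation flow
`j_a = k_a·E1·E2`, which implements integral feedback; `E1` actuates
`j_c`.  Four cases A1–A4: one/both disturbances × first-order/saturable
activation.  The per-index wiring of the eight antithetic motifs is not
fully pinned by published material available to us; we mirror the basic
set (odd motifs activating, even inhibiting) and choose the sensing sign
that closes the negative loop through the annihilation reaction (equal to
the actuation sign for inflow controllers, opposite for outflow).  Under
this reconstruction motif pairs (1,3), (2,4), (5,7), (6,8) coincide
symbolically — the analogue of the B1≡B4 duplications — so per-motif
antithetic asymmetries reported elsewhere are not resolved; family-level
counts and scores are unaffected.

## Identifiability as augmented observability

Parameters are adjoined to the state as constant states,
`x~ = (x, p) ∈ R^N`, `N = n+q`.  Stacking the Jacobians (with respect to
`x~`) of the successive Lie derivatives `L_f^k g` of the output functions
gives the generalized observability–identifiability matrix `OI(x~)`; generic
rank `N` is equivalent to local observability plus structural
identifiability with those outputs.  Derivative orders are added one at a
time and iteration stops when (i) the matrix reaches full rank, (ii) the
rank stalls between consecutive orders (it can then never grow), or
(iii) order `N−1` is reached.

**Flow measurements** enter in either of two equivalent ways.  *Method 1*
promotes the flow to a state: `j = k·h(x)` is replaced everywhere by a new
state `J` with `J' = dj/dt|_{k = J/h(x)}`, and the leading rate constant
`k` leaves the parameter list (so `N` is unchanged; the new state takes the
eliminated constant's column).  *Method 2* simply uses the flow expression
as an output function.  Both give the same verdicts; method 2 is cheaper.

**Per-element diagnosis.**  An element of `x~` is reported identifiable
(parameter) or observable (state) iff deleting its column lowers the
generic rank by one; a rank-neutral column is pinned by no output
derivative.  On full-rank instances every element is flagged.

**Symmetries.**  A supplied infinitesimal generator `v` (one component per
element of `x~`) is verified as a Lie symmetry by `OI(x~)·v = 0` at the
stopping order; a valid generator certifies unidentifiability along its
orbit.  Only verification is implemented, not discovery.

## Rank evaluation: sensitivity jets

Building `OI(x~)` symbolically and taking its rank by elimination is the
textbook route, but the entries swell so quickly that single instances
with 8–10 parameters take minutes to hours.  The package instead evaluates
the matrix *at points* using an identity: writing `y(t)` for the output
along the solution started at `x0`, the k-th row block is

    ∂(y^(k)(0))/∂x~  =  k! · [t^k] ∂y(t)/∂x~ ,

the k-th Taylor coefficient of the output sensitivity.  The sensitivity
`S(t) = ∂x(t)/∂x~` obeys the variational equation `S' = (∂f/∂x)S + [0 |
∂f/∂p]` with `S(0) = [I | 0]`, so truncated power series (jets) of `x(t)`
and `S(t)` can be propagated through the model's *first-order* Jacobians
only — small, fixed expressions — and the full `OI` matrix at a point
drops out exactly, with no high-order symbolic differentiation anywhere.

Two evaluation modes share this engine:

* **symbolic (exact) mode** — jet coefficients are exact rationals
  (`fractions.Fraction`), evaluated at 3 deterministic pseudo-random
  rational points drawn from a ~10⁶-element value set in [1/2, 3/2];
  the rank over Q is exact (fraction Gaussian elimination, no tolerance)
  and, by the Schwartz–Zippel lemma, equals the generic rank except on a
  measure-zero variety — with three independent points a miss is
  astronomically unlikely.  The reported rank is the maximum over points.
* **numeric mode** — float jets at `draws = 10` seeded uniform points from
  [0.5, 1.5] (the randomized-substitution protocol standard for this rank
  test), SVD rank with
  threshold `σ_max · max(rows, N) · 1e−10`, maximum over draws reported
  and per-draw ranks retained.  Singular draws (a zero series constant
  term) are resampled, with a bounded retry count.

The fully symbolic route (`lie_stack` → `build_oi` → `generic_rank` on the
symbolic matrix) is retained; the test suite uses it as an independent
oracle against the jet engine on small instances.  `auto` mode selects
exact arithmetic up to `N ≤ 8` and numeric above — both are always
available explicitly, and on every instance where both were run they agree.

Generic points only: verdicts valid on a measure-zero set of special
initial conditions (e.g. absorbing states) are not detected, and
identifiability is local.

## Sweeps, classification, scores

One *instance* is a model structure plus a measurement combination
(concentrations and flows of the model, singles and pairs): 21/28 combos
for basic models with one/two disturbances, 36/45 for antithetic — 3648
instances in all.  Measurement combinations are classified structurally:

* *always insufficient* — any single measurement; any pair related to the
  same species; (antithetic) any pair related only to controller species;
* *always sufficient* — both concentrations (basic); concentration of `A`,
  or the outflow disturbance `d_o`, with any controller-related
  measurement (antithetic);
* *case and motif dependent* — the rest (11 combos per two-disturbance
  basic model, 8 per one-disturbance model).

An empirical classifier over sweep records (grouping by species-relation
pattern, never by literal flow names) is provided separately and is checked
against the structural rules in the tests.

The identifiability score of a record set is the fraction of full-rank
instances.  Score tables are aggregated by case and by motif over the
dependent combos only (the two fixed-outcome classes carry no case/motif
information), and the basic-versus-antithetic comparison over the
kinetically comparable cases (B2/B5/B8/B11 vs A1–A4) drops only the
always-insufficient combos.  Scores are reported raw and rounded to two
decimals, with the denominator recorded; per-motif means are recorded
alongside pooled fractions (they coincide when denominators match).

## Numerical and design choices

* Canonical ordering: states in species order, then rate constants in
  flow-table order (`k_i, k_o, k_c, k_s, k_d, k_s1, k_s2, k_a`), then
  binding constants alphabetically.  Reports and CSV output are
  byte-stable given a seed.
* Per-instance seeds are derived from the sweep seed and the instance key
  (CRC32, below 2³¹), so any single row can be reproduced in isolation.
* Numeric tolerance: relative SVD threshold `1e−10`; drawing range
  [0.5, 1.5].  Exact mode has no tolerance.
* Augmenting two flows (method 1) proceeds sequentially in combo order;
  the flows never share a leading rate constant, so the result is
  order-independent.
* Degenerate inputs: invalid selections raise typed errors; a zero partial
  derivative in the loop-gain check raises a degenerate-point error;
  per-instance failures in sweeps are recorded (`stop_condition =
  "error:…"`) and do not abort the batch.

## Problem sizes used in the shipped checks

The acceptance script evaluates the three worked single-instance ranks in
exact mode (N = 8) and the 336-instance comparable-case score in numeric
mode (10 draws); the test suite additionally sweeps case B1 (64
instances), case B8 (88), the motif-3/4 two-disturbance block (132) and
the full 3648-instance corpus in exact mode.  On a single CPU the full
corpus completes in roughly ten minutes with the jet engine.

## What the library models do and do not capture

The models are the idealized deterministic rate equations of the motif
family: mass-action/Michaelis–Menten kinetics, constant volume, no inputs
(autonomous), no measurement noise, no sampling design.  Structural
identifiability results therefore say what is *possible in principle* from
perfect continuous records of the chosen outputs; they say nothing about
practical identifiability from finite noisy data, about stochastic
(master-equation) treatments of the antithetic pair, or about
initial-condition-dependent degeneracies.  Autocatalytic motifs, Hill
cooperativity, SBML exchange and time-course simulation (beyond the test
oracle that validates flow-state augmentation) are out of scope.
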