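# motif-ident

Structural identifiability analysis of biomolecular controller motifs,
with flow measurements as first-class model outputs.

## The problem

Controller motifs are small reaction networks with negative feedback that
hold a controlled species `A` at a homeostatic setpoint — the standard
building blocks of models of cellular regulation (ion homeostasis,
nutrient uptake, synthetic integral controllers).  Before fitting such a
model to data, one should ask whether the parameters are *structurally
identifiable*: can they be determined, even in principle, from the chosen
measurements?  The answer depends only on the model structure and the
output set, and it decides which experiments are worth doing.

`motif-ident` answers that question for the complete library of

* **basic controller motifs** — 8 wirings of a controlled species `A` and
  one controller `E` (inflow/outflow compensation × activating/inhibiting
  links), × 12 kinetic cases `B1–B12` (one or two disturbances,
  first-order or saturable activation, zero-order / first-order /
  Michaelis–Menten degradation of `E`): 96 models;
* **antithetic controller motifs** — 8 wirings of `A` with a controller
  pair `E1`, `E2` annihilating through `j_a = k_a·E1·E2` (integral
  feedback), × 4 cases `A1–A4`: 32 models;

and for every combination of one or two measurements drawn from the
species concentrations and the named flows (`d_i`, `d_o`, `j_c`, `j_s`,
`j_d`, `j_s1`, `j_s2`, `j_a`) — 3648 instances in all.  Flow measurements
enter either by promoting the flow to a state (method 1) or by placing
the flow expression directly in the output (method 2); both give the same
verdicts.

## The test

Parameters are treated as constant states, `x~ = (x, p)`, and successive
Lie derivatives of the outputs `y = g(x, p)` along the dynamics
`x' = f(x, p)` are stacked into the generalized
observability–identifiability matrix

    OI(x~) = [ ∂g/∂x~ ; ∂(L_f g)/∂x~ ; ∂(L_f² g)/∂x~ ; … ]

Generic rank `N = n + q` ⇔ the model is locally observable and
structurally identifiable with those outputs.  Orders are added until the
rank saturates (full rank, a rank plateau, or order `N−1`).  Ranks are
evaluated by propagating Taylor jets of the state and its sensitivity
`∂x/∂x~` through the model's first-order Jacobians — exactly, in rational
arithmetic ("symbolic" mode), or in floats at 10 seeded random draws from
[0.5, 1.5] ("numeric" mode).  See `docs/methods.md` for the details and
for the design decisions.

## Worked example

Which of the six parameters of basic motif 3 under case B8
(`dA/dt = k_i − k_o·A + k_c·E`, `dE/dt = k_s·K_iA/(K_iA+A) − k_d·E`)
can be recovered by measuring the controller concentration `E` together
with the inflow disturbance `d_i`?

    $ motif-ident analyze --family basic --motif 3 --case B8 --measurements E,di --mode symbolic
    basic-m3-B8  measurements [E,di]  method 2
    x~ = (A, E, k_i, k_o, k_c, k_s, k_d, K_iA)
    rank OI(x~) = 7 of N = 8  ->  unidentifiable
    stopped after 6 Lie derivative(s) (rank_plateau, symbolic mode)
    identifiable parameters:   [k_i, k_o, k_d]
    unidentifiable parameters: [k_c, k_s, K_iA]
    observable states:         [E]
    unobservable states:       [A]

The rank falls one short of `N = 8`: the pair pins the two disturbance
constants and the degradation constant, but the actuation and sensing
parameters (`k_c`, `k_s`, `K_iA`) stay entangled and `A` itself cannot be
reconstructed.  Measuring both concentrations instead is sufficient:

    $ motif-ident analyze --family basic --motif 3 --case B8 --measurements A,E --mode symbolic --no-elements
    basic-m3-B8  measurements [A,E]  method 2
    x~ = (A, E, k_i, k_o, k_c, k_s, k_d, K_iA)
    rank OI(x~) = 8 of N = 8  ->  identifiable and observable
    stopped after 3 Lie derivative(s) (full_rank, symbolic mode)

Batch runs stream one record per instance to CSV and aggregate
identifiability scores (the fraction of full-rank instances) by case,
motif and controller type:

    $ motif-ident sweep --families basic --cases B8 --dependent-only \
        --mode numeric --seed 1 --out b8.csv --json-out b8.json --no-progress
    88 instances -> b8.csv
    aggregates -> b8.json

Unidentifiability can be certified by a Lie symmetry: the translational
generator `E → E − ε, k_i → k_i + ε·k_c` (a JSON file
`{"E": "-1", "k_i": "k_c"}`) lies in the OI nullspace of motif 3 case B7
with outputs `A, j_s`, and is broken by the first-order controller
degradation of case B8:

    $ motif-ident check-symmetry --family basic --motif 3 --case B7 \
        --measurements A,js --generator generator.json
    basic-m3-B7 [A,j_s]: generator IS a symmetry (model unidentifiable along it)

The same functionality is available as a library
(`motif_ident.build_model`, `build_output_model`, `assess`,
`element_identifiability`, `check_symmetry`, `run_sweep`, …), and
user-defined rational ODE models can be supplied in a plain-text grammar
(`motif_ident.model_from_text`).

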