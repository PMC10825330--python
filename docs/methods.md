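# Methods

This note records the models implemented in `uaextract`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not establish.

## Experiment design

The design is a four-factor central composite *circumscribed* design:
2⁴ = 16 factorial corners at coded ±1, 8 axial points at ±α, and 6 center
replicates — 30 runs. α defaults to the rotatable value 2^(k/4) = 2 for
k = 4 and is configurable.

The source study tabulates only each factor's minimum/average/maximum and
never states whether those extremes are the ±1 factorial levels or the ±α
axial extremes. We default to **table-levels-are-axial** (extremes at ±α,
factorial cube strictly inside), because the measured responses never
exceed the tabulated factor ranges — consistent with no experiment having
been run outside them. The alternative (`table-levels-are-factorial`,
axial points extrapolating beyond the table) is available through the
`axial_convention` argument. The solvent ratio is stored canonically as ml
solvent per g solid (15–35), even though the source writes it both as
"1:15–1:35 g/ml" and in ml/g.

Run ordering is deterministic (factorial in binary order, axial per factor
minus-then-plus, then centers); randomised run order is out of scope.

## Surrogate network

Architecture: one hidden layer, log-sigmoid activation on hidden **and**
output units. The published weight table contains exactly
112 = 4·12 + 12 + 4·12 + 4 values, which pins the architecture at 4-12-4
with biases — even though the accompanying text and figure claim three
input neurons. Four process factors exist; we implement four inputs and
note the source's internal contradiction here rather than guessing it
away. The flat 112-value table is packaged, partitioned under a documented
layout assumption (input-to-hidden weights row-major, hidden biases,
hidden-to-output weights row-major, output biases); because that layout is
an assumption, the table is used for structural tests only, never as a
numeric oracle.

Because the output units are sigmoidal, targets are affinely mapped to
[0.05, 0.95]; the margin keeps extreme targets out of the saturated tails.
Training minimises scaled-space SSE with Levenberg–Marquardt: exact
analytic Jacobian, step (JᵀJ + μI)⁻¹Jᵀr, μ ×10 on rejection and ×0.1 on
acceptance (start 10⁻³, ceiling 10¹⁰). Steps are accepted only if they
lower the training SSE, making the accepted-cycle SSE non-increasing by
construction. Data are split 70/15/15 (train/validation/test) by a seeded
shuffle; the cycle ceiling defaults to 5000. Hidden-layer size can be
selected over 3–15 units by lowest final validation MSE, ties to the
smaller network.

**Generalization caveat.** A 112-parameter network interpolates the ~21
training rows of a 30-run design. Training R² ≈ 1 therefore certifies
optimizer correctness, not predictive power; with 2 % response noise the
4–5-point test split typically shows R² ≈ 0.8–0.9. This mirrors the
experimental situation (30 runs cannot validate 112 parameters) and is why
the end-to-end test judges the surrogate by the *optimization* it enables
(see below), not by held-out R².

Variable importance defaults to the signed **connection-weights** method,
RI(i,o) = Σ_h u[h,i]·w[o,h], because the published influence values are
signed; Garson's nonnegative per-output-normalised variant is provided as
an alternative. The published influence *magnitudes* use an unstated
normalisation and are not reproduced; only signs/rankings are compared,
qualitatively.

## Genetic algorithm

The published fitness expression mixes "max" and "min" across responses,
but the accompanying text states all four responses were maximised; the
text wins, with per-response directions configurable. The aggregation of
four objectives into one scalar is unstated in the source; we use the sum
of min–max-normalised responses (range [0, 4], consistent with the
reported best fitness 3.087), normalised against the training design's
observed response ranges.

GA hyperparameters are unstated in the source; defaults are population 50,
200 generations, tournament size 3, BLX-0.5 crossover with probability
0.8, Gaussian mutation with probability 0.1 and σ = 5 % of each factor
range, elitism 2, boundary clipping. "The network output fed as the
initial population" is read as seeding the initial population with the
design points. The exact published optimum (230.176 W, …, fitness 3.087)
depends on the authors' stochastically trained network and is explicitly
not a reproduction target; what is tested is that the GA reaches within
2 % of a dense-grid oracle on a known truth surface.

## Kinetics

Pseudo-second-order model, fitted per temperature. The nonlinear fit
(scipy `curve_fit`) is initialised from the exact linearisation
t/C = 1/(kCs²) + t/Cs, which is also exposed as `method="linearized"` and
serves as an independent closed-form oracle: on noiseless data the two
agree to 10⁻⁹, and the nonlinear SSE is never worse. Whether the source
fitted the nonlinear or linearised form is unstated; both are provided.
Least squares is unweighted (no weights are given). Sampling grid for
synthetic time courses: t ∈ {2.5, 5, 10, 15, 20, 25} min, matching a
25-minute extraction window. Rate constants are stored in absolute units
(e.g. 0.00556) and only formatted as k×10⁻² for display.

## Thermodynamics and transport

- Kelvin conversion is **T = °C + 273 exactly** (not 273.15): under this
  convention the published ΔG° tables are collinear with their printed
  ΔH°/ΔS° to < 1 J/mol, which identifies it as the convention used.
- R = 8.314 J/(mol·K), fixed, never configurable.
- Cmax in Ke = Cs/(Cmax − Cs) is the content after exhaustive extraction;
  it is never printed in the source and must be supplied (the synthetic
  truth uses the maximum observed response).
- Energies are joules per mole internally; kJ/mol only at presentation.

The published De/Kt/Bi tables come with no method. We implement declared
assumptions: De from the least-squares slope of ln(1 − C/Cs) vs t under
the first-term Fourier solution (slab default, half-thickness L; sphere
available), and Kt from the initial-rate film model dC/dt|₀ = k·Cs² =
(Kt/L)·Cs, i.e. Kt = k·Cs·L. Published De/Kt magnitudes are therefore not
numeric targets; what *is* asserted is the identity Bi = Kt·L/De and the
table-implied characteristic length L = Bi·De/Kt ≈ 1.52×10⁻⁴ m, which is
constant across all 16 published rows to 0.06 % — strong evidence the
published tables were generated with a single L. Neither the particle
geometry nor L is stated in the source; L is inferred from that
self-consistency.

## Fit statistics and assays

R² = 1 − SSE/SST and RMSE = √(SSE/(n−1)) use standard squared-residual
definitions; the source prints these formulas without the squares/root,
which we treat as transcription artifacts (its own tabulated values are on
the standard scale). The mean absolute relative deviation Rd uses 100/n by
default — a single pair then reproduces the published per-response
deviations at the optimum (e.g. 6.960 %) — with the printed 100/(n−1)
selectable. Assay helpers (Folin-Ciocalteu content c·V/w, DPPH
(1 − As/Ac)·100, β-carotene A·D/(2592·10)) are pure unit conversions; the
flavonoid assay has no closed formula beyond the calibration pattern and
reuses c·V/w with quercetin-equivalent units.

## Synthetic data: what it emulates, what it does not

Truth surfaces are full quadratics in coded factors — the model class a
CCD is built to identify — with linear coefficients signed per the
published influence table, mild negative curvature, and one interaction
each. Coefficients were calibrated once against the published response
ranges (e.g. phenolics 7.723–24.619 mg GAE/g over the design) and frozen.
Response noise is additive Gaussian, homoscedastic per response, sd = 2 %
of each surface's range (the source reports only triplicate ±sd with no
structure); kinetic noise is 1 % of the local Cs.

The kinetic/thermodynamic truth is taken from the published tables
themselves: k(T) = k₀·exp(−Ea/RT) with (Ea, k₀) fitted from the published
rate constants, and Cs(T) = Cmax·Ke/(1+Ke) with Ke from the published
ΔH°/ΔS°. This construction reproduces the published Cs values to ~2 %,
i.e. the source's own tables are mutually consistent under it.

A green test on synthetic data establishes that the estimators invert the
stated generative model at the stated noise level — not that real
extraction data satisfy pseudo-second-order kinetics, homoscedastic noise,
or a quadratic response surface. Ultrasound physics (cavitation, power
draw), non-Gaussian error, and figure-level raw data are not emulated.

## Numerical choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  stage is bit-reproducible for a fixed seed, and pipeline artifacts embed
  the seed and a config hash (no timestamps).
- LM stops on cycle ceiling, damping ceiling, or relative SSE improvement
  < 10⁻¹⁴; singular normal equations raise the damping instead of failing.
- Hidden-size ties break to the smaller network; GA solution sets are
  deduplicated at 10⁻⁶ precision, best first.
- Degenerate inputs (zero factor range, Cs ≥ Cmax, non-positive rate
  constants, all-zero concentrations) raise `ValueError` with specific
  messages; questionable-but-legal situations (non-monotone fitted k(T),
  fitted Cs below 80 % of the observed maximum, surrogate extrapolation
  beyond 3× the normalisation range) emit `RuntimeWarning`s.

## Known limitations

- The surrogate cannot be validated out-of-sample from a 30-run design
  (see the generalization caveat above).
- Transport estimators are stated assumptions, not reproductions of the
  source's (unstated) method.
- The exact published trained network, optimum point, fitness value, and
  influence magnitudes are stochastic-training artifacts and are not
  reproduction targets.
- Only pseudo-second-order kinetics is implemented; first-order, Peleg,
  and two-site models are out of scope, as are Box–Behnken designs,
  blocking, and multi-objective (Pareto) optimization.
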