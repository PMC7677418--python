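# Methods

## Decision model

A participant is a moral-weight vector **w** ∈ R^d (d = 18 in the
autonomous-vehicle mode, 16 in the abstract mode).  An option θ is a
nonnegative integer vector of character counts plus, in av mode, four
binary context slots (intervene, passenger side, legal crossing, illegal
crossing).  Its feature content is λ = Aθ, with A the binary trait
matrix (identity in abstract mode), and its utility u(θ) = wᵀλ.  The
probability of choosing the intervention option θ₁ over the status quo
θ₀ is the logistic function of Δu = u(θ₁) − u(θ₀).

Two decision processes are simulated.  *Stochastic*: Y ~
Bernoulli(σ(Δu)).  *Deterministic*: Y = 1 iff Δu > 0; exact ties
(|Δu| ≤ 1e−12) resolve to the status quo Y = 0.  The ground-truth
predictor applies the identical rule at the true **w**, which is why its
deterministic-process accuracy is exactly 1 by construction — a useful
end-to-end invariant rather than a finding.

## Populations and the skew transform

The Gaussian baseline draws **w** ~ Normal(w^g, Σ^g) via a Cholesky (or,
for singular PSD Σ^g, eigendecomposition) square root; non-PSD input is
an error, never silently repaired.  Skewed variants push each marginal
through

ŵ = ξ + (α/κ)(1 − e^{−κz}),  z = (w − μ)/σ,

with α = |κσ| / sqrt(e^{κ²}(e^{κ²}−1)) and ξ = μ + (α/κ)(e^{κ²/2} − 1).
Since E[e^{−κz}] = e^{κ²/2} and Var(e^{−κz}) = e^{κ²}(e^{κ²}−1) for
standard-normal z, this choice preserves the marginal mean and variance
*exactly in expectation* at every shape κ.  It is a NORTA-style
construction: correlations are induced in the Gaussian stage only, so
cross-covariances survive the transform approximately while marginal
moments survive exactly; we deliberately do not re-correct correlations,
and only marginal moments are asserted in tests.

|κ| < 1e−8 takes the analytic Gaussian limit (identity transform),
avoiding the 0/0 in α/κ; consequently an all-zero shape vector returns
the raw Gaussian sample bit-for-bit.

Five fixture shape vectors per mode (average |κ| ≈ 0.5 … 2.5) ship as
CSV package data.  Note the extreme entries (|κ| up to 4.6) produce
near-degenerate marginals: essentially a constant minus a tiny lognormal
whose variance is carried by astronomically rare draws.  Moments are
still preserved in expectation, but a finite sample's variance along
such a coordinate is typically far from its expectation — which is a
property of the construction, not a bug.

### Numerical notes

* **Moment checks.**  `moment_zscores` divides each deviation by the
  larger of two consistent Monte-Carlo SE estimates: the analytic
  estimator SE (from exact central moments of the shifted-lognormal
  marginal, `marginal_central_moments`) and the batch-means MCSE.
  Either alone misjudges the error scale for heavy-tailed shapes: the
  analytic SE cannot see that one extreme draw moved both the estimate
  and its realized error, while the batch MCSE collapses when a typical
  sample contains no far-tail draw at all.  The conservative combination
  keeps the statistic approximately standard normal across all fixture
  shapes (checked by repeated simulation).
* **Density evaluation.**  For nonzero κ the density has one finite
  support endpoint ξ + α/κ.  At |κ| ≈ 4 the bounded-side mass sits
  within one float ULP of that endpoint, so `gg_pdf(x)` cannot resolve
  it; `gg_pdf_from_bound(s)` evaluates the same density as a function of
  the distance s from the endpoint, cancellation-free.  Quadrature and
  tail work should integrate in s with log-spaced panels; that reaches
  machine-precision normalization for every fixture shape.

## Scenario generator

Each option carries 0–5 characters; with probability 0.75 one shared
count is drawn for both options (avoiding dilemmas dominated by group
size), otherwise counts are independent; the empty-vs-empty draw carries
no decision content and is redrawn.  Characters are uniform over a
20-type vocabulary (man … cat) with a documented binary trait matrix
shipped as editable CSV; one uniformly chosen side is the passenger
group and the pedestrian side's crossing legality is a fair binary draw.
θ₁ always has intervene = 1, θ₀ has 0.  Abstract mode draws counts the
same way and assigns each character to one uniform dimension — a choice
we document rather than inherit, since only the vector length is
externally constrained.  A survey is 13 scenarios: the first 8 are the
fitting split, the last 5 are held out.

## Predictors

* **ML** maximizes the Bernoulli log-likelihood minus a vanishing ridge
  (1e−6·‖w‖²).  With 8 observations in 18 dimensions the data are
  almost always linearly separable, so the unpenalized MLE diverges; the
  ridge keeps the optimum finite and unique without materially moving
  predictions.  L-BFGS with analytic gradients, gradient tolerance 1e−8,
  max 500 iterations, start at 0.
* **HB-MAP** maximizes log-likelihood − ½(w − w^g)ᵀ(Σ^g)⁻¹(w − w^g) —
  both terms concave, unique optimum, started at w^g.  The prior uses
  the *true* group mean and covariance but always the normal form: the
  deliberate mismatch probed by the skewed populations.  Zero records
  return w^g exactly.
* **DL** is a pure-numpy MLP: dense → batch-norm → ReLU blocks (widths
  64/64/32), final dense → sigmoid, binary cross entropy on logits,
  Adam at learning rate 5e−4, batch 128, max 200 epochs.  The learning
  rate multiplies by 0.1 when validation loss plateaus for 10 epochs;
  training stops after 20 epochs without improvement and restores the
  best-validation weights.  All randomness (init, shuffling) flows from
  one seed, so identical seed and data give identical models.  Input
  encoding is [λ₁‖λ₀] (the options' feature vectors — their sufficient
  statistics under the choice model); a raw-θ concatenation is available
  as a config alternative.  A brief per-participant fine-tune
  (few full-batch epochs at 5e−5) exists but is off by default: in our
  runs, as an ablation, it does not significantly move accuracy.
* **GT** thresholds Δu at the true **w** with the shared tie rule.

## Study protocol

Per (mode, process, skew level): sample 3,000 participants (1,000 set
aside as the test group), give everyone a fresh random survey, simulate
decisions.  HB and ML are fit *per test participant* on that person's 8
fitting answers and scored on their 5 held-out answers; DL trains on the
training participants' 8-answer splits (their 5-answer splits serve as
validation) at sizes 25–2,000 and never sees a test participant's
answers; GT needs no fitting.  Accuracy is the matched fraction of the
1,000 × 5 held-out decisions.  One master seed fans out into named
independent streams (population / scenarios / decisions / model init)
via `numpy` SeedSequence spawning, making every table reproducible.

Qualitative comparisons are averaged over 3 seeds; the shipped tests run
a scaled replication (levels × {25, 2000} training sizes, stochastic,
plus the extreme-skew deterministic block) in a few minutes on one CPU.
The acceptance script uses 800 + 200 participants and sizes (25, 500) to
stay under a minute; problem sizes are stated in `scripts/acceptance.py`.

## Group parameters: illustrative defaults

The shipped w^g and Σ^g are **not** estimates from any survey; they are
documented illustrative defaults (mixed-sign means with large positive
weight on Human/Infancy/Young-type features; diagonal-dominant PSD
covariance with a few plausible correlations; the abstract mode uses a
frozen randomly generated pair).  Everything is overridable by
constructing a `PopulationSpec` or editing the CSVs.

This matters for one headline comparison.  Whether the group-trained
network overtakes the normal-prior HB model at high skew depends on how
much the prior mismatch actually hurts HB, which in turn depends on
(w^g, Σ^g).  Under the shipped defaults, HB sits essentially at the
group-information Bayes ceiling even at the most skewed level (measured
by Monte-Carlo majority vote over population draws: ceiling ≈ 0.918,
HB ≈ 0.92, DL(2000) ≈ 0.91 deterministic), so a group-only predictor can
tie but not beat it, and the corresponding test currently fails by about
one accuracy point.  The other trends — HB ≥ ML everywhere, DL growing
with training size and with skew, GT dominating — are robustly
reproduced.

## What the generator does not emulate

Real Moral Machine items are targeted at isolating single factors; ours
are fully random.  Real populations have unknown, possibly multimodal
weight distributions and item-order effects; ours are exactly the
generalized-Gaussian family with i.i.d. participants and scenarios.
Passing tests therefore validate the estimators and the simulation
machinery under the stated model, not claims about human populations.

## Known limitations

* Cross-covariances are only approximately preserved under skew (element-wise
  transform; no copula correction).
* The MLP is CPU-sized; no architecture search, no GPU path.
* No significance testing between models; accuracy differences are read
  against binomial Monte-Carlo slack only.
* The per-participant fits use the 8-question split only; full posterior
  inference over (w_i, w^g, Σ^g) is out of scope.
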