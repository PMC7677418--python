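# moralsim

Simulation study of moral-dilemma decision prediction: who can forecast a
survey respondent's forced choices — a Bayesian model with the right prior
family, one with no prior, a neural network trained on other people's
answers, or an oracle that knows the respondent exactly?

## The problem

In Moral Machine-style surveys, a participant repeatedly chooses which of
two groups of characters an autonomous vehicle should spare.  A standard
cognitive model treats each choice as a noisy comparison of social
utilities: a participant with moral-weight vector **w** assigns option
θ the utility

```
u(θ) = wᵀ A θ
```

where A is a binary trait matrix mapping character counts to abstract
features (Male, Young, Doctor, Human, Legal, ...), and picks the
intervention option θ₁ over the status quo θ₀ with probability

```
P(Y = 1 | θ₀, θ₁) = 1 / (1 + exp(−(u(θ₁) − u(θ₀)))).
```

Across a population, weights are heterogeneous: the baseline model is
**w** ~ Normal(w^g, Σ^g).  This package asks what happens to decision
*prediction* when that normality assumption is wrong.  It builds skewed
populations by pushing each Gaussian marginal through a moment-preserving
generalized-Gaussian transform

```
ŵ = ξ + (α/κ)(1 − e^{−κ(w−μ)/σ}),
α = |κσ| / sqrt(e^{κ²}(e^{κ²}−1)),    ξ = μ + (α/κ)(e^{κ²/2} − 1),
```

so every skew level shares the same mean and marginal variances as the
Gaussian baseline, and then compares four predictors of held-out
decisions:

* **GT** — knows each participant's exact **w** (the accuracy ceiling);
* **HB** — per-participant MAP estimate under the *normal* population
  prior with the true (w^g, Σ^g), even when the population is skewed;
* **ML** — per-participant maximum likelihood, no prior;
* **DL** — a small dense network (batch-norm blocks, sigmoid output,
  binary cross entropy) trained only on *other* participants' answers.

Each simulated participant answers 13 random dilemmas (8 for fitting, 5
held out).  Decisions are simulated either stochastically (Bernoulli at
the logistic probability) or deterministically (always the
maximum-likelihood choice).  Two modes ship with the package: the
18-feature autonomous-vehicle mode with a 20-character vocabulary, and a
16-dimensional abstract mode where A is the identity.

## Worked example

```python
import numpy as np
import moralsim as ms

cfg = ms.ExperimentConfig(n_participants=800, n_test_participants=200,
                          dl_train_sizes=(25, 500), master_seed=1)
df = ms.run_level(cfg, "2.5", process="deterministic",
                  seedseq=np.random.SeedSequence(entropy=1, spawn_key=(1, 1)))
print(df[["model", "dl_train_size", "accuracy"]])
```

prints

```
  model  dl_train_size  accuracy
0    GT            NaN     1.000
1    HB            NaN     0.917
2    ML            NaN     0.697
3    DL           25.0     0.798
4    DL          500.0     0.883
```

Reading: at the most-skewed population level ("2.5") with deterministic
decisions, the oracle is exactly right on all 1,000 held-out decisions
(there is no choice noise to miss); the normal-prior HB model still
predicts 91.7% despite the prior mismatch; maximum likelihood fit on only
8 answers per person manages 69.7%; and the group-trained network climbs
from 79.8% to 88.3% as its training pool grows from 25 to 500
participants.  Skew helps the network: the same configuration at the
Gaussian level ("0") gives DL(500) = 78.3%.

The same study runs from the shell:

```
moralsim reproduce --mode av --process deterministic \
    --levels 0,2.5 --sizes 25,500 --seed 1 --out results/
```

writing a tidy `results.csv`, diagnostic plots, and a `run.log`.

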