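"""Decision predictors: ground truth, HB-MAP, maximum likelihood, deep learning.

Given a participant's observed decisions on a handful of dilemmas, each
predictor forecasts their held-out decisions:

* **GT** (ground truth) uses the participant's exact simulated weight
  vector — the upper bound on achievable accuracy, limited only by the
  stochasticity of the decision process itself.
* **ML** maximizes the per-participant decision log-likelihood (a
  logistic regression on feature differences, with a vanishing ridge so
  the optimum stays finite on separable data).
* **HB-MAP** maximizes the posterior of the participant's weights under
  a multivariate normal population prior with the *true* group mean and
  covariance.  The prior is always normal even when the population is
  skewed — the deliberate model mismatch the study probes.
* **DL** is a feed-forward network (dense -> batch-normalization -> ReLU
  blocks, sigmoid output, binary cross entropy) trained on many training
  participants' decisions; it never sees the test participant's own
  answers (an optional brief individual fine-tune is off by default).

The MLP is a compact, fully seeded numpy implementation (Adam,
learning-rate decay on validation plateau, early stopping with
best-weights restore).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .choice import TIE_TOLERANCE, sigmoid
from .population import PopulationSpec
from .scenarios import CharacterVocabulary, Scenario, features

__all__ = [
    "DecisionData",
    "FitResult",
    "log_likelihood",
    "fit_ml",
    "fit_hb_map",
    "predict_from_w",
    "gt_predict",
    "DLModelSpec",
    "MoralMLP",
    "build_dl",
    "train_dl",
    "fine_tune_dl",
    "encode_scenario",
]


# ---------------------------------------------------------------------------
# Per-participant likelihood models (ML and HB-MAP)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionData:
    """Observed decisions in sufficient-statistic form.

    ``X`` rows are feature differences lambda(theta1) - lambda(theta0);
    ``y`` are the binary decisions.  The choice likelihood depends on the
    data only through these.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if y.size and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("decisions must be binary")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_records(cls, records, vocab: CharacterVocabulary | None = None
                     ) -> "DecisionData":
        """Build from a list of (Scenario, decision) pairs."""
        if not records:
            return cls(np.zeros((0, 1)), np.zeros(0))
        X = np.array([features(s.theta1, vocab) - features(s.theta0, vocab)
                      for s, _ in records])
        y = np.array([y for _, y in records], dtype=float)
        return cls(X, y)

    def __len__(self) -> int:
        return self.y.shape[0]


def _as_data(records, vocab) -> DecisionData:
    if isinstance(records, DecisionData):
        return records
    return DecisionData.from_records(records, vocab)


def log_likelihood(w: np.ndarray, records,
                   vocab: CharacterVocabulary | None = None) -> float:
    """Bernoulli log-likelihood of the decisions under weights ``w``.

    Sum over records of y ln p + (1-y) ln(1-p) with p the logistic choice
    probability; the empty record list gives 0.
    """
    data = _as_data(records, vocab)
    if len(data) == 0:
        return 0.0
    z = data.X @ np.asarray(w, dtype=float)
    return float(np.sum(data.y * z - np.logaddexp(0.0, z)))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a per-participant weight fit."""

    w_hat: np.ndarray
    objective_value: float
    converged: bool
    iterations: int
    message: str = ""


_OPT_DEFAULTS = {"gtol": 1e-8, "maxiter": 500}


def _maximize(fun_grad, x0, optimizer_config=None) -> FitResult:
    opts = dict(_OPT_DEFAULTS)
    if optimizer_config:
        opts.update(optimizer_config)

    def neg(w):
        f, g = fun_grad(w)
        return -f, -g

    res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B",
                            options=opts)
    return FitResult(w_hat=res.x, objective_value=float(-res.fun),
                     converged=bool(res.success), iterations=int(res.nit),
                     message=str(res.message))


def fit_ml(records, penalty: float = 1e-6,
           vocab: CharacterVocabulary | None = None,
           dim: int | None = None,
           optimizer_config: dict | None = None) -> FitResult:
    """Maximum-likelihood weights (ridge-stabilized logistic regression).

    Maximizes ``log_likelihood(w) - penalty * ||w||^2``.  With few
    observations in many dimensions the data are typically linearly
    separable and the raw MLE diverges; the default penalty of 1e-6 keeps
    the optimum finite without materially moving predictions.  Zero
    records return the zero vector.
    """
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    data = _as_data(records, vocab)
    if len(data) == 0:
        d = dim if dim is not None else data.X.shape[1]
        return FitResult(np.zeros(d), 0.0, True, 0, "no data")
    X, y = data.X, data.y

    def fun_grad(w):
        z = X @ w
        ll = np.sum(y * z - np.logaddexp(0.0, z)) - penalty * w @ w
        grad = X.T @ (y - sigmoid(z)) - 2.0 * penalty * w
        return ll, grad

    return _maximize(fun_grad, np.zeros(X.shape[1]), optimizer_config)


def fit_hb_map(records, spec: PopulationSpec,
               vocab: CharacterVocabulary | None = None,
               allow_pseudo_inverse: bool = False,
               optimizer_config: dict | None = None) -> FitResult:
    """Posterior-mode weights under the normal population prior.

    Maximizes ``log_likelihood(w) - (w - w_g)' Sigma_g^{-1} (w - w_g)/2``.
    The prior uses the exact group mean and covariance but is always the
    normal form regardless of the population's true shape.  Both terms
    are concave so the optimum is unique.  Zero records return the prior
    mode ``w_g`` exactly.
    """
    wg = spec.group_mean
    cov = spec.group_cov
    data = _as_data(records, vocab)
    if len(data) == 0:
        return FitResult(wg.copy(), 0.0, True, 0, "prior mode")
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        if not allow_pseudo_inverse:
            raise ValueError(
                "singular group covariance; pass allow_pseudo_inverse=True "
                "to fit in its row space"
            ) from None
        prec = np.linalg.pinv(cov)
    prec = (prec + prec.T) / 2.0
    X, y = data.X, data.y

    def fun_grad(w):
        z = X @ w
        d = w - wg
        lp = np.sum(y * z - np.logaddexp(0.0, z)) - 0.5 * d @ prec @ d
        grad = X.T @ (y - sigmoid(z)) - prec @ d
        return lp, grad

    return _maximize(fun_grad, wg.copy(), optimizer_config)


def predict_from_w(w_hat: np.ndarray, s: Scenario,
                   vocab: CharacterVocabulary | None = None) -> int:
    """Maximum-likelihood decision at the estimated weights (ties -> 0)."""
    du = float(np.asarray(w_hat, dtype=float)
               @ (features(s.theta1, vocab) - features(s.theta0, vocab)))
    return int(du > TIE_TOLERANCE)


def gt_predict(true_w: np.ndarray, s: Scenario,
               vocab: CharacterVocabulary | None = None) -> int:
    """Ground-truth prediction: :func:`predict_from_w` at the exact weights."""
    return predict_from_w(true_w, s, vocab)


# ---------------------------------------------------------------------------
# Deep-learning predictor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DLModelSpec:
    """Hyperparameters of the MLP decision model.

    ``input_encoding`` selects how a scenario becomes a network input:
    ``feature_concat`` concatenates the two options' feature vectors
    [lambda1 || lambda0] (their sufficient statistics under the choice
    model); ``raw_theta_concat`` concatenates the raw option vectors.
    The learning rate is multiplied by ``decay_factor`` whenever the
    validation loss plateaus for ``plateau_patience`` epochs; training
    stops after ``early_stop_patience`` epochs without improvement and
    the best-validation weights are restored.
    """

    input_encoding: str = "feature_concat"
    hidden_widths: tuple[int, ...] = (64, 64, 32)
    learning_rate: float = 5e-4
    decay_factor: float = 0.1
    batch_size: int = 128
    max_epochs: int = 200
    plateau_patience: int = 10
    early_stop_patience: int = 20
    fine_tune_epochs: int = 0
    fine_tune_lr: float = 5e-5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.hidden_widths or any(h < 1 for h in self.hidden_widths):
            raise ValueError("hidden widths must be >= 1")
        if not (0 < self.decay_factor <= 1):
            raise ValueError("decay_factor must be in (0, 1]")


def encode_scenario(s: Scenario, vocab: CharacterVocabulary | None = None,
                    encoding: str = "feature_concat") -> np.ndarray:
    """Flat network input for one scenario (intervention option first)."""
    if encoding == "feature_concat":
        return np.concatenate([features(s.theta1, vocab),
                               features(s.theta0, vocab)])
    if encoding == "raw_theta_concat":
        return np.concatenate([s.theta1.theta, s.theta0.theta]).astype(float)
    raise ValueError(f"unknown input encoding {encoding!r}")


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class MoralMLP:
    """Feed-forward net: [dense -> batchnorm -> ReLU]* -> dense -> sigmoid.

    Pure-numpy, trained with Adam on binary cross entropy (computed on
    logits for stability).  All randomness (init, shuffling) flows from
    the spec seed, so identical seed and data give identical models.
    """

    def __init__(self, spec: DLModelSpec, input_dim: int):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.spec = spec
        self.input_dim = input_dim
        self._rng = np.random.default_rng(spec.seed)
        self.lr = spec.learning_rate
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        widths = [input_dim, *spec.hidden_widths]
        for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
            # He-normal init, appropriate for the ReLU blocks
            self.params[f"W{i}"] = self._rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
            self.params[f"b{i}"] = np.zeros(fan_out)
            self.params[f"g{i}"] = np.ones(fan_out)
            self.params[f"beta{i}"] = np.zeros(fan_out)
            self.running[f"mean{i}"] = np.zeros(fan_out)
            self.running[f"var{i}"] = np.ones(fan_out)
        self.params["W_out"] = self._rng.normal(
            0.0, np.sqrt(1.0 / widths[-1]), (widths[-1], 1))
        self.params["b_out"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    @property
    def n_hidden(self) -> int:
        return len(self.spec.hidden_widths)

    @property
    def n_parameters(self) -> int:
        """Trainable parameter count (dense weights/biases + BN gain/shift)."""
        return sum(v.size for v in self.params.values())

    # -- forward / backward -------------------------------------------------

    def _forward_train(self, X):
        cache = {"a0": X}
        a = X
        for i in range(self.n_hidden):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            m = z.mean(axis=0)
            v = z.var(axis=0)
            invstd = 1.0 / np.sqrt(v + _BN_EPS)
            zhat = (z - m) * invstd
            h = self.params[f"g{i}"] * zhat + self.params[f"beta{i}"]
            a_next = np.maximum(h, 0.0)
            cache[f"zhat{i}"] = zhat
            cache[f"invstd{i}"] = invstd
            cache[f"h{i}"] = h
            cache[f"a{i + 1}"] = a_next
            self.running[f"mean{i}"] = (_BN_MOMENTUM * self.running[f"mean{i}"]
                                        + (1 - _BN_MOMENTUM) * m)
            self.running[f"var{i}"] = (_BN_MOMENTUM * self.running[f"var{i}"]
                                       + (1 - _BN_MOMENTUM) * v)
            a = a_next
        logits = (a @ self.params["W_out"] + self.params["b_out"]).ravel()
        return logits, cache

    def _backward(self, logits, y, cache):
        B = y.shape[0]
        grads = {}
        dlogit = (sigmoid(logits) - y)[:, None] / B
        a_last = cache[f"a{self.n_hidden}"]
        grads["W_out"] = a_last.T @ dlogit
        grads["b_out"] = dlogit.sum(axis=0)
        da = dlogit @ self.params["W_out"].T
        for i in range(self.n_hidden - 1, -1, -1):
            dh = da * (cache[f"h{i}"] > 0)
            zhat = cache[f"zhat{i}"]
            grads[f"g{i}"] = (dh * zhat).sum(axis=0)
            grads[f"beta{i}"] = dh.sum(axis=0)
            dzhat = dh * self.params[f"g{i}"]
            n = dh.shape[0]
            dz = (cache[f"invstd{i}"] / n) * (
                n * dzhat - dzhat.sum(axis=0)
                - zhat * (dzhat * zhat).sum(axis=0))
            grads[f"W{i}"] = cache[f"a{i}"].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            da = dz @ self.params[f"W{i}"].T
        return grads

    def _adam_step(self, grads):
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mh = m / (1 - b1 ** t)
            vh = v / (1 - b2 ** t)
            self.params[k] -= self.lr * mh / (np.sqrt(vh) + eps)

    # -- inference ----------------------------------------------------------

    def logits(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode logits (batch norm uses running statistics)."""
        a = np.atleast_2d(np.asarray(X, dtype=float))
        for i in range(self.n_hidden):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            zhat = ((z - self.running[f"mean{i}"])
                    / np.sqrt(self.running[f"var{i}"] + _BN_EPS))
            a = np.maximum(self.params[f"g{i}"] * zhat
                           + self.params[f"beta{i}"], 0.0)
        return (a @ self.params["W_out"] + self.params["b_out"]).ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Thresholded decisions; probability exactly 0.5 maps to 0."""
        return (self.logits(X) > TIE_TOLERANCE).astype(int)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean binary cross entropy in inference mode."""
        z = self.logits(X)
        y = np.asarray(y, dtype=float)
        return float(np.mean(np.logaddexp(0.0, z) - y * z))

    def copy(self) -> "MoralMLP":
        return _copy.deepcopy(self)

    # -- training -----------------------------------------------------------

    def _run_epochs(self, X, y, n_epochs, on_epoch_end=None):
        n = X.shape[0]
        bs = min(self.spec.batch_size, n)
        for _ in range(n_epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                logits, cache = self._forward_train(X[idx])
                grads = self._backward(logits, y[idx], cache)
                self._adam_step(grads)
            if on_epoch_end is not None and on_epoch_end():
                break

    def fit(self, X_train, y_train, X_val, y_val) -> dict:
        """Train with plateau lr-decay and early stopping; returns history."""
        X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
        y_train = np.asarray(y_train, dtype=float).ravel()
        if X_train.shape[0] == 0:
            raise ValueError("empty training set")
        X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
        y_val = np.asarray(y_val, dtype=float).ravel()
        spec = self.spec
        history = {"train_loss": [], "val_loss": [], "lr": [],
                   "best_epoch": -1}
        state = {"best": np.inf, "best_params": None, "best_running": None,
                 "since_best": 0, "since_decay": 0}

        def on_epoch_end():
            vl = self.loss(X_val, y_val)
            history["train_loss"].append(self.loss(X_train, y_train))
            history["val_loss"].append(vl)
            history["lr"].append(self.lr)
            if vl < state["best"] - 1e-9:
                state["best"] = vl
                state["best_params"] = {k: v.copy()
                                        for k, v in self.params.items()}
                state["best_running"] = {k: v.copy()
                                         for k, v in self.running.items()}
                state["since_best"] = 0
                state["since_decay"] = 0
                history["best_epoch"] = len(history["val_loss"]) - 1
            else:
                state["since_best"] += 1
                state["since_decay"] += 1
            if (spec.decay_factor < 1.0
                    and state["since_decay"] >= spec.plateau_patience):
                self.lr *= spec.decay_factor
                state["since_decay"] = 0
            return state["since_best"] >= spec.early_stop_patience

        self._run_epochs(X_train, y_train, spec.max_epochs, on_epoch_end)
        if state["best_params"] is not None:
            self.params = state["best_params"]
            self.running = state["best_running"]
        return history


def build_dl(spec: DLModelSpec, input_dim: int) -> MoralMLP:
    """Construct an untrained MLP with seeded initialization."""
    return MoralMLP(spec, input_dim)


def train_dl(model: MoralMLP, train: tuple, validation: tuple,
             spec: DLModelSpec | None = None) -> tuple[MoralMLP, dict]:
    """Train ``model`` on (X, y) train/validation arrays; returns history.

    The returned model carries the weights of the best validation epoch.
    """
    X_tr, y_tr = train
    X_va, y_va = validation
    history = model.fit(X_tr, y_tr, X_va, y_va)
    return model, history


def fine_tune_dl(model: MoralMLP, individual: tuple,
                 spec: DLModelSpec | None = None) -> MoralMLP:
    """Briefly fine-tune a trained model on one participant's train split.

    Runs ``spec.fine_tune_epochs`` full-batch epochs at the low
    fine-tune learning rate on a copy; zero epochs (the default — the
    ablation found no significant effect) returns the model unchanged.
    """
    spec = spec or model.spec
    if spec.fine_tune_epochs <= 0:
        return model
    X, y = individual
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    tuned = model.copy()
    tuned.lr = spec.fine_tune_lr
    tuned._run_epochs(X, y, spec.fine_tune_epochs)
    return tuned
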