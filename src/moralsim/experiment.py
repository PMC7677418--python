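"""Full simulation study: populations -> surveys -> decisions -> predictors.

One *level* of the study fixes a mode (av or abstract), a decision
process (stochastic or deterministic) and a skew level.  It samples a
participant population, gives every participant a fresh random survey
(13 dilemmas: 8 train + 5 held-out), simulates their decisions, then
evaluates four predictors on the test participants' held-out decisions:

* GT uses each participant's exact weights (no fitting);
* HB-MAP and ML are fit per test participant on that participant's 8
  training answers only;
* DL is trained on the *training* participants' answers at each
  configured training size and never sees a test participant's answers.

The full study crosses skew levels x processes x modes x seeds and
returns one tidy accuracy table (one row per model / level / size /
seed).  Everything is reproducible from a single master seed, split into
named independent streams.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choice import TIE_TOLERANCE, sigmoid
from .population import (KAPPA_LEVELS, PopulationSpec, default_population_spec,
                         kappa_table, sample_population)
from .predictors import (DecisionData, DLModelSpec, build_dl, encode_scenario,
                         fine_tune_dl, fit_hb_map, fit_ml, train_dl)
from .scenarios import (CharacterVocabulary, ScenarioConfig, Survey,
                        default_vocabulary, generate_survey)

__all__ = [
    "ExperimentConfig",
    "ParticipantRecord",
    "AccuracyRecord",
    "simulate_participants",
    "GroundTruthPredictor",
    "MAPPredictor",
    "MLPredictor",
    "DLPredictor",
    "evaluate_accuracy",
    "run_level",
    "run_full_study",
    "plot_results",
]

logger = logging.getLogger("moralsim")


def setup_logging(level=logging.INFO, logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Study-level configuration (defaults reproduce the full design)."""

    mode: tuple[str, ...] = ("av",)
    process: tuple[str, ...] = ("stochastic",)
    kappa_levels: tuple[str, ...] = KAPPA_LEVELS
    n_participants: int = 3000
    n_test_participants: int = 1000
    n_scenarios: int = 13
    n_train_scenarios: int = 8
    dl_train_sizes: tuple[int, ...] = (25, 50, 200, 500, 1000, 2000)
    master_seed: int = 0
    n_seeds: int = 1
    fine_tune: bool = False
    dl_spec: DLModelSpec = field(default_factory=DLModelSpec)
    population: PopulationSpec | None = None  # base (w_g, Sigma_g) override

    def __post_init__(self):
        for name in ("mode", "process", "kappa_levels", "dl_train_sizes"):
            v = getattr(self, name)
            if isinstance(v, (str, int)):
                v = (v,)
            object.__setattr__(self, name, tuple(v))
        if self.n_test_participants >= self.n_participants:
            raise ValueError("n_test_participants must be < n_participants")
        if self.dl_train_sizes and (
                max(self.dl_train_sizes)
                > self.n_participants - self.n_test_participants):
            raise ValueError("largest DL training size exceeds the number of "
                             "training participants")
        unknown = set(self.kappa_levels) - set(KAPPA_LEVELS)
        if unknown:
            raise ValueError(f"unknown kappa levels {sorted(unknown)}")

    def population_spec(self, mode: str, level: str) -> PopulationSpec:
        if self.population is not None and self.population.mode == mode:
            return dataclasses.replace(
                self.population, kappa=kappa_table(mode, level), label=level)
        return default_population_spec(mode, level)


@dataclass(frozen=True)
class ParticipantRecord:
    """One simulated participant, in array form.

    ``X`` holds the per-scenario feature differences (n_scenarios x dim),
    ``enc`` the per-scenario DL input encodings, ``y`` the simulated
    decisions.  ``true_w`` is hidden from every predictor except GT.
    """

    participant_id: int
    true_w: np.ndarray
    survey: Survey
    X: np.ndarray
    enc: np.ndarray
    y: np.ndarray

    @property
    def train_idx(self) -> np.ndarray:
        return self.survey.train_indices

    @property
    def test_idx(self) -> np.ndarray:
        return self.survey.test_indices


def _option_matrix(survey: Survey, which: int) -> np.ndarray:
    opts = [(s.theta1 if which else s.theta0).theta for s in survey.scenarios]
    return np.asarray(opts, dtype=float)


def simulate_participants(
    spec: PopulationSpec,
    n_participants: int,
    process: str,
    seedseq: np.random.SeedSequence,
    n_scenarios: int = 13,
    n_train: int = 8,
    vocab: CharacterVocabulary | None = None,
    encoding: str = "feature_concat",
) -> list[ParticipantRecord]:
    """Sample a population and simulate every participant's survey answers."""
    pop_ss, scen_ss, dec_ss = seedseq.spawn(3)
    weights = sample_population(spec, n_participants,
                                np.random.default_rng(pop_ss))
    scen_rng = np.random.default_rng(scen_ss)
    dec_rng = np.random.default_rng(dec_ss)
    sc_config = ScenarioConfig(mode=spec.mode) if spec.mode == "abstract" \
        else ScenarioConfig(mode="av",
                            vocabulary=vocab or default_vocabulary())
    if spec.mode == "av":
        transform = sc_config.vocabulary.full_transform.T
    else:
        transform = np.eye(spec.dim)
    records = []
    for pid in range(n_participants):
        survey = generate_survey(scen_rng, sc_config, n_scenarios, n_train)
        t1 = _option_matrix(survey, 1)
        t0 = _option_matrix(survey, 0)
        if encoding == "feature_concat":
            f1, f0 = t1 @ transform, t0 @ transform
            enc = np.hstack([f1, f0])
            X = f1 - f0
        elif encoding == "raw_theta_concat":
            enc = np.hstack([t1, t0])
            X = (t1 - t0) @ transform
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
        du = X @ weights[pid]
        if process == "deterministic":
            y = (du > TIE_TOLERANCE).astype(int)
        elif process == "stochastic":
            y = (dec_rng.random(len(du)) < sigmoid(du)).astype(int)
        else:
            raise ValueError(f"unknown decision process {process!r}")
        records.append(ParticipantRecord(
            participant_id=pid, true_w=weights[pid], survey=survey,
            X=X, enc=enc, y=y))
    return records


# ---------------------------------------------------------------------------
# Predictor adapters
# ---------------------------------------------------------------------------

class GroundTruthPredictor:
    """Maximum-likelihood decision at the participant's exact weights."""

    name = "GT"

    def predict(self, record: ParticipantRecord, idx: np.ndarray) -> np.ndarray:
        return (record.X[idx] @ record.true_w > TIE_TOLERANCE).astype(int)


class _PerParticipantPredictor:
    """Fits one weight vector per participant on their train split."""

    def predict(self, record: ParticipantRecord, idx: np.ndarray) -> np.ndarray:
        data = DecisionData(record.X[record.train_idx],
                            record.y[record.train_idx])
        w_hat = self._fit(data).w_hat
        return (record.X[idx] @ w_hat > TIE_TOLERANCE).astype(int)


class MAPPredictor(_PerParticipantPredictor):
    """Hierarchical-Bayes posterior mode under the normal population prior."""

    name = "HB"

    def __init__(self, spec: PopulationSpec):
        self.spec = spec

    def _fit(self, data):
        return fit_hb_map(data, self.spec)


class MLPredictor(_PerParticipantPredictor):
    """Per-participant maximum likelihood (no population prior)."""

    name = "ML"

    def __init__(self, penalty: float = 1e-6):
        self.penalty = penalty

    def _fit(self, data):
        return fit_ml(data, penalty=self.penalty)


class DLPredictor:
    """Trained MLP over scenario encodings, optional individual fine-tune."""

    name = "DL"

    def __init__(self, model, spec: DLModelSpec | None = None,
                 fine_tune: bool = False):
        self.model = model
        self.spec = spec or model.spec
        self.fine_tune = fine_tune

    def predict(self, record: ParticipantRecord, idx: np.ndarray) -> np.ndarray:
        model = self.model
        if self.fine_tune:
            tr = record.train_idx
            model = fine_tune_dl(model, (record.enc[tr], record.y[tr]),
                                 self.spec)
        return model.predict(record.enc[idx])


@dataclass(frozen=True)
class AccuracyRecord:
    accuracy: float
    n_correct: int
    n_decisions: int


def evaluate_accuracy(predictor, records: list[ParticipantRecord],
                      split: str = "test") -> AccuracyRecord:
    """Fraction of held-out decisions a predictor matches."""
    correct = total = 0
    for rec in records:
        idx = rec.test_idx if split == "test" else rec.train_idx
        if idx.size == 0:
            raise ValueError(f"participant {rec.participant_id} has no "
                             f"{split} decisions")
        pred = np.asarray(predictor.predict(rec, idx))
        correct += int((pred == rec.y[idx]).sum())
        total += int(idx.size)
    return AccuracyRecord(accuracy=correct / total, n_correct=correct,
                          n_decisions=total)


# ---------------------------------------------------------------------------
# Study orchestration
# ---------------------------------------------------------------------------

def _stack_split(records, idx_attr):
    X = np.vstack([r.enc[getattr(r, idx_attr)] for r in records])
    y = np.concatenate([r.y[getattr(r, idx_attr)] for r in records])
    return X, y


def _dl_seed(seedseq: np.random.SeedSequence) -> int:
    return int(seedseq.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def run_level(config: ExperimentConfig, level: str, mode: str | None = None,
              process: str | None = None,
              seedseq: np.random.SeedSequence | None = None,
              seed_id: int = 0) -> pd.DataFrame:
    """Run one (mode, process, skew level) block; returns tidy rows."""
    mode = mode or config.mode[0]
    process = process or config.process[0]
    if seedseq is None:
        seedseq = np.random.SeedSequence(config.master_seed)
    sim_ss, dl_ss = seedseq.spawn(2)
    spec = config.population_spec(mode, level)
    t0 = time.perf_counter()
    records = simulate_participants(
        spec, config.n_participants, process, sim_ss,
        n_scenarios=config.n_scenarios, n_train=config.n_train_scenarios,
        encoding=config.dl_spec.input_encoding)
    n_train_part = config.n_participants - config.n_test_participants
    train_records = records[:n_train_part]
    test_records = records[n_train_part:]
    logger.info("level %s %s/%s: simulated %d participants in %.1fs",
                level, mode, process, len(records), time.perf_counter() - t0)

    rows = []

    def add_row(model, acc: AccuracyRecord, size=None):
        rows.append({
            "mode": mode, "process": process, "kappa_level": level,
            "model": model, "dl_train_size": size,
            "accuracy": acc.accuracy, "n_decisions": acc.n_decisions,
            "seed": seed_id,
        })

    add_row("GT", evaluate_accuracy(GroundTruthPredictor(), test_records))
    add_row("HB", evaluate_accuracy(MAPPredictor(spec), test_records))
    add_row("ML", evaluate_accuracy(MLPredictor(), test_records))

    for size, size_ss in zip(config.dl_train_sizes,
                             dl_ss.spawn(max(len(config.dl_train_sizes), 1))):
        subset = train_records[:size]
        X_tr, y_tr = _stack_split(subset, "train_idx")
        X_va, y_va = _stack_split(subset, "test_idx")
        dl_spec = dataclasses.replace(config.dl_spec, seed=_dl_seed(size_ss))
        model = build_dl(dl_spec, X_tr.shape[1])
        model, history = train_dl(model, (X_tr, y_tr), (X_va, y_va), dl_spec)
        predictor = DLPredictor(model, dl_spec, fine_tune=config.fine_tune)
        add_row("DL", evaluate_accuracy(predictor, test_records), size)
        logger.info("level %s %s/%s: DL size %d best val loss %.4f "
                    "(epoch %d)", level, mode, process, size,
                    min(history["val_loss"]), history["best_epoch"])
    return pd.DataFrame(rows)


def run_full_study(config: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Cross levels x processes x modes x seeds; returns the accuracy table.

    With ``out_dir`` set, writes ``results.csv`` and summary plots there;
    completed level blocks are kept even if a later block fails.
    """
    root = np.random.SeedSequence(config.master_seed)
    frames: list[pd.DataFrame] = []
    failures = []
    for mode in config.mode:
        for process in config.process:
            for level in config.kappa_levels:
                for rep in range(config.n_seeds):
                    # independent, reproducible stream per block
                    ss = np.random.SeedSequence(
                        entropy=config.master_seed,
                        spawn_key=(config.mode.index(mode),
                                   config.process.index(process),
                                   KAPPA_LEVELS.index(level), rep))
                    try:
                        frames.append(run_level(config, level, mode=mode,
                                                process=process, seedseq=ss,
                                                seed_id=rep))
                    except Exception:  # pragma: no cover - defensive path
                        logger.exception("level %s %s/%s seed %d failed",
                                         level, mode, process, rep)
                        failures.append((mode, process, level, rep))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame())
    if failures:
        logger.warning("failed blocks: %s", failures)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        if len(table):
            plot_results(table, out)
    return table


def plot_results(table: pd.DataFrame, out_dir) -> None:
    """Diagnostic plots: accuracy vs DL training size, and vs skew level."""
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    mean = (table.groupby(["mode", "process", "kappa_level", "model",
                           "dl_train_size"], dropna=False)["accuracy"]
            .mean().reset_index())
    for (mode, process), sub in mean.groupby(["mode", "process"]):
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        dl = sub[sub.model == "DL"]
        for level, block in dl.groupby("kappa_level"):
            block = block.sort_values("dl_train_size")
            axes[0].plot(block.dl_train_size, block.accuracy, "o-",
                         label=f"|k|={level}")
        axes[0].set(xlabel="DL training participants", ylabel="accuracy",
                    title=f"DL accuracy ({mode}, {process})", xscale="log")
        axes[0].legend(fontsize=7)
        order = [l for l in KAPPA_LEVELS if l in set(sub.kappa_level)]
        for model, block in sub.groupby("model"):
            if model == "DL":
                block = block[block.dl_train_size == block.dl_train_size.max()]
            block = block.set_index("kappa_level").reindex(order)
            axes[1].plot(order, block.accuracy, "o-", label=model)
        axes[1].set(xlabel="skew level |k|", ylabel="accuracy",
                    title=f"model comparison ({mode}, {process})")
        axes[1].legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"accuracy_{mode}_{process}.png", dpi=120)
        plt.close(fig)
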