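"""Random dilemma scenario generation.

A scenario is a pair of options: theta0 (non-intervention, the vehicle
stays on course) and theta1 (intervention, the vehicle swerves).  In the
autonomous-vehicle (av) mode an option is a count vector over character
types (man, girl, dog, ...) plus four binary context slots: intervene,
passenger side, legal crossing and illegal crossing.  A binary trait
matrix A maps character counts to the 18 abstract features, so an
option's feature content is lambda = A theta.  In the abstract mode theta
is a length-16 nonnegative integer vector and the transform is the
identity.

Each option carries 0-5 characters; with probability 0.75 the two options
share one drawn count so that group-size comparisons do not dominate
every dilemma.  Scenarios where both options are empty carry no decision
content and are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .population import AV_FEATURES, Mode, feature_names

__all__ = [
    "CONTEXT_SLOTS",
    "CharacterVocabulary",
    "OptionVector",
    "Scenario",
    "Survey",
    "ScenarioConfig",
    "default_vocabulary",
    "features",
    "generate_scenario",
    "generate_abstract_scenario",
    "generate_survey",
    "save_surveys_jsonl",
]

#: Binary context slots appended after the character slots (av mode).
CONTEXT_SLOTS: tuple[str, ...] = ("intervene", "passenger", "legal", "illegal")

_CONTEXT_FEATURE = {"intervene": "Intervene", "passenger": "Passenger",
                    "legal": "Legal", "illegal": "Illegal"}


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class CharacterVocabulary:
    """Character types and their binary feature profiles.

    ``trait_matrix`` has one row per av feature and one column per
    character; entry (f, c) = 1 when character c carries feature f.  Every
    character is exactly one of Human / NonHuman.
    """

    characters: tuple[str, ...]
    trait_matrix: np.ndarray

    def __post_init__(self):
        mat = np.asarray(self.trait_matrix)
        object.__setattr__(self, "trait_matrix", mat)
        if mat.shape != (len(AV_FEATURES), len(self.characters)):
            raise ScenarioError(
                f"trait matrix must be {len(AV_FEATURES)}x{len(self.characters)}"
            )
        if not np.isin(mat, (0, 1)).all():
            raise ScenarioError("trait matrix entries must be binary")
        human = mat[AV_FEATURES.index("Human")] + mat[AV_FEATURES.index("NonHuman")]
        if not (human == 1).all():
            raise ScenarioError("each character must be exactly one of "
                                "Human / NonHuman")

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def full_transform(self) -> np.ndarray:
        """18 x (n_characters + 4) matrix mapping a full av theta to features."""
        n = self.n_characters
        full = np.zeros((len(AV_FEATURES), n + len(CONTEXT_SLOTS)))
        full[:, :n] = self.trait_matrix
        for j, slot in enumerate(CONTEXT_SLOTS):
            full[AV_FEATURES.index(_CONTEXT_FEATURE[slot]), n + j] = 1.0
        return full


def default_vocabulary() -> CharacterVocabulary:
    """The shipped 20-character Moral Machine vocabulary (editable CSV)."""
    path = resources.files("moralsim.data").joinpath("vocabulary_av.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, index_col=0)
    if list(df.index) != list(AV_FEATURES):
        raise ScenarioError("vocabulary CSV feature rows out of order")
    return CharacterVocabulary(tuple(df.columns), df.to_numpy(dtype=int))


@dataclass(frozen=True)
class OptionVector:
    """One option: integer character counts plus binary context slots.

    In av mode ``theta`` has ``n_characters + 4`` entries (the last four
    are the context slots, in :data:`CONTEXT_SLOTS` order); in abstract
    mode ``theta`` is the length-16 dimension-count vector itself.
    """

    theta: np.ndarray
    mode: Mode = "av"

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=int))
        if (self.theta < 0).any():
            raise ScenarioError("theta entries must be nonnegative")

    def character_counts(self) -> np.ndarray:
        if self.mode == "av":
            return self.theta[: -len(CONTEXT_SLOTS)]
        return self.theta

    @property
    def count(self) -> int:
        """Total characters in the option."""
        return int(self.character_counts().sum())

    def context(self, slot: str) -> int:
        if self.mode != "av":
            raise ScenarioError("context slots exist only in av mode")
        return int(self.theta[len(self.theta) - len(CONTEXT_SLOTS)
                              + CONTEXT_SLOTS.index(slot)])


@dataclass(frozen=True)
class Scenario:
    """A dilemma: theta0 = stay on course, theta1 = swerve (intervene)."""

    theta0: OptionVector
    theta1: OptionVector
    mode: Mode = "av"
    equal_count_forced: bool = False

    def __post_init__(self):
        if self.mode == "av":
            if self.theta1.context("intervene") != 1 or \
                    self.theta0.context("intervene") != 0:
                raise ScenarioError("av scenario requires intervene(theta1)=1, "
                                    "intervene(theta0)=0")
        if self.theta0.count == 0 and self.theta1.count == 0:
            raise ScenarioError("scenario with both options empty")


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the random scenario generator.

    ``equal_count_prob`` is the chance that one shared character count is
    drawn for both options (0.75 by default); ``max_count`` bounds the
    characters per option.
    """

    mode: Mode = "av"
    equal_count_prob: float = 0.75
    max_count: int = 5
    vocabulary: CharacterVocabulary = field(default_factory=default_vocabulary)

    @property
    def dim(self) -> int:
        return len(feature_names(self.mode))


def features(theta: OptionVector, vocab: CharacterVocabulary | None = None
             ) -> np.ndarray:
    """Per-feature content lambda = A theta (identity in abstract mode)."""
    if theta.mode == "abstract":
        return theta.theta.astype(float)
    if vocab is None:
        raise ScenarioError("av-mode features need a vocabulary")
    mat = vocab.full_transform
    if mat.shape[1] != theta.theta.shape[0]:
        raise ScenarioError(
            f"theta length {theta.theta.shape[0]} does not match vocabulary "
            f"({mat.shape[1]} slots)"
        )
    return mat @ theta.theta


def _draw_counts(rng: np.random.Generator, config: ScenarioConfig
                 ) -> tuple[int, int, bool]:
    """Counts for both options; redraws the empty-vs-empty case."""
    while True:
        forced = rng.random() < config.equal_count_prob
        if forced:
            c0 = c1 = int(rng.integers(0, config.max_count + 1))
        else:
            c0 = int(rng.integers(0, config.max_count + 1))
            c1 = int(rng.integers(0, config.max_count + 1))
        if c0 or c1:
            return c0, c1, forced


def generate_scenario(rng: np.random.Generator,
                      config: ScenarioConfig | None = None) -> Scenario:
    """Draw one random av-mode dilemma.

    Characters are sampled uniformly from the vocabulary; one uniformly
    chosen side is the passenger group, and the other (pedestrian) side's
    crossing legality is a fair binary draw.
    """
    config = config or ScenarioConfig()
    if config.mode != "av":
        return generate_abstract_scenario(rng, config)
    vocab = config.vocabulary
    c0, c1, forced = _draw_counts(rng, config)
    n = vocab.n_characters
    thetas = []
    for c in (c0, c1):
        t = np.zeros(n + len(CONTEXT_SLOTS), dtype=int)
        if c:
            np.add.at(t, rng.integers(0, n, size=c), 1)
        thetas.append(t)
    passenger_side = int(rng.integers(0, 2))
    legal_crossing = int(rng.integers(0, 2))
    off = n + 1  # context block starts at n: intervene, passenger, legal, illegal
    thetas[1][n] = 1
    thetas[passenger_side][off] = 1
    thetas[1 - passenger_side][off + 1 if legal_crossing else off + 2] = 1
    return Scenario(
        theta0=OptionVector(thetas[0], "av"),
        theta1=OptionVector(thetas[1], "av"),
        mode="av", equal_count_forced=forced,
    )


def generate_abstract_scenario(rng: np.random.Generator,
                               config: ScenarioConfig | None = None) -> Scenario:
    """Draw one abstract-mode dilemma.

    Counts are drawn exactly as in av mode; each character contributes +1
    to one uniformly chosen abstract dimension.  There are no context
    slots.
    """
    config = config or ScenarioConfig(mode="abstract")
    dim = config.dim
    c0, c1, forced = _draw_counts(rng, config)
    thetas = []
    for c in (c0, c1):
        t = np.zeros(dim, dtype=int)
        if c:
            np.add.at(t, rng.integers(0, dim, size=c), 1)
        thetas.append(t)
    return Scenario(
        theta0=OptionVector(thetas[0], "abstract"),
        theta1=OptionVector(thetas[1], "abstract"),
        mode="abstract", equal_count_forced=forced,
    )


@dataclass(frozen=True)
class Survey:
    """An ordered scenario list with a train / held-out split."""

    scenarios: tuple[Scenario, ...]
    n_train: int

    @property
    def train_indices(self) -> np.ndarray:
        return np.arange(self.n_train)

    @property
    def test_indices(self) -> np.ndarray:
        return np.arange(self.n_train, len(self.scenarios))


def generate_survey(rng: np.random.Generator,
                    config: ScenarioConfig | None = None,
                    n_scenarios: int = 13,
                    n_train: int = 8) -> Survey:
    """Generate one participant's survey (default 13 scenarios, 8 train + 5
    held-out)."""
    if n_scenarios < 1:
        raise ScenarioError(f"n_scenarios must be >= 1, got {n_scenarios}")
    config = config or ScenarioConfig()
    scen = tuple(generate_scenario(rng, config) for _ in range(n_scenarios))
    return Survey(scenarios=scen, n_train=min(n_train, n_scenarios))


def save_surveys_jsonl(surveys, path, decisions=None, process: str = "") -> None:
    """Persist surveys (and optional decisions) as JSON lines."""
    import json

    with open(path, "w") as fh:
        for pid, survey in enumerate(surveys):
            for sid, s in enumerate(survey.scenarios):
                row = {
                    "participant_id": pid,
                    "scenario_id": sid,
                    "mode": s.mode,
                    "theta0": s.theta0.theta.tolist(),
                    "theta1": s.theta1.theta.tolist(),
                    "split": "train" if sid < survey.n_train else "test",
                }
                if decisions is not None:
                    row["y"] = int(decisions[pid][sid])
                    row["process"] = process
                fh.write(json.dumps(row) + "\n")
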