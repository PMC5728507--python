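"""Final-model construction and fusion.

After the swarm search, every pbest solution (and optionally gbest) is
decoded and retrained from scratch with the long epoch budget on all
training samples, then scored on a held-out validation split for ranking.
The top h candidates by score form the ensemble; classification predictions
are fused by majority vote over the members' argmax labels, regression by
the (optionally score-weighted) mean of the members' outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .data import Dataset
from .encoding import NetworkConfig, SearchSpace, decode_particle
from .fitness import EvalProtocol, derive_seed, score_model, split_train_val, train_config
from .nn import MLPModel, load_model, predict, save_model


@dataclass
class ScoredClassifier:
    """A trained network together with the configuration that produced it
    and its ranking score."""

    model: MLPModel
    config: NetworkConfig
    score: float


@dataclass
class Ensemble:
    """The h highest-scored candidates plus the fusion task."""

    members: list[ScoredClassifier]
    task: Literal["classification", "regression"]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    @property
    def h(self) -> int:
        return len(self.members)


def train_final(
    solutions: Sequence[np.ndarray],
    space: SearchSpace,
    full_training_data: Dataset,
    protocol: EvalProtocol,
    seed: int,
) -> list[ScoredClassifier]:
    """Retrain one candidate per solution with final_epochs on all training
    samples; each is scored on the λ-held-out part of a split of the same
    pool for ranking.  Divergent members keep a -inf score so selection
    never picks them."""
    _, ranking_val = split_train_val(
        full_training_data, protocol.lambda_fraction, protocol.split_seed
    )
    out = []
    for position in solutions:
        config = decode_particle(np.asarray(position, dtype=float), space)
        member_seed = derive_seed(seed, np.asarray(position, dtype=float))
        model, history = train_config(
            config, full_training_data, protocol, protocol.final_epochs, member_seed
        )
        score = float("-inf") if history.diverged else score_model(model, ranking_val)
        out.append(ScoredClassifier(model=model, config=config, score=score))
    return out


def select_top(candidates: Sequence[ScoredClassifier], h: int) -> Ensemble:
    """The h best-scored candidates, ties broken by lower candidate index;
    no retraining happens."""
    if not 1 <= h <= len(candidates):
        raise ValueError(f"h={h} outside [1, {len(candidates)}]")
    scores = np.array([c.score for c in candidates])
    order = np.argsort(-scores, kind="stable")[:h]
    members = [candidates[i] for i in order]
    return Ensemble(members=members, task=candidates[order[0]].model.task)


def vote_predict(ensemble: Ensemble, features: np.ndarray) -> np.ndarray:
    """Majority vote over members' argmax labels.

    Vote ties go to the class with the larger sum of members' class scores,
    then to the lower class index.
    """
    if ensemble.task != "classification":
        raise ValueError("vote_predict requires a classification ensemble")
    raws, votes = [], []
    for member in ensemble.members:
        raw, labels = predict(member.model, features)
        raws.append(raw)
        votes.append(labels)
    votes = np.stack(votes)            # (h, n)
    score_sum = np.sum(raws, axis=0)   # (n, n_classes)
    n, n_classes = score_sum.shape
    counts = np.zeros((n, n_classes), dtype=int)
    for member_votes in votes:
        counts[np.arange(n), member_votes] += 1
    # lexicographic winner: vote count, then summed score; argmax keeps the
    # lowest class index on exact ties
    top = counts.max(axis=1, keepdims=True)
    tied = counts == top
    tie_break = np.where(tied, score_sum, -np.inf)
    return tie_break.argmax(axis=1)


def mean_predict(
    ensemble: Ensemble,
    features: np.ndarray,
    weights: Literal["uniform", "score"] = "uniform",
) -> np.ndarray:
    """Regression fusion: unweighted mean of member outputs by default, or
    softmax-of-score weighted mean."""
    if ensemble.task != "regression":
        raise ValueError("mean_predict requires a regression ensemble")
    outputs = np.stack(
        [predict(member.model, features)[1] for member in ensemble.members]
    )
    if weights == "uniform":
        return outputs.mean(axis=0)
    scores = np.array([member.score for member in ensemble.members])
    w = np.exp(scores - scores.max())
    w /= w.sum()
    return w @ outputs


def save_ensemble(ensemble: Ensemble, directory: str | Path) -> None:
    """Write a manifest (configs, scores, model paths) plus one model
    archive per member, loadable for prediction-only runs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"task": ensemble.task, "members": []}
    for i, member in enumerate(ensemble.members):
        model_file = f"member_{i:03d}.json"
        save_model(member.model, directory / model_file)
        manifest["members"].append(
            {"model": model_file, "score": member.score, "config": vars(member.config)}
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(directory: str | Path) -> Ensemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    members = []
    for entry in manifest["members"]:
        model, _ = load_model(directory / entry["model"])
        members.append(
            ScoredClassifier(
                model=model,
                config=NetworkConfig(**entry["config"]),
                score=entry["score"],
            )
        )
    return Ensemble(members=members, task=manifest["task"])
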