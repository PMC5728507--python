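"""Experiment orchestration: cross-validation, the PSO-vs-random comparison
at equal candidate budget, metrics, and report tables.

`run_comparison` is the top-level experiment.  For every fold it (a) runs
the swarm search on the fold's training data, retrains finals from the
pbest solutions, builds the top-h majority-vote ensemble and the gbest
individual model, and scores everything on the fold's test set; (b) runs
the random baseline arm — the same number of uniformly drawn configurations
trained with the same final epoch budget — through the identical
candidate/ensemble/individual pipeline.  Reports carry per-candidate score
tables with Avg/Std summary rows, fully reproducible from the config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold, StratifiedKFold

from .data import (
    Dataset,
    load_dataset_csv,
    make_classification_data,
    make_qsar_data,
)
from .encoding import SearchSpace, encode_config, random_config
from .ensembles import Ensemble, select_top, train_final, vote_predict, mean_predict
from .fitness import EvalProtocol, batch_evaluate, make_fitness, split_train_val
from .nn import predict as nn_predict
from .pso import PSOSettings, SearchResult, run_pso

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid experiment configuration; message lists the offending keys."""


# ---------------------------------------------------------------------------
# Metrics

def accuracy(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Fraction of exact label matches."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError(
            f"length mismatch: {true_labels.shape} vs {predicted_labels.shape}"
        )
    return float(np.mean(true_labels == predicted_labels))


def mape(
    actual: np.ndarray, predicted: np.ndarray, epsilon: float | None = None
) -> float:
    """Mean absolute percentage error, mean of |actual - predicted|/|actual|.

    Zero actual values are rejected unless `epsilon` supplies a denominator
    floor.
    """
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.shape != predicted.shape:
        raise ValueError(f"length mismatch: {actual.shape} vs {predicted.shape}")
    denom = np.abs(actual)
    if epsilon is None:
        if np.any(denom == 0):
            raise ValueError(
                "zero actual value makes MAPE undefined; pass epsilon to floor the denominator"
            )
    else:
        denom = np.maximum(denom, epsilon)
    return float(np.mean(np.abs(actual - predicted) / denom))


# ---------------------------------------------------------------------------
# Cross-validation

def kfold_split(
    dataset: Dataset, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint, exhaustive, near-equal folds (first n mod k folds get the
    extra record), stratified by class for classification."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > dataset.n_samples:
        raise ValueError(f"k={k} exceeds n={dataset.n_samples}")
    if dataset.task == "classification":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train_idx, test_idx)
        for train_idx, test_idx in splitter.split(dataset.features, dataset.targets)
    ]


# ---------------------------------------------------------------------------
# Experiment report

@dataclass
class ExperimentReport:
    """Per-candidate test scores by arm/fold with Avg/Std summary rows,
    ensemble and individual test scores, and run metadata."""

    candidate_scores: dict[str, np.ndarray]        # arm -> (n_candidates, k) test metric
    validation_scores: dict[str, np.ndarray]       # arm -> (n_candidates, k) search-protocol score
    ensemble_scores: dict[str, np.ndarray]         # arm -> (k,)
    individual_scores: dict[str, np.ndarray]       # arm -> (k,)
    gbest_histories: list[list[float]]             # PSO arm, one per fold
    metric_name: str
    metadata: dict[str, Any] = field(default_factory=dict)

    def candidate_table(self, arm: str) -> pd.DataFrame:
        """Candidate-by-fold table with Avg and Std rows appended (the
        layout of the per-candidate result tables)."""
        scores = self.candidate_scores[arm]
        k = scores.shape[1]
        frame = pd.DataFrame(
            scores,
            index=[str(i + 1) for i in range(scores.shape[0])],
            columns=[f"fold_{j + 1}" for j in range(k)],
        )
        frame.loc["Avg"] = scores.mean(axis=0)
        frame.loc["Std"] = scores.std(axis=0)
        return frame

    def summary(self) -> dict[str, Any]:
        out: dict[str, Any] = {"metric": self.metric_name, "arms": {}}
        for arm, scores in self.candidate_scores.items():
            out["arms"][arm] = {
                "candidate_avg_per_fold": scores.mean(axis=0).tolist(),
                "candidate_std_per_fold": scores.std(axis=0).tolist(),
                "validation_avg_per_fold": self.validation_scores[arm].mean(axis=0).tolist(),
                "ensemble_per_fold": self.ensemble_scores[arm].tolist(),
                "individual_per_fold": self.individual_scores[arm].tolist(),
                "ensemble_mean": float(self.ensemble_scores[arm].mean()),
                "individual_mean": float(self.individual_scores[arm].mean()),
            }
        out["metadata"] = self.metadata
        return out

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for arm in self.candidate_scores:
            self.candidate_table(arm).to_csv(directory / f"candidates_{arm}.csv")
        (directory / "summary.json").write_text(json.dumps(self.summary(), indent=2))
        trace = pd.DataFrame(
            {
                f"fold_{i + 1}": pd.Series(h)
                for i, h in enumerate(self.gbest_histories)
            }
        )
        trace.to_csv(directory / "gbest_history.csv", index_label="t")


# ---------------------------------------------------------------------------
# Config handling

_TOP_KEYS = {"seed", "task", "data", "space", "pso", "protocol", "split", "h"}


def _build(cls, payload: dict, context: str):
    valid = {f.name for f in dc_fields(cls)}
    bad = set(payload) - valid
    if bad:
        raise ConfigError(f"{context}: unknown keys {sorted(bad)}")
    pairs = {
        k: tuple(v) if isinstance(v, list) and k.endswith("bounds") else v
        for k, v in payload.items()
    }
    return cls(**pairs)


def load_config(source: str | Path | dict) -> dict:
    """Load and validate an experiment config from a YAML/JSON file or dict."""
    if isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = dict(source)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    bad = set(cfg) - _TOP_KEYS
    if bad:
        raise ConfigError(f"unknown top-level keys {sorted(bad)}")
    if "data" not in cfg:
        raise ConfigError("missing required key: data")
    return cfg


def build_dataset(data_cfg: dict, seed: int) -> Dataset:
    kind = data_cfg.get("kind")
    params = {k: v for k, v in data_cfg.items() if k != "kind"}
    if kind == "synthetic_classification":
        return make_classification_data(seed=params.pop("seed", seed), **params)
    if kind == "synthetic_qsar":
        return make_qsar_data(seed=params.pop("seed", seed), **params)
    if kind == "csv":
        return load_dataset_csv(
            params["path"],
            task=params.get("task", "classification"),
            target_column=params.get("target_column", "target"),
            feature_scale=params.get("feature_scale", "unit_interval"),
        )
    raise ConfigError(f"data.kind must be synthetic_classification, synthetic_qsar or csv, got {kind!r}")


def _fold_seed(master: int, fold: int, arm: int) -> int:
    digest = hashlib.blake2b(
        f"{master}:{fold}:{arm}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)


# ---------------------------------------------------------------------------
# Arms

def _test_metric(task: str):
    if task == "classification":
        return "accuracy", accuracy
    return "mape", mape


def _score_arm(
    candidates, h: int, task: str, test: Dataset, metric
) -> tuple[np.ndarray, float, Ensemble]:
    """Test-set scores of every candidate plus the top-h ensemble score."""
    per_candidate = []
    for cand in candidates:
        _, out = nn_predict(cand.model, test.features)
        per_candidate.append(metric(test.targets, out))
    ensemble = select_top(candidates, h)
    if task == "classification":
        fused = vote_predict(ensemble, test.features)
    else:
        fused = mean_predict(ensemble, test.features)
    return np.array(per_candidate), metric(test.targets, fused), ensemble


def run_search(
    train_ds: Dataset,
    space: SearchSpace,
    pso_settings: PSOSettings,
    protocol: EvalProtocol,
    seed: int,
) -> SearchResult:
    """λ-split the training data once, then run the swarm over the space."""
    tr, te = split_train_val(train_ds, protocol.lambda_fraction, protocol.split_seed)
    fitness = make_fitness(space, tr, te, protocol, seed)
    settings = PSOSettings(**{**asdict(pso_settings), "seed": seed})
    return run_pso(fitness, space.box(), settings)


def run_comparison(config: str | Path | dict) -> ExperimentReport:
    """Full DNN-PSO vs DNN-NONPSO experiment over k folds (or one holdout
    split); both arms train the same number of candidate networks with the
    same final epoch budget."""
    cfg = load_config(config)
    master_seed = int(cfg.get("seed", 0))
    task = cfg.get("task", "classification")
    dataset = build_dataset(cfg["data"], master_seed)
    if dataset.task != task:
        raise ConfigError(f"task {task!r} does not match data task {dataset.task!r}")

    space = _build(SearchSpace, cfg.get("space", {}), "space")
    pso_settings = _build(PSOSettings, cfg.get("pso", {}), "pso")
    protocol = _build(EvalProtocol, {**cfg.get("protocol", {}), "task": task}, "protocol")
    h = int(cfg.get("h", pso_settings.population_size))

    split_cfg = cfg.get("split", {"mode": "kfold", "k": 5})
    if split_cfg.get("mode", "kfold") == "kfold":
        folds = kfold_split(dataset, int(split_cfg.get("k", 5)), master_seed)
    elif split_cfg["mode"] == "holdout":
        tr, te = split_train_val(
            dataset, float(split_cfg.get("fraction", 0.8)), master_seed
        )
        folds = None
    else:
        raise ConfigError(f"split.mode must be kfold or holdout, got {split_cfg['mode']!r}")

    metric_name, metric = _test_metric(task)
    arms = ("pso", "random")
    cand_scores: dict[str, list[np.ndarray]] = {a: [] for a in arms}
    val_scores: dict[str, list[np.ndarray]] = {a: [] for a in arms}
    ens_scores: dict[str, list[float]] = {a: [] for a in arms}
    ind_scores: dict[str, list[float]] = {a: [] for a in arms}
    histories: list[list[float]] = []
    t0 = time.perf_counter()

    fold_pairs = (
        [(dataset.subset(tr_idx), dataset.subset(te_idx)) for tr_idx, te_idx in folds]
        if folds is not None
        else [(tr, te)]
    )
    for f, (train_ds, test_ds) in enumerate(fold_pairs):
        pso_seed = _fold_seed(master_seed, f, 0)
        rand_seed = _fold_seed(master_seed, f, 1)
        fold_protocol = _build(
            EvalProtocol, {**asdict(protocol), "split_seed": pso_seed}, "protocol"
        )

        # one λ-split per fold, shared by both arms' candidate scoring
        tr, te = split_train_val(
            train_ds, fold_protocol.lambda_fraction, fold_protocol.split_seed
        )

        # --- PSO arm
        fitness = make_fitness(space, tr, te, fold_protocol, pso_seed)
        result = run_pso(
            fitness, space.box(), PSOSettings(**{**asdict(pso_settings), "seed": pso_seed})
        )
        val_scores["pso"].append(np.array(result.pbest_scores))
        histories.append(result.gbest_history)
        logger.info("fold %d: gbest score %.4f", f, result.gbest_score)
        candidates = train_final(
            result.pbest_positions, space, train_ds, fold_protocol, pso_seed
        )
        scores, ens, _ = _score_arm(candidates, h, task, test_ds, metric)
        cand_scores["pso"].append(scores)
        ens_scores["pso"].append(ens)
        individual = train_final(
            [result.gbest_position], space, train_ds, fold_protocol, pso_seed
        )[0]
        _, out = nn_predict(individual.model, test_ds.features)
        ind_scores["pso"].append(metric(test_ds.targets, out))

        # --- random arm, equal candidate count and epochs
        rng = np.random.default_rng(rand_seed)
        positions = [
            encode_config(random_config(space, rng), space)
            for _ in range(pso_settings.population_size)
        ]
        val_scores["random"].append(
            np.array(batch_evaluate(positions, space, tr, te, fold_protocol, pso_seed))
        )
        rand_protocol = _build(
            EvalProtocol, {**asdict(protocol), "split_seed": rand_seed}, "protocol"
        )
        rand_candidates = train_final(positions, space, train_ds, rand_protocol, rand_seed)
        scores, ens, _ = _score_arm(rand_candidates, h, task, test_ds, metric)
        cand_scores["random"].append(scores)
        ens_scores["random"].append(ens)
        best = max(range(len(rand_candidates)), key=lambda i: rand_candidates[i].score)
        _, out = nn_predict(rand_candidates[best].model, test_ds.features)
        ind_scores["random"].append(metric(test_ds.targets, out))

    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return ExperimentReport(
        candidate_scores={a: np.column_stack(cand_scores[a]) for a in arms},
        validation_scores={a: np.column_stack(val_scores[a]) for a in arms},
        ensemble_scores={a: np.array(ens_scores[a]) for a in arms},
        individual_scores={a: np.array(ind_scores[a]) for a in arms},
        gbest_histories=histories,
        metric_name=metric_name,
        metadata={
            "seed": master_seed,
            "config_hash": config_hash,
            "h": h,
            "population_size": pso_settings.population_size,
            "max_iterations": pso_settings.max_iterations,
            "elapsed_seconds": round(time.perf_counter() - t0, 3),
        },
    )
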