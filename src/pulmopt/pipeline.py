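"""End-to-end orchestration and the optimizer benchmark harness.

The diagnostic pipeline chains: cohort load-or-generate -> class-aware
imputation -> encoding/scaling -> stratified 70/30 split -> TDO wrapper
feature selection (fit on training rows only) -> IGWO-trained conv-net
classifier on the selected columns -> held-out macro metrics under both
formula conventions.  The master seed is split into independent
per-stage streams (generation / split / selection / training) so that
changing one stage's settings does not reshuffle the others.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .classifier import IGWOConvNetClassifier
from .datasets import DIAGNOSES, CohortSpec, generate_cohort
from .feature_selection import TDOFeatureSelector
from .metrics import CONVENTIONS, macro_report
from .optim.core import Bounds, benchmark_function
from .optim.gwo import IGWOConfig, gwo_minimize, igwo_minimize
from .optim.tdo import TDOConfig, tdo_minimize
from .preprocessing import impute_missing, prepare_features, read_cohort_csv, stratified_split

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "benchmark_optimizers"]

logger = logging.getLogger("pulmopt.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n": 400,
        "effect_size": 3.0,
        "missing_rate": 0.3,
    },
    "split": {"train_frac": 0.7},
    "selection": {
        "enabled": True,
        "alpha": 0.9,
        "cv_folds": 3,
        "pop_size": 20,
        "iterations": 40,
    },
    "network": {"n_filters": 4, "kernel_size": 3, "hidden_units": 8},
    "training": {
        "weight_bound": 1.0,
        "pop_size": 30,
        "iterations": 300,
        "p_sc": 0.3,
    },
}


def load_config(path: str | Path) -> dict:
    """Read a YAML config file and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    """Overlay a user config onto :data:`DEFAULT_CONFIG`, rejecting
    unknown keys so typos fail loudly."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if key == "cohort" and isinstance(value, dict) and "csv" in value:
            config["cohort"] = dict(value)
            continue
        if key not in config:
            raise ValueError(f"configuration error: unknown key {key!r}")
        if isinstance(config[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration error: {key!r} must be a mapping")
            for sub, sval in value.items():
                if sub not in config[key]:
                    raise ValueError(
                        f"configuration error: unknown key {key}.{sub}"
                    )
                config[key][sub] = sval
        else:
            config[key] = value
    return config


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).generate_state(4) % (2**31)
    return dict(
        zip(("generate", "split", "selection", "training"), (int(c) for c in children))
    )


def _load_or_generate(cohort_cfg: dict, seed: int) -> pd.DataFrame:
    if "csv" in cohort_cfg:
        logger.info("loading cohort from %s", cohort_cfg["csv"])
        return read_cohort_csv(cohort_cfg["csv"])
    spec = CohortSpec(
        n=cohort_cfg.get("n", 400),
        effect_size=cohort_cfg.get("effect_size", 3.0),
        missing_rate=cohort_cfg.get("missing_rate", 0.0),
        seed=seed,
    )
    logger.info("generating cohort: %s", spec)
    return generate_cohort(spec)


def run_pipeline(config: dict | str | Path, out: str | Path | None = None) -> dict:
    """Run the full diagnostic pipeline; returns (and optionally writes)
    the JSON-serializable report."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = merge_config(config)
    if config.get("seed") is None:
        raise ValueError("configuration error: missing key 'seed'")
    seeds = _stage_seeds(int(config["seed"]))

    table = _load_or_generate(config["cohort"], seeds["generate"])
    table = impute_missing(table)
    X, y, feature_names, encoder = prepare_features(table)

    train_idx, test_idx = stratified_split(
        y, train_frac=config["split"]["train_frac"], seed=seeds["split"]
    )
    X_train, y_train = X[train_idx], y[train_idx]
    X_test, y_test = X[test_idx], y[test_idx]
    logger.info("split: %d train / %d test", len(train_idx), len(test_idx))

    sel_cfg = config["selection"]
    if sel_cfg.get("enabled", True):
        selector = TDOFeatureSelector(
            alpha=sel_cfg["alpha"],
            cv_folds=sel_cfg["cv_folds"],
            pop_size=sel_cfg["pop_size"],
            iterations=sel_cfg["iterations"],
            random_state=seeds["selection"],
        ).fit(X_train, y_train)
        support = selector.support_
        logger.info(
            "selected %d/%d features: %s",
            support.sum(),
            support.size,
            [n for n, s in zip(feature_names, support) if s],
        )
    else:
        support = np.ones(X.shape[1], dtype=bool)

    net_cfg = config["network"]
    train_cfg = config["training"]
    # a very sparse mask can undercut the conv kernel; clip it so the
    # network stays valid on the selected columns
    kernel = min(net_cfg["kernel_size"], int(support.sum()))
    model = IGWOConvNetClassifier(
        n_filters=net_cfg["n_filters"],
        kernel_size=kernel,
        hidden_units=net_cfg["hidden_units"],
        weight_bound=train_cfg["weight_bound"],
        pop_size=train_cfg["pop_size"],
        iterations=train_cfg["iterations"],
        p_sc=train_cfg["p_sc"],
        random_state=seeds["training"],
    ).fit(X_train[:, support], y_train)
    y_pred = model.predict(X_test[:, support])

    metrics: dict = {"overall_accuracy": float(np.mean(y_pred == y_test))}
    for convention in CONVENTIONS:
        rep = macro_report(y_test, y_pred, DIAGNOSES, convention)
        metrics[convention] = {
            "macro": rep["macro"].to_dict(),
            "per_class": {c: r.to_dict() for c, r in rep["per_class"].items()},
        }

    report = {
        "config": config,
        "stage_seeds": seeds,
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "feature_names": feature_names,
        "selected_features": [n for n, s in zip(feature_names, support) if s],
        "training_loss": model.training_loss(),
        "metrics": metrics,
    }
    if out is not None:
        Path(out).write_text(json.dumps(report, indent=2, sort_keys=True))
        logger.info("report written to %s", out)
    return report


_ALGORITHMS = {
    "tdo": "tdo",
    "gwo": "gwo",
    "igwo": "igwo",
}


def _run_algorithm(
    name: str, function: str, dim: int, pop: int, iters: int, seed: int
):
    objective = benchmark_function(function)
    bounds = Bounds.cube(-5.0, 5.0, dim)
    budget = pop * (iters + 1)
    if name == "tdo":
        return tdo_minimize(
            objective,
            bounds,
            TDOConfig(pop_size=pop, iterations=iters, seed=seed),
            max_evaluations=budget,
        )
    config = IGWOConfig(pop_size=pop, iterations=iters, seed=seed)
    if name == "gwo":
        return gwo_minimize(objective, bounds, config, max_evaluations=budget)
    if name == "igwo":
        return igwo_minimize(objective, bounds, config, max_evaluations=budget)
    raise KeyError(f"unknown algorithm {name!r}; available: {sorted(_ALGORITHMS)}")


def benchmark_optimizers(
    functions: Sequence[str],
    algorithms: Sequence[str],
    dim: int = 10,
    pop_size: int = 30,
    iterations: int = 200,
    seeds: Iterable[int] = range(20),
) -> pd.DataFrame:
    """Run each algorithm on each benchmark under an equalized evaluation
    budget (``pop_size * (iterations + 1)`` objective calls per run).

    Returns a tidy table (function, algorithm, dim, seed, best_fitness,
    evaluations); medians can be taken per (function, algorithm) group.
    An empty seed list yields an empty table.
    """
    for name in algorithms:
        if name not in _ALGORITHMS:
            raise KeyError(
                f"unknown algorithm {name!r}; available: {sorted(_ALGORITHMS)}"
            )
    rows = []
    for function in functions:
        benchmark_function(function)  # fail fast on unknown names
        for algorithm in algorithms:
            for seed in seeds:
                result = _run_algorithm(
                    algorithm, function, dim, pop_size, iterations, int(seed)
                )
                rows.append(
                    {
                        "function": function,
                        "algorithm": algorithm,
                        "dim": dim,
                        "seed": int(seed),
                        "best_fitness": result.best_fitness,
                        "evaluations": result.n_evaluations,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["function", "algorithm", "dim", "seed", "best_fitness", "evaluations"],
    )
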