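"""End-to-end surrogate-training protocol on synthetic descriptor data.

One run per rule: draw a stratified descriptor table, label it with the
rule's counter, split 80/20, train Random Forest surrogates at the requested
ensemble sizes, and report held-out metrics (micro accuracy/precision/
recall/F1 and micro-average ROC AUC for classifiers; MSE/MAE/R^2 for
regressors). This is the protocol behind the reference-style metrics table
and the ``pepscreen reproduce`` subcommand.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    LabelledDataset,
    SamplerConfig,
    SplitSpec,
    build_dataset_from_descriptor_table,
    sample_descriptor_vectors,
    split_dataset,
)
from .evaluation import classification_metrics, regression_metrics, roc_micro
from .models import ModelSpec, TrainedModel, train_model
from .rules import RuleSet, builtin_ruleset

PARITY_SPLIT = SplitSpec(test_fraction=0.2, seed=42)


def parity_dataset(
    rule: str,
    n_rows: int = 200_000,
    sampler_seed: int = 7,
    ruleset: RuleSet | None = None,
    max_batches: int = 2000,
) -> LabelledDataset:
    """A stratified synthetic descriptor dataset labelled for one rule."""
    rs = ruleset or builtin_ruleset(rule)
    cfg = SamplerConfig(
        n=n_rows, seed=sampler_seed, stratify_ruleset=rs, max_batches=max_batches
    )
    table = sample_descriptor_vectors(cfg)
    return build_dataset_from_descriptor_table(
        table,
        [rs],
        provenance={
            "sampler": {"n": n_rows, "seed": sampler_seed, "stratify_rule": rs.name}
        },
    )


def evaluate_classifier(model: TrainedModel, test: LabelledDataset) -> dict:
    X = pd.DataFrame(test.features, columns=test.feature_names)
    y_true = test.targets[model.spec.rule]
    y_pred = model.estimator.predict(X)
    report = classification_metrics(y_true, y_pred)
    scores = model.estimator.predict_proba(X)
    _, auc = roc_micro(y_true, scores, classes=model.estimator.classes_)
    out = report.as_dict()
    out["auc_micro"] = auc
    return out


def evaluate_regressor(model: TrainedModel, test: LabelledDataset) -> dict:
    X = pd.DataFrame(test.features, columns=test.feature_names)
    y_true = test.targets[model.spec.rule]
    return regression_metrics(y_true, model.estimator.predict(X)).as_dict()


def parity_run(
    rules: tuple[str, ...] = ("ro5", "bro5", "muegge"),
    n_rows: int = 200_000,
    tree_counts: tuple[int, ...] = (10, 20, 30),
    tasks: tuple[str, ...] = ("classifier",),
    sampler_seed: int = 7,
    split: SplitSpec = PARITY_SPLIT,
    model_seed: int = 0,
    muegge_variant: str = "core6",
    ro5_logp_lower: bool = True,
) -> dict:
    """Train and evaluate surrogates for each (rule, task, n_trees) cell.

    Returns a JSON-serializable report with the resolved configuration, its
    hash, and per-cell held-out metrics.
    """
    config = {
        "rules": list(rules),
        "n_rows": n_rows,
        "tree_counts": list(tree_counts),
        "tasks": list(tasks),
        "sampler_seed": sampler_seed,
        "split": {"test_fraction": split.test_fraction, "seed": split.seed},
        "model_seed": model_seed,
        "muegge_variant": muegge_variant,
        "ro5_logp_lower": ro5_logp_lower,
    }
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    results: dict = {"config": config, "config_hash": config_hash, "metrics": {}}
    for rule in rules:
        rs = builtin_ruleset(
            rule,
            variant=muegge_variant if rule == "muegge" else None,
            logp_lower=ro5_logp_lower,
        )
        ds = parity_dataset(rule, n_rows=n_rows, sampler_seed=sampler_seed, ruleset=rs)
        train, test = split_dataset(ds, split)
        rule_block: dict = {}
        for task in tasks:
            task_block: dict = {}
            for n_trees in tree_counts:
                spec = ModelSpec(
                    task=task,
                    rule=rule,
                    n_trees=n_trees,
                    seed=model_seed,
                    variant=rs.variant if rule == "muegge" else None,
                )
                model = train_model(train, spec)
                task_block[str(n_trees)] = (
                    evaluate_classifier(model, test)
                    if task == "classifier"
                    else evaluate_regressor(model, test)
                )
            rule_block[task] = task_block
        results["metrics"][rule] = rule_block
    return results
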