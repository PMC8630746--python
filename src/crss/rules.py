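"""Distillation of consensus stage labels into portable decision rules.

A CART-style decision tree is trained on the raw parameter values (plus the
binary HRCA flag) with the consensus stages as labels; its root-to-leaf
paths become an explicit, mutually exclusive and exhaustive rule set.  The
rule set — not the consensus machinery — is what gets deployed: staging a
new patient requires only their laboratory values and the serialized rules.

Note the tree sees raw continuous values, not the dichotomized flags, so the
learned split thresholds may legitimately differ from the risk-scoring
cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "fit_tree",
    "extract_rules",
    "fit_stage_classifier",
    "predict_stage",
    "predict_frame",
]


@dataclass(frozen=True)
class Condition:
    """A single comparison ``feature <op> threshold`` with op in {"<=", ">"}."""

    feature: str
    op: str
    threshold: float

    def holds(self, value: float) -> bool:
        if self.op == "<=":
            return value <= self.threshold
        if self.op == ">":
            return value > self.threshold
        raise ValueError(f"unknown comparator {self.op!r}")

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions leading to one predicted stage.

    ``probs`` are the training class proportions in the leaf, ordered by
    ``RuleSet.classes``; ``n_train`` is the number of training patients that
    reached the leaf.
    """

    conditions: tuple[Condition, ...]
    stage: int
    probs: tuple[float, ...]
    n_train: int

    def matches(self, features: Mapping[str, float]) -> bool:
        return all(c.holds(features[c.feature]) for c in self.conditions)

    def __str__(self) -> str:
        cond = " AND ".join(str(c) for c in self.conditions) or "always"
        return f"IF {cond} THEN stage {self.stage}"


@dataclass(frozen=True)
class RuleSet:
    """Ordered decision rules equivalent to a fitted classification tree."""

    rules: tuple[Rule, ...]
    feature_names: tuple[str, ...]
    classes: tuple[int, ...]
    depth: int
    training_fidelity: float | None = None

    def _check_features(self, features: Mapping[str, float]) -> None:
        referenced = {c.feature for r in self.rules for c in r.conditions}
        missing = sorted(
            f for f in referenced
            if f not in features or features[f] is None
            or (isinstance(features[f], float) and np.isnan(features[f]))
        )
        if missing:
            raise ValueError(f"missing features required by the rules: {missing}")

    def match(self, features: Mapping[str, float]) -> Rule:
        self._check_features(features)
        hits = [r for r in self.rules if r.matches(features)]
        if len(hits) != 1:  # cannot happen for a rule set from a tree
            raise RuntimeError(f"expected exactly one matching rule, got {len(hits)}")
        return hits[0]

    def predict(self, features: Mapping[str, float]) -> int:
        return self.match(features).stage

    def predict_proba_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Class-probability matrix (n x len(classes)) for a feature table."""
        out = np.zeros((len(df), len(self.classes)))
        matched = np.zeros(len(df), dtype=bool)
        for rule in self.rules:
            mask = np.ones(len(df), dtype=bool)
            for c in rule.conditions:
                col = df[c.feature].to_numpy(dtype=float)
                mask &= (col <= c.threshold) if c.op == "<=" else (col > c.threshold)
            out[mask] = rule.probs
            matched |= mask
        if not matched.all():
            raise RuntimeError("some rows matched no rule")
        return out

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "classes": list(self.classes),
            "depth": self.depth,
            "training_fidelity": self.training_fidelity,
            "rules": [
                {
                    "conditions": [
                        {"feature": c.feature, "op": c.op, "threshold": c.threshold}
                        for c in r.conditions
                    ],
                    "stage": r.stage,
                    "probs": list(r.probs),
                    "n_train": r.n_train,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RuleSet":
        try:
            rules = tuple(
                Rule(
                    conditions=tuple(
                        Condition(c["feature"], c["op"], float(c["threshold"]))
                        for c in r["conditions"]
                    ),
                    stage=int(r["stage"]),
                    probs=tuple(float(p) for p in r["probs"]),
                    n_train=int(r["n_train"]),
                )
                for r in payload["rules"]
            )
            return cls(
                rules=rules,
                feature_names=tuple(payload["feature_names"]),
                classes=tuple(int(c) for c in payload["classes"]),
                depth=int(payload["depth"]),
                training_fidelity=payload.get("training_fidelity"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed rule-set payload: {exc}") from exc

    def to_text(self) -> str:
        return "\n".join(str(r) for r in self.rules)


def fit_tree(
    X: pd.DataFrame,
    labels,
    max_depth: int = 4,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> DecisionTreeClassifier:
    """Train the stage classifier (CART, Gini impurity) on raw features."""
    y = np.asarray(labels, dtype=int)
    present = np.unique(y)
    if present.size < 3:
        raise ValueError(
            f"all three stages must be present in the labels; found {present.tolist()}"
        )
    if X.isna().to_numpy().any():
        raise ValueError("features must be complete (impute before training)")
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
    )
    tree.fit(X.to_numpy(dtype=float), y)
    return tree


def extract_rules(
    tree: DecisionTreeClassifier,
    feature_names: Sequence[str],
    training_fidelity: float | None = None,
) -> RuleSet:
    """Unroll a fitted tree into root-to-leaf rules.

    The rules partition the feature space: every input satisfies exactly one
    rule, and rule thresholds are exactly the tree's split thresholds.
    """
    t = tree.tree_
    classes = tuple(int(c) for c in tree.classes_)
    rules: list[Rule] = []

    def walk(node: int, conditions: tuple[Condition, ...]) -> None:
        if t.children_left[node] == -1:  # leaf
            counts = np.asarray(t.value[node][0], dtype=float)
            probs = tuple((counts / counts.sum()).tolist())
            stage = classes[int(np.argmax(counts))]
            rules.append(
                Rule(
                    conditions=conditions,
                    stage=stage,
                    probs=probs,
                    n_train=int(t.n_node_samples[node]),
                )
            )
            return
        feat = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conditions + (Condition(feat, "<=", thr),))
        walk(t.children_right[node], conditions + (Condition(feat, ">", thr),))

    walk(0, ())
    return RuleSet(
        rules=tuple(rules),
        feature_names=tuple(feature_names),
        classes=classes,
        depth=int(tree.get_depth()),
        training_fidelity=training_fidelity,
    )


def fit_stage_classifier(
    X: pd.DataFrame,
    labels,
    max_depth: int = 4,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> RuleSet:
    """Fit the tree and return its rule set, with training fidelity recorded.

    Fidelity is the fraction of training patients whose rule-predicted stage
    equals the consensus label it was trained on.
    """
    tree = fit_tree(X, labels, max_depth=max_depth,
                    min_samples_leaf=min_samples_leaf, seed=seed)
    y = np.asarray(labels, dtype=int)
    fidelity = float(np.mean(tree.predict(X.to_numpy(dtype=float)) == y))
    return extract_rules(tree, list(X.columns), training_fidelity=fidelity)


def predict_stage(rules: RuleSet, features: Mapping[str, float]) -> int:
    """Stage (1/2/3) of the unique rule matching the patient's features."""
    return rules.predict(features)


def predict_frame(rules: RuleSet, df: pd.DataFrame) -> np.ndarray:
    """Vectorized rule-based stage prediction for a feature table."""
    referenced = sorted({c.feature for r in rules.rules for c in r.conditions})
    missing = [f for f in referenced if f not in df.columns]
    if missing:
        raise ValueError(f"missing features required by the rules: {missing}")
    if df[referenced].isna().to_numpy().any():
        bad = sorted(df[referenced].columns[df[referenced].isna().any()].tolist())
        raise ValueError(f"missing features required by the rules: {bad}")
    probs = rules.predict_proba_frame(df)
    return np.asarray(rules.classes, dtype=int)[np.argmax(probs, axis=1)]
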