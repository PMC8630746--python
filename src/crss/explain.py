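"""Exact Shapley-value attributions for the stage classifier.

For one patient and one stage, the model's class-probability output is
treated as a cooperative game over the features.  The value of a coalition S
is the interventional expectation: every background patient has the features
in S overwritten with the explained patient's values, and the mean predicted
probability of the target stage is taken.  With k features the Shapley
contribution of each feature is computed exactly from all 2^k coalition
values — cheap for the seven clinical features used here — so the efficiency
identity base_value + sum(contributions) = f(patient) holds to numerical
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from crss.rules import RuleSet

__all__ = ["Attribution", "coalition_values", "shapley_exact", "shap_ranking"]

MAX_EXACT_FEATURES = 15


@dataclass(frozen=True)
class Attribution:
    """Per-feature contributions to one patient's stage probability.

    ``base_value`` is the mean predicted probability of the stage over the
    background cohort; contributions sum to the patient's own predicted
    probability minus the base value.
    """

    patient_id: str
    stage: int
    base_value: float
    contributions: dict[str, float]
    model_output: float

    @property
    def efficiency_gap(self) -> float:
        return abs(self.base_value + sum(self.contributions.values()) - self.model_output)


def _class_probability(rules: RuleSet, df: pd.DataFrame, stage: int) -> np.ndarray:
    probs = rules.predict_proba_frame(df)
    col = rules.classes.index(stage)
    return probs[:, col]


def coalition_values(
    rules: RuleSet,
    patient: pd.Series | dict,
    background: pd.DataFrame,
    stage: int,
    features: list[str],
) -> np.ndarray:
    """v(S) for every coalition S (indexed by bitmask) of the given features.

    v(S) is the mean class-``stage`` probability over the background cohort
    with the features in S fixed to the patient's values.
    """
    k = len(features)
    pat = pd.Series(patient)
    base = background[features].reset_index(drop=True)
    values = np.empty(2**k)
    for mask in range(2**k):
        mixed = base.copy()
        for i in range(k):
            if mask >> i & 1:
                mixed[features[i]] = pat[features[i]]
        values[mask] = float(np.mean(_class_probability(rules, mixed, stage)))
    return values


def shapley_exact(
    rules: RuleSet,
    patient: pd.Series | dict,
    background: pd.DataFrame,
    stage: int,
    patient_id: str = "",
) -> Attribution:
    """Exact interventional Shapley attribution of one stage probability.

    Enumerates all 2^k feature coalitions; refuses more than
    ``MAX_EXACT_FEATURES`` features (use a sampling approximation beyond
    that — the clinical models here have seven).
    """
    features = list(rules.feature_names)
    k = len(features)
    if k > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{k} features exceed the exact-enumeration limit of "
            f"{MAX_EXACT_FEATURES}; use a sampling approximation"
        )
    if len(background) == 0:
        raise ValueError("background cohort must be non-empty")
    if stage not in rules.classes:
        raise ValueError(f"stage {stage} not among model classes {rules.classes}")

    v = coalition_values(rules, patient, background, stage, features)

    # Shapley formula: phi_i = sum over S not containing i of
    # |S|! (k - |S| - 1)! / k!  *  (v(S + i) - v(S)).
    sizes = np.array([bin(m).count("1") for m in range(2**k)])
    fact = [factorial(s) for s in range(k + 1)]
    contributions = {}
    for i, name in enumerate(features):
        phi = 0.0
        bit = 1 << i
        for mask in range(2**k):
            if mask & bit:
                continue
            s = sizes[mask]
            weight = fact[s] * fact[k - s - 1] / fact[k]
            phi += weight * (v[mask | bit] - v[mask])
        contributions[name] = phi

    return Attribution(
        patient_id=str(patient_id),
        stage=stage,
        base_value=float(v[0]),
        contributions=contributions,
        model_output=float(v[2**k - 1]),
    )


def shap_ranking(attributions: list[Attribution]) -> pd.DataFrame:
    """Features ordered by mean absolute contribution across attributions.

    Also reports the mean signed contribution and the fraction of patients
    for which the feature pushed toward the explained stage, mirroring the
    content of a beeswarm-style impact summary.
    """
    if not attributions:
        raise ValueError("need at least one attribution")
    features = list(attributions[0].contributions)
    rows = []
    for f in features:
        vals = np.array([a.contributions[f] for a in attributions])
        rows.append(
            {
                "feature": f,
                "mean_abs_contribution": float(np.abs(vals).mean()),
                "mean_contribution": float(vals.mean()),
                "fraction_positive": float((vals > 0).mean()),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "mean_abs_contribution", ascending=False, kind="stable"
    )
    return out.reset_index(drop=True)
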