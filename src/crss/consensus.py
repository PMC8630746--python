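"""The consensus risk-stratification core.

Three per-parameter weighting schemes are derived from survival analyses of
the dichotomized parameters:

1. *multivariate rank* — parameters are ranked 1..k by the hazard ratios of
   a multivariate Cox fit (highest hazard gets the highest rank);
2. *univariate hazard ratio* — for each parameter the larger of its PFS and
   OS univariate hazard ratios, minmax-scaled to [0, 1];
3. *p-value* — for each parameter the smaller of its PFS and OS log-rank
   p-values, transformed to -log10 and minmax-scaled so that stronger
   evidence yields a larger weight (a literal minmax of the raw p-values is
   available for fidelity experiments but inverts the intended meaning).

Each scheme turns a patient's high-risk flags into a weighted risk score;
each score vector yields an n x n adjacency graph of pairwise absolute score
differences; each graph is clustered with a Gaussian mixture model.  The
three clusterings are fused into a consensus graph counting co-assignments,
which agglomerative clustering cuts into three clusters, ordered into stages
1 (low), 2 (intermediate) and 3 (high) by mean rank-scheme risk score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.mixture import GaussianMixture

from crss.cohort_io import Cohort, CutoffRule, dichotomize_cohort, impute_median
from crss.rules import RuleSet, fit_stage_classifier
from crss.survival import CoxFit, fit_cox, logrank_test

__all__ = [
    "WeightTable",
    "StageAssignment",
    "StageModel",
    "weights_multivariate_rank",
    "weights_univariate_hr",
    "weights_pvalue",
    "risk_scores",
    "adjacency",
    "gmm_labels",
    "consensus",
    "agglomerate",
    "order_stages",
    "fit_stage_model",
]

N_STAGES = 3
N_BASE_CLUSTERINGS = 3


@dataclass(frozen=True)
class WeightTable:
    """Nonnegative per-parameter weights under one scheme."""

    scheme: str  # multivariate_rank | univariate_hr_minmax | pvalue_scaled
    weights: dict[str, float]


@dataclass(frozen=True)
class StageAssignment:
    """Final ordered stages plus the raw-cluster-to-stage mapping."""

    stages: np.ndarray  # values in {1, 2, 3}
    cluster_order: dict[int, int]  # raw cluster id -> stage


def _minmax(values: dict[str, float]) -> dict[str, float]:
    arr = np.array(list(values.values()), dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        # Degenerate spread: every parameter carries equal, full weight.
        return {k: 1.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def weights_multivariate_rank(multi_fit: CoxFit, parameters: Sequence[str] | None = None) -> WeightTable:
    """Ranks 1..k by ascending hazard ratio from one multivariate Cox fit.

    The parameter with the highest hazard ratio receives the highest rank k.
    Exact hazard-ratio ties are broken by parameter name order.
    """
    params = list(parameters) if parameters is not None else list(multi_fit.names)
    missing = [p for p in params if p not in multi_fit.hazard_ratios]
    if missing:
        raise ValueError(f"parameters absent from the multivariate fit: {missing}")
    ordered = sorted(params, key=lambda p: (multi_fit.hazard_ratios[p], p))
    return WeightTable(
        scheme="multivariate_rank",
        weights={p: float(rank) for rank, p in enumerate(ordered, start=1)},
    )


def weights_univariate_hr(
    pfs_fits: Mapping[str, CoxFit],
    os_fits: Mapping[str, CoxFit],
) -> WeightTable:
    """Per-parameter max of the PFS and OS univariate hazard ratios, minmax-scaled."""
    missing = [p for p in pfs_fits if p not in os_fits] + [p for p in os_fits if p not in pfs_fits]
    if missing:
        raise ValueError(f"parameters missing an endpoint fit: {sorted(set(missing))}")
    maxima = {
        p: max(pfs_fits[p].hazard_ratios[p], os_fits[p].hazard_ratios[p])
        for p in pfs_fits
    }
    return WeightTable(scheme="univariate_hr_minmax", weights=_minmax(maxima))


def weights_pvalue(
    pfs_p: Mapping[str, float],
    os_p: Mapping[str, float],
    mode: str = "neg_log10_minmax",
) -> WeightTable:
    """Per-parameter min of the PFS and OS log-rank p-values, scaled to [0, 1].

    The default mode maps p through -log10 before minmax scaling, so the most
    significant parameter gets weight 1.  ``literal_minmax`` scales the raw
    p-values instead (most significant gets 0); it is kept for fidelity
    experiments only.
    """
    if mode not in ("neg_log10_minmax", "literal_minmax"):
        raise ValueError(f"unknown p-value weight mode {mode!r}")
    if set(pfs_p) != set(os_p):
        raise ValueError("PFS and OS p-value tables must cover the same parameters")
    minima = {}
    for p in pfs_p:
        m = min(pfs_p[p], os_p[p])
        if not 0 <= m <= 1:
            raise ValueError(f"p-value for {p!r} outside [0, 1]: {m}")
        if m == 0.0:
            warnings.warn(f"p-value for {p!r} is exactly 0; clamping to 1e-300")
            m = 1e-300
        minima[p] = m
    if mode == "literal_minmax":
        return WeightTable(scheme="pvalue_scaled", weights=_minmax(minima))
    neglog = {p: -np.log10(v) for p, v in minima.items()}
    return WeightTable(scheme="pvalue_scaled", weights=_minmax(neglog))


def risk_scores(flags: pd.DataFrame, table: WeightTable) -> np.ndarray:
    """Weighted high-risk burden per patient.

    ``flags`` is the boolean patient x parameter matrix from
    :func:`crss.cohort_io.dichotomize_cohort`; the score is the sum of the
    weights of the parameters flagged high risk.
    """
    missing = [p for p in table.weights if p not in flags.columns]
    if missing:
        raise ValueError(f"flags missing weighted parameters: {missing}")
    cols = list(table.weights)
    mat = flags[cols].to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("flags contain missing entries; resolve HRCA/imputation first")
    w = np.array([table.weights[p] for p in cols], dtype=float)
    return mat @ w


def adjacency(scores) -> np.ndarray:
    """Pairwise absolute score differences (symmetric, zero diagonal)."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("adjacency needs at least two patients")
    return np.abs(s[:, None] - s[None, :])


def gmm_labels(graph: np.ndarray, n_components: int = N_STAGES, seed: int = 0) -> np.ndarray:
    """Cluster the rows of an adjacency graph with a Gaussian mixture model.

    Each patient's row of pairwise differences is one observation.  The
    mixture uses diagonal covariances with a small variance floor (full
    covariances are singular for rows of an n x n matrix) and keeps the best
    of 10 seeded restarts, so the labels are deterministic given the seed.
    """
    g = np.asarray(graph, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("adjacency graph must be a square matrix")
    n_distinct = np.unique(g, axis=0).shape[0]
    if n_components > n_distinct:
        raise ValueError(
            f"{n_components} components requested but only {n_distinct} distinct "
            f"rows; use fewer components"
        )
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        reg_covar=1e-6,
        n_init=10,
        random_state=seed,
    )
    return gmm.fit_predict(g)


def consensus(labelings: Sequence[np.ndarray]) -> np.ndarray:
    """Co-clustering counts over exactly three base clusterings.

    Entry (i, j) counts the clusterings in which patients i and j share a
    label; the diagonal is zero by convention.
    """
    if len(labelings) != N_BASE_CLUSTERINGS:
        raise ValueError(f"consensus is defined for exactly {N_BASE_CLUSTERINGS} labelings")
    arrays = [np.asarray(l) for l in labelings]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("labelings must have equal length")
    out = np.zeros((n, n), dtype=int)
    for a in arrays:
        out += (a[:, None] == a[None, :]).astype(int)
    np.fill_diagonal(out, 0)
    return out


def agglomerate(consensus_graph: np.ndarray, n_stages: int = N_STAGES) -> np.ndarray:
    """Cut the consensus graph into clusters by average-linkage agglomeration.

    The distance between patients is ``3 - consensus`` (never co-clustered is
    maximally distant).  A consensus of all zeros still yields ``n_stages``
    clusters, with a degeneracy warning, because all distances tie.
    """
    c = np.asarray(consensus_graph)
    n = c.shape[0]
    if n < n_stages:
        raise ValueError(f"cannot form {n_stages} stages from {n} patients")
    if not (c == c.T).all():
        raise ValueError("consensus graph must be symmetric")
    off_diag = c[~np.eye(n, dtype=bool)]
    if off_diag.size and off_diag.max() == 0:
        warnings.warn("all-zero consensus graph: clusters are arbitrary ties")
    dist = (N_BASE_CLUSTERINGS - c).astype(float)
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(
        n_clusters=n_stages, metric="precomputed", linkage="average"
    )
    return model.fit_predict(dist)


def order_stages(raw_labels: np.ndarray, rank_scores: np.ndarray) -> StageAssignment:
    """Map raw clusters to ordered stages by ascending mean rank-scheme score.

    The lowest-scoring cluster becomes stage 1 (low risk) and the highest
    stage 3; equal means are broken toward the smaller raw cluster id.
    """
    labels = np.asarray(raw_labels)
    scores = np.asarray(rank_scores, dtype=float)
    cluster_ids = np.unique(labels)
    if cluster_ids.size != N_STAGES:
        raise ValueError(f"expected {N_STAGES} non-empty clusters, got {cluster_ids.size}")
    means = {int(c): float(scores[labels == c].mean()) for c in cluster_ids}
    ordered = sorted(means, key=lambda c: (means[c], c))
    cluster_order = {c: stage for stage, c in enumerate(ordered, start=1)}
    stages = np.array([cluster_order[int(l)] for l in labels], dtype=int)
    return StageAssignment(stages=stages, cluster_order=cluster_order)


@dataclass
class StageModel:
    """A fitted, self-contained staging model.

    Bundles the dichotomization cutoffs, the three weight tables, the
    decision rules distilled from the consensus stages, and the training
    configuration, so that stage prediction for new patients needs no
    survival data and no re-clustering.
    """

    cutoffs: dict[str, CutoffRule]
    weights: dict[str, WeightTable]
    rules: RuleSet
    seed: int
    config: dict
    provenance: str = "unspecified"
    stage_counts: dict[int, int] = field(default_factory=dict)

    def predict(self, features: Mapping[str, float]) -> int:
        return self.rules.predict(features)

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        from crss.rules import predict_frame

        return predict_frame(self.rules, df)

    def to_json(self) -> str:
        payload = {
            "format": "crss-stage-model",
            "version": 1,
            "provenance": self.provenance,
            "seed": self.seed,
            "config": self.config,
            "cutoffs": {
                p: {"threshold": r.threshold, "direction": r.direction}
                for p, r in sorted(self.cutoffs.items())
            },
            "weights": {
                name: {"scheme": t.scheme, "weights": dict(sorted(t.weights.items()))}
                for name, t in sorted(self.weights.items())
            },
            "stage_counts": {str(k): v for k, v in sorted(self.stage_counts.items())},
            "rules": self.rules.to_dict(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "StageModel":
        try:
            payload = json.loads(text)
            if payload.get("format") != "crss-stage-model":
                raise ValueError("not a crss-stage-model document")
            cutoffs = {
                p: CutoffRule(parameter=p, threshold=float(s["threshold"]),
                              direction=s["direction"])
                for p, s in payload["cutoffs"].items()
            }
            weights = {
                name: WeightTable(scheme=t["scheme"],
                                  weights={k: float(v) for k, v in t["weights"].items()})
                for name, t in payload["weights"].items()
            }
            return cls(
                cutoffs=cutoffs,
                weights=weights,
                rules=RuleSet.from_dict(payload["rules"]),
                seed=int(payload["seed"]),
                config=payload["config"],
                provenance=payload.get("provenance", "unspecified"),
                stage_counts={int(k): int(v) for k, v in payload["stage_counts"].items()},
            )
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise ValueError(f"malformed stage-model JSON: {exc}") from exc

    @classmethod
    def load(cls, path: str | Path) -> "StageModel":
        return cls.from_json(Path(path).read_text())


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic component seeds derived from one pipeline seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def fit_stage_model(
    cohort: Cohort,
    cutoffs: Mapping[str, CutoffRule],
    seed: int = 0,
    parameters: Sequence[str] | None = None,
    include_hrca: bool = True,
    pvalue_mode: str = "neg_log10_minmax",
    rank_endpoint: str = "os",
    tree_max_depth: int = 4,
    tree_min_leaf: int = 5,
    return_details: bool = False,
):
    """Run the full consensus staging pipeline on a model-building cohort.

    Patients without HRCA assessment are excluded (when HRCA is included as
    a parameter); remaining missing parameter values are median-imputed.
    Returns the fitted :class:`StageModel` and the training
    :class:`StageAssignment`; with ``return_details=True`` a dict of
    intermediate artifacts (flags, scores, consensus graph, Cox fits) is
    returned as well.

    Raises ``ValueError`` when fewer than three stages are recoverable.
    """
    params = list(parameters) if parameters is not None else [
        p for p in cutoffs
    ]
    seeds = _sub_seeds(seed, 4)

    df = cohort.to_frame()
    if include_hrca:
        df = df[df["hrca"].notna()].reset_index(drop=True)
        if df.empty:
            raise ValueError("no patients with HRCA assessment available")
    sub = Cohort.from_frame(df, provenance=cohort.provenance)
    sub = impute_median(sub, params)
    df = sub.to_frame()

    rules_map = {p: cutoffs[p] for p in params}
    flags = dichotomize_cohort(sub, rules_map, include_hrca=include_hrca).reset_index(drop=True)
    feature_params = params + (["hrca"] if include_hrca else [])
    flag_mat = flags[feature_params].astype(float)

    endpoints = {
        "pfs": (df["pfs_time"].to_numpy(float), df["pfs_event"].to_numpy(int)),
        "os": (df["os_time"].to_numpy(float), df["os_event"].to_numpy(int)),
    }

    # Univariate Cox per dichotomized parameter, per endpoint.
    uni: dict[str, dict[str, CoxFit]] = {"pfs": {}, "os": {}}
    for ep, (t, e) in endpoints.items():
        for p in feature_params:
            uni[ep][p] = fit_cox(t, e, flag_mat[[p]])

    # Multivariate Cox on all flags for the rank weights.
    if rank_endpoint not in endpoints:
        raise ValueError(f"rank_endpoint must be 'pfs' or 'os', got {rank_endpoint!r}")
    t, e = endpoints[rank_endpoint]
    multi = fit_cox(t, e, flag_mat)

    # Log-rank p per parameter, per endpoint.
    logrank_p: dict[str, dict[str, float]] = {"pfs": {}, "os": {}}
    for ep, (t, e) in endpoints.items():
        for p in feature_params:
            m = flag_mat[p].to_numpy() > 0.5
            logrank_p[ep][p] = logrank_test(t[m], e[m], t[~m], e[~m]).p_value

    w_rank = weights_multivariate_rank(multi, feature_params)
    w_hr = weights_univariate_hr(uni["pfs"], uni["os"])
    w_p = weights_pvalue(logrank_p["pfs"], logrank_p["os"], mode=pvalue_mode)

    tables = {"rank": w_rank, "hr": w_hr, "pvalue": w_p}
    scores = {name: risk_scores(flags, tab) for name, tab in tables.items()}
    labelings = [
        gmm_labels(adjacency(scores[name]), n_components=N_STAGES, seed=s)
        for name, s in zip(("rank", "hr", "pvalue"), seeds[:3])
    ]
    cons = consensus(labelings)
    raw = agglomerate(cons, n_stages=N_STAGES)
    if np.unique(raw).size < N_STAGES:
        raise ValueError("fewer than three stages recovered from the consensus graph")
    assignment = order_stages(raw, scores["rank"])

    features = df[params].copy()
    if include_hrca:
        features["hrca"] = df["hrca"].astype(float)
    ruleset = fit_stage_classifier(
        features,
        assignment.stages,
        max_depth=tree_max_depth,
        min_samples_leaf=tree_min_leaf,
        seed=seeds[3],
    )

    unique, counts = np.unique(assignment.stages, return_counts=True)
    model = StageModel(
        cutoffs=dict(rules_map),
        weights=tables,
        rules=ruleset,
        seed=seed,
        config={
            "parameters": params,
            "include_hrca": include_hrca,
            "pvalue_mode": pvalue_mode,
            "rank_endpoint": rank_endpoint,
            "tree_max_depth": tree_max_depth,
            "tree_min_leaf": tree_min_leaf,
        },
        provenance=cohort.provenance,
        stage_counts={int(u): int(c) for u, c in zip(unique, counts)},
    )
    if return_details:
        details = {
            "frame": df,
            "flags": flags,
            "scores": scores,
            "labelings": labelings,
            "consensus": cons,
            "raw_labels": raw,
            "univariate_fits": uni,
            "multivariate_fit": multi,
            "logrank_p": logrank_p,
            "patient_ids": df["patient_id"].tolist(),
        }
        return model, assignment, details
    return model, assignment
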