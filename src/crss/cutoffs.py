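"""Survival-guided cutoff discovery (K-adaptive-partitioning style).

For each prognostic parameter the search scans candidate thresholds —
midpoints between consecutive distinct observed values, constrained so that
neither side of the split falls below a minimum group fraction — and keeps
the threshold maximizing the two-sample log-rank chi-square between the
resulting high- and low-risk groups.  The scan is run once per endpoint
(PFS and OS); the candidate closer to the established clinical cutoff wins.

The p-value attached to a selected cutoff is the unadjusted log-rank p at
that cutoff.  Because the threshold is chosen to maximize separation, this
p-value is optimistically biased (the maximally-selected-statistic problem)
and is reported as a descriptive quantity only, not an honest test level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from crss.cohort_io import Cohort, CutoffRule
from crss.survival import _as_survival_arrays, _logrank_chi2, logrank_test

__all__ = [
    "CutoffCandidate",
    "candidate_grid",
    "kap_search",
    "select_cutoff",
    "derive_cutoffs",
    "cutoff_table",
]


def _high_mask(v: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    """Vectorized dichotomization with the same boundary semantics as
    :func:`crss.cohort_io.dichotomize`."""
    if direction == "high_if_gt":
        return v > threshold
    if direction == "high_if_ge":
        return v >= threshold
    if direction == "high_if_le":
        return v <= threshold
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class CutoffCandidate:
    """Best threshold for one parameter on one endpoint."""

    parameter: str
    endpoint: str  # "PFS" or "OS"
    threshold: float
    direction: str
    chi_square: float
    p_value: float
    group_sizes: tuple[int, int]  # (n_low_risk, n_high_risk)


def candidate_grid(values, min_fraction: float = 0.1) -> np.ndarray:
    """Candidate thresholds: midpoints between consecutive distinct values.

    Midpoints that would leave either side of the split with fewer than
    ``min_fraction * n`` subjects are dropped.  Because candidates sit
    strictly between observed values, group sizes do not depend on whether
    the boundary is inclusive.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if not 0 < min_fraction < 0.5:
        raise ValueError("min_fraction must be in (0, 0.5)")
    distinct = np.unique(v)
    if distinct.size < 2:
        raise ValueError("need at least two distinct values to form a cutoff grid")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = v.size
    min_count = min_fraction * n
    n_below = np.searchsorted(v, mids, side="left")  # strictly below midpoint
    keep = (n_below >= min_count) & ((n - n_below) >= min_count)
    return mids[keep]


def kap_search(
    values,
    times,
    events,
    direction: str,
    min_fraction: float = 0.1,
    parameter: str = "",
    endpoint: str = "",
) -> CutoffCandidate:
    """Exhaustively maximize log-rank separation over the candidate grid.

    Ties in chi-square are broken toward the smaller threshold.  The search
    is deterministic; the returned p-value is descriptive (see module note).
    """
    v = np.asarray(values, dtype=float)
    t, e = _as_survival_arrays(times, events)
    if v.shape != t.shape:
        raise ValueError("values and survival arrays must have equal length")
    grid = candidate_grid(v, min_fraction=min_fraction)
    if grid.size == 0:
        raise ValueError("candidate grid is empty; relax min_fraction")

    best_chi2 = -1.0
    best_threshold = float("nan")
    for threshold in grid:  # ascending, so first max wins the tie-break
        high = _high_mask(v, float(threshold), direction)
        chi2 = _logrank_chi2(t, e, high)
        if chi2 > best_chi2:
            best_chi2 = chi2
            best_threshold = float(threshold)

    high = _high_mask(v, best_threshold, direction)
    result = logrank_test(t[high], e[high], t[~high], e[~high])
    return CutoffCandidate(
        parameter=parameter,
        endpoint=endpoint,
        threshold=best_threshold,
        direction=direction,
        chi_square=result.chi_square,
        p_value=result.p_value,
        group_sizes=(int((~high).sum()), int(high.sum())),
    )


def select_cutoff(
    established: float,
    pfs_candidate: CutoffCandidate,
    os_candidate: CutoffCandidate,
) -> CutoffRule:
    """Reconcile PFS- and OS-derived candidates against the established cutoff.

    The candidate whose threshold is closer (absolute difference) to the
    established value is chosen; an exact distance tie goes to the smaller
    threshold.
    """
    if pfs_candidate.parameter != os_candidate.parameter:
        raise ValueError("candidates describe different parameters")
    d_pfs = abs(pfs_candidate.threshold - established)
    d_os = abs(os_candidate.threshold - established)
    if d_pfs < d_os:
        chosen = pfs_candidate
    elif d_os < d_pfs:
        chosen = os_candidate
    else:
        chosen = min(pfs_candidate, os_candidate, key=lambda c: c.threshold)
    return CutoffRule(parameter=chosen.parameter, threshold=chosen.threshold,
                      direction=chosen.direction)


def derive_cutoffs(
    cohort: Cohort,
    established: Mapping[str, CutoffRule],
    parameters=None,
    min_fraction: float = 0.1,
) -> dict[str, CutoffRule]:
    """Propose a cutoff per parameter from the cohort's PFS and OS endpoints.

    For each parameter the grid search runs once per endpoint and the
    candidate closer to the established cutoff is kept, with the established
    rule's high-risk direction carried through.
    """
    df = cohort.to_frame()
    params = list(parameters) if parameters is not None else list(established)
    out: dict[str, CutoffRule] = {}
    for p in params:
        rule = established[p]
        mask = df[p].notna()
        v = df.loc[mask, p].to_numpy(dtype=float)
        candidates = {}
        for endpoint, (tcol, ecol) in (
            ("PFS", ("pfs_time", "pfs_event")),
            ("OS", ("os_time", "os_event")),
        ):
            candidates[endpoint] = kap_search(
                v,
                df.loc[mask, tcol].to_numpy(dtype=float),
                df.loc[mask, ecol].to_numpy(dtype=int),
                direction=rule.direction,
                min_fraction=min_fraction,
                parameter=p,
                endpoint=endpoint,
            )
        out[p] = select_cutoff(rule.threshold, candidates["PFS"], candidates["OS"])
    return out


def cutoff_table(
    cohort: Cohort,
    established: Mapping[str, CutoffRule],
    proposed: Mapping[str, CutoffRule],
) -> pd.DataFrame:
    """Per-parameter comparison of established vs proposed cutoffs.

    Columns report both thresholds and the (descriptive) log-rank p-values
    of the resulting high/low split for PFS and OS under each cutoff.
    """
    df = cohort.to_frame()
    rows = []
    for p, est in established.items():
        prop = proposed[p]
        mask = df[p].notna()
        v = df.loc[mask, p].to_numpy(dtype=float)
        row: dict[str, object] = {
            "parameter": p,
            "established_cutoff": est.threshold,
            "proposed_cutoff": prop.threshold,
            "direction": est.direction,
        }
        for endpoint, (tcol, ecol) in (
            ("pfs", ("pfs_time", "pfs_event")),
            ("os", ("os_time", "os_event")),
        ):
            t = df.loc[mask, tcol].to_numpy(dtype=float)
            e = df.loc[mask, ecol].to_numpy(dtype=int)
            for label, rule in (("established", est), ("proposed", prop)):
                high = _high_mask(v, rule.threshold, rule.direction)
                if high.all() or not high.any():
                    pval = float("nan")
                else:
                    pval = logrank_test(t[high], e[high], t[~high], e[~high]).p_value
                row[f"{endpoint}_p_{label}"] = pval
        rows.append(row)
    return pd.DataFrame(rows)
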