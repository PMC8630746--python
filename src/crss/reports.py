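"""Tabular evaluation of a staging system against survival endpoints.

Two report shapes are produced for any stage assignment (CRSS, ISS, R-ISS,
or anything else that maps patients to ordered stages 1..3):

* a Cox summary per endpoint — the hazard ratio treating stage as a single
  ordinal covariate, the stage-2-vs-1 and stage-3-vs-1 dummy hazard ratios
  with 95% confidence intervals, Harrell's C, AIC and BIC;
* a Kaplan–Meier summary — per-stage survival percentage at yearly horizons
  plus median survival in weeks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from crss.cohort_io import Cohort, assign_iss, assign_riss, normalize_ldh
from crss.survival import fit_cox, kaplan_meier, km_summary, logrank_test

__all__ = [
    "stage_cox_report",
    "stage_km_report",
    "stage_logrank",
    "baseline_stages",
]


def stage_cox_report(times, events, stages, label: str = "stage") -> pd.DataFrame:
    """Cox-based discrimination summary for one endpoint (Table-2 shape)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(stages, dtype=int)

    ordinal = fit_cox(t, e, pd.DataFrame({label: s.astype(float)}))
    dummies = pd.DataFrame({"stage2": (s == 2).astype(float),
                            "stage3": (s == 3).astype(float)})
    per_stage = fit_cox(t, e, dummies)

    rows = [
        {
            "term": "stage (ordinal)",
            "hazard_ratio": ordinal.hazard_ratios[label],
            "ci_lower": ordinal.ci_lower[label],
            "ci_upper": ordinal.ci_upper[label],
            "p": ordinal.p_values[label],
            "c_index": ordinal.c_index,
            "aic": ordinal.aic,
            "bic": ordinal.bic,
        }
    ]
    for term, name in (("2 vs 1", "stage2"), ("3 vs 1", "stage3")):
        rows.append(
            {
                "term": term,
                "hazard_ratio": per_stage.hazard_ratios[name],
                "ci_lower": per_stage.ci_lower[name],
                "ci_upper": per_stage.ci_upper[name],
                "p": per_stage.p_values[name],
                "c_index": per_stage.c_index,
                "aic": per_stage.aic,
                "bic": per_stage.bic,
            }
        )
    return pd.DataFrame(rows)


def stage_km_report(times, events, stages, horizons_years=(1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Per-stage survival at yearly horizons, in percent (Table-3 shape)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(stages, dtype=int)
    rows = []
    for stage in sorted(np.unique(s)):
        mask = s == stage
        curve = kaplan_meier(t[mask], e[mask])
        summ = km_summary(curve, horizons_years)
        row: dict[str, object] = {"stage": int(stage), "n": int(mask.sum())}
        for y in horizons_years:
            row[f"year_{y}_pct"] = 100.0 * summ[f"year_{y}"]
        row["median_weeks"] = summ["median_weeks"]
        rows.append(row)
    return pd.DataFrame(rows)


def stage_logrank(times, events, stages) -> pd.DataFrame:
    """Pairwise log-rank tests between successive stages."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(stages, dtype=int)
    rows = []
    levels = sorted(np.unique(s))
    for a, b in zip(levels[:-1], levels[1:]):
        res = logrank_test(t[s == a], e[s == a], t[s == b], e[s == b])
        rows.append({"comparison": f"{a} vs {b}", "chi_square": res.chi_square,
                     "p": res.p_value})
    return pd.DataFrame(rows)


def baseline_stages(cohort: Cohort) -> pd.DataFrame:
    """ISS and R-ISS stages per patient, for benchmarking.

    R-ISS is left missing for patients lacking HRCA or LDH assessment (such
    patients are simply excluded from R-ISS comparisons).  LDH is called
    high when the rescaled value exceeds the common upper limit of normal.
    """
    rows = []
    for rec in cohort:
        if rec.b2m is None or rec.albumin is None:
            iss = None
        else:
            iss = assign_iss(rec.b2m, rec.albumin)
        riss = None
        if iss is not None and rec.hrca is not None and rec.ldh is not None:
            ldh_high = normalize_ldh(rec.ldh, rec.ldh_uln) > 280.0
            riss = assign_riss(iss, rec.hrca, ldh_high)
        rows.append({"patient_id": rec.patient_id, "iss": iss, "riss": riss})
    return pd.DataFrame(rows)
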