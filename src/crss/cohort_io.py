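"""Reading, validation, and preprocessing of myeloma patient cohorts.

A cohort is a table of newly diagnosed multiple myeloma (NDMM) patients with
the prognostic parameters used throughout the package — age, serum albumin,
beta-2 microglobulin (b2m), calcium, renal function (eGFR, derived from
creatinine when absent), hemoglobin, LDH, and a pooled high-risk cytogenetics
flag (HRCA: del17p, t(4;14) or t(14;16)) — plus two right-censored endpoints,
progression-free survival (PFS) and overall survival (OS), in weeks.

This module provides CSV ingestion with row-level validation, median
imputation, the MDRD eGFR formula, LDH rescaling to a common upper limit of
normal, dichotomization against cutoff rules, and ISS / R-ISS stage
assignment used as benchmarking baselines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "CutoffRule",
    "Cohort",
    "SchemaError",
    "CohortValidationError",
    "CANONICAL_DIRECTIONS",
    "RISK_PARAMETERS",
    "read_cohort",
    "impute_median",
    "egfr_mdrd",
    "normalize_ldh",
    "dichotomize",
    "dichotomize_cohort",
    "assign_iss",
    "assign_riss",
    "load_cutoffs",
    "save_cutoffs",
]

#: Continuous parameters that take part in risk scoring, in canonical order.
RISK_PARAMETERS = ("age", "albumin", "b2m", "calcium", "egfr", "hemoglobin")

#: Direction of the "high risk" side for each parameter.  Age is risky above
#: the threshold (strict), b2m and calcium at or above, and albumin, eGFR and
#: hemoglobin at or below — matching how staging cutoffs are conventionally
#: typeset (">65", "≥5.5", "≤3.5").
CANONICAL_DIRECTIONS: Mapping[str, str] = {
    "age": "high_if_gt",
    "b2m": "high_if_ge",
    "calcium": "high_if_ge",
    "albumin": "high_if_le",
    "egfr": "high_if_le",
    "hemoglobin": "high_if_le",
    "ldh": "high_if_gt",
}

#: LDH common scale: a value equal to the assay's upper limit of normal maps
#: to 280 U/L after rescaling.
LDH_REFERENCE_ULN = 280.0

_VALID_DIRECTIONS = frozenset({"high_if_gt", "high_if_ge", "high_if_le"})


class SchemaError(ValueError):
    """The input table lacks mandatory columns or has an unusable layout."""


class CohortValidationError(ValueError):
    """One or more rows violate the patient-record invariants."""

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {row}: {msg}" for row, msg in self.problems)
        super().__init__(f"invalid patient rows — {lines}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's parameters, cytogenetics flag, and censored endpoints.

    Times are in weeks; events are 1 for observed, 0 for censored.  ``hrca``
    is None when cytogenetics were not assessed; such patients can still
    contribute to cutoff discovery but are excluded from model building.
    """

    patient_id: str
    age: float
    albumin: float | None
    b2m: float | None
    calcium: float | None
    hemoglobin: float | None
    female: bool
    pfs_time: float
    pfs_event: int
    os_time: float
    os_event: int
    creatinine: float | None = None
    egfr: float | None = None
    ldh: float | None = None
    ldh_uln: float | None = None
    hrca: bool | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        for name in ("pfs_time", "os_time"):
            t = getattr(self, name)
            if not (t > 0):
                problems.append(f"{name} must be > 0, got {t!r}")
        for name in ("pfs_event", "os_event"):
            e = getattr(self, name)
            if e not in (0, 1):
                problems.append(f"{name} must be 0 or 1, got {e!r}")
        for name in ("age", "albumin", "b2m", "calcium", "hemoglobin",
                     "creatinine", "egfr", "ldh"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                problems.append(f"{name} must be > 0 when present, got {v!r}")
        if self.ldh is not None and (self.ldh_uln is None or not self.ldh_uln > 0):
            problems.append("ldh_uln must be > 0 when ldh is present")
        if self.creatinine is None and self.egfr is None:
            problems.append("either creatinine or egfr is required")
        return problems


@dataclass(frozen=True)
class CutoffRule:
    """A dichotomizing threshold for one parameter.

    ``direction`` states which side of the threshold is high risk:
    ``high_if_gt`` (strictly above), ``high_if_ge`` (at or above) or
    ``high_if_le`` (at or below).
    """

    parameter: str
    threshold: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in _VALID_DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; "
                f"expected one of {sorted(_VALID_DIRECTIONS)}"
            )


@dataclass
class Cohort:
    """An ordered, uniquely identified collection of patient records."""

    records: list[PatientRecord]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a cohort must contain at least one patient")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Materialize the cohort as a DataFrame (None becomes NaN)."""
        cols = [f.name for f in fields(PatientRecord)]
        df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "unspecified") -> "Cohort":
        records = [_record_from_row(row) for _, row in df.iterrows()]
        return cls(records=records, provenance=provenance)

    def with_records(self, records: list[PatientRecord]) -> "Cohort":
        return Cohort(records=records, provenance=self.provenance)


_MANDATORY = (
    "patient_id", "age", "albumin", "b2m", "calcium", "hemoglobin",
    "female", "pfs_time", "pfs_event", "os_time", "os_event",
)
_OPTIONAL = ("creatinine", "egfr", "ldh", "ldh_uln", "hrca")

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def _parse_bool(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float, np.floating)):
        if value in (0, 1):
            return bool(value)
        raise ValueError(f"cannot interpret {value!r} as boolean")
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def _parse_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _record_from_row(row: Mapping[str, object]) -> PatientRecord:
    def get(name: str) -> object:
        return row.get(name) if name in row else None

    female = _parse_bool(get("female"))
    if female is None:
        raise ValueError("female must be present (0/1)")
    pfs_event = _parse_float(get("pfs_event"))
    os_event = _parse_float(get("os_event"))
    if pfs_event is None or os_event is None:
        raise ValueError("pfs_event and os_event are mandatory")
    pfs_time = _parse_float(get("pfs_time"))
    os_time = _parse_float(get("os_time"))
    if pfs_time is None or os_time is None:
        raise ValueError("pfs_time and os_time are mandatory")
    age = _parse_float(get("age"))
    if age is None:
        raise ValueError("age is mandatory")

    creatinine = _parse_float(get("creatinine"))
    egfr = _parse_float(get("egfr"))
    # Supplied eGFR takes precedence over creatinine-derived values.
    if egfr is None and creatinine is not None and creatinine > 0 and age > 0:
        egfr = egfr_mdrd(creatinine, age, female=female)

    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age=age,
        albumin=_parse_float(get("albumin")),
        b2m=_parse_float(get("b2m")),
        calcium=_parse_float(get("calcium")),
        hemoglobin=_parse_float(get("hemoglobin")),
        female=female,
        pfs_time=pfs_time,
        pfs_event=int(pfs_event) if pfs_event in (0.0, 1.0) else -1,
        os_time=os_time,
        os_event=int(os_event) if os_event in (0.0, 1.0) else -1,
        creatinine=creatinine,
        egfr=egfr,
        ldh=_parse_float(get("ldh")),
        ldh_uln=_parse_float(get("ldh_uln")),
        hrca=_parse_bool(get("hrca")),
    )


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> Cohort:
    """Read a patient cohort from a comma-separated file.

    Parameters
    ----------
    path:
        CSV file with a header row; missing values are empty strings or "NA".
    schema:
        Optional mapping from canonical field names (see ``PatientRecord``)
        to the column names used in the file.
    provenance:
        Label stored on the cohort; defaults to the file name.

    Raises
    ------
    SchemaError
        If mandatory columns are missing or the file is empty.
    CohortValidationError
        If any row fails type coercion or violates record invariants; the
        error lists the offending 1-based data row numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, na_values=["NA"], dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if df.empty:
        raise SchemaError(f"{path} contains a header but no rows")

    records: list[PatientRecord] = []
    problems: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        try:
            rec = _record_from_row(row)
        except (ValueError, TypeError, KeyError) as exc:
            problems.append((rownum, str(exc)))
            continue
        for msg in rec.validate():
            problems.append((rownum, msg))
        records.append(rec)
    if problems:
        raise CohortValidationError(problems)
    return Cohort(records=records, provenance=provenance or path.name)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV (missing values as empty fields, booleans 0/1)."""
    df = cohort.to_frame()
    for col in ("female", "hrca"):
        df[col] = df[col].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else int(v))
    df.to_csv(path, index=False, float_format="%.10g")


def impute_median(cohort: Cohort, parameters: Iterable[str]) -> Cohort:
    """Replace missing values of each named parameter with the column median.

    The median is taken over non-missing values only; present values are
    never altered, so the operation is idempotent.  A parameter with no
    observed value at all raises ``ValueError``.
    """
    params = list(parameters)
    medians: dict[str, float] = {}
    for p in params:
        values = [getattr(r, p) for r in cohort.records]
        observed = [v for v in values if v is not None]
        if not observed:
            raise ValueError(f"parameter {p!r} has no observed values to impute from")
        medians[p] = float(np.median(observed))
    new_records = []
    for r in cohort.records:
        updates = {p: medians[p] for p in params if getattr(r, p) is None}
        new_records.append(replace(r, **updates) if updates else r)
    return cohort.with_records(new_records)


def egfr_mdrd(
    creatinine: float,
    age: float,
    female: bool = False,
    black: bool = False,
) -> float:
    """Estimated glomerular filtration rate via the 4-variable MDRD equation.

    Uses the IDMS-traceable form::

        eGFR = 175 * SCr^-1.154 * age^-0.203 * 0.742[female] * 1.212[black]

    with serum creatinine in mg/dl, age in years, and the result in
    ml/min/1.73 m^2.
    """
    if not creatinine > 0:
        raise ValueError(f"creatinine must be > 0, got {creatinine!r}")
    if not age > 0:
        raise ValueError(f"age must be > 0, got {age!r}")
    value = 175.0 * creatinine ** -1.154 * age ** -0.203
    if female:
        value *= 0.742
    if black:
        value *= 1.212
    return value


def normalize_ldh(ldh: float, uln: float) -> float:
    """Rescale an LDH measurement to a common upper limit of normal of 280 U/L.

    Different laboratories report LDH against different reference ranges;
    multiplying by ``280 / uln`` maps a value at the assay's upper limit of
    normal to exactly 280.
    """
    if not uln > 0:
        raise ValueError(f"LDH upper limit of normal must be > 0, got {uln!r}")
    if ldh < 0:
        raise ValueError(f"LDH must be >= 0, got {ldh!r}")
    return ldh * LDH_REFERENCE_ULN / uln


def dichotomize(value: float, rule: CutoffRule) -> bool:
    """True when ``value`` falls on the high-risk side of the cutoff.

    Boundary handling follows the rule's direction exactly: ``high_if_ge``
    and ``high_if_le`` include the threshold, ``high_if_gt`` excludes it.
    Missing values must be imputed beforehand.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(
            f"cannot dichotomize a missing {rule.parameter} value; impute first"
        )
    if rule.direction == "high_if_gt":
        return value > rule.threshold
    if rule.direction == "high_if_ge":
        return value >= rule.threshold
    return value <= rule.threshold


def dichotomize_cohort(
    cohort: Cohort,
    rules: Mapping[str, CutoffRule],
    include_hrca: bool = True,
) -> pd.DataFrame:
    """High-risk flag matrix (patients x parameters) under the given rules.

    HRCA, when included, contributes a column that is simply the presence of
    any high-risk cytogenetic aberration; patients with unassessed HRCA get a
    missing entry there.
    """
    df = cohort.to_frame()
    out = pd.DataFrame(index=df.index)
    for name, rule in rules.items():
        out[name] = df[name].map(lambda v, r=rule: dichotomize(v, r))
    if include_hrca:
        out["hrca"] = df["hrca"]
    out.index = df["patient_id"]
    return out


def assign_iss(b2m: float, albumin: float) -> int:
    """International Staging System stage from b2m (mg/L) and albumin (g/dl).

    Stage I: b2m < 3.5 and albumin >= 3.5; stage III: b2m >= 5.5; stage II
    otherwise.
    """
    if b2m is None or albumin is None:
        raise ValueError("assign_iss requires both b2m and albumin")
    if b2m >= 5.5:
        return 3
    if b2m < 3.5 and albumin >= 3.5:
        return 1
    return 2


def assign_riss(iss: int, hrca: bool, ldh_high: bool) -> int:
    """Revised ISS stage from the ISS stage, HRCA, and high-LDH flags.

    R-ISS I requires ISS I with neither HRCA nor elevated LDH; R-ISS III
    requires ISS III plus HRCA or elevated LDH; everything else is II.
    """
    if iss not in (1, 2, 3):
        raise ValueError(f"iss must be 1, 2 or 3, got {iss!r}")
    if hrca is None or ldh_high is None:
        raise ValueError("assign_riss requires hrca and ldh_high flags")
    if iss == 1 and not hrca and not ldh_high:
        return 1
    if iss == 3 and (hrca or ldh_high):
        return 3
    return 2


def load_cutoffs(source: str | Path) -> dict[str, CutoffRule]:
    """Load cutoff rules from a JSON file or a bundled preset name.

    Bundled presets: ``"established"`` (consensus staging-criteria cutoffs),
    ``"proposed_mmin"`` and ``"proposed_mmrf"`` (survival-derived cutoffs for
    an Indian-ethnicity-like and a US-registry-like cohort respectively).
    The JSON layout is ``{parameter: {"threshold": x, "direction": d}}``.
    """
    presets = {"established", "proposed_mmin", "proposed_mmrf"}
    if isinstance(source, str) and source in presets:
        ref = resources.files("crss.data").joinpath(f"cutoffs_{source}.json")
        payload = json.loads(ref.read_text())
    else:
        payload = json.loads(Path(source).read_text())
    return {
        p: CutoffRule(parameter=p, threshold=float(spec["threshold"]),
                      direction=spec["direction"])
        for p, spec in payload.items()
    }


def save_cutoffs(rules: Mapping[str, CutoffRule], path: str | Path) -> None:
    payload = {
        p: {"threshold": r.threshold, "direction": r.direction}
        for p, r in rules.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
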