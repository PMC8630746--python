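"""Synthetic NDMM cohorts with planted risk structure.

The generator emulates the statistical skeleton the staging pipeline relies
on, without attempting to copy any real cohort's joint distribution:

* each patient belongs to one of three latent risk strata (low /
  intermediate / high, equiprobable by default);
* each continuous parameter has a planted high-risk cutoff.  Under the
  default ``burden`` flag model a patient's stratum sets how many of the k
  parameters are flagged high-risk (a narrow band per stratum) and the
  flagged subset is chosen uniformly, so strata are cleanly identifiable
  from the high-risk burden; the ``independent`` model instead flags each
  parameter independently with a stratum-specific probability.  Either way
  the per-parameter flag probability averaged over strata equals the
  fraction implied by the parameter's marginal distribution, and values are
  drawn from the side-truncated marginal given the flag — so the pooled
  marginal of every parameter is exactly the configured distribution;
* HRCA is a per-stratum Bernoulli flag;
* survival follows a proportional-hazards model: each planted high-risk
  flag multiplies an exponential baseline hazard by exp(effect); death and
  progression share the multiplier, PFS = min(progression, death) so
  PFS <= OS per patient, and censoring is independent exponential with an
  administrative follow-up cap.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from crss.cohort_io import Cohort, CutoffRule, load_cutoffs

__all__ = [
    "ParamSpec",
    "SimConfig",
    "generate",
    "generate_with_truth",
    "default_configs",
    "single_marker_cohort",
]


@dataclass(frozen=True)
class ParamSpec:
    """Marginal distribution of one continuous parameter, in clinical units.

    ``family`` is "normal" (loc = mean, scale = sd) or "lognormal"
    (loc and scale are the mean and sd of the log).
    """

    family: str
    loc: float
    scale: float

    def dist(self):
        if self.family == "normal":
            return stats.norm(self.loc, self.scale)
        if self.family == "lognormal":
            return stats.lognorm(s=self.scale, scale=math.exp(self.loc))
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic cohort.

    ``separation`` controls how strongly the three latent strata differ in
    their per-parameter high-risk probabilities (0 = no stratum structure,
    1 = maximal); the stratum-averaged probability always equals the
    fraction implied by the marginal distribution and the planted cutoff.
    Hazards are per week.
    """

    name: str
    n: int
    parameters: dict[str, ParamSpec]
    cutoffs: dict[str, CutoffRule]
    effects: dict[str, float]
    seed: int = 0
    stratum_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    separation: float = 0.9
    flag_model: str = "burden"
    hrca_prevalence: tuple[float, float, float] = (0.05, 0.35, 0.70)
    baseline_os: float = 0.0015
    baseline_progression: float = 0.001
    censor_rate: float = 0.0015
    followup_cap: float = 572.0
    missing_rate: float = 0.0
    hrca_missing_rate: float = 0.0
    female_fraction: float = 0.42
    ldh: ParamSpec = field(default_factory=lambda: ParamSpec("lognormal", math.log(190.0), 0.4))
    ldh_uln: float = 280.0

    def implied_high_fraction(self, parameter: str) -> float:
        """Fraction of the marginal distribution on the high-risk side."""
        spec = self.parameters[parameter]
        rule = self.cutoffs[parameter]
        F = float(spec.dist().cdf(rule.threshold))
        return F if rule.direction == "high_if_le" else 1.0 - F

    def stratum_flag_probs(self, parameter: str) -> tuple[float, float, float]:
        """Per-stratum probability of the high-risk flag for one parameter.

        Chosen so the mixture over equiprobable strata reproduces the
        marginal high-risk fraction exactly.
        """
        p = self.implied_high_fraction(parameter)
        q1 = p * (1.0 - self.separation)
        q3 = p + (1.0 - p) * self.separation
        q2 = 3.0 * p - q1 - q3
        return (q1, q2, q3)

    def validate(self) -> None:
        if self.n < 30:
            raise ValueError(f"n must be >= 30, got {self.n}")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError(f"separation must be in [0, 1], got {self.separation}")
        if abs(sum(self.stratum_probs) - 1.0) > 1e-9:
            raise ValueError("stratum_probs must sum to 1")
        for name, eff in self.effects.items():
            if eff < 0:
                raise ValueError(f"effects[{name!r}] must be >= 0, got {eff}")
        for probs, label in ((self.hrca_prevalence, "hrca_prevalence"),):
            if any(not 0 <= q <= 1 for q in probs):
                raise ValueError(f"{label} entries must be in [0, 1]")
        for rate, label in (
            (self.baseline_os, "baseline_os"),
            (self.baseline_progression, "baseline_progression"),
            (self.followup_cap, "followup_cap"),
        ):
            if rate <= 0:
                raise ValueError(f"{label} must be > 0, got {rate}")
        if self.censor_rate < 0:
            raise ValueError(f"censor_rate must be >= 0, got {self.censor_rate}")
        for r, label in ((self.missing_rate, "missing_rate"),
                         (self.hrca_missing_rate, "hrca_missing_rate")):
            if not 0 <= r <= 1:
                raise ValueError(f"{label} must be in [0, 1], got {r}")
        if self.flag_model not in ("burden", "independent"):
            raise ValueError(f"flag_model must be 'burden' or 'independent', "
                             f"got {self.flag_model!r}")
        for p in self.parameters:
            if p not in self.cutoffs:
                raise ValueError(f"no planted cutoff for parameter {p!r}")
        if self.flag_model == "burden":
            fracs = [self.implied_high_fraction(p) for p in self.parameters]
            if max(fracs) - min(fracs) > 0.02:
                raise ValueError(
                    "the burden flag model requires all parameters to share the "
                    "same implied high-risk fraction (cutoff at a common "
                    "quantile); use flag_model='independent' instead"
                )
        for p in self.parameters:
            for q in self.stratum_flag_probs(p):
                if not 0.0 <= q <= 1.0:
                    raise ValueError(
                        f"stratum flag probability for {p!r} falls outside [0, 1]; "
                        f"move the cutoff closer to the distribution's median or "
                        f"lower the separation"
                    )


def _truncated_draw(rng, spec: ParamSpec, rule: CutoffRule, high: np.ndarray) -> np.ndarray:
    """Draw values from the marginal, truncated to the flagged side of the cutoff."""
    dist = spec.dist()
    F = float(dist.cdf(rule.threshold))
    u = rng.uniform(size=high.size)
    low_side_is_high_risk = rule.direction == "high_if_le"
    on_lower = high == low_side_is_high_risk
    q = np.where(on_lower, u * F, F + u * (1.0 - F))
    values = dist.ppf(np.clip(q, 1e-12, 1 - 1e-12))
    return np.maximum(values, 1e-3)  # clinical parameters are positive


def generate_with_truth(config: SimConfig) -> tuple[Cohort, np.ndarray, pd.DataFrame]:
    """Generate a cohort and return the latent strata and planted flags too."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    strata = rng.choice(3, size=n, p=config.stratum_probs)  # 0, 1, 2

    params = list(config.parameters)
    k = len(params)
    flags = pd.DataFrame(index=range(n))
    if config.flag_model == "burden":
        # Stratum fixes the number of flagged parameters (randomized between
        # the two integers bracketing k * q_s); the flagged subset is uniform,
        # so each parameter's flag probability within a stratum is exactly q_s.
        q_strata = np.asarray(config.stratum_flag_probs(params[0]))
        target = k * q_strata[strata]
        burden = np.floor(target).astype(int)
        burden += (rng.uniform(size=n) < (target - np.floor(target))).astype(int)
        flag_mat = np.zeros((n, k), dtype=bool)
        for i in range(n):
            chosen = rng.permutation(k)[: burden[i]]
            flag_mat[i, chosen] = True
        for j, p in enumerate(params):
            flags[p] = flag_mat[:, j]
    else:
        for p in params:
            q = np.asarray(config.stratum_flag_probs(p))[strata]
            flags[p] = rng.uniform(size=n) < q
    values: dict[str, np.ndarray] = {}
    for p, spec in config.parameters.items():
        values[p] = _truncated_draw(rng, spec, config.cutoffs[p], flags[p].to_numpy())

    hrca = rng.uniform(size=n) < np.asarray(config.hrca_prevalence)[strata]
    flags["hrca"] = hrca

    lp = np.zeros(n)
    for p, eff in config.effects.items():
        if p == "hrca":
            lp += eff * hrca
        elif p in flags.columns:
            lp += eff * flags[p].to_numpy()
        else:
            raise ValueError(f"effects name unknown parameter {p!r}")
    mult = np.exp(lp)

    death = rng.exponential(1.0, size=n) / (config.baseline_os * mult)
    prog = rng.exponential(1.0, size=n) / (config.baseline_progression * mult)
    pfs_raw = np.minimum(prog, death)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    ctime = np.minimum(censor, config.followup_cap)

    os_time = np.minimum(death, ctime)
    os_event = (death <= ctime).astype(int)
    pfs_time = np.minimum(pfs_raw, ctime)
    pfs_event = (pfs_raw <= ctime).astype(int)
    # Guard against zero-length follow-up after rounding.
    os_time = np.maximum(os_time, 0.1)
    pfs_time = np.maximum(pfs_time, 0.1)

    female = rng.uniform(size=n) < config.female_fraction
    ldh = config.ldh.dist().ppf(np.clip(rng.uniform(size=n), 1e-12, 1 - 1e-12))

    df = pd.DataFrame({"patient_id": [f"P{i + 1:04d}" for i in range(n)]})
    for p in config.parameters:
        df[p] = np.round(values[p], 4)
    df["ldh"] = np.round(ldh, 2)
    df["ldh_uln"] = config.ldh_uln
    df["hrca"] = hrca
    df["female"] = female
    df["pfs_time"] = np.round(pfs_time, 2)
    df["pfs_event"] = pfs_event
    df["os_time"] = np.round(os_time, 2)
    df["os_event"] = os_event

    # Optional missingness to exercise imputation and the HRCA-known split.
    # age and egfr stay complete: age is mandatory on ingestion and egfr has
    # no creatinine fallback in synthetic cohorts.
    imputable = [p for p in config.parameters if p not in ("age", "egfr")]
    if config.missing_rate > 0:
        for p in imputable:
            hit = rng.uniform(size=n) < config.missing_rate
            df.loc[hit, p] = np.nan
    if config.hrca_missing_rate > 0:
        hit = rng.uniform(size=n) < config.hrca_missing_rate
        df["hrca"] = df["hrca"].astype(object)
        df.loc[hit, "hrca"] = None

    cohort = Cohort.from_frame(df, provenance=f"synthetic:{config.name}:seed={config.seed}")
    return cohort, strata + 1, flags


def generate(config: SimConfig) -> Cohort:
    """Generate a synthetic cohort (see :func:`generate_with_truth`)."""
    cohort, _, _ = generate_with_truth(config)
    return cohort


_LN = math.log


def default_configs(n: int = 400, seed: int = 0) -> dict[str, SimConfig]:
    """Named presets planting the bundled survival-derived cutoffs.

    ``mmin_like`` mirrors an Indian-ethnicity NDMM cohort (cutoffs from
    ``proposed_mmin``); ``mmrf_like`` mirrors a US registry cohort (cutoffs
    from ``proposed_mmrf``).  Each marginal is centered on its planted
    cutoff (median at the cutoff), which keeps the per-stratum flag
    probabilities symmetric (0.05 / 0.5 / 0.95 at the default separation)
    and the planted change point identifiable, while spreads stay within
    clinically plausible ranges.
    """
    # Equal log-hazard steps for the six laboratory parameters keep the
    # weighted burden, not any single marker, in charge of the staging;
    # HRCA gets a slightly smaller step for the same reason.
    effects = {
        "age": _LN(1.4),
        "albumin": _LN(1.4),
        "b2m": _LN(1.4),
        "calcium": _LN(1.4),
        "egfr": _LN(1.4),
        "hemoglobin": _LN(1.4),
        "hrca": _LN(1.25),
    }
    mmin = SimConfig(
        name="mmin_like",
        n=n,
        seed=seed,
        separation=1.0,
        parameters={
            "age": ParamSpec("normal", 67.0, 11.0),
            "albumin": ParamSpec("normal", 3.5, 0.6),
            "b2m": ParamSpec("lognormal", _LN(4.78), 0.55),
            "calcium": ParamSpec("normal", 11.0, 1.3),
            "egfr": ParamSpec("lognormal", _LN(48.2), 0.5),
            "hemoglobin": ParamSpec("normal", 12.3, 2.1),
        },
        cutoffs=load_cutoffs("proposed_mmin"),
        effects=dict(effects),
        ldh=ParamSpec("lognormal", _LN(190.0), 0.4),
        ldh_uln=250.0,
    )
    mmrf = SimConfig(
        name="mmrf_like",
        n=n,
        seed=seed,
        separation=1.0,
        parameters={
            "age": ParamSpec("normal", 69.0, 10.0),
            "albumin": ParamSpec("normal", 3.5, 0.6),
            "b2m": ParamSpec("lognormal", _LN(5.5), 0.6),
            "calcium": ParamSpec("normal", 10.52, 1.3),
            "egfr": ParamSpec("lognormal", _LN(48.3), 0.5),
            "hemoglobin": ParamSpec("normal", 9.59, 1.9),
        },
        cutoffs=load_cutoffs("proposed_mmrf"),
        effects=dict(effects),
        ldh=ParamSpec("lognormal", _LN(200.0), 0.4),
        ldh_uln=280.0,
    )
    return {"mmin_like": mmin, "mmrf_like": mmrf}


def single_marker_cohort(
    n: int = 600,
    threshold: float = 5.0,
    hazard_ratio: float = 3.0,
    seed: int = 0,
    baseline: float = 0.005,
    censor_rate: float = 0.002,
    direction: str = "high_if_gt",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One uniform(0, 10) marker with a planted hazard step at ``threshold``.

    Returns (values, times, events) for change-point recovery experiments:
    subjects on the high-risk side of the threshold have their exponential
    event hazard multiplied by ``hazard_ratio``; censoring is independent
    exponential (about 20% at the defaults).
    """
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, 10.0, size=n)
    if direction == "high_if_gt":
        high = values > threshold
    elif direction == "high_if_ge":
        high = values >= threshold
    elif direction == "high_if_le":
        high = values <= threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    hazard = baseline * np.where(high, hazard_ratio, 1.0)
    event_time = rng.exponential(1.0, size=n) / hazard
    censor = rng.exponential(1.0 / censor_rate, size=n) if censor_rate > 0 else np.full(n, np.inf)
    times = np.minimum(event_time, censor)
    events = (event_time <= censor).astype(int)
    return values, np.maximum(times, 1e-3), events
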