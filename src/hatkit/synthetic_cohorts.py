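"""Synthetic multi-cohort generator for the health-score pipeline.

Generates per-participant records for several aging cohorts with the
statistical structure the downstream analysis assumes: a latent health
factor ``theta`` that declines with age drives five health indicators
(gait speed, MMSE, chronic-disease count, I-ADL, P-ADL), a Gompertz
time-to-death, and annual hospital-admission indicators.  Two realistic
data defects can be injected: one cohort with systematically missing
gait speed, and one cohort where planned admissions cannot be separated
from unplanned ones.

Ages are drawn from untruncated normals so that the configured
mean/SD are reproduced exactly in expectation; a handful of simulated
participants may fall slightly below 60 years, which is harmless for
every downstream step.

Item-level missingness is applied as an *exact count* per cohort
(``round(rate * n)`` rows each lose one randomly chosen indicator), so
that complete-case inclusion counts are deterministic given the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortConfig",
    "LatentModel",
    "OutcomeModel",
    "GeneratorConfig",
    "default_config",
    "generate_cohort",
    "generate_outcomes",
    "inject_defects",
    "generate_all",
]

SEX_CODES = ("female", "male")
EDUCATION_CODES = ("primary", "high_school", "university")

#: indicator columns, in canonical item order
INDICATORS = ("gait_speed", "mmse", "n_chronic", "iadl", "padl")

_IADL_THRESHOLDS = np.array([1.0, 1.2, 1.4, 1.6, 1.85, 2.15, 2.5, 2.9])
_PADL_THRESHOLDS = np.array([1.95, 2.25, 2.55, 2.85, 3.25, 3.75])


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass
class CohortConfig:
    """Configuration block for a single cohort."""

    name: str
    n_baseline: int
    age_mean: float
    age_sd: float
    female_frac: float
    education_probs: tuple[float, float, float]
    indicator_missing_rate: float = 0.0
    gait_systematically_missing: bool = False
    admissions_unplanned_distinguishable: bool = True
    # indicator marginals this cohort should reproduce
    gait_mean: float = 1.1
    gait_sd: float = 0.4
    mmse_mu: float = 28.6
    mmse_sd: float = 3.4
    chronic_mean: float = 3.8
    chronic_sd: float = 2.4

    def validate(self) -> None:
        if self.n_baseline <= 0:
            raise ConfigError(f"cohort {self.name!r}: n_baseline must be > 0")
        if not 0.0 <= self.female_frac <= 1.0:
            raise ConfigError(f"cohort {self.name!r}: female_frac not in [0, 1]")
        if not 0.0 <= self.indicator_missing_rate <= 1.0:
            raise ConfigError(
                f"cohort {self.name!r}: indicator_missing_rate not in [0, 1]"
            )
        probs = np.asarray(self.education_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise ConfigError(f"cohort {self.name!r}: education_probs must be a 3-vector >= 0")
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ConfigError(f"cohort {self.name!r}: education_probs must sum to 1")
        for fld in ("age_sd", "gait_mean", "gait_sd", "mmse_sd", "chronic_mean", "chronic_sd"):
            if getattr(self, fld) <= 0:
                raise ConfigError(f"cohort {self.name!r}: {fld} must be > 0")


@dataclass
class LatentModel:
    """Latent health factor: theta ~ N(slope * (age - center), sd^2)."""

    theta_age_slope: float = -0.042
    theta_sd: float = 0.90
    age_center: float = 73.4
    # indicator links (loading of theta on each indicator scale)
    gait_loading: float = 0.30        # log m/s per theta unit
    nonwalker_frac: float = 0.012     # lowest-gait fraction set exactly to 0
    mmse_loading: float = 2.1         # MMSE points per theta unit
    chronic_loading: float = -0.16    # log-count per theta unit
    chronic_age_coef: float = 0.015   # log-count per year
    chronic_dispersion: float = 9.0   # negative-binomial size
    disability_noise_sd: float = 0.55
    padl_extra_noise_sd: float = 0.30

    def validate(self) -> None:
        if self.theta_sd <= 0:
            raise ConfigError("latent: theta_sd must be > 0")
        if not 0.0 <= self.nonwalker_frac < 1.0:
            raise ConfigError("latent: nonwalker_frac not in [0, 1)")
        if self.chronic_dispersion <= 0:
            raise ConfigError("latent: chronic_dispersion must be > 0")


@dataclass
class OutcomeModel:
    """Gompertz mortality and annual logistic admission models."""

    gompertz_intercept: float = -4.80
    gompertz_age_coef: float = 0.085   # per year of baseline age
    gompertz_time_coef: float = 0.17   # log-hazard growth per follow-up year
    theta_hazard_coef: float = -0.90   # per theta unit (healthier -> lower hazard)
    admission_logit_intercept: float = -1.82
    admission_theta_coef: float = -0.55
    admission_age_coef: float = 0.015
    planned_admission_rate: float = 0.16   # annual extra rate, defect cohorts only
    followup_censor_years: float = 16.0

    def validate(self) -> None:
        if self.followup_censor_years <= 0:
            raise ConfigError("outcome: followup_censor_years must be > 0")
        if self.gompertz_age_coef <= 0:
            raise ConfigError("outcome: gompertz_age_coef must be > 0")
        if not 0.0 <= self.planned_admission_rate <= 1.0:
            raise ConfigError("outcome: planned_admission_rate not in [0, 1]")


@dataclass
class GeneratorConfig:
    cohorts: list[CohortConfig] = field(default_factory=list)
    latent: LatentModel = field(default_factory=LatentModel)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def validate(self) -> None:
        if not self.cohorts:
            raise ConfigError("config must define at least one cohort")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigError("cohort names must be unique")
        for c in self.cohorts:
            c.validate()
        self.latent.validate()
        self.outcome.validate()

    def cohort(self, name: str) -> CohortConfig:
        for c in self.cohorts:
            if c.name == name:
                return c
        raise ConfigError(f"unknown cohort name {name!r}")

    def cohort_index(self, name: str) -> int:
        for i, c in enumerate(self.cohorts):
            if c.name == name:
                return i
        raise ConfigError(f"unknown cohort name {name!r}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for c in d["cohorts"]:
            c["education_probs"] = list(c["education_probs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        cohorts = [CohortConfig(**{**c, "education_probs": tuple(c["education_probs"])})
                   for c in d.get("cohorts", [])]
        latent = LatentModel(**d.get("latent", {}))
        outcome = OutcomeModel(**d.get("outcome", {}))
        cfg = cls(cohorts=cohorts, latent=latent, outcome=outcome,
                  seed=int(d.get("seed", 0)))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def default_config(seed: int = 0) -> GeneratorConfig:
    """Four-cohort configuration calibrated to the published marginals.

    Baseline sizes 3363/1402/2931/766 with per-cohort missingness rates
    chosen so that complete-case inclusion yields 3096/1228/2390/588
    participants (7302 pooled).  ``cohort_b`` has systematically missing
    gait speed and cannot distinguish unplanned admissions; ``cohort_a``
    plays the development-cohort role.
    """
    cohorts = [
        CohortConfig("cohort_a", 3363, 74.0, 10.9, 0.641, (0.170, 0.494, 0.336),
                     indicator_missing_rate=267 / 3363,
                     gait_mean=1.0, gait_sd=0.5, mmse_mu=29.6, mmse_sd=5.6,
                     chronic_mean=4.0, chronic_sd=2.4),
        CohortConfig("cohort_b", 1402, 75.9, 10.0, 0.576, (0.568, 0.322, 0.110),
                     indicator_missing_rate=174 / 1402,
                     gait_systematically_missing=True,
                     admissions_unplanned_distinguishable=False,
                     gait_mean=1.0, gait_sd=0.4, mmse_mu=27.9, mmse_sd=5.9,
                     chronic_mean=2.8, chronic_sd=2.1),
        CohortConfig("cohort_c", 2931, 71.1, 9.7, 0.541, (0.382, 0.428, 0.190),
                     indicator_missing_rate=541 / 2931,
                     gait_mean=1.3, gait_sd=0.3, mmse_mu=27.3, mmse_sd=3.3,
                     chronic_mean=4.7, chronic_sd=2.3),
        CohortConfig("cohort_d", 766, 74.4, 9.7, 0.529, (0.760, 0.191, 0.049),
                     indicator_missing_rate=178 / 766,
                     gait_mean=0.9, gait_sd=0.3, mmse_mu=29.2, mmse_sd=3.2,
                     chronic_mean=2.1, chronic_sd=1.8),
    ]
    return GeneratorConfig(cohorts=cohorts, seed=seed)


def _rng(config: GeneratorConfig, cohort_name: str, stage: int) -> np.random.Generator:
    # independent, deterministic substream per (seed, cohort, stage)
    idx = config.cohort_index(cohort_name)
    return np.random.default_rng([int(config.seed), idx, stage])


def generate_cohort(config: GeneratorConfig, cohort_name: str) -> pd.DataFrame:
    """Draw baseline covariates and the five health indicators for one cohort.

    The latent health factor is kept in a ``_theta`` column (leading
    underscore marks it as internal; it is dropped when writing CSV).
    Deterministic given ``(config, config.seed)``.
    """
    config.validate()
    cc = config.cohort(cohort_name)
    lat = config.latent
    rng = _rng(config, cohort_name, 0)
    n = cc.n_baseline

    age = rng.normal(cc.age_mean, cc.age_sd, n)
    sex = np.where(rng.random(n) < cc.female_frac, "female", "male")
    education = rng.choice(np.array(EDUCATION_CODES), size=n,
                           p=np.asarray(cc.education_probs, dtype=float))

    theta = lat.theta_age_slope * (age - lat.age_center) + rng.normal(0.0, lat.theta_sd, n)

    # gait: lognormal calibrated to the cohort's target mean/SD
    cv2 = (cc.gait_sd / cc.gait_mean) ** 2
    v = np.log1p(cv2)
    m = np.log(cc.gait_mean) - v / 2.0
    noise_var = max(v - lat.gait_loading ** 2, 0.0)
    gait = np.exp(m + lat.gait_loading * theta + rng.normal(0.0, np.sqrt(noise_var), n))
    if lat.nonwalker_frac > 0:
        q = np.quantile(gait, lat.nonwalker_frac)
        gait = np.where(gait <= q, 0.0, gait)

    # MMSE: clipped/rounded normal (clipping at 30 creates the usual left skew)
    noise_sd = np.sqrt(max(cc.mmse_sd ** 2 - lat.mmse_loading ** 2, 0.0))
    mmse_latent = cc.mmse_mu + lat.mmse_loading * theta + rng.normal(0.0, noise_sd, n)
    mmse = np.clip(np.round(mmse_latent), 0, 30).astype(float)

    # chronic disease count: negative binomial, mean increasing with age
    # and frailty.  Intercept corrected for the lognormal mean of the
    # linear predictor so the marginal mean hits the target.
    lin = lat.chronic_age_coef * (age - lat.age_center) + lat.chronic_loading * theta
    lin_var = (lat.chronic_age_coef * cc.age_sd) ** 2 + \
        (lat.chronic_loading ** 2) * (lat.theta_age_slope ** 2 * cc.age_sd ** 2 + lat.theta_sd ** 2)
    mu = cc.chronic_mean * np.exp(lin - lin_var / 2.0)
    r = lat.chronic_dispersion
    n_chronic = np.minimum(rng.negative_binomial(r, r / (r + mu)), 60).astype(float)

    # disabilities: shared frailty score against fixed ordered thresholds;
    # P-ADL thresholds are strictly more extreme than I-ADL ones.
    frailty = -theta + rng.normal(0.0, lat.disability_noise_sd, n)
    iadl = (frailty[:, None] > _IADL_THRESHOLDS[None, :]).sum(axis=1).astype(float)
    frailty_p = frailty + rng.normal(0.0, lat.padl_extra_noise_sd, n)
    padl = (frailty_p[:, None] > _PADL_THRESHOLDS[None, :]).sum(axis=1).astype(float)

    return pd.DataFrame({
        "participant_id": [f"{cohort_name}-{i:05d}" for i in range(n)],
        "cohort": cohort_name,
        "age": age,
        "sex": sex,
        "education": education,
        "gait_speed": gait,
        "mmse": mmse,
        "n_chronic": n_chronic,
        "iadl": iadl,
        "padl": padl,
        "_theta": theta,
    })


def generate_outcomes(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Attach mortality and admission outcomes.

    Time to death follows a Gompertz hazard,
    ``h(t) = exp(b0 + b_age*(age0 - center) + b_theta*theta + b_t*t)``,
    administratively censored at the follow-up horizon.  The follow-up
    slope ``b_t`` is decoupled from the cross-sectional age gradient so
    the marginal mortality curve stays steep despite the frailty
    heterogeneity induced by theta.  Admissions are
    annual Bernoulli draws (years 1..3) from a logistic model in age and
    theta; death truncates admission eligibility at the start of the year
    of death.
    """
    if "_theta" not in table.columns:
        raise ValueError("table lacks internal _theta column; generate_cohort output required")
    out = config.outcome
    cohort_name = str(table["cohort"].iloc[0])
    rng = _rng(config, cohort_name, 1)
    n = len(table)
    age = table["age"].to_numpy(dtype=float)
    theta = table["_theta"].to_numpy(dtype=float)

    b = out.gompertz_time_coef
    lam = np.exp(out.gompertz_intercept
                 + out.gompertz_age_coef * (age - config.latent.age_center)
                 + out.theta_hazard_coef * theta)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite hazard; check Gompertz parameters")
    e = rng.exponential(1.0, n)
    t_death = np.log1p(b * e / lam) / b
    horizon = out.followup_censor_years
    death_event = (t_death <= horizon).astype(int)
    death_time = np.minimum(t_death, horizon)
    death_time = np.maximum(death_time, 1e-6)  # death_time must be > 0

    p_adm = 1.0 / (1.0 + np.exp(-(out.admission_logit_intercept
                                  + out.admission_theta_coef * theta
                                  + out.admission_age_coef * (age - config.latent.age_center))))
    yearly = rng.random((n, 3)) < p_adm[:, None]
    eligible = death_time[:, None] > np.array([0.0, 1.0, 2.0])[None, :]
    yearly &= eligible
    admit_1y = yearly[:, 0].astype(int)
    admit_3y = yearly.any(axis=1).astype(int)

    table = table.copy()
    table["death_time"] = death_time
    table["death_event"] = death_event
    table["admit_1y"] = admit_1y
    table["admit_3y"] = admit_3y
    table["admissions_unplanned"] = 1
    return table


def inject_defects(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Apply the configured data defects to one cohort's table.

    * systematic gait missingness: every gait value blanked;
    * indistinguishable admissions: extra planned admissions folded into
      the admission flags and ``admissions_unplanned`` set to 0;
    * item-level missingness: exactly ``round(rate * n)`` rows each lose
      one randomly chosen indicator (gait excluded when it is already
      systematically missing), so inclusion counts are deterministic.
    """
    cohort_name = str(table["cohort"].iloc[0])
    cc = config.cohort(cohort_name)
    rng = _rng(config, cohort_name, 2)
    table = table.copy()
    n = len(table)

    if not cc.admissions_unplanned_distinguishable and "admit_1y" in table.columns:
        p = config.outcome.planned_admission_rate
        death_time = table["death_time"].to_numpy(dtype=float)
        yearly = rng.random((n, 3)) < p
        yearly &= death_time[:, None] > np.array([0.0, 1.0, 2.0])[None, :]
        table["admit_1y"] = (table["admit_1y"].to_numpy(dtype=int) | yearly[:, 0]).astype(int)
        table["admit_3y"] = (table["admit_3y"].to_numpy(dtype=int)
                             | yearly.any(axis=1)).astype(int)
        table["admissions_unplanned"] = 0

    if cc.gait_systematically_missing:
        table["gait_speed"] = np.nan
        blankable = [c for c in INDICATORS if c != "gait_speed"]
    else:
        blankable = list(INDICATORS)

    n_incomplete = int(round(cc.indicator_missing_rate * n))
    if n_incomplete > 0:
        rows = rng.choice(n, size=n_incomplete, replace=False)
        cols = rng.integers(0, len(blankable), size=n_incomplete)
        for r, ci in zip(rows, cols):
            table.iloc[r, table.columns.get_loc(blankable[ci])] = np.nan
    return table


def generate_all(config: GeneratorConfig, with_defects: bool = True,
                 cohort_names: Iterable[str] | None = None) -> dict[str, pd.DataFrame]:
    """Generate every configured cohort end to end (covariates, outcomes, defects)."""
    config.validate()
    names = list(cohort_names) if cohort_names is not None else [c.name for c in config.cohorts]
    out = {}
    for name in names:
        t = generate_cohort(config, name)
        t = generate_outcomes(t, config)
        if with_defects:
            t = inject_defects(t, config)
        out[name] = t
    return out
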