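"""Synthetic NHANES-like cohort generation with known ground truth.

The generator emulates the structure of a stratified two-PSU-per-stratum
national examination survey so every pipeline stage is testable without
external data:

* survey design — H strata × 2 PSUs, weights built as inverse inclusion
  probabilities that vary by stratum and age band (so weighted and
  unweighted estimands genuinely differ);
* intakes — per-sex log-normal marginals whose parameters are derived from
  the packaged tertile boundaries (the boundaries are treated as the 1/3
  and 2/3 quantiles of a log-normal), with a shared correlation between
  dietary intakes and total energy; alcohol and serum cotinine are
  zero-inflated;
* outcome — ln(T/S) = α_sex + β_sex·OBS + γ_age·age + N(0, σ), where OBS is
  the participant's oxidative balance score computed with tertiles
  recomputed from the generated sample itself, σ defaults to 0.24 (the
  scale of observed log T/S dispersion in adult cohorts) and β defaults to
  a realistic positive female effect with a null male effect;
* planted exclusion violations — extra rows carrying exactly one violation
  each (missing value, age ≥ 85, pregnancy, failed recall, implausible
  energy), with their ids recorded in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .schema import CutpointSet, OBSSchema, load_default_cutpoints, load_default_schema
from .scoring import compute_cutpoints, compute_obs
from .telomere import ReplicateSet

__all__ = ["SimulationConfig", "GroundTruth", "generate_cohort",
           "generate_replicate_sets"]

#: z-score of the 2/3 quantile of the standard normal
_Z23 = float(stats.norm.ppf(2 / 3))

_ETHNICITY_PROBS = {
    "non_hispanic_white": 0.60,
    "non_hispanic_black": 0.14,
    "mexican_american": 0.20,
    "other_race": 0.03,
    "other_hispanic": 0.03,
}
_EDUCATION_PROBS = {
    "less_than_9th": 0.08,
    "9_11th_grade": 0.14,
    "high_school_or_ged": 0.23,
    "some_college": 0.26,
    "college_graduate": 0.29,
}
_PIR_PROBS = {"le_1.3": 0.19, "1.3_to_3.5": 0.37, "gt_3.5": 0.44}

#: per-sex mean/sd of daily energy intake (kcal) in the emulated population
_ENERGY = {"male": (2477.0, 781.0), "female": (1818.0, 622.0)}
#: sampling envelope for plausible energy, inside the exclusion bounds
_ENERGY_ENVELOPE = {"male": (900.0, 4100.0), "female": (550.0, 3400.0)}


class SimulationConfig(BaseModel):
    """Parameters of one synthetic cohort draw."""

    n: int = Field(1600, ge=8)
    n_strata: int = Field(14, ge=1)
    psus_per_stratum: int = Field(2, ge=2)
    sex_ratio: float = Field(0.5, gt=0, lt=1)  # probability of male
    age_range: tuple[int, int] = (20, 84)
    beta_male: float = 0.0        # ln(T/S) change per OBS point
    beta_female: float = 0.004
    alpha_male: float = 0.13      # ln(T/S) intercepts
    alpha_female: float = 0.05
    gamma_age: float = -0.002     # ln(T/S) change per year of age
    sigma: float = Field(0.24, gt=0)
    energy_rho: float = Field(0.45, ge=-1, le=1)  # dietary intake ↔ energy
    alcohol_zero_prob_male: float = Field(0.40, ge=0, le=1)
    alcohol_zero_prob_female: float = Field(0.55, ge=0, le=1)
    cotinine_zero_prob: float = Field(0.10, ge=0, le=1)
    # planting rates: extra violating rows appended per clean participant
    missing_rate: float = Field(0.0, ge=0, le=1)
    age_over_rate: float = Field(0.0, ge=0, le=1)
    pregnant_rate: float = Field(0.0, ge=0, le=1)
    recall_rate: float = Field(0.0, ge=0, le=1)
    implausible_energy_rate: float = Field(0.0, ge=0, le=1)
    # replicate-set generation
    n_replicate_samples: int = Field(50, ge=0)
    replicate_wells: int = Field(6, ge=3)
    replicate_cv: float = Field(0.065, gt=0)
    outlier_fraction: float = Field(0.1, ge=0, le=1)
    outlier_factor: float = Field(2.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_sizes(self) -> "SimulationConfig":
        if self.n < 8 * self.n_strata:
            raise ValueError("n must be at least 8 × n_strata")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        return self


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    beta: dict[str, float]
    alpha: dict[str, float]
    gamma_age: float
    sigma: float
    obs_true: pd.Series                 # id → OBS of clean participants
    cutpoints: CutpointSet              # tertiles the outcome model used
    violations: dict[str, list[int]]    # step name → planted row ids
    clean_ids: list[int]


def _lognormal_params_from_cutpoints(t1: float, t2: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal whose tertiles are (t1, t2)."""
    mu = 0.5 * (math.log(t1) + math.log(t2))
    sigma = (math.log(t2) - math.log(t1)) / (2 * _Z23)
    return mu, sigma


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _draw_categorical(rng, probs: dict[str, float], size: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=size, p=p)


def generate_cohort(
    config: SimulationConfig,
    schema: OBSSchema | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """One reproducible synthetic cohort plus its ground truth."""
    schema = schema or load_default_schema()
    packaged = load_default_cutpoints()
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = np.where(rng.uniform(size=n) < config.sex_ratio, "male", "female")
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)

    # design: strata round-robin, PSU uniform within stratum
    stratum = rng.permutation(np.arange(n) % config.n_strata)
    psu = rng.integers(1, config.psus_per_stratum + 1, size=n)
    base_p = 0.5 + 0.4 * stratum / max(config.n_strata - 1, 1)
    band_mult = np.where(age < 40, 1.25, np.where(age < 60, 1.0, 0.7))
    weight = 1.0 / (base_p * band_mult)

    energy = np.empty(n)
    z_energy = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        mean, sd = _ENERGY[s]
        lo, hi = _ENERGY_ENVELOPE[s]
        energy[m] = _truncated_normal(rng, mean, sd, lo, hi, m.sum())
        z_energy[m] = (energy[m] - mean) / sd

    data: dict[str, np.ndarray] = {}
    rho = config.energy_rho
    for comp in schema:
        if comp.rule == "fixed_alcohol":
            vals = np.zeros(n)
            for s, p0 in (("male", config.alcohol_zero_prob_male),
                          ("female", config.alcohol_zero_prob_female)):
                m = sex == s
                drink = rng.uniform(size=m.sum()) >= p0
                mu = math.log(12.0 if s == "male" else 6.0)
                draw = np.exp(rng.normal(mu, 1.1, size=m.sum()))
                vals[m] = np.where(drink, draw, 0.0)
            data[comp.name] = vals
            continue
        vals = np.empty(n)
        r = rho if comp.group == "dietary" else 0.0
        for s in ("male", "female"):
            m = sex == s
            mu, sg = _lognormal_params_from_cutpoints(*packaged.lookup(comp.name, s))
            z = r * z_energy[m] + math.sqrt(1 - r * r) * rng.normal(size=m.sum())
            vals[m] = np.exp(mu + sg * z)
        if comp.name == "cotinine":
            vals = np.where(rng.uniform(size=n) < config.cotinine_zero_prob, 0.0, vals)
        data[comp.name] = vals

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "stratum": stratum,
            "psu": psu,
            "weight": weight,
            "sex": sex,
            "age": age.astype(float),
            "ethnicity": _draw_categorical(rng, _ETHNICITY_PROBS, n),
            "education": _draw_categorical(rng, _EDUCATION_PROBS, n),
            "pir": _draw_categorical(rng, _PIR_PROBS, n),
            "energy": energy,
            "crp": np.exp(rng.normal(math.log(0.17), 0.9, size=n)),
            "pregnant": np.zeros(n, dtype=bool),
            "recall_status": np.full(n, "ok", dtype=object),
            **data,
        }
    )

    # outcome built on the score as the analysis will recompute it:
    # tertiles from the generated sample itself
    cutpoints = compute_cutpoints(cohort, schema)
    obs_true = compute_obs(cohort, schema, cutpoints)["obs_total"].astype(float)
    alpha = {"male": config.alpha_male, "female": config.alpha_female}
    beta = {"male": config.beta_male, "female": config.beta_female}
    a = np.where(sex == "male", alpha["male"], alpha["female"])
    b = np.where(sex == "male", beta["male"], beta["female"])
    ln_ts = (
        a + b * obs_true.to_numpy() + config.gamma_age * age
        + rng.normal(0.0, config.sigma, size=n)
    )
    cohort["ltl"] = np.exp(ln_ts)

    violations = _plant_violations(cohort, schema, config, rng)
    planted = [row for rows in violations.values() for row in rows]
    full = pd.concat([cohort] + planted, ignore_index=True) if planted else cohort
    truth = GroundTruth(
        beta=beta,
        alpha=alpha,
        gamma_age=config.gamma_age,
        sigma=config.sigma,
        obs_true=pd.Series(obs_true.to_numpy(), index=cohort["id"].to_numpy()),
        cutpoints=cutpoints,
        violations={k: [int(r["id"].iloc[0]) for r in v] for k, v in violations.items()},
        clean_ids=cohort["id"].tolist(),
    )
    return full, truth


def _plant_violations(cohort, schema, config, rng):
    """Extra single-violation rows cloned from clean participants."""
    n = len(cohort)
    next_id = n
    out: dict[str, list[pd.DataFrame]] = {
        "missing_data": [],
        "age_out_of_range": [],
        "pregnant": [],
        "recall_below_minimum": [],
        "implausible_energy": [],
    }

    def clone() -> pd.DataFrame:
        nonlocal next_id
        row = cohort.iloc[[int(rng.integers(0, n))]].copy()
        row["id"] = next_id
        next_id += 1
        return row

    for _ in range(round(config.missing_rate * n)):
        row = clone()
        row[str(rng.choice(list(schema.names)))] = np.nan
        out["missing_data"].append(row)
    for _ in range(round(config.age_over_rate * n)):
        row = clone()
        row["age"] = float(rng.integers(85, 95))
        out["age_out_of_range"].append(row)
    for _ in range(round(config.pregnant_rate * n)):
        row = clone()
        row["sex"] = "female"
        row["pregnant"] = True
        out["pregnant"].append(row)
    for _ in range(round(config.recall_rate * n)):
        row = clone()
        row["recall_status"] = "below_minimum"
        out["recall_below_minimum"].append(row)
    for _ in range(round(config.implausible_energy_rate * n)):
        row = clone()
        s = str(row["sex"].iloc[0])
        hi = 4200.0 if s == "male" else 3500.0
        lo = 800.0 if s == "male" else 500.0
        row["energy"] = (
            float(rng.uniform(hi + 100, hi + 1500))
            if rng.uniform() < 0.5
            else float(rng.uniform(max(lo - 400, 50), lo - 10))
        )
        out["implausible_energy"].append(row)
    return out


def generate_replicate_sets(
    config: SimulationConfig,
) -> tuple[list[ReplicateSet], list[str]]:
    """Replicate T/S sets with a planted multiplicative outlier fraction.

    Returns (replicate sets, sample ids carrying a planted outlier).  Each
    sample has ``replicate_wells`` values: a log-normal base T/S times
    multiplicative well noise with coefficient of variation
    ``replicate_cv``; in a planted sample one random well is multiplied by
    ``outlier_factor``.
    """
    rng = np.random.default_rng(config.seed + 1)
    sets: list[ReplicateSet] = []
    planted: list[str] = []
    k = config.replicate_wells
    for i in range(config.n_replicate_samples):
        sid = f"S{i:04d}"
        base = math.exp(rng.normal(0.0, 0.2))
        vals = base * np.exp(rng.normal(0.0, config.replicate_cv, size=k))
        if rng.uniform() < config.outlier_fraction:
            j = int(rng.integers(0, k))
            vals[j] *= config.outlier_factor
            planted.append(sid)
        runs = [f"R{i}-{d}" for d in range(k // 2) for _ in (0, 1)]
        runs += [f"R{i}-x"] * (k - len(runs))
        sets.append(ReplicateSet(sample_id=sid, values=vals.tolist(),
                                 run_ids=runs[:k]))
    return sets, planted
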