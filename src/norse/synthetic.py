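"""Synthetic survey-like cohorts with known ground-truth sensitivities.

The generator emulates the statistical structure the NORSE estimators
assume: positive, mutually correlated anthropometrics; an adult age range;
and per-condition prevalence that is (by default) linear in the z-scores of
one or two derived biomarkers, so the normalized sensitivity of every
biomarker in the model is known in closed form and estimator output can be
checked against it exactly.

Anthropometric correlation is induced by a single latent "body size /
adiposity" factor: variable i's log-scale z is lambda_i * f + sqrt(1 -
lambda_i^2) * eps_i, which guarantees a positive semi-definite correlation
structure with corr(i, j) = lambda_i * lambda_j.  Default loadings give
waist-weight r ~ 0.90 and waist-hip r ~ 0.86.  Measurements are log-normal
around sex-specific typical values (cm / kg); trunk fat is a bounded share
of total fat so the two can never cross.  All defaults are invented,
plausible values for a large adult survey — they are not estimates fitted
to any real dataset.

Prevalence links:

* ``linear`` — P(%) = clip(alpha + age_term + g(age) * sum_j beta_j z_j,
  0, 100).  With no age profile, the ground-truth NORSE of biomarker j is
  exactly beta_j (chain rule: prevalence is linear in the z-score).
* ``logistic`` — p = expit(logit(alpha/100) + sum_j beta_j z_j); the
  ground-truth NORSE is the population mean derivative E[100 p(1-p) beta_j],
  evaluated by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import (
    CONDITIONS,
    BiomarkerRegistry,
    default_registry,
    derive_biomarker,
    validate_table,
    zscore,
)

__all__ = [
    "AnthropometricModel",
    "PrevalenceModel",
    "SyntheticConfig",
    "default_prevalence_models",
    "concave_age_profile",
    "generate_population",
    "ground_truth_norse",
]

_VARS = (
    "weight",
    "height",
    "waist_circ",
    "hip_circ",
    "thigh_circ",
    "max_calf_circ",
    "bicep_circ",
    "upper_arm_len",
    "leg_len",
    "total_fat_mass",
    "lean_mass",
)

# typical value (cm / kg) per sex, log-scale SD, factor loading
_DEFAULT_ANTHRO = {
    #                 male   female  log_sd  loading
    "weight":        (85.0,  74.0,   0.18,   0.95),
    "height":        (176.0, 162.0,  0.040,  0.15),
    "waist_circ":    (100.0, 95.0,   0.12,   0.95),
    "hip_circ":      (104.0, 110.0,  0.085,  0.90),
    "thigh_circ":    (53.0,  52.0,   0.10,   0.75),
    "max_calf_circ": (38.5,  37.0,   0.075,  0.70),
    "bicep_circ":    (33.5,  31.0,   0.11,   0.80),
    "upper_arm_len": (37.0,  34.5,   0.045,  0.20),
    "leg_len":       (41.0,  38.0,   0.055,  0.15),
    "total_fat_mass": (25.0, 30.0,   0.35,   0.90),
    "lean_mass":     (57.0,  42.0,   0.11,   0.60),
}


@dataclass(frozen=True)
class AnthropometricModel:
    """Per-sex log-normal location plus shared scale/loading per variable."""

    mean_male: Mapping[str, float]
    mean_female: Mapping[str, float]
    log_sd: Mapping[str, float]
    loading: Mapping[str, float]
    trunk_fat_share: float = 0.40  # central trunk share of total fat
    trunk_fat_share_spread: float = 0.10

    @classmethod
    def default(cls) -> "AnthropometricModel":
        return cls(
            mean_male={k: v[0] for k, v in _DEFAULT_ANTHRO.items()},
            mean_female={k: v[1] for k, v in _DEFAULT_ANTHRO.items()},
            log_sd={k: v[2] for k, v in _DEFAULT_ANTHRO.items()},
            loading={k: v[3] for k, v in _DEFAULT_ANTHRO.items()},
        )

    def __post_init__(self):
        for name, lam in self.loading.items():
            if not -1.0 <= lam <= 1.0:
                raise ValueError(
                    f"loading for {name!r} must lie in [-1, 1] "
                    "(single-factor correlation model)"
                )


@dataclass(frozen=True)
class PrevalenceModel:
    """One condition's generative risk model.

    ``betas`` maps registry biomarker names to coefficients in percentage
    points of prevalence per standard deviation of the biomarker (linear
    link) or log-odds per SD (logistic link).  ``alpha`` is the baseline
    prevalence in percent at the population mean.  ``age_profile``, if set,
    multiplies every beta by g(age); ``alpha_age`` adds a linear-in-age
    percentage-point trend to the baseline.
    """

    alpha: float
    betas: Mapping[str, float] = field(default_factory=dict)
    link: str = "linear"
    age_profile: Callable[[np.ndarray], np.ndarray] | None = None
    alpha_age: float = 0.0

    def __post_init__(self):
        if self.link not in ("linear", "logistic"):
            raise ValueError(f"link must be 'linear' or 'logistic', got {self.link!r}")


def concave_age_profile(peak: float = 55.0, half_width: float = 35.0):
    """Concave slope modulation g(age) = max(0, 1 - ((age-peak)/half_width)^2).

    Mirrors the low-high-low shape of sensitivity over age: risk in the
    young is low regardless of the biomarker, and in the elderly high
    regardless, so the slope peaks in mid-life.
    """

    def g(age):
        age = np.asarray(age, dtype=float)
        return np.clip(1.0 - ((age - peak) / half_width) ** 2, 0.0, None)

    return g


def default_prevalence_models() -> dict[str, PrevalenceModel]:
    """Plausible per-condition models: abdominal measures raise risk, and
    residual weight at fixed waist (a lean-mass proxy) lowers it."""
    return {
        "hypertension": PrevalenceModel(32.0, {"Waist circ": 8.0, "Weight": -3.0}),
        "arthritis": PrevalenceModel(25.0, {"BMI": 5.0}),
        "diabetes": PrevalenceModel(10.0, {"Waist circ": 5.0, "Weight": -2.0}),
        "high_cholesterol": PrevalenceModel(30.0, {"WHR": 6.0}),
        "coronary_heart_disease": PrevalenceModel(6.0, {"Waist circ": 2.5, "Weight": -1.0}),
        "cancer": PrevalenceModel(9.0, {"Waist circ": 1.5}),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification; identical config + seed gives
    bit-identical cohorts."""

    n: int = 10_000  # participants per sex
    seed: int = 0
    anthropometry: AnthropometricModel = field(default_factory=AnthropometricModel.default)
    prevalence: Mapping[str, PrevalenceModel] = field(default_factory=default_prevalence_models)
    age_range: tuple[float, float] = (20.0, 80.0)
    missingness: Mapping[str, float] = field(default_factory=dict)
    smoker_rate: float = 0.4
    sexes: tuple[str, ...] = ("male", "female")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def _draw_sex(
    cfg: SyntheticConfig, sex: str, rng: np.random.Generator, start_id: int
) -> pd.DataFrame:
    am = cfg.anthropometry
    means = am.mean_male if sex == "male" else am.mean_female
    n = cfg.n
    f = rng.standard_normal(n)
    data: dict[str, np.ndarray] = {}
    for var in _VARS:
        lam = am.loading[var]
        z = lam * f + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
        data[var] = means[var] * np.exp(am.log_sd[var] * z)
    share = am.trunk_fat_share + am.trunk_fat_share_spread * np.tanh(
        rng.standard_normal(n) / 2.0
    )
    data["trunk_fat_mass"] = share * data["total_fat_mass"]
    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi, n)
    df = pd.DataFrame(data)
    df.insert(0, "participant_id", np.arange(start_id, start_id + n))
    df.insert(1, "sex", sex)
    df.insert(2, "age", age)
    df["smoker_flag"] = (rng.random(n) < cfg.smoker_rate).astype(float)
    return df


def _percent_prevalence(
    model: PrevalenceModel, zmat: Mapping[str, np.ndarray], age: np.ndarray
) -> np.ndarray:
    lin = np.zeros_like(age)
    for name, beta in model.betas.items():
        lin = lin + beta * zmat[name]
    if model.age_profile is not None:
        lin = model.age_profile(age) * lin
    if model.link == "linear":
        p = model.alpha + model.alpha_age * (age - np.mean(age)) + lin
        return np.clip(p, 0.0, 100.0)
    from scipy.special import expit, logit

    base = logit(np.clip(model.alpha / 100.0, 1e-9, 1 - 1e-9))
    return 100.0 * expit(base + model.alpha_age * (age - np.mean(age)) + lin)


def _condition_zscores(
    df: pd.DataFrame, names: Sequence[str], registry: BiomarkerRegistry
) -> dict[str, np.ndarray]:
    out = {}
    for name in names:
        vec = zscore(derive_biomarker(df, name, registry))
        out[name] = vec.zscores.to_numpy(dtype=float)
    return out


def generate_population(
    config: SyntheticConfig, registry: BiomarkerRegistry | None = None
) -> pd.DataFrame:
    """Draw a cohort: anthropometrics, age, smoker and condition flags.

    Condition flags are Bernoulli draws from the per-participant prevalence,
    computed from z-scores standardized within sex over the full generated
    cohort (the same convention the estimation pipeline uses).  Missingness
    is applied last, completely at random per field.
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(config.seed)
    frames = []
    for i, sex in enumerate(config.sexes):
        df = _draw_sex(config, sex, rng, start_id=i * config.n)
        needed = sorted({b for m in config.prevalence.values() for b in m.betas})
        zmat = _condition_zscores(df, needed, registry)
        age = df["age"].to_numpy()
        for cond in CONDITIONS:
            model = config.prevalence.get(cond)
            if model is None:
                df[cond] = np.nan
                continue
            p = _percent_prevalence(model, zmat, age) / 100.0
            df[cond] = (rng.random(config.n) < p).astype(float)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for colname, rate in config.missingness.items():
        if rate <= 0:
            continue
        if colname not in out.columns:
            raise KeyError(f"missingness refers to unknown column {colname!r}")
        hole = rng.random(len(out)) < rate
        out.loc[hole, colname] = np.nan
    return validate_table(out)


def ground_truth_norse(
    config: SyntheticConfig,
    biomarker: str,
    condition: str,
    age_range: tuple[float, float] | None = None,
    n_mc: int = 100_000,
    registry: BiomarkerRegistry | None = None,
) -> float:
    """Analytic (linear link) or Monte Carlo (logistic) true NORSE.

    For the linear link the prevalence is alpha + beta * z, so the
    percentage-point change per SD of the biomarker is beta itself — scaled
    by the mean of the age profile over ``age_range`` when one is set.  A
    biomarker absent from the condition's model has true NORSE 0.  The
    logistic value averages the pointwise derivative 100 p(1-p) beta over a
    fresh cohort drawn with a seed derived from the config's.
    """
    model = config.prevalence.get(condition)
    if model is None:
        raise KeyError(f"no prevalence model for condition {condition!r}")
    beta = model.betas.get(biomarker, 0.0)
    if beta == 0.0:
        return 0.0
    lo, hi = age_range if age_range is not None else config.age_range
    lo = max(lo, config.age_range[0])
    hi = min(hi, config.age_range[1])
    if model.link == "linear":
        if model.age_profile is None:
            return float(beta)
        grid = np.linspace(lo, hi, 2001)  # age is uniform on its range
        return float(beta * np.mean(model.age_profile(grid)))
    # logistic: population-average derivative by Monte Carlo
    registry = registry if registry is not None else default_registry()
    mc_cfg = config.with_(n=n_mc // 2, seed=(config.seed + 1) % (2**31), missingness={})
    rng_check = np.random.default_rng(mc_cfg.seed)
    frames = []
    for i, sex in enumerate(mc_cfg.sexes):
        frames.append(_draw_sex(mc_cfg, sex, rng_check, start_id=i * mc_cfg.n))
    vals = []
    for df in frames:
        keep = (df["age"] >= lo) & (df["age"] <= hi)
        zmat = _condition_zscores(df, sorted(model.betas), registry)
        p = _percent_prevalence(model, zmat, df["age"].to_numpy()) / 100.0
        g = 1.0 if model.age_profile is None else model.age_profile(df["age"].to_numpy())
        deriv = 100.0 * p * (1.0 - p) * beta * g
        vals.append(deriv[keep.to_numpy()])
    return float(np.concatenate(vals).mean())
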