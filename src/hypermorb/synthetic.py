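"""Synthetic periodontitis cohorts with known, planted structure.

Every downstream stage of the pipeline is exercised on cohorts generated
here, so the generator gives exact control over the quantities the
analysis is supposed to recover:

* **Marginal prevalences** — disease flags are obtained by thresholding a
  latent Gaussian score at the quantile matching the target prevalence,
  so the expected empirical prevalence equals the target exactly.
* **Planted co-occurrence clusters** — each planted cluster contributes
  one shared standard-normal factor per participant; a disease's latent
  score is the strength-weighted sum of the factors of the clusters it
  belongs to plus independent standard-normal noise. Association between
  two diseases is monotone in the strengths of their shared clusters and
  zero when they share none.
* **CAL extent** — a logistic-transformed Gaussian with additive
  covariate effects (smoking, ethnicity, income) on the logit scale,
  which keeps extent in [0, 1] with realistic skew.
* **Missingness** — applied per field, completely at random, after
  generation.

Default demographic and prevalence parameters emulate a matched
NHANES-style periodontal cohort (mean age ~58, 58% female, hypertension
prevalence 0.639, ...). Obesity is special-cased: its flag is drawn from
the same latent model, then a BMI consistent with the flag is generated,
so that deriving obesity from BMI downstream reproduces the flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .catalog import DEFAULT_DISEASES, DiseaseCatalog
from .cohort import CYCLE_LEVELS, CohortTable, OBESITY_BMI_THRESHOLD
from .errors import ConfigurationError

#: Overall disease prevalences of the emulated matched cohort.
DEFAULT_PREVALENCE: dict[str, float] = {
    "diabetes": 0.218,
    "cancer": 0.159,
    "heart_attack": 0.049,
    "coronary_heart_disease": 0.045,
    "congestive_heart_failure": 0.035,
    "angina": 0.030,
    "stroke": 0.052,
    "hypertension": 0.639,
    "arthritis": 0.476,
    "liver_disease": 0.064,
    "osteoporosis": 0.110,
    "thyroid_disorder": 0.189,
    "emphysema": 0.023,
    "bronchitis": 0.083,
    "obesity": 0.459,
}

#: Planted clusters (disease subset, association strength). The defaults put
#: the three high-prevalence conditions in overlapping clusters so that the
#: hypertension-obesity pair dominates, as in real multimorbidity cohorts.
DEFAULT_CLUSTERS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("hypertension", "obesity"), 1.0),
    (("hypertension", "arthritis"), 0.6),
    (("diabetes", "hypertension", "obesity"), 0.5),
)

#: Per-field completely-at-random missingness fractions of the emulated survey
#: (diagnosis questions mostly ~0.1-4%; osteoporosis was not asked in one of
#: three cycles, hence ~35%). Obesity missingness arises through missing BMI.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "bmi": 0.010,
    "income_quintile": 0.096,
    "smoker": 0.001,
    "diabetes": 0.038,
    "hypertension": 0.001,
    "arthritis": 0.002,
    "congestive_heart_failure": 0.002,
    "coronary_heart_disease": 0.004,
    "angina": 0.003,
    "heart_attack": 0.001,
    "stroke": 0.001,
    "emphysema": 0.001,
    "bronchitis": 0.002,
    "liver_disease": 0.002,
    "thyroid_disorder": 0.003,
    "osteoporosis": 0.354,
}


@dataclass(frozen=True)
class CalExtentModel:
    """Logistic-Gaussian model for the proportion of sites with CAL >= 3 mm.

    ``extent = expit(logit(baseline_mean) + effects + noise)`` where the
    additive logit-scale effects are ``smoker_effect`` for smokers,
    ``ethnicity_other_effect`` for non-white participants and
    ``income_effect_per_quintile * (3 - quintile)`` (lower income, higher
    extent).
    """

    baseline_mean: float = 0.20
    smoker_effect: float = 0.6
    ethnicity_other_effect: float = 0.4
    income_effect_per_quintile: float = 0.15
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_mean < 1.0):
            raise ConfigurationError("cal_extent baseline mean must be in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("cal_extent noise sd must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic cohort; generation is a pure function of it."""

    n_participants: int = 2000
    disease_names: tuple[str, ...] = DEFAULT_DISEASES
    marginal_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    planted_clusters: tuple[tuple[tuple[str, ...], float], ...] = DEFAULT_CLUSTERS
    age_mean: float = 58.16
    age_sd: float = 13.22
    age_min: int = 30
    sex_proportion_female: float = 0.577
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"white": 0.461, "other": 0.539})
    income_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.157, 2: 0.153, 3: 0.219, 4: 0.208, 5: 0.263})
    smoker_probs: Mapping[str, float] = field(
        default_factory=lambda: {"yes": 0.474, "no": 0.526})
    cycle_probs: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 / 3.0 for c in CYCLE_LEVELS})
    cal_extent_model: CalExtentModel = CalExtentModel()
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if not self.disease_names:
            raise ConfigurationError("disease list must not be empty")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ConfigurationError("disease names must be distinct")
        for d in self.disease_names:
            p = self.marginal_prevalence.get(d)
            if p is None:
                raise ConfigurationError(f"no marginal prevalence given for {d!r}")
            _check_prob(p, f"prevalence of {d!r}")
        for diseases, strength in self.planted_clusters:
            if strength < 0:
                raise ConfigurationError("cluster association strength must be >= 0")
            unknown = [d for d in diseases if d not in self.disease_names]
            if unknown:
                raise ConfigurationError(
                    f"planted cluster mentions unknown disease(s) {unknown}")
        _check_prob(self.sex_proportion_female, "sex_proportion_female")
        for name, levels in (("ethnicity", self.ethnicity_probs),
                             ("income", self.income_probs),
                             ("smoker", self.smoker_probs),
                             ("cycle", self.cycle_probs)):
            for lev, p in levels.items():
                _check_prob(p, f"{name} level {lev!r}")
            if abs(sum(levels.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} level probabilities must sum to 1")
        for fld, p in self.missingness.items():
            _check_prob(p, f"missingness of {fld!r}")
        if self.age_sd < 0:
            raise ConfigurationError("age sd must be non-negative")


def _check_prob(p: float, what: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{what} must be a probability in [0, 1], got {p}")


def _draw_levels(rng: np.random.Generator, levels: Mapping, n: int) -> np.ndarray:
    keys = list(levels.keys())
    probs = np.array([levels[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=n, p=probs / probs.sum())
    return np.array(keys, dtype=object)[idx]


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Generate a cohort table from a :class:`SyntheticConfig`.

    Deterministic: identical configs (including seed) give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    diseases = list(config.disease_names)

    ids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    age = np.maximum(np.rint(rng.normal(config.age_mean, config.age_sd, n)),
                     config.age_min).astype(int)
    sex = np.where(rng.random(n) < config.sex_proportion_female, "female", "male")
    ethnicity = _draw_levels(rng, config.ethnicity_probs, n)
    income = _draw_levels(rng, config.income_probs, n).astype(float)
    smoker = _draw_levels(rng, config.smoker_probs, n)
    cycle = _draw_levels(rng, config.cycle_probs, n)

    # latent-factor disease flags
    factors = rng.standard_normal((len(config.planted_clusters), n))
    flags = np.zeros((n, len(diseases)), dtype=float)
    for j, d in enumerate(diseases):
        score = rng.standard_normal(n)
        var = 1.0
        for c, (members, strength) in enumerate(config.planted_clusters):
            if d in members:
                score = score + strength * factors[c]
                var += strength ** 2
        p = config.marginal_prevalence[d]
        threshold = np.sqrt(var) * norm.isf(p)  # P(score > threshold) = p
        flags[:, j] = (score > threshold).astype(float)

    # BMI consistent with the latent obesity flag
    if "obesity" in diseases:
        obese = flags[:, diseases.index("obesity")] == 1
        above = OBESITY_BMI_THRESHOLD + np.abs(rng.normal(0.0, 5.5, n))
        below = np.maximum(OBESITY_BMI_THRESHOLD - 1e-6 - np.abs(rng.normal(0.0, 4.5, n)), 16.0)
        bmi = np.where(obese, above, below)
    else:
        bmi = np.clip(rng.normal(28.0, 6.0, n), 16.0, 60.0)

    m = config.cal_extent_model
    lin = np.full(n, logit(m.baseline_mean))
    lin += np.where(smoker == "yes", m.smoker_effect, 0.0)
    lin += np.where(ethnicity == "other", m.ethnicity_other_effect, 0.0)
    lin += m.income_effect_per_quintile * (3.0 - income)
    cal = expit(lin + rng.normal(0.0, m.noise_sd, n))

    frame = pd.DataFrame({
        "participant_id": ids,
        "age": age,
        "sex": sex,
        "ethnicity": ethnicity,
        "income_quintile": income,
        "smoker": smoker,
        "cycle": cycle,
        "bmi": bmi,
        "cal_extent": cal,
    })
    for j, d in enumerate(diseases):
        frame[d] = flags[:, j]

    # per-field MCAR missingness, applied after generation
    for fld in sorted(config.missingness):
        p_miss = config.missingness[fld]
        if p_miss == 0.0 or fld not in frame.columns:
            continue
        mask = rng.random(n) < p_miss
        if fld in ("sex", "ethnicity", "smoker", "cycle"):
            frame.loc[mask, fld] = None
        else:
            frame.loc[mask, fld] = np.nan

    # obesity is derived from BMI, so a missing BMI hides the obesity flag
    if "obesity" in diseases:
        frame["obesity"] = np.where(frame["bmi"].isna(), np.nan,
                                    (frame["bmi"] >= OBESITY_BMI_THRESHOLD).astype(float))

    catalog = DiseaseCatalog(tuple(diseases))
    return CohortTable(frame=frame, catalog=catalog)


def pairwise_odds_ratio(table: CohortTable, disease_a: str, disease_b: str) -> float:
    """Empirical odds ratio of co-occurrence from the 2x2 contingency table.

    Computed on binarized flags under the table's missing policy, with a
    0.5 continuity correction in every cell.
    """
    matrix = table.binarize()
    a = matrix[:, table.catalog.index(disease_a)].astype(bool)
    b = matrix[:, table.catalog.index(disease_b)].astype(bool)
    n11 = np.sum(a & b) + 0.5
    n10 = np.sum(a & ~b) + 0.5
    n01 = np.sum(~a & b) + 0.5
    n00 = np.sum(~a & ~b) + 0.5
    return float((n11 * n00) / (n10 * n01))
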