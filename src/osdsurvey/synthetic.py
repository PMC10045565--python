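"""Synthetic survey-respondent generator with known ground truth.

Emulates the statistical structure the analyses assume, with every
generating parameter exposed and recorded so that recovery can be tested:

* attitude items (Trust, Hype, GM) drawn from a Gaussian copula over a
  shared scepticism factor, discretised onto the 5-point scale by the
  configured class probabilities (so the Hype/Trust rank correlation is
  approximately ``hype_trust_corr``);
* a latent confidence ``c = base + curvature * trust^2 + ...`` that links
  attitude extremity to self-assessed understanding (the U shape), emitted
  through the six ordinal items as binomial draws with ``p = c`` so the
  subjective score is conditionally unbiased for ``c``;
* a latent per-item accuracy rising linearly in attitude
  (``knowledge_slope`` on the knowledge-score scale), emitted as the twelve
  true/false answers against the embedded answer key;
* an overconfident subgroup (fraction ``overconfident_fraction``) whose
  accuracy is pushed down and confidence up, creating the low-knowledge /
  high-subjective pool;
* covariates (age, religiosity, education, ten political items with
  missingness, sex, vaccine stance) with plausible cross-correlations and
  mild links into confidence/accuracy.

All draws come from one ``numpy.random.default_rng(seed)``; identical
config and seed give identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ParameterError
from .scoring import DEFAULT_ANSWER_KEY

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_respondents",
           "write_respondents", "write_truth"]

#: Fixed per-item difficulty offsets (accuracy scale) for the 12 knowledge
#: items; spread keeps the items informative without ceiling effects.
KNOW_ITEM_DIFFICULTY = np.linspace(-0.11, 0.11, 12)

#: Theoretical maxima of the six subjective items.
_SUBJ_MAXIMA = np.array([3, 3, 4, 4, 4, 4])

_DEFAULT_COVARIATE_PARAMS = {
    "age_mean": 48.0, "age_sd": 17.0, "age_min": 18, "age_max": 95,
    "education_probs": (0.25, 0.45, 0.30),     # none / non-degree / degree
    "religiosity_probs": (0.50, 0.30, 0.20),   # none / lapsed / practicing
    # latent correlations among (education, age, religiosity, politics)
    "corr_edu_age": -0.14, "corr_edu_rel": 0.04, "corr_edu_pol": -0.26,
    "corr_age_rel": 0.20, "corr_age_pol": 0.24, "corr_rel_pol": 0.17,
    # links into confidence (subjective scale) and accuracy (probability)
    "conf_edu": 0.04, "conf_rel": -0.01,
    "accuracy_edu": 0.08, "accuracy_rel": -0.02, "accuracy_pol": -0.02,
    "accuracy_age": 0.02,
    "political_item_noise_sd": 0.8,
    "sex_male_rate": 0.48,
    # log-odds of being male per unit of Trust attitude strength
    "sex_extremity": 0.25,
    # vaccine stance: base shares (taken / will take / will not / prefer
    # not to say) plus age and overconfidence effects on declining
    "vaccine_base_probs": (0.85, 0.08, 0.045, 0.025),
    "vaccine_age_effect": -0.9, "vaccine_overconf_effect": 2.0,
}


@dataclass
class SyntheticConfig:
    """Generating parameters; defaults are the package's study conditions.

    ``curvature`` is the quadratic coefficient linking Trust attitude to the
    mean subjective score (0..1 scale per squared attitude unit);
    ``knowledge_slope`` the linear coefficient linking attitude to the mean
    knowledge score (-1..1 scale per attitude unit).
    ``attitude_class_probs`` orders classes -2..+2 (strong reject first).
    """

    n_respondents: int = 2051
    curvature: float = 0.15
    knowledge_slope: float = 0.10
    overconfident_fraction: float = 0.05
    attitude_class_probs: tuple = (0.02, 0.12, 0.34, 0.35, 0.17)
    hype_trust_corr: float = 0.44
    gm_corr: float = 0.20
    base_subjective: float = 0.30
    confidence_noise_sd: float = 0.06
    base_accuracy: float = 0.70
    ability_noise_sd: float = 0.12
    overconfident_boost: float = 0.25   # confidence shift of the subgroup
    overconfident_drop: float = 0.20    # accuracy shift of the subgroup
    missing_rate_political: float = 0.03
    covariate_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if int(self.n_respondents) < 1:
            raise ParameterError("n_respondents must be >= 1")
        probs = np.asarray(self.attitude_class_probs, dtype=float)
        if probs.size != 5 or np.any(probs < 0):
            raise ParameterError(
                "attitude_class_probs must be 5 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ParameterError("attitude_class_probs must sum to 1")
        for name in ("overconfident_fraction", "missing_rate_political"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("hype_trust_corr", "gm_corr"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [-1, 1], got {v}")
        if self.curvature < 0:
            raise ParameterError("curvature must be >= 0")
        for name in ("confidence_noise_sd", "ability_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        unknown = set(self.covariate_params) - set(_DEFAULT_COVARIATE_PARAMS)
        if unknown:
            raise ParameterError(f"unknown covariate_params: {sorted(unknown)}")

    @property
    def covariates(self) -> dict:
        return {**_DEFAULT_COVARIATE_PARAMS, **self.covariate_params}


@dataclass
class SyntheticTruth:
    """Realised generating parameters and per-respondent latent traits."""

    config: SyntheticConfig
    latents: pd.DataFrame  #: confidence, accuracy, overconfident, z_* latents

    def __post_init__(self):
        assert len(self.latents) == self.config.n_respondents


def _spearman_to_pearson(r_s: float) -> float:
    """Latent Pearson correlation giving Spearman ``r_s`` for a Gaussian
    copula (exact for continuous margins)."""
    return 2.0 * np.sin(np.pi * r_s / 6.0)


def _discretise(z: np.ndarray, probs) -> np.ndarray:
    """Map standard-normal draws to ordinal classes with given probabilities
    (first class = lowest z)."""
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    return np.searchsorted(cuts, z, side="left")


def generate_respondents(config: SyntheticConfig,
                         ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic respondent table plus its ground truth.

    The returned table carries raw item-level columns only (``trust_raw``,
    ``hype_raw``, ``gm_raw``, ``subj_q1..6``, ``know_q1..12``,
    ``pol_q1..10``, ``age``, ``religiosity``, ``education``, ``sex``,
    ``vaccine_status``); scores are derived downstream by the scoring
    module.
    """
    if not isinstance(config, SyntheticConfig):
        config = SyntheticConfig(**config)
    cov = config.covariates
    n = int(config.n_respondents)
    rng = np.random.default_rng(config.seed)

    # --- attitudes via Gaussian copula over a shared scepticism factor
    r_th = _spearman_to_pearson(config.hype_trust_corr)
    r_g = _spearman_to_pearson(config.gm_corr)
    R_att = np.array([[1.0, r_th, r_g],
                      [r_th, 1.0, r_g],
                      [r_g, r_g, 1.0]])
    z_att = rng.multivariate_normal(np.zeros(3), R_att, size=n,
                                    method="cholesky")
    probs = np.asarray(config.attitude_class_probs, dtype=float)
    trust = _discretise(z_att[:, 0], probs) - 2
    hype = _discretise(z_att[:, 1], probs) - 2
    gm = _discretise(z_att[:, 2], probs) - 2

    # --- covariates from a second latent Gaussian (edu, age, rel, pol)
    R_cov = np.array(
        [[1.0, cov["corr_edu_age"], cov["corr_edu_rel"], cov["corr_edu_pol"]],
         [cov["corr_edu_age"], 1.0, cov["corr_age_rel"], cov["corr_age_pol"]],
         [cov["corr_edu_rel"], cov["corr_age_rel"], 1.0, cov["corr_rel_pol"]],
         [cov["corr_edu_pol"], cov["corr_age_pol"], cov["corr_rel_pol"], 1.0]])
    z_cov = rng.multivariate_normal(np.zeros(4), R_cov, size=n,
                                    method="cholesky")
    edu_z, age_z, rel_z, pol_z = z_cov.T
    age = np.clip(np.round(cov["age_mean"] + cov["age_sd"] * age_z),
                  cov["age_min"], cov["age_max"]).astype(int)
    education = _discretise(edu_z, cov["education_probs"])
    religiosity = _discretise(rel_z, cov["religiosity_probs"])

    # --- overconfident subgroup
    overconf = rng.random(n) < config.overconfident_fraction

    # --- latent confidence -> six subjective items (binomial emission)
    conf = (config.base_subjective
            + config.curvature * trust.astype(float) ** 2
            + cov["conf_edu"] * edu_z + cov["conf_rel"] * rel_z
            + config.overconfident_boost * overconf
            + rng.normal(0.0, config.confidence_noise_sd, n))
    conf_p = np.clip(conf, 0.0, 1.0)
    subj = {f"subj_q{i + 1}": rng.binomial(m, conf_p)
            for i, m in enumerate(_SUBJ_MAXIMA)}

    # --- latent accuracy -> twelve true/false answers
    accuracy = (config.base_accuracy
                + 0.5 * config.knowledge_slope * trust.astype(float)
                + cov["accuracy_edu"] * edu_z + cov["accuracy_rel"] * rel_z
                + cov["accuracy_pol"] * pol_z + cov["accuracy_age"] * age_z
                - config.overconfident_drop * overconf
                + rng.normal(0.0, config.ability_noise_sd, n))
    key = np.asarray(DEFAULT_ANSWER_KEY, dtype=bool)
    know = {}
    for i in range(12):
        p_i = np.clip(accuracy + KNOW_ITEM_DIFFICULTY[i], 0.02, 0.98)
        correct = rng.random(n) < p_i
        know[f"know_q{i + 1}"] = np.where(correct, key[i], ~key[i])

    # --- ten political items: coded (right-wing-positive) latent,
    #     re-expressed as raw agreement per the questionnaire's direction
    pol_items = {}
    for j in range(10):
        coded = np.clip(np.round(
            1.1 * (pol_z + rng.normal(0.0, cov["political_item_noise_sd"], n))
        ), -2, 2)
        raw = coded if j >= 6 else -coded  # items 1-6: agreement = left
        miss = rng.random(n) < config.missing_rate_political
        pol_items[f"pol_q{j + 1}"] = np.where(miss, np.nan, raw)

    # --- sex, with men mildly over-represented at attitude extremes
    base_logit = np.log(cov["sex_male_rate"] / (1 - cov["sex_male_rate"]))
    p_male = 1.0 / (1.0 + np.exp(-(base_logit
                                   + cov["sex_extremity"] * np.abs(trust))))
    sex = np.where(rng.random(n) < p_male, "male", "female")

    # --- vaccine stance: decliners younger and more overconfident
    base = np.log(np.asarray(cov["vaccine_base_probs"], dtype=float))
    logits = np.tile(base, (n, 1))
    overconf_latent = conf_p - accuracy
    logits[:, 2] += (cov["vaccine_age_effect"] * age_z
                     + cov["vaccine_overconf_effect"] * overconf_latent)
    logits[:, 3] += 0.5 * cov["vaccine_overconf_effect"] * overconf_latent
    expl = np.exp(logits - logits.max(axis=1, keepdims=True))
    pvac = expl / expl.sum(axis=1, keepdims=True)
    u = rng.random(n)
    vac_idx = (u[:, None] > np.cumsum(pvac, axis=1)).sum(axis=1)
    vaccine = np.array(["taken", "will_take", "will_not",
                        "prefer_not_say"])[vac_idx]

    records = pd.DataFrame({
        "trust_raw": trust, "hype_raw": hype, "gm_raw": gm,
        "vaccine_status": vaccine,
        **subj, **know,
        "age": age, "religiosity": religiosity, "education": education,
        **pol_items,
        "sex": sex,
    })
    latents = pd.DataFrame({
        "confidence": conf_p, "accuracy": accuracy,
        "overconfident": overconf,
        "z_trust": z_att[:, 0], "z_hype": z_att[:, 1], "z_gm": z_att[:, 2],
        "edu_z": edu_z, "age_z": age_z, "rel_z": rel_z, "pol_z": pol_z,
    })
    return records, SyntheticTruth(config=config, latents=latents)


def write_respondents(records: pd.DataFrame, path) -> None:
    """Write the respondent table as comma-separated text with a header."""
    records.to_csv(path, index=False)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the ground truth as a structured-text (JSON) sidecar."""
    payload = {
        "config": dataclasses.asdict(truth.config),
        "latents": {c: truth.latents[c].tolist()
                    for c in truth.latents.columns},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
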