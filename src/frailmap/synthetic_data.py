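"""Synthetic survey, area, vaccination and risk-factor data with known truth.

The generator emulates the shapes of the restricted inputs used in
small-area frailty / vaccination-equity studies of England: a national
ageing-survey sample of adults 50+ (with design/non-response weights and missing
deficit items), area-level age-sex population tables keyed by deprivation
rank, first-dose vaccination counts from an age-based (frailty-blind)
roll-out, and area risk-factor diagnosis counts.

Generative model for deficits
-----------------------------
Respondent *i* has a latent propensity ``u_i ~ Normal(0, sigma_u^2)`` and
deficit probability ``pi_i = expit(alpha + gamma_age[a_i] + gamma_sex*s_i +
gamma_imd[q_i] + u_i)``; the D deficit items are iid Bernoulli(pi_i) given
u_i.  This is deliberately the simplest process that produces a graded
frailty-index distribution with age, sex and deprivation gradients; it is a
documented stand-in, not an empirical model of any survey.

Non-response follows a logistic propensity in age band and deprivation
quintile whose intercept is calibrated (root-finding on the realised
sample) so the expected non-response rate equals ``nonresponse_target``.
Supplied weights are the truth-based inverse response propensities,
rescaled to mean 1 over responders, mirroring surveys that ship weights
with the data.  Item missingness is MAR on age band only.

Ground truth comes in two independent flavours: exact stratum category
probabilities by Gauss-Hermite quadrature over the propensity distribution
(``true_stratum_probs``, used to fill :class:`SimulationTruth`) and a
brute-force Monte-Carlo oracle (``oracle_stratum_probs``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import binom

from .area_estimation import imd_rank_to_quintile
from .frailty_index import CutPoints
from .strata import AGE_BANDS, CATEGORIES, SEXES, stratum_grid

__all__ = [
    "GeneratorConfig",
    "SimulationTruth",
    "RISK_FACTORS",
    "generate_survey",
    "generate_areas",
    "oracle_stratum_probs",
    "true_stratum_probs",
    "true_area_counts",
]

#: The seven area-level risk factors tabulated alongside frailty.
RISK_FACTORS: tuple[str, ...] = (
    "atrial_fibrillation",
    "chronic_kidney_disease",
    "diabetes",
    "learning_disabilities",
    "obesity",
    "smoking_current",
    "smoking_former",
)

# survey age-band distribution: decreasing with age, ~6.3% aged 85+
_SURVEY_AGE_DIST = (
    0.165, 0.160, 0.150, 0.140, 0.125, 0.105, 0.092, 0.044, 0.019,
)
# area population age shares (population pyramids thin faster than survey
# samples of the same ages)
_POP_AGE_DIST = (0.22, 0.19, 0.16, 0.14, 0.12, 0.08, 0.05, 0.03, 0.01)
_FEMALE_SHARE = 0.52

# non-response propensity offsets (logit scale): response declines with age
# and with deprivation; the intercept is calibrated at generation time
_RESP_AGE_OFFSET = (0.0, -0.05, -0.10, -0.15, -0.20, -0.30, -0.40, -0.55, -0.70)
_RESP_IMD_OFFSET = (-0.40, -0.25, -0.15, -0.05, 0.0)  # quintile 1 = most deprived

# item-missingness age factors (relative; normalised against the survey age
# distribution so the marginal rate matches item_missing_rate)
_MISS_AGE_FACTOR = (0.60, 0.73, 0.85, 0.98, 1.10, 1.23, 1.35, 1.48, 1.60)

# per-factor baseline prevalence among the 50+ population
_RISK_BASE_PREV = {
    "atrial_fibrillation": 0.045,
    "chronic_kidney_disease": 0.09,
    "diabetes": 0.17,
    "learning_disabilities": 0.012,
    "obesity": 0.28,
    "smoking_current": 0.12,
    "smoking_former": 0.33,
}


def _default_gamma_age() -> tuple[float, ...]:
    return (0.0, 0.07, 0.14, 0.22, 0.30, 0.38, 0.48, 0.58, 0.68)


def _default_gamma_imd() -> tuple[float, ...]:
    # quintile 1 (most deprived) carries the largest deficit excess
    return (0.22, 0.16, 0.10, 0.05, 0.0)


def _default_dose_uptake() -> tuple[float, ...]:
    # age-based roll-out part-way through: near-complete 70+, partial 50s
    return (0.28, 0.33, 0.45, 0.70, 0.88, 0.93, 0.95, 0.96, 0.96)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    ``alpha`` is the baseline deficit log-odds for the reference respondent
    (age 50-54, male, least-deprived quintile, u = 0); its default is
    calibrated so the population category mix is roughly 52% robust, 34%
    pre-frail, 14% frail, in line with deficit-accumulation prevalences
    reported for English older adults.
    """

    n_respondents: int = 8355
    n_areas: int = 135
    n_deficits: int = 30
    alpha: float = -1.5
    gamma_age: tuple[float, ...] = field(default_factory=_default_gamma_age)
    gamma_sex: float = 0.06
    gamma_imd: tuple[float, ...] = field(default_factory=_default_gamma_imd)
    sigma_u: float = 0.2
    nonresponse_target: float = 0.176
    item_missing_rate: float = 0.05
    dose_uptake: tuple[float, ...] = field(default_factory=_default_dose_uptake)
    risk_depr_coef: float = 0.15
    area_pop_mean: float = 160_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [
            self.alpha, self.gamma_sex, self.sigma_u,
            self.nonresponse_target, self.item_missing_rate,
            self.risk_depr_coef, self.area_pop_mean,
            *self.gamma_age, *self.gamma_imd, *self.dose_uptake,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("all generator parameters must be finite")
        if self.n_deficits < 1:
            raise ValueError("n_deficits must be >= 1")
        if self.n_areas < 5:
            raise ValueError("n_areas must be >= 5")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        for name, p in (
            ("nonresponse_target", self.nonresponse_target),
            ("item_missing_rate", self.item_missing_rate),
        ):
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {p}")
        if len(self.gamma_age) != len(AGE_BANDS):
            raise ValueError(f"gamma_age needs {len(AGE_BANDS)} entries")
        if len(self.gamma_imd) != 5:
            raise ValueError("gamma_imd needs 5 entries")
        if len(self.dose_uptake) != len(AGE_BANDS):
            raise ValueError(f"dose_uptake needs {len(AGE_BANDS)} entries")
        if any(not (0.0 <= u <= 1.0) for u in self.dose_uptake):
            raise ValueError("dose_uptake entries must lie in [0, 1]")

    def linear_predictor(
        self, age_idx: np.ndarray, is_female: np.ndarray, quintile: np.ndarray
    ) -> np.ndarray:
        """Deficit log-odds before the respondent propensity term."""
        g_age = np.asarray(self.gamma_age)[age_idx]
        g_imd = np.asarray(self.gamma_imd)[np.asarray(quintile) - 1]
        return self.alpha + g_age + self.gamma_sex * np.asarray(is_female) + g_imd


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study.

    ``stratum_probs`` holds the exact (quadrature) category probabilities
    for each of the 90 strata.  ``complete_survey`` is the responders'
    pre-deletion deficit table (no missing cells), kept so imputation can
    be benchmarked against it.  ``area_expected_counts`` is filled once an
    area table exists (see :func:`true_area_counts`).
    """

    config: GeneratorConfig
    stratum_probs: pd.DataFrame
    complete_survey: pd.DataFrame | None = None
    realized_nonresponse: float | None = None
    area_expected_counts: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "config": asdict(self.config),
            "stratum_probs": self.stratum_probs.to_dict(orient="list"),
            "realized_nonresponse": self.realized_nonresponse,
        }
        if self.area_expected_counts is not None:
            out["area_expected_counts"] = self.area_expected_counts.to_dict(
                orient="list"
            )
        return out


def _category_count_bounds(n_deficits: int, cuts: CutPoints) -> tuple[int, int]:
    """Deficit-count thresholds equivalent to the score cut-points.

    With D items the score is k/D, so robust means k <= floor(robust_max*D)
    and pre-frail means k <= floor(prefrail_max*D).  A small epsilon guards
    against decimal cut-points that are not exactly representable.
    """
    k_robust = math.floor(cuts.robust_max * n_deficits + 1e-9)
    k_prefrail = math.floor(cuts.prefrail_max * n_deficits + 1e-9)
    return k_robust, k_prefrail


def true_stratum_probs(
    config: GeneratorConfig,
    cuts: CutPoints = CutPoints(),
    n_quad: int = 80,
) -> pd.DataFrame:
    """Exact stratum category probabilities under the generative model.

    Integrates the Binomial(D, expit(eta + u)) category probabilities over
    u ~ Normal(0, sigma_u^2) with Gauss-Hermite quadrature (n_quad nodes).
    Returns the 90-row table with columns p_robust, p_prefrail, p_frail.
    """
    grid = stratum_grid()
    age_idx = grid["age_band"].map(dict(zip(AGE_BANDS, range(9)))).to_numpy()
    is_female = (grid["sex"] == "female").to_numpy().astype(float)
    eta = config.linear_predictor(age_idx, is_female, grid["imd_quintile"].to_numpy())

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    u = math.sqrt(2.0) * config.sigma_u * nodes  # (n_quad,)
    w = weights / math.sqrt(math.pi)

    k_robust, k_prefrail = _category_count_bounds(config.n_deficits, cuts)
    pi = expit(eta[:, None] + u[None, :])  # (90, n_quad)
    cdf_robust = binom.cdf(k_robust, config.n_deficits, pi)
    cdf_prefrail = binom.cdf(k_prefrail, config.n_deficits, pi)

    p_robust = cdf_robust @ w
    p_prefrail = (cdf_prefrail - cdf_robust) @ w
    p_frail = 1.0 - cdf_prefrail @ w

    out = grid.copy()
    out["p_robust"] = p_robust
    out["p_prefrail"] = p_prefrail
    out["p_frail"] = p_frail
    return out


def _calibrated_response_propensity(
    age_idx: np.ndarray, quintile: np.ndarray, target_nonresponse: float
) -> np.ndarray:
    """Response probabilities with the intercept solved on the realised
    sample so the mean response rate equals 1 - target_nonresponse."""
    if target_nonresponse == 0.0:
        return np.ones(len(age_idx))
    offset = (
        np.asarray(_RESP_AGE_OFFSET)[age_idx]
        + np.asarray(_RESP_IMD_OFFSET)[np.asarray(quintile) - 1]
    )
    target = 1.0 - target_nonresponse

    def gap(c: float) -> float:
        return float(expit(c + offset).mean() - target)

    c = brentq(gap, -30.0, 30.0)
    return expit(c + offset)


def generate_survey(
    config: GeneratorConfig,
    cuts: CutPoints = CutPoints(),
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw survey microdata and its ground truth.

    Returns ``(survey, truth)`` where ``survey`` contains only responders,
    with columns id, age_band, sex, imd_quintile, weight and one column per
    deficit item (NaN where MAR-missing).  ``truth`` echoes the config and
    carries the exact stratum probabilities, the realised non-response
    fraction and the pre-deletion complete table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_respondents
    D = config.n_deficits

    age_idx = rng.choice(len(AGE_BANDS), size=n, p=_SURVEY_AGE_DIST)
    is_female = rng.random(n) < 0.5
    quintile = rng.integers(1, 6, size=n)

    u = rng.normal(0.0, config.sigma_u, size=n)
    pi = expit(config.linear_predictor(age_idx, is_female.astype(float), quintile) + u)
    deficits = (rng.random((n, D)) < pi[:, None]).astype(float)

    propensity = _calibrated_response_propensity(
        age_idx, quintile, config.nonresponse_target
    )
    responds = rng.random(n) < propensity
    realized_nonresponse = float(1.0 - responds.mean())

    weight = 1.0 / propensity[responds]
    weight = weight / weight.mean()  # mean 1 over responders

    deficit_cols = [f"deficit_{j + 1:03d}" for j in range(D)]
    base = pd.DataFrame(
        {
            "id": np.arange(1, n + 1)[responds],
            "age_band": np.asarray(AGE_BANDS)[age_idx[responds]],
            "sex": np.where(is_female[responds], "female", "male"),
            "imd_quintile": quintile[responds],
            "weight": weight,
        }
    )
    complete = pd.concat(
        [
            base.reset_index(drop=True),
            pd.DataFrame(deficits[responds], columns=deficit_cols),
        ],
        axis=1,
    )

    survey = complete.copy()
    if config.item_missing_rate > 0:
        factor = np.asarray(_MISS_AGE_FACTOR)
        factor = factor / float(factor @ np.asarray(_SURVEY_AGE_DIST))
        p_miss = config.item_missing_rate * factor[age_idx[responds]]
        mask = rng.random((int(responds.sum()), D)) < p_miss[:, None]
        vals = survey[deficit_cols].to_numpy()
        vals[mask] = np.nan
        survey[deficit_cols] = vals

    truth = SimulationTruth(
        config=config,
        stratum_probs=true_stratum_probs(config, cuts),
        complete_survey=complete,
        realized_nonresponse=realized_nonresponse,
    )
    return survey, truth


def generate_areas(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the area population, vaccination and risk-factor tables.

    * areas: long table (area_id, name, imd_rank, imd_quintile, age_band,
      sex, population) with IMD ranks a permutation of 1..n_areas
      (1 = most deprived) and log-normal population cells rounded
      half-to-even;
    * doses: first doses per area, allocated proportional to the over-50
      population times the per-age-band uptake — frailty-blind;
    * risks: long table (area_id, factor, count) with deprivation-graded
      prevalence (sign and strength set by ``risk_depr_coef``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_areas = config.n_areas
    area_ids = [f"area_{i + 1:03d}" for i in range(n_areas)]
    ranks = rng.permutation(n_areas) + 1
    quintiles = np.array(
        [imd_rank_to_quintile(int(r), n_areas) for r in ranks]
    )

    base_pop = rng.lognormal(math.log(config.area_pop_mean), 0.45, size=n_areas)
    age_share = np.asarray(_POP_AGE_DIST)
    sex_share = {"female": _FEMALE_SHARE, "male": 1.0 - _FEMALE_SHARE}

    rows = []
    for i, aid in enumerate(area_ids):
        noise = rng.lognormal(0.0, 0.15, size=(len(AGE_BANDS), len(SEXES)))
        for a, band in enumerate(AGE_BANDS):
            for s, sex in enumerate(SEXES):
                expected = base_pop[i] * age_share[a] * sex_share[sex] * noise[a, s]
                count = int(np.rint(expected))  # round half-to-even
                rows.append((aid, aid, int(ranks[i]), int(quintiles[i]),
                             band, sex, count))
    areas = pd.DataFrame(
        rows,
        columns=["area_id", "name", "imd_rank", "imd_quintile",
                 "age_band", "sex", "population"],
    )

    uptake = dict(zip(AGE_BANDS, config.dose_uptake))
    dosed = areas.assign(
        doses=lambda df: df["population"] * df["age_band"].map(uptake)
    )
    doses = (
        dosed.groupby("area_id", as_index=False)["doses"].sum()
        .assign(first_doses=lambda df: np.rint(df["doses"]).astype(int))
        [["area_id", "first_doses"]]
    )

    pop50 = areas.groupby("area_id")["population"].sum()
    risk_rows = []
    for factor in RISK_FACTORS:
        base_prev = _RISK_BASE_PREV[factor]
        for aid, q in zip(area_ids, quintiles):
            mult = 1.0 + config.risk_depr_coef * (3 - int(q))
            noise = rng.lognormal(0.0, 0.10)
            count = int(np.rint(pop50[aid] * base_prev * mult * noise))
            risk_rows.append((aid, factor, max(count, 0)))
    risks = pd.DataFrame(risk_rows, columns=["area_id", "factor", "count"])
    return areas, doses, risks


def oracle_stratum_probs(
    config: GeneratorConfig,
    n_mc: int,
    cuts: CutPoints = CutPoints(),
) -> pd.DataFrame:
    """Brute-force Monte-Carlo oracle for the stratum category probabilities.

    For every (age band, sex, quintile) cell, simulates ``n_mc`` respondents
    from the generative model, scores them with the frailty index and
    cut-points, and returns empirical category proportions.  Independent of
    :func:`true_stratum_probs` (simulation vs quadrature), so the two can
    cross-check each other.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10000 for a usable oracle")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    grid = stratum_grid()
    k_robust, k_prefrail = _category_count_bounds(config.n_deficits, cuts)

    p_rob, p_pre, p_fra = [], [], []
    age_lookup = dict(zip(AGE_BANDS, range(len(AGE_BANDS))))
    for _, row in grid.iterrows():
        eta = config.linear_predictor(
            np.array([age_lookup[row["age_band"]]]),
            np.array([1.0 if row["sex"] == "female" else 0.0]),
            np.array([row["imd_quintile"]]),
        )[0]
        u = rng.normal(0.0, config.sigma_u, size=n_mc)
        k = rng.binomial(config.n_deficits, expit(eta + u))
        p_rob.append(float(np.mean(k <= k_robust)))
        p_pre.append(float(np.mean((k > k_robust) & (k <= k_prefrail))))
        p_fra.append(float(np.mean(k > k_prefrail)))

    out = grid.copy()
    out["p_robust"] = p_rob
    out["p_prefrail"] = p_pre
    out["p_frail"] = p_fra
    return out


def po_pseudo_true_probs(
    config: GeneratorConfig, cuts: CutPoints = CutPoints()
) -> pd.DataFrame:
    """Best proportional-odds approximation to the exact stratum truth.

    Fits the weighted proportional-odds model to the *exact* category
    probabilities (three pseudo-observations per stratum, weighted by the
    survey stratum frequencies times the true category probability) — the
    large-sample limit of the survey MLE.  Cells where this approximation
    still misses the truth are structurally unrepresentable by the
    proportional-odds form, not estimation error; recovery tests document
    them as model-misspecification cells.
    """
    from .ordinal_model import fit_proportional_odds, predict_strata

    truth = true_stratum_probs(config, cuts)
    age_w = dict(zip(AGE_BANDS, _SURVEY_AGE_DIST))
    rows = []
    for _, r in truth.iterrows():
        stratum_w = age_w[r["age_band"]] * 0.5 * (1.0 / 5.0)
        for cat, col in zip(CATEGORIES, ["p_robust", "p_prefrail", "p_frail"]):
            rows.append(
                {
                    "age_band": r["age_band"],
                    "sex": r["sex"],
                    "imd_quintile": r["imd_quintile"],
                    "frailty_category": cat,
                    "weight": stratum_w * r[col],
                }
            )
    pseudo = pd.DataFrame(rows)
    pseudo = pseudo[pseudo["weight"] > 0]
    fit = fit_proportional_odds(pseudo)
    return predict_strata(fit)


def true_area_counts(
    stratum_probs: pd.DataFrame, areas: pd.DataFrame
) -> pd.DataFrame:
    """Expected per-area category counts implied by exact stratum
    probabilities: sum of population x probability over the area's cells."""
    merged = areas.merge(
        stratum_probs, on=["age_band", "sex", "imd_quintile"], how="left",
        validate="many_to_one",
    )
    if merged[["p_robust", "p_prefrail", "p_frail"]].isna().any().any():
        raise ValueError("stratum probability table does not cover all strata")
    for cat, col in zip(CATEGORIES, ["p_robust", "p_prefrail", "p_frail"]):
        merged[cat] = merged["population"] * merged[col]
    out = (
        merged.groupby("area_id", as_index=False)[list(CATEGORIES)].sum()
        .melt(id_vars="area_id", var_name="category", value_name="expected")
        .sort_values(["area_id", "category"], ignore_index=True)
    )
    return out
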