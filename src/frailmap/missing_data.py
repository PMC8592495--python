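"""Multiple imputation by chained equations (MICE) for deficit items.

Missing deficit cells are filled by iterated per-item models conditioned on
the always-observed demographics (age band, sex, IMD quintile, one-hot
coded) and all other deficit items.  Binary items use a ridge-regularised
logistic model (the penalty keeps sparse strata with complete separation
estimable); graded items use predictive-mean matching on a ridge linear
model.  Each of the m imputations is made "proper" by refitting every item
model on a bootstrap resample of the observed rows, so between-imputation
variability reflects model uncertainty (the classical bootstrap variant of
chained equations).

Observed cells are never altered; imputation happens on the deficit items
and scoring runs afterwards, because the frailty index is a deterministic
function of the items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge

from .frailty_index import DeficitSchema
from .strata import AGE_BANDS, QUINTILES

__all__ = ["MiceConfig", "mice_impute"]


@dataclass(frozen=True)
class MiceConfig:
    """Chained-equation settings.

    m completed tables, n_iter chained sweeps each; per-kind imputation
    models default to ridge logistic for binary items and predictive-mean
    matching for graded items.  ``ridge_c`` is the inverse regularisation
    strength of the logistic models; ``pmm_donors`` the donor-pool size.
    """

    m: int = 10
    n_iter: int = 10
    seed: int = 0
    method: tuple[tuple[str, str], ...] = (
        ("binary", "logistic"),
        ("graded", "pmm"),
    )
    ridge_c: float = 1.0
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _demographic_design(survey: pd.DataFrame) -> np.ndarray:
    cols = []
    band = survey["age_band"].to_numpy()
    for b in AGE_BANDS[1:]:
        cols.append((band == b).astype(float))
    cols.append((survey["sex"].to_numpy() == "female").astype(float))
    q = survey["imd_quintile"].to_numpy()
    for qq in QUINTILES[1:]:
        cols.append((q == qq).astype(float))
    return np.column_stack(cols)


def _bootstrap_fit_rows(rng: np.random.Generator, obs_idx: np.ndarray,
                        target: np.ndarray, binary: bool) -> np.ndarray:
    """Bootstrap resample of observed rows; for binary targets retries a few
    times to keep both classes, falling back to the full observed set."""
    for _ in range(10):
        boot = rng.choice(obs_idx, size=len(obs_idx), replace=True)
        if not binary or len(np.unique(target[boot])) > 1:
            return boot
    return obs_idx


def mice_impute(
    survey: pd.DataFrame,
    schema: DeficitSchema,
    cfg: MiceConfig = MiceConfig(),
) -> list[pd.DataFrame]:
    """Produce m completed copies of ``survey``.

    Missingness must be confined to the deficit items; demographics are
    required complete.  Distinct imputations use independent sub-streams of
    ``cfg.seed`` and, with the seed fixed, the result is reproducible
    bit-for-bit.  A deficit item with no observed values at all is
    inestimable and raises.
    """
    item_cols = schema.names
    missing_demo = survey[["age_band", "sex", "imd_quintile"]].isna().any().any()
    if missing_demo:
        raise ValueError("demographic columns must be fully observed")
    values = survey[item_cols].to_numpy(dtype=float)
    miss_mask = np.isnan(values)

    all_missing = miss_mask.all(axis=0)
    if all_missing.any():
        bad = [item_cols[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"deficit items missing for all respondents: {bad}")

    if not miss_mask.any():
        return [survey.copy() for _ in range(cfg.m)]

    demo = _demographic_design(survey)
    kinds = {it.name: it.kind for it in schema.items}
    method = dict(cfg.method)
    items_with_missing = [j for j in range(len(item_cols)) if miss_mask[:, j].any()]

    completed: list[pd.DataFrame] = []
    for k in range(cfg.m):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, k]))
        filled = values.copy()
        # initialise missing cells by sampling observed values of the item
        for j in items_with_missing:
            obs_vals = values[~miss_mask[:, j], j]
            filled[miss_mask[:, j], j] = rng.choice(
                obs_vals, size=int(miss_mask[:, j].sum()), replace=True
            )
        for _ in range(cfg.n_iter):
            for j in items_with_missing:
                name = item_cols[j]
                binary = kinds[name] == "binary"
                target = filled[:, j]
                others = np.delete(filled, j, axis=1)
                X = np.column_stack([demo, others])
                obs_idx = np.flatnonzero(~miss_mask[:, j])
                mis_idx = np.flatnonzero(miss_mask[:, j])
                y_obs = values[obs_idx, j]

                if binary and method.get("binary", "logistic") == "logistic":
                    classes = np.unique(y_obs)
                    if len(classes) == 1:
                        filled[mis_idx, j] = classes[0]
                        continue
                    boot = _bootstrap_fit_rows(rng, obs_idx, values[:, j], True)
                    model = LogisticRegression(
                        C=cfg.ridge_c, solver="lbfgs", max_iter=200
                    )
                    model.fit(X[boot], values[boot, j])
                    p1 = model.predict_proba(X[mis_idx])[:, 1]
                    filled[mis_idx, j] = (rng.random(len(mis_idx)) < p1).astype(float)
                else:
                    boot = _bootstrap_fit_rows(rng, obs_idx, values[:, j], False)
                    model = Ridge(alpha=1.0)
                    model.fit(X[boot], values[boot, j])
                    pred_obs = model.predict(X[obs_idx])
                    pred_mis = model.predict(X[mis_idx])
                    # predictive-mean matching: draw from the nearest donors
                    order = np.argsort(pred_obs)
                    pos = np.searchsorted(pred_obs[order], pred_mis)
                    n_donors = min(cfg.pmm_donors, len(obs_idx))
                    for t, i_mis in enumerate(mis_idx):
                        lo = max(0, min(pos[t] - n_donors // 2,
                                        len(obs_idx) - n_donors))
                        pool = order[lo:lo + n_donors]
                        donor = rng.choice(pool)  # local index into observed rows
                        filled[i_mis, j] = y_obs[donor]
        out = survey.copy()
        out[item_cols] = filled
        completed.append(out)
    return completed
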