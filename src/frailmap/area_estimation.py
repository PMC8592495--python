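"""Post-stratification of stratum probabilities onto area population tables.

Synthetic (small-area) estimation: each area contributes 18 age-sex
population cells and one deprivation quintile; the expected number of
people in frailty category k is the sum over cells of population times the
model probability for (age band, sex, area quintile).  Population counts
are treated as fixed constants, so all uncertainty comes from the fitted
model coefficients and is propagated by a parametric bootstrap: draws of
(beta, theta) from a multivariate normal centred at the pooled estimate
with the pooled (Rubin total) covariance, pushed through the probability
and sum-product steps; 95% intervals are the 2.5/97.5 percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .strata import CATEGORIES

__all__ = [
    "AreaEstimates",
    "imd_rank_to_quintile",
    "post_stratify",
    "bootstrap_cis",
]


def imd_rank_to_quintile(rank: int, n_areas: int) -> int:
    """Deprivation quintile from an IMD rank: ceiling(5 * rank / n_areas).

    Rank 1 is the most deprived area and maps to quintile 1.
    """
    if not 1 <= rank <= n_areas:
        raise ValueError(f"rank {rank} outside 1..{n_areas}")
    return math.ceil(5 * rank / n_areas)


def _stratum_prob_lookup(probs: pd.DataFrame) -> pd.DataFrame:
    required = {"age_band", "sex", "imd_quintile", "p_robust", "p_prefrail", "p_frail"}
    missing = required - set(probs.columns)
    if missing:
        raise ValueError(f"stratum probability table lacks columns: {sorted(missing)}")
    return probs


def post_stratify(probs: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Expected frailty-category counts per area.

    ``probs`` is the 90-row stratum probability table; ``areas`` the long
    area table with columns area_id, imd_quintile, age_band, sex,
    population.  Returns a long table (area_id, category, expected).
    Deterministic; raises naming the stratum if a probability row is
    missing for any populated cell.
    """
    probs = _stratum_prob_lookup(probs)
    merged = areas.merge(
        probs, on=["age_band", "sex", "imd_quintile"], how="left",
        validate="many_to_one",
    )
    missing = merged["p_robust"].isna()
    if missing.any():
        row = merged.loc[missing.idxmax()]
        raise ValueError(
            "no stratum probability row for "
            f"(age_band={row['age_band']!r}, sex={row['sex']!r}, "
            f"imd_quintile={row['imd_quintile']!r})"
        )
    for cat, col in zip(CATEGORIES, ["p_robust", "p_prefrail", "p_frail"]):
        merged[cat] = merged["population"] * merged[col]
    return (
        merged.groupby("area_id", as_index=False)[list(CATEGORIES)].sum()
        .melt(id_vars="area_id", var_name="category", value_name="expected")
        .sort_values(["area_id", "category"], ignore_index=True)
    )


@dataclass
class AreaEstimates:
    """Per-area expected category counts with bootstrap intervals.

    ``estimates`` has columns area_id, category, expected, ci_lo, ci_hi.
    ``draws`` is the retained bootstrap array of shape (B, n_areas, 3) in
    the order of ``area_ids`` x (robust, pre_frail, frail), kept so that
    downstream ratio intervals can reuse the *joint* draws.
    """

    estimates: pd.DataFrame
    draws: np.ndarray
    area_ids: list[str]

    def draws_for(self, categories: list[str]) -> pd.DataFrame:
        """Bootstrap draws of the summed count over ``categories``:
        one row per area, one column per draw."""
        idx = [CATEGORIES.index(c) for c in categories]
        total = self.draws[:, :, idx].sum(axis=2)  # (B, n_areas)
        return pd.DataFrame(total.T, index=self.area_ids)


def _area_cell_matrix(areas: pd.DataFrame, probs_grid: pd.DataFrame):
    """Sparse-free mapping: N (n_areas x 90) population matrix aligned to
    the stratum grid rows."""
    key = ["age_band", "sex", "imd_quintile"]
    grid = probs_grid[key].copy()
    grid["_col"] = np.arange(len(grid))
    merged = areas.merge(grid, on=key, how="left", validate="many_to_one")
    if merged["_col"].isna().any():
        row = merged.loc[merged["_col"].isna().idxmax()]
        raise ValueError(
            f"no stratum row for (age_band={row['age_band']!r}, "
            f"sex={row['sex']!r}, imd_quintile={row['imd_quintile']!r})"
        )
    area_ids = sorted(areas["area_id"].unique())
    a_index = {a: i for i, a in enumerate(area_ids)}
    N = np.zeros((len(area_ids), len(grid)))
    rows = merged["area_id"].map(a_index).to_numpy()
    cols = merged["_col"].to_numpy(dtype=int)
    np.add.at(N, (rows, cols), merged["population"].to_numpy(dtype=float))
    return N, area_ids


def bootstrap_cis(
    fit,
    areas: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> AreaEstimates:
    """Parametric-bootstrap area estimates from a (pooled) fit.

    Draws B coefficient vectors from Normal(point, cov), rejecting draws
    with theta_1 >= theta_2, recomputes stratum probabilities and area
    counts for each, and forms percentile intervals.  Raises if the
    covariance is not positive semi-definite after symmetrisation or if
    more than half of the proposals are rejected (a pathological fit).
    """
    from .ordinal_model import _THETA_NAMES, predict_strata, _stratum_design

    if B < 100:
        raise ValueError("B must be >= 100")
    point = fit.params.to_numpy()
    cov = 0.5 * (fit.cov.to_numpy() + fit.cov.to_numpy().T)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
        raise ValueError("fit covariance is not positive semi-definite")
    cov = cov - min(eigvals.min(), 0.0) * np.eye(len(cov))

    names = list(fit.params.index)
    i1, i2 = names.index("theta_1"), names.index("theta_2")
    rng = np.random.default_rng(seed)
    evals, evecs = np.linalg.eigh(cov)
    chol = evecs * np.sqrt(np.clip(evals, 0.0, None))  # cov = chol @ chol.T

    accepted = []
    n_proposed = 0
    while len(accepted) < B:
        block = point + rng.standard_normal((B, len(point))) @ chol.T
        n_proposed += B
        ok = block[:, i1] < block[:, i2]
        accepted.extend(block[ok])
        if n_proposed >= 2 * B and len(accepted) < n_proposed / 2:
            raise ValueError(
                "more than half of bootstrap proposals violate "
                "theta_1 < theta_2; the fit is pathological"
            )
    draws_params = np.stack(accepted[:B])

    grid, X = _stratum_design(fit.params.index)
    beta_idx = [j for j, n in enumerate(names) if n not in _THETA_NAMES]
    eta = draws_params[:, beta_idx] @ X.T            # (B, 90)
    c1 = expit(draws_params[:, [i1]] - eta)
    c2 = expit(draws_params[:, [i2]] - eta)
    probs_draws = np.stack([c1, c2 - c1, 1.0 - c2], axis=2)  # (B, 90, 3)

    N, area_ids = _area_cell_matrix(areas, grid)
    # (B, n_areas, 3) expected counts per draw
    counts_draws = np.einsum("ac,bck->bak", N, probs_draws)

    point_probs = predict_strata(fit)
    point_counts = post_stratify(point_probs, areas)

    alpha = (1.0 - level) / 2.0
    lo = np.quantile(counts_draws, alpha, axis=0)
    hi = np.quantile(counts_draws, 1.0 - alpha, axis=0)
    ci = pd.DataFrame(
        {
            "area_id": np.repeat(area_ids, 3),
            "category": list(CATEGORIES) * len(area_ids),
            "ci_lo": lo.ravel(),
            "ci_hi": hi.ravel(),
        }
    )
    estimates = point_counts.merge(ci, on=["area_id", "category"], validate="one_to_one")
    return AreaEstimates(estimates=estimates, draws=counts_draws, area_ids=area_ids)
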