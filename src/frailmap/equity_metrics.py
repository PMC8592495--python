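"""Vaccination-equity ratios: doses per at-risk person, extreme-ratio
factors, risk-factor denominators and quintile heatmap tables.

The central quantity is the ratio of first vaccine doses administered in
an area to the size of an at-risk denominator there — the estimated frail
(or frail + pre-frail) population, the over-50 population, or the number of
people diagnosed with a given risk factor.  Higher means more doses per
person at risk.  Uncertainty in estimated denominators is carried through
by dividing the fixed dose count by each retained bootstrap draw of the
denominator; fixed denominators (e.g. official population counts) yield
point ratios without intervals.

The spread between areas is summarised by the extreme-ratio factor,
max ratio / min ratio; its interval recomputes the factor within each
joint bootstrap draw, letting the arg-max and arg-min areas vary by draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EquityRatioRecord",
    "ExtremeFactor",
    "dose_ratio",
    "area_dose_ratios",
    "over50_ratios",
    "extreme_factor",
    "total_risk_diagnoses_ratio",
    "assign_quintiles",
    "heatmap_table",
    "top_bottom_subsets",
]


@dataclass(frozen=True)
class EquityRatioRecord:
    """One area's doses-per-denominator ratio (CI present only when the
    denominator is estimated)."""

    area_id: str | None
    denominator_kind: str
    doses: int
    denominator: float
    ratio: float
    ci_lo: float | None = None
    ci_hi: float | None = None


@dataclass(frozen=True)
class ExtremeFactor:
    """Max-to-min spread of the area ratios, >= 1 by construction."""

    max_area: str
    min_area: str
    factor: float
    ci_lo: float | None = None
    ci_hi: float | None = None

    def display(self, decimals: int = 1) -> float:
        return round(self.factor, decimals)


def _records_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for c in ("ci_lo", "ci_hi"):
        df[c] = pd.to_numeric(df[c])  # None -> NaN, keeps columns float
    return df


def dose_ratio(
    doses: int,
    denominator_point: float,
    denominator_draws: np.ndarray | None = None,
    level: float = 0.95,
    denominator_kind: str = "frail",
    area_id: str | None = None,
) -> EquityRatioRecord:
    """doses / denominator with an optional percentile interval.

    When bootstrap draws of the denominator are supplied, the interval is
    formed from doses / draw_b with the dose count held fixed.
    """
    if doses < 0:
        raise ValueError("doses must be >= 0")
    if denominator_point <= 0:
        raise ValueError("denominator must be > 0")
    ratio = doses / denominator_point
    ci_lo = ci_hi = None
    if denominator_draws is not None:
        draws = np.asarray(denominator_draws, dtype=float)
        if (draws <= 0).any():
            raise ValueError("all denominator draws must be > 0")
        ratio_draws = doses / draws
        alpha = (1.0 - level) / 2.0
        ci_lo = float(np.quantile(ratio_draws, alpha))
        ci_hi = float(np.quantile(ratio_draws, 1.0 - alpha))
    return EquityRatioRecord(
        area_id=area_id,
        denominator_kind=denominator_kind,
        doses=int(doses),
        denominator=float(denominator_point),
        ratio=float(ratio),
        ci_lo=ci_lo,
        ci_hi=ci_hi,
    )


def area_dose_ratios(
    doses: pd.DataFrame,
    area_estimates,
    categories: tuple[str, ...] = ("frail",),
    denominator_kind: str | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Doses per estimated person in ``categories``, for every area.

    ``doses`` has columns area_id, first_doses; ``area_estimates`` is the
    :class:`~frailmap.area_estimation.AreaEstimates` carrying point counts
    and retained joint bootstrap draws.  Returns a table with columns
    area_id, denominator_kind, doses, denominator, ratio, ci_lo, ci_hi.
    """
    kind = denominator_kind or "+".join(categories)
    est = area_estimates.estimates
    denom = (
        est[est["category"].isin(categories)]
        .groupby("area_id")["expected"].sum()
    )
    draw_df = area_estimates.draws_for(list(categories))  # area x B
    rows = []
    for _, r in doses.iterrows():
        aid = r["area_id"]
        if aid not in denom.index:
            raise ValueError(f"no estimate for area {aid!r}")
        rec = dose_ratio(
            int(r["first_doses"]),
            float(denom[aid]),
            denominator_draws=draw_df.loc[aid].to_numpy(),
            level=level,
            denominator_kind=kind,
            area_id=aid,
        )
        rows.append(rec.__dict__)
    return _records_frame(rows)


def over50_ratios(doses: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Doses per person aged 50+, a fixed-denominator (point-only) ratio."""
    pop = areas.groupby("area_id")["population"].sum()
    rows = []
    for _, r in doses.iterrows():
        aid = r["area_id"]
        if aid not in pop.index:
            raise ValueError(f"no population for area {aid!r}")
        rec = dose_ratio(
            int(r["first_doses"]), float(pop[aid]),
            denominator_kind="over50", area_id=aid,
        )
        rows.append(rec.__dict__)
    return _records_frame(rows)


def extreme_factor(
    ratios: pd.Series,
    ratio_draws: pd.DataFrame | None = None,
    level: float = 0.95,
) -> ExtremeFactor:
    """Max ratio / min ratio across areas.

    ``ratios`` is indexed by area_id.  With ``ratio_draws`` (one row per
    area, one column per joint bootstrap draw) the interval recomputes the
    factor within each draw, with the extreme areas free to vary by draw.
    """
    if len(ratios) < 2:
        raise ValueError("need at least two areas")
    if (ratios <= 0).any():
        raise ValueError("all ratios must be > 0")
    max_area = ratios.idxmax()
    min_area = ratios.idxmin()
    factor = float(ratios.max() / ratios.min())
    ci_lo = ci_hi = None
    if ratio_draws is not None:
        draws = ratio_draws.to_numpy(dtype=float)
        factor_b = draws.max(axis=0) / draws.min(axis=0)
        alpha = (1.0 - level) / 2.0
        ci_lo = float(np.quantile(factor_b, alpha))
        ci_hi = float(np.quantile(factor_b, 1.0 - alpha))
    return ExtremeFactor(
        max_area=str(max_area), min_area=str(min_area),
        factor=factor, ci_lo=ci_lo, ci_hi=ci_hi,
    )


def total_risk_diagnoses_ratio(
    doses: pd.DataFrame,
    risks: pd.DataFrame,
    factors: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Doses per total risk-factor diagnosis, area by area.

    The denominator sums diagnosed counts over the configured factor set,
    so a person with several risk factors is counted once per diagnosis.
    """
    if factors is None:
        factors = tuple(sorted(risks["factor"].unique()))
    if len(factors) == 0:
        raise ValueError("factor set must not be empty")
    sub = risks[risks["factor"].isin(factors)]
    denom = sub.groupby("area_id")["count"].sum()
    rows = []
    for _, r in doses.iterrows():
        aid = r["area_id"]
        if aid not in denom.index:
            raise ValueError(f"area {aid!r} missing from the risk-factor table")
        rec = dose_ratio(
            int(r["first_doses"]), float(denom[aid]),
            denominator_kind="total_risk_diagnoses", area_id=aid,
        )
        rows.append(rec.__dict__)
    return _records_frame(rows)


def assign_quintiles(
    values: pd.Series, larger_is_advantaged: bool = True
) -> pd.Series:
    """Advantage quintiles (1 = least advantaged, 5 = most advantaged).

    Group sizes are as equal as possible (they differ by at most one, with
    the larger groups taking the earlier quintiles); ties are broken by
    area_id lexicographic order.
    """
    if len(values) < 5:
        raise ValueError("need at least five areas")
    if values.isna().any() or not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("values must be finite (no NaN)")
    # least advantaged areas first, so quintile 1 is filled first
    df = pd.DataFrame(
        {"value": values.to_numpy(dtype=float), "tie": values.index.astype(str)},
        index=values.index,
    )
    df = df.sort_values(["value", "tie"], ascending=[larger_is_advantaged, True])
    n = len(df)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q <= rem else 0) for q in range(1, 6)]
    labels = np.repeat(np.arange(1, 6), sizes)
    out = pd.Series(labels, index=df.index, name="quintile")
    return out.reindex(values.index)


def heatmap_table(
    metrics: dict[str, pd.Series],
    deprivation_quintile: pd.Series,
    larger_is_advantaged: bool = True,
) -> pd.DataFrame:
    """Wide quintile table: one row per area, one quintile column per
    metric, plus the area deprivation quintile.

    All metrics must cover the same area set.  Column order follows the
    metric names sorted, so input ordering does not change the result.
    """
    if not metrics:
        raise ValueError("need at least one metric")
    area_sets = {name: frozenset(s.index) for name, s in metrics.items()}
    ref = frozenset(deprivation_quintile.index)
    for name, ids in area_sets.items():
        if ids != ref:
            raise ValueError(
                f"metric {name!r} covers a different area set than the "
                "deprivation table"
            )
    out = pd.DataFrame(index=sorted(ref))
    out.index.name = "area_id"
    for name in sorted(metrics):
        out[name] = assign_quintiles(metrics[name], larger_is_advantaged)
    out["deprivation_quintile"] = deprivation_quintile.reindex(out.index)
    return out.reset_index()


def top_bottom_subsets(
    heatmap: pd.DataFrame, over50_ratio: pd.Series, n: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The top-n and bottom-n areas by doses per person over 50, as subset
    views of the heatmap (the figure-style detail panels)."""
    ranked = over50_ratio.sort_values(ascending=False)
    top_ids = list(ranked.index[:n])
    bottom_ids = list(ranked.index[-n:])
    by_id = heatmap.set_index("area_id")
    return (
        by_id.loc[top_ids].reset_index(),
        by_id.loc[bottom_ids].reset_index(),
    )
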