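"""Readers, writers, configuration and the end-to-end pipeline.

File conventions (declared in a JSON sidecar next to every CSV written):
UTF-8, comma-separated, header row required, empty string = missing.  Sex
is encoded as the strings female/male; IMD quintile as integers 1-5 with
1 = most deprived; age bands are the nine labels "50-54" ... "85-89",
"90+".
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .area_estimation import AreaEstimates, bootstrap_cis
from .equity_metrics import (
    _records_frame,
    area_dose_ratios,
    dose_ratio,
    extreme_factor,
    heatmap_table,
    over50_ratios,
    top_bottom_subsets,
    total_risk_diagnoses_ratio,
)
from .frailty_index import CutPoints, DeficitSchema, score_table
from .missing_data import MiceConfig, mice_impute
from .ordinal_model import fit_proportional_odds, pool_rubin, predict_strata
from .strata import AGE_BANDS

__all__ = [
    "PipelineConfig",
    "read_survey",
    "read_areas",
    "read_doses",
    "read_risks",
    "write_csv_with_sidecar",
    "run_pipeline",
]

_CONVENTIONS = {
    "encoding": "UTF-8, comma-separated, header row; empty string = missing",
    "sex": "female | male",
    "imd_quintile": "integer 1..5; 1 = most deprived",
    "age_band": list(AGE_BANDS),
}


def write_csv_with_sidecar(df: pd.DataFrame, path, description: str) -> None:
    """Write a CSV and a ``<name>.schema.json`` sidecar declaring columns."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "description": description,
        "columns": list(df.columns),
        "conventions": _CONVENTIONS,
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_survey(path) -> pd.DataFrame:
    """Read and validate survey microdata.

    Requires columns id, age_band, sex, imd_quintile, weight and at least
    one deficit_* column; empty deficit cells parse as missing.  Rejects
    unknown age-band labels, non-positive weights and duplicate ids,
    naming the offending row.
    """
    df = pd.read_csv(path)
    required = ["id", "age_band", "sex", "imd_quintile", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survey file lacks columns: {missing}")
    deficit_cols = [c for c in df.columns if c.startswith("deficit_")]
    if not deficit_cols:
        raise ValueError("survey file has no deficit_* columns")

    bad_band = ~df["age_band"].isin(AGE_BANDS)
    if bad_band.any():
        row = int(np.flatnonzero(bad_band)[0])
        raise ValueError(
            f"row {row}: unknown age band {df['age_band'].iloc[row]!r}; "
            f"expected one of {list(AGE_BANDS)}"
        )
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise ValueError(f"row {row}: sex must be female|male")
    bad_q = ~df["imd_quintile"].isin([1, 2, 3, 4, 5])
    if bad_q.any():
        row = int(np.flatnonzero(bad_q)[0])
        raise ValueError(f"row {row}: imd_quintile must be an integer 1..5")
    bad_w = ~(df["weight"] > 0)
    if bad_w.any():
        row = int(np.flatnonzero(bad_w)[0])
        raise ValueError(f"row {row}: non-positive weight")
    dup = df["id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValueError(f"row {row}: duplicate id {df['id'].iloc[row]!r}")
    df[deficit_cols] = df[deficit_cols].astype(float)
    return df


def read_areas(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["area_id", "imd_rank", "imd_quintile", "age_band", "sex", "population"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"area file lacks columns: {missing}")
    if (df["population"] < 0).any():
        raise ValueError("population counts must be >= 0")
    bad_band = ~df["age_band"].isin(AGE_BANDS)
    if bad_band.any():
        row = int(np.flatnonzero(bad_band)[0])
        raise ValueError(f"row {row}: unknown age band {df['age_band'].iloc[row]!r}")
    ranks = sorted(df.groupby("area_id")["imd_rank"].first())
    if ranks != list(range(1, len(ranks) + 1)):
        raise ValueError("imd_rank values must be a permutation of 1..n_areas")
    return df


def read_doses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"area_id", "first_doses"}.issubset(df.columns):
        raise ValueError("dose file needs columns area_id, first_doses")
    if (df["first_doses"] < 0).any():
        raise ValueError("dose counts must be >= 0")
    return df


def read_risks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"area_id", "factor", "count"}.issubset(df.columns):
        raise ValueError("risk file needs columns area_id, factor, count")
    if (df["count"] < 0).any():
        raise ValueError("risk-factor counts must be >= 0")
    return df


@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-loadable)."""

    survey_path: str
    areas_path: str
    doses_path: str
    risks_path: str
    out_dir: str
    schema_path: str | None = None
    robust_max: float = 0.24
    prefrail_max: float = 0.36
    mice_m: int = 10
    mice_n_iter: int = 10
    bootstrap_b: int = 1000
    seed: int = 0
    factors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_b < 100:
            raise ValueError("bootstrap_b must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "factors" in raw and raw["factors"] is not None:
            raw["factors"] = tuple(raw["factors"])
        return cls(**raw)


def _schema_for(survey: pd.DataFrame, cfg: PipelineConfig) -> DeficitSchema:
    if cfg.schema_path:
        return DeficitSchema.from_yaml(cfg.schema_path)
    n = len([c for c in survey.columns if c.startswith("deficit_")])
    return DeficitSchema.default(n)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute impute -> score -> fit -> pool -> predict -> post-stratify
    -> bootstrap -> ratios -> heatmap, writing every artifact to
    ``cfg.out_dir``.  Returns the run log (also written as run_log.json).

    Identical config + seed gives byte-identical numeric outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "frailmap_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "stages": {},
    }

    def stage(name):
        log["stages"][name] = {}
        return log["stages"][name]

    try:
        survey = read_survey(cfg.survey_path)
        areas = read_areas(cfg.areas_path)
        doses = read_doses(cfg.doses_path)
        risks = read_risks(cfg.risks_path)
        schema = _schema_for(survey, cfg)
        cuts = CutPoints(cfg.robust_max, cfg.prefrail_max)
        s = stage("read")
        s.update(n_respondents=len(survey), n_areas=areas["area_id"].nunique(),
                 n_deficit_items=len(schema))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'read' failed: {exc}") from exc

    try:
        mice_cfg = MiceConfig(m=cfg.mice_m, n_iter=cfg.mice_n_iter, seed=cfg.seed)
        completed = mice_impute(survey, schema, mice_cfg)
        n_missing = int(survey[schema.names].isna().sum().sum())
        stage("impute").update(m=mice_cfg.m, n_iter=mice_cfg.n_iter,
                               n_missing_cells=n_missing)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'impute' failed: {exc}") from exc

    try:
        scored = [score_table(t, schema, cuts) for t in completed]
        stage("score").update(n_tables=len(scored))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'score' failed: {exc}") from exc

    try:
        fits = [fit_proportional_odds(t) for t in scored]
        pooled = pool_rubin(fits)
        stage("fit").update(
            m=len(fits),
            n_iterations=[f.n_iter for f in fits],
            loglik=[f.loglik for f in fits],
            converged=[f.converged for f in fits],
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        probs = predict_strata(pooled)
        write_csv_with_sidecar(
            probs, out / "stratum_probs.csv",
            "Predicted P(robust/pre-frail/frail) per (age band, sex, IMD quintile)",
        )
        estimates = bootstrap_cis(pooled, areas, B=cfg.bootstrap_b, seed=cfg.seed)
        write_csv_with_sidecar(
            estimates.estimates, out / "area_estimates.csv",
            "Expected frailty-category counts per area with 95% bootstrap CIs",
        )
        stage("estimate").update(B=cfg.bootstrap_b)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'estimate' failed: {exc}") from exc

    try:
        ratios_frail = area_dose_ratios(doses, estimates, ("frail",), "frail")
        ratios_fp = area_dose_ratios(
            doses, estimates, ("frail", "pre_frail"), "frail_plus_prefrail"
        )
        ratios_50 = over50_ratios(doses, areas)
        factor_names = cfg.factors or tuple(sorted(risks["factor"].unique()))
        per_factor = []
        for f in factor_names:
            sub = risks[risks["factor"] == f].set_index("area_id")["count"]
            for _, r in doses.iterrows():
                rec = dose_ratio(
                    int(r["first_doses"]), float(sub[r["area_id"]]),
                    denominator_kind=f"per_factor({f})", area_id=r["area_id"],
                )
                per_factor.append(rec.__dict__)
        ratios_total = total_risk_diagnoses_ratio(doses, risks, factor_names)
        all_ratios = pd.concat(
            [ratios_frail, ratios_fp, ratios_50,
             _records_frame(per_factor), ratios_total],
            ignore_index=True,
        )
        write_csv_with_sidecar(
            all_ratios, out / "ratios.csv",
            "Doses per at-risk person by area and denominator kind",
        )

        ef_frail = extreme_factor(
            ratios_frail.set_index("area_id")["ratio"],
            _ratio_draws(doses, estimates, ["frail"]),
        )
        ef_fp = extreme_factor(
            ratios_fp.set_index("area_id")["ratio"],
            _ratio_draws(doses, estimates, ["frail", "pre_frail"]),
        )
        ef_50 = extreme_factor(ratios_50.set_index("area_id")["ratio"])
        stage("ratios").update(
            extreme_factor_frail=ef_frail.__dict__,
            extreme_factor_frail_plus_prefrail=ef_fp.__dict__,
            extreme_factor_over50=ef_50.__dict__,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'ratios' failed: {exc}") from exc

    try:
        metrics = {}
        for f in factor_names:
            sub = risks[risks["factor"] == f].set_index("area_id")["count"]
            d = doses.set_index("area_id")["first_doses"]
            metrics[f"doses_per_{f}"] = (d / sub).dropna()
        metrics["doses_per_frail"] = ratios_frail.set_index("area_id")["ratio"]
        metrics["doses_per_prefrail"] = (
            doses.set_index("area_id")["first_doses"]
            / estimates.estimates.query("category == 'pre_frail'")
            .set_index("area_id")["expected"]
        )
        depr = areas.groupby("area_id")["imd_quintile"].first()
        heat = heatmap_table(metrics, depr)
        write_csv_with_sidecar(
            heat, out / "heatmap.csv",
            "Advantage quintile (5 = most advantaged) per area and metric",
        )
        top, bottom = top_bottom_subsets(
            heat, ratios_50.set_index("area_id")["ratio"]
        )
        write_csv_with_sidecar(top, out / "heatmap_top10.csv",
                               "Top ten areas by doses per person over 50")
        write_csv_with_sidecar(bottom, out / "heatmap_bottom10.csv",
                               "Bottom ten areas by doses per person over 50")
        stage("heatmap").update(n_metrics=len(metrics))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'heatmap' failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return log


def _ratio_draws(
    doses: pd.DataFrame, estimates: AreaEstimates, categories: list[str]
) -> pd.DataFrame:
    """Joint draws of doses / denominator, one row per area."""
    denom_draws = estimates.draws_for(categories)  # area x B
    d = doses.set_index("area_id")["first_doses"].reindex(denom_draws.index)
    return denom_draws.rdiv(d, axis=0)
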