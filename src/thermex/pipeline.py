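"""Two-stage pipeline orchestration: classify, select, fit, pool, report.

``run_pipeline`` reads community panels and metadata, computes the national
relative-humidity cutoff, selects the best event definition per province by
average Q-AIC (or applies the fixed 90th/10th-percentile >=2-day definition),
fits the community-level quasi-Poisson models, pools effects across
communities by REML meta-analysis (optionally stratified by humidity), runs
per-IQR meta-regression on community-level modifiers, and writes tidy
long-format CSV tables plus a JSON run summary and a log file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import firststage as fs
from . import meta
from .io import RunConfig, panel_groups, read_holidays, read_metadata, read_panel

logger = logging.getLogger(__name__)

FIXED_DEFINITIONS = {
    ev.HEAT_WAVE: ev.EventDefinition(ev.HEAT_WAVE, 90.0, 2),
    ev.COLD_SPELL: ev.EventDefinition(ev.COLD_SPELL, 10.0, 2),
}

#: community-level modifier columns entered one at a time in meta-regression
METAREG_PREDICTORS = (
    "latitude", "population", "gdp_per_capita", "urbanization_rate",
    "elderly_rate", "college_rate", "literacy_rate", "migrant_rate",
    "temperature", "diurnal_temperature_range", "humidity", "pm25", "ndvi",
)


def _model_config(cfg: RunConfig, kind: str) -> fs.ModelConfig:
    return fs.default_config(
        kind,
        season_df=cfg.season_df,
        covariates=(
            ("rh", cfg.covariate_df, cfg.covariate_lag_df, cfg.covariate_max_lag),
            ("pressure", cfg.covariate_df, cfg.covariate_lag_df, cfg.covariate_max_lag),
        ),
        pm25_df=3 if cfg.adjust_pm25 else None,
        humidity_split=cfg.humidity_split,
        qaic_variant=cfg.qaic_variant,
    )


def effects_to_frame(effects: list[fs.EventEffect]) -> pd.DataFrame:
    rows = [asdict(e) for e in effects]
    df = pd.DataFrame(rows)
    # 2-decimal presentation columns alongside full precision
    for col in ("pct", "pct_lo", "pct_hi"):
        if col in df.columns:
            df[f"{col}_2dp"] = df[col].round(2)
    return df


def pool_effects(effects: list[fs.EventEffect]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """REML-pool first-stage effects by (kind, event_type, stratum).

    Communities with missing or non-converged effects are excluded listwise
    per analysis, with counts logged.  Returns the pooled table and the
    low-vs-high humidity contrast table (empty without stratification).
    """
    df = effects_to_frame(effects)
    pooled_rows, contrast_rows = [], []
    for (kind, etype, stratum), sub in df.groupby(
        ["kind", "event_type", "stratum"], dropna=False, sort=True
    ):
        ok = sub[np.isfinite(sub["beta"]) & np.isfinite(sub["se"]) & (sub["se"] > 0) & sub["converged"]]
        dropped = len(sub) - len(ok)
        if dropped:
            logger.info(
                "%s/%s/%s: excluded %d of %d communities (missing or non-converged)",
                kind, etype, stratum or "-", dropped, len(sub),
            )
        if len(ok) < 2:
            logger.warning("%s/%s/%s: <2 usable communities; skipped", kind, etype, stratum or "-")
            continue
        p = meta.meta_reml(ok["beta"].to_numpy(), (ok["se"] ** 2).to_numpy())
        pooled_rows.append(
            {"kind": kind, "event_type": etype, "stratum": stratum or "", **asdict(p)}
        )
    pooled = pd.DataFrame(pooled_rows)
    if not pooled.empty and (pooled["stratum"] != "").any():
        for (kind, etype), sub in pooled.groupby(["kind", "event_type"]):
            lo = sub[sub["stratum"] == ev.LOW]
            hi = sub[sub["stratum"] == ev.HIGH]
            if len(lo) == 1 and len(hi) == 1:
                z, p_val = meta.z_diff_test(
                    lo["beta"].iloc[0], lo["se"].iloc[0],
                    hi["beta"].iloc[0], hi["se"].iloc[0],
                )
                contrast_rows.append(
                    {"kind": kind, "event_type": etype,
                     "contrast": "low_vs_high_humidity", "z": z, "p": p_val}
                )
    return pooled, pd.DataFrame(contrast_rows)


def run_meta_regression(
    effects: list[fs.EventEffect], metadata: pd.DataFrame,
    event_type: str = "compound", predictors=METAREG_PREDICTORS,
) -> pd.DataFrame:
    """Per-IQR meta-regression of compound-event effects on each modifier."""
    df = effects_to_frame(effects)
    rows = []
    for kind, sub in df[df["event_type"] == event_type].groupby("kind"):
        ok = sub[np.isfinite(sub["beta"]) & (sub["se"] > 0) & sub["converged"]]
        merged = ok.merge(metadata, on="community_id", how="inner")
        for pred in predictors:
            if pred not in merged.columns:
                continue
            x = merged[pred].to_numpy(dtype=float)
            if merged.shape[0] < 3 or np.ptp(x[np.isfinite(x)]) == 0:
                continue
            keep = np.isfinite(x)
            try:
                res = meta.meta_regression(
                    merged["beta"].to_numpy()[keep],
                    (merged["se"] ** 2).to_numpy()[keep],
                    x[keep], predictor=pred,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("meta-regression on %s (%s) failed: %s", pred, kind, exc)
                continue
            rows.append({"kind": kind, "event_type": event_type, **asdict(res)})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full two-stage analysis and write result tables.

    Outputs under ``cfg.output_dir``: community_effects.csv,
    selected_definitions.csv, qaic_grid.csv, pooled_effects.csv,
    contrasts.csv, metareg.csv, summary.json and run.log.  Reruns with the
    same inputs and config produce identical files.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("thermex")
    prev_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    root.addHandler(handler)
    try:
        return _run(cfg, out_dir)
    finally:
        root.removeHandler(handler)
        root.setLevel(prev_level)
        handler.close()


def _run(cfg: RunConfig, out_dir: Path) -> dict:
    paths = sorted(Path(cfg.panel_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no panel CSVs in {cfg.panel_dir}")
    panels = {p.stem: read_panel(p) for p in paths}
    metadata = read_metadata(cfg.metadata_csv)
    holidays = read_holidays(cfg.holiday_csv) if cfg.holiday_csv else set()
    groups = cfg.groups or panel_groups(next(iter(panels.values())))
    logger.info("loaded %d panels, groups=%s", len(panels), groups)

    rh_cutoff = ev.national_rh_median(list(panels.values()))
    logger.info("national relative-humidity cutoff: %.2f%%", rh_cutoff)

    provinces: dict[str, list[str]] = {}
    meta_ids = set(metadata["community_id"])
    for cid in panels:
        if cid not in meta_ids:
            raise ValueError(f"community {cid!r} missing from metadata")
    for _, row in metadata.iterrows():
        if row["community_id"] in panels:
            provinces.setdefault(str(row["province_id"]), []).append(row["community_id"])

    all_effects: list[fs.EventEffect] = []
    selected_rows, qaic_tables = [], []
    for kind in cfg.kinds:
        mcfg = _model_config(cfg, kind)
        for prov, cids in sorted(provinces.items()):
            if cfg.fixed_definition:
                best = FIXED_DEFINITIONS[kind]
                logger.info("province %s %s: fixed definition %s (selection skipped)",
                            prov, kind, best.label())
            else:
                best, table = fs.select_definition(
                    [panels[c] for c in cids], kind, groups, mcfg, holidays
                )
                table.insert(0, "province_id", prov)
                qaic_tables.append(table)
            selected_rows.append(
                {"province_id": prov, "kind": kind, "percentile": best.percentile,
                 "min_duration": best.min_duration, "fixed": cfg.fixed_definition}
            )
            for cid in cids:
                panel = panels[cid]
                cal = ev.build_event_calendar(
                    panel["date"], panel["tmax"].to_numpy(),
                    panel["tmin"].to_numpy(), best,
                )
                if cfg.humidity_split:
                    cal = ev.split_by_humidity(cal, panel["rh"].to_numpy(), rh_cutoff)
                base = fs.build_base_design(panel, mcfg, holidays)
                for group in groups:
                    effects, _ = fs.estimate_event_effects(
                        panel, cal, mcfg, group, holidays,
                        community_id=cid, definition=best.label(), base=base,
                    )
                    for e in effects:
                        e.stratum = f"{group}:{e.stratum}" if e.stratum else group
                    all_effects.extend(effects)

    effects_df = effects_to_frame(all_effects)
    pooled_df, contrasts_df = pool_effects(all_effects)
    total_effects = [e for e in all_effects if e.stratum == groups[0]]
    metareg_df = run_meta_regression(total_effects, metadata)

    effects_df.to_csv(out_dir / "community_effects.csv", index=False)
    pd.DataFrame(selected_rows).to_csv(out_dir / "selected_definitions.csv", index=False)
    if qaic_tables:
        pd.concat(qaic_tables, ignore_index=True).to_csv(out_dir / "qaic_grid.csv", index=False)
    pooled_df.to_csv(out_dir / "pooled_effects.csv", index=False)
    contrasts_df.to_csv(out_dir / "contrasts.csv", index=False)
    metareg_df.to_csv(out_dir / "metareg.csv", index=False)

    summary = {
        "config": asdict(cfg),
        "n_communities": len(panels),
        "n_provinces": len(provinces),
        "groups": list(groups),
        "rh_cutoff": rh_cutoff,
        "selected_definitions": selected_rows,
        "n_first_stage_effects": len(all_effects),
        "n_pooled_rows": int(len(pooled_df)),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
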