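"""First stage: community-level quasi-Poisson regression of daily deaths.

One model per (community, season, mortality group).  The linear predictor
contains a natural cubic spline of day-of-season (seasonality within the
analysis season), indicator variables for the year (long-term trend), day-of-
week and public-holiday dummies, cross-bases for relative humidity and air
pressure (lagged nonlinear confounder adjustment), and the event-type dummies
of interest — daytime-only, nighttime-only and compound — entered either as a
single-lag term or as a moving average over lags 0..L so the coefficient is
the log rate ratio for a window fully covered by the event.

Analyses are season-restricted: heat waves May-September, cold spells
November-March, with cold seasons spanning the turn of the year.  Rows whose
lag history is incomplete (the first ``max_lag`` days of each season block)
are dropped from the likelihood, not imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import events as ev
from .glm import GLMFit, fit_quasipoisson, qaic
from .meta import pct_change
from .splines import SplineSpec, build_cross_basis, lag_knots, natural_cubic_basis

logger = logging.getLogger(__name__)

#: default cumulative reporting windows: heat-wave effects at lag 0-1 days,
#: cold-spell effects at lag 0-14 days
DEFAULT_MA_LAG = {ev.HEAT_WAVE: 1, ev.COLD_SPELL: 14}


@dataclass
class ModelConfig:
    """First-stage model specification for one season."""

    season: str  # "hot" or "cold"
    season_df: int = 4
    covariates: tuple[tuple[str, int, int, int], ...] = (
        ("rh", 5, 4, 10),
        ("pressure", 5, 4, 10),
    )
    pm25_df: int | None = None
    event_lag_mode: tuple[str, int] = ("ma", 1)
    humidity_split: bool = False
    qaic_variant: str = "penalty"

    def __post_init__(self) -> None:
        if self.season not in ("hot", "cold"):
            raise ValueError("season must be 'hot' or 'cold'")
        if not 3 <= self.season_df <= 8:
            raise ValueError("season_df must be in [3, 8]")
        for name, vdf, ldf, maxlag in self.covariates:
            if not 1 <= maxlag <= 21:
                raise ValueError(f"max_lag for {name} must be in [1, 21]")
        mode, arg = self.event_lag_mode
        if mode not in ("ma", "single") or arg < 0:
            raise ValueError("event_lag_mode must be ('ma', L>=0) or ('single', l>=0)")

    @property
    def kind(self) -> str:
        return ev.HEAT_WAVE if self.season == "hot" else ev.COLD_SPELL

    @property
    def lag_label(self) -> str:
        mode, arg = self.event_lag_mode
        return f"lag 0-{arg} MA" if mode == "ma" else f"lag {arg}"


def default_config(kind: str, **overrides) -> ModelConfig:
    """Season-appropriate defaults: MA lag 0-1 (heat) or 0-14 (cold)."""
    season = "hot" if kind == ev.HEAT_WAVE else "cold"
    cfg = ModelConfig(season=season, event_lag_mode=("ma", DEFAULT_MA_LAG[kind]))
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class EventEffect:
    """One estimated event-type effect on the percentage-change scale."""

    community_id: str
    kind: str
    event_type: str
    definition: str
    lag_spec: str
    stratum: str
    beta: float
    se: float
    pct: float
    pct_lo: float
    pct_hi: float
    n_event_days: int
    converged: bool

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.beta)

    @property
    def variance(self) -> float:
        return self.se**2


def season_day_index(dates: pd.Series | pd.DatetimeIndex, season: str) -> pd.DataFrame:
    """Within-season day index (1-based) and season-year label.

    Hot season: index 1 on 1 May, labelled by the calendar year.  Cold
    season: index 1 on 1 November, continuing through 31 March of the next
    calendar year, labelled by the starting November's year.  Out-of-season
    dates are excluded from the result.
    """
    dates = pd.DatetimeIndex(dates)
    if season == "hot":
        mask = np.isin(dates.month, ev.HOT_SEASON_MONTHS)
        d = dates[mask]
        start_year = d.year
        start = pd.to_datetime({"year": start_year, "month": 5, "day": 1})
    elif season == "cold":
        mask = np.isin(dates.month, ev.COLD_SEASON_MONTHS)
        d = dates[mask]
        start_year = np.where(d.month >= 11, d.year, d.year - 1)
        start = pd.to_datetime(
            {"year": start_year, "month": 11, "day": 1}
        )
    else:
        raise ValueError("season must be 'hot' or 'cold'")
    index = (d - pd.DatetimeIndex(start)).days + 1
    return pd.DataFrame(
        {"date": d, "day_index": index.astype(int), "season_year": start_year},
    )


def moving_average_indicator(flags: np.ndarray, L: int) -> np.ndarray:
    """Mean of the event flag over lags 0..L; NaN on the first L days.

    The value lies in [0, 1]: 1 means every day of the lag window was an
    event day, so exp(beta) is the rate ratio of a fully exposed window.
    """
    if L < 0:
        raise ValueError("L must be nonnegative")
    f = np.asarray(flags, dtype=float)
    if L == 0:
        return f.copy()
    out = np.convolve(f, np.ones(L + 1) / (L + 1.0), mode="full")[: f.size]
    out[:L] = np.nan
    return out


def _single_lag(flags: np.ndarray, lag: int) -> np.ndarray:
    f = np.asarray(flags, dtype=float)
    if lag == 0:
        return f.copy()
    out = np.empty_like(f)
    out[lag:] = f[:-lag]
    out[:lag] = np.nan
    return out


@dataclass
class BaseDesign:
    """Confounder part of the design, shared across candidate definitions."""

    X: np.ndarray
    colnames: list[str]
    rows: np.ndarray  # positional indices of in-season rows in the panel
    dates: pd.DatetimeIndex
    blocks: list[np.ndarray]  # index arrays into the in-season row space


def build_base_design(
    panel: pd.DataFrame, cfg: ModelConfig, holidays: set | None = None
) -> BaseDesign:
    """Assemble the confounder columns on the season-restricted rows."""
    dates_all = pd.DatetimeIndex(panel["date"])
    blocks_abs = ev.season_blocks(dates_all, cfg.kind)
    if not blocks_abs:
        raise ValueError(f"panel has no days in the {cfg.season} season")
    rows = np.concatenate(blocks_abs)
    dates = dates_all[rows]
    # block index arrays re-expressed in the in-season row space
    blocks, pos = [], 0
    for b in blocks_abs:
        blocks.append(np.arange(pos, pos + b.size))
        pos += b.size

    sdi = season_day_index(dates, cfg.season)
    cols: list[np.ndarray] = [np.ones(rows.size)]
    names: list[str] = ["intercept"]

    basis = natural_cubic_basis(
        sdi["day_index"].to_numpy(dtype=float), SplineSpec(df=cfg.season_df)
    )
    cols.append(basis)
    names += [f"season_ns{i+1}" for i in range(cfg.season_df)]

    # trend: calendar-year indicators in the hot season, season-year in the
    # cold season (a season spanning the New Year is one unit)
    year = dates.year.to_numpy() if cfg.season == "hot" else sdi["season_year"].to_numpy()
    levels = np.unique(year)
    for lev in levels[1:]:
        cols.append((year == lev).astype(float)[:, None])
        names.append(f"year_{lev}")

    dow = dates.dayofweek.to_numpy()
    for d in range(1, 7):
        cols.append((dow == d).astype(float)[:, None])
        names.append(f"dow_{d}")

    holidays = holidays or set()
    hol = np.array([d in holidays for d in dates.normalize()], dtype=float)
    cols.append(hol[:, None])
    names.append("holiday")

    for varname, vdf, ldf, maxlag in cfg.covariates:
        x = panel[varname].to_numpy(dtype=float)[rows]
        var_spec = SplineSpec(
            df=vdf,
            boundary_knots=(float(np.nanmin(x)), float(np.nanmax(x))),
            interior_knots=np.quantile(
                x[np.isfinite(x)], np.linspace(0, 1, vdf + 1)[1:-1]
            ),
        )
        lspec = lag_knots(maxlag, ldf)
        cb = np.full((rows.size, vdf * ldf), np.nan)
        for blk in blocks:
            if blk.size > maxlag:
                cb[blk] = build_cross_basis(x[blk], var_spec, lspec, maxlag).matrix
        cols.append(cb)
        names += [f"cb_{varname}_{i+1}" for i in range(vdf * ldf)]

    if cfg.pm25_df:
        pm = panel["pm25"].to_numpy(dtype=float)[rows]
        finite = np.isfinite(pm)
        if finite.sum() < 30:
            raise ValueError("too few days with PM2.5 data for the spline")
        spec = SplineSpec(
            df=cfg.pm25_df,
            boundary_knots=(float(pm[finite].min()), float(pm[finite].max())),
            interior_knots=np.quantile(
                pm[finite], np.linspace(0, 1, cfg.pm25_df + 1)[1:-1]
            ),
        )
        pb = np.full((rows.size, cfg.pm25_df), np.nan)
        pb[finite] = natural_cubic_basis(pm[finite], spec)
        cols.append(pb)
        names += [f"pm25_ns{i+1}" for i in range(cfg.pm25_df)]

    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
    return BaseDesign(X=X, colnames=names, rows=rows, dates=dates, blocks=blocks)


def event_regressors(
    calendar: pd.DataFrame, base: BaseDesign, cfg: ModelConfig
) -> tuple[np.ndarray, list[str]]:
    """Event-type regressors (3, or 6 when humidity-stratified) on base rows."""
    etype = calendar["event_type"].to_numpy()[base.rows]
    if cfg.humidity_split:
        stratum = calendar["humidity_stratum"].to_numpy()[base.rows]
        indicators = {
            f"{t}_{s}": (etype == t) & (stratum == s)
            for t in ev.EVENT_TYPES
            for s in (ev.LOW, ev.HIGH)
        }
    else:
        indicators = {t: etype == t for t in ev.EVENT_TYPES}
    mode, arg = cfg.event_lag_mode
    shape = (_single_lag, moving_average_indicator)[mode == "ma"]
    E = np.full((base.rows.size, len(indicators)), np.nan)
    for j, (_name, ind) in enumerate(indicators.items()):
        ind = ind.astype(float)
        for blk in base.blocks:
            E[blk, j] = shape(ind[blk], arg)
    return E, [f"event_{n}" for n in indicators]


@dataclass
class DesignInfo:
    X: np.ndarray
    y: np.ndarray
    colnames: list[str]
    event_cols: dict[str, int]
    mask: np.ndarray
    dates: pd.DatetimeIndex
    n_event_days: dict[str, int]


def _group_column(panel: pd.DataFrame, group: str) -> np.ndarray:
    col = f"deaths_{group}" if f"deaths_{group}" in panel.columns else group
    if col not in panel.columns:
        raise KeyError(f"missing count column for group {group!r}")
    return panel[col].to_numpy(dtype=float)


def build_design(
    panel: pd.DataFrame,
    calendar: pd.DataFrame,
    cfg: ModelConfig,
    group: str,
    holidays: set | None = None,
    base: BaseDesign | None = None,
) -> DesignInfo:
    """Full design matrix, response and row mask for one community model.

    Rows with incomplete lag history (cross-basis or event window) or missing
    counts are masked out.  Event regressors that are identically zero on the
    retained rows are left in place — the fit drops them as aliased and the
    effect is reported missing.
    """
    if len(calendar) != len(panel) or not (
        pd.DatetimeIndex(calendar["date"]) == pd.DatetimeIndex(panel["date"])
    ).all():
        raise ValueError("event calendar is misaligned with the panel")
    if base is None:
        base = build_base_design(panel, cfg, holidays)
    E, enames = event_regressors(calendar, base, cfg)
    X = np.column_stack([base.X, E])
    names = base.colnames + enames
    y = _group_column(panel, group)[base.rows]
    mask = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    etype = calendar["event_type"].to_numpy()[base.rows][mask]
    n_event_days = {t: int((etype == t).sum()) for t in ev.EVENT_TYPES}
    event_cols = {n.removeprefix("event_"): len(base.colnames) + j for j, n in enumerate(enames)}
    for name, j in event_cols.items():
        if not np.any(X[mask, j]):
            logger.warning("event regressor %r is all zero; effect will be missing", name)
    return DesignInfo(
        X=X[mask], y=y[mask], colnames=names, event_cols=event_cols,
        mask=mask, dates=base.dates[mask], n_event_days=n_event_days,
    )


def estimate_event_effects(
    panel: pd.DataFrame,
    calendar: pd.DataFrame,
    cfg: ModelConfig,
    group: str,
    holidays: set | None = None,
    community_id: str = "",
    definition: str = "",
    base: BaseDesign | None = None,
) -> tuple[list[EventEffect], GLMFit]:
    """Fit one community-season model and extract the event-type effects."""
    d = build_design(panel, calendar, cfg, group, holidays, base=base)
    fit = fit_quasipoisson(d.y, d.X)
    if not fit.converged:
        logger.warning("fit did not converge (community=%s group=%s)", community_id, group)
    effects = []
    for name, j in d.event_cols.items():
        beta = float(fit.beta[j])
        se = float(np.sqrt(fit.cov[j, j])) if np.isfinite(beta) else float("nan")
        if np.isfinite(beta) and np.isfinite(se):
            pct, lo, hi = pct_change(beta, se)
        else:
            beta = se = pct = lo = hi = float("nan")
        etype = name
        stratum = ""
        for s in (ev.LOW, ev.HIGH):
            if name.endswith(f"_{s}"):
                etype, stratum = name[: -len(s) - 1], s
        effects.append(
            EventEffect(
                community_id=community_id, kind=cfg.kind, event_type=etype,
                definition=definition, lag_spec=cfg.lag_label, stratum=stratum,
                beta=beta, se=se, pct=pct, pct_lo=lo, pct_hi=hi,
                n_event_days=d.n_event_days.get(etype, 0),
                converged=fit.converged,
            )
        )
    return effects, fit


def lag_profile(
    panel: pd.DataFrame,
    calendar: pd.DataFrame,
    cfg: ModelConfig,
    group: str,
    lags: range = range(22),
    holidays: set | None = None,
    community_id: str = "",
) -> list[EventEffect]:
    """Single-lag effect estimates for each lag (default lags 0-21 days)."""
    base = build_base_design(panel, cfg, holidays)
    out: list[EventEffect] = []
    for lag in lags:
        c = replace(cfg, event_lag_mode=("single", int(lag)))
        effects, _ = estimate_event_effects(
            panel, calendar, c, group, holidays, community_id=community_id, base=base
        )
        out.extend(effects)
    return out


def select_definition(
    panels: list[pd.DataFrame],
    kind: str,
    groups: list[str],
    cfg: ModelConfig | None = None,
    holidays: set | None = None,
    candidates: list[ev.EventDefinition] | None = None,
) -> tuple[ev.EventDefinition, pd.DataFrame]:
    """Q-AIC selection of the best event definition for one province.

    Each candidate definition (default: the full 18-definition grid) is
    fitted per community and group; the candidate with the minimum average
    Q-AIC wins.  Ties break toward the less severe percentile, then the
    shorter duration.  Candidates producing zero event days in every
    community are excluded from the competition.
    """
    if not panels:
        raise ValueError("at least one community panel is required")
    cfg = cfg or default_config(kind)
    candidates = candidates if candidates is not None else ev.enumerate_definitions(kind)
    bases = [build_base_design(p, cfg, holidays) for p in panels]
    rows = []
    for cand in candidates:
        qaics: list[float] = []
        any_events = False
        for panel, base in zip(panels, bases):
            cal = ev.build_event_calendar(
                panel["date"], panel["tmax"].to_numpy(), panel["tmin"].to_numpy(), cand
            )
            if (cal["event_type"] != "none").any():
                any_events = True
            for group in groups:
                d = build_design(panel, cal, cfg, group, holidays, base=base)
                fit = fit_quasipoisson(d.y, d.X)
                if fit.converged:
                    qaics.append(qaic(fit, cfg.qaic_variant))
        excluded = not any_events
        if excluded:
            logger.warning("definition %s has zero events everywhere; excluded", cand.label())
        rows.append(
            {
                "kind": cand.kind, "percentile": cand.percentile,
                "min_duration": cand.min_duration,
                "mean_qaic": float(np.mean(qaics)) if qaics else float("nan"),
                "n_fits": len(qaics), "excluded": excluded,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[~table["excluded"] & np.isfinite(table["mean_qaic"])]
    if ok.empty:
        raise ValueError("no candidate definition produced any events")
    best_q = ok["mean_qaic"].min()
    tied = [
        candidates[i]
        for i in ok.index[np.isclose(ok["mean_qaic"], best_q, rtol=0, atol=0)]
    ]
    if len(tied) > 1:
        logger.info("Q-AIC tie among %d definitions; breaking by severity", len(tied))
    best = min(tied, key=lambda d: (d.severity, d.min_duration))
    return best, table
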