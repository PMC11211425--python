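"""Reading and writing panels, metadata, holidays and run configuration.

Daily panel CSV schema (one file per community):

    date,tmin,tmean,tmax,rh,pressure[,pm25],deaths_<group>[,deaths_<group>...]

with ISO-8601 dates, temperatures in degC, relative humidity in %, pressure
in hPa, PM2.5 in ug/m3 and nonnegative integer daily death counts.  The
metadata CSV has one row per community with the community-level modifier
columns; the holiday CSV has columns ``date,label``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("date", "tmin", "tmean", "tmax", "rh", "pressure")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate one community's daily panel."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col!r}")
    if not any(c.startswith("deaths_") for c in df.columns):
        raise ValueError(f"{path.name}: missing column 'deaths_<group>'")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path.name}: unparseable date ({exc})") from exc
    gaps = (df["date"].diff().dt.days > 1).sum()
    if gaps:
        logger.warning("%s: %d gap(s) in the daily date sequence", path.name, gaps)
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a daily panel in the canonical CSV schema (ISO dates)."""
    out = panel.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def panel_groups(panel: pd.DataFrame) -> list[str]:
    """Mortality group labels present in a panel."""
    return [c.removeprefix("deaths_") for c in panel.columns if c.startswith("deaths_")]


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("community_id", "province_id"):
        if col not in df.columns:
            raise ValueError(f"metadata: missing column {col!r}")
    return df


def read_holidays(path: str | Path) -> set[pd.Timestamp]:
    df = pd.read_csv(path)
    if "date" not in df.columns:
        raise ValueError("holiday file: missing column 'date'")
    return set(pd.to_datetime(df["date"], format="ISO8601").dt.normalize())


def write_holidays(holidays: set[pd.Timestamp], path: str | Path) -> None:
    df = pd.DataFrame(
        {"date": sorted(d.strftime("%Y-%m-%d") for d in holidays)}
    )
    df["label"] = "holiday"
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one two-stage pipeline run (YAML round-trippable)."""

    panel_dir: str
    metadata_csv: str
    output_dir: str
    holiday_csv: str | None = None
    groups: list[str] | None = None  # None: infer from the first panel
    kinds: list[str] = field(default_factory=lambda: ["heat_wave", "cold_spell"])
    humidity_split: bool = False
    fixed_definition: bool = False  # 90th/10th percentile, >=2 days; skip selection
    season_df: int = 4
    covariate_df: int = 5
    covariate_lag_df: int = 4
    covariate_max_lag: int = 10
    adjust_pm25: bool = False
    qaic_variant: str = "penalty"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
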