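"""Reading GPS fixes and assembling filtered bird-month panels.

Transmitters report hourly fixes between 0500 and 2000 local time; a
bird-month enters the analysis only with at least ``min_fixes`` retained
fixes, which guards against months fragmented by recapture and husbandry
gaps.  Local time is fixed-offset standard time (default UTC-8, PST)
with no daylight-saving transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_FIX_COLUMNS = ("bird_id", "timestamp", "x_m", "y_m")
ATTRIBUTE_COLUMNS = ("bird_id", "sex", "age_class", "breeder", "release_site", "rearing")


@dataclass
class BirdMonth:
    """All retained fixes of one bird in one calendar month."""

    bird_id: str
    year: int
    month: int
    fixes: pd.DataFrame

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def points(self):
        return self.fixes[["x_m", "y_m"]].to_numpy()


def read_fixes(path) -> pd.DataFrame:
    """Read a fix table (CSV: bird_id, timestamp ISO-8601, x_m, y_m).

    Duplicate (bird_id, timestamp) rows keep the first occurrence, since
    a transmitter emits at most one fix per schedule slot.
    """
    fixes = pd.read_csv(path)
    missing = [c for c in REQUIRED_FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"fix table {path} is missing columns: {missing}")
    try:
        fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    except (ValueError, TypeError) as err:
        raise ValueError(f"malformed timestamp in {path}: {err}") from None
    n_raw = len(fixes)
    fixes = fixes.drop_duplicates(subset=["bird_id", "timestamp"], keep="first")
    if len(fixes) < n_raw:
        logger.warning("dropped %d duplicate (bird_id, timestamp) rows", n_raw - len(fixes))
    fixes = fixes.sort_values(["bird_id", "timestamp"], kind="stable").reset_index(drop=True)
    logger.info("read %d fixes (%d raw rows) from %s", len(fixes), n_raw, path)
    return fixes


def read_attributes(path) -> pd.DataFrame:
    """Read the bird attribute table keyed by bird_id."""
    attrs = pd.read_csv(path)
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in attrs.columns]
    if missing:
        raise ValueError(f"attribute table {path} is missing columns: {missing}")
    if attrs["bird_id"].duplicated().any():
        raise ValueError("attribute table has duplicate bird_id rows")
    return attrs


def window_filter(
    fixes: pd.DataFrame,
    start_hour: int = 5,
    end_hour: int = 20,
    tz_offset_hours: float = 0.0,
) -> pd.DataFrame:
    """Keep fixes whose local time falls in [start_hour, end_hour] inclusive.

    Both endpoints are scheduled transmitter slots, so both are kept.
    ``tz_offset_hours`` shifts timestamps recorded in UTC to local
    standard time (e.g. -8 for PST); synthetic data is already local.
    """
    if fixes.empty:
        return fixes.copy()
    local = fixes["timestamp"] + pd.Timedelta(hours=tz_offset_hours)
    minutes = local.dt.hour * 60 + local.dt.minute
    keep = (minutes >= start_hour * 60) & (minutes <= end_hour * 60)
    out = fixes[keep].reset_index(drop=True)
    logger.info("window filter kept %d of %d fixes", len(out), len(fixes))
    return out


def build_panels(fixes: pd.DataFrame, min_fixes: int = 100) -> list[BirdMonth]:
    """Group fixes into bird-months and drop under-sampled panels."""
    panels: list[BirdMonth] = []
    if fixes.empty:
        return panels
    ym = fixes["timestamp"]
    for (bird, year, month), grp in fixes.groupby(
        [fixes["bird_id"], ym.dt.year, ym.dt.month], sort=True
    ):
        if len(grp) >= min_fixes:
            panels.append(BirdMonth(str(bird), int(year), int(month), grp.reset_index(drop=True)))
        else:
            logger.info(
                "dropped panel %s %d-%02d with %d < %d fixes",
                bird, year, month, len(grp), min_fixes,
            )
    return panels
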