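"""Farmer yield-elicitation records and sensitivity typing.

Each farmer states three points of their subjective yield distribution
for a crop: the peak yield (py), the still-good yield (sgy, the lowest
yield they would still call acceptable) and their own long-run average
(avy_farm).  The willingness to accept fluctuation is wta = py - sgy.

A farmer's sensitivity type combines two conditions: whether sgy exceeds
avy_farm, and whether avy_farm exceeds the regional average avy_region.
A farmer who places the acceptability floor above their own average while
already out-yielding the region is highly sensitive to fluctuations; the
mirror case (sgy below average, farm above region) is low-sensitive.
Ties go to the less-sensitive side.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class SensitivityType(enum.Enum):
    HIGH_SENSITIVE = "high_sensitive"          # sgy > avy_farm, farm > region
    LOW_SENSITIVE = "low_sensitive"            # sgy <= avy_farm, farm > region
    DEMANDING_UNDERPERFORMER = "demanding_underperformer"  # sgy > avy_farm, farm <= region
    STANDARD = "standard"                      # sgy <= avy_farm, farm <= region


@dataclass(frozen=True)
class FarmerElicitation:
    farmer_id: str
    crop: str
    py: float
    sgy: float
    avy_farm: float | None = None

    def __post_init__(self) -> None:
        for name in ("py", "sgy"):
            v = getattr(self, name)
            if v is None or not v > 0:
                raise ValueError(f"{name} must be > 0")
        if self.avy_farm is not None and not self.avy_farm > 0:
            raise ValueError("avy_farm must be > 0 when present")
        if self.py < self.sgy:
            raise ValueError(
                f"peak yield {self.py} below still-good yield {self.sgy}: "
                "record rejected")


def wta(e: FarmerElicitation) -> float:
    """Willingness to accept fluctuation, py - sgy (dt/ha, >= 0)."""
    return e.py - e.sgy


def classify_sensitivity(e: FarmerElicitation, avy_region: float) -> SensitivityType:
    """Classify a farmer by (sgy vs avy_farm) and (avy_farm vs avy_region);
    strict inequalities mark the sensitive / outperforming side, so ties
    land on the less-sensitive label."""
    if avy_region <= 0:
        raise ValueError("avy_region must be > 0")
    if e.avy_farm is None:
        raise ValueError("cannot classify a record without avy_farm")
    floor_above_avg = e.sgy > e.avy_farm
    farm_above_region = e.avy_farm > avy_region
    if farm_above_region:
        return SensitivityType.HIGH_SENSITIVE if floor_above_avg \
            else SensitivityType.LOW_SENSITIVE
    return SensitivityType.DEMANDING_UNDERPERFORMER if floor_above_avg \
        else SensitivityType.STANDARD


def _descriptives(values: np.ndarray) -> dict:
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return {
        "mean": mean,
        "min": float(values.min()),
        "max": float(values.max()),
        "sd": sd,
        "skewness": float(stats.skew(values, bias=True)) if sd > 0 else float("nan"),
        "variance": sd * sd,
        "variation_coefficient": sd / mean if mean != 0 else float("nan"),
        "n": n,
    }


def summarize_elicitations(records, avy_region: float) -> dict:
    """Descriptive table over py / sgy / avy_farm / wta plus the count and
    share of highly sensitive farmers.

    Records missing ``avy_farm`` contribute to the py/sgy/wta rows but not
    to the avy_farm row or the sensitivity share, so per-variable n can
    differ.  Returns ``{"table": DataFrame, "n_high_sensitive": int,
    "share_high_sensitive_pct": float, "n_classified": int}``.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records to summarise")
    columns = {
        "py": [e.py for e in records],
        "sgy": [e.sgy for e in records],
        "avy_farm": [e.avy_farm for e in records if e.avy_farm is not None],
        "wta": [wta(e) for e in records],
    }
    table = pd.DataFrame({name: _descriptives(np.asarray(vals, dtype=float))
                          for name, vals in columns.items() if len(vals)}).T
    table["n"] = table["n"].astype(int)
    classified = [e for e in records if e.avy_farm is not None]
    n_high = sum(classify_sensitivity(e, avy_region) is SensitivityType.HIGH_SENSITIVE
                 for e in classified)
    share = 100.0 * n_high / len(classified) if classified else float("nan")
    return {"table": table, "n_high_sensitive": n_high,
            "share_high_sensitive_pct": share, "n_classified": len(classified)}


def read_elicitations_csv(path) -> list[FarmerElicitation]:
    """Read `farmer_id,crop,py,sgy,avy_farm` (avy_farm may be empty)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        avy = row.get("avy_farm")
        records.append(FarmerElicitation(
            farmer_id=str(row["farmer_id"]), crop=str(row["crop"]),
            py=float(row["py"]), sgy=float(row["sgy"]),
            avy_farm=None if pd.isna(avy) else float(avy)))
    return records
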