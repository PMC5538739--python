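"""Mean-standard-deviation risk statistics for yield and ARS series.

One row per scenario: yield moments (mean, SD with the n-1 denominator,
population-moment skewness m3 / m2^(3/2), coefficient of variation), the
relative frequency of seasons at or above the still-good yield, and the
mean and SD of the annual risk scores.  A comparison across scenarios
flags cases where the yield-variance ranking and the ARS ranking tell
different stories — the situation the score exists to surface, since a
season can deliver an acceptable yield while deviating wildly mid-season.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

#: marker for statistics that are undefined on the given input
UNDEFINED = float("nan")


@dataclass(frozen=True)
class YieldRiskSummary:
    scenario: str
    mean_yield: float
    sd_yield: float
    skewness: float
    variation_coefficient: float
    rel_freq_ge_sgy: float
    mean_ars: float
    sd_ars: float
    n_years: int

    def to_dict(self) -> dict:
        return asdict(self)


def _ars_totals(ars) -> np.ndarray:
    return np.asarray([getattr(a, "total", a) for a in ars], dtype=float)


def summarize(yields, ars, sgy: float, label: str = "") -> YieldRiskSummary:
    """Summarise one scenario.  ``ars`` may be ARSRecord objects or plain
    totals.  Skewness is reported as NaN when the yield SD is zero."""
    y = np.asarray(list(yields), dtype=float)
    a = _ars_totals(ars)
    if len(y) != len(a):
        raise ValueError("yields and ARS series must have equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 seasons to summarise")
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    skew = float(stats.skew(y, bias=True)) if sd > 0 else UNDEFINED
    cv = sd / mean if mean != 0 else UNDEFINED
    return YieldRiskSummary(
        scenario=label, mean_yield=mean, sd_yield=sd, skewness=skew,
        variation_coefficient=float(cv),
        rel_freq_ge_sgy=float((y >= sgy).mean()),
        mean_ars=float(a.mean()), sd_ars=float(a.std(ddof=1)),
        n_years=len(y))


def compare_scenarios(scenarios, sgy: float,
                      divergence_rank_gap: int = 2) -> pd.DataFrame:
    """Summarise a list of ``(label, yields, ars)`` scenarios.

    Adds a ``divergent`` flag where the scenario's rank by yield SD and
    its rank by mean ARS differ by at least ``divergence_rank_gap`` —
    i.e. where mean-variance analysis and the ARS methodology would rank
    the scenario's riskiness differently.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    summaries = [summarize(y, a, sgy, label) for label, y, a in scenarios]
    df = pd.DataFrame([s.to_dict() for s in summaries])
    if len(df) > 1:
        sd_rank = df["sd_yield"].rank(method="average")
        ars_rank = df["mean_ars"].rank(method="average")
        df["rank_gap"] = (sd_rank - ars_rank).abs()
        df["divergent"] = df["rank_gap"] >= divergence_rank_gap
    else:
        df["rank_gap"] = 0.0
        df["divergent"] = False
    return df
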