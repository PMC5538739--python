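"""Simulated-experience knowledge pool and acceptance ranges.

The pool is the modeled farmer's "memory": a grid of what-if seasons
(sowing day-of-year x weather year), reduced to those whose final yield
met the still-good-yield (sgy) threshold, summarised per observation
point (OP) and parameter as a Tukey boxplot whisker interval — the range
of fluctuation that historically was still compatible with an acceptable
yield.  OP 0 (sowing) is instead summarised as the relative frequency
with which each sowing day led to a yield >= sgy.

Observation schedule (defaults):

==== =============================== =========================
OP   anchor                          parameters
==== =============================== =========================
0    the sowing day itself           (success frequency only)
1    sowing + 30 days                10 standard parameters
2    fertilization 1 (BBCH 25)       "
3    fertilization 1 + 14 days       "
4    fertilization 2 (BBCH 30)       "
5    fertilization 3 (BBCH 39)       "
6    fertilization 3 + 14 days       "
7    harvest (maturity)              ", biomass = generative
==== =============================== =========================

The 10 standard parameters are LAI, soil water at four depths, soil
temperature at three depths, biomass (above-ground at OP 1-6, generative
at OP 7) and BBCH.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .cropsim import CropParams, GrowthTrace, SoilProfile, simulate_season
from .weathergen import DAYS_PER_YEAR, WeatherSeries

logger = logging.getLogger(__name__)

DEFAULT_SGY = 69.17  # dt/ha, regional still-good-yield mean

QUANTILE_CONVENTION = "linear"  # interpolation between order statistics


@dataclass(frozen=True)
class ObservationPointSpec:
    """Anchor rule and parameter list for one observation point."""

    op_index: int
    anchor_event: str          # sowing | fertilization_1..3 | harvest
    offset_days: int = 0
    parameters: tuple[str, ...] = ()
    label: str = ""

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)


def default_observation_scheme(soil: SoilProfile | None = None,
                               include_bbch: bool = True) -> list[ObservationPointSpec]:
    """The standard 8-OP scheme (OP 0 plus seven monitored OPs with 10
    parameters each; at harvest the biomass parameter switches from
    above-ground to generative biomass)."""
    soil = soil or SoilProfile()
    base = ["lai", *soil.water_columns, *soil.temp_columns]
    params = tuple(base + ["agb"] + (["bbch"] if include_bbch else []))
    params_harvest = tuple(base + ["gen_biomass"] + (["bbch"] if include_bbch else []))
    return [
        ObservationPointSpec(0, "sowing", 0, (), "Planting (day-of-year)"),
        ObservationPointSpec(1, "sowing", 30, params, "30 days after planting"),
        ObservationPointSpec(2, "fertilization_1", 0, params, "Fertilization 1"),
        ObservationPointSpec(3, "fertilization_1", 14, params, "14 days after fertilization 1"),
        ObservationPointSpec(4, "fertilization_2", 0, params, "Fertilization 2"),
        ObservationPointSpec(5, "fertilization_3", 0, params, "Fertilization 3"),
        ObservationPointSpec(6, "fertilization_3", 14, params, "14 days after fertilization 3"),
        ObservationPointSpec(7, "harvest", 0, params_harvest, "Harvest"),
    ]


def max_possible_score(scheme) -> int:
    """OP 0 contributes one binary score; every other OP one per parameter."""
    return 1 + sum(op.n_parameters for op in scheme if op.op_index != 0)


@dataclass
class AcceptanceRange:
    """Whisker interval of tolerable fluctuation for one (OP, parameter)."""

    op_index: int
    parameter: str
    lower: float
    upper: float
    q1: float
    q3: float
    iqr: float
    n_values: int

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class KnowledgePool:
    """Acceptance ranges plus per-DOY sowing success frequencies, tied to
    an sgy threshold.  ``values`` keeps the contributing observations per
    (op, parameter) so the pool can be updated year-on-year."""

    sgy: float
    ranges: dict[tuple[int, str], AcceptanceRange]
    op0_freq: dict[int, float]
    op0_counts: dict[int, tuple[int, int]]  # doy -> (successes, total)
    n_traces: int
    n_kept: int
    values: dict[tuple[int, str], list[float]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def range_for(self, op_index: int, parameter: str) -> AcceptanceRange:
        try:
            return self.ranges[(op_index, parameter)]
        except KeyError:
            raise KeyError(f"no acceptance range for OP {op_index} parameter "
                           f"{parameter!r}") from None

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sgy": self.sgy,
            "n_traces": self.n_traces,
            "n_kept": self.n_kept,
            "quantile_convention": QUANTILE_CONVENTION,
            "ranges": [asdict(r) for r in
                       sorted(self.ranges.values(), key=lambda r: (r.op_index, r.parameter))],
            "op0_freq": {str(k): v for k, v in sorted(self.op0_freq.items())},
            "op0_counts": {str(k): list(v) for k, v in sorted(self.op0_counts.items())},
            "values": {f"{op}:{p}": v for (op, p), v in sorted(self.values.items())},
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgePool":
        ranges = {}
        for r in d["ranges"]:
            ar = AcceptanceRange(**r)
            ranges[(ar.op_index, ar.parameter)] = ar
        values = {}
        for key, v in d.get("values", {}).items():
            op, p = key.split(":", 1)
            values[(int(op), p)] = list(v)
        return cls(sgy=d["sgy"], ranges=ranges,
                   op0_freq={int(k): v for k, v in d["op0_freq"].items()},
                   op0_counts={int(k): tuple(v) for k, v in d["op0_counts"].items()},
                   n_traces=d["n_traces"], n_kept=d["n_kept"],
                   values=values, provenance=d.get("provenance", {}))

    @classmethod
    def load(cls, path) -> "KnowledgePool":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# grid construction and filtering

def build_grid(series: WeatherSeries, doys, crop: CropParams,
               soil: SoilProfile) -> list[GrowthTrace]:
    """Simulate one season per (sowing DOY, weather year).

    Because autumn-sown seasons run into the following calendar year, a
    series of Y years supports Y-1 sowing years: the trace count is
    ``len(doys) * (Y - 1)``.
    """
    doys = list(doys)
    if not doys:
        raise ValueError("doys must be non-empty")
    if any(not 1 <= d <= DAYS_PER_YEAR for d in doys):
        raise ValueError("sowing DOYs must lie within the calendar year")
    years = series.years[:-1]
    if not years:
        raise ValueError("weather series must span at least two years")
    traces = []
    for doy in doys:
        for year in years:
            tid = f"doy{doy}_y{year}"
            traces.append(simulate_season(series, doy, crop, soil,
                                          sowing_year=year, trace_id=tid))
    return traces


def filter_by_sgy(traces, sgy: float) -> list[GrowthTrace]:
    """Keep seasons whose final yield did not fall below sgy (>= sgy)."""
    if not traces:
        raise ValueError("no traces to filter")
    kept = [t for t in traces if t.yield_dt >= sgy]
    if not kept:
        raise ValueError(
            f"no season reached sgy = {sgy} dt/ha; lower the threshold or "
            "widen the simulation grid")
    return kept


def tukey_whisker_range(values) -> tuple[float, float]:
    """Tukey boxplot whiskers: the innermost data points within the fences
    ``q1 - 1.5*IQR`` and ``q3 + 1.5*IQR`` (quartiles by linear
    interpolation).  Both returned bounds are actual data points."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError("whisker range needs at least 4 values")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return float(inside.min()), float(inside.max())


def op0_frequencies(traces, sgy: float) -> dict[int, float]:
    """Relative success frequency per sowing DOY: share of that DOY's
    seasons with yield >= sgy."""
    counts = op0_counts(traces, sgy)
    return {doy: succ / total for doy, (succ, total) in counts.items()}


def op0_counts(traces, sgy: float) -> dict[int, tuple[int, int]]:
    counts: dict[int, list[int]] = {}
    for t in traces:
        c = counts.setdefault(t.sowing_doy, [0, 0])
        c[1] += 1
        if t.yield_dt >= sgy:
            c[0] += 1
    return {d: (c[0], c[1]) for d, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# OP snapshots

def _op_date(trace: GrowthTrace, spec: ObservationPointSpec):
    """(year, doy) of an OP for a trace, or None if never reached."""
    ev = trace.event(spec.anchor_event)
    if ev is None:
        return None
    year, doy = ev.year, ev.doy + spec.offset_days
    while doy > DAYS_PER_YEAR:
        doy -= DAYS_PER_YEAR
        year += 1
    return year, doy


def op_snapshot(trace: GrowthTrace, spec: ObservationPointSpec) -> dict[str, float] | None:
    """End-of-day parameter values at an OP, or None if the season never
    reached the OP (failed seasons, or offsets past the series end)."""
    if spec.op_index == 0:
        return {}
    date = _op_date(trace, spec)
    if date is None:
        return None
    row = trace.state_on(*date)
    if row is None:
        # offset past harvest: hold the last recorded state (post-harvest
        # observation of a finished season) when within 30 days of it
        last = trace.daily.iloc[-1]
        span = (date[0] - int(last["year"])) * DAYS_PER_YEAR + date[1] - int(last["doy"])
        if 0 < span <= 30 and not trace.failed:
            row = last
        else:
            return None
    missing = [p for p in spec.parameters if p not in row.index]
    if missing:
        raise KeyError(f"trace lacks parameter(s) {missing} required by OP "
                       f"{spec.op_index}")
    return {p: float(row[p]) for p in spec.parameters}


def build_pool(traces, sgy: float, scheme=None) -> KnowledgePool:
    """Initialize a knowledge pool from a grid of simulated seasons.

    Acceptance ranges use only seasons with yield >= sgy; OP 0 success
    frequencies use all seasons (failures included).
    """
    scheme = scheme if scheme is not None else default_observation_scheme()
    kept = filter_by_sgy(traces, sgy)
    values: dict[tuple[int, str], list[float]] = {
        (op.op_index, p): [] for op in scheme if op.op_index != 0
        for p in op.parameters}
    for trace in kept:
        for op in scheme:
            if op.op_index == 0:
                continue
            snap = op_snapshot(trace, op)
            if snap is None:
                continue
            for p, v in snap.items():
                values[(op.op_index, p)].append(v)
    ranges = {}
    for (op_index, p), vals in values.items():
        if len(vals) < 4:
            raise ValueError(f"OP {op_index} parameter {p!r} has only "
                             f"{len(vals)} contributing values (need >= 4)")
        lo, hi = tukey_whisker_range(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        ranges[(op_index, p)] = AcceptanceRange(
            op_index=op_index, parameter=p, lower=lo, upper=hi,
            q1=float(q1), q3=float(q3), iqr=float(q3 - q1), n_values=len(vals))
    counts = op0_counts(traces, sgy)
    pool = KnowledgePool(
        sgy=sgy, ranges=ranges,
        op0_freq={d: s / t for d, (s, t) in counts.items()},
        op0_counts=counts,
        n_traces=len(traces), n_kept=len(kept), values=values,
        provenance={"quantile_convention": QUANTILE_CONVENTION,
                    "scheme": [op.op_index for op in scheme]})
    logger.info("pool built: sgy=%.2f, %d/%d seasons kept, %d ranges, "
                "quantiles=%s", sgy, pool.n_kept, pool.n_traces,
                len(ranges), QUANTILE_CONVENTION)
    return pool


def ranges_report(pool: KnowledgePool, scheme=None):
    """Wide table of acceptance ranges: one Min and one Max row per OP."""
    import pandas as pd

    scheme = scheme if scheme is not None else default_observation_scheme()
    rows = []
    for op in scheme:
        if op.op_index == 0:
            continue
        for bound in ("Min", "Max"):
            row = {"op": f"OP{op.op_index}", "label": op.label, "bound": bound}
            for p in op.parameters:
                r = pool.range_for(op.op_index, p)
                row[p] = r.lower if bound == "Min" else r.upper
            rows.append(row)
    return pd.DataFrame(rows)
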