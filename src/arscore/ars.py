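"""Annual Risk Score (ARS) computation.

Each monitored parameter at each observation point earns a binary utility
score: 0 when the observed value lies inside its acceptance range
(boundaries inclusive), 1 when outside.  Per-OP scores are the sum over
parameters; the annual score is the sum over OPs plus the OP-0 sowing
score, which is 1 when the sowing day's historical success frequency is
below 0.5.  With the default scheme (10 parameters x 7 OPs + OP 0) the
annual maximum is 71.  Higher = more perceived climatic risk; the score
never steers management, it only records perception.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .cropsim import GrowthTrace
from .knowledge import (AcceptanceRange, KnowledgePool, ObservationPointSpec,
                        default_observation_scheme, max_possible_score,
                        op_snapshot)

logger = logging.getLogger(__name__)


@dataclass
class ARSRecord:
    """Per-OP partial scores and the annual total for one season."""

    crop: str
    year: int
    sowing_doy: int
    op0_score: int
    alpha_t: dict[int, int]           # op index -> per-OP utility sum
    total: int
    max_possible: int
    yield_dt: float
    failed: bool = False
    unreached_ops: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        assert self.total == self.op0_score + sum(self.alpha_t.values())


def score_observation(value: float, rng: AcceptanceRange) -> int:
    """0 when ``lower <= value <= upper`` (inclusive), else 1."""
    if not math.isfinite(value):
        raise ValueError(f"non-finite observation value {value!r}")
    return 0 if rng.contains(value) else 1


def score_op(observation: dict[str, float], op_index: int,
             pool: KnowledgePool) -> int:
    """Per-OP utility sum: the number of parameters outside their ranges."""
    return sum(score_observation(v, pool.range_for(op_index, p))
               for p, v in observation.items())


def score_op0(sowing_doy: int, pool: KnowledgePool) -> int:
    """1 when the sowing day's relative success frequency is below 0.5
    (exactly 0.5 scores 0); a day absent from the pool is treated as
    risky."""
    freq = pool.op0_freq.get(sowing_doy)
    if freq is None:
        logger.warning("sowing DOY %d absent from pool; scored as risky",
                       sowing_doy)
        return 1
    return 1 if freq < 0.5 else 0


def score_season(trace: GrowthTrace, pool: KnowledgePool,
                 scheme=None, crop_label: str = "winter_wheat") -> ARSRecord:
    """Score a whole season against the pool.

    OPs a failed season never reached score their full parameter count
    (maximally risky): a season that dies mid-way must not out-score a
    completed risky one.  Scoring never mutates the trace or pool.
    """
    scheme = scheme if scheme is not None else default_observation_scheme()
    alpha_t: dict[int, int] = {}
    unreached = []
    for op in scheme:
        if op.op_index == 0:
            continue
        snap = op_snapshot(trace, op)
        if snap is None:
            alpha_t[op.op_index] = op.n_parameters
            unreached.append(op.op_index)
        else:
            alpha_t[op.op_index] = score_op(snap, op.op_index, pool)
    op0 = score_op0(trace.sowing_doy, pool)
    total = op0 + sum(alpha_t.values())
    return ARSRecord(crop=crop_label, year=trace.weather_year_label,
                     sowing_doy=trace.sowing_doy, op0_score=op0,
                     alpha_t=alpha_t, total=total,
                     max_possible=max_possible_score(scheme),
                     yield_dt=trace.yield_dt, failed=trace.failed,
                     unreached_ops=tuple(unreached))


def records_to_frame(records) -> pd.DataFrame:
    """Scores table: year, op0, alpha_1..alpha_m, total, max_possible, yield."""
    rows = []
    for r in records:
        row = {"year": r.year, "sowing_doy": r.sowing_doy, "op0": r.op0_score}
        for op_index in sorted(r.alpha_t):
            row[f"alpha_{op_index}"] = r.alpha_t[op_index]
        row.update(total=r.total, max_possible=r.max_possible,
                   yield_dt=r.yield_dt, failed=int(r.failed))
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.6f")
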