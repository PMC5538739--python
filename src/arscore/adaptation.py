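"""Year-on-year adaptation of the knowledge pool and planning rules.

After each harvest, the outcome decides what the new season's
observations teach the pool:

* yield >= sgy, observation inside its range — the value joins the
  distribution without (usually) shifting the whiskers;
* yield >= sgy, observation outside its range — the value is collated as
  a non-downside-risk point; accumulating such outliers eventually shifts
  the acceptance range;
* yield < sgy — the acceptance ranges are untouched: the loss was exactly
  what the threshold predicts.  OP-0 success frequencies are updated with
  the season's outcome in every case.

Expected ARS per crop is a (pluggable) weighted mean of past annual
scores; the planning constraint compares a crop's current score, summed
over the fields growing it, against that expectation.  The literal
reading keeps the comparison as "current >= expected"; because a higher
ARS means more perceived risk, a risk-averse planner may want the
opposite direction, so both readings sit behind a mode flag.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ars import ARSRecord
from .cropsim import GrowthTrace
from .knowledge import (AcceptanceRange, KnowledgePool, default_observation_scheme,
                        op_snapshot, tukey_whisker_range)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pool update

def update_pool(pool: KnowledgePool, trace: GrowthTrace,
                record: ARSRecord | None = None,
                scheme=None) -> KnowledgePool:
    """Return a new pool updated with one finished season.

    The input pool is never mutated.  If the season's yield is below sgy
    the acceptance ranges and their value sets are returned unchanged
    (only OP-0 counts move); otherwise every reached OP's observations
    join the value sets and the whisker ranges are recomputed.
    """
    scheme = scheme if scheme is not None else default_observation_scheme()
    new = copy.deepcopy(pool)
    if not new.values:
        raise ValueError("pool carries no value sets; rebuild it with "
                         "build_pool before updating")

    # OP-0 frequency update happens either way
    succ, total = new.op0_counts.get(trace.sowing_doy, (0, 0))
    total += 1
    if trace.yield_dt >= new.sgy:
        succ += 1
    new.op0_counts[trace.sowing_doy] = (succ, total)
    new.op0_freq[trace.sowing_doy] = succ / total
    new.n_traces += 1

    if trace.yield_dt < new.sgy:
        return new

    new.n_kept += 1
    for op in scheme:
        if op.op_index == 0:
            continue
        snap = op_snapshot(trace, op)
        if snap is None:
            continue
        for p, v in snap.items():
            key = (op.op_index, p)
            if key not in new.values:
                raise KeyError(f"pool has no value set for OP {op.op_index} "
                               f"parameter {p!r}")
            new.values[key].append(v)
            vals = new.values[key]
            lo, hi = tukey_whisker_range(vals)
            q1, q3 = np.percentile(vals, [25, 75])
            new.ranges[key] = AcceptanceRange(
                op_index=op.op_index, parameter=p, lower=lo, upper=hi,
                q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
                n_values=len(vals))
    return new


# ---------------------------------------------------------------------------
# expected ARS

WEIGHTING_SCHEMES = ("uniform", "exponential_decay", "fixed_window")


@dataclass
class ARSHistory:
    """Ordered annual ARS totals for one crop plus a weighting scheme."""

    crop: str
    totals: list[float]
    scheme: str = "uniform"
    decay: float = 0.7        # weight ratio year t-1 : year t
    window: int = 5           # fixed_window length

    def weights(self) -> np.ndarray:
        n = len(self.totals)
        if self.scheme == "uniform":
            w = np.ones(n)
        elif self.scheme == "exponential_decay":
            w = self.decay ** np.arange(n - 1, -1, -1)
        elif self.scheme == "fixed_window":
            w = np.zeros(n)
            w[-self.window:] = 1.0
        else:
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be non-negative and finite")
        return w / w.sum()


def expected_ars(history: ARSHistory) -> float:
    """Weighted mean of past annual scores (uniform = plain average)."""
    if not history.totals:
        raise ValueError("empty ARS history")
    return float(np.dot(history.weights(), np.asarray(history.totals, dtype=float)))


def expected_ars_weighted(totals, weights) -> float:
    """Explicit-weight variant; weights are normalised to sum 1."""
    w = np.asarray(list(weights), dtype=float)
    t = np.asarray(list(totals), dtype=float)
    if len(w) != len(t) or not len(t):
        raise ValueError("totals and weights must be equal-length, non-empty")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be non-negative and finite")
    return float(np.dot(w / w.sum(), t))


# ---------------------------------------------------------------------------
# planning constraint

@dataclass
class PlanningContext:
    """Fields with their allocated crop and the current year's score."""

    allocations: list[tuple[str, str, float]]  # (field id, crop, current ARS)
    expected: dict[str, float]                 # crop -> expected ARS


def planning_constraint(ctx: PlanningContext, mode: str = "literal") -> pd.DataFrame:
    """Evaluate the per-crop planning rule.

    ``literal`` keeps the stated direction (sum of current scores over the
    crop's fields >= expected score, satisfied when current >= expected);
    ``inverted`` flips it to the risk-averse reading (current <= expected,
    since a higher score means more perceived risk).  Returns one row per
    crop with the comparison, the verdict and the offending fields.
    """
    if mode not in ("literal", "inverted"):
        raise ValueError("mode must be 'literal' or 'inverted'")
    crops = sorted({crop for _, crop, _ in ctx.allocations})
    missing = [c for c in crops if c not in ctx.expected]
    if missing:
        raise KeyError(f"no expected ARS for crop(s): {missing}")
    rows = []
    for crop in crops:
        fields = [(f, s) for f, c, s in ctx.allocations if c == crop]
        current = sum(s for _, s in fields)
        exp = ctx.expected[crop]
        satisfied = current >= exp if mode == "literal" else current <= exp
        rows.append({
            "crop": crop, "n_fields": len(fields),
            "current_ars_sum": current, "expected_ars": exp,
            "mode": mode, "satisfied": satisfied,
            "fields": ";".join(f for f, _ in fields),
        })
        if not satisfied:
            logger.info("planning rule violated for %s (mode=%s): "
                        "current %.2f vs expected %.2f on fields %s",
                        crop, mode, current, exp,
                        ", ".join(f for f, _ in fields))
    return pd.DataFrame(rows)
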