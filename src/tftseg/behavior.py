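"""Behavioral performance scoring and NASA-TLX workload aggregation.

Performance is the hit rate normalized to 0-100: correct exercises
divided by exercises attempted in the session.  Workload follows the
two-step NASA-TLX procedure: 15 pairwise comparisons of the six factors
give integer weights summing to 15; each factor is then rated on a
21-point scale (0-100 in steps of 5) and the overall score is the
weighted mean of the ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six NASA-TLX workload factors.
TLX_FACTORS = ("mental", "physical", "temporal", "performance",
               "effort", "frustration")

#: Rating scale: 21 tick marks, 0..100 in steps of 5 ("20 equal intervals").
TLX_STEP = 5.0


@dataclass
class TLXRecord:
    """One participant's NASA-TLX response."""

    ratings: tuple[float, ...]                  # 6 values, 0-100 step 5
    weights: dict[str, int]                     # factor -> 0..5, sum 15
    choices: list[tuple[str, str, str]] = field(default_factory=list)
    overall: float = float("nan")


def normalize_score(hits: int, attempts: int) -> float:
    """Session score: 100 * hits / attempts.

    Returns NaN (an explicit missing marker) when no exercise was
    attempted, keeping longitudinal tables rectangular.
    """
    if hits < 0 or attempts < 0:
        raise ValueError("counts must be non-negative")
    if hits > attempts:
        raise ValueError(f"hits ({hits}) exceed attempts ({attempts})")
    if attempts == 0:
        return float("nan")
    return 100.0 * hits / attempts


def tlx_weights(choices) -> dict[str, int]:
    """Factor weights from the 15 pairwise comparisons.

    ``choices`` is an iterable of (factor_a, factor_b, winner) covering
    every unordered pair of the six factors exactly once.  A factor's
    weight is the number of pairs it won; weights sum to 15.
    """
    expected = {frozenset((TLX_FACTORS[i], TLX_FACTORS[j]))
                for i in range(6) for j in range(i + 1, 6)}
    seen = set()
    wins = dict.fromkeys(TLX_FACTORS, 0)
    for a, b, winner in choices:
        pair = frozenset((a, b))
        if pair not in expected:
            raise ValueError(f"unknown factor pair: ({a}, {b})")
        if pair in seen:
            raise ValueError(f"duplicate pair: ({a}, {b})")
        if winner not in (a, b):
            raise ValueError(f"winner {winner!r} not in pair ({a}, {b})")
        seen.add(pair)
        wins[winner] += 1
    if seen != expected:
        missing = expected - seen
        raise ValueError(f"incomplete pairwise set; {len(missing)} pairs missing")
    return wins


def tlx_overall(ratings, weights) -> float:
    """Overall workload: sum(rating * weight) / 15, in [0, 100]."""
    if isinstance(weights, dict):
        w = np.array([weights[f] for f in TLX_FACTORS], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    r = np.asarray(ratings, dtype=float)
    if r.shape != (6,) or w.shape != (6,):
        raise ValueError("need 6 ratings and 6 weights")
    if np.any((r < 0) | (r > 100)):
        raise ValueError("ratings must lie in [0, 100]")
    if w.sum() != 15 or np.any(w < 0):
        raise ValueError("weights must be non-negative and sum to 15")
    return float((r * w).sum() / 15.0)


def improvement(cohort: pd.DataFrame, from_session: int = 1,
                to_phase: str = "execution_same") -> pd.Series:
    """Per-participant score change from a session to an execution phase.

    Default: execution of the trained task minus the first (baseline)
    training session.  Indexed by participant; raises if either record
    is missing for any participant.
    """
    start = cohort[(cohort["session"] == from_session)
                   & (cohort["phase"] == "training")]
    end = cohort[cohort["phase"] == to_phase]
    s0 = start.set_index("participant")["score"]
    s1 = end.set_index("participant")["score"]
    missing = set(s0.index) ^ set(s1.index)
    if missing:
        raise ValueError(f"participants missing a session: {sorted(missing)}")
    return (s1 - s0).rename("improvement")


def workload_change(cohort: pd.DataFrame) -> pd.Series:
    """Per-participant TLX change: execution of trained task - session 1."""
    first = cohort[(cohort["session"] == 1) & (cohort["phase"] == "training")]
    ex = cohort[cohort["phase"] == "execution_same"]
    t0 = first.set_index("participant")["tlx"]
    t1 = ex.set_index("participant")["tlx"]
    return (t1 - t0).rename("workload_change")
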