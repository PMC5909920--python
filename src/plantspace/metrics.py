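"""Accuracy metrics for interval-distance estimation.

Two regimes: pairwise metrics when every estimated interval has a matched
ground-truth partner (controlled experiments), and row-wise metrics
comparing unpaired per-row means when estimated and true plant counts
differ (field conditions with missed plants and weeds).

Pairwise:  d_e = mean |ed_i - d_i|   (mean absolute error)
           d_t = mean (ed_i - d_i)   (signed bias)
           r   = d_e / d             (relative to the design spacing d)
Row-wise:  d_t = mean(ed) - mean(d)  (bias of unpaired means)
           r   = d_t / mean(d)

All distance metrics are in the unit of their inputs; ``r`` is returned as
a fraction (reports print it as percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, PairingError, UndefinedMetricError


@dataclass(frozen=True)
class EvalReport:
    """Aggregate accuracy report; ``per_row`` holds (row_id, d_t, r) triples."""

    d_e: float | None
    r: float | None
    d_t: float
    per_row: tuple[tuple[int, float, float], ...]
    n: int
    n_prime: int

    def to_frame(self) -> pd.DataFrame:
        """Row-by-row table with r in percent, plus an 'all' summary row."""
        rows = [
            {"row_id": rid, "d_t": dt, "r_pct": 100.0 * r} for rid, dt, r in self.per_row
        ]
        rows.append(
            {
                "row_id": "all",
                "d_t": self.d_t,
                "r_pct": 100.0 * self.r if self.r is not None else np.nan,
            }
        )
        return pd.DataFrame(rows)


def pairwise_metrics(
    estimated: list[float], truth: list[float], design_d: float
) -> tuple[float, float, float]:
    """(d_e, r, d_t) for rank-matched interval pairs.

    ``design_d`` is the nominal planting spacing the relative error is
    referred to, so a large absolute error on a wide spacing can still be a
    small r.
    """
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if est.shape != tru.shape:
        raise PairingError(f"paired lengths differ: {est.size} vs {tru.size}")
    if est.size == 0:
        raise UndefinedMetricError("pairwise metrics undefined on empty input")
    if design_d <= 0:
        raise InvalidInputError("design_d must be > 0")
    diff = est - tru
    d_e = float(np.mean(np.abs(diff)))
    d_t = float(np.mean(diff))
    return d_e, d_e / design_d, d_t


def rowwise_metrics(
    estimated: list[float], truth: list[float]
) -> tuple[float, float]:
    """(d_t, r) from unpaired means; estimated and truth counts may differ."""
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    if tru.size == 0 or est.size == 0:
        raise UndefinedMetricError("row-wise metrics undefined on empty input")
    d_t = float(np.mean(est) - np.mean(tru))
    return d_t, d_t / float(np.mean(tru))


def match_by_rank(
    estimated: list[float], truth: list[float]
) -> tuple[list[float], list[float]]:
    """Pair intervals by along-row rank, dropping unmatched trailing ones.

    With a missed or spurious plant the tail ranks have no partner; those
    regimes are what the row-wise metrics exist for.
    """
    n = min(len(estimated), len(truth))
    return list(estimated[:n]), list(truth[:n])


def evaluate_rows(
    estimated_by_row: dict[int, list[float]],
    truth_by_row: dict[int, list[float]],
    mode: str = "rowwise",
    design_d: float | None = None,
) -> EvalReport:
    """Per-row accuracy over matched row ids, plus pooled summary.

    ``mode="pairwise"`` rank-matches intervals within each row and needs
    ``design_d``; ``mode="rowwise"`` compares unpaired per-row means.
    """
    common = sorted(set(estimated_by_row) & set(truth_by_row))
    if not common:
        raise UndefinedMetricError("no matching row ids between estimate and truth")
    per_row = []
    all_est: list[float] = []
    all_tru: list[float] = []
    for rid in common:
        est, tru = estimated_by_row[rid], truth_by_row[rid]
        if not est or not tru:
            continue
        if mode == "pairwise":
            if design_d is None:
                raise InvalidInputError("pairwise mode requires design_d")
            e, t = match_by_rank(est, tru)
            _, r_row, dt_row = pairwise_metrics(e, t, design_d)
            all_est.extend(e)
            all_tru.extend(t)
        elif mode == "rowwise":
            dt_row, r_row = rowwise_metrics(est, tru)
            all_est.extend(est)
            all_tru.extend(tru)
        else:
            raise InvalidInputError(f"unknown mode {mode!r}")
        per_row.append((rid, dt_row, r_row))
    if not per_row:
        raise UndefinedMetricError("no row had both estimated and true intervals")
    if mode == "pairwise":
        d_e, r, d_t = pairwise_metrics(all_est, all_tru, design_d)
    else:
        d_e = None
        d_t, r = rowwise_metrics(all_est, all_tru)
    return EvalReport(d_e, r, d_t, tuple(per_row), len(all_est), len(all_tru))
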