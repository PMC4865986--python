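"""Cohort-level comparison of drug-count measures.

Two descriptive summaries: per-measure count percentiles (25th, 50th,
75th, 95th, nearest-rank convention) and, against a reference measure,
the distribution of per-patient change in count binned as 0, 1, or >=2
drugs. The comparison report stacks both side by side, one row per
measure, which is the natural shape for a measure-sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import count_cohort
from .measures import MeasureSpec
from .model import DrugProduct, PatientHistory

PERCENTILES = (25, 50, 75, 95)


@dataclass(frozen=True)
class PercentileSummary:
    measure_id: str
    n_patients: int
    p25: float
    p50: float
    p75: float
    p95: float


@dataclass(frozen=True)
class ChangeDistribution:
    measure_id: str
    reference_id: str
    pct_no_change: float
    pct_change_1: float
    pct_change_ge2: float


def nearest_rank(sorted_values: Sequence, p: float):
    """The p-th percentile as the value at rank ceil(p/100 * n) (1-based)."""
    n = len(sorted_values)
    rank = max(1, math.ceil(p / 100 * n))
    return sorted_values[rank - 1]


def percentile_summary(
    counts: Sequence[int],
    measure_id: str,
    convention: str = "nearest_rank",
) -> PercentileSummary:
    """Count percentiles for one measure over a cohort.

    ``nearest_rank`` (the default) always returns an observed count, so
    integer counts give integer percentiles; ``linear`` interpolates
    (numpy's default) for users who prefer it.
    """
    if len(counts) == 0:
        raise ValueError("percentile_summary requires at least one count")
    values = sorted(counts)
    if convention == "nearest_rank":
        ps = [nearest_rank(values, p) for p in PERCENTILES]
    elif convention == "linear":
        ps = list(np.percentile(values, PERCENTILES))
    else:
        raise ValueError(f"unknown percentile convention {convention!r}")
    return PercentileSummary(measure_id, len(values), *ps)


def change_distribution(
    reference_counts: Sequence[int],
    variant_counts: Sequence[int],
    measure_id: str = "variant",
    reference_id: str = "reference",
) -> ChangeDistribution:
    """Percent of patients whose count changed by 0, 1 or >=2 drugs.

    Inputs are per-patient counts aligned on the same patients in the
    same order; the binning uses the absolute difference, so the result
    is symmetric in direction of change.
    """
    if len(reference_counts) != len(variant_counts):
        raise ValueError(
            f"length mismatch: {len(reference_counts)} reference vs "
            f"{len(variant_counts)} variant counts"
        )
    if len(reference_counts) == 0:
        raise ValueError("change_distribution requires at least one patient")
    deltas = np.abs(np.asarray(variant_counts) - np.asarray(reference_counts))
    n = len(deltas)
    return ChangeDistribution(
        measure_id=measure_id,
        reference_id=reference_id,
        pct_no_change=100.0 * np.count_nonzero(deltas == 0) / n,
        pct_change_1=100.0 * np.count_nonzero(deltas == 1) / n,
        pct_change_ge2=100.0 * np.count_nonzero(deltas >= 2) / n,
    )


def comparison_report(
    histories: Sequence[PatientHistory],
    measures: Sequence[MeasureSpec],
    dictionary: Mapping[str, DrugProduct],
    reference_id: str = "default",
    percentile_convention: str = "nearest_rank",
) -> pd.DataFrame:
    """One row per measure: count percentiles plus change-from-reference bins.

    The reference measure's own change row is (100, 0, 0) by construction.
    """
    ids = [m.measure_id for m in measures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate measure_id in measure list")
    if reference_id not in ids:
        raise ValueError(f"reference_id {reference_id!r} not among measures {ids}")

    counts_by_measure = {
        m.measure_id: [r.count for r in count_cohort(histories, m, dictionary)]
        for m in measures
    }
    reference = counts_by_measure[reference_id]
    rows = []
    for m in measures:
        counts = counts_by_measure[m.measure_id]
        summ = percentile_summary(counts, m.measure_id, percentile_convention)
        chg = change_distribution(reference, counts, m.measure_id, reference_id)
        rows.append({
            "measure_id": m.measure_id,
            "description": m.description,
            "n_patients": summ.n_patients,
            "p25": summ.p25, "p50": summ.p50, "p75": summ.p75, "p95": summ.p95,
            "pct_no_change": round(chg.pct_no_change, 1),
            "pct_change_1": round(chg.pct_change_1, 1),
            "pct_change_ge2": round(chg.pct_change_ge2, 1),
        })
    return pd.DataFrame(rows)


def render_report_text(report: pd.DataFrame) -> str:
    """Human-readable view; change percentages in (0, 1) render as "<1"."""
    view = report.copy()
    for col in ("pct_no_change", "pct_change_1", "pct_change_ge2"):
        if col not in view.columns:
            continue
        view[col] = [
            "<1" if 0 < v < 1 else format(v, "g") for v in view[col]
        ]
    return view.to_string(index=False)
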