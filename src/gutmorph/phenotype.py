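"""Rule-based phenotype classification and study-level summary.

Each cell is called from two published morphological criteria:

* **count criterion** — a cell is "high-vesicle" when its secretory-vesicle
  count is at least ``count_ratio`` (default 3) times a baseline count
  representing a typical main-stomach cell;
* **polarity criterion** — among high-vesicle cells, an apical fraction
  above 0.75 calls the cell exocrine-like (acinar-like) and one below
  0.50 calls it differentiating.

The two polarity bounds do not tile [0, 1]: a high-vesicle cell whose
apical fraction falls in [0.50, 0.75] is reported ``indeterminate``
rather than silently forced to a side.  Cells failing the count
criterion, including zero-vesicle cells, are called ``stomach``.

The baseline is either supervised (median count over caller-supplied
reference stomach cells) or unsupervised: the median of the lower half of
the per-cell counts (cells at or below the overall median), a robust
stand-in for the "typical" low-vesicle cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeThresholds",
    "PhenotypeCall",
    "SummaryReport",
    "baseline_count",
    "classify_cells",
    "summarize",
]

CALLS = ("exocrine", "differentiating", "indeterminate", "stomach")


@dataclass
class PhenotypeThresholds:
    """Published bounds: >=3x count enrichment, >75% / <50% apical."""

    count_ratio: float = 3.0
    apical_min: float = 0.75
    diff_max: float = 0.50

    def __post_init__(self):
        if self.count_ratio < 1:
            raise ValueError("count_ratio must be >= 1")
        if not 0 <= self.diff_max <= self.apical_min <= 1:
            raise ValueError(
                "thresholds must satisfy 0 <= diff_max <= apical_min <= 1"
            )


@dataclass
class PhenotypeCall:
    """One cell's call with the evidence it rests on (re-derivable)."""

    cell_id: int
    call: str
    n_secretory: int
    baseline: float
    ratio: float
    apical_fraction: float  # NaN for zero-vesicle cells


def baseline_count(counts, reference_cell_ids=None) -> float:
    """Baseline secretory count of a "typical" low-vesicle cell.

    ``counts`` maps cell id -> secretory count (mapping or Series).  With
    reference ids the baseline is their median; otherwise the median of
    the lower half (counts at or below the overall median).  A zero
    baseline is replaced by the smallest positive count; all-zero counts
    are an error in unsupervised mode.
    """
    series = pd.Series(dict(counts)) if not isinstance(counts, pd.Series) else counts
    if len(series) < 2:
        raise ValueError(f"need at least 2 cells for a baseline, got {len(series)}")
    if reference_cell_ids is not None:
        ref = series.loc[list(reference_cell_ids)]
        baseline = float(ref.median())
    else:
        overall = float(series.median())
        lower = series[series <= overall]
        baseline = float(lower.median())
    if baseline == 0:
        positive = series[series > 0]
        if positive.empty:
            raise ValueError("all cells have zero vesicles; no baseline exists")
        baseline = float(positive.min())
    return baseline


def classify_cells(
    cell_table: pd.DataFrame,
    thresholds: PhenotypeThresholds | None = None,
    baseline: float | None = None,
    reference_cell_ids=None,
) -> pd.DataFrame:
    """Call every cell from its count and apical fraction.

    ``cell_table`` needs columns ``cell_id``, ``n_secretory`` and
    ``apical_fraction`` (NaN allowed for zero-vesicle cells); this is the
    output of :func:`gutmorph.polarity.polarity_table`.  ``baseline`` is
    computed from the table itself when not supplied.  Returns the table
    with ``baseline``, ``ratio`` and ``call`` columns appended.
    """
    thresholds = thresholds or PhenotypeThresholds()
    counts = pd.Series(
        cell_table["n_secretory"].to_numpy(), index=cell_table["cell_id"]
    )
    if baseline is None:
        baseline = baseline_count(counts, reference_cell_ids)
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")

    out = cell_table.copy()
    out["baseline"] = baseline
    out["ratio"] = out["n_secretory"] / baseline

    calls = []
    for _, row in out.iterrows():
        high = row["n_secretory"] >= thresholds.count_ratio * baseline
        frac = row["apical_fraction"]
        if not high or row["n_secretory"] == 0:
            calls.append("stomach")
        elif not math.isnan(frac) and frac > thresholds.apical_min:
            calls.append("exocrine")
        elif not math.isnan(frac) and frac < thresholds.diff_max:
            calls.append("differentiating")
        else:
            calls.append("indeterminate")
    out["call"] = calls
    return out


@dataclass
class SummaryReport:
    """Study-level summary of a classified scene."""

    per_phenotype: pd.DataFrame
    count_ratio_exocrine_vs_stomach: float  # NaN when either class is absent
    count_ratio_differentiating_vs_stomach: float
    confusion: pd.DataFrame | None = None  # rows: truth, columns: call
    recall: pd.Series | None = None


def summarize(calls: pd.DataFrame, ground_truth: pd.DataFrame | None = None) -> SummaryReport:
    """Aggregate calls: per-class n, count and apical-fraction moments,
    headline mean-count ratios, and (with ground truth) a confusion matrix
    with per-class recall.

    ``ground_truth`` is the per-cell table from the scene generator
    (columns ``cell_id`` and ``phenotype``).  Degenerate cases (a class
    absent) yield NaN ratios, never a division error.
    """
    groups = calls.groupby("call")
    per = groups.agg(
        n=("cell_id", "size"),
        count_mean=("n_secretory", "mean"),
        count_sd=("n_secretory", "std"),
        apical_mean=("apical_fraction", "mean"),
        apical_sd=("apical_fraction", "std"),
    ).reindex(list(CALLS))

    def ratio(cls: str) -> float:
        num = per.loc[cls, "count_mean"]
        den = per.loc["stomach", "count_mean"]
        if np.isnan(num) or np.isnan(den) or den == 0:
            return float("nan")
        return float(num / den)

    confusion = None
    recall = None
    if ground_truth is not None:
        merged = calls.merge(
            ground_truth[["cell_id", "phenotype"]], on="cell_id", validate="one_to_one"
        )
        confusion = pd.crosstab(merged["phenotype"], merged["call"]).reindex(
            index=["exocrine", "differentiating", "stomach"],
            columns=list(CALLS),
            fill_value=0,
        )
        diag = pd.Series(
            {cls: confusion.loc[cls, cls] for cls in confusion.index},
            name="recall",
        )
        recall = diag / confusion.sum(axis=1).replace(0, np.nan)

    return SummaryReport(
        per_phenotype=per,
        count_ratio_exocrine_vs_stomach=ratio("exocrine"),
        count_ratio_differentiating_vs_stomach=ratio("differentiating"),
        confusion=confusion,
        recall=recall,
    )
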