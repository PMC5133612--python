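"""Descriptive indices over the classification grid.

From the sweep of percent-correct scores across window lengths, four summary
tables are derived per (attribute, phase) cell:

* occurrence counts — how many window lengths scored at or above each of the
  thresholds 75, 80, 85, 90, 95% correct;
* prominence — the mean of those five counts;
* modality specificity — threshold-summed counts normalized within each
  attribute row (rows sum to 100%): which phases carry an attribute;
* phase specificity — the same counts normalized within each phase column
  (columns sum to 100%): which attributes a phase carries;
* window-bin profile — mean score per five window-length classes, normalized
  within each attribute row.

Missing cells (NaN scores) contribute nothing to the counts; an all-zero
normalization slice is reported as undefined (NaN), never as 0/0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ATTRIBUTES, PHASES

logger = logging.getLogger(__name__)

THRESHOLDS: tuple[int, ...] = (75, 80, 85, 90, 95)

#: window-length classes (ms, inclusive bounds); on the standard 50 ms grid
#: the class sizes are 14, 13, 12, 13 and 13 window lengths.
WINDOW_BINS: dict[int, tuple[int, int]] = {
    1: (50, 700),
    2: (750, 1350),
    3: (1400, 1950),
    4: (2000, 2600),
    5: (2650, 3250),
}


def _cells(results: pd.DataFrame):
    attrs = [a for a in ATTRIBUTES if a in set(results["attribute"])]
    phases = [p for p in PHASES if p in set(results["phase"])]
    return attrs, phases


def count_occurrences(
    results: pd.DataFrame, thresholds: tuple[int, ...] = THRESHOLDS
) -> pd.DataFrame:
    """Occurrence counts: window lengths with score >= threshold, per cell.

    ``results`` is the long-format classification table (one row per
    attribute/phase/window cell). Counts are non-increasing in the threshold.
    """
    attrs, phases = _cells(results)
    rows = []
    for a in attrs:
        for p in phases:
            scores = results.loc[
                (results["attribute"] == a) & (results["phase"] == p),
                "percent_correct",
            ].to_numpy()
            if np.all(np.isnan(scores)) and scores.size:
                logger.info("cell %s/%s has no scores; counts are 0", a, p)
            for t in thresholds:
                rows.append(
                    {
                        "attribute": a,
                        "phase": p,
                        "threshold": t,
                        "count": int(np.nansum(scores >= t)),
                    }
                )
    return pd.DataFrame(rows)


def _count_matrix(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Threshold-summed counts as an attribute x phase matrix."""
    return (
        occurrences.groupby(["attribute", "phase"], sort=False)["count"]
        .sum()
        .unstack("phase")
    )


def prominence(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Mean occurrence count over the five thresholds, per cell."""
    return (
        occurrences.groupby(["attribute", "phase"], sort=False)["count"]
        .mean()
        .unstack("phase")
    )


def modality_specificity(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized counts: each attribute's row sums to 100%."""
    m = _count_matrix(occurrences)
    totals = m.sum(axis=1)
    if (totals == 0).any():
        logger.warning(
            "all-zero occurrence row(s) %s: modality specificity undefined",
            list(totals.index[totals == 0]),
        )
    return m.div(totals.replace(0, np.nan), axis=0) * 100.0


def phase_specificity(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Column-normalized counts: each phase's column sums to 100%."""
    m = _count_matrix(occurrences)
    totals = m.sum(axis=0)
    if (totals == 0).any():
        logger.warning(
            "all-zero occurrence column(s) %s: phase specificity undefined",
            list(totals.index[totals == 0]),
        )
    return m.div(totals.replace(0, np.nan), axis=1) * 100.0


def window_bin_profile(
    results: pd.DataFrame, bins: dict[int, tuple[int, int]] | None = None
) -> pd.DataFrame:
    """Mean score per window class, normalized within each attribute row.

    Rows are attributes, columns are (phase, window class); each attribute's
    values are divided by the row total and scaled to sum to 100.
    """
    bins = bins or WINDOW_BINS
    attrs, phases = _cells(results)
    table = {}
    for a in attrs:
        row = {}
        for p in phases:
            cell = results[(results["attribute"] == a) & (results["phase"] == p)]
            for cls, (lo, hi) in bins.items():
                sel = cell[(cell["window_ms"] >= lo) & (cell["window_ms"] <= hi)]
                row[(p, cls)] = float(np.nanmean(sel["percent_correct"])) if len(sel) else np.nan
        table[a] = row
    df = pd.DataFrame(table).T
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["phase", "window_class"])
    totals = df.sum(axis=1)
    return df.div(totals.replace(0, np.nan), axis=0) * 100.0


def bin_sizes(bins: dict[int, tuple[int, int]] | None = None, step: int = 50) -> dict[int, int]:
    """Number of window lengths (multiples of ``step``) inside each class."""
    bins = bins or WINDOW_BINS
    return {
        cls: int(hi // step - (lo - 1) // step) for cls, (lo, hi) in bins.items()
    }
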