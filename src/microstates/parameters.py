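"""Per-subject microstate parameters and transition syntax.

Quantifies, per subject and class: duration (mean lifespan of a state, ms,
over non-truncated segments), occurrence (segments per analyzed second),
coverage (percent of assigned samples), mean GFP (mean field strength over
the class's samples, microvolts) and class GEV.  Transition syntax is the
relative percentage of each ordered class pair among consecutive segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backfitting import Segmentation
from .preprocessing import GFPSeries

__all__ = [
    "TruncationPolicy",
    "compute_parameters",
    "transition_table",
    "TransitionTable",
    "exclude_outliers",
    "aggregate_overall",
    "PARAMETER_COLUMNS",
]

logger = logging.getLogger(__name__)

#: the per-class parameter columns of a ParameterTable
PARAMETER_COLUMNS = ("duration_ms", "occurrence_per_s", "coverage_pct", "mean_gfp_uv", "gev_class")


class TruncationPolicy:
    """How segments cut off by an epoch edge enter the statistics.

    DURATION_ONLY (default): truncated segments are excluded from duration
    means only — their samples still count for occurrence, coverage, mean
    GFP and transitions.  STRICT: truncated segments are excluded from
    duration, occurrence and transition counting as well.
    """

    DURATION_ONLY = "duration-only"
    STRICT = "strict"


def compute_parameters(
    seg: Segmentation,
    gfp: GFPSeries,
    policy: str = TruncationPolicy.DURATION_ONLY,
    gev_class: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-class parameter rows for one subject's segmentation.

    Returns a DataFrame with one row per class: duration_ms (NaN when no
    qualifying segment exists — never zero), occurrence_per_s, coverage_pct,
    mean_gfp_uv and gev_class (NaN unless supplied).
    """
    if seg.labels.size != gfp.values.size:
        raise ValueError("segmentation and GFP series must be aligned")
    analyzed_s = sum(stop - start for start, stop in seg.epochs) / seg.fs_hz
    n_assigned = seg.n_assigned
    rows = []
    for k in range(seg.k):
        class_segs = [s for s in seg.segments if s.cls == k]
        full = [s for s in class_segs if not s.truncated]
        if full:
            duration = float(np.mean([s.duration_ms(seg.fs_hz) for s in full]))
        else:
            duration = float("nan")
            logger.info("class %d has no non-truncated segment; duration missing", k)
        counted = full if policy == TruncationPolicy.STRICT else class_segs
        occurrence = len(counted) / analyzed_s
        sel = seg.labels == k
        n_k = int(sel.sum())
        coverage = 100.0 * n_k / n_assigned if n_assigned else float("nan")
        mean_gfp = float(gfp.values[sel].mean()) if n_k else float("nan")
        rows.append(
            {
                "class": k,
                "duration_ms": duration,
                "occurrence_per_s": occurrence,
                "coverage_pct": coverage,
                "mean_gfp_uv": mean_gfp,
                "gev_class": float(gev_class[k]) if gev_class is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TransitionTable:
    """K x K transition counts and row-normalized percentages.

    ``percentages[i, j]`` is 100 * counts[i, j] / row-total; rows with no
    outgoing transition are NaN.  The diagonal is structurally zero
    (consecutive segments always differ in class).
    """

    counts: np.ndarray
    percentages: np.ndarray
    n_transitions: int


def transition_table(
    seg: Segmentation, policy: str = TruncationPolicy.DURATION_ONLY
) -> TransitionTable:
    """Count ordered transitions between consecutive segments per epoch.

    Pairs never span an epoch boundary.  Under the STRICT policy, pairs
    involving a truncated segment are dropped.
    """
    K = seg.k
    counts = np.zeros((K, K), dtype=int)
    for start, stop in seg.epochs:
        ep_segs = [s for s in seg.segments if start <= s.start and s.stop <= stop]
        for a, b in zip(ep_segs[:-1], ep_segs[1:]):
            if b.start != a.stop:
                continue  # unassigned gap between runs
            if policy == TruncationPolicy.STRICT and (a.truncated or b.truncated):
                continue
            counts[a.cls, b.cls] += 1
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / row_tot[:, None]
    pct[row_tot == 0] = np.nan
    return TransitionTable(counts=counts, percentages=pct, n_transitions=int(counts.sum()))


def exclude_outliers(
    table: pd.DataFrame, parameter: str, n_sd: float = 3.0
) -> tuple[pd.DataFrame, list[str]]:
    """Single-pass M +/- 3 SD screen, per group and class, for one parameter.

    ``table`` is a long ParameterTable with columns subject_id, group,
    class and the parameter columns.  A subject is excluded from this
    parameter's analyses when any of its class values falls outside its own
    group's mean +/- ``n_sd`` * SD for that class.  The screen is not
    iterated after removal.
    """
    if parameter not in table.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    stats = table.groupby(["group", "class"])[parameter].agg(["mean", "std"])
    excluded: set[str] = set()
    for (group, cls), sub in table.groupby(["group", "class"]):
        m, sd = stats.loc[(group, cls), "mean"], stats.loc[(group, cls), "std"]
        if not np.isfinite(sd) or sd == 0:
            continue
        bad = sub.loc[np.abs(sub[parameter] - m) > n_sd * sd, "subject_id"]
        excluded.update(bad)
    if excluded:
        logger.info("outlier screen on %s excluded: %s", parameter, sorted(excluded))
    kept = table[~table["subject_id"].isin(excluded)].copy()
    return kept, sorted(excluded)


def aggregate_overall(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per-subject overall value: unweighted mean of the four class values.

    Subjects with a missing class value get a missing overall (logged).
    Returns columns subject_id, group, migraine, <parameter>.
    """
    if parameter not in table.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    out = []
    for subject, sub in table.groupby("subject_id", sort=False):
        vals = sub[parameter].to_numpy(dtype=float)
        if np.isnan(vals).any():
            overall = float("nan")
            logger.info("subject %s: missing class value for %s; overall missing", subject, parameter)
        else:
            overall = float(vals.mean())
        out.append(
            {
                "subject_id": subject,
                "group": sub["group"].iloc[0],
                "migraine": bool(sub["migraine"].iloc[0]) if "migraine" in sub else False,
                parameter: overall,
            }
        )
    return pd.DataFrame(out)
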