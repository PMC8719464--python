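"""Multi-reader multi-case (MRMC) observer-study analytics.

In a fully crossed MRMC design every reader assesses every case twice —
once unaided and once aided by the model's probability of malignancy (POM)
— recording a BI-RADS category, a benign/malignant call, a POM (0-100%)
and the diagnosis time.  This module reproduces the study arithmetic:

* per-reader ROC curves and AUCs from the recorded POMs, with the
  reader-averaged AUC comparison between sessions;
* an AUC-difference test by case-level bootstrap (readers fixed) — a
  documented substitute for variance-component MRMC inference;
* binary metrics (sensitivity, specificity, PPV, NPV) and reconstruction
  of integer confusion matrices from printed rates;
* tabulation of BI-RADS category changes between sessions, with the
  "closer to biopsy" convention that a change counts as concordant when it
  moves toward the recall side (category 4 and above) for malignant truth
  and toward 3 and below for benign truth;
* per-reader diagnosis-time comparison with a paired t-test.

ROC construction follows the rank-threshold sweep: POMs are ranked
ascending, TPR/FPR computed at each distinct threshold, and the AUC taken
by the trapezoidal rule, which equals the Mann-Whitney statistic with
half-credit for ties.

Reader records are pandas DataFrames with columns ``reader_id, session,
case_id, birads, call, pom_percent, time_s``; truth is a mapping or a
DataFrame with ``case_id, pathology``.  A packaged fixture
(``data/reader_study.json``) carries the summary tables of the six-reader,
51-case study (22 malignant, 29 benign) this module was built around.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIRADS_ORDER",
    "RocCurve",
    "ConfusionCounts",
    "BinaryMetrics",
    "BiradsChangeTable",
    "DesignError",
    "load_reader_study",
    "records_from_frame",
    "roc_from_poms",
    "reader_average_auc",
    "auc_difference_test",
    "binary_metrics",
    "confusion_from_rates",
    "birads_changes",
    "time_comparison",
]

#: Ordinal positions of BI-RADS assessment categories; plain "4" sits
#: between 3 and 4a.
BIRADS_ORDER: dict[str, float] = {
    "1": 1.0,
    "2": 2.0,
    "3": 3.0,
    "4": 3.5,
    "4a": 4.0,
    "4b": 5.0,
    "4c": 6.0,
    "5": 7.0,
}

RECORD_COLUMNS = ("reader_id", "session", "case_id", "birads", "call", "pom_percent", "time_s")
SESSIONS = ("unaided", "aided")


class DesignError(ValueError):
    """The records violate the fully crossed reader x case design."""


def load_reader_study() -> dict:
    """Packaged summary tables of the six-reader, 51-case observer study."""
    text = resources.files("perceptcad.data").joinpath("reader_study.json").read_text()
    return json.loads(text)


def records_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a reader-record table against the record contract."""
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"reader records missing columns {sorted(missing)}")
    out = frame.copy()
    out["birads"] = out["birads"].astype(str).str.lower()
    bad = ~out["birads"].isin(BIRADS_ORDER)
    if bad.any():
        raise ValueError(f"unknown BI-RADS categories: {sorted(out.loc[bad, 'birads'].unique())}")
    if not out["session"].isin(SESSIONS).all():
        raise ValueError(f"session must be one of {SESSIONS}")
    if not out["call"].isin(("benign", "malignant")).all():
        raise ValueError("call must be benign or malignant")
    if ((out["pom_percent"] < 0) | (out["pom_percent"] > 100)).any():
        raise ValueError("POM must lie in [0, 100] percent")
    if (out["time_s"] <= 0).any():
        raise ValueError("time_s must be positive")
    return out


def _truth_series(truth) -> pd.Series:
    if isinstance(truth, pd.DataFrame):
        truth = truth.set_index("case_id")["pathology"]
    elif isinstance(truth, Mapping):
        truth = pd.Series(truth)
    if not truth.isin(("benign", "malignant")).all():
        raise ValueError("pathology must be benign or malignant")
    return truth


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    """A threshold-sweep ROC: ascending thresholds with FPR/TPR and AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_from_poms(poms: Sequence[float], truth: Sequence[int]) -> RocCurve:
    """ROC curve and trapezoidal AUC from per-case scores.

    Thresholds are the ranked distinct POMs (ascending); at each threshold
    a case is called positive when its POM >= threshold.  The trapezoidal
    AUC equals the Mann-Whitney statistic with half-credit for ties.
    """
    scores = np.asarray(poms, dtype=np.float64)
    y = np.asarray(truth, dtype=int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("poms and truth must be equal-length 1-D")
    if not np.isfinite(scores).all():
        raise ValueError("POMs must be finite")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both classes must be present")
    thresholds = np.unique(scores)  # ascending
    # predicted positive iff score >= t; prepend a sub-minimal threshold so
    # the curve starts at (1,1) and ends at (0,0) after the max threshold
    tpr = np.empty(len(thresholds) + 1)
    fpr = np.empty(len(thresholds) + 1)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[i] = (pred & (y == 1)).sum() / n_pos
        fpr[i] = (pred & (y == 0)).sum() / n_neg
    tpr[-1], fpr[-1] = 0.0, 0.0
    # ascending-threshold sweep yields nonincreasing rates; integrate along FPR
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return RocCurve(thresholds=thresholds, fpr=fpr[::-1], tpr=tpr[::-1], auc=auc)


def _pivot_session(records: pd.DataFrame, session: str) -> pd.DataFrame:
    """reader x case POM matrix for one session; errors list missing cells."""
    sub = records[records["session"] == session]
    pivot = sub.pivot_table(index="reader_id", columns="case_id", values="pom_percent")
    if pivot.isna().any().any():
        gaps = [
            (r, c)
            for r in pivot.index
            for c in pivot.columns
            if pd.isna(pivot.loc[r, c])
        ]
        raise DesignError(f"missing reader x case cells in session {session!r}: {gaps[:10]}")
    return pivot


def reader_average_auc(records: pd.DataFrame, truth, session: str):
    """Per-reader AUCs and their arithmetic mean for one session.

    Requires the fully crossed design (every reader scored every case).
    Returns ``(average, per_reader)`` with the average reported at full
    precision (round to 3 decimals for tables).
    """
    records = records_from_frame(records)
    truth = _truth_series(truth)
    pivot = _pivot_session(records, session)
    y = (truth.loc[pivot.columns] == "malignant").astype(int).to_numpy()
    per_reader = {
        reader: roc_from_poms(pivot.loc[reader].to_numpy(), y).auc for reader in pivot.index
    }
    return float(np.mean(list(per_reader.values()))), per_reader


def auc_difference_test(
    records: pd.DataFrame,
    truth,
    n_boot: int = 2000,
    seed: int = 0,
):
    """Aided-minus-unaided reader-averaged AUC with bootstrap inference.

    Cases are resampled with replacement (readers fixed) to build the
    percentile interval and a two-sided p-value for the difference in
    reader-averaged AUC.  This case-level bootstrap stands in for
    variance-component MRMC inference.  Resamples missing a class are
    redrawn.  Returns a dict with ``difference``, ``ci`` (2.5/97.5
    percentiles), ``p_value`` and the per-session averages.
    """
    import logging

    if n_boot < 100:
        logging.getLogger(__name__).warning("n_boot=%d is small; interval will be crude", n_boot)
    records = records_from_frame(records)
    truth = _truth_series(truth)
    pivots = {s: _pivot_session(records, s) for s in SESSIONS}
    cases = pivots["unaided"].columns
    if not cases.equals(pivots["aided"].columns):
        raise DesignError("sessions cover different case sets")
    y = (truth.loc[cases] == "malignant").astype(int).to_numpy()
    mats = {s: pivots[s].to_numpy() for s in SESSIONS}

    def avg_auc(mat, yy, idx) -> float:
        return float(
            np.mean([roc_from_poms(mat[r, idx], yy[idx]) .auc for r in range(mat.shape[0])])
        )

    full_idx = np.arange(len(cases))
    observed = {s: avg_auc(mats[s], y, full_idx) for s in SESSIONS}
    diff = observed["aided"] - observed["unaided"]

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, len(cases), len(cases))
            if 0 < y[idx].sum() < len(idx):
                break
        boots[b] = avg_auc(mats["aided"], y, idx) - avg_auc(mats["unaided"], y, idx)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    # two-sided p: how often the bootstrap difference crosses zero
    p_low = (np.sum(boots <= 0) + 1) / (n_boot + 1)
    p_high = (np.sum(boots >= 0) + 1) / (n_boot + 1)
    p_value = min(1.0, 2 * min(p_low, p_high))
    return {
        "difference": diff,
        "unaided": observed["unaided"],
        "aided": observed["aided"],
        "ci": (float(lo), float(hi)),
        "p_value": float(p_value),
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# binary metrics and confusion reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class BinaryMetrics:
    """Sens/spec/PPV/NPV at full precision; NaN marks an undefined metric."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def rounded(self, decimals: int = 3) -> "BinaryMetrics":
        def _r(v: float) -> float:
            if np.isnan(v):
                return v
            # round half up, as in the printed tables
            q = 10**decimals
            return float(np.floor(v * q + 0.5) / q)

        return BinaryMetrics(*(_r(getattr(self, f)) for f in
                               ("sensitivity", "specificity", "ppv", "npv")))


def binary_metrics(counts: ConfusionCounts) -> BinaryMetrics:
    """Sensitivity, specificity, PPV and NPV from a confusion matrix.

    A zero denominator yields NaN (an undefined-metric marker), never an
    exception.
    """

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return BinaryMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
    )


def confusion_from_rates(
    sens: float, spec: float, n_pos: int, n_neg: int, atol: float | None = None
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed sens/spec.

    ``tp = round(sens * n_pos)`` and ``tn = round(spec * n_neg)``.  The
    reconstruction must agree with the printed rate to within ``atol``
    (default: half a count, ``0.5/n``); pass e.g. ``atol=0.0005`` to demand
    that the count reproduces a 3-decimal printed rate exactly, in which
    case a typo'd rate raises an inconsistency error.
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("rates must lie in [0, 1]")
    tp = int(round(sens * n_pos))
    tn = int(round(spec * n_neg))
    tol_pos = 0.5 / n_pos if atol is None else atol
    tol_neg = 0.5 / n_neg if atol is None else atol
    if abs(tp / n_pos - sens) > tol_pos:
        raise ValueError(f"sensitivity {sens} inconsistent with any count of {n_pos}")
    if abs(tn / n_neg - spec) > tol_neg:
        raise ValueError(f"specificity {spec} inconsistent with any count of {n_neg}")
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


# ---------------------------------------------------------------------------
# BI-RADS change tabulation
# ---------------------------------------------------------------------------


@dataclass
class BiradsChangeTable:
    """Per-reader counts of BI-RADS category changes between sessions."""

    per_reader: pd.DataFrame  # index reader_id; columns n_increase, n_decrease,
    #                           n_total, n_closer_to_biopsy, n_not_matching
    totals: pd.Series

    def validate(self) -> None:
        pr = self.per_reader
        if not (pr["n_total"] == pr["n_increase"] + pr["n_decrease"]).all():
            raise ValueError("n_total must equal n_increase + n_decrease")
        if not self.totals.equals(pr.sum()):
            raise ValueError("grand totals must be the column sums")


def _matched_sessions(unaided: pd.DataFrame, aided: pd.DataFrame, value: str) -> pd.DataFrame:
    u = unaided.set_index(["reader_id", "case_id"])[value]
    a = aided.set_index(["reader_id", "case_id"])[value]
    if u.index.has_duplicates or a.index.has_duplicates:
        raise DesignError("duplicate reader x case records")
    if not u.index.sort_values().equals(a.index.sort_values()):
        raise DesignError("unaided and aided sessions do not cover the same reader x case pairs")
    return pd.DataFrame({"unaided": u, "aided": a.loc[u.index]}).reset_index()


def birads_changes(unaided: pd.DataFrame, aided: pd.DataFrame, truth) -> BiradsChangeTable:
    """Count per-reader BI-RADS increases/decreases and biopsy concordance.

    A changed case counts as "closer to biopsy" when the aided category
    moved toward the recall side (>= 4) for malignant truth, or toward the
    follow-up side (<= 3) for benign truth; every other change is "not
    matching".
    """
    unaided = records_from_frame(unaided)
    aided = records_from_frame(aided)
    truth = _truth_series(truth)
    pairs = _matched_sessions(unaided, aided, "birads")
    rank_u = pairs["unaided"].map(BIRADS_ORDER)
    rank_a = pairs["aided"].map(BIRADS_ORDER)
    malignant = pairs["case_id"].map(truth) == "malignant"
    increase = rank_a > rank_u
    decrease = rank_a < rank_u
    changed = increase | decrease
    closer = changed & ((malignant & increase) | (~malignant & decrease))
    tab = pd.DataFrame(
        {
            "reader_id": pairs["reader_id"],
            "n_increase": increase.astype(int),
            "n_decrease": decrease.astype(int),
            "n_closer_to_biopsy": closer.astype(int),
            "n_not_matching": (changed & ~closer).astype(int),
        }
    ).groupby("reader_id").sum()
    tab["n_total"] = tab["n_increase"] + tab["n_decrease"]
    tab = tab[["n_increase", "n_decrease", "n_total", "n_closer_to_biopsy", "n_not_matching"]]
    table = BiradsChangeTable(per_reader=tab, totals=tab.sum())
    table.validate()
    return table


# ---------------------------------------------------------------------------
# diagnosis-time comparison
# ---------------------------------------------------------------------------


def time_comparison(unaided: pd.DataFrame, aided: pd.DataFrame) -> pd.DataFrame:
    """Per-reader mean diagnosis times, difference, percent change, paired t.

    Means are reported to 2 decimals; the difference is aided minus
    unaided; percent change is relative to the unaided mean; the p-value is
    a two-sided paired t-test over per-case times.
    """
    unaided = records_from_frame(unaided)
    aided = records_from_frame(aided)
    pairs = _matched_sessions(unaided, aided, "time_s")
    rows = []
    for reader, grp in pairs.groupby("reader_id"):
        if len(grp) < 2:
            raise ValueError(f"reader {reader}: need >= 2 paired cases for the t-test")
        mean_u = round(float(grp["unaided"].mean()), 2)
        mean_a = round(float(grp["aided"].mean()), 2)
        diff = round(mean_a - mean_u, 2)
        if np.allclose(grp["aided"], grp["unaided"]):
            p = 1.0
        else:
            p = float(stats.ttest_rel(grp["aided"], grp["unaided"]).pvalue)
        rows.append(
            {
                "reader_id": reader,
                "mean_unaided_s": mean_u,
                "mean_aided_s": mean_a,
                "difference_s": diff,
                "percent_change": round(100.0 * diff / mean_u, 1),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("reader_id")
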