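"""Careless / improbable response screening.

Implements the four multiple-hurdle exclusion criteria —

1. LongString: an unbroken run of "yes" across the 42-item lifetime
   prescription block in presentation order, required to span at least two
   drug classes;
2. even-odd consistency on the prescription block (mechanical yes/no
   alternation shows up as a strongly negative correlation);
3. the same on the shorter illicitly-manufactured-drug block, with a
   stricter threshold;
4. total last-12-month products endorsed (modified outlier rule);

plus the three internal-consistency validation metrics (section completion
time, Mahalanobis distance over lifetime prescription, nonprescription and
illicit responses, and contradictory first/last-use timeline answers) and
the rejected introductory-timing rule (reported, never flags).

A respondent is excluded when flagged by any single criterion.

Even-odd operationalization: for binary endorsement blocks the package's
default statistic is the Pearson correlation between the response sequence
and itself shifted by one presentation position (``mode="serial"``).  This
is the only split that yields -1 for strict alternation, ~0 for random
responding, and is undefined for constant rows; a positional split-half
variant (odd-position vector vs even-position vector, paired) is available
as ``mode="split"``.  Both are interpretations — the field's even-odd
index is defined for multi-item scales, not binary blocks — and the choice
is documented rather than load-bearing: flagging uses whichever mode is
configured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codebook import RECENCY_RANK
from .types import (
    CutPoints,
    EndorsementMatrix,
    ItemCatalog,
    Panel,
    PanelValidationError,
    RESPONDENT_ID,
)


# ---------------------------------------------------------------------------
# Criterion metrics
# ---------------------------------------------------------------------------

def longest_positive_run(
    responses: np.ndarray, class_labels: np.ndarray
) -> tuple[int, int]:
    """Length of the longest run of 1s and the number of distinct drug
    classes inside that run (earliest maximal run on ties).

    Both vectors must be in the respondent's presentation order.
    """
    responses = np.asarray(responses)
    class_labels = np.asarray(class_labels)
    if responses.shape != class_labels.shape:
        raise PanelValidationError(
            "responses and class labels must have equal length"
        )
    best_len = best_start = cur = start = 0
    for i, v in enumerate(responses):
        if v:
            if cur == 0:
                start = i
            cur += 1
            if cur > best_len:
                best_len, best_start = cur, start
        else:
            cur = 0
    if best_len == 0:
        return 0, 0
    spanned = len(set(class_labels[best_start:best_start + best_len]))
    return best_len, spanned


def alternation_consistency(
    responses: np.ndarray, mode: str = "serial"
) -> float:
    """Even-odd consistency of a binary response vector in presentation
    order; NaN (undefined, never flagged) for short or constant input.

    ``mode="serial"`` correlates the vector with its one-position shift;
    ``mode="split"`` correlates the odd-position half against the
    even-position half, paired positionally (trailing unpaired element
    dropped).
    """
    x = np.asarray(responses, dtype=float)
    if x.size < 4:
        return float("nan")
    if mode == "serial":
        a, b = x[:-1], x[1:]
    elif mode == "split":
        k = x.size // 2
        a, b = x[0:2 * k:2], x[1:2 * k:2]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _alternation_consistency_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise serial-mode consistency for a matrix already in each
    respondent's presentation order (vectorized)."""
    A = X[:, :-1].astype(float)
    B = X[:, 1:].astype(float)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A * A).sum(axis=1))
    sb = np.sqrt((B * B).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=1) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    if X.shape[1] < 4:
        r[:] = np.nan
    return r


def total_endorsed(row: np.ndarray) -> int:
    """Count of products endorsed in a last-12-month row."""
    return int(np.asarray(row).sum())


def flag_overendorser(count: int, cut: int) -> bool:
    """Flag iff ``count >= cut`` (the conservative cut is inclusive)."""
    return count >= cut


def mahalanobis_distances(
    X: np.ndarray, ridge_scale: float = 1e-6
) -> np.ndarray:
    """Mahalanobis distance of each row from the sample mean.

    ``d_i = sqrt((x_i - xbar)' S^-1 (x_i - xbar))`` with the sample
    covariance ``S``; when ``S`` is singular (binary blocks routinely have
    zero-variance items) a ridge ``eps*I`` with
    ``eps = ridge_scale * trace(S)/p`` is added.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    centered = X - X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1) if n > 1 else np.zeros((p, p))
    S = np.atleast_2d(S)
    if np.trace(S) <= 0:
        raise PanelValidationError(
            "zero-variance endorsement matrix: Mahalanobis distance undefined"
        )
    try:
        solved = np.linalg.solve(S, centered.T)
    except np.linalg.LinAlgError:
        solved = None
    if solved is None or not np.isfinite(solved).all() or (
        np.linalg.matrix_rank(S) < p
    ):
        eps = ridge_scale * np.trace(S) / p
        solved = np.linalg.solve(S + eps * np.eye(p), centered.T)
    d2 = np.einsum("ij,ji->i", centered, solved)
    return np.sqrt(np.clip(d2, 0.0, None))


def contradiction_count(timelines: pd.DataFrame) -> pd.Series:
    """Per-respondent count of drug classes whose most-recent-use answer is
    strictly less recent than the first-use answer (absent pairs count 0).
    """
    if timelines.empty:
        return pd.Series(dtype=int)
    for col in ("first_use_period", "last_use_period"):
        unknown = ~timelines[col].isin(RECENCY_RANK)
        if unknown.any():
            raise PanelValidationError(
                f"unknown recency category {timelines.loc[unknown, col].iloc[0]!r}"
            )
    first = timelines["first_use_period"].map(RECENCY_RANK)
    last = timelines["last_use_period"].map(RECENCY_RANK)
    contradict = (last < first).astype(int)
    return contradict.groupby(timelines[RESPONDENT_ID]).sum()


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per-respondent exclusion report plus the summary block."""

    report: pd.DataFrame
    summary: dict

    @property
    def excluded_ids(self) -> list[str]:
        r = self.report
        return list(r.loc[r["excluded"], RESPONDENT_ID])

    @property
    def n_excluded(self) -> int:
        return int(self.report["excluded"].sum())


def _ordered_subsequence(matrix: EndorsementMatrix, catalog: ItemCatalog,
                         category: str) -> tuple[np.ndarray, np.ndarray]:
    """(values, class labels) for items of ``category``, per-row in
    presentation order."""
    cat_of = catalog.category_of()
    cls_of = catalog.class_of()
    member = np.array([cat_of[it] == category for it in matrix.items])
    k = int(member.sum())
    mask = member[matrix.presentation_order]
    sel = matrix.presentation_order[mask].reshape(matrix.n, k)
    values = np.take_along_axis(matrix.values, sel, axis=1)
    labels = np.array([cls_of[it] for it in matrix.items], dtype=object)[sel]
    return values, labels


def screen(panel: Panel, cuts: CutPoints | None = None,
           alternation_mode: str = "serial") -> ScreenResult:
    """Compute every criterion and validation metric for every respondent
    and combine them multiple-hurdles style (excluded = any flag)."""
    cuts = cuts or CutPoints()
    cuts.validate()
    lifetime = panel.matrices["lifetime"]
    last12m = panel.matrices["last12m"]
    n = panel.n

    rx_vals, rx_labels = _ordered_subsequence(lifetime, panel.catalog,
                                              "prescription")
    il_vals, _ = _ordered_subsequence(lifetime, panel.catalog, "illicit")

    runs = np.empty(n, dtype=int)
    spans = np.empty(n, dtype=int)
    for i in range(n):
        runs[i], spans[i] = longest_positive_run(rx_vals[i], rx_labels[i])

    if alternation_mode == "serial":
        rx_r = _alternation_consistency_rows(rx_vals)
        il_r = _alternation_consistency_rows(il_vals)
    else:
        rx_r = np.array([alternation_consistency(v, alternation_mode)
                         for v in rx_vals])
        il_r = np.array([alternation_consistency(v, alternation_mode)
                         for v in il_vals])

    totals = last12m.values.sum(axis=1).astype(int)

    # validation metrics
    cat_of = panel.catalog.category_of()
    maha_items = [it for it in lifetime.items
                  if cat_of[it] in ("prescription", "nonprescription", "illicit")]
    maha_cols = [lifetime.items.index(it) for it in maha_items]
    maha = mahalanobis_distances(lifetime.values[:, maha_cols])

    contra = contradiction_count(panel.timelines)
    contra = (
        contra.reindex(panel.respondent_ids).fillna(0).astype(int).to_numpy()
        if len(contra) else np.zeros(n, dtype=int)
    )

    time_rx = panel.respondents["time_rx_s"].to_numpy()
    time_intro = panel.respondents["time_intro_s"].to_numpy()

    c1 = (runs >= cuts.c1_min_run) & (spans >= cuts.c1_min_classes)
    with np.errstate(invalid="ignore"):
        c2 = np.nan_to_num(rx_r, nan=0.0) < cuts.c2_threshold
        c2 &= ~np.isnan(rx_r)
        c3 = np.nan_to_num(il_r, nan=0.0) < cuts.c3_threshold
        c3 &= ~np.isnan(il_r)
    c4 = totals >= cuts.c4_max_endorsed
    fast_intro = time_intro < cuts.intro_fast_seconds  # reported, never flags
    excluded = c1 | c2 | c3 | c4

    report = pd.DataFrame({
        RESPONDENT_ID: panel.respondent_ids,
        "longest_run": runs,
        "classes_spanned": spans,
        "rx_alternation_r": rx_r,
        "illicit_alternation_r": il_r,
        "total_endorsed": totals,
        "mahalanobis_d": maha,
        "rx_section_time_s": time_rx,
        "intro_time_s": time_intro,
        "fast_intro": fast_intro,
        "contradiction_count": contra,
        "c1": c1, "c2": c2, "c3": c3, "c4": c4,
        "excluded": excluded,
    })
    summary = _summarize(report)
    return ScreenResult(report=report, summary=summary)


def _summarize(report: pd.DataFrame) -> dict:
    flags = report[["c1", "c2", "c3", "c4"]].to_numpy()
    overlap = flags.T.astype(int) @ flags.astype(int)
    excluded = report["excluded"]
    n = len(report)

    def group_stats(mask: pd.Series) -> dict:
        sub = report.loc[mask]
        if not len(sub):
            return {"n": 0}
        return {
            "n": int(len(sub)),
            "rx_time_median_s": float(sub["rx_section_time_s"].median()),
            "rx_time_iqr_s": [
                float(sub["rx_section_time_s"].quantile(0.25)),
                float(sub["rx_section_time_s"].quantile(0.75)),
            ],
            "mahalanobis_mean": float(sub["mahalanobis_d"].mean()),
            "mahalanobis_sd": float(sub["mahalanobis_d"].std(ddof=1))
            if len(sub) > 1 else 0.0,
            "contradiction_pct": float(
                100 * (sub["contradiction_count"] > 0).mean()
            ),
        }

    return {
        "n": n,
        "n_excluded": int(excluded.sum()),
        "pct_excluded": float(100 * excluded.mean()) if n else 0.0,
        "criterion_counts": {
            f"c{k + 1}": int(flags[:, k].sum()) for k in range(4)
        },
        "pairwise_overlap": {
            f"c{i + 1}&c{j + 1}": int(overlap[i, j])
            for i in range(4) for j in range(i + 1, 4)
        },
        "excluded_stats": group_stats(excluded),
        "included_stats": group_stats(~excluded),
        "n_fast_intro": int(report["fast_intro"].sum()),
    }


def summary_table(summary: dict, suppress_below: int = 5) -> pd.DataFrame:
    """Printable criterion summary; counts below ``suppress_below`` are
    suppressed for disclosure protection (display only — stored values are
    never altered)."""
    rows = []
    for crit, count in summary["criterion_counts"].items():
        shown = "-" if 0 < count < suppress_below else str(count)
        rows.append({"criterion": crit, "n_flagged": shown})
    rows.append({"criterion": "any", "n_flagged": str(summary["n_excluded"])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Attrition vs dispensing volume
# ---------------------------------------------------------------------------

def relative_decrease(n_before: float, n_after: float) -> float:
    """Percentage decrease ``100*(n_before - n_after)/n_before``."""
    if n_before <= 0:
        raise PanelValidationError("relative decrease undefined for n_before <= 0")
    return 100.0 * (n_before - n_after) / n_before


def attrition_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation (average-rank ties, two-sided t-approximation
    p-value) between relative decrease and dispensing volume."""
    rho, p = stats.spearmanr(table["relative_decrease_pct"],
                             table["dispensing_volume"])
    return float(rho), float(p)


def endorsement_attrition_analysis(
    excluded_ids, last12m: EndorsementMatrix, catalog: ItemCatalog
) -> tuple[pd.DataFrame, float, float]:
    """Per-ingredient endorsement counts before/after exclusions, the
    relative decrease, and its Spearman correlation with dispensing volume.

    Only ingredients carrying a dispensing volume enter the correlation;
    ingredients with zero endorsements before exclusion are dropped from it
    (logged in the returned table with NaN decrease).
    """
    keep = ~np.isin(last12m.respondents, list(excluded_ids))
    ing_of = catalog.ingredient_of()
    vol = catalog.table.dropna(subset=["dispensing_volume"]) if (
        "dispensing_volume" in catalog.table.columns
    ) else pd.DataFrame(columns=catalog.table.columns)
    vol_of = dict(zip(vol["ingredient"], vol["dispensing_volume"]))

    records = []
    items = np.array(last12m.items)
    ingredients = np.array([ing_of[it] for it in items], dtype=object)
    for ing in dict.fromkeys(ingredients):
        if ing not in vol_of:
            continue
        cols = np.nonzero(ingredients == ing)[0]
        before = int(last12m.values[:, cols].sum())
        after = int(last12m.values[keep][:, cols].sum())
        records.append({
            "ingredient": ing,
            "n_before": before,
            "n_after": after,
            "relative_decrease_pct": relative_decrease(before, after)
            if before > 0 else np.nan,
            "dispensing_volume": float(vol_of[ing]),
        })
    table = pd.DataFrame(records)
    usable = table.dropna(subset=["relative_decrease_pct"])
    if len(usable) >= 3:
        rho, p = attrition_correlation(usable)
    else:
        rho, p = float("nan"), float("nan")
    return table, rho, p
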