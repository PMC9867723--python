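"""Two-step time-course differential analysis and core-gene classification.

Step 1 (time-course gate): for every feature and every donor trajectory,
take the log2 deviation from the 0 h baseline at the time point where its
absolute value is largest (a signed score), aggregate the per-donor scores
within each group by the median, and keep features whose absolute group
median exceeds a threshold in at least one group.

Step 2 (group comparison): at each time point, compute the PD-minus-HC
difference of group medians (the "median log2FC") and a shrinkage
t-statistic whose per-feature variances are shrunk toward the median
variance with a James-Stein-derived intensity; p-values are
Benjamini-Hochberg adjusted across features within each time point.

Core features are those with adjusted p <= alpha and |median log2FC| >=
a group gate at one or more time points; they are further labelled by
activation window (early 0-2 h, intermediary 4-8 h, late 12-24 h),
direction (increased / decreased / mixed) and recurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import CohortDesign, ExpressionMatrix, SchemaError
from .simulate import WINDOWS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Gates of the two-step procedure (all on the log2 scale).

    ``tc_log2`` is the time-course gate on the absolute group-median
    deviation score.  The default 0.5 matches the reported per-gate counts;
    the alternative reading "fold change >= 1.5" corresponds to
    ``tc_log2 = log2(1.5) ~ 0.585`` and can be set explicitly.
    """

    tc_log2: float = 0.5
    grp_log2: float = 0.5
    alpha_adj: float = 0.05
    min_recurrence: int = 2

    def __post_init__(self) -> None:
        if self.tc_log2 <= 0 or self.grp_log2 <= 0:
            raise ValueError("gates must be > 0")
        if not (0 < self.alpha_adj <= 1):
            raise ValueError("alpha_adj must be in (0, 1]")
        if self.min_recurrence < 1:
            raise ValueError("min_recurrence must be >= 1")

    @classmethod
    def from_fold_change(cls, tc_abs_fc: float = 1.5, **kw) -> "Thresholds":
        return cls(tc_log2=float(np.log2(tc_abs_fc)), **kw)


# ---------------------------------------------------------------------------
# step 1: time-course deviation gate
# ---------------------------------------------------------------------------

def max_deviation(profile: pd.Series) -> tuple[float, float]:
    """Max |log2 deviation from t=0| of one sample trajectory.

    ``profile`` is indexed by time in hours.  Returns ``(max_abs, signed)``
    where ``signed`` is the deviation at the time point of maximum absolute
    deviation.  Missing interior time points are simply absent from the
    index; the 0 h baseline is required.
    """
    profile = profile.dropna()
    if 0.0 not in profile.index.astype(float):
        raise ValueError("baseline (t=0) value required for deviation scoring")
    prof = profile.copy()
    prof.index = prof.index.astype(float)
    base = prof.loc[0.0]
    rest = prof.drop(index=0.0)
    if rest.empty:
        raise ValueError("need at least one post-baseline time point")
    dev = rest - base
    signed = float(dev.iloc[np.argmax(np.abs(dev.to_numpy()))])
    return abs(signed), signed


def deviation_scores(matrix: ExpressionMatrix, design: CohortDesign) -> pd.DataFrame:
    """Per-feature, per-donor signed max-deviation scores (features x donors)."""
    matrix.require_stage("log2", "batchcorr")
    X = matrix.data
    scores = {}
    for donor in design.donors:
        sub = design.donor_samples(donor)
        times = sub["time_h"].to_numpy()
        if 0.0 not in times:
            raise ValueError(f"donor {donor!r} lacks a 0 h baseline sample")
        cols = X[sub.index].to_numpy()
        base = cols[:, times == 0.0][:, 0]
        rest = cols[:, times != 0.0]
        dev = rest - base[:, None]
        idx = np.argmax(np.abs(dev), axis=1)
        scores[donor] = dev[np.arange(dev.shape[0]), idx]
    return pd.DataFrame(scores, index=X.index)


def timecourse_gate(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Step-1 gate: group medians of signed deviation scores, thresholded.

    Returns one row per feature with columns ``median_dev_PD``,
    ``median_dev_HC`` and ``passes_tc_gate``.
    """
    per_donor = deviation_scores(matrix, design)
    groups = {d: design.group_of_donor(d) for d in per_donor.columns}
    pd_cols = [d for d in per_donor.columns if groups[d] == "PD"]
    hc_cols = [d for d in per_donor.columns if groups[d] == "HC"]
    if not pd_cols or not hc_cols:
        raise SchemaError("both PD and HC donors are required")
    med_pd = per_donor[pd_cols].median(axis=1)
    med_hc = per_donor[hc_cols].median(axis=1)
    passes = (med_pd.abs() >= thresholds.tc_log2) | (med_hc.abs() >= thresholds.tc_log2)
    return pd.DataFrame(
        {
            "median_dev_PD": med_pd,
            "median_dev_HC": med_hc,
            "passes_tc_gate": passes,
        }
    )


# ---------------------------------------------------------------------------
# step 2: shrinkage t-test per time point
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageState:
    """Variance shrinkage toward the median variance for one sample group."""

    lambda_star: float
    v_target: float
    v_g: np.ndarray
    v_g_star: np.ndarray


def shrink_variances(X: np.ndarray, lambda_override: float | None = None) -> ShrinkageState:
    """James-Stein shrinkage of per-feature variances toward their median.

    ``X`` is features x samples for one group.  The optimal intensity is

        lambda* = min(1, sum_g Var^(v_g) / sum_g (v_g - v_target)^2)

    with ``v_target`` the median of the empirical variances ``v_g`` and
    ``Var^(v_g)`` the usual unbiased estimate of the variance of ``v_g``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples per group")
    xbar = X.mean(axis=1, keepdims=True)
    w = (X - xbar) ** 2
    wbar = w.mean(axis=1)
    v_g = n / (n - 1) * wbar
    v_target = float(np.median(v_g))
    if lambda_override is not None:
        lam = float(lambda_override)
    else:
        var_v = n / (n - 1) ** 3 * ((w - wbar[:, None]) ** 2).sum(axis=1)
        denom = float(((v_g - v_target) ** 2).sum())
        lam = 1.0 if denom == 0.0 else min(1.0, float(var_v.sum()) / denom)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")
    v_star = lam * v_target + (1.0 - lam) * v_g
    return ShrinkageState(lam, v_target, v_g, v_star)


def shrinkage_t(
    X_pd: np.ndarray,
    X_hc: np.ndarray,
    lambda_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray, ShrinkageState, ShrinkageState]:
    """Shrinkage t-statistics and two-sided p-values, PD vs HC.

    p-values use a Student-t reference with ``n_pd + n_hc - 2`` degrees of
    freedom, a deterministic and conservative choice documented in the
    methods note.
    """
    st_pd = shrink_variances(X_pd, lambda_override)
    st_hc = shrink_variances(X_hc, lambda_override)
    n1, n2 = X_pd.shape[1], X_hc.shape[1]
    diff = X_pd.mean(axis=1) - X_hc.mean(axis=1)
    se = np.sqrt(st_pd.v_g_star / n1 + st_hc.v_g_star / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, p, st_pd, st_hc


def differential_table(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    thresholds: Thresholds = Thresholds(),
    gated_features: pd.Index | list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature, per-timepoint group comparison (step 2).

    Rows hold the PD-minus-HC difference of group medians (``median_log2fc``),
    the shrinkage-t statistic, its raw p-value and the BH-adjusted p-value
    (adjusted across features separately within each time point), plus the
    group sample sizes actually available.
    """
    matrix.require_stage("log2", "batchcorr")
    if gated_features is None:
        feats = matrix.feature_ids
    else:
        feats = pd.Index(gated_features)
        missing = feats.difference(matrix.feature_ids)
        if len(missing):
            raise SchemaError(f"gated features absent from matrix: {list(missing[:5])}")
    if len(feats) == 0:
        logger.warning("empty gated feature set; returning empty table")
        return pd.DataFrame(
            columns=["feature_id", "time_h", "median_log2fc", "t_shrink",
                     "p_raw", "p_adj", "n_pd", "n_hc"]
        )
    sub = matrix.data.loc[feats]
    blocks = []
    for t in design.time_points:
        pd_ids = design.samples_at("PD", t)
        hc_ids = design.samples_at("HC", t)
        if len(pd_ids) < 2 or len(hc_ids) < 2:
            logger.warning("skipping %s h: fewer than 2 samples in a group", t)
            continue
        X1 = sub[pd_ids].to_numpy()
        X2 = sub[hc_ids].to_numpy()
        fc = np.median(X1, axis=1) - np.median(X2, axis=1)
        tstat, praw, _, _ = shrinkage_t(X1, X2)
        padj = multipletests(praw, method="fdr_bh")[1]
        blocks.append(
            pd.DataFrame(
                {
                    "feature_id": feats,
                    "time_h": float(t),
                    "median_log2fc": fc,
                    "t_shrink": tstat,
                    "p_raw": praw,
                    "p_adj": padj,
                    "n_pd": len(pd_ids),
                    "n_hc": len(hc_ids),
                }
            )
        )
    if not blocks:
        return pd.DataFrame(
            columns=["feature_id", "time_h", "median_log2fc", "t_shrink",
                     "p_raw", "p_adj", "n_pd", "n_hc"]
        )
    return pd.concat(blocks, ignore_index=True)


# ---------------------------------------------------------------------------
# core-gene classification
# ---------------------------------------------------------------------------

def _windows_of(times: list[float]) -> tuple[str, ...]:
    hit = []
    for name, members in WINDOWS.items():
        if any(t in members for t in times):
            hit.append(name)
    return tuple(hit)


def classify_core(
    table: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Label core features (adj. p and group-FC gates at >= 1 time point).

    Returns one row per feature with ``is_core``, the core time points, the
    activation windows they fall into, a direction label (``increased`` /
    ``decreased`` / ``mixed``) and the recurrence count.
    """
    columns = ["feature_id", "is_core", "core_time_points", "windows",
               "direction", "recurrence"]
    if table.empty:
        return pd.DataFrame(columns=columns)
    records = []
    for fid, sub in table.groupby("feature_id", sort=False):
        hit = sub[
            (sub["p_adj"] <= thresholds.alpha_adj)
            & (sub["median_log2fc"].abs() >= thresholds.grp_log2)
        ]
        times = sorted(hit["time_h"].tolist())
        signs = set(np.sign(hit["median_log2fc"]).astype(int))
        if not times:
            direction = "none"
        elif signs == {1}:
            direction = "increased"
        elif signs == {-1}:
            direction = "decreased"
        else:
            direction = "mixed"
        records.append(
            {
                "feature_id": fid,
                "is_core": bool(times),
                "core_time_points": "+".join(f"{t:g}" for t in times),
                "windows": "+".join(_windows_of(times)),
                "direction": direction,
                "recurrence": len(times),
            }
        )
    return pd.DataFrame(records)


def window_venn(core: pd.DataFrame) -> dict[str, int]:
    """Venn partition of core features over the three activation windows."""
    counts: dict[str, int] = {}
    names = list(WINDOWS)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts["+".join(combo)] = 0
    for _, row in core[core["is_core"]].iterrows():
        key = row["windows"]
        if key:
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# activation-marker QC
# ---------------------------------------------------------------------------

def marker_qc(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    marker_ids: list[str],
    alpha: float = 0.05,
    min_induction_log2: float = 1.0,
) -> dict:
    """QC on activation markers: induced in both groups, no group difference.

    For each marker and time point, reports group medians, ranges and a
    two-sided unpaired-t p-value.  QC passes when each marker's group median
    rises by at least ``min_induction_log2`` from baseline in both groups
    and no per-timepoint group difference is significant at ``alpha`` after
    BH adjustment across the marker x time-point family (so a clean cohort
    fails the family with probability at most ``alpha``).
    """
    matrix.require_stage("log2", "batchcorr")
    present = [m for m in marker_ids if m in matrix.feature_ids]
    absent = [m for m in marker_ids if m not in matrix.feature_ids]
    rows = []
    induced_ok = True
    diff_ok = True
    for fid in present:
        vals = matrix.data.loc[fid]
        for grp in ("PD", "HC"):
            base = vals[design.samples_at(grp, 0.0)].median()
            later = max(
                vals[design.samples_at(grp, t)].median()
                for t in design.time_points
                if t > 0
            )
            if later - base < min_induction_log2:
                induced_ok = False
        for t in design.time_points:
            a = vals[design.samples_at("PD", t)].to_numpy()
            b = vals[design.samples_at("HC", t)].to_numpy()
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            else:
                p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
                if np.isnan(p):
                    p = 1.0
            rows.append(
                {
                    "marker": fid,
                    "time_h": float(t),
                    "median_PD": float(np.median(a)),
                    "median_HC": float(np.median(b)),
                    "range_PD": float(np.ptp(a)),
                    "range_HC": float(np.ptp(b)),
                    "p_unpaired_t": p,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p_unpaired_t"], method="fdr_bh")[1]
        diff_ok = bool((table["p_adj"] >= alpha).all())
    return {
        "table": table,
        "markers_missing": absent,
        "induced": induced_ok,
        "no_group_difference": diff_ok,
        "qc_pass": induced_ok and diff_ok and not absent,
        "complete": not absent,
    }
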