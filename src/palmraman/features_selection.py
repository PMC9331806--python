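"""Chemometric feature extraction and one-way ANOVA feature selection.

From each sample's fitted peak table a fixed 27-entry feature vector is built:
intensity, gravity center and FWHM for the seven reliable band components
(P1-P5, P7, P8 — chlorophyll-a P6 is excluded as unreliable in the
three-class cohort), plus six intensity ratios (P1..P5 over the carotene
reference P8, and beta-carotene over carotene P2/P3).  Each feature is then
tested for a ripeness-class effect with a classical one-way ANOVA F-test and
selected at a Bonferroni-adjusted level alpha/27, which makes "how many
features are significant" stable rather than a seed accident.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

PEAKS_USED: Tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "P7", "P8")
RATIO_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("P1", "P8"), ("P2", "P8"), ("P3", "P8"), ("P4", "P8"), ("P5", "P8"),
    ("P2", "P3"))

#: canonical ordering of the 27 features
FEATURE_NAMES: Tuple[str, ...] = tuple(
    f"{kind}_{p}" for p in PEAKS_USED for kind in ("intensity", "position", "fwhm")
) + tuple(f"ratio_{a}_{b}" for a, b in RATIO_PAIRS)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 27

#: fallback positions for pruned components (the fit window centers)
INIT_CENTER_BY_PEAK: Dict[str, float] = {
    "P1": 1244.0, "P2": 1258.0, "P3": 1281.0, "P4": 1306.0,
    "P5": 1318.0, "P6": 1325.0, "P7": 1335.0, "P8": 1357.0}


def extract_features(peak_table: pd.DataFrame) -> pd.Series:
    """27-entry feature vector from one sample's peak table.

    Absent (pruned) components contribute intensity 0, position equal to
    their nominal window center, and a missing (NaN) FWHM; ratios whose
    denominator component is absent are missing as well.  Missing entries are
    excluded listwise from that feature's ANOVA downstream.
    """
    required = {"peak", "center_cm-1", "intensity_au", "fwhm_cm-1", "present"}
    if not required.issubset(peak_table.columns):
        raise ValueError(f"peak table missing columns {required - set(peak_table.columns)}")
    by_peak = peak_table.set_index("peak")
    values: Dict[str, float] = {}
    intensity: Dict[str, float] = {}
    present: Dict[str, bool] = {}
    for p in PEAKS_USED:
        if p not in by_peak.index:
            raise ValueError(f"peak table lacks component {p}")
        row = by_peak.loc[p]
        ok = bool(row["present"])
        present[p] = ok
        intensity[p] = float(row["intensity_au"]) if ok else 0.0
        values[f"intensity_{p}"] = intensity[p]
        values[f"position_{p}"] = float(row["center_cm-1"]) if ok else INIT_CENTER_BY_PEAK[p]
        values[f"fwhm_{p}"] = float(row["fwhm_cm-1"]) if ok else np.nan
    for a, b in RATIO_PAIRS:
        if present[b] and intensity[b] > 0:
            values[f"ratio_{a}_{b}"] = intensity[a] / intensity[b]
        else:
            values[f"ratio_{a}_{b}"] = np.nan
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def feature_table(peak_tables: Sequence[pd.DataFrame],
                  labels: Sequence[str],
                  sample_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Stack per-sample feature vectors into a samples x features table."""
    if len(peak_tables) != len(labels):
        raise ValueError("one label per peak table required")
    rows = [extract_features(t) for t in peak_tables]
    table = pd.DataFrame(rows).reset_index(drop=True)
    table.insert(0, "label", list(labels))
    ids = sample_ids if sample_ids is not None else [f"s{i:03d}" for i in range(len(labels))]
    table.insert(0, "sample_id", list(ids))
    return table


def one_way_anova(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    ``F = MS_between / MS_within`` with ``(k - 1, N - k)`` degrees of freedom
    and the p value from the upper tail of the F distribution.  Degenerate
    zero within-group variance gives ``(0, 1)`` when the group means also
    coincide and ``(inf, 0)`` otherwise.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(f_dist.sf(f_stat, df_b, df_w))
    return float(f_stat), p


@dataclass(frozen=True)
class SelectionResult:
    """Selected feature names plus the full per-feature ANOVA table."""

    selected: Tuple[str, ...]
    anova: pd.DataFrame          # feature, F, p, significant, degenerate, group means
    alpha: float
    alpha_adjusted: float


def select_features(table: pd.DataFrame, labels: Optional[Sequence[str]] = None,
                    alpha: float = 0.05) -> SelectionResult:
    """One-way ANOVA per feature with Bonferroni control across the 27 tests.

    ``table`` is a samples x features frame (a ``label`` column is used when
    ``labels`` is not given).  Missing values are dropped listwise from that
    feature's ANOVA only; a feature whose groups shrink below two values, or
    with zero variance everywhere, is flagged degenerate.
    """
    if labels is None:
        if "label" not in table.columns:
            raise ValueError("provide labels or a 'label' column")
        labels = table["label"].to_numpy()
    labels = np.asarray(labels)
    feats = [c for c in FEATURE_NAMES if c in table.columns]
    if len(feats) != N_FEATURES:
        missing = set(FEATURE_NAMES) - set(feats)
        raise ValueError(f"feature table missing {sorted(missing)}")
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2 or len(table) < 2 * len(classes):
        raise ValueError("need >= 2 classes and >= 2 samples per class")
    alpha_adj = alpha / N_FEATURES
    rows = []
    for name in FEATURE_NAMES:
        col = table[name].to_numpy(dtype=float)
        groups, means = [], {}
        usable = True
        for c in classes:
            vals = col[labels == c]
            vals = vals[np.isfinite(vals)]
            means[c] = float(vals.mean()) if vals.size else np.nan
            if vals.size < 2:
                usable = False
            groups.append(vals)
        if not usable:
            rows.append({"feature": name, "F": np.nan, "p": np.nan,
                         "significant": False, "degenerate": True, **{
                             f"mean_{c}": means[c] for c in classes}})
            continue
        f_stat, p = one_way_anova(groups)
        degenerate = not np.isfinite(f_stat)
        rows.append({"feature": name, "F": f_stat, "p": p,
                     "significant": bool(p < alpha_adj),
                     "degenerate": degenerate,
                     **{f"mean_{c}": means[c] for c in classes}})
    anova = pd.DataFrame(rows)
    selected = tuple(anova.loc[anova["significant"], "feature"])
    return SelectionResult(selected, anova, alpha, alpha_adj)


@dataclass(frozen=True)
class TrendSummary:
    """Per-peak class-ordered mean intensities with a monotonicity verdict."""

    table: pd.DataFrame          # peak, mean per class (in ripeness order), verdict
    class_order: Tuple[str, ...]
    degenerate: bool = False


def trend_by_class(table: pd.DataFrame, labels: Optional[Sequence[str]] = None,
                   class_order: Optional[Sequence[str]] = None) -> TrendSummary:
    """Ripening trend of each band intensity: class means and a strict verdict.

    Adjacent class means are compared strictly: all increasing -> "increasing",
    all decreasing -> "decreasing", otherwise "non-monotone".  A single class
    is reported "increasing" by convention and flagged degenerate.
    """
    if labels is None:
        labels = table["label"].to_numpy()
    labels = np.asarray(labels)
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    class_order = tuple(class_order)
    rows = []
    degenerate = len(class_order) < 2
    for p in PEAKS_USED:
        col = table[f"intensity_{p}"].to_numpy(dtype=float)
        means = [float(np.nanmean(col[labels == c])) for c in class_order]
        if degenerate:
            verdict = "increasing"
        else:
            diffs = np.diff(means)
            if np.all(diffs > 0):
                verdict = "increasing"
            elif np.all(diffs < 0):
                verdict = "decreasing"
            else:
                verdict = "non-monotone"
        rows.append({"peak": p, **{f"mean_{c}": m for c, m in zip(class_order, means)},
                     "verdict": verdict})
    return TrendSummary(pd.DataFrame(rows), class_order, degenerate)
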