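"""Behavioral scoring and the group x state intervention statistics.

Scoring follows the study protocol: the subjective fatigue scale (SFS)
sums 15 items scored 0-4 into a 0-60 total with four severity bands;
the 2-back + parity task is scored as percent-correct over all trials
(non-responses count as incorrect) with mean reaction time over
responded trials only.

The inferential layer mirrors the study's screening-then-test flow:
Shapiro-Wilk normality and Levene variance-homogeneity screens, one-way
ANOVA with Bonferroni post-hoc for state comparisons of SFS, paired t
for task accuracy, and — for the HRV features — independent-samples t
or Mann-Whitney U depending on the normality screen.  The independent
(unpaired) comparison of what are physically within-subject states
reproduces the study's own analysis choice; a paired variant sits
behind ``paired=True``.  Sign conventions follow the published tables:
the mean difference X-bar is (first sample) - (second sample), so an
increase after intervention appears as a negative X-bar and negative t.

Intervention effect size per feature uses the relative rate of change,
100 x (post_stimulation - post_fatigue) / post_fatigue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sst

from .containers import GROUPS, STATES, InsufficientDataError, InvalidSpecError, TrialRecord
from .hrv import FEATURE_NAMES

__all__ = [
    "StatResult",
    "ChangeTable",
    "score_sfs",
    "score_task",
    "rate_of_change",
    "normality_check",
    "variance_homogeneity",
    "oneway_anova_bonferroni",
    "paired_t",
    "two_sample_compare",
    "feature_change_table",
    "baseline_repeated_anova",
    "cohort_behavior_frame",
    "cohort_features_frame",
]

ALPHA = 0.05

SFS_BANDS = (
    (0, 15, "normal state"),
    (16, 30, "mild fatigue"),
    (31, 45, "moderate fatigue"),
    (46, 60, "severe fatigue"),
)


@dataclass
class StatResult:
    """One test's outcome: statistic, p, mean difference, significance."""

    test: str
    statistic: float
    p_value: float
    xbar: Optional[float] = None
    alpha: float = ALPHA
    extra: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise InvalidSpecError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    @property
    def direction(self) -> int:
        """Sign of the mean difference (0 when undefined)."""
        if self.xbar is None or self.xbar == 0 or np.isnan(self.xbar):
            return 0
        return 1 if self.xbar > 0 else -1


def score_sfs(items: Sequence[int]) -> Tuple[int, str]:
    """Total SFS score (0-60) and its severity band."""
    items = list(items)
    if len(items) != 15:
        raise InvalidSpecError(f"SFS needs exactly 15 items, got {len(items)}")
    if any((not float(i).is_integer()) or i < 0 or i > 4 for i in items):
        raise InvalidSpecError("every SFS item must be an integer in 0..4")
    total = int(sum(items))
    for lo, hi, name in SFS_BANDS:
        if lo <= total <= hi:
            return total, name
    raise AssertionError("unreachable: total outside 0..60")


def score_task(trials: Sequence[TrialRecord]) -> Tuple[float, float]:
    """Accuracy (%) and mean RT (ms) for one session's trials.

    Accuracy counts non-responses as incorrect in the denominator; the
    mean RT averages responded trials only and is NaN when the
    participant never responded.
    """
    if not trials:
        raise InsufficientDataError("no trials to score")
    n_correct = sum(1 for t in trials if t.correct)
    acc = 100.0 * n_correct / len(trials)
    rts = [t.rt_ms for t in trials if t.responded]
    mean_rt = float(np.mean(rts)) if rts else float("nan")
    return acc, mean_rt


def rate_of_change(value_post_fatigue: float, value_post_stimulation: float) -> float:
    """Relative rate of change, %: 100 (post_stim - post_fatigue)/post_fatigue.

    A larger absolute value indicates a stronger stimulation effect; the
    sign carries the direction.  Undefined for a zero baseline.
    """
    if value_post_fatigue == 0:
        raise InvalidSpecError("zero post-fatigue baseline; rate of change undefined")
    return 100.0 * (value_post_stimulation - value_post_fatigue) / value_post_fatigue


def normality_check(sample: Sequence[float]) -> StatResult:
    """Shapiro-Wilk normality screen; consistent with normality when p > 0.05."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= x.size <= 5000):
        raise InvalidSpecError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        return StatResult("shapiro-wilk", float("nan"), 0.0, extra={"degenerate": True})
    w, p = sst.shapiro(x)
    return StatResult("shapiro-wilk", float(w), float(p))


def variance_homogeneity(*groups: Sequence[float]) -> StatResult:
    """Levene test (center = mean) for homogeneity of variance."""
    if len(groups) < 2:
        raise InvalidSpecError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise InvalidSpecError("every group needs n >= 2")
    stat, p = sst.levene(*arrs, center="mean")
    return StatResult("levene", float(stat), float(p))


def oneway_anova_bonferroni(
    samples: Mapping[str, Sequence[float]], alpha: float = ALPHA
) -> Tuple[StatResult, Dict[Tuple[str, str], StatResult]]:
    """One-way ANOVA across states with Bonferroni-corrected post-hoc t-tests.

    Pairwise comparisons run only when the omnibus p < alpha; each
    pairwise p is multiplied by the number of pairs and capped at 1.
    """
    if len(samples) != 3:
        raise InvalidSpecError(f"expected 3 state samples, got {len(samples)}")
    keys = list(samples)
    arrs = [np.asarray(samples[k], dtype=float) for k in keys]
    if any(a.size < 2 for a in arrs):
        raise InvalidSpecError("every state sample needs n >= 2")
    f, p = sst.f_oneway(*arrs)
    if np.isnan(f):  # all samples identical and constant
        f, p = 0.0, 1.0
    omnibus = StatResult("oneway-anova", float(f), float(p), alpha=alpha)
    pairwise: Dict[Tuple[str, str], StatResult] = {}
    if omnibus.significant:
        pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]]
        for a, b in pairs:
            t, praw = sst.ttest_ind(samples[a], samples[b])
            padj = min(1.0, float(praw) * len(pairs))
            pairwise[(a, b)] = StatResult(
                "bonferroni-t",
                float(t),
                padj,
                xbar=float(np.mean(samples[a]) - np.mean(samples[b])),
                alpha=alpha,
                extra={"p_raw": float(praw)},
            )
    return omnibus, pairwise


def paired_t(pre: Sequence[float], post: Sequence[float]) -> StatResult:
    """Paired t-test on pre - post differences.

    With X-bar = mean(pre - post), an improvement (post > pre) yields a
    negative t, matching the published accuracy tables.
    """
    a = np.asarray(pre, dtype=float)
    b = np.asarray(post, dtype=float)
    if a.size != b.size:
        raise InvalidSpecError("paired samples must have equal length")
    if a.size < 2:
        raise InvalidSpecError("need n >= 2 pairs")
    t, p = sst.ttest_rel(a, b)
    if np.isnan(t):  # zero-variance differences
        t, p = 0.0, 1.0
    return StatResult("paired-t", float(t), float(p), xbar=float(np.mean(a - b)))


def two_sample_compare(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = ALPHA,
    paired: bool = False,
) -> StatResult:
    """Independent-samples t or Mann-Whitney U, gated on normality.

    Both samples passing the Shapiro-Wilk screen (p > 0.05) selects a
    t-test (pooled-variance when Levene passes, Welch otherwise);
    either failing selects Mann-Whitney U.  ``extra["branch"]`` records
    which test ran.  ``paired=True`` substitutes a paired t / Wilcoxon
    pair instead (the within-subject variant).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidSpecError("each sample needs n >= 2")
    xbar = float(np.mean(x) - np.mean(y))

    def _normal(s: np.ndarray) -> bool:
        if np.ptp(s) == 0:
            return False
        return sst.shapiro(s).pvalue > 0.05

    normal = _normal(x) and _normal(y)
    if paired:
        if x.size != y.size:
            raise InvalidSpecError("paired comparison needs equal lengths")
        if normal:
            t, p = sst.ttest_rel(x, y)
            return StatResult("paired-t", float(t), float(p), xbar=xbar, alpha=alpha,
                              extra={"branch": "paired-t"})
        d = x - y
        if np.all(d == 0):
            return StatResult("wilcoxon", 0.0, 1.0, xbar=0.0, alpha=alpha,
                              extra={"branch": "wilcoxon", "degenerate": True})
        w, p = sst.wilcoxon(x, y)
        return StatResult("wilcoxon", float(w), float(p), xbar=xbar, alpha=alpha,
                          extra={"branch": "wilcoxon"})

    if normal:
        equal_var = variance_homogeneity(x, y).p_value > 0.05
        t, p = sst.ttest_ind(x, y, equal_var=equal_var)
        name = "independent-t" if equal_var else "welch-t"
        return StatResult(name, float(t), float(p), xbar=xbar, alpha=alpha,
                          extra={"branch": name})
    if np.ptp(np.concatenate([x, y])) == 0:
        return StatResult("mann-whitney", float("nan"), 1.0, xbar=0.0, alpha=alpha,
                          extra={"branch": "mann-whitney", "degenerate": True})
    u, p = sst.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult("mann-whitney", float(u), float(p), xbar=xbar, alpha=alpha,
                      extra={"branch": "mann-whitney"})


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------


@dataclass
class ChangeTable:
    """Feature-by-group change report (rate-of-change or X-bar/p style)."""

    frame: pd.DataFrame
    contrast: str
    alpha: float = ALPHA
    exclusions: Dict[str, int] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=True)


def _require_columns(features: pd.DataFrame) -> None:
    need = {"subject", "group", "state"}
    missing = need - set(features.columns)
    if missing:
        raise InvalidSpecError(f"feature table missing columns: {sorted(missing)}")


def _paired_cell(
    pivoted: pd.DataFrame, feat: str, state_a: str, state_b: str
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Per-subject values for two states, pairwise-deleting missing ones."""
    a = pivoted[(feat, state_a)].to_numpy(dtype=float)
    b = pivoted[(feat, state_b)].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok], int((~ok).sum())


def feature_change_table(
    features: pd.DataFrame,
    contrast: str,
    alpha: float = ALPHA,
    paired: bool = False,
    correction: Optional[str] = None,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> ChangeTable:
    """Feature-change report across groups for one contrast.

    ``contrast="fatigue"`` (pre-fatigue vs post-fatigue): per group x
    feature, the mean per-subject rate of change (%), plus an omnibus
    one-way ANOVA of the per-subject rates across the three groups
    (columns ``F`` and ``P``).

    ``contrast="stimulation"`` (post-fatigue vs post-stimulation): per
    group x feature, the mean difference X-bar = mean(post-fatigue) -
    mean(post-stimulation), the p-value and branch of
    :func:`two_sample_compare`, and a significance flag at ``alpha``.

    Missing feature values are pairwise-deleted per cell with the count
    recorded in ``exclusions``.  ``correction="bh"`` applies an optional
    Benjamini-Hochberg adjustment across features within each group
    (the study applies none; off by default).
    """
    _require_columns(features)
    if contrast == "fatigue":
        pair = ("pre-fatigue", "post-fatigue")
    elif contrast == "stimulation":
        pair = ("post-fatigue", "post-stimulation")
    else:
        raise InvalidSpecError(f"unknown contrast {contrast!r}")
    groups = [g for g in GROUPS if g in set(features["group"])]
    # one pivot per group; columns become (feature, state)
    pivots = {
        g: features[features["group"] == g].pivot(
            index="subject", columns="state", values=list(feature_names)
        )
        for g in groups
    }

    exclusions: Dict[str, int] = {}
    rows = []
    if contrast == "fatigue":
        for feat in feature_names:
            row: Dict[str, float] = {}
            group_rates: List[np.ndarray] = []
            for g in groups:
                a, b, dropped = _paired_cell(pivots[g], feat, *pair)
                if dropped:
                    exclusions[f"{g}/{feat}"] = dropped
                with np.errstate(divide="ignore", invalid="ignore"):
                    rates = 100.0 * (b - a) / a
                rates = rates[np.isfinite(rates)]
                group_rates.append(rates)
                row[g] = float(np.mean(rates)) if rates.size else float("nan")
            if all(r.size >= 2 for r in group_rates) and len(group_rates) == 3:
                f, p = sst.f_oneway(*group_rates)
                if np.isnan(f):
                    f, p = 0.0, 1.0
                row["F"], row["P"] = float(f), float(p)
            else:
                row["F"], row["P"] = float("nan"), float("nan")
            rows.append(pd.Series(row, name=feat))
        frame = pd.DataFrame(rows)
    else:
        for feat in feature_names:
            row = {}
            for g in groups:
                a, b, dropped = _paired_cell(pivots[g], feat, *pair)
                if dropped:
                    exclusions[f"{g}/{feat}"] = dropped
                try:
                    res = two_sample_compare(a, b, alpha=alpha, paired=paired)
                except InvalidSpecError:
                    res = StatResult("undefined", float("nan"), float("nan"),
                                     xbar=float("nan"), alpha=alpha)
                row[f"{g}_xbar"] = res.xbar
                row[f"{g}_p"] = res.p_value
                row[f"{g}_branch"] = res.extra.get("branch", res.test)
                row[f"{g}_significant"] = res.significant
            rows.append(pd.Series(row, name=feat))
        frame = pd.DataFrame(rows)
        if correction == "bh":
            from statsmodels.stats.multitest import multipletests

            for g in groups:
                p = frame[f"{g}_p"].to_numpy(dtype=float)
                ok = np.isfinite(p)
                adj = np.full_like(p, np.nan)
                if ok.sum():
                    adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
                frame[f"{g}_p_adj"] = adj
                frame[f"{g}_significant"] = adj < alpha
        elif correction is not None:
            raise InvalidSpecError(f"unknown correction {correction!r}")
    return ChangeTable(frame, contrast=contrast, alpha=alpha, exclusions=exclusions)


def baseline_repeated_anova(values: pd.DataFrame) -> StatResult:
    """Repeated-measures one-way ANOVA of pre-fatigue baselines across groups.

    ``values`` is wide-form: rows = subjects, columns = the three
    groups' baseline values.  No sphericity correction is applied; the
    result is flagged accordingly.
    """
    x = values.to_numpy(dtype=float)
    if x.shape[1] != 3 or x.shape[0] < 2:
        raise InvalidSpecError("need subjects x 3 conditions")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        return StatResult("rm-anova", 0.0, 1.0, extra={"sphericity": "uncorrected"})
    f = ms_cond / ms_err
    p = float(sst.f.sf(f, df_cond, df_err))
    return StatResult("rm-anova", float(f), p, extra={"sphericity": "uncorrected"})


# ---------------------------------------------------------------------------
# Cohort frames
# ---------------------------------------------------------------------------


def cohort_behavior_frame(sessions) -> pd.DataFrame:
    """Long-form behavior table: subject, group, state, sfs_total, acc, mean_rt."""
    rows = []
    for s in sessions:
        total, band = score_sfs(s.sfs_items)
        acc, rt = score_task(s.trials)
        rows.append(
            {
                "subject": s.subject,
                "group": s.group,
                "state": s.state,
                "sfs_total": total,
                "sfs_band": band,
                "acc": acc,
                "mean_rt": rt,
            }
        )
    return pd.DataFrame(rows)


def cohort_features_frame(sessions, **extract_kwargs) -> pd.DataFrame:
    """Long-form 21-feature table computed from each session's RR series."""
    from .hrv import extract_all

    rows = []
    for s in sessions:
        if s.features is not None:
            vals = dict(s.features)
        elif s.rr is not None:
            vals = extract_all(s.rr, **extract_kwargs).to_dict()
        else:
            raise InvalidSpecError(f"session {s.subject}/{s.group}/{s.state} has no RR or features")
        row = {"subject": s.subject, "group": s.group, "state": s.state}
        row.update({k: vals.get(k, float("nan")) for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
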