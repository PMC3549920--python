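"""Mass-univariate group comparison with multiple-testing correction,
p-value ranking, fold-wise selection stability, the motion-confound check,
and the ROI-level non-parametric group test.

Feature tables are samples x features; the 2-runs-per-subject samples are
treated as independent observations in the mass-univariate tests (the
cohort's sample count implies this convention; the independence violation is
noted in output metadata rather than corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FeatureTable",
    "StatsResult",
    "two_sample_ttest",
    "fdr_select",
    "bonferroni_select",
    "rank_topk",
    "stability",
    "motion_confound_check",
    "ranksum_group_test",
]

GROUPS = ("patient", "control")


@dataclass
class FeatureTable:
    values: np.ndarray  # n_samples x n_features
    labels: np.ndarray  # per sample, "patient" | "control"
    subject_ids: np.ndarray  # per sample
    feature_ids: np.ndarray  # voxel or pair index per feature
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be samples x features")
        n = self.values.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject ids must match sample count")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature ids must match feature count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows=None, cols=None) -> "FeatureTable":
        rows = slice(None) if rows is None else np.asarray(rows)
        cols = slice(None) if cols is None else np.asarray(cols)
        return FeatureTable(
            values=self.values[rows][:, cols],
            labels=self.labels[rows],
            subject_ids=self.subject_ids[rows],
            feature_ids=self.feature_ids[cols],
            kind=self.kind,
        )


@dataclass
class StatsResult:
    statistic: np.ndarray  # per feature (t, or correlation for confound check)
    pvalues: np.ndarray
    alpha: float
    fdr_mask: np.ndarray
    bonferroni_mask: np.ndarray
    zero_variance_flags: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columnwise pooled-variance two-sample t (Student reference,
    df = n1 + n2 - 2).  Returns (t, p, zero-variance-unequal-mean flags)."""
    n1, n2 = a.shape[0], b.shape[0]
    dof = n1 + n2 - 2
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss1 = ((a - m1) ** 2).sum(axis=0)
    ss2 = ((b - m2) ** 2).sum(axis=0)
    pooled = (ss1 + ss2) / dof
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    zero = se == 0.0
    flagged = zero & (diff != 0.0)
    t[zero & (diff == 0.0)] = 0.0
    p[zero & (diff == 0.0)] = 1.0
    t[flagged & (diff > 0)] = np.inf
    t[flagged & (diff < 0)] = -np.inf
    p[flagged] = 0.0
    return t, p, flagged


def two_sample_ttest(table: FeatureTable, alpha: float = 0.05) -> StatsResult:
    """Per-feature pooled-variance two-sample t-test (patient vs control),
    with BH-FDR and Bonferroni selection masks at ``alpha``."""
    in_a = table.labels == GROUPS[0]
    in_b = table.labels == GROUPS[1]
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p, flagged = _pooled_ttest(table.values[in_a], table.values[in_b])
    return StatsResult(
        statistic=t,
        pvalues=p,
        alpha=alpha,
        fdr_mask=fdr_select(p, alpha),
        bonferroni_mask=bonferroni_select(p, alpha),
        zero_variance_flags=flagged,
        metadata={
            "test": "two_sample_t_pooled",
            "groups": GROUPS,
            "note": "runs of one subject treated as independent samples",
        },
    )


def fdr_select(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection mask.

    Sort ascending, find the largest k with p_(k) <= k * alpha / N, select
    every feature with p <= that cutoff p-value (so ties are all-in).
    """
    p = np.asarray(pvalues, dtype=float)
    _check_pvalues(p, alpha)
    n = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, n + 1) * alpha / n)
    if not below.any():
        return np.zeros(n, dtype=bool)
    cutoff = sorted_p[np.flatnonzero(below)[-1]]
    return p <= cutoff


def bonferroni_select(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Select features with p <= alpha / N (N = number of finite p-values)."""
    p = np.asarray(pvalues, dtype=float)
    _check_pvalues(p, alpha)
    n = int(np.isfinite(p).sum())
    if n == 0:
        return np.zeros(p.size, dtype=bool)
    return p <= alpha / n


def _check_pvalues(p: np.ndarray, alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("p-values must lie in [0, 1]")


def rank_topk(pvalues: np.ndarray, k: int, feature_ids: np.ndarray | None = None) -> np.ndarray:
    """Ids of the k smallest p-values; ties broken by ascending feature id so
    every pipeline is bit-reproducible."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    ids = np.arange(n) if feature_ids is None else np.asarray(feature_ids)
    order = np.lexsort((ids, p))
    return ids[order[:k]]


def stability(topk_sets: list, k: int) -> float:
    """|intersection over all fold-wise top-k sets| / k."""
    if len(topk_sets) < 2:
        raise ValueError("need at least 2 sets")
    sets = [set(np.asarray(s).tolist()) for s in topk_sets]
    for s in sets:
        if len(s) != k:
            raise ValueError(f"set size {len(s)} != k={k}")
    common = set.intersection(*sets)
    return len(common) / k


def motion_confound_check(
    table: FeatureTable, motion_summary: np.ndarray, alpha: float = 0.05
) -> StatsResult:
    """Correlate each feature with a per-sample motion summary; p-values from
    the t transform of Pearson r, then BH-FDR at ``alpha``.

    An empty FDR mask supports the claim that features are not motion-driven.
    """
    m = np.asarray(motion_summary, dtype=float)
    if m.shape != (table.n_samples,):
        raise ValueError("motion summary length must equal the sample count")
    if m.std() == 0.0:
        raise ValueError("motion summary is constant")
    n = table.n_samples
    x = (m - m.mean()) / m.std()
    feats = table.values
    fz = feats - feats.mean(axis=0)
    fsd = fz.std(axis=0)
    safe = np.where(fsd == 0.0, 1.0, fsd)
    r = (x @ (fz / safe)) / n
    r[fsd == 0.0] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r**2))
    t[np.abs(r) == 1.0] = np.sign(r[np.abs(r) == 1.0]) * np.inf
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[np.abs(r) == 1.0] = 0.0
    return StatsResult(
        statistic=r,
        pvalues=p,
        alpha=alpha,
        fdr_mask=fdr_select(p, alpha),
        bonferroni_mask=bonferroni_select(p, alpha),
        metadata={"test": "motion_confound_pearson"},
    )


def ranksum_group_test(
    per_subject_values: np.ndarray,
    labels: np.ndarray,
    n_comparisons: int = 1,
    signed_rank: bool = False,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value, Bonferroni-scaled
    by the number of connectivity measures tested.

    ``signed_rank=True`` switches to the paired signed-rank statistic for
    equal-sized groups (provided for completeness; groups of distinct
    subjects call for the rank-sum form).
    """
    values = np.asarray(per_subject_values, dtype=float)
    labels = np.asarray(labels)
    a = values[labels == GROUPS[0]]
    b = values[labels == GROUPS[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.all(values == values[0]):
        return 1.0
    if signed_rank:
        if len(a) != len(b):
            raise ValueError("signed-rank requires equal group sizes")
        p = stats.wilcoxon(a, b, alternative="two-sided").pvalue
    else:
        ties = len(np.unique(values)) < len(values)
        p = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic" if ties else "exact"
        ).pvalue
    return float(min(1.0, p * n_comparisons))
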