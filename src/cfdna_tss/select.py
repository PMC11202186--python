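"""Feature reduction for the early-detection panel.

Four steps, cheapest first, all computed on the normalized training
matrix only:

1. near-zero-variance filter (frequency-ratio / distinct-fraction rule);
2. greedy pairwise-correlation pruning at |r| > 0.9;
3. per-transcript two-group screen (Wilcoxon rank-sum by default,
   Welch t as an option) at p < 0.01;
4. stage-monotone selection: keep transcripts whose group means order
   strictly across healthy → stage I → II → III → IV (either direction),
   rank by |mean(stage I) − mean(healthy)|, and take the top k per
   direction (a 2k-per-direction pre-cut is kept as an intermediate
   artifact).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STAGE_ORDER = ["healthy", "I", "II", "III", "IV"]
DIRECTION_UP = "cancer_up"
DIRECTION_DOWN = "healthy_up"


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_near_zero_variance(
    matrix: pd.DataFrame, freq_cut: float = 19.0, unique_cut: float = 0.10
) -> pd.Index:
    """Drop quasi-constant features; return surviving column ids.

    A feature is dropped when the ratio of its most-common to second-most-
    common value frequency exceeds ``freq_cut``, or when its fraction of
    distinct values falls below ``unique_cut``.  Constant features (no
    second value) are always dropped.
    """
    keep = []
    n = len(matrix)
    for col in matrix.columns:
        x = matrix[col].dropna()
        counts = x.value_counts().to_numpy()
        if len(counts) < 2:
            continue
        freq_ratio = counts[0] / counts[1]
        unique_frac = len(counts) / n
        if freq_ratio > freq_cut or unique_frac < unique_cut:
            continue
        keep.append(col)
    return pd.Index(keep)


def filter_high_correlation(matrix: pd.DataFrame, cutoff: float = 0.9) -> pd.Index:
    """Greedy pairwise-Pearson pruning; return surviving column ids.

    While any |r| > cutoff remains, the worst pair is found and the member
    with the larger mean absolute correlation (over remaining features) is
    dropped — the caret ``findCorrelation`` heuristic.
    """
    corr = matrix.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(matrix.columns), dtype=bool)
    while True:
        sub = np.where(alive)[0]
        c = corr[np.ix_(sub, sub)]
        if c.size == 0 or np.nanmax(c) <= cutoff:
            break
        i, j = np.unravel_index(np.nanargmax(c), c.shape)
        mean_i = np.nanmean(c[i])
        mean_j = np.nanmean(c[j])
        drop = sub[i] if mean_i >= mean_j else sub[j]
        alive[drop] = False
    return matrix.columns[alive]


# ---------------------------------------------------------------------------
# two-group screen
# ---------------------------------------------------------------------------


@dataclass
class GroupDiffResult:
    """Per-transcript two-group comparison: p-values, group means, survivors."""

    pvalues: pd.Series
    group_means: pd.DataFrame  # groups × transcripts
    retained: pd.Index
    alpha: float
    method: str

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def group_difference_screen(
    matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.01,
    method: str = "wilcoxon",
) -> GroupDiffResult:
    """Two-sided per-transcript test between the two label groups.

    ``method`` is "wilcoxon" (rank-sum, the default — robust to the
    right-skewed coverage ratios) or "welch".  Constant transcripts have
    no defined p-value and are excluded.  Each group needs n >= 3.
    """
    labels = labels.loc[matrix.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    a = matrix.loc[labels == groups[0]].to_numpy()
    b = matrix.loc[labels == groups[1]].to_numpy()
    if min(len(a), len(b)) < 3:
        raise ValueError("each group needs >= 3 samples")

    if method == "wilcoxon":
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
        # mannwhitneyu yields p=1 for constant columns; mark them undefined
        const = np.all(matrix.to_numpy() == matrix.to_numpy()[0], axis=0)
        p[const] = np.nan
    elif method == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")

    pvalues = pd.Series(p, index=matrix.columns)
    means = matrix.groupby(labels, observed=True).mean()
    retained = matrix.columns[(pvalues < alpha).to_numpy()]
    return GroupDiffResult(
        pvalues=pvalues, group_means=means, retained=retained, alpha=alpha, method=method
    )


# ---------------------------------------------------------------------------
# stage-monotone panel
# ---------------------------------------------------------------------------


@dataclass
class FeaturePanel:
    """Ordered panel of selected transcripts with direction labels.

    ``table`` columns: transcript_id, direction (cancer_up / healthy_up),
    rank_score = |mean(stage I) − mean(healthy)|, non-increasing within
    each direction.  ``precut`` holds the wider top-2k-per-direction
    intermediate.
    """

    table: pd.DataFrame
    k_per_direction: int
    precut: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for direction, grp in self.table.groupby("direction"):
            if (np.diff(grp["rank_score"].to_numpy()) > 1e-12).any():
                raise ValueError(f"rank scores not non-increasing within {direction}")
            if len(grp) > self.k_per_direction:
                raise ValueError("panel exceeds configured cap")

    @property
    def transcript_ids(self) -> pd.Index:
        return pd.Index(self.table["transcript_id"])

    def direction_counts(self) -> pd.Series:
        return self.table["direction"].value_counts()

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, k_per_direction: Optional[int] = None) -> "FeaturePanel":
        table = pd.read_csv(path, sep="\t")
        k = k_per_direction or int(table["direction"].value_counts().max())
        return cls(table=table, k_per_direction=k)


def stage_group_means(
    matrix: pd.DataFrame, labels: pd.Series, stages: pd.Series
) -> pd.DataFrame:
    """Group means per transcript for healthy and each cancer stage (rows
    ordered healthy, I, II, III, IV)."""
    labels = labels.loc[matrix.index]
    stages = stages.loc[matrix.index]
    group = stages.where(labels != "healthy", "healthy")
    means = matrix.groupby(group, observed=True).mean()
    missing = [g for g in STAGE_ORDER if g not in means.index or means.loc[g].isna().all()]
    if missing:
        raise ValueError(
            f"stage groups {missing} have no samples; merge or drop stages explicitly "
            "before monotone selection"
        )
    return means.loc[STAGE_ORDER]


def select_stage_monotone(
    matrix: pd.DataFrame,
    labels: pd.Series,
    stages: pd.Series,
    k_per_direction: int = 100,
    precut_per_direction: int = 200,
) -> FeaturePanel:
    """Build the final feature panel from stage-monotone transcripts.

    A transcript is *cancer_up* when its five group means increase
    strictly healthy → I → II → III → IV, *healthy_up* when they decrease
    strictly.  Within each direction, transcripts are ranked by
    |mean(stage I) − mean(healthy)| descending, ties broken by transcript
    id, and the top ``k_per_direction`` kept (``precut_per_direction``
    kept as the intermediate pre-cut).
    """
    means = stage_group_means(matrix, labels, stages)
    diffs = means.diff().iloc[1:]  # 4 consecutive stage steps
    increasing = (diffs > 0).all(axis=0)
    decreasing = (diffs < 0).all(axis=0)
    score = (means.loc["I"] - means.loc["healthy"]).abs()

    def top(mask: pd.Series, direction: str, k: int) -> pd.DataFrame:
        ids = matrix.columns[mask.to_numpy()]
        ranked = (
            pd.DataFrame({"transcript_id": ids, "rank_score": score[ids].to_numpy()})
            .sort_values(["rank_score", "transcript_id"], ascending=[False, True])
            .head(k)
        )
        ranked.insert(1, "direction", direction)
        return ranked

    precut = pd.concat(
        [
            top(increasing, DIRECTION_UP, precut_per_direction),
            top(decreasing, DIRECTION_DOWN, precut_per_direction),
        ],
        ignore_index=True,
    )
    table = pd.concat(
        [
            top(increasing, DIRECTION_UP, k_per_direction),
            top(decreasing, DIRECTION_DOWN, k_per_direction),
        ],
        ignore_index=True,
    )
    return FeaturePanel(table=table, k_per_direction=k_per_direction, precut=precut)


def select_features(
    matrix: pd.DataFrame,
    labels: pd.Series,
    stages: pd.Series,
    k_per_direction: int = 100,
    alpha: float = 0.01,
    cor_cutoff: float = 0.9,
    freq_cut: float = 19.0,
    unique_cut: float = 0.10,
    method: str = "wilcoxon",
) -> FeaturePanel:
    """Run the full filter chain and monotone selection on one matrix."""
    keep = filter_near_zero_variance(matrix, freq_cut=freq_cut, unique_cut=unique_cut)
    keep = filter_high_correlation(matrix[keep], cutoff=cor_cutoff)
    screen = group_difference_screen(matrix[keep], labels, alpha=alpha, method=method)
    return select_stage_monotone(
        matrix[screen.retained], labels, stages, k_per_direction=k_per_direction
    )
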