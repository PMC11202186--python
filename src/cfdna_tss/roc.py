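"""ROC curves, trapezoidal AUC and DeLong confidence intervals.

The AUC here is the usual Mann–Whitney concordance: the probability that
a random case outscores a random control, ties counted one half.  The
95% CI uses the DeLong (1988) structural-components variance with a
normal approximation, truncated to [0, 1] — the pROC default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics


def roc_points(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Threshold-swept ROC curve as a tidy (threshold, fpr, tpr) table."""
    fpr, tpr, thresholds = metrics.roc_curve(y, scores)
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})


def auc_trapezoid(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by trapezoid over the threshold-swept ROC."""
    fpr, tpr, _ = metrics.roc_curve(y, scores)
    return float(metrics.auc(fpr, tpr))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for binary labels y ∈ {0, 1}."""
    y = np.asarray(y, dtype=bool)
    pos = np.asarray(scores, dtype=float)[y]
    neg = np.asarray(scores, dtype=float)[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")
    all_r = _midranks(np.concatenate([pos, neg]))
    pos_r = _midranks(pos)
    neg_r = _midranks(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components V10 (cases) and V01 (controls)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(auc), float(var)


def delong_ci(
    scores: np.ndarray, y: np.ndarray, level: float = 0.95
) -> Tuple[float, float, float]:
    """(AUC, lower, upper) DeLong normal-approximation CI, clipped to [0, 1]."""
    auc, var = delong_variance(scores, y)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return auc, float(np.clip(auc - z * se, 0.0, 1.0)), float(np.clip(auc + z * se, 0.0, 1.0))


def bootstrap_ci(
    scores: np.ndarray,
    y: np.ndarray,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """Percentile-bootstrap AUC CI, stratified by class."""
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        aucs[b] = auc_trapezoid(scores[idx], y[idx])
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
    return auc_trapezoid(scores, y), float(lo), float(hi)


@dataclass
class RocEvaluation:
    """Evaluation of one scored cohort, overall and per case-subgroup.

    ``table`` rows: subgroup name, case/control counts, AUC, 95% CI.
    ``curves`` maps subgroup name to its ROC point table.
    """

    table: pd.DataFrame
    curves: Dict[str, pd.DataFrame]

    @property
    def auc(self) -> float:
        return float(self.table.set_index("subgroup").loc["all", "auc"])


def evaluate_roc(
    scores: pd.Series,
    labels: pd.Series,
    positive_label: str,
    case_subgroups: Optional[Mapping[str, Iterable[str]]] = None,
    ci: str = "delong",
    seed: int = 0,
) -> RocEvaluation:
    """Score a cohort overall and for case subgroups vs *all* controls.

    ``case_subgroups`` maps a name (e.g. "early_stage") to the sample ids
    of the cases in that subgroup; each subgroup ROC uses those cases
    against every control in the cohort.  Empty subgroups are skipped.
    """
    labels = labels.loc[scores.index]
    y_all = (labels == positive_label).to_numpy()
    control_ids = scores.index[~y_all]
    rows = []
    curves: Dict[str, pd.DataFrame] = {}

    subgroup_items = [("all", list(scores.index[y_all]))]
    for name, ids in (case_subgroups or {}).items():
        subgroup_items.append((name, [i for i in ids if i in scores.index and y_all[scores.index.get_loc(i)]]))

    for name, case_ids in subgroup_items:
        if len(case_ids) == 0:
            import warnings

            warnings.warn(f"subgroup {name!r} has no cases in this cohort; skipped")
            continue
        ids = list(case_ids) + list(control_ids)
        s = scores.loc[ids].to_numpy()
        y = np.concatenate([np.ones(len(case_ids), bool), np.zeros(len(control_ids), bool)])
        if ci == "delong":
            auc, lo, hi = delong_ci(s, y)
        elif ci == "bootstrap":
            auc, lo, hi = bootstrap_ci(s, y, seed=seed)
        else:
            raise ValueError(f"unknown ci method {ci!r}")
        rows.append((name, len(case_ids), len(control_ids), auc, lo, hi))
        curves[name] = roc_points(s, y)

    table = pd.DataFrame(
        rows, columns=["subgroup", "n_cases", "n_controls", "auc", "ci_low", "ci_high"]
    )
    return RocEvaluation(table=table, curves=curves)
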