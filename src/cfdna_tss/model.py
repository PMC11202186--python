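"""Cohort splitting and random-forest classification of cfDNA profiles.

Two classifiers share this machinery: a cancer-vs-healthy screen trained
on the 200-feature stage-monotone panel (forest of 1500 trees, one
feature per split) and an EGFR-mutation-status model trained on the
pathway-derived gene features (2500 trees, five per split).  Prediction
error is estimated with three repeats of stratified ten-fold
cross-validation on the training cohort; the final forest is refit on
all training data and judged on held-out cohorts by ROC/AUC with DeLong
confidence intervals.

The API follows the model/results convention: build a
:class:`TssClassifier` from a feature matrix and labels, call
:meth:`~TssClassifier.fit`, and work with the returned
:class:`TssClassifierResults` (CV summary, held-out evaluation,
``summary()`` table).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .roc import RocEvaluation, auc_trapezoid, evaluate_roc


# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation split with per-stratum ceiling rounding.

    Each stratum of size n contributes exactly ``ceil(train_fraction * n)``
    samples to training — the rounding used by caret's
    ``createDataPartition``, and the only rule consistent with splitting
    (96, 100) into (68, 70) and (29, 36) into (21, 26) at 70%.
    """

    train_fraction: float = 0.7
    stratify_by: str = "label"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_split(
    sample_sheet: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> Tuple[List[str], List[str]]:
    """Partition sample ids into (train, validation) per stratum.

    Within each stratum the training members are chosen uniformly at
    random under ``spec.seed``; the partition is disjoint and exhaustive.
    """
    if spec.stratify_by not in sample_sheet.columns:
        raise KeyError(f"sample sheet lacks column {spec.stratify_by!r}")
    rng = np.random.default_rng(spec.seed)
    train: List[str] = []
    val: List[str] = []
    for _, grp in sample_sheet.groupby(spec.stratify_by, sort=True, observed=True):
        ids = grp["sample_id"].to_numpy()
        if len(ids) == 0:
            continue
        n_train = math.ceil(spec.train_fraction * len(ids))
        if n_train == len(ids):
            warnings.warn(
                f"stratum of size {len(ids)} leaves an empty validation side at "
                f"fraction {spec.train_fraction}"
            )
        pick = rng.choice(len(ids), size=n_train, replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[pick] = True
        train.extend(ids[mask])
        val.extend(ids[~mask])
    return train, val


# ---------------------------------------------------------------------------
# random forest model / results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RfSpec:
    """Random-forest hyperparameters and the repeated-CV layout.

    ``mtry`` is the number of features considered per split.  The printed
    settings are (1500, 1) for the cancer screen and (2500, 5) for the
    EGFR model, assessed with 3 × 10-fold stratified CV.
    """

    n_trees: int = 1500
    mtry: int = 1
    cv_folds: int = 10
    cv_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class TssClassifier:
    """Random-forest classifier over normalized cfDNA features.

    Parameters
    ----------
    features : DataFrame
        Training samples × features, already normalized with params fitted
        on these training samples only.
    labels : Series
        Binary labels indexed like ``features``.
    spec : RfSpec
    positive_label : str, optional
        The class whose forest probability is the predictor score;
        defaults to the lexicographically larger label (so "cancer" beats
        "healthy" only by explicit choice — pass it).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: pd.Series,
        spec: RfSpec = RfSpec(),
        positive_label: Optional[str] = None,
    ) -> None:
        labels = labels.loc[features.index]
        classes = sorted(labels.unique())
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {classes}")
        if spec.mtry > features.shape[1]:
            raise ValueError(
                f"mtry={spec.mtry} exceeds the {features.shape[1]}-feature panel"
            )
        self.features = features
        self.labels = labels
        self.spec = spec
        self.positive_label = positive_label or classes[-1]
        if self.positive_label not in classes:
            raise ValueError(f"positive_label {self.positive_label!r} not in {classes}")

    @classmethod
    def from_dataframe(
        cls,
        matrix: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        training_ids: Iterable[str],
        label_col: str = "label",
        positive_label: Optional[str] = None,
        spec: RfSpec = RfSpec(),
        feature_ids: Optional[Iterable[str]] = None,
    ) -> "TssClassifier":
        """Build from a full cohort matrix + sample sheet, restricted to
        the training ids (and optionally to a feature panel)."""
        ids = list(training_ids)
        labels = sample_sheet.set_index("sample_id")[label_col]
        feats = matrix.loc[ids]
        if feature_ids is not None:
            feats = feats[list(feature_ids)]
        return cls(feats, labels.loc[ids], spec=spec, positive_label=positive_label)

    def fit(self, compute_cv: bool = True) -> "TssClassifierResults":
        """Fit the forest on all training data; optionally run repeated CV."""
        X = self.features.to_numpy()
        y = (self.labels == self.positive_label).to_numpy()
        cv_aucs = None
        if compute_cv:
            cv_aucs = self._cross_validate(X, y)
        forest = RandomForestClassifier(
            n_estimators=self.spec.n_trees,
            max_features=self.spec.mtry,
            random_state=self.spec.seed,
        ).fit(X, y)
        return TssClassifierResults(model=self, forest=forest, cv_fold_aucs=cv_aucs)

    def _cross_validate(self, X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        folds = self.spec.cv_folds
        minority = int(min((~y).sum(), y.sum()))
        if minority < folds:
            warnings.warn(
                f"smallest class has {minority} members; reducing CV folds "
                f"from {folds} to {minority}"
            )
            folds = minority
        cv = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=self.spec.cv_repeats, random_state=self.spec.seed
        )
        rows = []
        for k, (tr, te) in enumerate(cv.split(X, y)):
            forest = RandomForestClassifier(
                n_estimators=self.spec.n_trees,
                max_features=self.spec.mtry,
                random_state=self.spec.seed,
            ).fit(X[tr], y[tr])
            scores = forest.predict_proba(X[te])[:, 1]
            auc = auc_trapezoid(scores, y[te]) if len(set(y[te])) == 2 else np.nan
            rows.append((k // folds, k % folds, auc))
        return pd.DataFrame(rows, columns=["repeat", "fold", "auc"])


@dataclass
class TssClassifierResults:
    """Fitted forest plus CV assessment and held-out evaluation methods."""

    model: TssClassifier
    forest: RandomForestClassifier
    cv_fold_aucs: Optional[pd.DataFrame] = None
    evaluations: Dict[str, RocEvaluation] = field(default_factory=dict)

    @property
    def training_ids(self) -> pd.Index:
        return self.model.features.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.model.features.columns

    @property
    def cv_auc(self) -> float:
        if self.cv_fold_aucs is None:
            raise ValueError("fit was run with compute_cv=False")
        return float(self.cv_fold_aucs["auc"].mean())

    def predict_score(self, features: pd.DataFrame) -> pd.Series:
        """Positive-class forest probability (vote fraction) per sample."""
        X = features[self.feature_ids].to_numpy()
        return pd.Series(self.forest.predict_proba(X)[:, 1], index=features.index)

    def evaluate(
        self,
        features: pd.DataFrame,
        labels: pd.Series,
        cohort_name: str = "validation",
        case_subgroups: Optional[Mapping[str, Iterable[str]]] = None,
        ci: str = "delong",
    ) -> RocEvaluation:
        """ROC/AUC on a cohort disjoint from training (enforced)."""
        overlap = features.index.intersection(self.training_ids)
        if len(overlap) > 0:
            raise ValueError(
                f"evaluation cohort shares {len(overlap)} samples with training "
                f"(e.g. {list(overlap[:3])}); leakage refused"
            )
        scores = self.predict_score(features)
        ev = evaluate_roc(
            scores,
            labels,
            positive_label=self.model.positive_label,
            case_subgroups=case_subgroups,
            ci=ci,
        )
        self.evaluations[cohort_name] = ev
        return ev

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Random-forest cfDNA classifier",
            "=" * 46,
            f"positive class      : {self.model.positive_label}",
            f"training samples    : {len(self.training_ids)}",
            f"features            : {len(self.feature_ids)}",
            f"trees / mtry        : {spec.n_trees} / {spec.mtry}",
        ]
        if self.cv_fold_aucs is not None:
            per_rep = self.cv_fold_aucs.groupby("repeat")["auc"].mean()
            lines.append(
                f"CV AUC ({spec.cv_repeats}x{spec.cv_folds}-fold) : "
                f"{self.cv_auc:.3f} (repeat means: "
                + ", ".join(f"{v:.3f}" for v in per_rep)
                + ")"
            )
        for name, ev in self.evaluations.items():
            for row in ev.table.itertuples(index=False):
                lines.append(
                    f"{name}/{row.subgroup:<12s}: AUC {row.auc:.3f} "
                    f"(95% CI {row.ci_low:.3f}-{row.ci_high:.3f}, "
                    f"{row.n_cases} cases / {row.n_controls} controls)"
                )
        return "\n".join(lines)
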