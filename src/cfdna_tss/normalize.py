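"""Training-cohort z-score normalization, frozen for reuse on later cohorts.

Per-transcript mean and standard deviation are estimated on the training
samples only and then applied unchanged to validation / test cohorts, so
no information leaks from evaluation data into the feature scale.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix

MatrixLike = Union[CoverageMatrix, pd.DataFrame]


def _as_frame(matrix: MatrixLike) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, CoverageMatrix) else matrix


@dataclass
class NormalizationParams:
    """Frozen per-transcript mean/sd plus the transcripts dropped at fit time.

    ``flagged`` collects transcripts unusable for z-scoring: fully masked
    in training, masked in more than ``max_missing_frac`` of training
    samples, or with zero training variance (these die in the near-zero-
    variance filter anyway).
    """

    mean: pd.Series
    sd: pd.Series
    flagged: pd.Index
    n_train: int
    max_missing_frac: float = 0.2

    @property
    def transcript_ids(self) -> pd.Index:
        return self.mean.index

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "flagged": list(self.flagged),
            "n_train": self.n_train,
            "max_missing_frac": self.max_missing_frac,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "NormalizationParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mean=pd.Series(payload["mean"], dtype=float),
            sd=pd.Series(payload["sd"], dtype=float),
            flagged=pd.Index(payload["flagged"]),
            n_train=int(payload["n_train"]),
            max_missing_frac=float(payload["max_missing_frac"]),
        )


def fit_normalization(
    matrix: MatrixLike, training_ids: Iterable[str], max_missing_frac: float = 0.2
) -> NormalizationParams:
    """Estimate per-transcript mean and sample sd over unmasked training entries.

    Transcripts masked in > ``max_missing_frac`` of training samples, or
    with sd == 0, are flagged and excluded downstream.
    """
    values = _as_frame(matrix)
    training_ids = list(training_ids)
    missing = [s for s in training_ids if s not in values.index]
    if missing:
        raise KeyError(f"training ids absent from matrix: {missing[:5]} ...")
    train = values.loc[training_ids]
    n_obs = train.notna().sum(axis=0)
    if (n_obs < 2).all():
        raise ValueError("need >= 2 unmasked training samples for at least one transcript")

    mean = train.mean(axis=0, skipna=True)
    sd = train.std(axis=0, ddof=1, skipna=True)
    missing_frac = 1.0 - n_obs / len(training_ids)
    bad = (n_obs < 2) | (missing_frac > max_missing_frac) | (sd.fillna(0.0) == 0.0)
    flagged = values.columns[bad]
    keep = values.columns[~bad]
    return NormalizationParams(
        mean=mean[keep],
        sd=sd[keep],
        flagged=flagged,
        n_train=len(training_ids),
        max_missing_frac=max_missing_frac,
    )


def apply_normalization(matrix: MatrixLike, params: NormalizationParams) -> pd.DataFrame:
    """z = (x - mean) / sd with frozen training params.

    Masked (NaN) entries are imputed with the training mean, i.e. z = 0.
    Transcripts flagged at fit time are dropped; transcripts in the
    params but absent from the matrix are dropped with a warning.
    """
    values = _as_frame(matrix)
    common = params.transcript_ids.intersection(values.columns)
    if len(common) < len(params.transcript_ids):
        warnings.warn(
            f"{len(params.transcript_ids) - len(common)} transcripts in params "
            "are absent from the matrix and were dropped"
        )
    z = (values[common] - params.mean[common]) / params.sd[common]
    return z.fillna(0.0)
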