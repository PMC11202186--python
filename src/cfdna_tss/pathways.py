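"""Pathway activity ("path") scores from normalized TSS coverage.

A pathway's score in a sample is the mean normalized TSS coverage of the
pathway's genes, where each gene's value is first averaged over its
transcripts so multi-transcript genes are not over-weighted.  Gene sets
come from any GMT file; the "EGFR-related" subset is flagged as every set
containing a configurable anchor symbol (default ``EGFR``).
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import TssAnnotation

logger = logging.getLogger(__name__)


@dataclass
class PathwayDB:
    """Named gene sets with an EGFR-related subset flag."""

    sets: Dict[str, List[str]]
    anchor: str = "EGFR"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    @classmethod
    def from_gmt(cls, path: str | os.PathLike, anchor: str = "EGFR") -> "PathwayDB":
        from gseapy.parser import read_gmt

        sets = {name: list(genes) for name, genes in read_gmt(os.fspath(path)).items()}
        if not sets:
            raise ValueError(f"no gene sets parsed from {path!r}")
        return cls(sets=sets, anchor=anchor)

    @property
    def names(self) -> List[str]:
        return list(self.sets)

    def is_anchor_related(self, name: str) -> bool:
        return self.anchor in self.sets[name]

    @property
    def anchor_related(self) -> List[str]:
        return [n for n in self.sets if self.is_anchor_related(n)]

    def genes(self, names: Optional[Iterable[str]] = None) -> Set[str]:
        names = self.names if names is None else list(names)
        out: Set[str] = set()
        for n in names:
            out |= set(self.sets[n])
        return out


def gene_level_values(
    normalized: pd.DataFrame, annotation: TssAnnotation
) -> pd.DataFrame:
    """Collapse the samples × transcripts matrix to samples × genes.

    A gene's value is the mean of its transcripts' normalized values;
    transcripts absent from the matrix are ignored.
    """
    t2g = annotation.transcript_to_gene()
    present = normalized.columns.intersection(t2g.index)
    if len(present) == 0:
        raise ValueError("no matrix transcripts found in the annotation")
    return normalized[present].T.groupby(t2g[present]).mean().T.rename_axis(columns=None)


def path_score(gene_matrix: pd.DataFrame, genes: Iterable[str]) -> pd.Series:
    """Per-sample mean over the pathway genes present in the matrix.

    Returns all-NaN (pathway missing) when no gene overlaps the matrix.
    """
    genes = list(genes)
    present = [g for g in genes if g in gene_matrix.columns]
    if not present:
        return pd.Series(np.nan, index=gene_matrix.index)
    if len(present) < len(genes):
        logger.info("pathway coverage %d/%d genes present", len(present), len(genes))
    return gene_matrix[present].mean(axis=1)


def path_score_matrix(gene_matrix: pd.DataFrame, db: PathwayDB) -> pd.DataFrame:
    """Samples × pathways score matrix (NaN columns where no gene overlaps)."""
    return pd.DataFrame(
        {name: path_score(gene_matrix, genes) for name, genes in db.sets.items()}
    )


@dataclass
class PathwayTestResult:
    """Per-pathway two-group comparison with significant-fraction summaries."""

    pvalues: pd.Series
    alpha: float
    anchor_related: List[str]

    @property
    def significant(self) -> pd.Index:
        return self.pvalues.index[(self.pvalues < self.alpha).to_numpy()]

    def fraction_table(self) -> pd.DataFrame:
        """Significant / total / fraction rows for all, anchor-related and
        other pathways (pathways with undefined p excluded from totals)."""
        tested = self.pvalues.dropna().index
        sig = set(self.significant)
        rows = []
        for name, subset in [
            ("all", list(tested)),
            ("egfr_related", [p for p in tested if p in self.anchor_related]),
            ("non_egfr", [p for p in tested if p not in self.anchor_related]),
        ]:
            n_sig = sum(p in sig for p in subset)
            total = len(subset)
            rows.append((name, n_sig, total, n_sig / total if total else np.nan))
        return pd.DataFrame(rows, columns=["subset", "significant", "total", "fraction"])


def pathway_group_test(
    scores: pd.DataFrame,
    labels: pd.Series,
    db: PathwayDB,
    alpha: float = 0.01,
) -> PathwayTestResult:
    """Two-sided Wilcoxon rank-sum per pathway between the two label groups.

    Pathways with constant or missing scores get NaN p-values and are
    excluded from the fraction summaries.
    """
    labels = labels.loc[scores.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    pvals = {}
    for name in scores.columns:
        x = scores[name]
        a = x[labels == groups[0]].dropna()
        b = x[labels == groups[1]].dropna()
        if len(a) < 3 or len(b) < 3 or x.dropna().nunique() < 2:
            pvals[name] = np.nan
            continue
        pvals[name] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return PathwayTestResult(
        pvalues=pd.Series(pvals), alpha=alpha, anchor_related=db.anchor_related
    )


def egfr_feature_set(
    gene_matrix: pd.DataFrame,
    db: PathwayDB,
    labels: pd.Series,
    alpha: float = 0.01,
) -> List[str]:
    """Gene-level feature list for the mutation-status model.

    Restricts to genes of the anchor-related (EGFR-containing) pathways
    present in the matrix, tests each gene between the two label groups
    (Wilcoxon, two-sided), and retains genes with p < alpha, ordered by
    p-value then symbol.
    """
    candidates = sorted(db.genes(db.anchor_related) & set(gene_matrix.columns))
    if not candidates:
        warnings.warn("no anchor-related pathway genes overlap the matrix")
        return []
    labels = labels.loc[gene_matrix.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    a = gene_matrix.loc[labels == groups[0], candidates].to_numpy()
    b = gene_matrix.loc[labels == groups[1], candidates].to_numpy()
    with np.errstate(invalid="ignore"):
        p = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided").pvalue
    order = pd.DataFrame({"gene": candidates, "p": p}).sort_values(["p", "gene"])
    return list(order.loc[order["p"] < alpha, "gene"]) if alpha < 1 else list(order["gene"])
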