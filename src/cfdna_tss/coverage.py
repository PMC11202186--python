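"""TSS relative coverage from aligned cfDNA fragments.

The central quantity is the *TSS relative coverage*: the mean per-base
fragment depth in a 1 kb window centred on a transcription start site,
divided by the mean depth of the two flanking 1 kb windows.  Active
promoters sit in nucleosome-depleted regions, so cfDNA fragments are
under-represented there and the ratio drops below 1.

Window convention: all three windows are half-open 1000-base intervals,

    central      [tss - 500,  tss + 500)
    left flank   [tss - 1500, tss - 500)
    right flank  [tss + 500,  tss + 1500)

so the divisors are exact and the three windows partition
``[tss - 1500, tss + 1500)``.  The statistic is symmetric about the TSS
and is therefore applied identically on both strands.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CENTRAL_HALF = 500
FLANK_WIDTH = 1000
WINDOW_REACH = CENTRAL_HALF + FLANK_WIDTH  # 1500 bp either side of the TSS

ANNOTATION_COLUMNS = ["chrom", "tss_pos", "strand", "transcript_id", "gene_symbol"]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class TssAnnotation:
    """Table of TSS locations with a transcript-to-gene mapping.

    One row per transcript: chrom, 0-based TSS coordinate, strand,
    transcript id (unique) and gene symbol.  Sites closer than 1500 bp to
    the chromosome start cannot carry a full left flank and are flagged
    unusable rather than dropped.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table lacks columns {missing}")
        if self.table["transcript_id"].duplicated().any():
            dup = self.table.loc[self.table["transcript_id"].duplicated(), "transcript_id"]
            raise ValueError(f"duplicate transcript ids: {sorted(set(dup))[:5]} ...")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def usable(self) -> pd.Series:
        """Boolean per transcript: full ±1500 bp window fits on the chromosome."""
        return self.table["tss_pos"] >= WINDOW_REACH

    @property
    def transcript_ids(self) -> pd.Index:
        return pd.Index(self.table["transcript_id"])

    def transcript_to_gene(self) -> pd.Series:
        return pd.Series(
            self.table["gene_symbol"].values, index=self.table["transcript_id"].values
        )

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "TssAnnotation":
        """Read a BED6 annotation: chrom, start, start+1, transcript_id[|gene], score, strand.

        The name field may be ``transcript_id`` or ``transcript_id|gene_symbol``;
        without an explicit gene the transcript id doubles as the symbol.
        """
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
        name_parts = bed["name"].str.split("|", n=1, expand=True)
        tids = name_parts[0]
        genes = name_parts[1] if name_parts.shape[1] > 1 else pd.Series([None] * len(bed))
        genes = genes.fillna(tids)
        return cls(
            pd.DataFrame(
                {
                    "chrom": bed["chrom"],
                    "tss_pos": bed["start"].astype(np.int64),
                    "strand": bed["strand"],
                    "transcript_id": tids,
                    "gene_symbol": genes,
                }
            )
        )

    def to_bed(self, path: str | os.PathLike) -> None:
        bed = pd.DataFrame(
            {
                "chrom": self.table["chrom"],
                "start": self.table["tss_pos"],
                "end": self.table["tss_pos"] + 1,
                "name": self.table["transcript_id"] + "|" + self.table["gene_symbol"],
                "score": 0,
                "strand": self.table["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# fragment input
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadFilterSpec:
    """BAM record filters: drop MAPQ < min_mapq and any flag bit in flag_mask.

    The default mask 3840 removes secondary (256), QC-fail (512),
    duplicate (1024) and supplementary (2048) records, matching
    ``samtools view -q 2 -F 3840``.
    """

    min_mapq: int = 2
    flag_mask: int = 3840


def read_fragments(
    path: str | os.PathLike, filters: ReadFilterSpec = ReadFilterSpec()
) -> pd.DataFrame:
    """Load fragment intervals from a BED3 file or a coordinate-sorted BAM.

    BAM records are filtered per the spec; one fragment is emitted per
    template, taken from the leftmost mate of a pair (TLEN > 0) or from the
    read span for unpaired records.  BED input is passed through unfiltered
    (assumed pre-filtered by its producer).

    Returns a DataFrame with columns chrom, start, end (0-based half-open).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    lower = path.lower()
    if lower.endswith((".bed", ".bed3", ".bed.gz")):
        frags = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        return frags
    if lower.endswith((".bam", ".cram")):
        return pd.DataFrame(
            _iter_bam_fragments(path, filters), columns=["chrom", "start", "end"]
        )
    raise ValueError(
        f"unrecognised fragment file extension: {path!r} (expected .bed or .bam)"
    )


def _iter_bam_fragments(
    path: str, filters: ReadFilterSpec
) -> Iterator[Tuple[str, int, int]]:
    import pysam

    with pysam.AlignmentFile(path, "rb") as bam:
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise ValueError(
                f"BAM {path!r} has no index; coordinate-sort and run `samtools index` first"
            ) from exc
        if bam.header.get("HD", {}).get("SO") != "coordinate":
            raise ValueError(
                f"BAM {path!r} is not coordinate-sorted; run `samtools sort` first"
            )
        for rec in bam:
            if rec.is_unmapped:
                continue
            if rec.flag & filters.flag_mask:
                continue
            if rec.mapping_quality < filters.min_mapq:
                continue
            if rec.is_paired:
                # count each template once, from its leftmost mate
                if rec.template_length <= 0:
                    continue
                yield rec.reference_name, rec.reference_start, rec.reference_start + rec.template_length
            else:
                yield rec.reference_name, rec.reference_start, rec.reference_end


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------


@dataclass
class DepthWindow:
    """Per-base depth over the central and two flanking windows of one TSS."""

    central: np.ndarray
    left_flank: np.ndarray
    right_flank: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (
            ("central", self.central),
            ("left_flank", self.left_flank),
            ("right_flank", self.right_flank),
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (FLANK_WIDTH,):
                raise ValueError(f"{name} must hold exactly {FLANK_WIDTH} per-base depths")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative depths")
            setattr(self, name, arr)


def tss_relative_coverage(window: DepthWindow) -> float:
    """Relative coverage = mean central depth / mean flank depth.

    Returns NaN (a masked value, not an error) when both flanks are empty.
    """
    central = window.central.sum() / FLANK_WIDTH
    background = (window.left_flank.sum() + window.right_flank.sum()) / (2 * FLANK_WIDTH)
    if background == 0:
        return float("nan")
    return float(central / background)


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------


@dataclass
class CoverageMatrix:
    """Samples × transcripts matrix of TSS relative coverage.

    Masked entries (zero flanking depth, or unusable TSS geometry) are NaN
    in ``values``; ``mask`` mirrors them as booleans.
    """

    values: pd.DataFrame

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | os.PathLike, mask_path: str | os.PathLike | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")
        if mask_path is not None:
            self.mask.astype(int).to_csv(mask_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CoverageMatrix":
        values = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(values.rename_axis(index=None))


FragmentSource = Union[
    Mapping[str, pd.DataFrame], Iterable[Tuple[str, pd.DataFrame]]
]


def build_coverage_matrix(
    fragments_by_sample: FragmentSource, annotation: TssAnnotation
) -> CoverageMatrix:
    """Compute the relative-coverage matrix for a cohort.

    ``fragments_by_sample`` maps sample id → fragment DataFrame
    (chrom/start/end), or is an iterable of such pairs (streamed, one
    sample in memory at a time).  Per-base depth is the number of
    fragments overlapping each base.  Transcripts sharing a TSS
    coordinate are computed once and share the value.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    usable = annotation.usable
    if not usable.any():
        raise ValueError("no usable TSS: every site is < 1500 bp from its chromosome start")
    n_unusable = int((~usable).sum())
    if n_unusable:
        logger.info("masking %d TSS records too close to a chromosome start", n_unusable)

    ann = annotation.table
    # unique (chrom, tss_pos) sites, mapped back to transcripts afterwards
    sites = ann.loc[usable, ["chrom", "tss_pos"]].drop_duplicates()
    site_index = pd.MultiIndex.from_frame(sites)

    items = (
        fragments_by_sample.items()
        if isinstance(fragments_by_sample, Mapping)
        else fragments_by_sample
    )

    rows = {}
    for sample_id, frags in items:
        if len(frags) == 0:
            raise ValueError(f"sample {sample_id!r} has no fragments")
        rows[sample_id] = _site_relative_coverage(frags, sites)
    if not rows:
        raise ValueError("no samples provided")

    site_values = pd.DataFrame.from_dict(rows, orient="index")
    site_values.columns = site_index

    # broadcast unique-site values to every transcript at that site
    key = pd.MultiIndex.from_frame(ann[["chrom", "tss_pos"]])
    out = pd.DataFrame(
        np.nan, index=site_values.index, columns=ann["transcript_id"], dtype=float
    )
    present = key.isin(site_index)
    out.loc[:, ann.loc[present.nonzero()[0], "transcript_id"]] = site_values.loc[
        :, key[present]
    ].to_numpy()
    out.columns.name = None
    return CoverageMatrix(out)


def _site_relative_coverage(frags: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    """Relative coverage at each unique TSS site for one sample.

    Uses a prefix-sum of the per-base depth track per chromosome so each
    window sum is two array lookups.
    """
    values = np.full(len(sites), np.nan)
    for chrom, idx in sites.groupby("chrom", sort=False).groups.items():
        pos = sites.loc[idx, "tss_pos"].to_numpy(dtype=np.int64)
        sel = frags["chrom"] == chrom
        starts = frags.loc[sel, "start"].to_numpy(dtype=np.int64)
        ends = frags.loc[sel, "end"].to_numpy(dtype=np.int64)
        out_pos = sites.index.get_indexer(idx)
        if len(starts) == 0:
            continue
        reach = int(pos.max()) + WINDOW_REACH
        depth_prefix = _depth_prefix(starts, ends, reach)

        def wsum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            a = np.clip(a, 0, reach)
            b = np.clip(b, 0, reach)
            return depth_prefix[b] - depth_prefix[a]

        central = wsum(pos - CENTRAL_HALF, pos + CENTRAL_HALF)
        flanks = wsum(pos - WINDOW_REACH, pos - CENTRAL_HALF) + wsum(
            pos + CENTRAL_HALF, pos + WINDOW_REACH
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = (central / FLANK_WIDTH) / (flanks / (2 * FLANK_WIDTH))
        vals[flanks == 0] = np.nan
        values[out_pos] = vals
    return values


def _depth_prefix(starts: np.ndarray, ends: np.ndarray, length: int) -> np.ndarray:
    """prefix[i] = total fragment-overlap depth summed over bases [0, i)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    s = np.clip(starts, 0, length)
    e = np.clip(ends, 0, length)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    depth = np.cumsum(diff[:-1])
    prefix = np.zeros(length + 1, dtype=np.float64)
    np.cumsum(depth, out=prefix[1:])
    return prefix
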