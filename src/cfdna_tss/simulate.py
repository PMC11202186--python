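"""Synthetic cfDNA cohort generator with planted class, stage and pathway structure.

The generator emulates what the downstream statistic actually measures:
shallow (~6×) whole-genome fragment coverage that dips inside the
nucleosome-depleted window around each TSS.  Fragment *midpoints* are
drawn from a density that is flat at the background rate everywhere
except TSS ± 500 bp, where it is scaled by that sample's depletion
fraction for that TSS; fragment lengths follow the canonical ~167 bp
mono-nucleosomal cfDNA distribution (Normal(167, 10) truncated to
[80, 300]).

Planted structure, all on one synthetic chromosome ``chrS``:

* informative-up transcripts gain ``stage_effect`` of central coverage per
  stage step healthy → I → II → III → IV; informative-down lose it;
* all remaining TSSs share one class-independent depletion;
* genes of the planted "EGFR" pathways gain ``pathway_effect`` in
  EGFR-positive samples.

Per-(sample, TSS) multiplicative noise is applied to the depletion
fraction itself: a global per-sample depth factor would cancel exactly in
the relative-coverage ratio, so biological sample-to-sample variation has
to enter through the depletion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import TssAnnotation, WINDOW_REACH, CENTRAL_HALF

CHROM = "chrS"
STAGES = ["I", "II", "III", "IV"]
#: depth multiplier applied per stage step, ordered healthy, I, II, III, IV
STAGE_STEPS = {"healthy": 0, "I": 1, "II": 2, "III": 3, "IV": 4}
DEPLETION_MAX = 1.5


@dataclass
class SimConfig:
    """Study-design and signal parameters of a synthetic cohort.

    Defaults describe a modest lung-cancer-style case/control cohort
    sequenced to ~6× with a pronounced, stage-graded accessibility signal
    at 100 + 100 planted TSSs out of 2000.
    """

    n_healthy: int = 60
    n_cancer_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"I": 15, "II": 15, "III": 15, "IV": 15}
    )
    n_tss: int = 2000
    n_informative_up: int = 100
    n_informative_down: int = 100
    background_depth: float = 6.0  # mean reads per base, genome-wide
    depletion_healthy: float = 0.5  # central/flank depth ratio of an active TSS
    stage_effect: float = 0.12  # per-stage additive shift on the depletion fraction
    frag_len_mean: float = 167.0
    frag_len_sd: float = 10.0
    frag_len_min: int = 80
    frag_len_max: int = 300
    noise_sd: float = 0.08  # multiplicative noise on per-(sample,TSS) depletion
    n_pathways: int = 30
    n_egfr_pathways: int = 5
    genes_per_pathway: int = 20
    pathway_effect: float = 0.1  # depletion shift for EGFR-pathway genes in EGFR+ samples
    egfr_positive_fraction: float = 0.45
    transcripts_per_gene: int = 1
    tss_spacing: int = 4000  # bp between adjacent TSSs on chrS
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_healthy": self.n_healthy,
            "n_tss": self.n_tss,
            "n_informative_up": self.n_informative_up,
            "n_informative_down": self.n_informative_down,
            "n_pathways": self.n_pathways,
            "n_egfr_pathways": self.n_egfr_pathways,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if any(v < 0 for v in self.n_cancer_per_stage.values()):
            raise ValueError("per-stage counts must be >= 0")
        if set(self.n_cancer_per_stage) - set(STAGES):
            raise ValueError(f"stages must be among {STAGES}")
        if self.n_informative_up + self.n_informative_down > self.n_tss:
            raise ValueError("more informative TSSs requested than n_tss")
        if not 0 < self.depletion_healthy < 1:
            raise ValueError("depletion_healthy must lie in (0, 1)")
        if self.n_egfr_pathways > self.n_pathways:
            raise ValueError("n_egfr_pathways cannot exceed n_pathways")
        if self.transcripts_per_gene < 1 or self.transcripts_per_gene > 3:
            raise ValueError("transcripts_per_gene must be 1..3")
        if self.tss_spacing < 2 * WINDOW_REACH:
            raise ValueError(
                f"tss_spacing={self.tss_spacing} bp would overlap adjacent ±{WINDOW_REACH} bp "
                f"windows; use spacing >= {2 * WINDOW_REACH} or request fewer TSSs per chromosome"
            )

    @property
    def n_cancer(self) -> int:
        return sum(self.n_cancer_per_stage.get(s, 0) for s in STAGES)

    @property
    def n_samples(self) -> int:
        return self.n_healthy + self.n_cancer

    @property
    def chrom_length(self) -> int:
        return self.tss_spacing * self.n_tss

    def tss_positions(self) -> np.ndarray:
        half = self.tss_spacing // 2
        return half + self.tss_spacing * np.arange(self.n_tss, dtype=np.int64)


@dataclass
class SyntheticCohort:
    """A generated cohort: annotation, sample sheet, pathway sets and truth.

    Fragments are not held in memory: :meth:`fragments` regenerates a
    sample's fragment table deterministically from per-sample seeds, and
    :meth:`fragment_items` streams the whole cohort.
    """

    config: SimConfig
    annotation: TssAnnotation
    sample_sheet: pd.DataFrame  # sample_id, label, stage, egfr_status
    truth: pd.DataFrame  # transcript_id, direction in {up, down, none}, base depletion/stage
    pathways: Dict[str, List[str]]
    egfr_pathways: List[str]
    depletion: pd.DataFrame  # samples × transcripts expected depletion (noise-free)
    _sample_seeds: Dict[str, np.random.SeedSequence] = field(repr=False, default_factory=dict)
    paths: Dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.sample_sheet["sample_id"])

    def fragments(self, sample_id: str) -> pd.DataFrame:
        """Regenerate the fragment table (chrom/start/end) for one sample."""
        cfg = self.config
        rng = np.random.Generator(np.random.PCG64(self._sample_seeds[sample_id]))
        depl = self.depletion.loc[sample_id].to_numpy()
        return _draw_sample_fragments(cfg, depl, rng)

    def fragment_items(self) -> Iterator[Tuple[str, pd.DataFrame]]:
        for sid in self.sample_ids:
            yield sid, self.fragments(sid)

    def write(self, outdir: str | os.PathLike, bam: bool = False) -> Dict[str, str]:
        """Write TSS BED, per-sample fragment BEDs (optionally BAMs), sample
        sheet TSV, pathway GMT and truth TSV under ``outdir``."""
        out = Path(outdir)
        (out / "fragments").mkdir(parents=True, exist_ok=True)
        paths = {
            "tss_bed": str(out / "tss.bed"),
            "sample_sheet": str(out / "samples.tsv"),
            "gmt": str(out / "pathways.gmt"),
            "truth": str(out / "truth.tsv"),
            "fragment_dir": str(out / "fragments"),
        }
        self.annotation.to_bed(paths["tss_bed"])
        self.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
        with open(paths["gmt"], "w") as fh:
            for name, genes in self.pathways.items():
                desc = "planted_egfr" if name in self.egfr_pathways else "background"
                fh.write("\t".join([name, desc, *genes]) + "\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        for sid, frags in self.fragment_items():
            bed = out / "fragments" / f"{sid}.bed"
            frags.to_csv(bed, sep="\t", header=False, index=False)
            if bam:
                _write_bam(frags, str(out / "fragments" / f"{sid}.bam"), self.config)
        self.paths = paths
        return paths


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Build a synthetic cohort per ``config``; ``config.seed`` fixes everything."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    meta_seed, frag_root = root.spawn(2)
    rng = np.random.Generator(np.random.PCG64(meta_seed))

    annotation = _make_annotation(config)
    sheet = _make_sample_sheet(config, rng)
    truth, directions = _plant_directions(config, rng, annotation)
    pathways, egfr_pathways = _make_pathways(config, rng, annotation)
    depletion = _expected_depletion(
        config, annotation, sheet, directions, pathways, egfr_pathways, rng
    )

    sample_seeds = dict(zip(sheet["sample_id"], frag_root.spawn(len(sheet))))
    return SyntheticCohort(
        config=config,
        annotation=annotation,
        sample_sheet=sheet,
        truth=truth,
        pathways=pathways,
        egfr_pathways=egfr_pathways,
        depletion=depletion,
        _sample_seeds=sample_seeds,
    )


# ---------------------------------------------------------------------------
# cohort pieces
# ---------------------------------------------------------------------------


def _make_annotation(config: SimConfig) -> TssAnnotation:
    pos = config.tss_positions()
    n = config.n_tss
    k = config.transcripts_per_gene
    gene_idx = np.arange(n) // k
    genes = np.array([f"G{i + 1:06d}" for i in gene_idx])
    # one real anchor symbol so GMT anchor-flagging is exercised end to end
    genes[gene_idx == gene_idx[-1]] = "EGFR"
    tids = np.array([f"T{i + 1:06d}" for i in range(n)])
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    return TssAnnotation(
        pd.DataFrame(
            {
                "chrom": CHROM,
                "tss_pos": pos,
                "strand": strands,
                "transcript_id": tids,
                "gene_symbol": genes,
            }
        )
    )


def _make_sample_sheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(config.n_healthy):
        rows.append((f"H{i + 1:04d}", "healthy", "NA", "NA"))
    c = 0
    for stage in STAGES:
        for _ in range(config.n_cancer_per_stage.get(stage, 0)):
            c += 1
            rows.append((f"C{c:04d}", "cancer", stage, None))
    sheet = pd.DataFrame(rows, columns=["sample_id", "label", "stage", "egfr_status"])
    cancer = sheet["label"] == "cancer"
    egfr = np.where(
        rng.random(int(cancer.sum())) < config.egfr_positive_fraction,
        "positive",
        "wild-type",
    )
    sheet.loc[cancer, "egfr_status"] = egfr
    sheet["egfr_status"] = sheet["egfr_status"].fillna("NA")
    return sheet


def _plant_directions(
    config: SimConfig, rng: np.random.Generator, annotation: TssAnnotation
) -> Tuple[pd.DataFrame, np.ndarray]:
    n = config.n_tss
    directions = np.array(["none"] * n, dtype=object)
    chosen = rng.choice(n, size=config.n_informative_up + config.n_informative_down, replace=False)
    directions[chosen[: config.n_informative_up]] = "up"
    directions[chosen[config.n_informative_up :]] = "down"
    truth = pd.DataFrame(
        {
            "transcript_id": annotation.table["transcript_id"],
            "gene_symbol": annotation.table["gene_symbol"],
            "direction": directions,
        }
    )
    return truth, directions


def _make_pathways(
    config: SimConfig, rng: np.random.Generator, annotation: TssAnnotation
) -> Tuple[Dict[str, List[str]], List[str]]:
    genes = list(dict.fromkeys(annotation.table["gene_symbol"]))
    pathways: Dict[str, List[str]] = {}
    egfr_pathways: List[str] = []
    size = min(config.genes_per_pathway, len(genes))
    for p in range(config.n_pathways):
        members = list(rng.choice(genes, size=size, replace=False))
        name = f"PW{p + 1:03d}"
        if p < config.n_egfr_pathways:
            if "EGFR" not in members:
                members[0] = "EGFR"
            egfr_pathways.append(name)
        else:
            members = [g for g in members if g != "EGFR"] or members
        pathways[name] = sorted(set(members))
    return pathways, egfr_pathways


def _expected_depletion(
    config: SimConfig,
    annotation: TssAnnotation,
    sheet: pd.DataFrame,
    directions: np.ndarray,
    pathways: Dict[str, List[str]],
    egfr_pathways: List[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Noise-free expected depletion fraction per (sample, transcript)."""
    base = np.full(config.n_tss, config.depletion_healthy)
    sign = np.where(directions == "up", 1.0, np.where(directions == "down", -1.0, 0.0))

    egfr_genes = set().union(*(pathways[p] for p in egfr_pathways)) if egfr_pathways else set()
    in_egfr_pathway = annotation.table["gene_symbol"].isin(egfr_genes).to_numpy()

    rows = np.empty((len(sheet), config.n_tss))
    for i, rec in enumerate(sheet.itertuples(index=False)):
        steps = STAGE_STEPS.get(rec.stage, 0)
        d = base + sign * config.stage_effect * steps
        if rec.egfr_status == "positive":
            d = d + in_egfr_pathway * config.pathway_effect
        rows[i] = np.clip(d, 0.0, DEPLETION_MAX)
    return pd.DataFrame(rows, index=sheet["sample_id"], columns=annotation.table["transcript_id"])


# ---------------------------------------------------------------------------
# fragment drawing
# ---------------------------------------------------------------------------


def _trunc_len_dist(config: SimConfig) -> stats.rv_continuous:
    a = (config.frag_len_min - config.frag_len_mean) / config.frag_len_sd
    b = (config.frag_len_max - config.frag_len_mean) / config.frag_len_sd
    return stats.truncnorm(a, b, loc=config.frag_len_mean, scale=config.frag_len_sd)


def expected_fragment_length(config: SimConfig) -> float:
    return float(_trunc_len_dist(config).mean())


def _draw_sample_fragments(
    config: SimConfig, depletion: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one sample's fragments.

    Midpoint rate is ``background_depth / E[len]`` per base so expected
    per-base depth equals ``background_depth`` away from TSSs.  Midpoints
    falling in a central window are thinned to that TSS's depletion
    fraction (with multiplicative noise); depletions above 1 add extra
    Poisson midpoints in the window.
    """
    L = config.chrom_length
    spacing = config.tss_spacing
    half = spacing // 2
    rate = config.background_depth / expected_fragment_length(config)

    noisy = depletion * (1.0 + rng.normal(0.0, config.noise_sd, size=depletion.shape))
    noisy = np.clip(noisy, 0.0, DEPLETION_MAX)

    n_bg = rng.poisson(rate * L)
    mid = rng.uniform(0.0, L, size=n_bg)
    offset = mid % spacing
    in_central = (offset >= half - CENTRAL_HALF) & (offset < half + CENTRAL_HALF)
    tss_of = (mid[in_central] // spacing).astype(np.int64)
    keep_p = np.minimum(noisy[tss_of], 1.0)
    drop = rng.random(len(tss_of)) >= keep_p
    delete_idx = np.flatnonzero(in_central)[drop]
    mid = np.delete(mid, delete_idx)

    excess = np.flatnonzero(noisy > 1.0)
    if len(excess):
        extra_n = rng.poisson(rate * 2 * CENTRAL_HALF * (noisy[excess] - 1.0))
        extras = []
        for t, n_extra in zip(excess, extra_n):
            if n_extra:
                lo = half + t * spacing - CENTRAL_HALF
                extras.append(rng.uniform(lo, lo + 2 * CENTRAL_HALF, size=n_extra))
        if extras:
            mid = np.concatenate([mid, *extras])

    lens = np.round(
        _trunc_len_dist(config).rvs(size=len(mid), random_state=rng)
    ).astype(np.int64)
    starts = np.round(mid - lens / 2.0).astype(np.int64)
    ends = starts + lens
    ok = (starts >= 0) & (ends <= L)
    starts, ends = starts[ok], ends[ok]
    order = np.argsort(starts, kind="stable")
    return pd.DataFrame({"chrom": CHROM, "start": starts[order], "end": ends[order]})


def _write_bam(frags: pd.DataFrame, path: str, config: SimConfig) -> None:
    """Export fragments as proper read pairs in a coordinate-sorted, indexed BAM."""
    import pysam

    read_len = 50
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CHROM, "LN": config.chrom_length}],
    }
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for i, (start, end) in enumerate(zip(frags["start"], frags["end"])):
            flen = int(end - start)
            rl = min(read_len, flen)
            for is_r1 in (True, False):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"frag{i:09d}"
                a.reference_name = CHROM
                a.mapping_quality = 60
                a.query_sequence = "A" * rl
                a.cigarstring = f"{rl}M"
                if is_r1:
                    a.flag = 99
                    a.reference_start = int(start)
                    a.next_reference_start = int(end) - rl
                    a.template_length = flen
                else:
                    a.flag = 147
                    a.reference_start = int(end) - rl
                    a.next_reference_start = int(start)
                    a.template_length = -flen
                a.next_reference_name = CHROM
                bam.write(a)
    pysam.sort("-o", path, unsorted)
    os.remove(unsorted)
    pysam.index(path)
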