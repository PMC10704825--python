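"""Parental-origin genotyping of hybrid offspring from variant sites.

Given jointly called variants for two parents and an offspring, the
pipeline follows the QTL-seq idea:

1.  drop low-quality sites (QD < 2.0 or FS > 60.0);
2.  keep positions where both parents are homozygous for *different*
    alleles — only these are informative about parental origin;
3.  compute a per-site index in [0, 1] measuring how much of the offspring
    derives from the non-reference parent.  The default ``allele_fraction``
    mode uses the offspring's read fraction of the other parent's allele,
    which resolves allelic dosage (an AAB region averages 1/3, an AAAB
    region 1/4, ...).  The literal ``genotype_match`` mode assigns 0 when
    the offspring genotype equals the reference parent's and 1 otherwise;
    it distinguishes homozygous blocks but not mixed dosages.
    Sites with offspring read depth < 7 are excluded as unreliable;
4.  average site indexes in 2 Mb windows sliding by 10 kb to reduce noise;
5.  classify windows — mean ≤ 0.2 homozygous for the reference parent,
    ≥ 0.8 homozygous for the other parent, between them heterozygous —
    and merge consecutive same-class windows into origin segments;
6.  summarize each parent's genetic contribution as the mean index
    (other parent) and its complement (reference parent).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeLayout, VariantSite

log = logging.getLogger("plantkaryo")

INDEX_MODES = ("allele_fraction", "genotype_match")


@dataclass
class GenotypingConfig:
    min_qd: float = 2.0
    max_fs: float = 60.0
    min_depth: int = 7
    window_size: int = 2_000_000
    step: int = 10_000
    low_threshold: float = 0.2
    high_threshold: float = 0.8
    min_sites_per_window: int = 10
    index_mode: str = "allele_fraction"

    def __post_init__(self) -> None:
        if not (0.0 < self.low_threshold < self.high_threshold < 1.0):
            raise ValueError("need 0 < low_threshold < high_threshold < 1")
        if self.window_size < self.step:
            raise ValueError("window_size must be >= step")
        if self.index_mode not in INDEX_MODES:
            raise ValueError(f"index_mode must be one of {INDEX_MODES}")


@dataclass
class InformativeSite:
    """A homozygous-differential parental marker with offspring evidence.

    Offspring allele depths are re-expressed by parental role: whichever
    VCF allele the reference parent carries contributes to
    ``ref_parent_count`` and the other parent's allele to
    ``other_parent_count``, regardless of which one is REF.
    """

    chrom: str
    pos: int
    ref_parent_allele: str
    other_parent_allele: str
    ref_parent_count: int
    other_parent_count: int
    depth: int
    offspring_gt: Optional[tuple[int, int]]
    ref_parent_allele_index: int  # 0 if the reference parent carries REF


@dataclass
class OriginSegment:
    chrom: str
    start: int
    end: int
    origin: str  # homozygous_ref_parent | heterozygous | homozygous_other_parent
    mean_index: float
    n_windows: int


# ---------------------------------------------------------------------------
# Site selection
# ---------------------------------------------------------------------------

def filter_variants(sites: Iterable[VariantSite], config: Optional[GenotypingConfig] = None
                    ) -> list[VariantSite]:
    """Drop sites with QD < min_qd or FS > max_fs; absent annotations pass."""
    config = config or GenotypingConfig()
    kept = []
    n_missing = 0
    for s in sites:
        if s.qd is None and s.fs is None:
            n_missing += 1
        if s.qd is not None and s.qd < config.min_qd:
            continue
        if s.fs is not None and s.fs > config.max_fs:
            continue
        kept.append(s)
    if n_missing:
        log.info("quality filter: %d sites had no QD/FS annotations (kept)", n_missing)
    return kept


def _is_hom(gt: Optional[tuple[int, int]]) -> bool:
    return gt is not None and gt[0] == gt[1]


def select_informative_sites(sites: Iterable[VariantSite]) -> list[InformativeSite]:
    """Keep sites where both parents are homozygous for different alleles."""
    out = []
    for s in sites:
        p1, p2 = s.ref_parent.gt, s.other_parent.gt
        if not (_is_hom(p1) and _is_hom(p2)) or p1[0] == p2[0]:
            continue
        ref_idx = p1[0]
        alleles = (s.ref, s.alt)
        ad = s.offspring.ad or (0, 0)
        dp = s.offspring.dp if s.offspring.dp is not None else ad[0] + ad[1]
        out.append(InformativeSite(
            chrom=s.chrom,
            pos=s.pos,
            ref_parent_allele=alleles[ref_idx],
            other_parent_allele=alleles[1 - ref_idx],
            ref_parent_count=ad[ref_idx],
            other_parent_count=ad[1 - ref_idx],
            depth=int(dp),
            offspring_gt=s.offspring.gt,
            ref_parent_allele_index=ref_idx,
        ))
    return out


# ---------------------------------------------------------------------------
# Per-site index
# ---------------------------------------------------------------------------

def site_index(site: InformativeSite, config: Optional[GenotypingConfig] = None
               ) -> Optional[float]:
    """Index in [0,1]: 0 = reference parent, 1 = other parent; None = excluded.

    ``allele_fraction``: other-parent read count over informative read count.
    ``genotype_match``: 0 iff the offspring genotype is homozygous for the
    reference parent's allele, else 1.  Either way, sites with offspring
    depth below ``min_depth`` are excluded.
    """
    config = config or GenotypingConfig()
    if site.depth < config.min_depth:
        return None
    if config.index_mode == "allele_fraction":
        denom = site.ref_parent_count + site.other_parent_count
        if denom == 0:
            return None
        return site.other_parent_count / denom
    # genotype_match
    gt = site.offspring_gt
    if gt is None:
        return None
    ref_hom = (site.ref_parent_allele_index, site.ref_parent_allele_index)
    return 0.0 if tuple(gt) == ref_hom else 1.0


def site_index_table(sites: Sequence[InformativeSite],
                     config: Optional[GenotypingConfig] = None) -> pd.DataFrame:
    """Frame (chrom, pos, index) of retained sites; excluded sites never enter."""
    config = config or GenotypingConfig()
    rows = [(s.chrom, s.pos, idx) for s in sites
            if (idx := site_index(s, config)) is not None]
    return pd.DataFrame(rows, columns=["chrom", "pos", "index"])


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def sliding_window_index(
    site_table: pd.DataFrame,
    layout: GenomeLayout,
    config: Optional[GenotypingConfig] = None,
) -> pd.DataFrame:
    """Mean site index in windows [k·step, k·step + window) per chromosome.

    Windows start at 0 and advance by ``step`` while the start lies inside
    the chromosome; the last windows overhang the end (clipped for
    reporting).  Windows with fewer than ``min_sites_per_window`` sites get
    a NaN mean.  Columns: chrom, start, end, mid, mean_index, n_sites.
    """
    config = config or GenotypingConfig()
    frames = []
    for chrom, length in layout.chromosomes:
        sub = site_table[site_table["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        idx = sub["index"].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(idx)])
        starts = np.arange(0, length, config.step, dtype=np.int64)
        ends = starts + config.window_size
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        mean = np.where(n >= config.min_sites_per_window, mean, np.nan)
        clipped_end = np.minimum(ends, length)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": clipped_end,
            "mid": (starts + clipped_end) // 2,
            "mean_index": mean,
            "n_sites": n,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def _window_class(mean: float, config: GenotypingConfig) -> str:
    if mean <= config.low_threshold:
        return "homozygous_ref_parent"
    if mean >= config.high_threshold:
        return "homozygous_other_parent"
    return "heterozygous"


def classify_origin(windows: pd.DataFrame,
                    config: Optional[GenotypingConfig] = None) -> list[OriginSegment]:
    """Classify windows by the 0.2/0.8 thresholds and merge same-class runs.

    Threshold boundary values belong to the homozygous classes.  Windows
    without a mean (too few markers) do not break a run: marker deserts
    bridge rather than fragment origin blocks.
    """
    config = config or GenotypingConfig()
    segments: list[OriginSegment] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        cur_class = None
        cur_start = cur_end = 0
        cur_means: list[float] = []
        for row in sub.itertuples(index=False):
            if math.isnan(row.mean_index):
                continue
            cls = _window_class(row.mean_index, config)
            if cls == cur_class:
                cur_end = row.end
                cur_means.append(row.mean_index)
            else:
                if cur_class is not None:
                    segments.append(OriginSegment(chrom, cur_start, cur_end, cur_class,
                                                  float(np.mean(cur_means)), len(cur_means)))
                cur_class, cur_start, cur_end = cls, row.start, row.end
                cur_means = [row.mean_index]
        if cur_class is not None:
            segments.append(OriginSegment(chrom, cur_start, cur_end, cur_class,
                                          float(np.mean(cur_means)), len(cur_means)))
    return segments


def contribution_summary(
    site_table: pd.DataFrame,
    windows: pd.DataFrame,
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Per-chromosome and genome-wide parental contributions.

    ``other_parent_fraction`` is the mean site index (the windowed mean is
    reported alongside); the reference parent's fraction is its complement.
    The genome-wide row is labelled chrom='genome'.
    """
    rows = []

    def _row(label, s_idx, w_idx):
        s_mean = float(np.mean(s_idx)) if len(s_idx) else np.nan
        w = w_idx[~np.isnan(w_idx)]
        w_mean = float(np.mean(w)) if len(w) else np.nan
        rows.append((label, len(s_idx), s_mean, w_mean, s_mean,
                     1.0 - s_mean if not math.isnan(s_mean) else np.nan))

    for chrom, _ in layout.chromosomes:
        _row(chrom,
             site_table.loc[site_table["chrom"] == chrom, "index"].to_numpy(),
             windows.loc[windows["chrom"] == chrom, "mean_index"].to_numpy())
    _row("genome", site_table["index"].to_numpy(), windows["mean_index"].to_numpy())
    return pd.DataFrame(rows, columns=[
        "chrom", "n_sites", "mean_site_index", "mean_window_index",
        "other_parent_fraction", "ref_parent_fraction",
    ])


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

@dataclass
class GenotypingResult:
    sites: pd.DataFrame            # chrom, pos, index
    windows: pd.DataFrame          # chrom, start, end, mid, mean_index, n_sites
    segments: list[OriginSegment]
    contributions: pd.DataFrame


def genotype_origin(
    variant_sites: Iterable[VariantSite],
    layout: GenomeLayout,
    config: Optional[GenotypingConfig] = None,
) -> GenotypingResult:
    """Run the full origin-genotyping pipeline on raw variant sites."""
    config = config or GenotypingConfig()
    filtered = filter_variants(variant_sites, config)
    informative = select_informative_sites(filtered)
    log.info("origin genotyping: %d informative sites after filters", len(informative))
    table = site_index_table(informative, config)
    windows = sliding_window_index(table, layout, config)
    segments = classify_origin(windows, config)
    contributions = contribution_summary(table, windows, layout)
    return GenotypingResult(table, windows, segments, contributions)


def write_genotyping_report(result: GenotypingResult, outdir) -> None:
    """Write site-index, window, origin-segment and contribution TSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = result.sites.copy()
    sites["pos"] = sites["pos"] + 1  # 1-based in the per-site report
    sites.to_csv(outdir / "site_index.tsv", sep="\t", index=False)
    result.windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.origin, round(s.mean_index, 6), s.n_windows)
         for s in result.segments],
        columns=["chrom", "start", "end", "origin", "mean_index", "n_windows"],
    ).to_csv(outdir / "origin_segments.tsv", sep="\t", index=False)
    result.contributions.to_csv(outdir / "contributions.tsv", sep="\t", index=False)
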