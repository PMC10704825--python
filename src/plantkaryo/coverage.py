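"""Integer copy-number calling from GC-normalized binned read depth.

The model is the Ratio × expected-ploidy convention used for molecular
karyotyping of aneuploid and polyploid plants from low-coverage (down to
~0.4×) whole-genome resequencing:

1.  raw per-bin counts are normalized against a degree-3 polynomial fit of
    count on GC over reliable bins (GC within the ExpectedGC interval,
    e.g. 0.30–0.50 for rapeseed, 0.25–0.45 for potato);
2.  each bin's *Ratio* is its normalized count divided by the median
    normalized count of its chromosome group — the subgenome, when an
    allopolyploid's subgenomes are analyzed separately with different
    expected ploidies;
3.  the per-chromosome ratio sequence is segmented by recursive binary
    segmentation with a BIC-style penalty;
4.  each segment's copy number is round(mean_ratio × ploidy), and the
    chromosome-level copy number is the length-weighted plurality of its
    segments, so whole-chromosome aneuploidy and partial losses or
    duplications (e.g. homoeologous exchanges) are both visible.

A ploidy scan is provided for material of uncertain ploidy: candidate
ploidies are ranked by how close ratio × ploidy lands to integers across
the genome, and the smallest equally-good candidate wins (integer multiples
of a fitting ploidy fit equally well).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BinTrack, GenomeLayout

log = logging.getLogger("plantkaryo")

_EPS = 1e-3


@dataclass
class KaryotypeConfig:
    """Tunables of the copy-number pipeline.

    bin_size : bp; 100 kb gives roughly 600+ reads per bin at 1× with short
        reads, enough for stable ratios at the depths this method targets.
    ploidy_by_subgenome : expected baseline copy number per subgenome label;
        use {"": p} for a genome without subgenome labels.
    expected_gc : GC interval of bins trusted for normalization.
    min_segment_bins : smallest segment the segmentation may produce.
    segmentation_penalty_scale : multiplier on the BIC-style split penalty.
    candidate_ploidies : optional set scanned when ploidy is in doubt.
    """

    bin_size: int = 100_000
    ploidy_by_subgenome: Mapping[str, int] = field(default_factory=lambda: {"": 2})
    expected_gc: tuple[float, float] = (0.30, 0.50)
    min_segment_bins: int = 10
    segmentation_penalty_scale: float = 3.0
    candidate_ploidies: Optional[tuple[int, ...]] = None
    min_eligible_bins: int = 50

    def __post_init__(self) -> None:
        low, high = self.expected_gc
        if not (0.0 <= low < high <= 1.0):
            raise ValueError(f"expected_gc {self.expected_gc} must satisfy 0 <= low < high <= 1")
        for label, p in self.ploidy_by_subgenome.items():
            if p < 1:
                raise ValueError(f"ploidy for subgenome {label!r} must be >= 1, got {p}")

    def ploidy_for(self, label: str) -> int:
        if label in self.ploidy_by_subgenome:
            return int(self.ploidy_by_subgenome[label])
        if len(self.ploidy_by_subgenome) == 1:
            return int(next(iter(self.ploidy_by_subgenome.values())))
        raise KeyError(f"no ploidy configured for subgenome {label!r}")


@dataclass
class CopySegment:
    chrom: str
    start: int
    end: int
    mean_ratio: float
    copy_number: Optional[int]
    n_bins: int
    low_confidence: bool = False


@dataclass
class ChromosomeKaryotype:
    chrom: str
    subgenome: str
    ploidy: int
    copy_number: int
    supporting_fraction: float
    segments: list[CopySegment]


@dataclass
class KaryotypeResult:
    chromosomes: list[ChromosomeKaryotype]
    total_chromosomes: int
    track: BinTrack
    ploidy_scan: Optional[dict] = None


# ---------------------------------------------------------------------------
# GC normalization
# ---------------------------------------------------------------------------

def normalize_gc(
    track: BinTrack,
    expected_gc: tuple[float, float] = (0.30, 0.50),
    min_eligible_bins: int = 50,
) -> BinTrack:
    """Fill ``normalized`` by removing the GC trend from raw counts.

    A degree-3 polynomial of count on GC is fit over eligible bins
    (unmasked, count > 0, GC inside ``expected_gc``); each eligible bin is
    rescaled by median(eligible counts) / fit(gc).  Bins outside the GC
    interval, already masked, with zero coverage or with a non-positive
    fitted value are flagged masked and excluded from everything downstream.
    """
    out = track.copy()
    df = out.bins
    low, high = expected_gc
    gc = df["gc"].to_numpy(dtype=float)
    count = df["count"].to_numpy(dtype=float)
    in_range = (gc >= low) & (gc <= high) & ~np.isnan(gc)
    eligible = in_range & ~df["masked"].to_numpy() & (count > 0)
    n_eligible = int(eligible.sum())
    if n_eligible < min_eligible_bins:
        raise ValueError(
            f"only {n_eligible} bins eligible for GC normalization "
            f"(need >= {min_eligible_bins}); use a larger bin size"
        )
    x = gc[eligible]
    y = count[eligible]
    med = float(np.median(y))
    if np.ptp(x) < 1e-6:
        fit_at = lambda g: np.full_like(g, float(np.mean(y)), dtype=float)
    else:
        coeffs = np.polyfit(x, y, deg=3)
        fit_at = lambda g: np.polyval(coeffs, g)

    eps = _EPS * max(med, 1.0)
    fitted = np.where(np.isnan(gc), np.nan, fit_at(np.nan_to_num(gc, nan=0.0)))
    normalized = count * med / np.maximum(fitted, eps)
    bad_fit = ~np.isnan(gc) & (fitted <= eps)
    masked = df["masked"].to_numpy() | ~in_range | (count <= 0) | bad_fit
    normalized[masked] = np.nan
    df["normalized"] = normalized
    df["masked"] = masked
    return out


# ---------------------------------------------------------------------------
# Ratio
# ---------------------------------------------------------------------------

def compute_ratio(track: BinTrack, group: Iterable[str]) -> BinTrack:
    """Fill ``ratio`` = normalized / median(normalized) within a chromosome group.

    The median baseline is computed over the unmasked bins of ``group`` only,
    so subgenomes analyzed separately each anchor their own baseline at 1.
    """
    group = list(group)
    if not group:
        raise ValueError("empty chromosome group")
    out = track.copy()
    df = out.bins
    in_group = df["chrom"].isin(group).to_numpy()
    usable = in_group & ~df["masked"].to_numpy() & ~df["normalized"].isna().to_numpy()
    if not usable.any():
        raise ValueError(f"no usable bins in group {group}")
    baseline = float(np.median(df.loc[usable, "normalized"]))
    if baseline <= 0:
        raise ValueError(f"median normalized count is {baseline}; no coverage in group {group}")
    ratio = df["normalized"].to_numpy() / baseline
    df.loc[in_group, "ratio"] = ratio[in_group]
    return out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

class _SsePrefix:
    """Prefix sums giving O(1) within-segment SSE and vectorized split search."""

    def __init__(self, x: np.ndarray):
        self.s1 = np.concatenate([[0.0], np.cumsum(x)])
        self.s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(self, i: int, j: int) -> float:
        n = j - i
        if n <= 0:
            return 0.0
        s = self.s1[j] - self.s1[i]
        return float(self.s2[j] - self.s2[i] - s * s / n)

    def best_split(self, i: int, j: int, min_bins: int):
        """Best single split of x[i:j] into x[i:k], x[k:j]: (k, SSE reduction)."""
        ks = np.arange(i + min_bins, j - min_bins + 1)
        if len(ks) == 0:
            return -1, -np.inf
        nl = ks - i
        nr = j - ks
        sl = self.s1[ks] - self.s1[i]
        sr = self.s1[j] - self.s1[ks]
        total = self.sse(i, j)
        sse_l = self.s2[ks] - self.s2[i] - sl * sl / nl
        sse_r = self.s2[j] - self.s2[ks] - sr * sr / nr
        red = total - sse_l - sse_r
        best = int(np.argmax(red))
        return int(ks[best]), float(red[best])


def segment_ratio(track: BinTrack, chrom: str, config: KaryotypeConfig) -> list[CopySegment]:
    """Recursive binary segmentation of a chromosome's unmasked ratio sequence.

    At each step the split maximizing the reduction in within-segment sum of
    squared deviations is accepted iff the reduction exceeds
    ``penalty_scale × σ̂² × log(n)``, where σ̂ is a MAD estimate of the
    bin-to-bin noise from first differences and n the chromosome's unmasked
    bin count.  Children smaller than ``min_segment_bins`` are never created.
    Boundaries snap to bin edges; masked bins appear as gaps at chromosome
    ends and are absorbed into the flanking segment in the interior.
    """
    sub = track.for_chrom(chrom)
    unmasked = sub[~sub["masked"] & ~sub["ratio"].isna()]
    r = unmasked["ratio"].to_numpy(dtype=float)
    n = len(r)
    starts = unmasked["start"].to_numpy()
    ends = unmasked["end"].to_numpy()

    if n == 0:
        return []
    if n < config.min_segment_bins:
        return [CopySegment(chrom, int(starts[0]), int(ends[-1]),
                            float(np.mean(r)), None, n, low_confidence=True)]

    diffs = np.abs(np.diff(r))
    sigma = 1.4826 * float(np.median(diffs)) / math.sqrt(2.0)
    lam = config.segmentation_penalty_scale * sigma * sigma * math.log(n)
    prefix = _SsePrefix(r)

    breakpoints: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * config.min_segment_bins:
            continue
        k, red = prefix.best_split(i, j, config.min_segment_bins)
        if k >= 0 and red > lam:
            breakpoints.append(k)
            stack.append((i, k))
            stack.append((k, j))
    bounds = [0] + sorted(breakpoints) + [n]

    segments = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        # genomic span: from this run's first bin start to the next segment's
        # first bin start (interior masked bins ride with the left segment)
        g_start = int(starts[i])
        g_end = int(starts[j]) if j < n else int(ends[n - 1])
        segments.append(CopySegment(chrom, g_start, g_end,
                                    float(np.mean(r[i:j])), None, j - i))
    return segments


def call_copy_numbers(segments: Sequence[CopySegment], ploidy: int) -> list[CopySegment]:
    """Set copy_number = max(0, round(mean_ratio × ploidy)), half away from zero."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    out = []
    for seg in segments:
        cn = max(0, int(math.floor(seg.mean_ratio * ploidy + 0.5)))
        out.append(CopySegment(seg.chrom, seg.start, seg.end, seg.mean_ratio,
                               cn, seg.n_bins, seg.low_confidence))
    return out


def chromosome_call(
    segments: Sequence[CopySegment],
    chrom: str,
    subgenome: str,
    ploidy: int,
) -> ChromosomeKaryotype:
    """Chromosome-level copy number: length-weighted plurality of segments.

    Ties are broken toward the copy number closest to the expected ploidy
    (then toward the smaller value), biasing ambiguous chromosomes toward
    euploidy.  The supporting fraction is the share of assayable length at
    the winning copy number; partial events remain visible as segments.
    """
    segs = [s for s in segments if s.copy_number is not None]
    if not segs:
        return ChromosomeKaryotype(chrom, subgenome, ploidy, 0, 0.0, list(segments))
    weights: dict[int, float] = {}
    for s in segs:
        weights[s.copy_number] = weights.get(s.copy_number, 0.0) + (s.end - s.start)
    total = sum(weights.values())
    best = sorted(weights, key=lambda cn: (-weights[cn], abs(cn - ploidy), cn))[0]
    return ChromosomeKaryotype(chrom, subgenome, ploidy, best,
                               weights[best] / total, list(segments))


# ---------------------------------------------------------------------------
# Ploidy scan
# ---------------------------------------------------------------------------

def scan_ploidy(
    track: BinTrack,
    group: Iterable[str],
    candidate_ploidies: Sequence[int],
) -> tuple[int, dict[int, float]]:
    """Pick the candidate ploidy whose ratios land closest to integers.

    fitness(p) = mean |ratio × p − round(ratio × p)| over unmasked bins of
    the group; the smallest candidate within 1e-3 of the minimum wins, since
    any integer multiple of a fitting ploidy fits equally well.
    """
    candidates = sorted(set(int(p) for p in candidate_ploidies))
    if not candidates:
        raise ValueError("candidate_ploidies must not be empty")
    group = list(group)
    df = track.bins
    usable = df["chrom"].isin(group) & ~df["masked"] & ~df["ratio"].isna()
    r = df.loc[usable, "ratio"].to_numpy(dtype=float)
    if len(r) == 0:
        raise ValueError("no ratio values available; run the ratio step first")
    fitness = {}
    for p in candidates:
        scaled = r * p
        fitness[p] = float(np.mean(np.abs(scaled - np.round(scaled))))
    best_val = min(fitness.values())
    selected = min(p for p in candidates if fitness[p] <= best_val + 1e-3)
    return selected, fitness


# ---------------------------------------------------------------------------
# End-to-end karyotype
# ---------------------------------------------------------------------------

def karyotype(
    track: BinTrack,
    layout: GenomeLayout,
    config: Optional[KaryotypeConfig] = None,
) -> KaryotypeResult:
    """Run normalize → per-subgenome ratio → segmentation → integer calls.

    When the layout labels subgenomes, each subgenome forms its own ratio
    baseline and uses its own expected ploidy, so e.g. an allotriploid with
    AAC constitution is analyzed as A at ploidy 2 and C at ploidy 1.  The
    total chromosome count is the sum of chromosome-level copy numbers.
    """
    config = config or KaryotypeConfig()
    track = normalize_gc(track, config.expected_gc, config.min_eligible_bins)

    scan_info = None
    chrom_calls: list[ChromosomeKaryotype] = []
    for label, chroms in layout.groups().items():
        track = compute_ratio(track, chroms)
        if config.candidate_ploidies:
            ploidy, fitness = scan_ploidy(track, chroms, config.candidate_ploidies)
            scan_info = (scan_info or {})
            scan_info[label] = {"selected": ploidy, "fitness": fitness}
            log.info("subgenome %r: ploidy scan selected %d (fitness %s)",
                     label, ploidy, {p: round(f, 4) for p, f in fitness.items()})
        else:
            ploidy = config.ploidy_for(label)
        for chrom in chroms:
            segs = segment_ratio(track, chrom, config)
            segs = call_copy_numbers(segs, ploidy)
            chrom_calls.append(chromosome_call(segs, chrom, label, ploidy))

    order = {c: i for i, c in enumerate(layout.names)}
    chrom_calls.sort(key=lambda k: order[k.chrom])
    total = int(sum(k.copy_number for k in chrom_calls))
    log.info("total chromosomes = %d", total)
    return KaryotypeResult(chrom_calls, total, track, scan_info)


def scatter_table(result: KaryotypeResult, layout: GenomeLayout,
                  config: Optional[KaryotypeConfig] = None) -> pd.DataFrame:
    """Per-bin plot table (chrom, start, ratio, ratio_x_ploidy) matching the
    Ratio × expected-ploidy axis of karyotype scatter plots."""
    config = config or KaryotypeConfig()
    ploidy_of_chrom = {k.chrom: k.ploidy for k in result.chromosomes}
    df = result.track.bins
    keep = ~df["masked"] & ~df["ratio"].isna()
    out = df.loc[keep, ["chrom", "start", "ratio"]].copy()
    out["ratio_x_ploidy"] = [
        r * ploidy_of_chrom.get(c, config.ploidy_for(layout.subgenome(c)))
        for c, r in zip(out["chrom"], out["ratio"])
    ]
    return out.reset_index(drop=True)
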