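"""Readers and writers for every external representation the pipeline touches.

Formats handled here:

* chrLen files — 2–3 column whitespace-delimited text: chromosome name,
  length in bp, optional subgenome label.  Only chromosomes listed in this
  file are analyzed, which is how subgenomes with different ploidies are
  processed separately.
* per-bin count tables — this package's own TSV dialect with header
  ``chrom  start  end  count  gc`` (0-based half-open bins).
* BAM alignments (coordinate-sorted + indexed) for counting reads into bins.
* FASTA (+ .fai) for per-bin GC content.
* VCF v4.x for parent/offspring genotypes, and an equivalent flat site-table
  TSV emitted by the simulator.
* karyotype report TSVs plus a JSON summary.

Coordinate convention: everything in memory is 0-based half-open.  VCF and
site-table positions are converted from 1-based on read and back on write.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("plantkaryo")

COUNT_TABLE_COLUMNS = ["chrom", "start", "end", "count", "gc"]
SITE_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "ref_parent_gt", "other_parent_gt", "offspring_gt",
    "offspring_ad", "offspring_dp", "qd", "fs",
]


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths, with optional subgenome labels.

    This is the coordinate frame for everything downstream: bins, segments
    and windows all refer to chromosomes declared here, and rows for other
    sequences are dropped on read.
    """

    chromosomes: tuple[tuple[str, int], ...]
    subgenome_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dup}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        for name in self.subgenome_of:
            if name not in names:
                raise ValueError(f"subgenome label for unknown chromosome {name!r}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def subgenome(self, chrom: str) -> str:
        """Subgenome label of ``chrom``; '' when no labels were given."""
        return self.subgenome_of.get(chrom, "")

    def groups(self) -> dict[str, list[str]]:
        """Chromosomes grouped by subgenome label, in layout order."""
        out: dict[str, list[str]] = {}
        for name, _ in self.chromosomes:
            out.setdefault(self.subgenome(name), []).append(name)
        return out


def read_chrlen(path: str | os.PathLike) -> GenomeLayout:
    """Parse a chrLen file (name, length[, subgenome]) into a GenomeLayout.

    Lines starting with '#' are ignored.  Malformed lines raise a
    ``ValueError`` naming the line number.
    """
    chroms: list[tuple[str, int]] = []
    sub: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected at least 2 columns, got {len(parts)}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: length {parts[1]!r} is not an integer") from exc
            chroms.append((name, length))
            if len(parts) >= 3:
                sub[name] = parts[2]
    return GenomeLayout(tuple(chroms), sub)


def write_chrlen(layout: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            label = layout.subgenome_of.get(name)
            if label:
                fh.write(f"{name}\t{length}\t{label}\n")
            else:
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Binned coverage track
# ---------------------------------------------------------------------------

@dataclass
class BinTrack:
    """Fixed-width genome bins with raw counts, GC and derived columns.

    ``bins`` columns: chrom, start, end, count, gc, masked, normalized,
    ratio.  ``normalized`` is filled by GC normalization and ``ratio`` by
    the per-group ratio step; both are NaN until then and stay NaN for
    masked bins.
    """

    bins: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "count", "gc")

    def __post_init__(self) -> None:
        df = self.bins
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"BinTrack missing column {col!r}")
        if "masked" not in df.columns:
            df["masked"] = False
        if "normalized" not in df.columns:
            df["normalized"] = np.nan
        if "ratio" not in df.columns:
            df["ratio"] = np.nan
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted bin")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: bins overlap or are out of order")
        gc = df["gc"].to_numpy(dtype=float)
        ok = np.isnan(gc) | ((gc >= 0.0) & (gc <= 1.0))
        if not ok.all():
            bad = df.loc[~ok].iloc[0]
            raise ValueError(f"gc outside [0,1] at {bad['chrom']}:{bad['start']} (gc={bad['gc']})")

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.bins[self.bins["chrom"] == chrom]

    def copy(self) -> "BinTrack":
        return BinTrack(self.bins.copy())

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))


def bins_from_layout(layout: GenomeLayout, bin_size: int) -> pd.DataFrame:
    """Tile each chromosome with ``bin_size`` bins; last bin may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for name, length in layout.chromosomes:
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def read_count_table(path: str | os.PathLike, layout: GenomeLayout) -> BinTrack:
    """Read the count-table TSV dialect into a BinTrack.

    Rows whose chromosome is not in ``layout`` are dropped with a logged
    warning; overlapping bins or gc outside [0,1] raise.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: count table missing columns {missing}")
    known = df["chrom"].isin(layout.names)
    n_dropped = int((~known).sum())
    if n_dropped:
        dropped = sorted(df.loc[~known, "chrom"].unique())
        log.warning("%s: dropped %d bins on chromosomes not in layout: %s", path, n_dropped, dropped)
        df = df[known].reset_index(drop=True)
    df = df.astype({"start": np.int64, "end": np.int64, "count": np.int64, "gc": float})
    return BinTrack(df)


def write_count_table(track: BinTrack, path: str | os.PathLike) -> None:
    track.bins[list(COUNT_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def count_reads_from_bam(
    bam: str | os.PathLike,
    layout: GenomeLayout,
    bin_size: int = 100_000,
    min_mapq: int = 1,
) -> BinTrack:
    """Count primary, non-duplicate alignments into fixed bins.

    Each retained alignment is assigned to exactly one bin by its leftmost
    aligned position (0-based).  GC is left NaN; fill it with
    :func:`gc_from_fasta`.  The BAM filters (no secondary/supplementary, no
    duplicates, MAPQ >= ``min_mapq``) mirror common depth-based CNV practice
    and are exposed as parameters.
    """
    import pysam

    bins = bins_from_layout(layout, bin_size)
    bins["count"] = 0
    bins["gc"] = np.nan
    offsets = {}
    pos = 0
    for name, length in layout.chromosomes:
        offsets[name] = pos
        pos += int(np.ceil(length / bin_size))
    counts = np.zeros(len(bins), dtype=np.int64)
    with pysam.AlignmentFile(str(bam), "rb") as fh:
        if not fh.has_index():
            raise ValueError(f"{bam}: missing BAM index")
        for name, length in layout.chromosomes:
            if name not in fh.references:
                continue
            for aln in fh.fetch(name):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                    continue
                if aln.mapping_quality < min_mapq:
                    continue
                b = aln.reference_start // bin_size
                if aln.reference_start < length:
                    counts[offsets[name] + b] += 1
    bins["count"] = counts
    return BinTrack(bins)


def gc_from_fasta(
    fasta: str | os.PathLike,
    layout: GenomeLayout,
    bin_size: int = 100_000,
    max_ambiguous_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-bin GC fraction (G+C)/(A+C+G+T), case-insensitive.

    Returns a frame with chrom, start, end, gc, masked; bins with more than
    ``max_ambiguous_frac`` ambiguous bases are flagged masked (gc NaN).
    """
    from pyfaidx import Fasta

    bins = bins_from_layout(layout, bin_size)
    gc_vals = np.full(len(bins), np.nan)
    masked = np.zeros(len(bins), dtype=bool)
    fa = Fasta(str(fasta))
    try:
        i = 0
        for name, length in layout.chromosomes:
            if name not in fa:
                raise ValueError(f"{fasta}: sequence {name!r} not found")
            seq = str(fa[name][:]).upper()
            n_bins = int(np.ceil(length / bin_size))
            for b in range(n_bins):
                chunk = seq[b * bin_size:(b + 1) * bin_size]
                at = chunk.count("A") + chunk.count("T")
                gcn = chunk.count("G") + chunk.count("C")
                total = at + gcn
                if len(chunk) == 0 or total < (1.0 - max_ambiguous_frac) * len(chunk):
                    masked[i] = True
                else:
                    gc_vals[i] = gcn / total
                i += 1
    finally:
        fa.close()
    bins["gc"] = gc_vals
    bins["masked"] = masked
    return bins


# ---------------------------------------------------------------------------
# Variant sites
# ---------------------------------------------------------------------------

@dataclass
class SampleCall:
    """Per-sample fields of one VCF record: GT, AD and DP, any may be absent."""

    gt: Optional[tuple[int, int]]
    ad: Optional[tuple[int, int]]
    dp: Optional[int]


@dataclass
class VariantSite:
    """One biallelic site with the three samples mapped to pedigree roles.

    ``pos`` is 0-based.  ``qd``/``fs`` are INFO annotations; ``None`` means
    the annotation was absent from the record (treated as passing by the
    downstream filter, with a logged count).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qd: Optional[float]
    fs: Optional[float]
    ref_parent: SampleCall
    other_parent: SampleCall
    offspring: SampleCall


@dataclass
class VcfReadResult:
    sites: list[VariantSite]
    n_multiallelic_skipped: int = 0
    n_missing_qc: int = 0


def _parse_gt_tuple(gt) -> Optional[tuple[int, int]]:
    if gt is None:
        return None
    alleles = tuple(a for a in gt if a is not None)
    if len(alleles) != 2:
        return None
    return (int(alleles[0]), int(alleles[1]))


def read_parent_offspring_vcf(
    vcf: str | os.PathLike,
    ref_parent: str,
    other_parent: str,
    offspring: str,
) -> VcfReadResult:
    """Read a multi-sample VCF, mapping the three samples to pedigree roles.

    Only biallelic records are retained (multi-allelic ones are counted and
    skipped).  No quality filtering happens here — records with failing
    QD/FS are passed through so the genotyping module owns the filter.
    """
    import pysam

    with pysam.VariantFile(str(vcf)) as fh:
        available = list(fh.header.samples)
        for sample in (ref_parent, other_parent, offspring):
            if sample not in available:
                raise ValueError(
                    f"sample {sample!r} not in {vcf}; available samples: {available}"
                )
        result = VcfReadResult(sites=[])
        for rec in fh:
            if rec.alts is None or len(rec.alts) != 1:
                result.n_multiallelic_skipped += 1
                continue
            qd = rec.info.get("QD")
            fs = rec.info.get("FS")
            if qd is None or fs is None:
                result.n_missing_qc += 1
            calls = {}
            for sample in (ref_parent, other_parent, offspring):
                s = rec.samples[sample]
                ad = s.get("AD")
                if ad is not None and len(ad) >= 2 and ad[0] is not None:
                    ad = (int(ad[0]), int(ad[1]))
                else:
                    ad = None
                dp = s.get("DP")
                calls[sample] = SampleCall(
                    gt=_parse_gt_tuple(s.get("GT")),
                    ad=ad,
                    dp=int(dp) if dp is not None else None,
                )
            result.sites.append(VariantSite(
                chrom=rec.chrom,
                pos=rec.pos - 1,
                ref=rec.ref,
                alt=rec.alts[0],
                qd=float(qd) if qd is not None else None,
                fs=float(fs) if fs is not None else None,
                ref_parent=calls[ref_parent],
                other_parent=calls[other_parent],
                offspring=calls[offspring],
            ))
    if result.n_multiallelic_skipped:
        log.info("%s: skipped %d multi-allelic records", vcf, result.n_multiallelic_skipped)
    return result


def _fmt_gt(gt: Optional[tuple[int, int]]) -> str:
    return "./." if gt is None else f"{gt[0]}/{gt[1]}"


def _parse_gt_str(s: str) -> Optional[tuple[int, int]]:
    s = s.replace("|", "/")
    if "." in s:
        return None
    a, b = s.split("/")
    return (int(a), int(b))


def write_site_table(sites: Sequence[VariantSite], path: str | os.PathLike) -> None:
    """Write sites to the flat TSV dialect (pos 1-based in the file)."""
    rows = []
    for s in sites:
        ad = s.offspring.ad or (0, 0)
        rows.append((
            s.chrom, s.pos + 1, s.ref, s.alt,
            _fmt_gt(s.ref_parent.gt), _fmt_gt(s.other_parent.gt), _fmt_gt(s.offspring.gt),
            f"{ad[0]},{ad[1]}",
            s.offspring.dp if s.offspring.dp is not None else ".",
            s.qd if s.qd is not None else ".",
            s.fs if s.fs is not None else ".",
        ))
    pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | os.PathLike) -> list[VariantSite]:
    """Read the flat site-table TSV back into VariantSite objects."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: site table missing columns {missing}")
    sites = []
    for row in df.itertuples(index=False):
        ad_str = row.offspring_ad
        ad = None
        if isinstance(ad_str, str) and "," in ad_str:
            a, b = ad_str.split(",")
            ad = (int(a), int(b))
        dp = None if row.offspring_dp in (".", None) else int(float(row.offspring_dp))
        qd = None if row.qd in (".", None) else float(row.qd)
        fs = None if row.fs in (".", None) else float(row.fs)
        sites.append(VariantSite(
            chrom=str(row.chrom),
            pos=int(row.pos) - 1,
            ref=row.ref,
            alt=row.alt,
            qd=qd,
            fs=fs,
            ref_parent=SampleCall(gt=_parse_gt_str(row.ref_parent_gt), ad=None, dp=None),
            other_parent=SampleCall(gt=_parse_gt_str(row.other_parent_gt), ad=None, dp=None),
            offspring=SampleCall(gt=_parse_gt_str(row.offspring_gt), ad=ad, dp=dp),
        ))
    return sites


def write_vcf(
    sites: Sequence[VariantSite],
    layout: GenomeLayout,
    path: str | os.PathLike,
    ref_parent: str = "P1",
    other_parent: str = "P2",
    offspring: str = "F1",
) -> None:
    """Write sites as a minimal uncompressed VCF v4.2 with GT:AD:DP fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in layout.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{ref_parent}\t{other_parent}\t{offspring}\n")
        for s in sites:
            info_parts = []
            if s.qd is not None:
                info_parts.append(f"QD={s.qd:g}")
            if s.fs is not None:
                info_parts.append(f"FS={s.fs:g}")
            info = ";".join(info_parts) or "."
            cols = []
            for call in (s.ref_parent, s.other_parent, s.offspring):
                ad = f"{call.ad[0]},{call.ad[1]}" if call.ad is not None else "."
                dp = str(call.dp) if call.dp is not None else "."
                cols.append(f"{_fmt_gt(call.gt)}:{ad}:{dp}")
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\t.\t{info}\tGT:AD:DP\t"
                     + "\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Karyotype reports
# ---------------------------------------------------------------------------

def write_karyotype_report(karyotypes, outdir: str | os.PathLike) -> dict:
    """Write segment and chromosome TSVs plus a JSON summary.

    ``karyotypes`` is a sequence of ChromosomeKaryotype (see coverage module).
    Returns the summary dict (also written to ``summary.json``): the total
    chromosome count is the sum of per-chromosome copy numbers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seg_rows = []
    chrom_rows = []
    for k in karyotypes:
        for seg in k.segments:
            seg_rows.append((seg.chrom, seg.start, seg.end,
                             round(seg.mean_ratio, 6), seg.copy_number))
        chrom_rows.append((k.chrom, k.subgenome, k.ploidy, k.copy_number,
                           round(k.supporting_fraction, 6)))
    pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "mean_ratio", "copy_number"]
    ).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(
        chrom_rows,
        columns=["chrom", "subgenome", "ploidy", "copy_number", "fraction_at_cn"],
    ).to_csv(outdir / "chromosomes.tsv", sep="\t", index=False)

    summary = {
        "total_chromosomes": int(sum(k.copy_number for k in karyotypes)),
        "n_chromosome_types": len(list(karyotypes)),
        "copy_number_by_chromosome": {k.chrom: int(k.copy_number) for k in karyotypes},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
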