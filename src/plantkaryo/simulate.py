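"""Synthetic binned-coverage and hybrid-genotype data with known truth.

Two generators provide a no-download test surface for the whole pipeline:

* :func:`simulate_coverage` draws per-bin read counts from a negative
  binomial whose mean is proportional to the local absolute copy number,
  modulated by a smooth quadratic GC bias.  Overdispersion (default 0.05)
  emulates real low-coverage resequencing libraries, for which a Poisson is
  too well-behaved; Poisson is available as the dispersion→0 limit.

* :func:`simulate_cross` places homozygous-differential parental markers
  uniformly along the genome and samples offspring reads binomially from a
  per-segment allelic dosage d/t (d copies from the non-reference parent
  out of t total), with Poisson site depth, so windowed index means have
  known expectations d/t.

Preset scenarios replicate published karyotypes: a near-tetraploid rapeseed
with compensating homoeologous exchanges (38 chromosomes), a monosomic
alien addition line, an allotriploid (2n = 29) with per-subgenome ploidies,
an autotetraploid, a hexaploid somatic hybrid (72 chromosomes, 2:1 genome
ratio) and a tetraploid potato aneuploid.  The emitted truth tables are
never read by the pipeline; they exist only for recovery checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coverage import KaryotypeConfig
from .genotyping import GenotypingConfig
from .io_formats import BinTrack, GenomeLayout, SampleCall, VariantSite, bins_from_layout

log = logging.getLogger("plantkaryo")

_BASES = np.array(list("ACGT"))


@dataclass
class CoverageSimConfig:
    """Binned-coverage generator settings.

    reads_per_copy : mean reads per 100 kb bin per chromosome copy at unit
        GC bias — 30 by default, i.e. ~60 reads/bin for a diploid baseline,
        the ~1× regime; scale down for the 0.4× regime.
    truth : (chrom, start, end, copy_number) tiling each chromosome.
    dispersion : negative-binomial overdispersion a in var = m + a·m²;
        0 selects the Poisson limit.
    gc_range : per-bin GC fractions are drawn uniformly from this interval.
    gc_bias_center/curvature : bias g(gc) = 1 − curvature·(gc − center)²,
        clipped at 0.1; the default curvature modulates counts by roughly
        ±20% across a 0.2-wide GC interval.
    """

    layout: GenomeLayout
    truth: list[tuple[str, int, int, int]]
    ploidy_by_subgenome: dict[str, int] = field(default_factory=lambda: {"": 2})
    reads_per_copy: float = 30.0
    dispersion: float = 0.05
    bin_size: int = 100_000
    gc_range: tuple[float, float] = (0.28, 0.52)
    gc_bias_center: Optional[float] = None
    gc_bias_curvature: float = 12.5
    seed: int = 0


@dataclass
class CrossSimConfig:
    """Hybrid-genotype generator settings.

    origin_truth : (chrom, start, end, other_parent_dosage, total_dosage)
        tiling each chromosome; the offspring carries d of t chromatids
        from the non-reference parent there.
    sites_per_mb : homozygous-differential marker density (20/Mb default,
        a conservative density for divergent parents).
    mean_depth : Poisson mean of per-site offspring depth (10, the upper
        recommended regime for genotyping).
    genotype_error_rate : probability that an offspring GT field is
        replaced by a random different genotype.
    fail_qc_fraction : fraction of sites emitted with failing QD or FS so
        quality filtering has tagged targets.
    """

    layout: GenomeLayout
    origin_truth: list[tuple[str, int, int, int, int]]
    sites_per_mb: float = 20.0
    mean_depth: float = 10.0
    genotype_error_rate: float = 0.0
    fail_qc_fraction: float = 0.0
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data; never read by the pipeline."""

    cn_segments: Optional[pd.DataFrame] = None      # chrom start end copy_number
    bin_cn: Optional[pd.DataFrame] = None           # chrom start end copy_number
    origin_segments: Optional[pd.DataFrame] = None  # chrom start end dosage total
    site_truth: Optional[pd.DataFrame] = None       # chrom pos dosage total fails_qc


def _segment_lookup(truth, chrom, pos):
    for c, s, e, *rest in truth:
        if c == chrom and s <= pos < e:
            return rest
    raise ValueError(f"truth segments do not cover {chrom}:{pos}")


def _check_tiling(layout: GenomeLayout, truth, n_value_cols: int) -> None:
    by_chrom: dict[str, list] = {}
    for row in truth:
        by_chrom.setdefault(row[0], []).append(row)
    for chrom, length in layout.chromosomes:
        segs = sorted(by_chrom.get(chrom, []), key=lambda r: r[1])
        if not segs:
            raise ValueError(f"truth segments missing for chromosome {chrom}")
        expect = 0
        for row in segs:
            if row[1] != expect:
                raise ValueError(f"truth segments do not tile {chrom} (gap at {expect})")
            expect = row[2]
        if expect != length:
            raise ValueError(f"truth segments end at {expect} != length {length} on {chrom}")


def simulate_coverage(config: CoverageSimConfig,
                      rng: Optional[np.random.Generator] = None
                      ) -> tuple[BinTrack, SimTruth]:
    """Draw a per-bin count table under the configured copy-number truth.

    Deterministic for a fixed config seed (or a supplied generator).
    """
    _check_tiling(config.layout, config.truth, 1)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bins = bins_from_layout(config.layout, config.bin_size)
    n = len(bins)
    lo, hi = config.gc_range
    gc = rng.uniform(lo, hi, size=n)
    center = config.gc_bias_center if config.gc_bias_center is not None else (lo + hi) / 2
    bias = np.maximum(1.0 - config.gc_bias_curvature * (gc - center) ** 2, 0.1)

    cn = np.array([
        _segment_lookup(config.truth, c, s)[0]
        for c, s in zip(bins["chrom"], bins["start"])
    ], dtype=float)
    width_frac = (bins["end"] - bins["start"]).to_numpy() / config.bin_size
    mean = config.reads_per_copy * cn * bias * width_frac

    if config.dispersion <= 1e-12:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.dispersion
        # gamma-poisson mixture == negative binomial with var = m + a m^2
        lam = rng.gamma(shape=r, scale=np.maximum(mean, 1e-12) / r)
        counts = rng.poisson(lam)
    counts[mean <= 0] = 0

    bins["count"] = counts.astype(np.int64)
    bins["gc"] = gc
    track = BinTrack(bins)
    truth = SimTruth(
        cn_segments=pd.DataFrame(config.truth, columns=["chrom", "start", "end", "copy_number"]),
        bin_cn=pd.DataFrame({"chrom": bins["chrom"], "start": bins["start"],
                             "end": bins["end"], "copy_number": cn.astype(int)}),
    )
    return track, truth


def simulate_cross(config: CrossSimConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[list[VariantSite], SimTruth]:
    """Draw parent/offspring variant sites under the configured origin truth.

    Parents are always homozygous-differential; which parent carries the REF
    allele is random per site, so downstream allele-role mapping is
    exercised.  The offspring GT is called from its simulated reads with
    the classification any caller would apply to a clean biallelic site
    (allele fraction < 0.2 / > 0.8 homozygous, else heterozygous), then
    corrupted at the configured error rate.
    """
    _check_tiling(config.layout, config.origin_truth, 2)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sites: list[VariantSite] = []
    truth_rows = []
    for chrom, length in config.layout.chromosomes:
        n_sites = int(round(length / 1e6 * config.sites_per_mb))
        pos = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))
        for p in pos:
            d, t = _segment_lookup(config.origin_truth, chrom, int(p))
            ref_b, alt_b = rng.choice(4, size=2, replace=False)
            ref, alt = _BASES[ref_b], _BASES[alt_b]
            ref_parent_has_ref = bool(rng.integers(2))
            depth = int(rng.poisson(config.mean_depth))
            other_reads = int(rng.binomial(depth, d / t)) if depth > 0 else 0
            ref_parent_reads = depth - other_reads

            fails = bool(rng.random() < config.fail_qc_fraction)
            if fails:
                if rng.integers(2):
                    qd, fs = 1.0, float(rng.uniform(0, 10))
                else:
                    qd, fs = float(rng.uniform(15, 30)), 80.0
            else:
                qd, fs = float(rng.uniform(15, 30)), float(rng.uniform(0, 10))

            rp_allele = 0 if ref_parent_has_ref else 1
            op_allele = 1 - rp_allele
            # offspring GT from simulated reads
            if depth == 0:
                off_gt = None
            else:
                frac = other_reads / depth
                if frac < 0.2:
                    off_gt = (rp_allele, rp_allele)
                elif frac > 0.8:
                    off_gt = (op_allele, op_allele)
                else:
                    off_gt = tuple(sorted((rp_allele, op_allele)))
            if off_gt is not None and config.genotype_error_rate > 0 \
                    and rng.random() < config.genotype_error_rate:
                options = [(0, 0), (0, 1), (1, 1)]
                options.remove(tuple(off_gt))
                off_gt = options[int(rng.integers(len(options)))]

            ad = [0, 0]
            ad[rp_allele] = ref_parent_reads
            ad[op_allele] = other_reads
            parent_depth = max(int(rng.poisson(config.mean_depth)), 1)
            sites.append(VariantSite(
                chrom=chrom, pos=int(p), ref=str(ref), alt=str(alt), qd=qd, fs=fs,
                ref_parent=SampleCall(gt=(rp_allele, rp_allele),
                                      ad=(parent_depth, 0) if rp_allele == 0 else (0, parent_depth),
                                      dp=parent_depth),
                other_parent=SampleCall(gt=(op_allele, op_allele),
                                        ad=(parent_depth, 0) if op_allele == 0 else (0, parent_depth),
                                        dp=parent_depth),
                offspring=SampleCall(gt=off_gt, ad=(ad[0], ad[1]), dp=depth),
            ))
            truth_rows.append((chrom, int(p), d, t, fails))
    truth = SimTruth(
        origin_segments=pd.DataFrame(config.origin_truth,
                                     columns=["chrom", "start", "end", "dosage", "total"]),
        site_truth=pd.DataFrame(truth_rows,
                                columns=["chrom", "pos", "dosage", "total", "fails_qc"]),
    )
    return sites, truth


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------

@dataclass
class Preset:
    name: str
    description: str
    layout: GenomeLayout
    coverage: CoverageSimConfig
    analysis: KaryotypeConfig
    cross: Optional[CrossSimConfig] = None
    genotyping: Optional[GenotypingConfig] = None
    expected_total: Optional[int] = None


_MB = 1_000_000

# approximate chromosome lengths (Mb): rapeseed A and C subgenomes
_A_LEN = {"A1": 38, "A2": 30, "A3": 33, "A4": 26, "A5": 28,
          "A6": 27, "A7": 26, "A8": 23, "A9": 36, "A10": 20}
_C_LEN = {"C1": 58, "C2": 52, "C3": 60, "C4": 56, "C5": 48,
          "C6": 42, "C7": 46, "C8": 44, "C9": 53}
# potato-like lengths (Mb)
_POTATO_LEN = [88, 46, 60, 69, 56, 59, 57, 59, 67, 61, 45, 61]


def _rapeseed_layout(a: bool = True, c: bool = True, c_only: Sequence[str] = ()) -> GenomeLayout:
    chroms = []
    sub = {}
    if a:
        for name, mb in _A_LEN.items():
            chroms.append((name, mb * _MB))
            sub[name] = "A"
    for name, mb in _C_LEN.items():
        if c or name in c_only:
            chroms.append((name, mb * _MB))
            sub[name] = "C"
    return GenomeLayout(tuple(chroms), sub)


def _potato_layout() -> GenomeLayout:
    return GenomeLayout(tuple((f"chr{i + 1:02d}", mb * _MB) for i, mb in enumerate(_POTATO_LEN)))


def _uniform_truth(layout: GenomeLayout, cn_of) -> list[tuple[str, int, int, int]]:
    return [(name, 0, length, cn_of(name)) for name, length in layout.chromosomes]


def _preset_qis4_8() -> Preset:
    """Near-tetraploid rapeseed, 38 chromosomes, compensating homoeologous
    exchange at the A1/C1 ends (A1 32–38 Mb and C1 50–58 Mb at two copies)."""
    layout = _rapeseed_layout()
    truth = []
    for name, length in layout.chromosomes:
        if name == "A1":
            truth += [(name, 0, 32 * _MB, 3), (name, 32 * _MB, length, 2)]
        elif name == "C1":
            truth += [(name, 0, 50 * _MB, 1), (name, 50 * _MB, length, 2)]
        elif name == "A10":
            truth.append((name, 0, length, 1))
        elif name == "C9":
            truth.append((name, 0, length, 3))
        else:
            truth.append((name, 0, length, 2))
    ploidies = {"A": 2, "C": 2}
    coverage = CoverageSimConfig(layout, truth, ploidies,
                                 gc_range=(0.28, 0.52))
    analysis = KaryotypeConfig(ploidy_by_subgenome=ploidies, expected_gc=(0.30, 0.50))
    # genotyping of the A genome: A1 is AAB (dosage 1/3 from the other
    # parent), A7 switches from other-parent to reference-parent homozygous
    # at mid-chromosome, the rest is heterozygous 1/2
    a_layout = _rapeseed_layout(c=False)
    origin = []
    for name, length in a_layout.chromosomes:
        if name == "A1":
            origin.append((name, 0, length, 1, 3))
        elif name == "A7":
            origin += [(name, 0, length // 2, 2, 2), (name, length // 2, length, 0, 2)]
        else:
            origin.append((name, 0, length, 1, 2))
    cross = CrossSimConfig(a_layout, origin)
    return Preset("QIS4_8", _preset_qis4_8.__doc__, layout, coverage, analysis,
                  cross=cross, genotyping=GenotypingConfig(), expected_total=38)


def _preset_ess1_17() -> Preset:
    """Monosomic alien addition line: two A genomes plus one extra C3."""
    layout = _rapeseed_layout(c=False, c_only=("C3",))
    truth = _uniform_truth(layout, lambda n: 1 if n == "C3" else 2)
    ploidies = {"A": 2, "C": 1}
    coverage = CoverageSimConfig(layout, truth, ploidies, gc_range=(0.28, 0.52))
    analysis = KaryotypeConfig(ploidy_by_subgenome=ploidies, expected_gc=(0.30, 0.50))
    return Preset("ESS1_17", _preset_ess1_17.__doc__, layout, coverage, analysis,
                  expected_total=21)


def _preset_21a020() -> Preset:
    """Allotriploid (2n = 29): A subgenome at two copies, C at one, from a
    single sequencing pool, analyzed per subgenome with ploidies A=2, C=1."""
    layout = _rapeseed_layout()
    truth = _uniform_truth(layout, lambda n: 2 if n.startswith("A") else 1)
    ploidies = {"A": 2, "C": 1}
    coverage = CoverageSimConfig(layout, truth, ploidies, gc_range=(0.28, 0.52))
    analysis = KaryotypeConfig(ploidy_by_subgenome=ploidies, expected_gc=(0.30, 0.50))
    return Preset("21A020", _preset_21a020.__doc__, layout, coverage, analysis,
                  expected_total=29)


def _preset_at() -> Preset:
    """Autotetraploid potato: 12 chromosome types, all at four copies."""
    layout = _potato_layout()
    truth = _uniform_truth(layout, lambda n: 4)
    ploidies = {"": 4}
    coverage = CoverageSimConfig(layout, truth, ploidies, gc_range=(0.23, 0.47))
    analysis = KaryotypeConfig(ploidy_by_subgenome=ploidies, expected_gc=(0.25, 0.45))
    return Preset("At", _preset_at.__doc__, layout, coverage, analysis,
                  expected_total=48)


def _preset_ea49() -> Preset:
    """Hexaploid somatic hybrid (72 chromosomes): every chromosome at six
    copies, four of them from the non-reference parent (2:1 genome ratio)."""
    layout = _potato_layout()
    truth = _uniform_truth(layout, lambda n: 6)
    ploidies = {"": 6}
    coverage = CoverageSimConfig(layout, truth, ploidies, gc_range=(0.23, 0.47))
    analysis = KaryotypeConfig(ploidy_by_subgenome=ploidies, expected_gc=(0.25, 0.45))
    cross = CrossSimConfig(layout, [(n, 0, l, 4, 6) for n, l in layout.chromosomes])
    return Preset("EA49", _preset_ea49.__doc__, layout, coverage, analysis,
                  cross=cross, genotyping=GenotypingConfig(), expected_total=72)


def _preset_desiree_aneuploid() -> Preset:
    """Tetraploid potato aneuploid: one chromosome 2 lost, the distal 60%
    of one chromosome 8 lost, and an extra chromosome 4."""
    layout = _potato_layout()
    truth = []
    for name, length in layout.chromosomes:
        if name == "chr02":
            truth.append((name, 0, length, 3))
        elif name == "chr04":
            truth.append((name, 0, length, 5))
        elif name == "chr08":
            cut = int(length * 0.4)
            truth += [(name, 0, cut, 4), (name, cut, length, 3)]
        else:
            truth.append((name, 0, length, 4))
    ploidies = {"": 4}
    coverage = CoverageSimConfig(layout, truth, ploidies, gc_range=(0.23, 0.47))
    analysis = KaryotypeConfig(ploidy_by_subgenome=ploidies, expected_gc=(0.25, 0.45))
    return Preset("Desiree-aneuploid", _preset_desiree_aneuploid.__doc__,
                  layout, coverage, analysis, expected_total=47)


_PRESETS = {
    "QIS4_8": _preset_qis4_8,
    "ESS1_17": _preset_ess1_17,
    "21A020": _preset_21a020,
    "At": _preset_at,
    "EA49": _preset_ea49,
    "Desiree-aneuploid": _preset_desiree_aneuploid,
}


def preset_names() -> list[str]:
    return list(_PRESETS)


def preset_scenarios(name: str, seed: int = 0) -> Preset:
    """Return ready-to-run configs for a named scenario.

    The seed is copied into the coverage and cross configs (the cross gets
    seed+1 so the two datasets are independent).
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    preset = _PRESETS[name]()
    preset.coverage = replace(preset.coverage, seed=seed)
    if preset.cross is not None:
        preset.cross = replace(preset.cross, seed=seed + 1)
    return preset
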