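# Methods

## Copy-number model

Reads are counted into fixed-width bins (default 100 kb) by leftmost aligned
position, keeping primary, non-duplicate, non-secondary alignments with
MAPQ ≥ 1 (all exposed as parameters; depth-based CNV callers differ little in
these choices and the bin totals dominate).

**GC normalization.** Read yield depends smoothly on fragment GC. Over
*eligible* bins — unmasked, non-zero count, GC inside the trusted interval
(defaults 0.30–0.50 for rapeseed-like genomes, 0.25–0.45 for potato-like
ones) — a degree-3 polynomial of count on GC is fit by least squares, and
each bin is rescaled by `median(eligible counts) / fit(gc)`. A cubic is
flexible enough for the unimodal bias of real libraries without chasing
noise; when eligible GC values are (near-)constant the fit degenerates to
the mean and normalization is the identity. Bins outside the GC interval,
N-rich bins, zero-coverage bins and bins where the fitted value is not
positive are masked: they are excluded from all baselines, fits and segment
statistics and appear as gaps, never as copy-number-0 calls. At least 50
eligible bins are required, otherwise the user is told to enlarge the bins.

**Ratio.** `ratio = normalized / median(normalized)`, the median taken over
unmasked bins of the chromosome *group* being analyzed — the whole genome,
or one subgenome when subgenomes are given in the chromosome-length file.
This anchors the group's modal dosage at ratio 1 (the median of unmasked
ratios is exactly 1), and makes everything scale-invariant: multiplying all
counts by a constant changes nothing downstream. The anchor assumes most of
the group sits at the expected ploidy; a genome in which more than half the
assayable length deviates would shift the baseline — the standard failure
mode of any median-normalized depth method.

**Segmentation.** Recursive binary segmentation on the chromosome's unmasked
ratio sequence: each candidate split maximizes the reduction in
within-segment sum of squared deviations (computed in O(1) per split from
prefix sums) and is accepted iff the reduction exceeds
`λ = s · σ̂² · log n`, with `s` = 3.0, `n` the chromosome's unmasked bin
count, and `σ̂ = 1.4826 · median(|Δratio|)/√2` — a MAD estimator on first
differences, robust to the very changepoints being sought. The penalty is
BIC-like: a true step of height h in k bins is accepted roughly when
`k·h² > λ`, so at default noise levels multi-megabase events at ±1 copy are
found while bin-level noise is not chased. Segments smaller than 10 bins
(1 Mb) are never produced; chromosomes with fewer than 10 usable bins give a
single segment flagged low-confidence. For a single changepoint the accepted
split equals the exhaustive SSE-minimizing split (tested against that
oracle). Breakpoints snap to bin edges; interior masked bins ride with the
left segment, so consecutive segments tile the assayable span exactly.

**Integer calls.** Segment copy number is `max(0, round(mean_ratio ×
ploidy))`, rounding halves away from zero so a ratio exactly between two
states resolves deterministically. The chromosome-level copy number is the
length-weighted plurality of its segments; a tie goes to the copy number
nearest the expected ploidy (then the smaller), biasing ambiguous
chromosomes toward euploidy. Both the per-segment calls and the chromosome
call are reported, since either may be the quantity of interest.

**Ploidy scan.** When ploidy is uncertain, `fitness(p) = mean |ratio·p −
round(ratio·p)|` over the group's unmasked bins; the selected ploidy is the
argmin, and among candidates within 1e-3 of it the smallest wins — any
integer multiple of a fitting ploidy fits equally, so the degeneracy must be
broken explicitly. The per-bin statistic needs reasonably tight ratios
(deep or low-dispersion data, or aneuploid chromosomes providing off-integer
evidence); a fully euploid genome is uninformative and yields the smallest
candidate by construction, which the output notes.

**Not implemented:** mappability correction (bins in repetitive regions
should be pre-masked or a larger bin size used), B-allele-frequency
refinement, and subclonal/fractional copy numbers.

## Origin genotyping

Variant sites (SNPs and InDels alike) pass quality control when QD ≥ 2.0
and FS ≤ 60.0; absent annotations pass, with a logged count, since only
annotated failures are evidence of a bad site. Only biallelic sites where
both parents are called homozygous for different alleles are informative;
the offspring's allele depths are re-expressed by parental role, so which
parent happens to carry the REF allele is irrelevant (swapping the parents
maps every index x to 1 − x exactly).

The per-site index has two modes. The default, `allele_fraction`, is the
offspring's read fraction of the other parent's allele — its expectation at
a site where d of t chromatids come from the other parent is d/t, so window
means read directly as dosage (1/3 for AₙAₙAᵣ, 2/3 for a 2:1 hexaploid
hybrid). The alternative `genotype_match` mode scores 0 when the offspring
genotype is homozygous for the reference parent's allele and 1 otherwise;
it is sharper for purely homozygous material but collapses all mixed
dosages to 1, so it cannot reproduce fractional window means — the reason
`allele_fraction` is the default. Sites with offspring depth below 7 reads
(DP when present, else the sum of allele depths) are excluded in both modes
as their indexes are unreliable.

Windows of 2 Mb advance by 10 kb from position 0 of each chromosome (the
last windows overhang and are clipped for reporting); the window value is
the plain arithmetic mean of the member sites' indexes. Windows with fewer
than 10 sites (a default; the marker density, not the method, sets what is
sensible) are reported as missing. Classification: mean ≤ 0.2 homozygous
for the reference parent, ≥ 0.8 homozygous for the other parent, otherwise
heterozygous — the boundary values are assigned to the homozygous classes so
classification is deterministic. Consecutive same-class windows merge into
origin segments, and missing windows bridge rather than split a run, since
marker deserts should not fragment origin blocks. Because windows overlap,
segments from different classes can overlap by up to one window around a
true transition; boundaries are therefore resolved to about one window.
Parental contributions are the mean site index (other parent) and its
complement, reported per chromosome and genome-wide, alongside the mean of
window values.

## Simulator

The coverage generator emulates binned low-coverage resequencing: per bin,
GC is drawn uniformly from a configurable range and the count from a
negative binomial with mean `reads_per_copy × CN × g(gc)` and overdispersion
0.05 (var = m + 0.05 m²), Poisson in the dispersion→0 limit. Real lcWGR
counts are overdispersed relative to Poisson; 0.05 at ~60 reads/bin gives a
coefficient of variation of ~26%, a realistically noisy but usable track.
The GC bias `g(gc) = 1 − c·(gc − center)²` with c = 12.5 modulates counts by
roughly ±20% across a 0.2-wide GC window, a nontrivial target for the
normalization. `reads_per_copy = 30` (≈60 reads/bin at a diploid baseline)
stands for the ~1× regime in this package's scaled-down problem sizes, and
12 for the ~0.4× regime; recovery tests run the lower one.

The cross generator places homozygous-differential markers uniformly
(20/Mb default — conservative for divergent parents), draws offspring depth
from Poisson(10), the other-parent read count binomially from the local
dosage d/t, and calls the offspring GT from those reads (fraction < 0.2 /
> 0.8 homozygous, else heterozygous), optionally corrupted at a configured
error rate; a configured fraction of sites is emitted with failing QD or FS
to give the quality filter tagged targets. Which parent carries REF is
random per site so allele-role mapping is always exercised.

What the simulator does *not* emulate: mappability structure, alignment
artifacts, GC bias that varies along the genome, linkage between marker
placement and recombination, parent genotyping errors, and segmental biases
of real libraries. Passing recovery tests therefore demonstrates the
statistical machinery (normalization, segmentation, dosage averaging) under
honest noise, not robustness to every real-data artifact; on real data the
ExpectedGC interval, bin size and MAPQ threshold are the knobs that absorb
those artifacts.

Preset scenarios mirror documented karyotypes (chromosome lengths are
realistic approximations): the near-tetraploid with 38 chromosomes whose
A1/C1 ends exchanged (A1 two-copy beyond 32 Mb, C1 two-copy beyond 50 Mb),
the AA+C3 addition line (21), the AAC allotriploid (29) simulated from one
pool so C bins average half the A depth, the autotetraploid (48), the
hexaploid hybrid (72, other-parent dosage 4/6) and a tetraploid aneuploid
with a lost chromosome, a partial loss and a gained chromosome (47).

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; VCF and site-table
  positions convert on read/write. Per-site report files print 1-based
  positions; window/segment files are BED-like half-open.
* All randomness flows through a single seed per generator; identical seeds
  give byte-identical output files.
* Problem sizes in the tests and the acceptance script (100 kb bins over
  ~750 Mb genomes, 10⁴–10⁵ marker sites, 20-seed recovery replicates) were
  chosen so the full suite runs in well under a minute while keeping
  per-chromosome bin counts (200–900) and per-window site counts (~40) in
  the regime where the estimators behave as on full-size data.
* Degenerate inputs: empty chromosomes yield no segments; an all-masked
  group raises rather than emitting a silent zero baseline; empty karyotype
  lists write header-only reports.
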