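# plantkaryo

Molecular karyotyping of aneuploid and polyploid plants from low-coverage
whole-genome resequencing.

Chromosome gains, losses and segmental dosage changes are routine in plant
breeding material — resynthesized allopolyploids, interploidy hybrids,
monosomic alien addition lines, protoplast regenerants — and confirming them
cytogenetically (FISH/GISH) is slow and expert-limited. This package infers
the karyotype from cheap short-read resequencing instead, for anyone who can
align reads and call variants:

* **Copy-number pipeline** (works down to ~0.4× depth): reads are counted
  into fixed bins (100 kb default), GC-corrected, and expressed as a per-bin
  *Ratio* — normalized depth over the median of the chromosome group. Local
  copy number is then `Ratio × expected ploidy`: the ratio track is segmented
  (recursive binary segmentation with a BIC-style penalty) and each segment
  gets the integer copy number `round(mean_ratio × ploidy)`. A chromosome's
  copy number is the length-weighted plurality of its segments, and the sum
  over chromosomes is the 2n count. Subgenomes of an allopolyploid with
  different ploidies (e.g. an AAC triploid) are analyzed separately via the
  subgenome column of the chromosome-length file. When ploidy is in doubt, a
  scan picks the candidate whose ratios land closest to integers.

* **Origin-genotyping pipeline** (needs ~5–10× plus parental data): at sites
  where the two parents are homozygous for different alleles, a per-site
  *index* in [0, 1] measures the offspring's match to the non-reference
  parent — by default the read fraction carrying that parent's allele, which
  resolves dosage (an AₙAₙAᵣ region averages 1/3). Sites with QD < 2.0,
  FS > 60.0 or offspring depth < 7 are excluded; indexes are averaged in
  2 Mb windows sliding by 10 kb; windows at ≤ 0.2 / ≥ 0.8 are homozygous for
  the reference / other parent and the rest heterozygous, giving origin
  blocks and per-parent genome contributions.

A seeded simulator generates binned coverage (negative-binomial counts with
a smooth GC bias, proportional to local copy number) and hybrid site tables
(binomial allele sampling from a known dosage), with ground-truth tables, so
the whole toolchain is testable without any downloads. Presets replicate
published karyotypes, e.g. a near-tetraploid rapeseed with 38 chromosomes
and compensating homoeologous exchange, an allotriploid with 2n = 29, and a
hexaploid somatic hybrid with 72 chromosomes and a 2:1 genome ratio.

## Worked example

```sh
plantkaryo simulate --preset QIS4_8 --seed 1 --outdir demo
plantkaryo karyotype --counts demo/counts.tsv --chrlen demo/chrlen.tsv \
    --ploidy-by-subgenome A=2,C=2 --outdir demo/kary
plantkaryo genotype --sites demo/sites.tsv --chrlen demo/chrlen_cross.tsv \
    --outdir demo/gen
plantkaryo plot --type karyotype --counts demo/counts.tsv \
    --chrlen demo/chrlen.tsv --ploidy-by-subgenome A=2,C=2 --out demo/kary.png
```

The karyotype command prints `total chromosomes = 38` — the simulated plant
is a recessive aneuploid: euploid-like in count, but `demo/kary/chromosomes.tsv`
shows three copies of A1 against one C1 (and one A10 against three C9):

```
chrom  subgenome  ploidy  copy_number  fraction_at_cn
A1     A          2       3            0.823684
A2     A          2       2            1.0
```

`segments.tsv` resolves the homoeologous exchange: the distal ~6 Mb of A1
drops back to two copies (truth: 32 Mb; recovered boundary 31.3 Mb):

```
chrom  start     end       mean_ratio  copy_number
A1     0         31300000  1.475917    3
A1     31300000  38000000  0.968786    2
```

The genotype command prints the genome-wide `other-parent fraction = 0.4842`,
and per-chromosome contributions show A1's three copies split 2:1 between
the parents (mean index 0.345 ≈ 1/3), while `origin_segments.tsv` paints A7
as other-parent homozygous on its first half and reference-parent homozygous
on the second.

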