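# adnaqc

Mapping-quality diagnostics for ancient-DNA (aDNA) alignments, computed
directly from BAM files, plus a provenance-tagged read simulator for
quantifying reference bias and spurious mapping.

## The problem

Ancient DNA is short (often 20–150 bp), chemically damaged (post-mortem
cytosine deamination reads as C→T near fragment ends) and frequently
diverged from the reference genome it must be mapped to. Under these
conditions short-read aligners misbehave in characteristic ways:

* **Reference bias** — reads carrying non-reference alleles are
  preferentially lost or trimmed, deflating the observed divergence.
  Because an alignment of length *L* with per-base divergence *p*
  carries Binomial(*L*, *p*) mismatches, the mean mismatches per bp,
  E[NM/*L*] = *p*, should be *independent of read length*. Dips in the
  mismatch-by-length curve (typically at short lengths, or under strict
  mapping-quality filters) are the fingerprint of reference bias.
* **Spurious mapping** — very short reads map to places they did not
  come from, and environmental (bacterial) or human contaminant reads
  map to the target genome, dominating the ultrashort length bins.

`adnaqc` makes both effects visible per sample and per read length, and
ships a simulator whose reads carry their true origin in the read name,
so any aligner's output can be scored exactly.

## What it computes

For up to six BAM files at once, rendered as a four-panel comparative
figure with per-panel TSVs:

1. **Edit distance by read length** — per-read mismatch rate NM/*L*
   averaged within each length bin (reads >300 bp merged into the
   300 bp bin; reads with indels, clipping or N bases excluded).
2. **Damage profile** — the read-local reference is reconstructed from
   the MD tag (no FASTA needed); C→T substitutions are split into CpG
   (reference CG dinucleotide) and non-CpG context, everything else is
   "other", and fractions of possible substitutions are reported per
   position from each read end. Reverse-strand G→A events are counted
   as C→T in molecule orientation.
3. **Fragment length distribution** — fraction of mapped reads per
   length.
4. **Genome coverage** — depth in non-overlapping 1000 bp windows,
   histogrammed with a cap at 5× the genome-wide mean, a dashed line at
   the sub-cap mean depth, and breadth reported as the fraction of
   windows outside the ~0× bin.

The simulator draws *n* reads per integer length bin (default design:
100 000 per bin over 20–200 bp, i.e. 18.1 M reads per library), injects
uniform per-base divergence into endogenous reads (standard scheme: 0%,
1–6% by 1%, 6–15% by 3%), optionally adds exponentially decaying
terminal deamination, and mixes endogenous/bacterial/human sources at
exact per-bin fractions (largest-remainder allocation). The evaluator
decodes read-name provenance in any resulting BAM and reports mismap
rates and source composition per read length.

## Worked example

```sh
adnaqc simulate --out sim --seed 1 --composition 1.0,0.0,0.0 \
    --divergence 0.02 --length-min 30 --length-max 60 --n-per-bin 200
adnaqc evaluate sim/truth.bam --tolerance 0 --out sim_eval
```

prints

```
simulated 6200 reads -> sim
6200 mapped reads, 0 mismapped endogenous (tolerance 0 bp)
```

Every read in the truth BAM sits at its origin, so the mismap rate is
identically zero — the null calibration for comparing a real aligner.
Re-mapping `sim/library.fastq.gz` with your aligner of choice and
running `evaluate` on that BAM then measures the aligner's own
mismapping. The QC report on the truth BAM,

```sh
printf 'sim\tsim/truth.bam\n' > bams.txt
adnaqc report -b bams.txt --out qc --error-bars
```

writes `qc/qc_report.svg` where the mismatch panel is flat at
0.02 mismatches/bp across all lengths (e.g. bin 30: rate 0.0180,
bin 60: rate 0.0198 in the run above, each within sampling error of
0.02) — deviations from that flat line on real aligner output are
reference bias.

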