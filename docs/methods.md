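# Methods

## Record retention and reference reconstruction

A record enters the statistics iff it is mapped, primary,
non-supplementary, not duplicate-flagged, has mapping quality ≥
`mq_min`, sits on a non-excluded contig and passes the optional length
bounds. Duplicate *marking* is expected upstream; the suite assumes
merged single-end aDNA reads, so "read length" is the stored query
sequence length (identical to the alignment span except under clipping,
and clipped reads are excluded from the mismatch panel anyway). Records
lacking NM or MD, or whose CIGAR and MD disagree, are skipped and
tallied rather than aborting the run. All internal coordinates are
0-based half-open.

The read-local reference is rebuilt from CIGAR + MD alone: one symbol
per read position, with a `-` marker at insertions and soft clips
(which consume read bases but no reference) and deleted reference bases
recorded separately, anchored to the read index they precede. This is
what lets every statistic run without the genome FASTA. The
reconstruction is validated two independent ways in the tests: against
the known genome slice for simulated truth placements, and against
htslib's own MD-based reference (`get_reference_sequence`).

## Substitution classification

For reverse-strand alignments both read and reconstructed reference are
reverse-complemented first, so positions index from the molecule's 5′
end and reverse-strand G→A appears as C→T. A reference C is CpG-context
iff the next reference base is G, where "next" looks past insertion
gaps (they consume no reference) and, when a deletion immediately
follows the position, uses the first deleted base (it *is* the next
reference base). A reference C at the final read position cannot see
its following base; it is classified non-CpG, since MD-only
reconstruction is defined entirely within the read. Positions at
insertion gaps or involving non-ACGT characters are class-less.

## Panel statistics

**Mismatch by length.** Per-read rate NM/L; bin statistic is the mean
of per-read rates (a pooled ΣNM/ΣL alternative is exposed as
`pooled_rates` — the two differ only in mixed-length bins, i.e. the cap
bin). Reads with indels, clips or unknown bases are excluded; lengths
above the cap (default 300 bp) merge into the cap bin. The standard
error is the sample SD of per-read rates over √n, reported NaN for
singleton bins.

**Damage profile.** K = 25 positions per read end by default. Cell
fractions are ratio-of-sums across reads (pooled numerator over pooled
denominator), which is stable at sparse positions; per-read averaging
is available (`per_read_damage`). Denominators count opportunities
(reads with a CpG-context reference C at the position, etc.), so empty
cells are reported absent, never zero. Reads with indels/clips are
*included* (gap positions simply contribute nothing); a strict mode
mirrors the mismatch panel's exclusions.

**Fragment lengths.** All retained reads, no exclusions, no cap merge —
lengths are reported as observed.

**Coverage.** Each non-excluded contig is split into floor(len/W)
windows of W = 1000 bp; trailing partial windows are dropped to avoid
edge-normalisation artifacts (contigs shorter than W contribute
nothing, tallied). Depth = aligned-base overlap / W, or a read count in
count mode (starts-in-window by default; an overlap mode exists because
the start definition is a genuine toss-up for technical comparisons).
The histogram uses 50 equal-width bins on [0, 5 × genome mean] with
deeper windows clipped into the top bin; breadth is the fraction of
windows outside the lowest bin, and the dashed figure line marks the
mean over windows below the cap. With a zero genome mean the histogram
degenerates to a single occupied bin and breadth 0.

## Simulator

Genomes are i.i.d. base draws at a chosen GC fraction — divergence and
mismap logic is genome-agnostic, so nothing downstream depends on real
genome structure (see limitations). Fragments are drawn uniformly:
n per integer length bin, start uniform over valid placements
genome-wide, strand uniform. Divergence substitutes each endogenous
base independently with probability p to a uniform alternative base (no
transition/transversion skew — the skew is an extension hook, not
modelled). Deamination applies C→T at rate d5·e^(−λ(i−1)) from the 5′
end and G→A at d3·e^(−λ(j−1)) from the 3′ end, after divergence and on
the diverged sequence; a site hit by both logs its final cause as
deamination, and a deamination that restores the original base drops
out of the substitution log (the log and the original/final sequence
diff are kept exactly consistent, and NM in the truth BAM equals the
log length — asserted in tests).

Source mixing uses largest-remainder allocation per bin so composition
targets are exact wherever they are multiples of 1/n_per_bin
(multinomial draws available); divergence and damage apply to
endogenous reads only, contaminants are emitted unmodified. FASTQ
qualities are constant Q37 (no sequencing-error or quality model; none
is simulated). Gzip members are written with empty name and zero mtime
so identical seeds give byte-identical files. The truth BAM places
every read at its origin with a full-match CIGAR and NM/MD computed by
direct comparison against the genome (deliberately *not* from the
substitution log, so the log-vs-NM test is a real cross-check).

Read names carry `source|contig|start|end|strand|serial`; the mismap
evaluator needs nothing else, so it scores BAMs from external aligners
identically. A read is mismapped iff contig, strand, or start (beyond
the tolerance, default 0 bp) disagree with its origin; strand disagreement
counts because a read at the right coordinate on the wrong strand did
not map correctly. Contaminants never enter the mismap rate — a mapped
contaminant is spurious by definition and is reported through the
composition panel instead.

## Problem sizes and statistical checks

The test suite exercises the full design arithmetic (181 bins ×
100 000 = 18.1 M reads; 10 divergence levels; 2 × 10 × 4 = 80 datasets)
but simulates at reduced scale: the flat-null check uses 1000 reads per
bin over 20–200 bp (181 000 reads, ~20 M bases), divergence recovery
uses ~1.2 M bases, damage recovery ~8 400 reads. Stochastic assertions
are bounds at 3 binomial σ computed from the realised denominators,
with fixed seeds throughout; exactness assertions (composition,
round-trip reconstruction, NM consistency, pileup equality) are exact.

## What passing tests do and do not show

The synthetic genomes have no repeats, no GC structure and no
homology between sources, so *every* contaminant read is novel sequence
and truth placements are unambiguous. Passing the flat-null and
zero-mismap calibrations therefore validates the *measurement
machinery*, not any aligner: real genomes add repeat-driven
mismapping, mappability structure and cross-species homology that make
the measured curves deviate — which is precisely what the tool is for.
Fragment lengths are uniform per bin by design, not an empirical aDNA
length distribution; no indels, adapters or PCR duplicates are
simulated.

## Known limitations

* No CRAM input; no realignment or base-quality recalibration.
* Depth is not GC- or mappability-corrected; no per-chromosome
  normalisation (coverage-based sex inference is downstream use).
* The damage model is substitution-only; depurination-driven
  fragmentation footprints are out of scope.
* MD-only reconstruction cannot classify CpG context across the read's
  final base (terminal C → non-CpG, see above); at typical K = 25 and
  read lengths ≥ 20 this affects only the 3′-terminal cell.
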