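"""Provenance-tagged ancient-read simulation.

Generates uniform-per-length-bin read libraries from synthetic genomes,
with per-base divergence on endogenous reads, optional terminal
cytosine-deamination damage, and endogenous/bacterial/human source
mixing. Every read's origin (source class, contig, coordinates, strand)
is encoded in its name, so any downstream BAM — produced here as a
truth alignment or by an external aligner — can be scored for spurious
mapping without side tables.

Read-name grammar: ``source|contig|start|end|strand|serial`` with
0-based half-open coordinates ("|" is never legal in contig names
generated here).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .ingest import revcomp

#: per-base divergence levels of the standard simulation design:
#: none, 1-6% in 1% steps, then 6-15% in 3% steps — 10 levels.
DIVERGENCE_LEVELS = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06,
                     0.09, 0.12, 0.15)

#: the four standard library compositions as
#: (endogenous, bacterial, human-contaminant) fractions
LIBRARY_COMPOSITIONS = (
    (1.00, 0.00, 0.00),
    (0.50, 0.49, 0.01),
    (0.10, 0.89, 0.01),
    (0.01, 0.98, 0.01),
)

SOURCES = ("endogenous", "bacterial", "human_contaminant")

DEFAULT_LENGTH_RANGE = (20, 200)
DEFAULT_N_PER_BIN = 100_000
_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
FASTQ_QUALITY = 37  # constant Phred quality written to FASTQ/BAM

CAUSE_DIVERGENCE = "divergence"
CAUSE_DEAMINATION = "deamination"

TRUTH_COLUMNS = ("name", "source", "contig", "start", "end", "strand",
                 "length", "seq_original", "seq_final", "substitutions")


def standard_dataset_count(n_genomes: int = 2,
                           levels: Sequence[float] = DIVERGENCE_LEVELS,
                           compositions: Sequence = LIBRARY_COMPOSITIONS,
                           ) -> int:
    """Datasets in the full factorial design: genomes x levels x compositions."""
    return n_genomes * len(levels) * len(compositions)


def total_reads(length_min: int = DEFAULT_LENGTH_RANGE[0],
                length_max: int = DEFAULT_LENGTH_RANGE[1],
                n_per_bin: int = DEFAULT_N_PER_BIN) -> int:
    """Reads per library: one bin per integer length, n_per_bin each."""
    return (length_max - length_min + 1) * n_per_bin


# ---------------------------------------------------------------------------
# synthetic genomes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    """An i.i.d. random genome, reproducible from its seed."""

    contigs: Dict[str, str]
    gc: float
    seed: int

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def slice(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        s = self.contigs[contig][start:end]
        return s if strand == "+" else revcomp(s)

    def write_fasta(self, path: Union[str, Path], width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def synthesize_genome(n_contigs: int, contig_length: int, gc: float,
                      seed: int, fasta_path: Optional[Union[str, Path]] = None,
                      name_prefix: str = "contig") -> SyntheticGenome:
    """Draw an i.i.d. genome with P(G) + P(C) = gc.

    The same seed always yields the same genome (and byte-identical
    FASTA). ``contig_length`` should be at least ~1 kb so fragment
    sampling has room.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc fraction must be in [0, 1], got {gc}")
    if n_contigs < 1 or contig_length < 1:
        raise ValueError("need at least one contig of positive length")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = {}
    for i in range(n_contigs):
        draw = rng.choice(_BASE_ARR, size=contig_length, p=p)
        contigs[f"{name_prefix}{i + 1}"] = draw.tobytes().decode("ascii")
    genome = SyntheticGenome(contigs=contigs, gc=gc, seed=seed)
    if fasta_path is not None:
        genome.write_fasta(fasta_path)
    return genome


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

@dataclass
class FragmentRecord:
    """A simulated read with full provenance.

    ``applied_substitutions`` lists ``(position, from, to, cause)`` with
    0-based read positions (molecule orientation); ``seq_original``
    differs from ``seq_final`` exactly at those positions.
    """

    name: str
    source: str
    contig: str
    start: int
    end: int
    strand: str
    seq_original: str
    seq_final: str
    applied_substitutions: Tuple[Tuple[int, str, str, str], ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


def fragment_name(source: str, contig: str, start: int, end: int,
                  strand: str, serial: int) -> str:
    return f"{source}|{contig}|{start}|{end}|{strand}|{serial}"


def sample_fragments(genome: SyntheticGenome, length_min: int,
                     length_max: int, n_per_bin: int,
                     seed: Optional[int] = None,
                     source: str = "endogenous",
                     serial_start: int = 0,
                     rng: Optional[np.random.Generator] = None,
                     ) -> List[FragmentRecord]:
    """Draw n_per_bin fragments per integer length in [length_min, length_max].

    Start positions are uniform over all valid placements genome-wide
    (contigs weighted by their valid-start counts), strands uniform;
    reverse-strand fragments carry the reverse complement of the genome
    slice. Raises if any contig is shorter than length_max.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(genome.contigs)
    lengths_by_contig = np.array([len(genome.contigs[c]) for c in names])
    if length_max > lengths_by_contig.min():
        raise ValueError(
            f"length_max {length_max} exceeds shortest contig "
            f"({lengths_by_contig.min()} bp)")
    serial = serial_start
    fragments: List[FragmentRecord] = []
    for frag_len in range(length_min, length_max + 1):
        valid = lengths_by_contig - frag_len + 1
        weights = valid / valid.sum()
        contig_idx = rng.choice(len(names), size=n_per_bin, p=weights)
        strands = rng.integers(0, 2, size=n_per_bin)
        for ci, si in zip(contig_idx, strands):
            contig = names[ci]
            start = int(rng.integers(0, valid[ci]))
            end = start + frag_len
            strand = "+-"[si]
            seq = genome.slice(contig, start, end, strand)
            fragments.append(FragmentRecord(
                name=fragment_name(source, contig, start, end, strand, serial),
                source=source, contig=contig, start=start, end=end,
                strand=strand, seq_original=seq, seq_final=seq))
            serial += 1
    return fragments


def inject_divergence(fragment: FragmentRecord, p: float,
                      rng: np.random.Generator) -> FragmentRecord:
    """Substitute each base independently with probability p.

    Substituted bases change to one of the three alternatives uniformly;
    events are logged with cause ``divergence``. Models sample-reference
    sequence divergence as uniform random mismatches along the read.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {p}")
    n = fragment.length
    if p == 0.0 or n == 0:
        return fragment
    hits = np.nonzero(rng.random(n) < p)[0]
    if hits.size == 0:
        return fragment
    offsets = rng.integers(1, 4, size=hits.size)
    seq = list(fragment.seq_final)
    subs = list(fragment.applied_substitutions)
    for pos, off in zip(hits, offsets):
        old = seq[pos]
        new = _BASES[(_BASES.index(old) + off) % 4]
        seq[pos] = new
        subs.append((int(pos), old, new, CAUSE_DIVERGENCE))
    return replace(fragment, seq_final="".join(seq),
                   applied_substitutions=tuple(subs))


def apply_deamination(fragment: FragmentRecord, d5: float, d3: float,
                      lam: float, rng: np.random.Generator) -> FragmentRecord:
    """Apply terminal deamination damage to the current sequence.

    C->T with probability d5*exp(-lam*(i-1)) at 1-based 5' position i,
    and G->A with probability d3*exp(-lam*(j-1)) at 1-based distance j
    from the 3' end — the exponential decay of post-mortem cytosine
    deamination from fragment termini (G->A being the complementary
    strand's signature). Applied after divergence; a site hit by both
    logs its final cause as deamination, and a site deamination returns
    to its original base drops out of the substitution log.
    """
    for name, rate in (("d5", d5), ("d3", d3)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    n = fragment.length
    if n == 0 or (d5 == 0.0 and d3 == 0.0):
        return fragment
    seq = np.frombuffer(fragment.seq_final.encode("ascii"), dtype=np.uint8).copy()
    idx = np.arange(n)
    prob = np.zeros(n)
    prob[seq == ord("C")] = d5 * np.exp(-lam * idx[seq == ord("C")])
    is_g = seq == ord("G")
    prob[is_g] = d3 * np.exp(-lam * (n - 1 - idx[is_g]))
    hits = np.nonzero(rng.random(n) < prob)[0]
    if hits.size == 0:
        return fragment
    subs = {pos: (old, new, cause)
            for pos, old, new, cause in fragment.applied_substitutions}
    orig = fragment.seq_original
    for pos in hits:
        pos = int(pos)
        new = "T" if chr(seq[pos]) == "C" else "A"
        seq[pos] = ord(new)
        if new == orig[pos]:      # deamination reverted a diverged base
            subs.pop(pos, None)
        else:
            subs[pos] = (orig[pos], new, CAUSE_DEAMINATION)
    final = seq.tobytes().decode("ascii")
    logged = tuple((pos, old, new, cause)
                   for pos, (old, new, cause) in sorted(subs.items()))
    return replace(fragment, seq_final=final, applied_substitutions=logged)


# ---------------------------------------------------------------------------
# library composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    """Recipe for one simulated library."""

    composition: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    divergence: float = 0.0
    deamination: Optional[Tuple[float, float, float]] = None  # (d5, d3, lam)
    length_range: Tuple[int, int] = DEFAULT_LENGTH_RANGE
    n_per_bin: int = DEFAULT_N_PER_BIN
    seed: int = 0
    allocation: str = "largest_remainder"   # or "multinomial"

    def __post_init__(self):
        if any(f < 0 for f in self.composition):
            raise ValueError("composition fractions must be non-negative")
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.allocation not in ("largest_remainder", "multinomial"):
            raise ValueError(f"unknown allocation {self.allocation!r}")


def largest_remainder_allocation(fractions: Sequence[float], total: int,
                                 ) -> List[int]:
    """Integer quotas summing to ``total``, deterministic.

    Floors the exact quotas, then hands remaining units to the largest
    fractional parts (ties broken by position), making composition
    targets exact wherever the fractions are multiples of 1/total.
    """
    exact = [f * total for f in fractions]
    counts = [int(math.floor(q)) for q in exact]
    rem = total - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def compose_library(spec: LibrarySpec, endogenous: SyntheticGenome,
                    bacterial: Optional[SyntheticGenome] = None,
                    human: Optional[SyntheticGenome] = None,
                    fastq_path: Optional[Union[str, Path]] = None,
                    truth_path: Optional[Union[str, Path]] = None,
                    ) -> List[FragmentRecord]:
    """Build a mixed-source library per the spec.

    Per length bin, read counts are allocated to sources by largest
    remainder on the composition fractions (or multinomially when the
    spec says so). Divergence and deamination are applied to endogenous
    reads only; contaminant reads are emitted unmodified. Optionally
    writes the FASTQ (gzipped when the path ends in .gz; constant
    quality) and the truth table TSV.
    """
    genomes = {"endogenous": endogenous, "bacterial": bacterial,
               "human_contaminant": human}
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    fragments: List[FragmentRecord] = []
    serial = 0
    for frag_len in range(lo, hi + 1):
        if spec.allocation == "largest_remainder":
            counts = largest_remainder_allocation(spec.composition,
                                                  spec.n_per_bin)
        else:
            counts = list(rng.multinomial(spec.n_per_bin, spec.composition))
        for source, count in zip(SOURCES, counts):
            if count == 0:
                continue
            genome = genomes[source]
            if genome is None:
                raise ValueError(f"composition requires a {source} genome")
            frags = sample_fragments(genome, frag_len, frag_len, count,
                                     source=source, serial_start=serial,
                                     rng=rng)
            serial += count
            if source == "endogenous":
                if spec.divergence > 0:
                    frags = [inject_divergence(f, spec.divergence, rng)
                             for f in frags]
                if spec.deamination is not None:
                    d5, d3, lam = spec.deamination
                    frags = [apply_deamination(f, d5, d3, lam, rng)
                             for f in frags]
            fragments.extend(frags)
    if fastq_path is not None:
        write_fastq(fragments, fastq_path)
    if truth_path is not None:
        write_truth_table(fragments, truth_path)
    return fragments


def write_fastq(fragments: Iterable[FragmentRecord],
                path: Union[str, Path]) -> None:
    """FASTQ with constant base quality; gzipped iff path ends in .gz.

    Gzip members are written with a zero mtime so identical libraries
    are byte-identical across runs.
    """
    path = str(path)
    if path.endswith(".gz"):
        def opener(p, mode):
            import io
            # no filename and zero mtime in the member header
            return io.TextIOWrapper(gzip.GzipFile(
                filename="", mode="wb", fileobj=open(p, "wb"), mtime=0))
    else:
        opener = open
    qchar = chr(FASTQ_QUALITY + 33)
    with opener(path, "wt") as fh:
        for frag in fragments:
            fh.write(f"@{frag.name}\n{frag.seq_final}\n+\n"
                     f"{qchar * frag.length}\n")


def _encode_subs(subs) -> str:
    return ";".join(f"{pos}:{old}>{new}:{cause}"
                    for pos, old, new, cause in subs)


def write_truth_table(fragments: Iterable[FragmentRecord],
                      path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for f in fragments:
            fh.write("\t".join((f.name, f.source, f.contig, str(f.start),
                                str(f.end), f.strand, str(f.length),
                                f.seq_original, f.seq_final,
                                _encode_subs(f.applied_substitutions))) + "\n")


# ---------------------------------------------------------------------------
# truth BAM
# ---------------------------------------------------------------------------

def _md_and_nm(read_fwd: str, ref_fwd: str) -> Tuple[str, int]:
    """MD tag and NM for a gapless alignment, by direct comparison."""
    a = np.frombuffer(read_fwd.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(ref_fwd.encode("ascii"), dtype=np.uint8)
    mism = np.nonzero(a != b)[0]
    if mism.size == 0:
        return str(len(ref_fwd)), 0
    parts = []
    prev = 0
    for pos in mism:
        parts.append(str(int(pos) - prev))
        parts.append(ref_fwd[pos])
        prev = int(pos) + 1
    parts.append(str(len(ref_fwd) - prev))
    return "".join(parts), int(mism.size)


def write_truth_bam(fragments: Sequence[FragmentRecord],
                    genome: SyntheticGenome,
                    bam_path: Union[str, Path]) -> None:
    """Place every fragment at its origin in a sorted, indexed BAM.

    Each record gets a full-match CIGAR, the correct strand flag, and NM
    and MD computed against the genome — the truth alignment that
    downstream oracles compare against. All fragments must originate
    from ``genome``'s contigs.
    """
    bam_path = str(bam_path)
    names = list(genome.contigs)
    order = {c: i for i, c in enumerate(names)}
    for frag in fragments:
        if frag.contig not in order:
            raise ValueError(f"fragment contig {frag.contig!r} not in genome")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome.contigs[c])} for c in names],
        "PG": [{"ID": "adnaqc-sim", "PN": "adnaqc",
                "DS": "truth placement; read name = "
                      "source|contig|start|end|strand|serial"}],
    }
    ordered = sorted(fragments, key=lambda f: (order[f.contig], f.start))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for frag in ordered:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = frag.name
            a.flag = 16 if frag.strand == "-" else 0
            a.reference_id = order[frag.contig]
            a.reference_start = frag.start
            a.mapping_quality = 60
            a.cigartuples = [(0, frag.length)]
            stored = (frag.seq_final if frag.strand == "+"
                      else revcomp(frag.seq_final))
            a.query_sequence = stored
            a.query_qualities = pysam.qualitystring_to_array(
                chr(FASTQ_QUALITY + 33) * frag.length)
            ref = genome.contigs[frag.contig][frag.start:frag.end]
            md, nm = _md_and_nm(stored, ref)
            a.set_tags([("NM", nm, "i"), ("MD", md, "Z")])
            bam.write(a)
    pysam.index(bam_path)
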