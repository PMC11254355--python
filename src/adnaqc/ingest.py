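"""Alignment ingestion for ancient-DNA QC.

Streams records from coordinate-sorted BAM files, applies record-level
retention filters (mapped, primary, non-supplementary, non-duplicate,
mapping-quality and contig filters), and reconstructs the read-local
reference sequence from the CIGAR string and MD tag so that every
downstream statistic can be computed without access to the genome FASTA.

The reconstructed reference is *read-oriented*: it carries exactly one
symbol per read position — the reference base at matched/mismatched
positions and a gap marker (``-``) at insertion and soft-clipped
positions, which consume read bases but no reference. Deleted reference
bases occupy no read position and are recorded separately, anchored to
the read index they precede.

Substitution classification follows the ancient-DNA damage convention:
for reverse-strand alignments both read and reconstructed reference are
reverse-complemented first, so positions index from the original
molecule's 5' end and reverse-strand G->A events are counted as C->T.
A reference C is CpG-context iff the next reference base visible within
the read (or, if a deletion immediately follows, the first deleted base)
is G.
"""

from __future__ import annotations

import logging
import os
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam

logger = logging.getLogger("adnaqc")

GAP = "-"
VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn-",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn-")

#: substitution classes reported by :func:`classify_substitutions`
CLASS_CPG_CT = "cpg_ct"
CLASS_NONCPG_CT = "noncpg_ct"
CLASS_OTHER = "other"
CLASS_MATCH = "match"


def revcomp(seq: str) -> str:
    """Reverse-complement, preserving the gap marker."""
    return seq.translate(_COMPLEMENT)[::-1]


class MDError(ValueError):
    """CIGAR/MD inconsistency (run lengths exhausted early or left over)."""


# ---------------------------------------------------------------------------
# options and observation types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis-time knobs shared by every panel.

    Parameters
    ----------
    mq_min
        Minimum mapping quality; records below are dropped. Filtering at
        analysis time (rather than requiring pre-filtered BAMs) allows
        several thresholds to be compared on one alignment file.
    excluded_contigs
        Reference sequence names excluded from every statistic
        (decoys, mitochondria, ...).
    min_length, max_length
        Optional read-length bounds in bp applied at ingest.
    damage_positions
        Number of positions profiled from each read end (K).
    error_bars
        Draw per-bin standard errors in the mismatch panel.
    count_mode
        Coverage windows tally read starts instead of aligned-base depth
        (recommended for within-sample technical comparisons).
    length_cap
        Mismatch-panel merge bin: reads longer than this are tallied in
        the cap bin (default 300 bp).
    window_size
        Coverage window width W in bp.
    pooled_rates
        Mismatch bin statistic as pooled sum(NM)/sum(len) instead of the
        default mean of per-read rates.
    per_read_damage
        Average damage fractions per read instead of the default
        ratio-of-sums pooling.
    strict_damage_exclusions
        Apply the mismatch-panel exclusions (indel/clip/N) to the damage
        panel as well.
    coverage_overlap_counts
        In count mode, count reads overlapping a window instead of reads
        starting in it.
    """

    mq_min: int = 0
    excluded_contigs: frozenset = frozenset()
    min_length: Optional[int] = None
    max_length: Optional[int] = None
    damage_positions: int = 25
    error_bars: bool = False
    count_mode: bool = False
    length_cap: int = 300
    window_size: int = 1000
    pooled_rates: bool = False
    per_read_damage: bool = False
    strict_damage_exclusions: bool = False
    coverage_overlap_counts: bool = False

    def __post_init__(self):
        if self.mq_min < 0:
            raise ValueError("mq_min must be >= 0")
        if self.damage_positions < 1:
            raise ValueError("damage_positions must be >= 1")
        if self.length_cap < 1:
            raise ValueError("length_cap must be >= 1")
        if not isinstance(self.excluded_contigs, frozenset):
            object.__setattr__(self, "excluded_contigs",
                               frozenset(self.excluded_contigs))

    def updated(self, **kwargs) -> "AnalysisOptions":
        return replace(self, **kwargs)


@dataclass
class ReadObservation:
    """One retained, mapped read and its read-local reference."""

    sample_id: str
    query_name: str
    length: int
    edit_distance: int
    mapq: int
    strand: str                      # '+' or '-'
    contig: str
    start: int                       # 0-based leftmost reference coordinate
    has_indel: bool
    has_clip: bool
    has_unknown_base: bool
    read_seq: str                    # as stored (reference orientation)
    ref_seq_aligned: str             # one symbol per read position
    deletions: tuple = ()            # ((read_index_preceded, ref_bases), ...)

    def __post_init__(self):
        if len(self.ref_seq_aligned) != len(self.read_seq):
            raise ValueError("ref_seq_aligned must have one entry per read position")


class DropTally(Counter):
    """Counts of records dropped per reason during ingestion."""

    def write_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("reason\tcount\n")
            for reason, count in sorted(self.items()):
                fh.write(f"{reason}\t{count}\n")


# ---------------------------------------------------------------------------
# MD-tag reference reconstruction
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")
# pysam integer opcodes -> CIGAR characters
_CIGAR_CODES = "MIDNSHP=X"


def _parse_cigar(cigar) -> list:
    """Accept a CIGAR string or pysam-style [(opcode, length), ...]."""
    if isinstance(cigar, str):
        ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
        if "".join(f"{n}{o}" for o, n in ops) != cigar:
            raise MDError(f"unparseable CIGAR {cigar!r}")
        return ops
    return [(_CIGAR_CODES[op], int(ln)) for op, ln in cigar]


class _MDCursor:
    """Sequential consumer of MD-tag tokens."""

    __slots__ = ("tokens", "idx", "run", "md")

    def __init__(self, md: str):
        self.md = md
        self.tokens = _MD_RE.findall(md)
        if "".join(a or b or c for a, b, c in self.tokens) != md:
            raise MDError(f"unparseable MD tag {md!r}")
        self.idx = 0
        self.run = 0  # remaining bases in the current match run

    def _advance(self) -> None:
        while self.run == 0 and self.idx < len(self.tokens):
            num, dele, mism = self.tokens[self.idx]
            if num:
                self.idx += 1
                self.run = int(num)
            else:
                break

    def take_aligned(self, read_slice: str, out: list) -> None:
        """Consume len(read_slice) aligned positions, appending ref bases."""
        pos, n = 0, len(read_slice)
        while pos < n:
            self._advance()
            if self.run > 0:
                take = min(self.run, n - pos)
                out.append(read_slice[pos:pos + take])  # match: ref == read
                self.run -= take
                pos += take
                continue
            if self.idx >= len(self.tokens):
                raise MDError(f"MD tag {self.md!r} exhausted before CIGAR")
            num, dele, mism = self.tokens[self.idx]
            if mism:
                out.append(mism.upper())  # mismatch: MD names the ref base
                self.idx += 1
                pos += 1
            else:
                raise MDError(f"MD tag {self.md!r}: deletion where aligned "
                              "base expected")

    def take_deletion(self, length: int) -> str:
        self._advance()
        if self.run > 0 or self.idx >= len(self.tokens):
            raise MDError(f"MD tag {self.md!r}: expected deletion")
        num, dele, mism = self.tokens[self.idx]
        if not dele or len(dele) - 1 != length:
            raise MDError(f"MD tag {self.md!r}: deletion length mismatch")
        self.idx += 1
        return dele[1:].upper()

    def assert_exhausted(self) -> None:
        self._advance()
        if self.run > 0 or self.idx < len(self.tokens):
            raise MDError(f"MD tag {self.md!r} has leftover tokens after CIGAR")


def reconstruct_reference(read_seq: str, cigar, md: str):
    """Rebuild the read-oriented reference from CIGAR + MD.

    Parameters
    ----------
    read_seq
        Read bases as stored in the alignment record.
    cigar
        CIGAR string (``"2M1I1M"``) or pysam ``cigartuples``.
    md
        Value of the MD auxiliary tag.

    Returns
    -------
    ref_aligned : str
        One symbol per read position: the reference base at aligned
        positions, ``-`` at insertions and soft clips.
    deletions : tuple of (int, str)
        Deleted reference bases, each anchored to the read index they
        precede (0-based; the deletion sits between index-1 and index).

    Raises
    ------
    MDError
        If CIGAR and MD are mutually inconsistent.
    """
    ops = _parse_cigar(cigar)
    cursor = _MDCursor(md)
    out: list = []
    deletions: list = []
    qpos = 0
    for op, ln in ops:
        if op in "M=X":
            cursor.take_aligned(read_seq[qpos:qpos + ln], out)
            qpos += ln
        elif op in "IS":
            out.append(GAP * ln)
            qpos += ln
        elif op == "D":
            deletions.append((qpos, cursor.take_deletion(ln)))
        elif op == "N":
            continue  # spliced skip: not represented in MD
        elif op in "HP":
            continue
        else:  # pragma: no cover - exhaustive over SAM opcodes
            raise MDError(f"unsupported CIGAR op {op!r}")
    if qpos != len(read_seq):
        raise MDError("CIGAR does not consume the full read sequence")
    cursor.assert_exhausted()
    return "".join(out), tuple(deletions)


# ---------------------------------------------------------------------------
# substitution classification
# ---------------------------------------------------------------------------

def oriented_alignment(obs: ReadObservation):
    """Read, reference and deletions in original-molecule (5'->3') orientation."""
    if obs.strand == "+":
        return obs.read_seq, obs.ref_seq_aligned, obs.deletions
    n = obs.length
    read = revcomp(obs.read_seq)
    ref = revcomp(obs.ref_seq_aligned)
    dels = tuple((n - idx, revcomp(bases)) for idx, bases in reversed(obs.deletions))
    return read, ref, dels


def position_contexts(obs: ReadObservation):
    """Per-position alignment context, 5'-oriented.

    Yields ``(position, ref_base, read_base, is_cpg_context)`` for every
    aligned position with unambiguous bases on both sides; ``position``
    is 1-based from the molecule's 5' end. Insertion/clip gaps and
    positions involving non-ACGT characters are omitted (class-less).
    """
    read, ref, dels = oriented_alignment(obs)
    del_after = {idx: bases for idx, bases in dels}
    n = len(read)
    out = []
    for i in range(n):
        fb = ref[i]
        if fb == GAP:
            continue
        rb = read[i]
        if rb not in VALID_BASES or fb not in VALID_BASES:
            continue
        cpg = False
        if fb == "C":
            # next reference base: a deletion immediately after this read
            # position takes precedence over the next in-read ref base
            nxt = None
            if (i + 1) in del_after and del_after[i + 1]:
                nxt = del_after[i + 1][0]
            else:
                j = i + 1
                while j < n and ref[j] == GAP:
                    j += 1
                if j < n:
                    nxt = ref[j]
            cpg = nxt == "G"
        out.append((i + 1, fb, rb, cpg))
    return out


def classify_substitutions(obs: ReadObservation):
    """Classify every scoreable read position.

    Returns a list of ``(position_from_5prime, class)`` with positions
    1-based in molecule orientation and class one of ``cpg_ct``
    (read T at a CpG-context reference C), ``noncpg_ct``, ``other``
    (any other mismatch) or ``match``.
    """
    result = []
    for pos, fb, rb, cpg in position_contexts(obs):
        if rb == fb:
            cls = CLASS_MATCH
        elif fb == "C" and rb == "T":
            cls = CLASS_CPG_CT if cpg else CLASS_NONCPG_CT
        else:
            cls = CLASS_OTHER
        result.append((pos, cls))
    return result


# ---------------------------------------------------------------------------
# BAM streaming
# ---------------------------------------------------------------------------

def _retention_reason(rec: pysam.AlignedSegment,
                      options: AnalysisOptions) -> Optional[str]:
    """Why a record is dropped, or None if retained."""
    if rec.is_unmapped:
        return "unmapped"
    if rec.is_secondary:
        return "secondary"
    if rec.is_supplementary:
        return "supplementary"
    if rec.is_duplicate:
        return "duplicate"
    if rec.mapping_quality < options.mq_min:
        return "mapq"
    if rec.reference_name in options.excluded_contigs:
        return "excluded_contig"
    qlen = rec.query_length
    if options.min_length is not None and qlen < options.min_length:
        return "length"
    if options.max_length is not None and qlen > options.max_length:
        return "length"
    return None


def open_indexed_bam(bam_path: Union[str, Path]) -> pysam.AlignmentFile:
    """Open a BAM, failing fast if it is missing or unindexed."""
    bam_path = os.fspath(bam_path)
    if not os.path.exists(bam_path):
        raise FileNotFoundError(f"BAM file not found: {bam_path}")
    bam = pysam.AlignmentFile(bam_path, "rb")
    try:
        bam.check_index()
    except (ValueError, AttributeError) as exc:
        bam.close()
        raise ValueError(
            f"BAM {bam_path} has no index; run `samtools index {bam_path}`"
        ) from exc
    return bam


def observation_from_record(rec: pysam.AlignedSegment,
                            sample_id: str = "") -> ReadObservation:
    """Build a ReadObservation from a retained pysam record.

    Raises KeyError if NM/MD are absent and MDError on inconsistency.
    """
    nm = rec.get_tag("NM")
    md = rec.get_tag("MD")
    seq = rec.query_sequence
    if seq is None:
        raise MDError("record stores no sequence")
    cig = rec.cigartuples or []
    ref_aligned, deletions = reconstruct_reference(seq, cig, str(md))
    has_indel = any(op in (1, 2) for op, _ in cig)
    has_clip = any(op in (4, 5) for op, _ in cig)
    return ReadObservation(
        sample_id=sample_id,
        query_name=rec.query_name,
        length=len(seq),
        edit_distance=int(nm),
        mapq=rec.mapping_quality,
        strand="-" if rec.is_reverse else "+",
        contig=rec.reference_name,
        start=rec.reference_start,
        has_indel=has_indel,
        has_clip=has_clip,
        has_unknown_base=not set(seq) <= VALID_BASES,
        read_seq=seq,
        ref_seq_aligned=ref_aligned,
        deletions=deletions,
    )


def load_alignments(bam_path: Union[str, Path],
                    options: Optional[AnalysisOptions] = None,
                    sample_id: Optional[str] = None,
                    tally: Optional[DropTally] = None,
                    ) -> Iterator[ReadObservation]:
    """Stream retained reads from an indexed BAM as ReadObservations.

    Retained records are mapped, primary, non-supplementary,
    non-duplicate, pass the MQ/contig/length filters, and carry parseable
    NM and MD tags. Records lacking those tags or with inconsistent
    CIGAR/MD are skipped with a tallied warning. Pass a
    :class:`DropTally` to collect per-reason drop counts; they are also
    logged when the stream is exhausted.
    """
    options = options or AnalysisOptions()
    if tally is None:
        tally = DropTally()
    if sample_id is None:
        sample_id = Path(bam_path).stem
    with open_indexed_bam(bam_path) as bam:
        for rec in bam.fetch(until_eof=True):
            reason = _retention_reason(rec, options)
            if reason is not None:
                tally[reason] += 1
                continue
            try:
                yield observation_from_record(rec, sample_id)
            except KeyError:
                tally["missing_tag"] += 1
            except MDError:
                tally["md_parse_error"] += 1
    if tally:
        logger.info("%s: dropped records by reason: %s", sample_id,
                    dict(sorted(tally.items())))
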