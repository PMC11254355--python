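"""Spurious-mapping and source-composition evaluation.

Decodes per-read provenance from the read names written by
:mod:`adnaqc.simulate` (``source|contig|start|end|strand|serial``) in
any BAM built from simulator output — the truth placement or the output
of an external aligner — and scores, per read length, how many
endogenous reads landed away from their origin and what fraction of
mapped reads each source contributes.

A read is mismapped iff its mapped contig differs from the origin
contig, its leftmost coordinate deviates from the origin start by more
than the tolerance, or its strand flag disagrees with the origin
strand. Only endogenous reads enter the mismap rate (a mapped
contaminant is spurious by definition and is reported through the
composition instead).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .ingest import AnalysisOptions, DropTally, load_alignments
from .panels import MismatchProfile
from .simulate import SOURCES

logger = logging.getLogger("adnaqc")


class Provenance(NamedTuple):
    source: str
    contig: str
    start: int
    end: int
    strand: str
    serial: int


def parse_provenance(name: str) -> Optional[Provenance]:
    """Decode a provenance-bearing read name; None if unparseable."""
    parts = name.split("|")
    if len(parts) != 6:
        return None
    source, contig, start, end, strand, serial = parts
    if strand not in "+-" or not strand:
        return None
    try:
        return Provenance(source, contig, int(start), int(end), strand,
                          int(serial))
    except ValueError:
        return None


@dataclass
class LengthTally:
    total: int = 0
    endogenous_total: int = 0
    mismapped: int = 0
    by_source: Counter = field(default_factory=Counter)

    @property
    def rate(self) -> float:
        """Mismapped fraction of mapped endogenous reads (NaN if none)."""
        return (self.mismapped / self.endogenous_total
                if self.endogenous_total else float("nan"))


@dataclass
class MismapSummary:
    """Per-length mapping outcome of a provenance-tagged BAM."""

    tolerance: int
    mq_min: int
    per_length: Dict[int, LengthTally] = field(default_factory=dict)
    unknown_provenance: int = 0

    @property
    def lengths(self) -> List[int]:
        return sorted(self.per_length)

    @property
    def total_mismapped(self) -> int:
        return sum(t.mismapped for t in self.per_length.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ln in self.lengths:
            t = self.per_length[ln]
            rows.append((ln, t.total, t.endogenous_total, t.mismapped,
                         t.rate, *(t.by_source.get(s, 0) for s in SOURCES)))
        return pd.DataFrame(rows, columns=["length", "total",
                                           "endogenous_total", "mismapped",
                                           "rate", *SOURCES])

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def mismap_rate_by_length(bam_path: Union[str, Path],
                          tolerance: int = 0,
                          options: Optional[AnalysisOptions] = None,
                          ) -> MismapSummary:
    """Score mapped reads against their origin coordinates.

    The MQ/contig/flag filters apply first (via the standard ingest
    filters); reads with unparseable names are tallied separately and
    excluded from every rate. Default tolerance 0 bp demands exact
    origin placement; a small tolerance absorbs clip-induced shifts in
    aligner output.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    options = options or AnalysisOptions()
    summary = MismapSummary(tolerance=tolerance, mq_min=options.mq_min)
    for obs in load_alignments(bam_path, options):
        prov = parse_provenance(obs.query_name)
        if prov is None:
            summary.unknown_provenance += 1
            continue
        tally = summary.per_length.setdefault(obs.length, LengthTally())
        tally.total += 1
        tally.by_source[prov.source] += 1
        if prov.source == "endogenous":
            tally.endogenous_total += 1
            mis = (obs.contig != prov.contig
                   or abs(obs.start - prov.start) > tolerance
                   or obs.strand != prov.strand)
            if mis:
                tally.mismapped += 1
    if summary.unknown_provenance:
        logger.warning("%d reads had unparseable provenance names",
                       summary.unknown_provenance)
    return summary


def composition_by_length(bam_path: Union[str, Path],
                          options: Optional[AnalysisOptions] = None,
                          ) -> pd.DataFrame:
    """Fractions of mapped reads per length attributed to each source.

    Returns a DataFrame (length, total, one fraction column per source);
    fractions sum to 1 for every populated length. Unmapped reads never
    appear, so losing contaminants to mapping failure raises the
    endogenous fraction correspondingly.
    """
    summary = mismap_rate_by_length(bam_path, tolerance=0, options=options)
    rows = []
    for ln in summary.lengths:
        t = summary.per_length[ln]
        fracs = [t.by_source.get(s, 0) / t.total for s in SOURCES]
        rows.append((ln, t.total, *fracs))
    return pd.DataFrame(rows, columns=["length", "total",
                                       *(f"frac_{s}" for s in SOURCES)])


def compare_runs(profiles: Sequence, labels: Sequence[str]) -> pd.DataFrame:
    """Align per-length statistics across >= 2 runs into long format.

    Accepts MismatchProfile or MismapSummary objects (one kind per
    call). The output covers the union of length support with missing
    bins explicit as NaN rows, ready for overlay plotting — e.g. one
    BAM scored at four MQ thresholds, or one library mapped by several
    aligners.
    """
    if len(profiles) < 2:
        raise ValueError("compare_runs needs at least two runs")
    if len(profiles) != len(labels):
        raise ValueError("one label per run required")
    frames = []
    all_lengths = set()
    supports = []
    for prof, label in zip(profiles, labels):
        if isinstance(prof, MismatchProfile):
            df = prof.to_frame()
        elif isinstance(prof, MismapSummary):
            df = prof.to_frame()
        else:
            raise TypeError(f"cannot compare {type(prof).__name__}")
        df = df.copy()
        df.insert(0, "label", label)
        frames.append(df)
        supports.append(set(df["length"]))
        all_lengths.update(df["length"])
    if supports and not set.intersection(*supports):
        logger.warning("compare_runs: runs have disjoint length support")
    lengths = sorted(all_lengths)
    out = []
    for df in frames:
        df = df.set_index("length").reindex(lengths)
        df["label"] = df["label"].ffill().bfill()
        out.append(df.reset_index())
    return pd.concat(out, ignore_index=True)
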