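"""The four per-sample QC statistics.

1. mismatch-by-length: mean per-base mismatch rate (NM / read length)
   stratified by read length — flat for unbiased mappings, deviations
   flag reference bias or spurious mapping;
2. damage profile: CpG and non-CpG C->T fractions (plus all other
   substitutions) by position from each read end — the post-mortem
   deamination signal;
3. fragment length distribution;
4. genome coverage in fixed windows with a capped depth histogram and
   breadth of coverage.

All statistics consume the ReadObservation stream from
:mod:`adnaqc.ingest` except the coverage windows, which scan the BAM
per contig.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .ingest import (AnalysisOptions, DropTally, ReadObservation,
                     VALID_BASES, open_indexed_bam, position_contexts,
                     _retention_reason)

logger = logging.getLogger("adnaqc")

DAMAGE_CLASSES = ("cpg_ct", "noncpg_ct", "other")

#: number of equal-width bins in the capped depth histogram
DEPTH_HIST_BINS = 50


# ---------------------------------------------------------------------------
# panel 1: mismatch rate by read length
# ---------------------------------------------------------------------------

@dataclass
class MismatchProfile:
    """Per-length-bin mismatch statistics.

    ``bins`` maps read length (bp; lengths above the cap are merged into
    the cap bin) to ``(n_reads, mean_rate, stderr)`` where rates are
    mismatches per base pair. The standard error is NaN for singleton
    bins.
    """

    bins: Dict[int, Tuple[int, float, float]] = field(default_factory=dict)
    length_cap: int = 300
    pooled: bool = False

    @property
    def lengths(self):
        return sorted(self.bins)

    def to_frame(self) -> pd.DataFrame:
        rows = [(ln, n, rate, se) for ln, (n, rate, se) in sorted(self.bins.items())]
        return pd.DataFrame(rows, columns=["length", "n", "rate", "stderr"])

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


class MismatchAccumulator:
    """Streaming accumulator for the mismatch panel.

    Excludes reads with indels, clipping or unknown bases (their edit
    distance mixes events the per-base rate cannot attribute). The bin
    statistic is the mean of per-read rates NM/len by default, or the
    pooled ratio sum(NM)/sum(len) when ``pooled`` is set.
    """

    def __init__(self, length_cap: int = 300, pooled: bool = False):
        self.length_cap = length_cap
        self.pooled = pooled
        self._n: Counter = Counter()
        self._sum: Counter = Counter()       # sum of per-read rates
        self._sumsq: Counter = Counter()
        self._nm: Counter = Counter()        # pooled mode: total mismatches
        self._len: Counter = Counter()       # pooled mode: total bases

    def add(self, obs: ReadObservation) -> None:
        if obs.has_indel or obs.has_clip or obs.has_unknown_base:
            return
        bin_ = min(obs.length, self.length_cap)
        rate = obs.edit_distance / obs.length
        self._n[bin_] += 1
        self._sum[bin_] += rate
        self._sumsq[bin_] += rate * rate
        if self.pooled:
            self._nm[bin_] += obs.edit_distance
            self._len[bin_] += obs.length

    def finalize(self) -> MismatchProfile:
        bins = {}
        for ln, n in self._n.items():
            if self.pooled:
                mean = self._nm[ln] / self._len[ln]
            else:
                mean = self._sum[ln] / n
            # stderr always from the per-read rate spread
            rmean = self._sum[ln] / n
            var = (self._sumsq[ln] - n * rmean * rmean) / (n - 1) if n > 1 else math.nan
            se = math.sqrt(max(var, 0.0) / n) if n > 1 else math.nan
            bins[ln] = (n, mean, se)
        if not bins:
            logger.warning("mismatch panel: no eligible reads")
        return MismatchProfile(bins=bins, length_cap=self.length_cap,
                               pooled=self.pooled)


def mismatch_by_length(observations: Iterable[ReadObservation],
                       options: Optional[AnalysisOptions] = None,
                       ) -> MismatchProfile:
    """Mean per-base mismatch rate stratified by read length.

    Reads longer than ``options.length_cap`` (default 300 bp) are merged
    into the cap bin; reads with indels, clipping or unknown bases are
    excluded.
    """
    options = options or AnalysisOptions()
    acc = MismatchAccumulator(length_cap=options.length_cap,
                              pooled=options.pooled_rates)
    for obs in observations:
        acc.add(obs)
    return acc.finalize()


# ---------------------------------------------------------------------------
# panel 2: damage profile
# ---------------------------------------------------------------------------

@dataclass
class DamageProfile:
    """Numerator/denominator tallies per profiled read position.

    Positions are signed: ``+i`` is the i-th base from the 5' end,
    ``-j`` the j-th base from the 3' end (1-based, K positions each).
    ``tallies[(position, class)] = [numerator, denominator]`` with
    classes ``cpg_ct`` (read T at CpG-context reference C), ``noncpg_ct``
    and ``other`` (non-C->T mismatches over all aligned bases).
    """

    k: int
    tallies: Dict[Tuple[int, str], list] = field(default_factory=dict)
    per_read: bool = False

    def fraction(self, position: int, cls: str) -> Optional[float]:
        """Substitution fraction, or None when the denominator is empty."""
        num, den = self.tallies.get((position, cls), (0, 0))
        return num / den if den > 0 else None

    @property
    def positions(self):
        five = list(range(1, self.k + 1))
        three = list(range(-self.k, 0))
        return five + three

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions:
            for cls in DAMAGE_CLASSES:
                num, den = self.tallies.get((pos, cls), (0, 0))
                frac = num / den if den > 0 else math.nan
                rows.append((pos, cls, num, den, frac))
        return pd.DataFrame(rows, columns=["position", "class", "numerator",
                                           "denominator", "fraction"])

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


class DamageAccumulator:
    """Streaming accumulator for the damage panel.

    Default pooling is ratio-of-sums across reads (stable at sparse
    positions); ``per_read`` instead averages per-read fractions over
    reads that have a non-empty denominator at the cell.
    """

    def __init__(self, k: int = 25, strict_exclusions: bool = False,
                 per_read: bool = False):
        self.k = k
        self.strict_exclusions = strict_exclusions
        self.per_read = per_read
        self._tallies: Dict[Tuple[int, str], list] = {}

    def _bump(self, pos: int, cls: str, num: float, den: float) -> None:
        cell = self._tallies.setdefault((pos, cls), [0, 0])
        cell[0] += num
        cell[1] += den

    def add(self, obs: ReadObservation) -> None:
        if self.strict_exclusions and (obs.has_indel or obs.has_clip
                                       or obs.has_unknown_base):
            return
        k = self.k
        n = obs.length
        per_read = {} if self.per_read else None
        for pos, fb, rb, cpg in position_contexts(obs):
            signed = []
            if pos <= k:
                signed.append(pos)
            pos3 = pos - n - 1          # -1 is the 3'-terminal base
            if -pos3 <= k:
                signed.append(pos3)
            if not signed:
                continue
            is_ct = fb == "C" and rb == "T"
            mismatch = rb != fb
            for sp in signed:
                sink = per_read if per_read is not None else None
                if fb == "C":
                    cls = "cpg_ct" if cpg else "noncpg_ct"
                    self._cell(sink, sp, cls, 1 if is_ct else 0, 1)
                self._cell(sink, sp, "other", 1 if (mismatch and not is_ct) else 0, 1)
        if per_read:
            for (sp, cls), (num, den) in per_read.items():
                self._bump(sp, cls, num / den, 1)

    def _cell(self, sink, pos, cls, num, den):
        if sink is None:
            self._bump(pos, cls, num, den)
        else:
            cell = sink.setdefault((pos, cls), [0, 0])
            cell[0] += num
            cell[1] += den

    def finalize(self) -> DamageProfile:
        return DamageProfile(k=self.k, tallies=dict(self._tallies),
                             per_read=self.per_read)


def damage_profile(observations: Iterable[ReadObservation],
                   k: Optional[int] = None,
                   options: Optional[AnalysisOptions] = None,
                   ) -> DamageProfile:
    """Terminal substitution fractions by read position.

    For 5' position i, the CpG C->T cell's denominator counts reads whose
    read-oriented reference carries a CpG-context C at i and the
    numerator those where the read base is T; analogously for non-CpG C.
    The ``other`` cell counts non-C->T mismatches over all aligned bases.
    Symmetric tallies are kept from the 3' end. Cells with empty
    denominators report no fraction (absent, not zero).
    """
    options = options or AnalysisOptions()
    acc = DamageAccumulator(k=k if k is not None else options.damage_positions,
                            strict_exclusions=options.strict_damage_exclusions,
                            per_read=options.per_read_damage)
    for obs in observations:
        acc.add(obs)
    return acc.finalize()


# ---------------------------------------------------------------------------
# panel 3: fragment length distribution
# ---------------------------------------------------------------------------

@dataclass
class LengthHistogram:
    """Read counts per fragment length, with derived fractions."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> Dict[int, float]:
        total = self.total
        if total == 0:
            return {}
        return {ln: c / total for ln, c in sorted(self.counts.items())}

    def to_frame(self) -> pd.DataFrame:
        total = self.total
        rows = [(ln, c, c / total) for ln, c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["length", "count", "fraction"])

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fragment_length_distribution(observations: Iterable[ReadObservation],
                                 ) -> LengthHistogram:
    """Distribution of retained mapped read lengths (no indel/clip
    exclusion and no cap merge — lengths are reported as observed)."""
    hist = LengthHistogram()
    for obs in observations:
        hist.counts[obs.length] += 1
    if not hist.counts:
        logger.warning("fragment-length panel: no reads")
    return hist


# ---------------------------------------------------------------------------
# panel 4: windowed genome coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageSummary:
    """Windowed depth with a capped histogram.

    ``windows`` is a DataFrame (contig, start, depth); the depth
    histogram has :data:`DEPTH_HIST_BINS` equal-width bins on
    [0, 5 x genome mean] with all deeper windows merged into the top
    bin. ``sub5x_mean`` averages windows below the cap (the dashed
    mean line of the report figure) and ``breadth`` is the fraction of
    windows outside the lowest (~0x) bin.
    """

    window_size: int
    windows: pd.DataFrame
    genome_mean: float
    sub5x_mean: float
    breadth: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    skipped_contigs: Tuple[str, ...] = ()
    count_mode: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


def coverage_windows(bam_path: Union[str, Path],
                     options: Optional[AnalysisOptions] = None,
                     ) -> CoverageSummary:
    """Depth in consecutive non-overlapping windows of W bp.

    Each non-excluded contig is partitioned into floor(len/W) windows;
    trailing partial windows are dropped so every window is normalised
    identically. Per-window depth is the aligned-base count overlapping
    the window divided by W, or a read count in ``count_mode``
    (read starts in the window by default, overlapping reads with
    ``coverage_overlap_counts``). Record retention matches
    :func:`adnaqc.ingest.load_alignments`.
    """
    options = options or AnalysisOptions()
    w = options.window_size
    contigs, starts, depth_arrays = [], [], []
    skipped = []
    with open_indexed_bam(bam_path) as bam:
        for contig, clen in zip(bam.references, bam.lengths):
            if contig in options.excluded_contigs:
                continue
            n_win = clen // w
            if n_win == 0:
                skipped.append(contig)
                continue
            span = n_win * w
            totals = np.zeros(n_win, dtype=np.float64)
            for rec in bam.fetch(contig):
                if _retention_reason(rec, options) is not None:
                    continue
                if options.count_mode:
                    if options.coverage_overlap_counts:
                        first = rec.reference_start // w
                        last = min(rec.reference_end - 1, span - 1) // w
                        if rec.reference_start < span:
                            totals[first:last + 1] += 1
                    elif rec.reference_start < span:
                        totals[rec.reference_start // w] += 1
                    continue
                for bs, be in rec.get_blocks():
                    be = min(be, span)
                    if bs >= be:
                        continue
                    wi = bs // w
                    while bs < be:
                        edge = min(be, (wi + 1) * w)
                        totals[wi] += edge - bs
                        bs = edge
                        wi += 1
            depths = totals if options.count_mode else totals / w
            contigs.extend([contig] * n_win)
            starts.extend(range(0, span, w))
            depth_arrays.append(depths)
    if skipped:
        logger.info("coverage: %d contig(s) shorter than window size %d "
                    "contributed no windows: %s", len(skipped), w, skipped[:5])
    depths = (np.concatenate(depth_arrays) if depth_arrays
              else np.zeros(0, dtype=np.float64))
    windows = pd.DataFrame({"contig": contigs, "window_start": starts,
                            "depth": depths})
    if depths.size == 0:
        return CoverageSummary(w, windows, 0.0, 0.0, 0.0,
                               np.zeros(DEPTH_HIST_BINS, dtype=int),
                               np.linspace(0, 1, DEPTH_HIST_BINS + 1),
                               tuple(skipped), options.count_mode)
    genome_mean = float(depths.mean())
    cap = 5.0 * genome_mean
    if cap <= 0:
        hist = np.zeros(DEPTH_HIST_BINS, dtype=int)
        hist[0] = depths.size
        edges = np.linspace(0, 1, DEPTH_HIST_BINS + 1)
        return CoverageSummary(w, windows, 0.0, 0.0, 0.0, hist, edges,
                               tuple(skipped), options.count_mode)
    edges = np.linspace(0.0, cap, DEPTH_HIST_BINS + 1)
    hist, _ = np.histogram(np.clip(depths, 0, cap), bins=edges)
    below = depths[depths < cap]
    sub5x_mean = float(below.mean()) if below.size else genome_mean
    breadth = float((depths >= edges[1]).mean())
    return CoverageSummary(w, windows, genome_mean, sub5x_mean, breadth,
                           hist, edges, tuple(skipped), options.count_mode)
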