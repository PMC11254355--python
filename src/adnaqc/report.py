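"""Comparative four-panel QC report for up to six samples.

Runs all four statistics on each sample in a single pass over its BAM,
writes per-sample per-panel TSVs, a drop-reason tally, a JSON run
manifest and a plain-text log, and renders the comparative four-panel
figure (mismatch-by-length, damage profile, fragment-length
distribution, capped depth histogram with dashed per-sample mean
lines).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .ingest import AnalysisOptions, DropTally, load_alignments
from .panels import (CoverageSummary, DamageAccumulator, DamageProfile,
                     LengthHistogram, MismatchAccumulator, MismatchProfile,
                     coverage_windows)

logger = logging.getLogger("adnaqc")

MAX_SAMPLES = 6

#: Okabe-Ito colourblind-safe cycle, assigned by sample order
SAMPLE_COLORS = ("#0072B2", "#D55E00", "#009E73", "#CC79A7",
                 "#E69F00", "#56B4E9")

DAMAGE_STYLES = {"noncpg_ct": "-", "cpg_ct": "--", "other": ":"}


def configure_logging(level: Union[int, str] = logging.INFO,
                      logfile: Optional[Union[str, Path]] = None) -> None:
    """Route package logging to stderr and optionally a file."""
    root = logging.getLogger("adnaqc")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile, mode="w")
        fh.setFormatter(fmt)
        root.addHandler(fh)


@dataclass
class Sample:
    label: str
    bam_path: Path
    overrides: Dict = field(default_factory=dict)

    def options(self, base: AnalysisOptions) -> AnalysisOptions:
        return base.updated(**self.overrides) if self.overrides else base


class SampleSet:
    """An ordered set of 1-6 uniquely labelled samples."""

    def __init__(self, samples: Sequence[Sample]):
        if len(samples) == 0:
            raise ValueError("at least one sample is required")
        if len(samples) > MAX_SAMPLES:
            raise ValueError(
                f"a maximum of {MAX_SAMPLES} samples is supported, "
                f"got {len(samples)}")
        labels = [s.label for s in samples]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        self.samples = list(samples)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)

    @classmethod
    def from_list_file(cls, path: Union[str, Path]) -> "SampleSet":
        """Two-column text file: label <tab/space> BAM path; a line with
        a single column is a path labelled by its basename."""
        samples = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) == 1:
                p = Path(parts[0])
                samples.append(Sample(label=p.stem, bam_path=p))
            else:
                samples.append(Sample(label=parts[0],
                                      bam_path=Path(parts[1].strip())))
        return cls(samples)


@dataclass
class SampleResult:
    label: str
    mismatch: MismatchProfile
    damage: DamageProfile
    lengths: LengthHistogram
    coverage: CoverageSummary
    drop_tally: DropTally
    n_retained: int


def analyze_sample(sample: Sample, options: AnalysisOptions) -> SampleResult:
    """All four panels for one sample; the three read-stream panels share
    a single pass over the BAM."""
    opts = sample.options(options)
    tally = DropTally()
    mism = MismatchAccumulator(length_cap=opts.length_cap,
                               pooled=opts.pooled_rates)
    dmg = DamageAccumulator(k=opts.damage_positions,
                            strict_exclusions=opts.strict_damage_exclusions,
                            per_read=opts.per_read_damage)
    lens = LengthHistogram()
    n = 0
    for obs in load_alignments(sample.bam_path, opts, sample.label, tally):
        n += 1
        mism.add(obs)
        dmg.add(obs)
        lens.counts[obs.length] += 1
    if n == 0:
        logger.warning("sample %s: zero retained reads; panels will be empty",
                       sample.label)
    cov = coverage_windows(sample.bam_path, opts)
    return SampleResult(sample.label, mism.finalize(), dmg.finalize(),
                        lens, cov, tally, n)


def run_report(samples: Union[SampleSet, Sequence[Sample]],
               options: Optional[AnalysisOptions] = None,
               out_dir: Union[str, Path] = ".",
               figure: bool = True,
               figure_name: str = "qc_report") -> List[SampleResult]:
    """Compute and write the full comparative report.

    Writes ``<label>.{mismatch,damage,lengths,coverage,drops}.tsv`` per
    sample, ``manifest.json``, ``run.log`` and (unless disabled) the
    four-panel figure as SVG and PNG. TSV contents are exactly the
    per-panel module outputs.
    """
    if not isinstance(samples, SampleSet):
        samples = SampleSet(list(samples))
    options = options or AnalysisOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    configure_logging(logging.INFO, out_dir / "run.log")

    results = []
    for sample in samples:
        logger.info("analysing %s (%s)", sample.label, sample.bam_path)
        res = analyze_sample(sample, options)
        results.append(res)
        res.mismatch.write_tsv(out_dir / f"{res.label}.mismatch.tsv")
        res.damage.write_tsv(out_dir / f"{res.label}.damage.tsv")
        res.lengths.write_tsv(out_dir / f"{res.label}.lengths.tsv")
        res.coverage.write_tsv(out_dir / f"{res.label}.coverage.tsv")
        res.drop_tally.write_tsv(out_dir / f"{res.label}.drops.tsv")
        logger.info("%s: %d retained reads, genome mean depth %.4g, "
                    "breadth %.3f", res.label, res.n_retained,
                    res.coverage.genome_mean, res.coverage.breadth)

    manifest = {
        "tool": "adnaqc",
        "version": __version__,
        "samples": [{"label": s.label, "bam": str(s.bam_path),
                     "overrides": s.overrides} for s in samples],
        "options": dataclasses.asdict(options.updated(
            excluded_contigs=frozenset())) | {
            "excluded_contigs": sorted(options.excluded_contigs)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str) + "\n")
    if figure:
        fig = render_figure(results, options)
        fig.savefig(out_dir / f"{figure_name}.svg")
        fig.savefig(out_dir / f"{figure_name}.png", dpi=150)
        plt.close(fig)
    return results


# ---------------------------------------------------------------------------
# figure
# ---------------------------------------------------------------------------

def render_figure(results: Sequence[SampleResult],
                  options: Optional[AnalysisOptions] = None) -> plt.Figure:
    """Render the comparative four-panel figure."""
    options = options or AnalysisOptions()
    fig, axes = plt.subplots(2, 2, figsize=(11, 8.5))
    ax_m, ax_d, ax_l, ax_c = axes.ravel()

    for i, res in enumerate(results):
        color = SAMPLE_COLORS[i % len(SAMPLE_COLORS)]
        _plot_mismatch(ax_m, res, color, options.error_bars)
        _plot_damage(ax_d, res, color)
        _plot_lengths(ax_l, res, color)
        _plot_coverage(ax_c, res, color)

    ax_m.set_xlabel("read length (bp)")
    ax_m.set_ylabel("mismatches per bp")
    ax_m.set_title("Edit distance by read length")
    if ax_m.get_legend_handles_labels()[0]:
        ax_m.legend(fontsize=8)

    ax_d.set_xlabel("read position (5' left, 3' right)")
    ax_d.set_ylabel("substitution fraction")
    ax_d.set_title("Damage profile (solid non-CpG C>T, dashed CpG C>T, "
                   "dotted other)")

    ax_l.set_xlabel("read length (bp)")
    ax_l.set_ylabel("fraction of reads")
    ax_l.set_title("Fragment length distribution")
    if ax_l.get_legend_handles_labels()[0]:
        ax_l.legend(fontsize=8)

    ax_c.set_xlabel("window depth (capped at 5x genome mean)")
    ax_c.set_ylabel("fraction of windows")
    ax_c.set_title(f"Coverage in {options.window_size} bp windows "
                   "(dashed line: mean depth)")
    fig.tight_layout()
    return fig


def _plot_mismatch(ax, res, color, error_bars):
    df = res.mismatch.to_frame()
    if df.empty:
        return
    if error_bars:
        ax.errorbar(df["length"], df["rate"], yerr=df["stderr"],
                    color=color, label=res.label, lw=1, elinewidth=0.5)
    else:
        ax.plot(df["length"], df["rate"], color=color, label=res.label, lw=1)


def _plot_damage(ax, res, color):
    prof = res.damage
    k = prof.k
    # x axis: 5' positions 1..K, a spacer, then 3' positions -K..-1
    xmap = {p: (p - 1 if p > 0 else 2 * k + p + k + 2) for p in prof.positions}
    for cls, style in DAMAGE_STYLES.items():
        xs, ys = [], []
        for p in prof.positions:
            frac = prof.fraction(p, cls)
            if frac is not None:
                xs.append(xmap[p])
                ys.append(frac)
        if xs:
            five = [(x, y) for x, y in zip(xs, ys) if x < k]
            three = [(x, y) for x, y in zip(xs, ys) if x >= k]
            for seg in (five, three):
                if seg:
                    ax.plot([x for x, _ in seg], [y for _, y in seg],
                            style, color=color, lw=1)
    ticks = [0, k - 1, 2 * k + 2, 3 * k + 1]
    ax.set_xticks(ticks)
    ax.set_xticklabels(["1", str(k), f"-{k}", "-1"])


def _plot_lengths(ax, res, color):
    df = res.lengths.to_frame()
    if df.empty:
        return
    ax.plot(df["length"], df["fraction"], color=color, label=res.label, lw=1)
    ax.fill_between(df["length"], df["fraction"], alpha=0.2, color=color)


def _plot_coverage(ax, res, color):
    cov = res.coverage
    if cov.n_windows == 0:
        return
    centers = 0.5 * (cov.hist_edges[:-1] + cov.hist_edges[1:])
    ax.step(centers, cov.hist_counts / cov.n_windows, where="mid",
            color=color, lw=1, label=res.label)
    ax.axvline(cov.sub5x_mean, color=color, ls="--", lw=1)
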