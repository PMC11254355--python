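import numpy as np
import pysam
import pytest

from adnaqc import (AnalysisOptions, LibrarySpec, ReadObservation,
                    compose_library, synthesize_genome, write_truth_bam)


def make_bam(path, references, records):
    """Write a sorted, indexed BAM from bare record dicts.

    ``references`` is [(name, length), ...]; each record dict may set
    qname, flag, ref (name or None for unmapped), pos, mapq, cigar
    (string), seq, nm, md, and extra ``tags``.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": ln} for n, ln in references]}
    ref_index = {n: i for i, (n, _) in enumerate(references)}
    segs = []
    for rec in records:
        a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
        a.query_name = rec.get("qname", f"read{len(segs)}")
        a.flag = rec.get("flag", 0)
        ref = rec.get("ref")
        a.reference_id = ref_index[ref] if ref is not None else -1
        a.reference_start = rec.get("pos", 0) if ref is not None else -1
        a.mapping_quality = rec.get("mapq", 60)
        if "cigar" in rec:
            a.cigarstring = rec["cigar"]
        seq = rec.get("seq")
        if seq:
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        tags = []
        if "nm" in rec:
            tags.append(("NM", rec["nm"], "i"))
        if "md" in rec:
            tags.append(("MD", rec["md"], "Z"))
        tags.extend(rec.get("tags", ()))
        if tags:
            a.set_tags(tags)
        segs.append(a)
    segs.sort(key=lambda a: (a.reference_id if a.reference_id >= 0 else 1 << 30,
                             a.reference_start))
    path = str(path)
    with pysam.AlignmentFile(path, "wb",
                             header=pysam.AlignmentHeader.from_dict(header)) as bam:
        for a in segs:
            bam.write(a)
    pysam.index(path)
    return path


def make_obs(read_seq, ref_seq, strand="+", nm=None, length=None,
             deletions=(), **kwargs):
    """ReadObservation from explicit read/reference strings."""
    if nm is None:
        nm = sum(1 for r, f in zip(read_seq, ref_seq)
                 if f != "-" and r != f)
    defaults = dict(sample_id="t", query_name="q", length=len(read_seq),
                    edit_distance=nm, mapq=60, strand=strand, contig="c1",
                    start=0, has_indel=False, has_clip=False,
                    has_unknown_base=not set(read_seq) <= set("ACGT"),
                    read_seq=read_seq, ref_seq_aligned=ref_seq,
                    deletions=tuple(deletions))
    defaults.update(kwargs)
    return ReadObservation(**defaults)


@pytest.fixture(scope="session")
def genome():
    return synthesize_genome(2, 20_000, 0.41, seed=7)


@pytest.fixture(scope="session")
def diverged_truth_bam(genome, tmp_path_factory):
    """2%-divergence endogenous library placed at its origins."""
    spec = LibrarySpec(composition=(1.0, 0.0, 0.0), divergence=0.02,
                       length_range=(30, 60), n_per_bin=120, seed=13)
    frags = compose_library(spec, genome)
    path = tmp_path_factory.mktemp("sim") / "diverged.bam"
    write_truth_bam(frags, genome, path)
    return path, frags


@pytest.fixture
def default_options():
    return AnalysisOptions()
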