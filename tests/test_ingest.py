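"""Reference reconstruction, substitution classification and BAM filtering."""

import pysam
import pytest
from hypothesis import given, settings, strategies as st

from adnaqc import (AnalysisOptions, DropTally, MDError,
                    classify_substitutions, load_alignments,
                    parse_provenance, reconstruct_reference, revcomp)
from adnaqc.ingest import observation_from_record

from conftest import make_bam, make_obs


class TestReconstructReference:
    @pytest.mark.parametrize("read,cigar,md,expect_ref,expect_dels", [
        ("ACGT", "4M", "4", "ACGT", ()),                 # all-match
        ("ACGT", "4M", "1G2", "AGGT", ()),               # mismatch names ref
        ("ACGT", "2M1I1M", "3", "AC-T", ()),             # insertion gap
        ("ACGT", "2M1D2M", "2^T2", "ACGT", ((2, "T"),)),  # deletion recorded
        ("ACGT", "2S2M", "2", "--GT", ()),               # clip gap, no MD
        ("ACGT", "1M2I1M", "0A1", "A--T", ()),           # leading 0-run
    ])
    def test_examples(self, read, cigar, md, expect_ref, expect_dels):
        ref, dels = reconstruct_reference(read, cigar, md)
        assert ref == expect_ref
        assert dels == expect_dels

    def test_accepts_pysam_cigartuples(self):
        ref, _ = reconstruct_reference("ACGT", [(0, 2), (1, 1), (0, 1)], "3")
        assert ref == "AC-T"

    @pytest.mark.parametrize("read,cigar,md", [
        ("ACGT", "4M", "3"),        # MD exhausted early
        ("ACGT", "4M", "5"),        # MD run left over
        ("ACGT", "4M", "2^A2"),     # deletion where aligned expected
        ("ACGT", "2M1D2M", "4"),    # missing deletion token
        ("ACGT", "2M1D2M", "2^TT2"),  # deletion length mismatch
        ("ACGT", "3M", "3"),        # CIGAR does not consume the read
    ])
    def test_inconsistency_rejected(self, read, cigar, md):
        with pytest.raises(MDError):
            reconstruct_reference(read, cigar, md)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_random_alignments_roundtrip(self, data):
        """Build a random gapped alignment, derive its CIGAR and MD, and
        require reconstruction to return the known reference."""
        bases = "ACGT"
        segs = data.draw(st.lists(
            st.tuples(st.sampled_from(["match", "mismatch", "ins", "del"]),
                      st.integers(1, 5)),
            min_size=1, max_size=8))
        # an alignment must start and end with an aligned base and never
        # put a deletion adjacent to an insertion
        read, ref, cigar, md_parts, dels = [], [], [], [], []
        run = 0
        qpos = 0

        def flush_run():
            nonlocal run
            md_parts.append(str(run))
            run = 0

        prev = None
        for kind, n in segs:
            if kind in ("ins", "del") and prev in ("ins", "del", None):
                kind = "match"
            if kind == "match":
                s = data.draw(st.text(bases, min_size=n, max_size=n))
                read.append(s)
                ref.append(s)
                cigar.append(f"{n}M")
                run += n
                qpos += n
            elif kind == "mismatch":
                for _ in range(n):
                    rb = data.draw(st.sampled_from(bases))
                    fb = data.draw(st.sampled_from(
                        [b for b in bases if b != rb]))
                    read.append(rb)
                    ref.append(fb)
                    flush_run()
                    md_parts.append(fb)
                    qpos += 1
                cigar.append(f"{n}M")
            elif kind == "ins":
                s = data.draw(st.text(bases, min_size=n, max_size=n))
                read.append(s)
                ref.append("-" * n)
                cigar.append(f"{n}I")
                qpos += n
            else:
                s = data.draw(st.text(bases, min_size=n, max_size=n))
                flush_run()
                md_parts.append("^" + s)
                cigar.append(f"{n}D")
                dels.append((qpos, s))
            prev = kind
        if prev in ("ins", "del"):
            read.append("A")
            ref.append("A")
            cigar.append("1M")
            run += 1
        flush_run()
        got_ref, got_dels = reconstruct_reference(
            "".join(read), "".join(cigar), "".join(md_parts))
        assert got_ref == "".join(ref)
        assert got_dels == tuple(dels)


class TestClassifySubstitutions:
    @pytest.mark.parametrize("ref,read,strand,pos,cls", [
        ("ACGT", "ATGT", "+", 2, "cpg_ct"),     # ref C followed by ref G
        ("ACAT", "ATAT", "+", 2, "noncpg_ct"),
        ("ACGT", "AAGT", "+", 2, "other"),
        ("GA", "AA", "-", 2, "noncpg_ct"),      # revcomp: ref TC, read TT
    ])
    def test_examples(self, ref, read, strand, pos, cls):
        obs = make_obs(read, ref, strand=strand)
        assert (pos, cls) in classify_substitutions(obs)

    def test_match_positions_reported(self):
        obs = make_obs("ACGT", "ACGT")
        assert classify_substitutions(obs) == [
            (1, "match"), (2, "match"), (3, "match"), (4, "match")]

    def test_terminal_reference_c_is_noncpg(self):
        # no following base within the read: cannot see CpG context
        obs = make_obs("AT", "AC")
        assert classify_substitutions(obs) == [(1, "match"), (2, "noncpg_ct")]

    def test_unknown_base_positions_classless(self):
        obs = make_obs("ANTG", "AACG")
        assert classify_substitutions(obs) == [
            (1, "match"), (3, "cpg_ct"), (4, "match")]

    def test_cpg_context_looks_across_insertion(self):
        # gap consumes no reference: the next ref base is still G
        obs = make_obs("TAG", "C-G", has_indel=True)
        assert (1, "cpg_ct") in classify_substitutions(obs)

    def test_cpg_context_uses_deleted_base(self):
        # deletion after the C: the true next reference base was deleted
        obs = make_obs("TA", "CA", deletions=((1, "G"),), has_indel=True)
        assert classify_substitutions(obs)[0] == (1, "cpg_ct")

    def test_reverse_strand_g_to_a_counts_as_ct(self):
        # stored (reference-orientation) C->A event; in molecule
        # orientation the ref is ACG and the read ATG: a CpG C->T
        obs = make_obs("CAT", "CGT", strand="-")
        assert classify_substitutions(obs) == [
            (1, "match"), (2, "cpg_ct"), (3, "match")]


class TestLoadAlignments:
    REFS = [("chr1", 10_000), ("chrM", 10_000)]

    def _records(self):
        base = dict(ref="chr1", seq="ACGTACGTAC", cigar="10M",
                    nm=0, md="10", mapq=37)
        return base

    def test_flag_filtering(self, tmp_path):
        base = self._records()
        bam = make_bam(tmp_path / "a.bam", self.REFS, [
            dict(base, qname="ok1", pos=100),
            dict(base, qname="ok2", pos=200),
            dict(base, qname="ok3", pos=300),
            dict(base, qname="unmapped", ref=None, flag=4),
            dict(base, qname="dup", pos=400, flag=1024),
            dict(base, qname="secondary", pos=500, flag=256),
            dict(base, qname="suppl", pos=600, flag=2048),
        ])
        tally = DropTally()
        obs = list(load_alignments(bam, AnalysisOptions(mq_min=1),
                                   tally=tally))
        assert sorted(o.query_name for o in obs) == ["ok1", "ok2", "ok3"]
        assert tally == {"unmapped": 1, "duplicate": 1, "secondary": 1,
                         "supplementary": 1}

    def test_mapq_threshold(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", self.REFS,
                       [dict(self._records(), pos=10, mapq=20)])
        tally = DropTally()
        assert list(load_alignments(bam, AnalysisOptions(mq_min=25),
                                    tally=tally)) == []
        assert tally == {"mapq": 1}

    def test_excluded_contig(self, tmp_path):
        base = self._records()
        bam = make_bam(tmp_path / "a.bam", self.REFS, [
            dict(base, qname="keep", pos=10),
            dict(base, qname="mito", ref="chrM", pos=10),
        ])
        obs = list(load_alignments(
            bam, AnalysisOptions(excluded_contigs=frozenset({"chrM"}))))
        assert [o.query_name for o in obs] == ["keep"]

    def test_missing_tags_skipped_with_tally(self, tmp_path):
        rec = dict(ref="chr1", pos=5, seq="ACGT", cigar="4M", mapq=30)
        bam = make_bam(tmp_path / "a.bam", self.REFS, [rec])
        tally = DropTally()
        assert list(load_alignments(bam, tally=tally)) == []
        assert tally == {"missing_tag": 1}

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            list(load_alignments(tmp_path / "nope.bam"))

    def test_unindexed_bam_fatal(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", self.REFS,
                       [dict(self._records(), pos=10)])
        (tmp_path / "a.bam.bai").unlink()
        with pytest.raises(ValueError, match="samtools index"):
            list(load_alignments(bam))

    def test_observation_fields(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", self.REFS, [
            dict(qname="r", ref="chr1", pos=42, flag=16, mapq=33,
                 seq="ACGTAAGTAC", cigar="10M", nm=1, md="2G7"),
        ])
        (obs,) = load_alignments(bam)
        assert obs.strand == "-" and obs.start == 42 and obs.mapq == 33
        assert obs.edit_distance == 1 and obs.length == 10
        assert obs.ref_seq_aligned == "ACGTAAGTAC"[:2] + "G" + "TAAGTAC"


class TestSimulatedOracles:
    def test_reconstruction_matches_genome_and_pysam(self, genome,
                                                     diverged_truth_bam):
        """Round trip: MD-based reconstruction equals the genome slice and
        pysam's own MD-based reference for every simulated read."""
        bam_path, _ = diverged_truth_bam
        n = 0
        with pysam.AlignmentFile(str(bam_path)) as bam:
            for rec in bam.fetch():
                obs = observation_from_record(rec)
                prov = parse_provenance(rec.query_name)
                assert obs.ref_seq_aligned == genome.slice(
                    prov.contig, prov.start, prov.end)
                assert obs.ref_seq_aligned == rec.get_reference_sequence().upper()
                n += 1
        assert n > 1000

    def test_substitution_count_matches_nm(self, diverged_truth_bam):
        """For indel/clip-free reads the classified non-match count equals
        the NM edit distance."""
        bam_path, _ = diverged_truth_bam
        for obs in load_alignments(bam_path):
            mismatches = sum(1 for _, cls in classify_substitutions(obs)
                             if cls != "match")
            assert mismatches == obs.edit_distance

    def test_strand_symmetry(self, genome, tmp_path):
        """The same molecule drawn from the opposite strand classifies
        identically: mirror the genome (reverse-complement every contig)
        so each fragment's placement flips strand while the molecule and
        its substitutions are untouched."""
        import dataclasses
        from adnaqc import (SyntheticGenome, inject_divergence,
                            sample_fragments, write_truth_bam)
        import numpy as np
        rng = np.random.default_rng(3)
        frags = [inject_divergence(f, 0.05, rng)
                 for f in sample_fragments(genome, 40, 40, 50, rng=rng)]
        mirror = SyntheticGenome(
            contigs={c: revcomp(s) for c, s in genome.contigs.items()},
            gc=genome.gc, seed=genome.seed)
        mirrored = []
        for f in frags:
            n = len(genome.contigs[f.contig])
            start, end = n - f.end, n - f.start
            strand = "-" if f.strand == "+" else "+"
            mirrored.append(dataclasses.replace(
                f, start=start, end=end, strand=strand,
                name=f.name.rsplit("|")[-1] and
                     f"endogenous|{f.contig}|{start}|{end}|{strand}|"
                     f"{f.name.rsplit('|', 1)[1]}"))
        fwd_bam = tmp_path / "fwd.bam"
        rev_bam = tmp_path / "rev.bam"
        write_truth_bam(frags, genome, fwd_bam)
        write_truth_bam(mirrored, mirror, rev_bam)
        key = lambda o: o.query_name.rsplit("|", 1)[1]
        fwd = {key(o): classify_substitutions(o)
               for o in load_alignments(fwd_bam)}
        rev = {key(o): classify_substitutions(o)
               for o in load_alignments(rev_bam)}
        assert len(fwd) == len(rev) == 50
        assert fwd == rev
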