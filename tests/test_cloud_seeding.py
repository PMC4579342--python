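"""Cloud seeding: clustering, end-marker splitting, abbreviated reference,
pass-2 domain collection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfaligner.cloud_seeding import (
    CandidateAlignment,
    Pass1Alignment,
    build_abbreviated_reference,
    cluster_pass1,
    collect_pass2,
    seed_clouds,
    split_on_end_markers,
)
from .conftest import random_seq


def p1(i, start, chrom="chr1", marker=False, rlen=100):
    return Pass1Alignment(f"r{i}", chrom, start, end_marker=marker,
                          read_length=rlen)


def brute_single_linkage(starts, max_gap):
    """O(n^2) transitive closure of |s_i - s_j| <= max_gap."""
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[i] - starts[j]) <= max_gap:
                pi, pj = find(i), find(j)
                parent[pi] = pj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestClusterPass1:
    def test_six_reads_within_gap_form_one_cloud(self):
        alns = [p1(i, s) for i, s in enumerate((0, 500, 1000, 1500, 2000, 2500))]
        clouds = cluster_pass1(alns, max_gap=3500, min_reads=6)
        assert len(clouds) == 1
        assert clouds[0].member_read_ids == {f"r{i}" for i in range(6)}
        assert clouds[0].start == 0 and clouds[0].end == 2600

    def test_below_min_reads_yields_no_cloud(self):
        alns = [p1(i, s) for i, s in enumerate((0, 10, 4000, 8000, 12000))]
        assert cluster_pass1(alns, min_reads=6) == []

    def test_gap_just_over_threshold_breaks_link(self):
        alns = [p1(i, s) for i, s in enumerate((0, 3500, 7001))]
        clouds = cluster_pass1(alns, max_gap=3500, min_reads=1)
        groups = sorted(tuple(sorted(c.member_read_ids)) for c in clouds)
        assert groups == [("r0", "r1"), ("r2",)]

    def test_empty_input(self):
        assert cluster_pass1([]) == []

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 50_000), min_size=0, max_size=120),
           st.integers(1, 5000))
    def test_matches_brute_force_transitive_closure(self, starts, max_gap):
        """Single-linkage equivalence against the O(n^2) oracle."""
        alns = [p1(i, s) for i, s in enumerate(starts)]
        clouds = cluster_pass1(alns, max_gap=max_gap, min_reads=1)
        got = sorted(
            tuple(sorted(int(r[1:]) for r in c.member_read_ids)) for c in clouds
        )
        assert got == brute_single_linkage(starts, max_gap)

    def test_idempotent_and_disjoint(self, rng):
        starts = rng.integers(0, 200_000, size=300)
        alns = [p1(i, int(s)) for i, s in enumerate(starts)]
        clouds = cluster_pass1(alns, min_reads=1)
        seen = set()
        for c in clouds:
            assert not (c.member_read_ids & seen)  # at most one cloud per read
            seen |= c.member_read_ids
            members = [a for a in alns if a.read_id in c.member_read_ids]
            again = cluster_pass1(members, min_reads=1)
            assert len(again) == 1
            assert again[0].member_read_ids == c.member_read_ids


class TestSplitOnEndMarkers:
    def _cloud(self, alns, **kw):
        clouds = cluster_pass1(alns, min_reads=kw.pop("min_reads", 6))
        assert len(clouds) == 1
        return clouds[0]

    def test_no_interior_markers_unchanged(self):
        alns = [p1(i, 200 * i) for i in range(8)]
        cloud = self._cloud(alns)
        out = split_on_end_markers(cloud, alns)
        assert len(out) == 1
        assert out[0].member_read_ids == cloud.member_read_ids

    def test_interior_marker_with_clean_junction_splits(self):
        left = [p1(i, 500 * i) for i in range(8)]          # 0..3500
        marker = [p1(100, 4000, marker=True)]
        right = [p1(10 + i, 4600 + 400 * i) for i in range(8)]  # 4600..7400
        alns = left + marker + right
        cloud = self._cloud(alns)
        out = split_on_end_markers(cloud, alns)
        assert len(out) == 2
        lc, rc = sorted(out, key=lambda c: c.start)
        assert lc.end == 4100 and lc.right_marker
        assert rc.start == 4600 and rc.left_marker
        assert {a.read_id for a in left + marker} == lc.member_read_ids
        assert {a.read_id for a in right} == rc.member_read_ids

    def test_straddled_junction_does_not_split(self):
        """Reads immediately after the marker (overlapping fragments) veto
        the split; the collision detector handles the cloud instead."""
        left = [p1(i, 500 * i) for i in range(8)]
        marker = [p1(100, 4000, marker=True)]
        right = [p1(10 + i, 4050 + 400 * i) for i in range(8)]
        alns = left + marker + right
        out = split_on_end_markers(self._cloud(alns), alns)
        assert len(out) == 1

    def test_boundary_marker_sets_flag_without_split(self):
        alns = [p1(i, 200 * i) for i in range(8)] + [p1(9, 50, marker=True)]
        out = split_on_end_markers(self._cloud(alns), alns)
        assert len(out) == 1
        assert out[0].left_marker and not out[0].right_marker


class TestAbbreviatedReference:
    def test_contigs_match_clouds_and_reference_substring(self, rng):
        ref = {"chr1": random_seq(rng, 30_000)}
        alns = [p1(i, 1000 + 300 * i) for i in range(8)]
        alns += [p1(20 + i, 20_000 + 300 * i) for i in range(8)]
        clouds = seed_clouds(alns)
        assert len(clouds) == 2
        ab = build_abbreviated_reference(clouds, ref, pad=500)
        assert len(ab.contigs) == len(clouds)
        for c in ab.contigs:
            assert c.sequence == ref[c.origin_chrom][
                c.origin_start : c.origin_start + len(c.sequence)
            ]

    def test_lift_round_trip_identity(self, rng):
        ref = {"chr1": random_seq(rng, 50_000)}
        alns = [p1(i, 5000 + 250 * i) for i in range(10)]
        clouds = seed_clouds(alns)
        ab = build_abbreviated_reference(clouds, ref)
        c = clouds[0]
        for g in rng.integers(c.start, c.end, size=50):
            contig, off = ab.genome_to_contig("chr1", int(g))
            assert ab.contig_to_genome(contig, off) == ("chr1", int(g))

    def test_out_of_bounds_cloud_clipped(self, rng, caplog):
        ref = {"chr1": random_seq(rng, 5000)}
        alns = [p1(i, 4000 + 120 * i) for i in range(8)]
        clouds = seed_clouds(alns)
        ab = build_abbreviated_reference(clouds, ref, pad=2000)
        assert all(
            c.origin_start >= 0
            and c.origin_start + len(c.sequence) <= 5000
            for c in ab.contigs
        )


class TestCollectPass2:
    def _setup(self, rng, n_contigs=2):
        ref = {"chr1": random_seq(rng, 40_000)}
        alns = []
        for k in range(n_contigs):
            alns += [p1(100 * k + i, 15_000 * k + 300 * i) for i in range(8)]
        clouds = seed_clouds(alns)
        ab = build_abbreviated_reference(clouds, ref)
        return ab

    def _aln(self, cloud, off, score=0.0, strand="+"):
        return CandidateAlignment(
            contig_id=cloud, contig_name=f"cloud{cloud}", offset=off,
            strand=strand, score=score,
        )

    def test_cap_and_high_copy_flag(self, rng):
        ab = self._setup(rng)
        reads = {"x": ("A" * 50, np.full(50, 30), False)}
        alns = {"x": [self._aln(0, 10 * i, score=-float(i)) for i in range(20)]}
        frags = collect_pass2(reads, ab, alns, max_alignments=15)
        assert frags[0].k == 15 and frags[0].high_copy
        # truncation keeps the highest-scoring candidates
        assert [a.offset for a in frags[0].alignments] == [10 * i for i in range(15)]

    def test_single_and_unmapped(self, rng):
        ab = self._setup(rng)
        reads = {
            "one": ("A" * 50, np.full(50, 30), False),
            "none": ("C" * 50, np.full(50, 30), False),
        }
        alns = {"one": [self._aln(1, 5)]}
        frags = {f.read_id: f for f in collect_pass2(reads, ab, alns)}
        assert frags["one"].k == 1 and not frags["one"].high_copy
        assert frags["none"].k == 0

    def test_unknown_contig_is_hard_error(self, rng):
        ab = self._setup(rng)
        reads = {"x": ("A" * 50, np.full(50, 30), False)}
        bad = CandidateAlignment(contig_id=99, contig_name="cloud99",
                                 offset=0, strand="+", score=0.0)
        with pytest.raises(ValueError, match="unknown contig"):
            collect_pass2(reads, ab, {"x": [bad]})


class TestSamLoaders:
    def _write_sam(self, path, refs, records):
        import pysam

        header = pysam.AlignmentHeader.from_references(
            [r[0] for r in refs], [r[1] for r in refs]
        )
        with pysam.AlignmentFile(str(path), "w", header=header) as f:
            for name, ref_id, pos, reverse, tags in records:
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.reference_id = ref_id
                a.reference_start = pos
                a.flag = 16 if reverse else 0
                a.query_sequence = "A" * 50
                a.cigarstring = "50M"
                a.mapping_quality = 30
                for k, v in tags:
                    a.set_tag(k, v)
                f.write(a)

    def test_pass1_from_sam(self, tmp_path):
        from rfaligner.cloud_seeding import pass1_from_sam

        p = tmp_path / "p1.sam"
        self._write_sam(p, [("chr1", 10_000)], [
            ("r1", 0, 100, False, [("EM", 1)]),
            ("r2_EM", 0, 900, True, []),
            ("r3", 0, 500, False, []),
        ])
        alns = {a.read_id: a for a in pass1_from_sam(str(p))}
        assert alns["r1"].end_marker and alns["r2_EM"].end_marker
        assert not alns["r3"].end_marker
        assert alns["r2_EM"].strand == "-"
        assert alns["r1"].start == 100 and alns["r1"].read_length == 50

    def test_pass2_from_sam_multi_hits_share_qname(self, rng, tmp_path):
        from rfaligner.cloud_seeding import pass2_from_sam

        ab = TestCollectPass2()._setup(rng)
        names = [c.name for c in ab.contigs]
        p = tmp_path / "p2.sam"
        self._write_sam(p, [(c.name, len(c.sequence)) for c in ab.contigs], [
            ("x", 0, 10, False, [("AS", -6)]),
            ("x", 1, 10, True, [("AS", 0)]),
        ])
        out = pass2_from_sam(str(p), ab)
        assert len(out["x"]) == 2
        assert {a.contig_name for a in out["x"]} == set(names[:2])

    def test_pass2_unknown_contig_is_error(self, rng, tmp_path):
        from rfaligner.cloud_seeding import pass2_from_sam

        ab = TestCollectPass2()._setup(rng)
        p = tmp_path / "p2.sam"
        self._write_sam(p, [("nonesuch", 1000)], [("x", 0, 10, False, [])])
        with pytest.raises(ValueError, match="unknown contig"):
            pass2_from_sam(str(p), ab)
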