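"""Candidate long-molecule seeding from pass-1 alignments.

A well's reads are first aligned to the full reference allowing a single
placement per read (pass 1).  Clusters of pass-1 placements seed *candidate
clouds* — putative hidden long DNA fragments.  Each candidate cloud is cut
out of the reference as a separate contig of an *abbreviated reference*, to
which the reads are re-aligned allowing multiple placements (pass 2).  The
pass-2 hits form each read's candidate-alignment domain for the random-field
model.

Coordinates are 0-based, half-open throughout; 1-based only at SAM
boundaries.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 3500
DEFAULT_MIN_READS = 6
DEFAULT_PAD = 1000
DEFAULT_MAX_ALIGNMENTS = 15


@dataclass
class Pass1Alignment:
    """A single-placement pass-1 alignment of one read."""

    read_id: str
    chrom: str
    start: int
    strand: str = "+"
    end_marker: bool = False
    read_length: int = 100
    unique: bool = True
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for read {self.read_id}")


@dataclass
class CandidateCloud:
    """A cluster of pass-1 placements: one putative hidden long fragment."""

    cloud_id: int
    chrom: str
    start: int
    end: int
    member_read_ids: set = field(default_factory=set)
    left_marker: bool = False
    right_marker: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cloud interval must be non-empty")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    cloud_id: int
    name: str
    sequence: str
    origin_chrom: str
    origin_start: int  # genome coordinate of contig offset 0 (includes pad)
    cloud_start: int   # unpadded cloud interval, genome coords
    cloud_end: int

    def __len__(self) -> int:
        return len(self.sequence)


class AbbreviatedReference:
    """Per-well reference: one contig per candidate cloud, with a coordinate
    lift between contig offsets and genome coordinates."""

    def __init__(self, contigs: list[Contig]):
        self.contigs = list(contigs)
        self.by_name = {c.name: c for c in self.contigs}
        self.by_cloud = {c.cloud_id: c for c in self.contigs}
        # reverse lookup: per chrom, sorted (start, end, contig) on the
        # unpadded cloud intervals (disjoint by construction of clustering)
        self._rev: dict[str, tuple[list[int], list[Contig]]] = {}
        per_chrom: dict[str, list[Contig]] = {}
        for c in self.contigs:
            per_chrom.setdefault(c.origin_chrom, []).append(c)
        for chrom, cs in per_chrom.items():
            cs.sort(key=lambda c: c.cloud_start)
            self._rev[chrom] = ([c.cloud_start for c in cs], cs)

    def contig_to_genome(self, contig_name: str, offset: int) -> tuple[str, int]:
        c = self.by_name[contig_name]
        return c.origin_chrom, c.origin_start + offset

    def genome_to_contig(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Inverse lift on covered (unpadded) bases; None if uncovered."""
        if chrom not in self._rev:
            return None
        starts, cs = self._rev[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and cs[i].cloud_start <= pos < cs[i].cloud_end:
            return cs[i].name, pos - cs[i].origin_start
        return None

    def fasta_records(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        for c in self.contigs:
            yield SeqRecord(Seq(c.sequence), id=c.name, description="")


@dataclass
class CandidateAlignment:
    """One element of a read's pass-2 domain."""

    contig_id: int          # cloud id of the contig
    contig_name: str
    offset: int             # 0-based on contig
    strand: str
    score: float
    n_mismatches: int = 0
    cigar: str | None = None  # None means full-length gapless match region
    indel_events: int = 0

    def key(self) -> tuple:
        return (self.contig_id, self.offset, self.strand)


@dataclass
class ReadFragment:
    """A sequenced fragment with its observed bases/qualities and its
    candidate-alignment domain.  The 'unassigned' element of the domain is
    implicit."""

    read_id: str
    seq: str
    quals: np.ndarray  # phred ints, sequencer orientation
    end_marker: bool = False
    alignments: list[CandidateAlignment] = field(default_factory=list)
    high_copy: bool = False

    @property
    def k(self) -> int:
        return len(self.alignments)

    def __len__(self) -> int:
        return len(self.seq)


def cluster_pass1(
    alignments: list[Pass1Alignment],
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[CandidateCloud]:
    """Single-linkage clustering of pass-1 starts into candidate clouds.

    Reads whose starts are within ``max_gap`` of one another (transitively)
    on the same chromosome join one cluster; clusters with fewer than
    ``min_reads`` members are discarded.  The cloud interval is
    [min start, max start + read_length).
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    clouds: list[CandidateCloud] = []
    by_chrom: dict[str, list[Pass1Alignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.chrom, []).append(a)
    cloud_id = 0
    for chrom in sorted(by_chrom):
        alns = sorted(by_chrom[chrom], key=lambda a: (a.start, a.read_id))
        block: list[Pass1Alignment] = []
        for a in alns:
            if block and a.start - block[-1].start > max_gap:
                cloud_id = _flush(block, clouds, cloud_id, min_reads)
                block = []
            block.append(a)
        cloud_id = _flush(block, clouds, cloud_id, min_reads)
    return clouds


def _flush(block, clouds, cloud_id, min_reads) -> int:
    if len(block) >= min_reads:
        start = block[0].start
        end = max(a.start + a.read_length for a in block)
        clouds.append(
            CandidateCloud(
                cloud_id=cloud_id,
                chrom=block[0].chrom,
                start=start,
                end=end,
                member_read_ids={a.read_id for a in block},
            )
        )
        return cloud_id + 1
    return cloud_id


DEFAULT_MIN_JUNCTION_GAP = 500


def split_on_end_markers(
    cloud: CandidateCloud,
    alignments: list[Pass1Alignment],
    min_reads: int = DEFAULT_MIN_READS,
    min_junction_gap: int = DEFAULT_MIN_JUNCTION_GAP,
) -> list[CandidateCloud]:
    """Split a candidate cloud at an interior end-marker read.

    Two long fragments closer than the clustering gap merge into one
    cluster; an end-marker read strictly interior to the cloud (farther
    than one read length from both boundaries) betrays the junction.  The
    cloud is split there when both halves retain ``min_reads`` members AND
    the junction shows a coverage break (no member read starts within
    ``min_junction_gap`` bp after the marker).  A junction without a
    coverage break indicates *overlapping* fragments (a collision, handled
    by ``quality.detect_collisions``) rather than two merely adjacent
    fragments, so the cloud is left unsplit.  Markers at the cloud
    boundaries set ``left_marker``/``right_marker`` instead.
    """
    members = [a for a in alignments if a.read_id in cloud.member_read_ids]
    markers = sorted(
        (a for a in members if a.end_marker), key=lambda a: (a.start, a.read_id)
    )
    out = replace(cloud, member_read_ids=set(cloud.member_read_ids))
    for m in markers:
        if m.start <= cloud.start + m.read_length:
            out.left_marker = True
        elif m.start + m.read_length >= cloud.end - m.read_length:
            out.right_marker = True
    interior = [
        m
        for m in markers
        if cloud.start + m.read_length < m.start
        and m.start + m.read_length < cloud.end - m.read_length
    ]
    for m in interior:
        left = [a for a in members if a.start <= m.start]
        right = [a for a in members if a.start > m.start]
        if (
            len(left) >= min_reads
            and len(right) >= min_reads
            and min(a.start for a in right) - m.start >= min_junction_gap
        ):
            rlen = m.read_length
            lcloud = CandidateCloud(
                cloud_id=cloud.cloud_id,
                chrom=cloud.chrom,
                start=cloud.start,
                end=m.start + rlen,
                member_read_ids={a.read_id for a in left},
                left_marker=out.left_marker,
                right_marker=True,
            )
            rcloud = CandidateCloud(
                cloud_id=cloud.cloud_id,  # renumbered by caller
                chrom=cloud.chrom,
                start=min(a.start for a in right),
                end=cloud.end,
                member_read_ids={a.read_id for a in right},
                left_marker=True,
                right_marker=out.right_marker,
            )
            lefts = split_on_end_markers(lcloud, alignments, min_reads, min_junction_gap)
            rights = split_on_end_markers(rcloud, alignments, min_reads, min_junction_gap)
            return lefts + rights
    return [out]


def seed_clouds(
    alignments: list[Pass1Alignment],
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: int = DEFAULT_MIN_READS,
    min_junction_gap: int = DEFAULT_MIN_JUNCTION_GAP,
) -> list[CandidateCloud]:
    """cluster_pass1 followed by end-marker splitting, with cloud ids
    renumbered consecutively."""
    clouds: list[CandidateCloud] = []
    for cloud in cluster_pass1(alignments, max_gap, min_reads):
        clouds.extend(split_on_end_markers(cloud, alignments, min_reads, min_junction_gap))
    for i, c in enumerate(clouds):
        c.cloud_id = i
    return clouds


def build_abbreviated_reference(
    clouds: list[CandidateCloud],
    reference: dict[str, str],
    pad: int = DEFAULT_PAD,
) -> AbbreviatedReference:
    """Cut one contig per candidate cloud out of the reference.

    Contigs extend ``pad`` bp beyond the cloud interval (clipped to the
    chromosome) so pass-2 alignments near boundaries are not truncated.
    """
    contigs = []
    for c in clouds:
        seq = reference[c.chrom]
        chrom_len = len(seq)
        if c.start >= chrom_len or c.end > chrom_len or c.start < 0:
            logger.warning(
                "cloud %d interval [%d,%d) clipped to chromosome %s",
                c.cloud_id, c.start, c.end, c.chrom,
            )
        start = min(max(c.start, 0), chrom_len)
        end = min(c.end, chrom_len)
        pstart = max(0, start - pad)
        pend = min(chrom_len, end + pad)
        contigs.append(
            Contig(
                cloud_id=c.cloud_id,
                name=f"cloud{c.cloud_id}",
                sequence=seq[pstart:pend],
                origin_chrom=c.chrom,
                origin_start=pstart,
                cloud_start=start,
                cloud_end=end,
            )
        )
    return AbbreviatedReference(contigs)


def pass1_from_sam(path: str, marker_tag: str = "EM",
                   marker_suffix: str = "_EM") -> list[Pass1Alignment]:
    """Load single-hit pass-1 alignments from an external aligner's SAM/BAM.

    The end-marker flag is read from the ``marker_tag`` tag when present,
    falling back to a read-name suffix.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(path) as f:
        for rec in f:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            em = bool(rec.get_tag(marker_tag)) if rec.has_tag(marker_tag) \
                else rec.query_name.endswith(marker_suffix)
            out.append(
                Pass1Alignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    end_marker=em,
                    read_length=rec.query_length or len(rec.query_sequence or ""),
                    unique=rec.mapping_quality > 0,
                    score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                )
            )
    return out


def pass2_from_sam(
    path: str, abbrev_ref: AbbreviatedReference
) -> dict[str, list[CandidateAlignment]]:
    """Load multi-hit pass-2 alignments (one record per hit, shared QNAME)
    against the abbreviated reference from an external aligner."""
    import pysam

    out: dict[str, list[CandidateAlignment]] = {}
    with pysam.AlignmentFile(path) as f:
        for rec in f:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            name = rec.reference_name
            contig = abbrev_ref.by_name.get(name)
            if contig is None:
                raise ValueError(f"alignment names unknown contig {name}")
            cigar = rec.cigarstring
            indels = sum(1 for op, _ in (rec.cigartuples or []) if op in (1, 2))
            out.setdefault(rec.query_name, []).append(
                CandidateAlignment(
                    contig_id=contig.cloud_id,
                    contig_name=name,
                    offset=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    score=float(rec.get_tag("AS")) if rec.has_tag("AS") else 0.0,
                    cigar=None if cigar and set(cigar) <= set("0123456789M")
                    else cigar,
                    indel_events=indels,
                )
            )
    return out


def collect_pass2(
    reads: dict[str, tuple[str, np.ndarray, bool]],
    abbrev_ref: AbbreviatedReference,
    alignments: dict[str, list[CandidateAlignment]],
    max_alignments: int = DEFAULT_MAX_ALIGNMENTS,
) -> list[ReadFragment]:
    """Assemble each read's pass-2 domain, capped at ``max_alignments``.

    ``reads`` maps read_id -> (seq, quals, end_marker).  Domains larger
    than the cap are truncated by descending aligner score (ties: leftmost
    (contig_id, offset), then + strand) and the read is flagged
    ``high_copy`` — such reads are unlikely to be informative and are
    later excluded from potentials.
    """
    frags = []
    for read_id in sorted(reads):
        seq, quals, em = reads[read_id]
        alns = alignments.get(read_id, [])
        for a in alns:
            if a.contig_name not in abbrev_ref.by_name:
                raise ValueError(f"alignment names unknown contig {a.contig_name}")
        # dedupe on (contig, offset, strand)
        seen: dict[tuple, CandidateAlignment] = {}
        for a in alns:
            k = a.key()
            if k not in seen or a.score > seen[k].score:
                seen[k] = a
        alns = sorted(
            seen.values(),
            key=lambda a: (-a.score, a.contig_id, a.offset, a.strand != "+"),
        )
        high_copy = len(alns) > max_alignments
        frags.append(
            ReadFragment(
                read_id=read_id,
                seq=seq,
                quals=np.asarray(quals, dtype=np.int64),
                end_marker=em,
                alignments=alns[:max_alignments],
                high_copy=high_copy,
            )
        )
    return frags
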