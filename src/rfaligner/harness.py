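"""End-to-end pipeline, built-in mini multi-mapper and evaluation.

The mini-mapper is exact-seed-and-extend (gapless, <= max_mismatches
substitutions) against desk-scale references, replacing an external
short-read aligner for both the single-best pass-1 and the multi-hit
pass-2 contracts.  Seeds are tiled disjointly across the read (plus one
tail seed), so every placement with at most ``floor(L/k) - 1`` mismatches
is provably recovered; denser error placements can in principle escape, as
with any seeded aligner.

``run_well`` executes the five pipeline steps for one well: pass-1
alignment, abbreviated-reference construction, pass-2 candidate collection,
MAP inference on the molecule MRF, and confidence queries — emitting
coordinate-lifted records against the original reference.

``evaluate`` reproduces the four-way comparison used to benchmark the
method on simulations: Baseline (standard single-pass alignment), Naive
(best hit on the abbreviated reference with score-gap MAPQ), RFA (the MRF
method), and Oracle (the true hit whenever the multi-mapper returned it —
the theoretical upper limit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloud_seeding import (
    AbbreviatedReference,
    CandidateAlignment,
    CandidateCloud,
    Pass1Alignment,
    ReadFragment,
    build_abbreviated_reference,
    collect_pass2,
    seed_clouds,
)
from .prior_model import PriorConfig, WellPrior, extract_features, fit_prior
from .quality import detect_collisions, well_confidences
from .rfa_mrf import (
    UNASSIGNED,
    InferenceConfig,
    build_mrf,
    map_inference,
    molecules_from_reference,
)
from .simulator import SimRead, encode, revcomp

logger = logging.getLogger(__name__)

MATCH_SCORE_PENALTY = 6  # score = -penalty * mismatches, bowtie2-like scale
CORRECT_TOL = 5
DEFAULT_SEED_LEN = 31
DEFAULT_MAX_MISMATCHES = 5
METHODS = ("baseline", "naive", "rfa", "oracle")


@dataclass
class Hit:
    chrom: str
    pos: int
    strand: str
    mismatches: int
    score: float
    mapq: int = 0
    unique: bool = True


class KmerIndex:
    """Sorted exact k-mer index over a (multi-sequence) reference."""

    def __init__(self, reference: dict[str, str], k: int = DEFAULT_SEED_LEN):
        if k < 4 or k > 31:
            raise ValueError("seed length must be in [4, 31]")
        self.k = k
        self.names = sorted(reference)
        self.seqs = {n: encode(reference[n]) for n in self.names}
        self.lengths = {n: len(self.seqs[n]) for n in self.names}
        offs = np.cumsum([0] + [self.lengths[n] for n in self.names])
        self.chrom_offsets = offs
        codes_parts, pos_parts = [], []
        for i, n in enumerate(self.names):
            s = self.seqs[n]
            if len(s) < k:
                continue
            c = _kmer_codes(s, k)
            codes_parts.append(c)
            pos_parts.append(np.arange(len(c), dtype=np.int64) + offs[i])
        if codes_parts:
            codes = np.concatenate(codes_parts)
            pos = np.concatenate(pos_parts)
            order = np.argsort(codes, kind="stable")
            self.sorted_codes = codes[order]
            self.positions = pos[order]
        else:
            self.sorted_codes = np.empty(0, dtype=np.int64)
            self.positions = np.empty(0, dtype=np.int64)

    def _locate(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.chrom_offsets, gpos, side="right") - 1)
        return ci, gpos - int(self.chrom_offsets[ci])

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        return self.positions[lo:hi]

    def align(self, seq: str, max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> list[Hit]:
        """All gapless placements of the read (both strands) with at most
        ``max_mismatches`` substitutions reachable through an exact seed."""
        fwd = encode(seq)
        L = len(fwd)
        k = self.k
        hits: dict[tuple, Hit] = {}
        for strand, arr in (("+", fwd), ("-", revcomp(fwd))):
            if L < k:
                continue
            seed_offsets = list(range(0, L - k + 1, k))
            if seed_offsets[-1] != L - k:
                seed_offsets.append(L - k)
            seen_starts = set()
            for off in seed_offsets:
                code = _code_of(arr[off : off + k])
                for gp in self.lookup(code):
                    gstart = int(gp) - off
                    key = (gstart, strand)
                    if key in seen_starts:
                        continue
                    seen_starts.add(key)
                    ci, local = self._locate(gstart) if gstart >= 0 else (-1, -1)
                    if ci < 0:
                        continue
                    name = self.names[ci]
                    if local < 0 or local + L > self.lengths[name]:
                        continue
                    mm = int((self.seqs[name][local : local + L] != arr).sum())
                    if mm <= max_mismatches:
                        hits[(name, local, strand)] = Hit(
                            chrom=name, pos=local, strand=strand,
                            mismatches=mm,
                            score=-float(MATCH_SCORE_PENALTY * mm),
                        )
        out = sorted(
            hits.values(), key=lambda h: (-h.score, h.chrom, h.pos, h.strand != "+")
        )
        return out


def _kmer_codes(s: np.ndarray, k: int) -> np.ndarray:
    n = len(s) - k + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + s[j : j + n].astype(np.int64)
    return codes


def _code_of(arr: np.ndarray) -> int:
    c = 0
    for b in arr:
        c = c * 4 + int(b)
    return c


def _gap_mapq(hits: list[Hit]) -> int:
    if not hits:
        return 0
    if len(hits) == 1:
        return 60
    gap = hits[0].score - hits[1].score
    return int(min(60, gap))


def mini_align(
    reads,
    reference: dict[str, str] | KmerIndex,
    max_hits: int = 15,
    mode: str = "multi",
    seed_len: int = DEFAULT_SEED_LEN,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> dict[str, list[Hit]]:
    """Map reads with the built-in exact mini multi-mapper.

    ``reads``: iterable of (read_id, sequence) or SimRead.  ``single`` mode
    returns the best hit only (pass-1 contract, score-gap MAPQ, tie =>
    unique=False); ``multi`` returns up to ``max_hits`` scored hits
    (pass-2 contract).  Ordering is deterministic.
    """
    index = reference if isinstance(reference, KmerIndex) else KmerIndex(reference, seed_len)
    out: dict[str, list[Hit]] = {}
    for r in reads:
        rid, seq = (r.read_id, r.seq) if isinstance(r, SimRead) else (r[0], r[1])
        hits = index.align(seq, max_mismatches)
        if mode == "single":
            if hits:
                best = hits[0]
                best.mapq = _gap_mapq(hits)
                best.unique = len(hits) == 1 or hits[1].score < best.score
                out[rid] = [best]
            else:
                out[rid] = []
        else:
            out[rid] = hits[: max_hits + 1]  # +1 so the cap overflow is visible
    return out


@dataclass
class WellConfig:
    max_gap: int = 3500
    min_reads: int = 6
    pad: int = 1000
    max_alignments: int = 15
    seed_len: int = DEFAULT_SEED_LEN
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    mapq_threshold: int = 10
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    existence_cutoff: float = 0.9
    seed: int = 0


@dataclass
class WellResult:
    well_id: int
    pass1: dict
    clouds: list[CandidateCloud]
    abbrev: AbbreviatedReference
    fragments: list[ReadFragment]
    graph: object
    assignment: object
    state: object
    read_conf: list
    cloud_conf: list
    excluded_reads: set
    table: pd.DataFrame  # per-read RFA output
    converged: bool = True


def _pass1_alignments(reads, hits: dict) -> list[Pass1Alignment]:
    out = []
    for r in reads:
        hs = hits.get(r.read_id, [])
        if hs:
            h = hs[0]
            out.append(
                Pass1Alignment(
                    read_id=r.read_id, chrom=h.chrom, start=h.pos,
                    strand=h.strand, end_marker=r.end_marker,
                    read_length=len(r.seq), unique=h.unique, score=h.score,
                )
            )
    return out


def _lift(abbrev: AbbreviatedReference, contig_name: str, offset: int):
    return abbrev.contig_to_genome(contig_name, offset)


def run_well(
    reads: list[SimRead],
    reference: dict[str, str],
    prior: WellPrior,
    config: WellConfig | None = None,
    index: KmerIndex | None = None,
    well_id: int = 0,
) -> WellResult:
    """Steps 1-5 for one well; idempotent given the config seed."""
    config = config or WellConfig()
    rng = np.random.default_rng(config.seed + 1_000_003 * well_id)
    if index is None:
        index = KmerIndex(reference, config.seed_len)
    # (1) pass 1: single-best alignment to the full reference
    p1_hits = mini_align(reads, index, mode="single",
                         max_mismatches=config.max_mismatches)
    p1 = _pass1_alignments(reads, p1_hits)
    # (2) candidate clouds + abbreviated reference
    clouds = seed_clouds(p1, config.max_gap, config.min_reads)
    abbrev = build_abbreviated_reference(clouds, reference, config.pad)
    empty = len(abbrev.contigs) == 0
    # (3) pass 2: multi-hit alignment to the abbreviated reference
    read_map = {r.read_id: (r.seq, r.quals, r.end_marker) for r in reads}
    if not empty:
        contig_ref = {c.name: c.sequence for c in abbrev.contigs}
        p2_index = KmerIndex(contig_ref, config.seed_len)
        p2_hits = mini_align(reads, p2_index, max_hits=config.max_alignments,
                             mode="multi", max_mismatches=config.max_mismatches)
        name_to_cloud = {c.name: c.cloud_id for c in abbrev.contigs}
        p2_alns = {
            rid: [
                CandidateAlignment(
                    contig_id=name_to_cloud[h.chrom], contig_name=h.chrom,
                    offset=h.pos, strand=h.strand, score=h.score,
                    n_mismatches=h.mismatches,
                )
                for h in hs
            ]
            for rid, hs in p2_hits.items()
        }
    else:
        p2_alns = {}
    fragments = collect_pass2(read_map, abbrev, p2_alns, config.max_alignments)
    # (4) MRF + MAP inference
    molecules = molecules_from_reference(abbrev)
    graph = build_mrf(fragments, molecules)
    infcfg = InferenceConfig(
        seed=config.inference.seed + 7_919 * well_id,
        restarts=config.inference.restarts,
        sweeps=config.inference.sweeps,
    )
    assignment, state = map_inference(graph, prior, infcfg)
    # (5) confidence queries + exclusion filters
    rconf, cconf = well_confidences(
        state, rng=rng, existence_cutoff=config.existence_cutoff
    )
    excluded_clouds = {c.cloud_id for c in cconf if c.excluded}
    coll_reads, coll_clouds, _ = detect_collisions(clouds, p1, prior.marker_eff)
    excluded_clouds |= coll_clouds
    cloud_of_frag = {}
    rows = []
    conf_by_read = {c.read_id: c for c in rconf}
    for n, frag in enumerate(fragments):
        c = conf_by_read.get(frag.read_id)
        k = int(state.choice[n]) if n < len(state.choice) else UNASSIGNED
        placed = False
        chrom = pos = strand = None
        mapq = 0
        cloud_id = None
        if frag.high_copy and frag.alignments:
            aln = frag.alignments[0]
            chrom, pos = _lift(abbrev, aln.contig_name, aln.offset)
            strand = aln.strand
            placed, mapq, cloud_id = True, 0, aln.contig_id
        elif k != UNASSIGNED:
            aln = graph.options[n][k][0]
            chrom, pos = _lift(abbrev, aln.contig_name, aln.offset)
            strand = aln.strand
            placed = True
            mapq = c.mapq if c else 0
            cloud_id = aln.contig_id
        excl = (frag.read_id in coll_reads) or (cloud_id in excluded_clouds)
        rows.append(
            {
                "read_id": frag.read_id, "well": well_id, "placed": placed,
                "chrom": chrom, "pos": pos, "strand": strand, "mapq": mapq,
                "posterior": c.posterior if c else 0.0,
                "multimapped": frag.k > 1, "high_copy": frag.high_copy,
                "excluded": excl, "cloud_id": cloud_id,
            }
        )
    table = pd.DataFrame(rows)
    return WellResult(
        well_id=well_id, pass1=p1_hits, clouds=clouds, abbrev=abbrev,
        fragments=fragments, graph=graph, assignment=assignment, state=state,
        read_conf=rconf, cloud_conf=cconf,
        excluded_reads=coll_reads | {
            r["read_id"] for r in rows if r["excluded"]
        },
        table=table, converged=assignment.converged,
    )


# ---------------------------------------------------------------- methods


def baseline_table(reads, result: WellResult) -> pd.DataFrame:
    """Standard single-pass short-read alignment with score-gap MAPQ."""
    multi = {f.read_id: f.k > 1 for f in result.fragments}
    rows = []
    for r in reads:
        hs = result.pass1.get(r.read_id, [])
        if hs:
            h = hs[0]
            rows.append({"read_id": r.read_id, "well": result.well_id,
                         "placed": True, "chrom": h.chrom, "pos": h.pos,
                         "strand": h.strand, "mapq": h.mapq,
                         "multimapped": multi.get(r.read_id, False),
                         "excluded": False})
        else:
            rows.append({"read_id": r.read_id, "well": result.well_id,
                         "placed": False, "chrom": None, "pos": None,
                         "strand": None, "mapq": 0,
                         "multimapped": multi.get(r.read_id, False),
                         "excluded": False})
    return pd.DataFrame(rows)


def naive_table(result: WellResult) -> pd.DataFrame:
    """Best pass-2 hit on the abbreviated reference, score-gap MAPQ,
    lifted to genome coordinates."""
    rows = []
    for f in result.fragments:
        if f.alignments:
            a = f.alignments[0]
            chrom, pos = result.abbrev.contig_to_genome(a.contig_name, a.offset)
            if len(f.alignments) == 1:
                mapq = 60
            else:
                mapq = int(min(60, f.alignments[0].score - f.alignments[1].score))
            rows.append({"read_id": f.read_id, "well": result.well_id,
                         "placed": True, "chrom": chrom, "pos": pos,
                         "strand": a.strand, "mapq": mapq,
                         "multimapped": f.k > 1, "excluded": False})
        else:
            rows.append({"read_id": f.read_id, "well": result.well_id,
                         "placed": False, "chrom": None, "pos": None,
                         "strand": None, "mapq": 0,
                         "multimapped": False, "excluded": False})
    return pd.DataFrame(rows)


def oracle_table(result: WellResult, truth: pd.DataFrame) -> pd.DataFrame:
    """True-hit selector: the true placement whenever the multi-mapper
    returned it, else unplaced.  Upper bound by construction."""
    t = truth.set_index("read_id")
    rows = []
    for f in result.fragments:
        placed = False
        chrom = pos = strand = None
        if f.read_id in t.index:
            tr = t.loc[f.read_id]
            for a in f.alignments:
                c, p = result.abbrev.contig_to_genome(a.contig_name, a.offset)
                if (
                    c == tr["chrom"]
                    and abs(int(p) - int(tr["pos"])) <= CORRECT_TOL
                    and a.strand == tr["strand"]
                ):
                    placed, chrom, pos, strand = True, c, int(p), a.strand
                    break
        rows.append({"read_id": f.read_id, "well": result.well_id,
                     "placed": placed, "chrom": chrom, "pos": pos,
                     "strand": strand, "mapq": 60 if placed else 0,
                     "multimapped": f.k > 1, "excluded": False})
    return pd.DataFrame(rows)


def method_tables(reads, result: WellResult, truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        "baseline": baseline_table(reads, result),
        "naive": naive_table(result),
        "rfa": result.table.drop(columns=["posterior", "high_copy", "cloud_id"]),
        "oracle": oracle_table(result, truth),
    }


# ---------------------------------------------------------------- evaluation


@dataclass
class EvalReport:
    per_well: pd.DataFrame     # method, well, metric columns
    aggregate: pd.DataFrame    # method-indexed pooled metrics
    mapq_threshold: int


def _is_correct(df: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    m = df.merge(truth, on="read_id", suffixes=("", "_true"), how="left")
    ok = (
        m["placed"].fillna(False)
        & (m["chrom"] == m["chrom_true"])
        & (m["strand"] == m["strand_true"])
        & ((m["pos"] - m["pos_true"]).abs() <= CORRECT_TOL)
    )
    return ok.set_axis(df.index)


def evaluate(
    tables: dict[str, pd.DataFrame],
    truth: pd.DataFrame,
    mapq_threshold: int = 10,
) -> EvalReport:
    """Four-way accuracy report after MAPQ filtering.

    Metrics, per well and pooled: fraction of all reads confidently and
    correctly placed; the same among multimapped reads (more than one
    pass-2 candidate); and the wrong-placement rate among confident
    multimapped reads.
    """
    need = set(truth["read_id"])
    rows = []
    agg = []
    for method, df in tables.items():
        have = set(df["read_id"])
        if not have <= need:
            raise ValueError(f"{method}: reads absent from truth")
        df = df.copy()
        df["correct"] = _is_correct(df, truth)
        df["confident"] = (
            df["placed"] & (df["mapq"] >= mapq_threshold) & ~df["excluded"]
        )
        for well, sub in df.groupby("well"):
            rows.append(_metrics(method, well, sub))
        agg.append(_metrics(method, None, df))
    per_well = pd.DataFrame(rows)
    aggregate = pd.DataFrame(agg).drop(columns="well").set_index("method")
    return EvalReport(per_well=per_well, aggregate=aggregate,
                      mapq_threshold=mapq_threshold)


def _metrics(method, well, df) -> dict:
    multi = df[df["multimapped"]]
    conf_multi = multi[multi["confident"]]
    return {
        "method": method,
        "well": well,
        "n_reads": len(df),
        "n_multimapped": len(multi),
        "frac_conf_correct_all": (df["confident"] & df["correct"]).mean() if len(df) else 0.0,
        "frac_conf_correct_multi": (multi["confident"] & multi["correct"]).mean() if len(multi) else 0.0,
        "wrong_rate_conf_multi": (~conf_multi["correct"]).mean() if len(conf_multi) else 0.0,
        "n_conf_multi": len(conf_multi),
    }


# ---------------------------------------------------------------- training


def train_prior(
    wells: list[list[SimRead]],
    reference: dict[str, str],
    prior_config: PriorConfig | None = None,
    config: WellConfig | None = None,
    index: KmerIndex | None = None,
) -> WellPrior:
    """Learn P(M) from the uniquely mapped clouds of training wells."""
    config = config or WellConfig()
    if index is None:
        index = KmerIndex(reference, config.seed_len)
    glen = sum(len(s) for s in reference.values())
    all_clouds: list[CandidateCloud] = []
    counts: dict[int, int] = {}
    well_of: dict[int, int] = {}
    n_clouds_per_well = []
    next_id = 0
    for wi, reads in enumerate(wells):
        hits = mini_align(reads, index, mode="single",
                          max_mismatches=config.max_mismatches)
        p1 = _pass1_alignments(reads, hits)
        unique_ids = {a.read_id for a in p1 if a.unique}
        clouds = seed_clouds(p1, config.max_gap, config.min_reads)
        n_clouds_per_well.append(len(clouds))
        for c in clouds:
            if c.member_read_ids <= unique_ids:
                c.cloud_id = next_id
                counts[next_id] = len(c.member_read_ids)
                well_of[next_id] = wi
                all_clouds.append(c)
                next_id += 1
    if prior_config is None:
        prior_config = PriorConfig(genome_length=glen)
    if prior_config.clouds_per_well is None and n_clouds_per_well:
        prior_config.clouds_per_well = float(np.mean(n_clouds_per_well))
    feats = extract_features(all_clouds, counts,
                             prior_config.outlier_quantile, well_of=well_of)
    return fit_prior(feats, prior_config)


# ---------------------------------------------------------------- study


def simulation_study(
    seed: int = 1,
    n_wells: int = 50,
    n_training_wells: int = 20,
    sim_config=None,
    well_config: WellConfig | None = None,
    mapq_threshold: int = 10,
):
    """The full simulation benchmark: genome, prior training, per-well
    alignment with all four methods, pooled evaluation.

    Returns (EvalReport, tables, truth).  All randomness derives from
    ``seed``.
    """
    from .simulator import SimConfig, make_repeat_genome, simulate_well

    cfg = sim_config or SimConfig(seed=seed)
    cfg.seed = seed
    well_config = well_config or WellConfig(seed=seed)
    genome, _ = make_repeat_genome(cfg)
    index = KmerIndex(genome, well_config.seed_len)
    training = [
        simulate_well(genome, cfg, seed=seed + 100_000 + w, well_id=w)[0]
        for w in range(n_training_wells)
    ]
    prior = train_prior(training, genome, config=well_config, index=index)
    tables: dict[str, list] = {m: [] for m in METHODS}
    truth_parts = []
    for w in range(n_wells):
        reads, _ = simulate_well(genome, cfg, seed=seed + 1 + w, well_id=w)
        truth = pd.DataFrame([vars(r.truth) for r in reads])
        truth_parts.append(truth)
        result = run_well(reads, genome, prior, well_config, index=index, well_id=w)
        for m, t in method_tables(reads, result, truth).items():
            tables[m].append(t)
    truth = pd.concat(truth_parts, ignore_index=True)
    tables = {m: pd.concat(ts, ignore_index=True) for m, ts in tables.items()}
    report = evaluate(tables, truth, mapq_threshold=mapq_threshold)
    return report, tables, truth


# ---------------------------------------------------------------- SAM output


def write_sam(result: WellResult, reference: dict[str, str], path: str) -> None:
    """Final lifted alignments as SAM, one record per read; unassigned
    reads become unmapped records.  Excluded (collision / low-confidence
    cloud) reads carry the XE:i:1 tag."""
    import pysam

    names = sorted(reference)
    header = pysam.AlignmentHeader.from_references(
        names, [len(reference[n]) for n in names]
    )
    frag_by_id = {f.read_id: f for f in result.fragments}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for row in result.table.to_dict("records"):
            a = pysam.AlignedSegment(header)
            a.query_name = row["read_id"]
            frag = frag_by_id[row["read_id"]]
            if row["placed"]:
                seq = frag.seq
                quals = np.asarray(frag.quals)
                if row["strand"] == "-":
                    seq = "".join("TGCA"["ACGT".index(b)] for b in reversed(seq))
                    quals = quals[::-1]
                a.reference_id = names.index(row["chrom"])
                a.reference_start = int(row["pos"])
                a.mapping_quality = int(row["mapq"])
                a.flag = 16 if row["strand"] == "-" else 0
                a.query_sequence = seq
                a.query_qualities = [int(q) for q in quals]
                a.cigarstring = f"{len(seq)}M"
            else:
                a.flag = 4
                a.query_sequence = frag.seq
                a.query_qualities = [int(q) for q in np.asarray(frag.quals)]
            a.set_tag("EM", 1 if frag.end_marker else 0)
            if row["excluded"]:
                a.set_tag("XE", 1)
            out.write(a)


def write_cloud_bed(result: WellResult, path: str) -> None:
    conf = {c.cloud_id: c for c in result.cloud_conf}
    with open(path, "w") as f:
        for cloud in result.clouds:
            c = conf.get(cloud.cloud_id)
            if c is None:
                continue
            f.write(
                f"{cloud.chrom}\t{cloud.start}\t{cloud.end}\tcloud{cloud.cloud_id}\t"
                f"{c.log_quality:.3f}\t{c.existence_posterior:.4f}\t{int(c.excluded)}\n"
            )
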