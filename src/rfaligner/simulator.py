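"""Read-cloud simulator with ground truth.

Generates (i) synthetic genomes carrying planted segmental duplications —
the ambiguity the aligner exists to resolve — and (ii) per-well read clouds:
long fragments drawn uniformly from the genome until the well holds its
target genome fraction, each fragment shot through a *stencil* of short-read
positions, with end-marker reads at the fragment boundaries and a
first-order base-quality/error model.

Two stencil modes exist.  The default parametric mode draws Poisson read
counts and uniform offsets (the standard shotgun model).  Empirical mode
cuts stencils out of user-supplied alignments of real clouds, preserving
protocol biases.

Every emitted read carries exactly one truth record, used by the Oracle
selector and all accuracy metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    a = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (a == 255).any():
        raise ValueError("non-ACGT base in sequence")
    return a


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


@dataclass
class ErrorModelConfig:
    """First-order (AR(1) on position) base-quality chain.

    Mean quality decays linearly from ``q_start`` to ``q_end`` along the
    read; q_i regresses to the profile with coefficient ``rho`` and
    innovation SD ``q_sigma``.  Substitution probability per base is
    10^(−q/10), uniform over the three alternatives.
    """

    q_start: float = 35.0
    q_end: float = 25.0
    rho: float = 0.7
    q_sigma: float = 3.0
    q_min: int = 2
    q_max: int = 40


@dataclass
class SimConfig:
    genome_length: int = 5_000_000
    n_duplications: int = 10
    dup_length_range: tuple = (5000, 20000)
    identity_range: tuple = (0.94, 0.99)
    c_f: float = 1.0          # long-fragment genome coverage (sets well count)
    c_r: float = 1.5          # short-read coverage of each fragment
    well_fraction: float = 0.02
    frag_mu: float = 9.2      # log-normal fragment size, log-bp
    frag_sigma: float = 0.3
    read_length: int = 100
    paired: bool = False
    insert_size: int = 350
    marker_eff: float = 0.77
    collision_rate: float = 0.02
    error_model: ErrorModelConfig = field(default_factory=ErrorModelConfig)
    diploid: bool = False
    het_rate: float = 1e-3
    seed: int = 0

    @property
    def total_depth(self) -> float:
        """Total sequencing depth C = C_F x C_R."""
        return self.c_f * self.c_r

    @property
    def n_wells(self) -> int:
        """Wells needed for C_F given each holds `well_fraction` of the genome."""
        return max(1, round(self.c_f / self.well_fraction))

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        em = d.pop("error_model", {})
        d["dup_length_range"] = tuple(d.get("dup_length_range", (5000, 20000)))
        d["identity_range"] = tuple(d.get("identity_range", (0.94, 0.99)))
        return cls(error_model=ErrorModelConfig(**em), **d)


def genome_equivalents(total_depth: float, standard_depth: float = 30.0) -> float:
    """How many standard-depth genomes a total budget C corresponds to."""
    return total_depth / standard_depth


@dataclass
class Stencil:
    """Relative read-start offsets from the fragment start (a 'cookie
    cutter' for one cloud), plus end-marker slot flags."""

    offsets: np.ndarray
    marker_left: bool = False
    marker_right: bool = False

    def __post_init__(self) -> None:
        self.offsets = np.sort(np.asarray(self.offsets, dtype=np.int64))


@dataclass
class FragmentTruth:
    well: int
    fragment_id: int
    chrom: str
    start: int
    size: int
    marker_left: bool
    marker_right: bool


@dataclass
class ReadTruth:
    read_id: str
    well: int
    fragment_id: int
    chrom: str
    pos: int
    strand: str
    end_marker: bool


@dataclass
class SimRead:
    read_id: str
    seq: str
    quals: np.ndarray
    end_marker: bool
    truth: ReadTruth

    def qual_string(self) -> str:
        return "".join(chr(q + 33) for q in self.quals)


def make_repeat_genome(config: SimConfig, seed=None):
    """Random genome with planted duplication pairs.

    Returns (genome: {chrom: str}, dups: list of dict BED-like records with
    both copies and their nominal identity).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    lo, hi = config.dup_length_range
    total_dup = 0
    intervals: list[tuple[int, int]] = []
    dups = []

    def overlaps(s, e):
        return any(s < e2 and s2 < e for s2, e2 in intervals)

    for i in range(config.n_duplications):
        length = int(rng.integers(lo, hi + 1))
        total_dup += 2 * length
        if total_dup > config.genome_length / 4:
            raise ValueError("duplications exceed a quarter of the genome")
        identity = float(rng.uniform(*config.identity_range))
        for _ in range(1000):
            src = int(rng.integers(0, config.genome_length - length))
            dst = int(rng.integers(0, config.genome_length - length))
            if abs(src - dst) >= length and not overlaps(src, src + length) \
                    and not overlaps(dst, dst + length):
                break
        else:
            raise RuntimeError("could not place duplication without overlap")
        copy = g[src : src + length].copy()
        n_mut = rng.binomial(length, 1.0 - identity)
        if n_mut:
            pos = rng.choice(length, size=n_mut, replace=False)
            copy[pos] = (copy[pos] + rng.integers(1, 4, size=n_mut)) % 4
        g[dst : dst + length] = copy
        intervals += [(src, src + length), (dst, dst + length)]
        dups.append(
            {"chrom": "chr1", "src_start": src, "dst_start": dst,
             "length": length, "identity": identity, "dup_id": i}
        )
    return {"chr1": decode(g)}, dups


def draw_stencil(config: SimConfig, fragment_size: int, rng) -> Stencil:
    """Parametric stencil: Poisson read count at C_R coverage, uniform
    offsets; flagged end-marker slots are snapped to the fragment ends
    (an end-marker read overlaps the fragment-end adapter by definition)."""
    rlen = config.read_length
    if fragment_size <= rlen:
        raise ValueError("fragment smaller than read length")
    n = rng.poisson(config.c_r * fragment_size / rlen)
    offsets = np.sort(rng.integers(0, fragment_size - rlen + 1, size=n))
    ml = bool(rng.random() < config.marker_eff)
    mr = bool(rng.random() < config.marker_eff)
    parts = [offsets]
    if ml:
        parts.insert(0, np.array([0]))
    if mr:
        parts.append(np.array([fragment_size - rlen]))
    return Stencil(np.concatenate(parts), marker_left=ml, marker_right=mr)


def load_stencils_from_sam(path: str) -> list[Stencil]:
    """Empirical stencils: one per contig/cloud in an alignment file; read
    starts are taken relative to the leftmost read of the cloud."""
    import pysam

    per_ref: dict[str, list[int]] = {}
    with pysam.AlignmentFile(path, "r") as f:
        for rec in f:
            if rec.is_unmapped:
                continue
            per_ref.setdefault(rec.reference_name, []).append(rec.reference_start)
    out = []
    for ref in sorted(per_ref):
        starts = np.sort(np.asarray(per_ref[ref]))
        out.append(Stencil(starts - starts[0]))
    return out


def apply_error_model(bases: np.ndarray, rng, config: SimConfig):
    """Emit observed bases + qualities through the first-order error model."""
    em = config.error_model
    n = len(bases)
    mu = em.q_start + (em.q_end - em.q_start) * np.arange(n) / max(1, n - 1)
    q = np.empty(n)
    eps = rng.normal(0.0, em.q_sigma, size=n)
    q[0] = mu[0] + eps[0]
    for i in range(1, n):
        q[i] = mu[i] + em.rho * (q[i - 1] - mu[i - 1]) + eps[i]
    q = np.clip(np.rint(q), em.q_min, em.q_max).astype(np.int64)
    err_p = 10.0 ** (-q / 10.0)
    errs = rng.random(n) < err_p
    obs = bases.copy()
    if errs.any():
        shift = rng.integers(1, 4, size=int(errs.sum())).astype(np.uint8)
        obs[errs] = (obs[errs] + shift) % 4
    return obs, q


def simulate_well(
    genome: dict[str, str],
    config: SimConfig,
    seed,
    well_id: int = 0,
    stencils: list[Stencil] | None = None,
):
    """One well: fragments drawn uniformly until the well holds
    ``well_fraction`` of the genome, reads emitted through stencils and the
    error model.  With probability ``collision_rate`` a fragment is placed
    overlapping an existing one; otherwise placements are rejected until
    non-overlapping.

    Returns (reads: list[SimRead], fragments: list[FragmentTruth]).
    """
    rng = np.random.default_rng(seed)
    chrom = sorted(genome)[0]
    gseq = encode(genome[chrom])
    hap = gseq
    if config.diploid:
        hap2 = gseq.copy()
        n_het = rng.binomial(len(gseq), config.het_rate)
        pos = rng.choice(len(gseq), size=n_het, replace=False)
        hap2[pos] = (hap2[pos] + rng.integers(1, 4, size=n_het).astype(np.uint8)) % 4
    glen = len(gseq)
    target = config.well_fraction * glen
    rlen = config.read_length
    placed: list[tuple[int, int]] = []
    frags: list[FragmentTruth] = []
    reads: list[SimRead] = []
    total = 0.0
    frag_id = 0
    sidx = 0
    while total < target:
        size = int(np.exp(rng.normal(config.frag_mu, config.frag_sigma)))
        size = max(size, rlen + 1)
        size = min(size, glen - 1)
        if total + size > target:
            # accept the overshooting fragment with probability deficit/size
            # so the expected well coverage equals the target (no half-
            # fragment overshoot bias)
            if rng.random() >= (target - total) / size:
                break
        collide = bool(placed) and rng.random() < config.collision_rate
        for _ in range(200):
            start = int(rng.integers(0, glen - size))
            hits = any(start < e and s < start + size for s, e in placed)
            if hits == collide or not placed:
                break
        placed.append((start, start + size))
        if stencils is not None:
            st = stencils[sidx % len(stencils)]
            sidx += 1
            offs = st.offsets[st.offsets <= size - rlen]
            st = Stencil(offs, st.marker_left, st.marker_right)
        else:
            st = draw_stencil(config, size, rng)
        src = hap
        if config.diploid and rng.random() < 0.5:
            src = hap2
        n_slots = len(st.offsets)
        for j, off in enumerate(st.offsets):
            is_marker = (st.marker_left and j == 0 and off == 0) or (
                st.marker_right and j == n_slots - 1 and off == size - rlen
            )
            pos = start + int(off)
            frag_bases = src[pos : pos + rlen]
            strand = "+" if rng.random() < 0.5 else "-"
            template = frag_bases if strand == "+" else revcomp(frag_bases)
            obs, q = apply_error_model(template, rng, config)
            name = f"w{well_id}_f{frag_id}_r{j}"
            if is_marker:
                name += "_EM"
            truth = ReadTruth(
                read_id=name, well=well_id, fragment_id=frag_id,
                chrom=chrom, pos=pos, strand=strand, end_marker=is_marker,
            )
            reads.append(
                SimRead(read_id=name, seq=decode(obs), quals=q,
                        end_marker=is_marker, truth=truth)
            )
        frags.append(
            FragmentTruth(well=well_id, fragment_id=frag_id, chrom=chrom,
                          start=start, size=size,
                          marker_left=st.marker_left,
                          marker_right=st.marker_right)
        )
        frag_id += 1
        total += size
    return reads, frags


def write_fastq(reads: list[SimRead], path: str) -> None:
    with open(path, "w") as f:
        for r in reads:
            f.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual_string()}\n")


def write_truth(reads: list[SimRead], path: str) -> None:
    with open(path, "w") as f:
        f.write("read_id\twell\tfragment_id\tchrom\tpos\tstrand\tend_marker\n")
        for r in reads:
            t = r.truth
            f.write(
                f"{t.read_id}\t{t.well}\t{t.fragment_id}\t{t.chrom}\t"
                f"{t.pos}\t{t.strand}\t{int(t.end_marker)}\n"
            )


def write_genome_fasta(genome: dict[str, str], path: str) -> None:
    with open(path, "w") as f:
        for chrom in sorted(genome):
            f.write(f">{chrom}\n")
            s = genome[chrom]
            for i in range(0, len(s), 80):
                f.write(s[i : i + 80] + "\n")


def write_dup_bed(dups: list[dict], path: str) -> None:
    with open(path, "w") as f:
        for d in dups:
            for which in ("src", "dst"):
                s = d[f"{which}_start"]
                f.write(
                    f"{d['chrom']}\t{s}\t{s + d['length']}\t"
                    f"dup{d['dup_id']}_{which}\t{d['identity']:.4f}\n"
                )
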