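"""Per-well Markov Random Field over reads and hidden long molecules.

Each candidate molecule c induces one potential

    phi_c(R_c) = sum over M_c of P(M_c) P(R_c | M_c)

over the reads currently assigned to it.  The hidden molecule sequence X_c
and read density lambda_c are never instantiated: X_c is eliminated
column-by-column (positions are independent given the reads), and lambda_c
by numeric quadrature on the prior's log-spaced grid.  The emission model
for an active molecule is the standard shotgun model: read count
n_c ~ Poisson(lambda * s_c), read starts uniform on the molecule (1/s_c
each), bases emitted from X_c with per-base error e = 10^(-q/10)
(probability 1-e of the true base, e/3 each alternative), and a fixed
log(1e-4) penalty per indel event in a candidate alignment (X_c models
substitutions only).  An empty molecule contributes log(1 - p_exist);
an unassigned read contributes log(p_offtarget).

MAP inference is local search: greedy initialisation, iterated conditional
modes sweeps in random order, interleaved with whole-cloud block moves,
over several restarts.  Every accepted move increases the joint score, so
the trajectory is monotone and the result is a single-read-move local
maximum.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .cloud_seeding import (
    AbbreviatedReference,
    CandidateAlignment,
    Contig,
    ReadFragment,
)
from .prior_model import WellPrior
from .simulator import encode, revcomp

logger = logging.getLogger(__name__)

UNASSIGNED = -1
LOG_INDEL_PENALTY = math.log(1e-4)


def _lse(a: np.ndarray) -> float:
    """logsumexp of a 1-D array (lean hot-path version)."""
    m = a.max()
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.exp(a - m).sum()))


def _lse0(a: np.ndarray) -> np.ndarray:
    """logsumexp along axis 0 of a (4, m) array."""
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m).sum(axis=0))


@dataclass
class CandidateMolecule:
    """A seeded hidden long molecule; sequence and density stay latent."""

    index: int
    cloud_id: int
    contig: Contig
    chrom: str
    start: int   # genome coordinate of the (unpadded) cloud interval
    size: int    # s_c, bp

    @property
    def exists(self) -> bool:  # only meaningful on a scorer-backed state
        return True


def molecules_from_reference(abbrev_ref: AbbreviatedReference) -> list[CandidateMolecule]:
    mols = []
    for i, c in enumerate(abbrev_ref.contigs):
        mols.append(
            CandidateMolecule(
                index=i,
                cloud_id=c.cloud_id,
                contig=c,
                chrom=c.origin_chrom,
                start=c.cloud_start,
                size=max(1, c.cloud_end - c.cloud_start),
            )
        )
    return mols


def oriented_read(frag: ReadFragment, strand: str):
    """Read bases/qualities oriented to the reference strand."""
    b = encode(frag.seq)
    q = np.asarray(frag.quals, dtype=float)
    if strand == "-":
        return revcomp(b), q[::-1]
    return b, q


def _cigar_columns(cigar: str, offset: int):
    """Map read indices to contig columns for a simple cigar; returns
    (read_idx, cols, indel_events)."""
    import re

    read_idx, cols = [], []
    r = 0
    c = offset
    events = 0
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        ln = int(length)
        if op in "M=X":
            read_idx.extend(range(r, r + ln))
            cols.extend(range(c, c + ln))
            r += ln
            c += ln
        elif op in "IS":
            if op == "I":
                events += 1
            r += ln
        elif op in "DN":
            if op == "D":
                events += 1
            c += ln
        # H, P consume nothing we track
    return np.asarray(read_idx), np.asarray(cols), events


class MoleculeScorer:
    """Incremental evaluator of one molecule's log-potential.

    Column statistics are additive in the assigned reads, so adding or
    removing one read costs O(read length); the potential itself is the
    cached column sum plus O(grid) terms.

    Given an assignment, the molecule's effective size s_c is inferred from
    the reads: the span of the assigned alignments (the seeded cloud
    interval is only the candidate region).  Size enters the uniform
    read-position term (1/s_c per read) and the (S, lambda) prior density.
    """

    def __init__(self, molecule: CandidateMolecule, prior: WellPrior):
        self.molecule = molecule
        self.prior = prior
        contig = molecule.contig
        self.ref = encode(contig.sequence)
        L = len(self.ref)
        self.L = L
        theta = prior.theta
        lp = np.full((4, L), math.log(theta / 3.0))
        lp[self.ref, np.arange(L)] = math.log1p(-theta)
        self.log_prior_cols = lp
        self.col_loglik = np.zeros((4, L))
        self.coverage = np.zeros(L, dtype=np.int64)
        self.col_term = np.zeros(L)
        self.col_sum = 0.0
        self.n_reads = 0
        self.indel_events = 0
        # marker bookkeeping: assigned end-marker reads near each boundary
        self.cb_start = contig.cloud_start - contig.origin_start
        self.cb_end = contig.cloud_end - contig.origin_start
        self._marker_left = 0
        self._marker_right = 0
        self._interior_markers = 0
        # dynamic extent: sorted alignment starts/ends of assigned reads
        self._starts: list[int] = []
        self._ends: list[int] = []
        # lambda-elimination grid (trapezoid quadrature weights)
        lam = prior.lambda_grid
        w = np.empty_like(lam)
        w[1:-1] = 0.5 * (lam[2:] - lam[:-2])
        w[0] = 0.5 * (lam[1] - lam[0])
        w[-1] = 0.5 * (lam[-1] - lam[-2])
        self._lam = lam
        self._log_lam = np.log(lam)
        self._log_w = np.log(w)
        self._static: dict[tuple, np.ndarray] = {}
        self._lam_cache: dict[tuple, float] = {}
        self._clip_warned = False

    # --- marker state -------------------------------------------------
    def _marker_side(self, frag: ReadFragment, aln: CandidateAlignment) -> str:
        rlen = len(frag.seq)
        if aln.offset <= self.cb_start + rlen:
            return "left"
        if aln.offset + rlen >= self.cb_end - rlen:
            return "right"
        return "interior"

    @property
    def b_state(self) -> tuple[int, int]:
        return (int(self._marker_left > 0), int(self._marker_right > 0))

    @property
    def exists(self) -> bool:
        return self.n_reads > 0

    @property
    def size(self) -> int:
        """Effective molecule size: span of the assigned reads (seeded
        cloud size when empty, where it only matters as a placeholder)."""
        if not self._starts:
            return self.molecule.size
        return max(1, self._ends[-1] - self._starts[0])

    # --- read add/remove ----------------------------------------------
    def _columns(self, frag: ReadFragment, aln: CandidateAlignment):
        b, q = oriented_read(frag, aln.strand)
        if aln.cigar is None:
            ridx = np.arange(len(b))
            cols = aln.offset + ridx
            events = 0
        else:
            ridx, cols, events = _cigar_columns(aln.cigar, aln.offset)
        keep = (cols >= 0) & (cols < self.L)
        if not keep.all():
            if not self._clip_warned:
                logger.warning(
                    "alignment extends outside molecule %s; clipping overlap",
                    self.molecule.contig.name,
                )
                self._clip_warned = True
            ridx, cols = ridx[keep], cols[keep]
        return b[ridx], q[ridx], cols, events

    def _contrib(self, b, q):
        e = 10.0 ** (-q / 10.0)
        m = len(b)
        contrib = np.tile(np.log(e / 3.0), (4, 1))
        contrib[b, np.arange(m)] = np.log1p(-e)
        return contrib

    def add_read(self, frag: ReadFragment, aln: CandidateAlignment) -> None:
        b, q, cols, events = self._columns(frag, aln)
        contrib = self._contrib(b, q)
        old = self.col_term[cols]
        self.col_loglik[:, cols] += contrib
        self.coverage[cols] += 1
        new = _lse0(self.log_prior_cols[:, cols] + self.col_loglik[:, cols])
        self.col_term[cols] = new
        self.col_sum += float(new.sum() - old.sum())
        self.n_reads += 1
        self.indel_events += events
        bisect.insort(self._starts, int(aln.offset))
        bisect.insort(self._ends, int(aln.offset) + len(frag.seq))
        if frag.end_marker:
            side = self._marker_side(frag, aln)
            if side == "left":
                self._marker_left += 1
            elif side == "right":
                self._marker_right += 1
            else:
                self._interior_markers += 1

    def remove_read(self, frag: ReadFragment, aln: CandidateAlignment) -> None:
        b, q, cols, events = self._columns(frag, aln)
        contrib = self._contrib(b, q)
        old = self.col_term[cols]
        self.col_loglik[:, cols] -= contrib
        self.coverage[cols] -= 1
        covered = self.coverage[cols] > 0
        new = np.zeros(len(cols))
        if covered.any():
            cc = cols[covered]
            new[covered] = _lse0(self.log_prior_cols[:, cc] + self.col_loglik[:, cc])
        # exactly zero residuals on uncovered columns
        zero = ~covered
        if zero.any():
            self.col_loglik[:, cols[zero]] = 0.0
        self.col_term[cols] = new
        self.col_sum += float(new.sum() - old.sum())
        self.n_reads -= 1
        self.indel_events -= events
        i = bisect.bisect_left(self._starts, int(aln.offset))
        del self._starts[i]
        i = bisect.bisect_left(self._ends, int(aln.offset) + len(frag.seq))
        del self._ends[i]
        if frag.end_marker:
            side = self._marker_side(frag, aln)
            if side == "left":
                self._marker_left -= 1
            elif side == "right":
                self._marker_right -= 1
            else:
                self._interior_markers -= 1

    # --- potential ------------------------------------------------------
    def _lambda_term(self, n: int, s: int, b: tuple[int, int]) -> float:
        lt = self._lam_cache.get((n, s, b))
        if lt is not None:
            return lt
        static = self._static.get((s, b))
        if static is None:
            kde = self.prior.kde_for(b)
            pts = np.column_stack(
                [np.full_like(self._lam, math.log(s)), self._log_lam]
            )
            # joint density over (S, lambda) = kde(log S, log lambda)/(S*lambda)
            static = kde.logpdf(pts) - math.log(s) - self._log_lam + self._log_w
            self._static[(s, b)] = static
            if len(self._static) > 4096:
                self._static.clear()
        lam_s = self._lam * s
        pois = n * np.log(lam_s) - lam_s - gammaln(n + 1)
        lt = _lse(static + pois)
        self._lam_cache[(n, s, b)] = lt
        if len(self._lam_cache) > 16384:
            self._lam_cache.clear()
        return lt

    def log_potential(self) -> float:
        """log phi_c at the current read set."""
        p = self.prior
        if self.n_reads == 0:
            return math.log1p(-p.p_exist)
        b = self.b_state
        s = self.size
        return (
            math.log(p.p_exist)
            + p.log_pB(b)
            - math.log(p.genome_length)
            + self._lambda_term(self.n_reads, s, b)
            - self.n_reads * math.log(s)
            + self.col_sum
            + self.indel_events * LOG_INDEL_PENALTY
        )


def compute_log_potential(
    molecule: CandidateMolecule,
    assigned_reads: list[tuple[ReadFragment, CandidateAlignment]],
    prior: WellPrior,
) -> float:
    """log phi_c(R_c) for an explicit read set (functional interface)."""
    sc = MoleculeScorer(molecule, prior)
    for frag, aln in assigned_reads:
        if aln.contig_id != molecule.cloud_id:
            raise ValueError("read not attached to this molecule")
        sc.add_read(frag, aln)
    return sc.log_potential()


@dataclass
class MRFGraph:
    """Read/molecule incidence plus domains, ready for inference."""

    fragments: list[ReadFragment]
    molecules: list[CandidateMolecule]
    # per fragment: list of (alignment, molecule_index), same order as domain
    options: list[list[tuple[CandidateAlignment, int]]] = field(default_factory=list)

    def attached_molecules(self, n: int) -> set[int]:
        return {m for _, m in self.options[n]}


def build_mrf(
    fragments: list[ReadFragment], molecules: list[CandidateMolecule]
) -> MRFGraph:
    """Incidence: read n attaches to molecule c iff some alignment in its
    domain falls within c's coordinate range.  Molecules with no attached
    (non-high-copy) reads are dropped."""
    by_cloud = {m.cloud_id: m for m in molecules}
    attached: dict[int, int] = {}
    raw_options = []
    for frag in fragments:
        opts = []
        if not frag.high_copy:
            for aln in frag.alignments:
                m = by_cloud.get(aln.contig_id)
                if m is not None:
                    opts.append((aln, m.cloud_id))
                    attached[m.cloud_id] = attached.get(m.cloud_id, 0) + 1
        raw_options.append(opts)
    kept = [m for m in molecules if attached.get(m.cloud_id, 0) > 0]
    index_of = {}
    for i, m in enumerate(kept):
        m.index = i
        index_of[m.cloud_id] = i
    options = [
        [(aln, index_of[cid]) for aln, cid in opts if cid in index_of]
        for opts in raw_options
    ]
    return MRFGraph(fragments=fragments, molecules=kept, options=options)


@dataclass
class Assignment:
    """A joint choice of one domain element (or unassigned) per read."""

    choice: np.ndarray
    score: float
    converged: bool = True

    def copy(self) -> "Assignment":
        return Assignment(self.choice.copy(), self.score, self.converged)


class MRFState:
    """Scorer-backed assignment state supporting O(read) moves."""

    def __init__(self, graph: MRFGraph, prior: WellPrior):
        self.graph = graph
        self.prior = prior
        self.scorers = [MoleculeScorer(m, prior) for m in graph.molecules]
        self.choice = np.full(len(graph.fragments), UNASSIGNED, dtype=np.int64)
        self._pot = np.array([s.log_potential() for s in self.scorers])
        # off-target route: contamination prior times a uniform background
        # base emission (1/4 per base), the generative counterpart of the
        # in-molecule emission so the two routes are on the same scale
        self.modelled = np.array(
            [not f.high_copy for f in graph.fragments], dtype=bool
        )
        self.log_p_off = np.array(
            [
                math.log(prior.p_offtarget) + len(f.seq) * math.log(0.25)
                if self.modelled[n] else 0.0
                for n, f in enumerate(graph.fragments)
            ]
        )
        self.total = float(self._pot.sum()) + float(self.log_p_off.sum())

    def molecule_of(self, n: int, k: int) -> int:
        return self.graph.options[n][k][1]

    def set_choice(self, n: int, k: int) -> None:
        """Move read n to domain element k (UNASSIGNED allowed)."""
        cur = self.choice[n]
        if cur == k:
            return
        frag = self.graph.fragments[n]
        if cur != UNASSIGNED:
            aln, mi = self.graph.options[n][cur]
            sc = self.scorers[mi]
            sc.remove_read(frag, aln)
            newp = sc.log_potential()
            self.total += newp - self._pot[mi] + self.log_p_off[n]
            self._pot[mi] = newp
        if k != UNASSIGNED:
            aln, mi = self.graph.options[n][k]
            sc = self.scorers[mi]
            sc.add_read(frag, aln)
            newp = sc.log_potential()
            self.total += newp - self._pot[mi] - self.log_p_off[n]
            self._pot[mi] = newp
        self.choice[n] = k

    def reads_of_molecule(self, mi: int) -> list[int]:
        out = []
        for n, k in enumerate(self.choice):
            if k != UNASSIGNED and self.graph.options[n][k][1] == mi:
                out.append(n)
        return out

    def assignment(self) -> Assignment:
        return Assignment(self.choice.copy(), self.total)


def score_assignment(graph: MRFGraph, assignment: Assignment, prior: WellPrior) -> float:
    """Total log score recomputed from scratch (audit path)."""
    state = MRFState(graph, prior)
    for n, k in enumerate(assignment.choice):
        if k != UNASSIGNED:
            state.set_choice(n, int(k))
    return state.total


@dataclass
class InferenceConfig:
    seed: int = 0
    restarts: int = 10
    sweeps: int = 100


def _greedy_init(state: MRFState) -> None:
    for n, opts in enumerate(state.graph.options):
        if opts:
            state.set_choice(n, 0)  # domains sorted by descending score


def _random_init(state: MRFState, rng) -> None:
    """Greedy for pinned (single-candidate) reads; uniform over the domain
    for ambiguous reads, whose coordination is what restarts explore."""
    for n, opts in enumerate(state.graph.options):
        if len(opts) == 1:
            state.set_choice(n, 0)
        elif opts:
            state.set_choice(n, int(rng.integers(0, len(opts))))


def _block_targets(state: MRFState, mi: int) -> list[int]:
    """Molecules that can accommodate every read currently in mi."""
    reads = state.reads_of_molecule(mi)
    if not reads:
        return []
    cands: set[int] | None = None
    for n in reads:
        mols = {m for _, m in state.graph.options[n]}
        cands = mols if cands is None else cands & mols
    cands.discard(mi)
    return sorted(cands)


def _best_option_in(state: MRFState, n: int, mi: int) -> int | None:
    best, best_score = None, -np.inf
    for k, (aln, m) in enumerate(state.graph.options[n]):
        if m == mi and aln.score > best_score:
            best, best_score = k, aln.score
    return best


def map_inference(
    graph: MRFGraph, prior: WellPrior, config: InferenceConfig | None = None
):
    """MAP joint read assignment by restarted ICM with block moves.

    Returns (Assignment, MRFState at that assignment).  Ties on equal
    score keep the current assignment (no move), making the procedure
    deterministic for a fixed seed.
    """
    config = config or InferenceConfig()
    rng = np.random.default_rng(config.seed)
    best: Assignment | None = None
    eps = 1e-9
    for restart in range(max(1, config.restarts)):
        state = MRFState(graph, prior)
        if restart == 0:
            _greedy_init(state)
        else:
            _random_init(state, rng)
        converged = False
        last = -np.inf
        all_reads = np.arange(len(graph.fragments))
        ambiguous = np.array(
            [n for n in all_reads if len(graph.options[n]) >= 2], dtype=np.int64
        )
        for sweep in range(config.sweeps):
            moved = False
            # pinned reads only need revisiting on the first sweep; later
            # sweeps explore the ambiguous reads whose domains interact
            pool = all_reads if sweep == 0 else ambiguous
            order = rng.permutation(pool)
            for n in order:
                opts = graph.options[n]
                if not opts:
                    continue
                cur = int(state.choice[n])
                best_k, best_total = cur, state.total
                for k in list(range(len(opts))) + [UNASSIGNED]:
                    if k == cur:
                        continue
                    state.set_choice(n, k)
                    if state.total > best_total + eps:
                        best_k, best_total = k, state.total
                state.set_choice(n, best_k)
                if best_k != cur:
                    moved = True
            # whole-cloud block moves
            for mi in range(len(graph.molecules)):
                reads = state.reads_of_molecule(mi)
                if not reads:
                    continue
                for target in _block_targets(state, mi):
                    old_total = state.total
                    old = [(n, int(state.choice[n])) for n in reads]
                    ok = True
                    for n in reads:
                        k = _best_option_in(state, n, target)
                        if k is None:
                            ok = False
                            break
                        state.set_choice(n, k)
                    if ok and state.total > old_total + eps:
                        moved = True
                        break
                    for n, k in old:
                        state.set_choice(n, k)
            assert state.total >= last - 1e-6 or moved, "score decreased"
            last = state.total
            if not moved:
                converged = True
                break
        if not converged:
            logger.warning("MAP inference hit sweep cap; returning best-so-far")
        a = state.assignment()
        a.converged = converged
        if best is None or a.score > best.score + eps:
            best = a
    # rebuild state at the best assignment
    final = MRFState(graph, prior)
    for n, k in enumerate(best.choice):
        if k != UNASSIGNED:
            final.set_choice(n, int(k))
    best.score = final.total
    return best, final
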