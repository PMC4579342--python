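"""Post-MAP confidence queries.

Once the joint MAP assignment has converged, reads interact only locally, so
per-read posteriors are computed by marginalising the read (and, when the
local neighbourhood is small enough, its neighbours jointly) over its domain
with all other reads fixed at the MAP.  The posterior converts to a MAPQ on
the standard Phred scale; the conventional confidence filter keeps MAPQ >= 10
(>= 90% mapping confidence).

Cloud-level queries: log P(R_c) at the MAP read set (proportional, in log
space, to the number of variants the assignment implies in the fragment); an
approximate molecule-existence posterior obtained by re-placing the whole
read set into each inactive candidate molecule that can host it and
renormalising; and end-marker collision detection for overlapping fragments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .cloud_seeding import CandidateCloud, Pass1Alignment, ReadFragment
from .prior_model import WellPrior
from .rfa_mrf import (
    UNASSIGNED,
    CandidateMolecule,
    MRFState,
    compute_log_potential,
)

logger = logging.getLogger(__name__)

MAPQ_CAP = 60
DEFAULT_CAP_LOCAL = 12
JOINT_STATE_CAP = 2_000
EXISTENCE_CUTOFF = 0.9
CONFIDENCE_FILTER_MAPQ = 10


def posterior_to_mapq(posterior: float) -> int:
    """Phred contract: p -> floor(-10 log10(1 - p)), capped at 60.

    floor (rather than round) keeps the contract posterior >= 0.9 <=> MAPQ
    >= 10 exact.
    """
    if posterior >= 1.0 - 10 ** (-MAPQ_CAP / 10.0):
        return MAPQ_CAP
    if posterior <= 0.0:
        return 0
    return min(MAPQ_CAP, int(-10.0 * math.log10(1.0 - posterior) + 1e-9))


@dataclass
class ReadConfidence:
    read_id: str
    posterior: float
    mapq: int
    choice: int  # domain index at MAP, or UNASSIGNED


@dataclass
class CloudConfidence:
    cloud_id: int
    log_quality: float
    existence_posterior: float
    excluded: bool
    low_quality: bool = False


def _footprints(state: MRFState, n: int) -> list[tuple[int, int, int]]:
    """(molecule index, start col, end col) footprint of read n's domain."""
    frag = state.graph.fragments[n]
    rlen = len(frag.seq)
    return [(mi, aln.offset, aln.offset + rlen) for aln, mi in state.graph.options[n]]


def _local_reads(state: MRFState, n: int) -> list[int]:
    """Ambiguous reads sharing a covered reference position with any
    candidate alignment of read n (read n excluded).  Single-candidate
    reads are pinned by their domain and are left fixed at the MAP."""
    foot = _footprints(state, n)
    out = []
    for m, opts in enumerate(state.graph.options):
        if m == n or len(opts) < 2:
            continue
        rlen = len(state.graph.fragments[m].seq)
        hit = False
        for aln, mi in opts:
            for fmi, fs, fe in foot:
                if mi == fmi and aln.offset < fe and fs < aln.offset + rlen:
                    hit = True
                    break
            if hit:
                break
        if hit:
            out.append(m)
    return out


def read_posterior(
    n: int,
    state: MRFState,
    cap_local: int = DEFAULT_CAP_LOCAL,
    joint_state_cap: int = JOINT_STATE_CAP,
) -> ReadConfidence:
    """Posterior mass of read n's MAP placement under local marginalisation.

    If the local read set is small (<= cap_local reads whose joint domain
    is enumerable), read n and its neighbours are marginalised jointly;
    otherwise neighbours stay fixed at the MAP and read n alone is
    marginalised.  Mutates nothing: the state is restored on exit.
    """
    graph = state.graph
    frag = graph.fragments[n]
    map_k = int(state.choice[n])
    if frag.high_copy:
        return ReadConfidence(frag.read_id, 0.0, 0, map_k)
    opts = graph.options[n]
    if not opts:
        return ReadConfidence(frag.read_id, 0.0, 0, UNASSIGNED)

    neighbours = _local_reads(state, n) if len(opts) > 1 else []
    n_states = len(opts) + 1
    for m in neighbours:
        n_states *= len(graph.options[m]) + 1
    my_options = list(range(len(opts))) + [UNASSIGNED]

    if neighbours and len(neighbours) <= cap_local and n_states <= joint_state_cap:
        reads = [n] + neighbours
        saved = [(m, int(state.choice[m])) for m in reads]
        mass = {k: [] for k in my_options}

        def rec(i: int):
            if i == len(reads):
                mass[int(state.choice[n])].append(state.total)
                return
            m = reads[i]
            for k in list(range(len(graph.options[m]))) + [UNASSIGNED]:
                state.set_choice(m, k)
                rec(i + 1)

        rec(0)
        for m, k in saved:
            state.set_choice(m, k)
        logmass = {k: logsumexp(v) for k, v in mass.items()}
    else:
        saved_k = int(state.choice[n])
        logmass = {}
        for k in my_options:
            state.set_choice(n, k)
            logmass[k] = state.total
        state.set_choice(n, saved_k)

    tot = logsumexp(list(logmass.values()))
    posterior = float(np.exp(logmass[map_k] - tot))
    return ReadConfidence(frag.read_id, posterior, posterior_to_mapq(posterior), map_k)


def cloud_quality(
    molecule: CandidateMolecule,
    assigned_reads,
    prior: WellPrior,
) -> float:
    """log P(R_c) at the MAP read set — the same elimination that computes
    the potential."""
    return compute_log_potential(molecule, assigned_reads, prior)


def existence_posterior(mi: int, state: MRFState) -> float:
    """Approximate P(E_c = 1 | rest of MAP) for active molecule mi.

    The whole read set of mi is re-placed into each *inactive* candidate
    molecule that can accommodate every member read; the resulting scores
    are softmax-renormalised and the MAP placement's mass returned.  With
    no alternative placement the posterior is 1.
    """
    reads = state.reads_of_molecule(mi)
    if not reads:
        return 1.0
    # inactive molecules able to host every member read
    cands: set[int] | None = None
    for n in reads:
        mols = {m for _, m in state.graph.options[n]}
        cands = mols if cands is None else cands & mols
    cands.discard(mi)
    occupied = {state.graph.options[n][k][1]
                for n, k in enumerate(state.choice) if k != UNASSIGNED}
    targets = sorted(c for c in cands if c not in occupied)
    if not targets:
        return 1.0
    from .rfa_mrf import _best_option_in

    saved = [(n, int(state.choice[n])) for n in reads]
    scores = [state.total]
    for t in targets:
        ok = True
        for n in reads:
            k = _best_option_in(state, n, t)
            if k is None:
                ok = False
                break
            state.set_choice(n, k)
        if ok:
            scores.append(state.total)
        for n, k in saved:
            state.set_choice(n, k)
    arr = np.asarray(scores)
    return float(np.exp(arr[0] - logsumexp(arr)))


def _marker_sites(
    cloud: CandidateCloud, alignments: list[Pass1Alignment]
) -> list[tuple[int, int]]:
    """Distinct marker positions in a cloud: marker starts clustered within
    one read length count as one site.  Returns (site position, read_length)."""
    ms = sorted(
        (a.start, a.read_length)
        for a in alignments
        if a.read_id in cloud.member_read_ids and a.end_marker
    )
    sites = []
    for pos, rlen in ms:
        if sites and pos - sites[-1][0] <= rlen:
            continue
        sites.append((pos, rlen))
    return sites


def detect_collisions(
    clouds: list[CandidateCloud],
    alignments: list[Pass1Alignment],
    marker_eff: float,
) -> tuple[set, set, float]:
    """Flag clouds formed by two overlapping long fragments.

    Run after end-marker splitting: a cloud showing more than two distinct
    marker sites, or retaining a strictly interior marker site (one the
    split rule could not act on), is a collision; its reads are excluded
    from variant-ready output.  Also returns the analytic detection
    probability 1 - (1 - marker_eff)^2 — the chance at least one of the two
    junction-adjacent end-markers was observed; both this and the
    both-markers expression 1 - marker_eff^2 are logged, since only the
    at-least-one form matches a ~95% detection rate at marker_eff = 0.77.

    Returns (excluded_read_ids, flagged_cloud_ids, analytic_rate).
    """
    analytic = 1.0 - (1.0 - marker_eff) ** 2
    logger.info(
        "collision detection: 1-(1-p)^2 = %.4f (cf. 1-p^2 = %.4f) at p = %.3f",
        analytic, 1.0 - marker_eff ** 2, marker_eff,
    )
    excluded: set = set()
    flagged: set = set()
    for cloud in clouds:
        sites = _marker_sites(cloud, alignments)
        interior = [
            (pos, rlen)
            for pos, rlen in sites
            if pos > cloud.start + rlen and pos + 2 * rlen < cloud.end
        ]
        if len(sites) > 2 or interior:
            flagged.add(cloud.cloud_id)
            excluded |= set(cloud.member_read_ids)
    return excluded, flagged, analytic


def simulate_collision_detection(
    n_collisions: int,
    marker_eff: float,
    rng,
    fragment_size: int = 5000,
    read_length: int = 100,
    read_spacing: int = 60,
    min_reads: int = 6,
) -> float:
    """Empirical collision-detection rate on constructed overlap events.

    Each event: two equal-size fragments overlapping by a uniform margin,
    member reads tiled densely along each fragment, boundary end-markers
    drawn independently with probability ``marker_eff`` per fragment end.
    The merged cloud goes through the split rule and then
    ``detect_collisions``; returns the flagged fraction.
    """
    from .cloud_seeding import seed_clouds

    detected = 0
    for i in range(n_collisions):
        overlap = int(rng.integers(3 * read_length, fragment_size - 3 * read_length))
        a_start = 0
        b_start = fragment_size - overlap
        alns = []
        rid = 0
        for fstart, tag in ((a_start, "A"), (b_start, "B")):
            fend = fstart + fragment_size
            for pos in range(fstart, fend - read_length + 1, read_spacing):
                alns.append(
                    Pass1Alignment(f"c{i}_{tag}{rid}", "chr1", pos,
                                   read_length=read_length)
                )
                rid += 1
            if rng.random() < marker_eff:  # left marker
                alns.append(
                    Pass1Alignment(f"c{i}_{tag}{rid}", "chr1", fstart,
                                   end_marker=True, read_length=read_length)
                )
                rid += 1
            if rng.random() < marker_eff:  # right marker
                alns.append(
                    Pass1Alignment(f"c{i}_{tag}{rid}", "chr1",
                                   fend - read_length,
                                   end_marker=True, read_length=read_length)
                )
                rid += 1
        clouds = seed_clouds(alns, min_reads=min_reads)
        _, flagged, _ = detect_collisions(clouds, alns, marker_eff)
        if flagged:
            detected += 1
    return detected / n_collisions


def null_log_qualities(
    state: MRFState,
    rng,
    shuffles_per_molecule: int = 3,
    qual_bin: int = 5,
) -> np.ndarray:
    """Per-well null distribution of cloud log-qualities: each active
    molecule re-scored with its reads' bases shuffled within base-quality
    strata (bins of ``qual_bin`` phred units)."""
    from .rfa_mrf import MoleculeScorer
    from .simulator import encode, decode

    nulls = []
    for mi, mol in enumerate(state.graph.molecules):
        reads = state.reads_of_molecule(mi)
        if not reads:
            continue
        for _ in range(shuffles_per_molecule):
            sc = MoleculeScorer(mol, state.prior)
            for n in reads:
                frag = state.graph.fragments[n]
                aln = state.graph.options[n][int(state.choice[n])][0]
                b = encode(frag.seq).copy()
                strata = np.asarray(frag.quals) // qual_bin
                for s in np.unique(strata):
                    idx = np.where(strata == s)[0]
                    b[idx] = b[rng.permutation(idx)]
                shuffled = ReadFragment(
                    read_id=frag.read_id, seq=decode(b), quals=frag.quals,
                    end_marker=frag.end_marker, alignments=frag.alignments,
                )
                sc.add_read(shuffled, aln)
            nulls.append(sc.log_potential())
    return np.asarray(nulls)


def well_confidences(
    state: MRFState,
    rng=None,
    cap_local: int = DEFAULT_CAP_LOCAL,
    existence_cutoff: float = EXISTENCE_CUTOFF,
    low_quality_percentile: float = 1.0,
) -> tuple[list[ReadConfidence], list[CloudConfidence]]:
    """All post-MAP queries for one well: per-read confidence and per-cloud
    quality/existence with exclusion flags."""
    rconf = [read_posterior(n, state, cap_local=cap_local)
             for n in range(len(state.graph.fragments))]
    cconf = []
    nulls = None
    if rng is not None:
        nulls = null_log_qualities(state, rng)
    cut = np.percentile(nulls, low_quality_percentile) if nulls is not None and len(nulls) else -np.inf
    for mi, mol in enumerate(state.graph.molecules):
        if not state.reads_of_molecule(mi):
            continue
        lq = float(state._pot[mi])
        ep = existence_posterior(mi, state)
        low = bool(lq < cut)
        cconf.append(
            CloudConfidence(
                cloud_id=mol.cloud_id,
                log_quality=lq,
                existence_posterior=ep,
                excluded=bool(ep < existence_cutoff) or low,
                low_quality=low,
            )
        )
    return rconf, cconf
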