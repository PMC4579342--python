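"""Shared fixtures: hand-built molecules, fragments and priors, plus an
independent brute-force potential oracle used across the MRF tests."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from rfaligner.cloud_seeding import CandidateAlignment, Contig, ReadFragment
from rfaligner.prior_model import CloudFeatures, PriorConfig, fit_prior
from rfaligner.rfa_mrf import CandidateMolecule
from rfaligner.simulator import decode, encode


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_prior(
    genome_length: int = 1_000_000,
    theta: float = 1e-3,
    p_exist: float = 0.5,
    frag_mu: float = 9.2,
    frag_sigma: float = 0.3,
    density: float = 0.015,
    n: int = 400,
    seed: int = 7,
):
    """A prior fitted on synthetic (size, density) features — full API
    object with controlled scalars."""
    r = np.random.default_rng(seed)
    feats = []
    for _ in range(n):
        s = float(np.exp(r.normal(frag_mu, frag_sigma)))
        lam = float(density * np.exp(r.normal(0, 0.2)))
        feats.append(
            CloudFeatures(
                size_bp=int(s),
                read_count=max(1, int(lam * s)),
                density=lam,
                left_marker=bool(r.random() < 0.77),
                right_marker=bool(r.random() < 0.77),
            )
        )
    prior = fit_prior(feats, PriorConfig(genome_length=genome_length, theta=theta))
    prior.p_exist = p_exist
    return prior


@pytest.fixture
def prior():
    return make_prior()


def toy_prior(**kw):
    """Prior matched to the tiny (tens of bp) molecules used in the MRF
    unit tests, so that assigning reads is favourable."""
    kw.setdefault("genome_length", 10_000)
    kw.setdefault("frag_mu", math.log(60.0))
    kw.setdefault("frag_sigma", 0.4)
    kw.setdefault("density", 0.15)
    return make_prior(**kw)


def make_contig(seq: str, cloud_id: int = 0, origin_start: int = 0,
                chrom: str = "chr1") -> Contig:
    return Contig(
        cloud_id=cloud_id, name=f"cloud{cloud_id}", sequence=seq,
        origin_chrom=chrom, origin_start=origin_start,
        cloud_start=origin_start, cloud_end=origin_start + len(seq),
    )


def make_molecule(seq: str, cloud_id: int = 0, origin_start: int = 0) -> CandidateMolecule:
    c = make_contig(seq, cloud_id, origin_start)
    return CandidateMolecule(
        index=cloud_id, cloud_id=cloud_id, contig=c, chrom=c.origin_chrom,
        start=c.cloud_start, size=len(seq),
    )


def make_fragment(read_id: str, seq: str, qual: int = 30,
                  end_marker: bool = False,
                  alignments: list[CandidateAlignment] | None = None) -> ReadFragment:
    return ReadFragment(
        read_id=read_id, seq=seq,
        quals=np.full(len(seq), qual, dtype=np.int64),
        end_marker=end_marker, alignments=alignments or [],
    )


def aln(cloud_id: int, offset: int, strand: str = "+", score: float = 0.0,
        cigar=None) -> CandidateAlignment:
    return CandidateAlignment(
        contig_id=cloud_id, contig_name=f"cloud{cloud_id}", offset=offset,
        strand=strand, score=score, cigar=cigar,
    )


def brute_force_log_potential(molecule, assigned, prior) -> float:
    """Independent oracle for log phi_c: exhaustive sum over every hidden
    molecule sequence X (4^L) and trapezoid quadrature over the lambda
    grid.  Only feasible for contigs of a few bases."""
    from rfaligner.rfa_mrf import LOG_INDEL_PENALTY, oriented_read

    if not assigned:
        return math.log1p(-prior.p_exist)
    L = len(molecule.contig.sequence)
    ref = encode(molecule.contig.sequence)
    theta = prior.theta

    # effective size = span of assigned alignments
    starts = [a.offset for _, a in assigned]
    ends = [a.offset + len(f.seq) for f, a in assigned]
    s = max(1, max(ends) - min(starts))
    n = len(assigned)

    # per-read observation probability table P(obs_j | x) per column
    obs = []  # list of (col, base, err)
    for f, a in assigned:
        b, q = oriented_read(f, a.strand)
        e = 10.0 ** (-q / 10.0)
        for j in range(len(b)):
            obs.append((a.offset + j, int(b[j]), float(e[j])))

    total_x = 0.0
    for x in itertools.product(range(4), repeat=L):
        px = 1.0
        for l in range(L):
            px *= (1 - theta) if x[l] == ref[l] else theta / 3.0
        lik = 1.0
        for col, base, e in obs:
            lik *= (1 - e) if x[col] == base else e / 3.0
        total_x += px * lik

    lam = prior.lambda_grid
    w = np.empty_like(lam)
    w[1:-1] = 0.5 * (lam[2:] - lam[:-2])
    w[0] = 0.5 * (lam[1] - lam[0])
    w[-1] = 0.5 * (lam[-1] - lam[-2])
    # marker state from assigned end-marker reads near boundaries
    ml = mr = False
    cbs = molecule.contig.cloud_start - molecule.contig.origin_start
    cbe = molecule.contig.cloud_end - molecule.contig.origin_start
    for f, a in assigned:
        if f.end_marker:
            rlen = len(f.seq)
            if a.offset <= cbs + rlen:
                ml = True
            elif a.offset + rlen >= cbe - rlen:
                mr = True
    b_state = (int(ml), int(mr))
    kde = prior.kde_for(b_state)
    pts = np.column_stack([np.full_like(lam, math.log(s)), np.log(lam)])
    # log-space quadrature: the KDE density can underflow linearly
    log_terms = (
        np.log(w)
        + kde.logpdf(pts) - math.log(s) - np.log(lam)
        + n * np.log(lam * s) - lam * s - math.lgamma(n + 1)
    )
    from scipy.special import logsumexp

    lam_log = float(logsumexp(log_terms))

    indels = sum(a.indel_events for _, a in assigned)
    return (
        math.log(prior.p_exist)
        + prior.log_pB(b_state)
        - math.log(prior.genome_length)
        + lam_log
        - n * math.log(s)
        + math.log(total_x)
        + indels * LOG_INDEL_PENALTY
    )


def random_seq(rng, length: int) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))
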