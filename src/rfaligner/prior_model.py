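"""Prior over hidden long molecules, learned from uniquely mapped clouds.

The per-molecule prior factorises as

    P(M_c) = P(E_c) * P(B_c) * P(S_c, lambda_c | B_c) * P(L_c | E_c)
             * prod_l P(X_l | E_c)

with E_c ~ Bernoulli(p_exist) the seed-is-real indicator, B_c the observed
end-marker pair, (S_c, lambda_c) the fragment size (bp) and read density
(reads/bp) modelled jointly by a 2-D kernel density estimate in
(log S, log lambda) per marker state, L_c uniform over the usable genome,
and X_l a categorical over bases putting 1-theta on the reference base and
theta/3 on each alternative (theta = SNP-rate prior, shared across
positions).  Everything conditioned on E_c = 0 is 1.

The size/density density and the marker table are learned from the
features of uniquely mapped training clouds; lambda_c is later eliminated
by quadrature on a fixed log-spaced grid stored here.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .cloud_seeding import CandidateCloud

logger = logging.getLogger(__name__)

B_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))
MIN_TRAINING_CLOUDS = 50
MIN_PER_STATE = 20


@dataclass
class CloudFeatures:
    size_bp: int
    read_count: int
    density: float
    left_marker: bool
    right_marker: bool

    @property
    def b_state(self) -> tuple[int, int]:
        return (int(self.left_marker), int(self.right_marker))


class DiagonalKDE2D:
    """2-D Gaussian product-kernel density with per-dimension Scott
    bandwidths floored at ``bw_floor`` (heavy right tails in fragment size
    make a floor necessary; degenerate all-identical data falls back to the
    floor alone)."""

    def __init__(self, data: np.ndarray, bw_floor: float = 0.05):
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[1] != 2:
            raise ValueError("expected n x 2 data")
        self.data = data
        n = len(data)
        scott = n ** (-1.0 / 6.0)
        sd = data.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
        self.bw = np.maximum(scott * sd, bw_floor)

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        # (m, n) standardized squared distances per dim
        z0 = (pts[:, None, 0] - self.data[None, :, 0]) / self.bw[0]
        z1 = (pts[:, None, 1] - self.data[None, :, 1]) / self.bw[1]
        logk = -0.5 * (z0 ** 2 + z1 ** 2) - math.log(
            2 * math.pi * self.bw[0] * self.bw[1]
        )
        return logsumexp(logk, axis=1) - math.log(len(self.data))

    def pdf(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(points))


@dataclass
class WellPrior:
    """Learned protocol prior P(M) for one library."""

    p_exist: float
    theta: float
    marker_eff: float
    pB: dict  # b-state tuple -> probability
    kdes: dict  # b-state tuple -> DiagonalKDE2D over (log S, log lambda)
    pooled_kde: DiagonalKDE2D
    lambda_grid: np.ndarray
    genome_length: int
    p_offtarget: float = 1e-5

    def kde_for(self, b_state: tuple[int, int]) -> DiagonalKDE2D:
        return self.kdes.get(tuple(b_state), self.pooled_kde)

    def log_pB(self, b_state) -> float:
        return math.log(self.pB[tuple(b_state)])

    # --- serialisation (single JSON file; wells can be aligned without
    # re-training) ---
    def to_json(self) -> str:
        d = {
            "p_exist": self.p_exist,
            "theta": self.theta,
            "marker_eff": self.marker_eff,
            "p_offtarget": self.p_offtarget,
            "genome_length": self.genome_length,
            "pB": {f"{k[0]}{k[1]}": v for k, v in self.pB.items()},
            "lambda_grid": self.lambda_grid.tolist(),
            "kdes": {
                f"{k[0]}{k[1]}": {"data": kde.data.tolist(), "bw": kde.bw.tolist()}
                for k, kde in self.kdes.items()
            },
            "pooled_kde": {
                "data": self.pooled_kde.data.tolist(),
                "bw": self.pooled_kde.bw.tolist(),
            },
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "WellPrior":
        d = json.loads(text)

        def mk(kd):
            k = DiagonalKDE2D(np.asarray(kd["data"]))
            k.bw = np.asarray(kd["bw"])
            return k

        return cls(
            p_exist=d["p_exist"],
            theta=d["theta"],
            marker_eff=d["marker_eff"],
            p_offtarget=d.get("p_offtarget", 1e-5),
            genome_length=d["genome_length"],
            pB={(int(k[0]), int(k[1])): v for k, v in d["pB"].items()},
            lambda_grid=np.asarray(d["lambda_grid"]),
            kdes={(int(k[0]), int(k[1])): mk(v) for k, v in d["kdes"].items()},
            pooled_kde=mk(d["pooled_kde"]),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            f.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "WellPrior":
        with open(path) as f:
            return cls.from_json(f.read())

    def fragment_size_mean(self, n_grid: int = 400) -> float:
        """E[S] under the pooled size/density KDE, by grid integration of
        the marginal over log S."""
        ls = self.pooled_kde.data[:, 0]
        lo, hi = ls.min() - 4 * self.pooled_kde.bw[0], ls.max() + 4 * self.pooled_kde.bw[0]
        grid = np.linspace(lo, hi, n_grid)
        # marginal over log S of a product-kernel KDE is the 1-D KDE
        z = (grid[:, None] - ls[None, :]) / self.pooled_kde.bw[0]
        dens = np.exp(-0.5 * z ** 2).sum(axis=1) / (
            len(ls) * self.pooled_kde.bw[0] * math.sqrt(2 * math.pi)
        )
        w = np.trapezoid(dens, grid)
        return float(np.trapezoid(np.exp(grid) * dens, grid) / w)


@dataclass
class PriorConfig:
    genome_length: int
    well_fraction: float = 0.02
    clouds_per_well: float | None = None
    theta: float = 1e-3
    p_offtarget: float = 1e-5
    lambda_grid_size: int = 64
    bw_floor: float = 0.05
    min_per_state: int = MIN_PER_STATE
    outlier_quantile: float = 0.99


def extract_features(
    clouds: list[CandidateCloud],
    read_counts: dict[int, int] | None = None,
    outlier_quantile: float = 0.99,
    min_clouds: int = MIN_TRAINING_CLOUDS,
    well_of: dict[int, int] | None = None,
) -> list[CloudFeatures]:
    """Features of uniquely mapped training clouds, with outliers removed.

    A cloud whose read density exceeds the ``outlier_quantile`` of the
    training set (unusually high coverage, e.g. copy-number variants or
    low-mappability pileups), or whose interval overlaps another training
    cloud of the *same well* (a collision candidate; ``well_of`` maps
    cloud_id to well, all clouds assumed co-well when omitted), is dropped.
    """
    feats = []
    ivals = []
    for c in clouds:
        n = read_counts[c.cloud_id] if read_counts else len(c.member_read_ids)
        if c.size <= 0 or n <= 0:
            continue
        feats.append(
            CloudFeatures(
                size_bp=c.size,
                read_count=n,
                density=n / c.size,
                left_marker=c.left_marker,
                right_marker=c.right_marker,
            )
        )
        w = well_of.get(c.cloud_id, 0) if well_of else 0
        ivals.append((w, c.chrom, c.start, c.end))
    dens = np.array([f.density for f in feats])
    if len(feats):
        cut = np.quantile(dens, outlier_quantile)
        keep = dens <= cut
        # drop clouds overlapping another training cloud in the same well
        for i, (w, chrom, s, e) in enumerate(ivals):
            for j, (w2, chrom2, s2, e2) in enumerate(ivals):
                if i != j and w == w2 and chrom == chrom2 and s < e2 and s2 < e:
                    keep[i] = False
                    break
        feats = [f for f, k in zip(feats, keep) if k]
    if len(feats) < min_clouds:
        raise ValueError(
            f"only {len(feats)} training clouds retained (< {min_clouds}); "
            "supply more training wells"
        )
    return feats


def fit_prior(features: list[CloudFeatures], config: PriorConfig) -> WellPrior:
    """Fit the protocol prior from training-cloud features."""
    if len(features) < MIN_TRAINING_CLOUDS:
        raise ValueError("need at least 50 training cloud features")
    counts = {b: 0 for b in B_STATES}
    for f in features:
        counts[f.b_state] += 1
    n = len(features)
    pB = {b: (counts[b] + 1.0) / (n + 4.0) for b in B_STATES}

    pts = np.array([[math.log(f.size_bp), math.log(f.density)] for f in features])
    pooled = DiagonalKDE2D(pts, bw_floor=config.bw_floor)
    kdes = {}
    for b in B_STATES:
        sub = pts[[f.b_state == b for f in features]]
        if len(sub) >= config.min_per_state:
            kdes[b] = DiagonalKDE2D(sub, bw_floor=config.bw_floor)

    marked = sum(f.left_marker + f.right_marker for f in features)
    marker_eff = marked / (2.0 * n)

    dens = np.array([f.density for f in features])
    lo, hi = np.quantile(dens, [0.01, 0.99])
    if not hi > lo:
        lo, hi = dens.min() * 0.5 + 1e-12, dens.max() * 2 + 1e-9
    lam_grid = np.geomspace(max(lo, 1e-9), hi, config.lambda_grid_size)

    mean_size = float(np.mean([f.size_bp for f in features]))
    expected_frags = config.well_fraction * config.genome_length / mean_size
    cpw = config.clouds_per_well if config.clouds_per_well else expected_frags
    p_exist = float(np.clip(expected_frags / cpw, 1e-3, 0.99))

    return WellPrior(
        p_exist=p_exist,
        theta=config.theta,
        marker_eff=marker_eff,
        pB=pB,
        kdes=kdes,
        pooled_kde=pooled,
        lambda_grid=lam_grid,
        genome_length=config.genome_length,
        p_offtarget=config.p_offtarget,
    )


def default_prior(
    genome_length: int,
    theta: float = 1e-3,
    marker_eff: float = 0.77,
    p_exist: float = 0.5,
    frag_mu: float = 9.2,
    frag_sigma: float = 0.3,
    c_r: float = 1.5,
    read_length: int = 100,
    seed: int = 0,
    n_synth: int = 500,
) -> WellPrior:
    """Untrained fallback prior built from nominal protocol settings by
    sampling synthetic (size, density) features."""
    rng = np.random.default_rng(seed)
    feats = []
    for _ in range(n_synth):
        s = int(np.exp(rng.normal(frag_mu, frag_sigma)))
        nreads = max(1, rng.poisson(c_r * s / read_length))
        feats.append(
            CloudFeatures(
                size_bp=s, read_count=nreads, density=nreads / s,
                left_marker=bool(rng.random() < marker_eff),
                right_marker=bool(rng.random() < marker_eff),
            )
        )
    cfg = PriorConfig(genome_length=genome_length, theta=theta)
    prior = fit_prior(feats, cfg)
    prior.p_exist = p_exist
    return prior


def prior_logprob(molecule, prior: WellPrior) -> float:
    """log of the (E, B, location) part of the molecule prior; the (S,
    lambda) term is deferred to the potential's grid elimination.

    ``molecule`` needs attributes ``exists`` (bool) and ``b_state``.
    """
    if not molecule.exists:
        return math.log1p(-prior.p_exist)
    return (
        math.log(prior.p_exist)
        + prior.log_pB(molecule.b_state)
        - math.log(prior.genome_length)
    )
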