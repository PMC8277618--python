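"""Two-point linkage estimation for autopolyploid F1 populations.

For a pair of markers, the expected joint offspring dosage table E(n_ij) is
a function of the recombination fraction r, the two parental segregation
types and the phase of the pair in each parent.  Under random bivalent
pairing, homologs are exchangeable, so the phase in one parent is fully
captured by the overlap count m = |S_A ∩ S_B| between the homolog sets
carrying the counted allele at the two loci (maximal overlap = coupling,
zero = repulsion).

The joint gamete distribution is computed by exact enumeration over
bivalent matchings; each table entry is a polynomial in r of degree at most
ploidy/2 per parent, which this module caches as coefficient tensors so
likelihood evaluations reduce to a polynomial evaluation plus a tensor
contraction.

Two likelihoods are provided: the discrete likelihood over observed class
counts O(n_ij)

    log L(r) = sum_ij O(n_ij) log E(n_ij),

and the full probabilistic likelihood over per-individual joint genotype
probabilities p_ij,z

    log L(r) = sum_z log sum_ij p_ij,z E(n_ij),

which reduces exactly to the discrete form when every posterior is one-hot.
The joint probability p_ij,z is taken as the product of the two per-locus
posteriors (calling noise assumed independent across loci).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .calling import MISSING, DosagePosteriors
from .simulate import _perfect_matchings

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


def phase_overlap_range(dA: int, dB: int, ploidy: int = 4) -> range:
    """Admissible overlap counts m = |S_A ∩ S_B| for dosages (dA, dB)."""
    return range(max(0, dA + dB - ploidy), min(dA, dB) + 1)


@dataclass(frozen=True)
class PhaseClass:
    """Phase of a marker pair in both parents, as overlap counts."""

    m1: int
    m2: int

    @property
    def overlaps(self) -> tuple[int, int]:
        return (self.m1, self.m2)


def _poly_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.convolve(a, b)


@lru_cache(maxsize=None)
def _gamete_poly(dA: int, dB: int, m: int, ploidy: int = 4) -> np.ndarray:
    """Joint gamete-dosage distribution as polynomials in r.

    Returns coefficients ``C[gA, gB, :]`` with
    P(gA, gB | r) = sum_k C[gA, gB, k] r^k, exact under uniform bivalent
    matchings, one transmitted chromatid per bivalent, and per-chromatid
    switch probability r between the loci.
    """
    if m not in phase_overlap_range(dA, dB, ploidy):
        raise ValueError(f"overlap {m} impossible for dosages ({dA}, {dB})")
    n = ploidy // 2
    S_A = set(range(dA))
    S_B = set(range(m)) | set(range(dA, dA + dB - m))
    deg = n  # one switch factor per bivalent
    out = np.zeros((n + 1, n + 1, deg + 1))
    matchings = _perfect_matchings(ploidy)
    for matching in matchings:
        # dist over (gA, gB) accumulated across bivalents; poly coeffs in r
        dist = {(0, 0): np.array([1.0])}
        for h1, h2 in matching:
            biv: dict[tuple[int, int], np.ndarray] = {}
            for h, other in ((h1, h2), (h2, h1)):
                a = int(h in S_A)
                # same-origin chromatid at locus B: weight (1 - r)/2
                key = (a, int(h in S_B))
                biv[key] = biv.get(key, np.zeros(2)) + np.array([0.5, -0.5])
                # switched origin: weight r/2
                key = (a, int(other in S_B))
                biv[key] = biv.get(key, np.zeros(2)) + np.array([0.0, 0.5])
            new: dict[tuple[int, int], np.ndarray] = {}
            for (ga, gb), pa in dist.items():
                for (xa, xb), pb in biv.items():
                    k = (ga + xa, gb + xb)
                    v = _poly_mul(pa, pb)
                    if k in new:
                        prev = new[k]
                        L = max(len(prev), len(v))
                        s = np.zeros(L)
                        s[: len(prev)] += prev
                        s[: len(v)] += v
                        new[k] = s
                    else:
                        new[k] = v
            dist = new
        for (ga, gb), p in dist.items():
            out[ga, gb, : len(p)] += p / len(matchings)
    return out


def two_locus_gamete_dist(
    dA: int, dB: int, m: int, r: float, ploidy: int = 4
) -> np.ndarray:
    """Joint distribution of gamete dosages at two loci for one parent.

    Depends on the dosages and the phase only through the overlap count m,
    by homolog exchangeability.  Returns an (n+1, n+1) array, n = ploidy/2.
    """
    if not 0 <= r <= 0.5:
        raise ValueError("r must be in [0, 0.5]")
    C = _gamete_poly(dA, dB, m, ploidy)
    powers = r ** np.arange(C.shape[2])
    return C @ powers


@lru_cache(maxsize=None)
def _offspring_poly(
    segA: tuple[int, int], segB: tuple[int, int], m1: int, m2: int, ploidy: int = 4
) -> np.ndarray:
    """E(n_ij) as polynomials in r: coefficients (ploidy+1, ploidy+1, deg+1)."""
    n = ploidy // 2
    G1 = _gamete_poly(segA[0], segB[0], m1, ploidy)
    G2 = _gamete_poly(segA[1], segB[1], m2, ploidy)
    deg = 2 * n
    E = np.zeros((ploidy + 1, ploidy + 1, deg + 1))
    for g1a in range(n + 1):
        for g1b in range(n + 1):
            for g2a in range(n + 1):
                for g2b in range(n + 1):
                    p = _poly_mul(G1[g1a, g1b], G2[g2a, g2b])
                    E[g1a + g2a, g1b + g2b, : len(p)] += p
    return E


def expected_offspring_table(
    segA: tuple[int, int],
    segB: tuple[int, int],
    phase: PhaseClass,
    r: float,
    ploidy: int = 4,
) -> np.ndarray:
    """Expected offspring joint dosage frequencies E(n_ij) at fraction r.

    The convolution over dosage pairs of the two parents' two-locus gamete
    distributions; rows index the dosage at marker A, columns at marker B.
    """
    C = _offspring_poly(tuple(segA), tuple(segB), phase.m1, phase.m2, ploidy)
    return C @ (r ** np.arange(C.shape[2]))


def loglik_discrete(counts: np.ndarray, E: np.ndarray) -> float:
    """Discrete two-point log-likelihood sum_ij O(n_ij) log E(n_ij).

    Cells with zero count contribute nothing regardless of E; a positive
    count on a zero-probability cell yields -inf.
    """
    O = np.asarray(counts, dtype=float)
    pos = O > 0
    if np.any(E[pos] <= 0):
        return -np.inf
    return float(np.sum(O[pos] * np.log(E[pos])))


def loglik_probabilistic(
    P_A: np.ndarray, P_B: np.ndarray, E: np.ndarray
) -> float:
    """Full probabilistic two-point log-likelihood.

    P_A, P_B are (individuals x ploidy+1) posterior matrices; the joint
    genotype probability of individual z is the outer product
    P_A[z, i] * P_B[z, j].
    """
    L = np.einsum("zi,ij,zj->z", P_A, E, P_B)
    if np.any(L <= 0):
        if np.any((P_A.sum(axis=1) == 0) | (P_B.sum(axis=1) == 0)):
            raise ValueError("individual with all-zero joint genotype mass")
        return -np.inf
    return float(np.log(L).sum())


@dataclass
class PairwiseLinkage:
    """Maximum-likelihood two-point result for one marker pair."""

    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    phase: PhaseClass
    loglik: float
    n_informative: int
    mode: str


def _counts_from_discrete(
    dA: np.ndarray, dB: np.ndarray, ploidy: int
) -> tuple[np.ndarray, int]:
    keep = (dA != MISSING) & (dB != MISSING)
    O = np.zeros((ploidy + 1, ploidy + 1))
    np.add.at(O, (dA[keep], dB[keep]), 1.0)
    return O, int(keep.sum())


def estimate_r(
    data_a,
    data_b,
    segA: tuple[int, int],
    segB: tuple[int, int],
    mode: str = "probabilistic",
    ploidy: int = 4,
    marker_a: str = "A",
    marker_b: str = "B",
    min_informative: int = 10,
    xatol: float = 1e-6,
) -> PairwiseLinkage | None:
    """Maximum-likelihood recombination fraction, LOD and phase for a pair.

    For every admissible phase-class pair the log-likelihood is maximised
    over r in [0, 0.5] by bounded scalar optimisation; the phase with the
    highest optimum is reported (ties broken toward larger overlap, i.e.
    coupling).  LOD = log10 L(r_hat) - log10 L(0.5).

    ``data_a``/``data_b`` are posterior matrices (individuals x ploidy+1)
    in probabilistic mode, or integer dosage vectors with MISSING in
    discrete mode (individuals missing at either marker are dropped).
    Returns None when fewer than ``min_informative`` individuals remain.
    """
    if mode == "discrete":
        O, n_inf = _counts_from_discrete(
            np.asarray(data_a), np.asarray(data_b), ploidy
        )
        if n_inf < min_informative:
            logger.debug("pair (%s, %s): only %d informative", marker_a, marker_b, n_inf)
            return None

        def make_eval(C):
            pos = O > 0

            def grid_ll(Eg):  # Eg: (K, K, G)
                with np.errstate(divide="ignore"):
                    logE = np.where(Eg > 0, np.log(np.maximum(Eg, 1e-300)), -np.inf)
                return np.einsum("ij,ijg->g", O, np.where(pos[:, :, None], logE, 0.0))

            def nll(r):
                return -loglik_discrete(O, C @ (r ** np.arange(C.shape[2])))

            return grid_ll, nll
    else:
        P_A = np.asarray(data_a, dtype=float)
        P_B = np.asarray(data_b, dtype=float)
        n_inf = P_A.shape[0]
        if n_inf < min_informative:
            return None

        def make_eval(C):
            def grid_ll(Eg):
                L = np.einsum("zi,ijg,zj->zg", P_A, Eg, P_B)
                with np.errstate(divide="ignore"):
                    return np.where(
                        (L > 0).all(axis=0), np.log(np.maximum(L, 1e-300)).sum(axis=0), -np.inf
                    )

            def nll(r):
                return -loglik_probabilistic(
                    P_A, P_B, C @ (r ** np.arange(C.shape[2]))
                )

            return grid_ll, nll

    # coarse grid over r to rank phases, then bounded Brent on the leaders
    grid = np.linspace(1e-6, 0.5, 21)
    phases = sorted(
        itertools.product(
            phase_overlap_range(segA[0], segB[0], ploidy),
            phase_overlap_range(segA[1], segB[1], ploidy),
        ),
        key=lambda p: -(p[0] + p[1]),
    )
    scored = []
    for m1, m2 in phases:
        C = _offspring_poly(tuple(segA), tuple(segB), m1, m2, ploidy)
        grid_ll, nll = make_eval(C)
        powers = grid[None, :] ** np.arange(C.shape[2])[:, None]
        ll_grid = grid_ll(np.tensordot(C, powers, axes=(2, 0)))
        gbest = float(np.max(ll_grid))
        scored.append((gbest, m1, m2, nll, float(ll_grid[-1])))
    scored.sort(key=lambda s: -s[0])
    best = None
    for gbest, m1, m2, nll, ll_half in scored[:2]:
        if not np.isfinite(gbest):
            continue
        res = minimize_scalar(
            nll, bounds=(1e-6, 0.5), method="bounded", options={"xatol": xatol}
        )
        ll_opt = -res.fun
        if not np.isfinite(ll_opt):
            continue
        if best is None or ll_opt > best[0] + 1e-9:
            best = (ll_opt, float(res.x), PhaseClass(m1, m2), ll_half)
    if best is None:
        return None
    ll_opt, r_hat, phase, ll_half = best
    lod = max((ll_opt - ll_half) / LOG10, 0.0)
    return PairwiseLinkage(
        marker_a, marker_b, r_hat, lod, phase, ll_opt, n_inf, mode
    )


def pairwise_linkage_scan(
    data,
    seg_types: dict[str, tuple[int, int]],
    mode: str = "probabilistic",
    pairs: list[tuple[str, str]] | None = None,
    ploidy: int = 4,
    min_informative: int = 10,
    parents: tuple[str, str] = ("P1", "P2"),
) -> pd.DataFrame:
    """Two-point scan over marker pairs.

    Parameters
    ----------
    data : DosagePosteriors (probabilistic) or DataFrame of discrete
        dosages (markers x samples, MISSING = -1).
    seg_types : marker -> (d1, d2); only these markers are scanned.
    pairs : optional explicit pair list (for subsampled desk-scale runs);
        by default all unordered pairs are scanned.

    Returns the linkage table: marker_a, marker_b, r, LOD, phase overlaps,
    mode, n_informative.  Deterministic given its inputs.
    """
    if isinstance(data, DosagePosteriors):
        samples = [s for s in data.samples if s not in parents]
        sub = data.select_samples(samples)
        get = {m: sub.P[i] for i, m in enumerate(sub.markers) if m in seg_types}
        if mode == "discrete":
            raise ValueError("discrete mode needs a discrete dosage DataFrame")
    else:
        cols = [c for c in data.columns if c not in parents]
        get = {
            m: data.loc[m, cols].to_numpy()
            for m in data.index
            if m in seg_types
        }
    markers = [m for m in seg_types if m in get]
    if pairs is None:
        pairs = list(itertools.combinations(markers, 2))
    rows = []
    for a, b in pairs:
        res = estimate_r(
            get[a],
            get[b],
            seg_types[a],
            seg_types[b],
            mode=mode,
            ploidy=ploidy,
            marker_a=a,
            marker_b=b,
            min_informative=min_informative,
        )
        if res is None:
            continue
        rows.append(
            (a, b, res.r_hat, res.lod, res.phase.m1, res.phase.m2,
             res.mode, res.n_informative)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_a", "marker_b", "r", "LOD",
            "phase1_overlap", "phase2_overlap", "mode", "n_informative",
        ],
    )
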