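"""Dosage-posterior genotype calling.

Two callers are provided, one per observation channel:

* :func:`call_array` fits, per marker, a (ploidy+1)-component normal mixture
  to arcsine-square-root transformed signal ratios by EM (component means
  initialised at the transformed expected class means, shared variance, free
  mixing proportions).  Posterior dosage probabilities are the component
  responsibilities.
* :func:`call_reads` applies an exact Bayes rule: the posterior over dosages
  is proportional to prior x beta-binomial likelihood of the counted-allele
  read count given the per-dosage read probability and overdispersion.

Posteriors travel through the rest of the pipeline as a
:class:`DosagePosteriors` tensor: markers x samples x (ploidy+1), each
probability vector non-negative and summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from scipy.stats import norm

from .observe import dosage_to_read_prob

#: sentinel for a missing discrete dosage
MISSING = -1


@dataclass
class DosagePosteriors:
    """Dosage posterior tensor: markers x samples x (ploidy+1).

    The central data structure of the pipeline.  ``meta`` holds per-marker
    fit information (e.g. the ``converged`` flag of the array caller).
    """

    P: np.ndarray
    markers: list[str]
    samples: list[str]
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 3:
            raise ValueError("P must be markers x samples x (ploidy+1)")
        if self.P.shape[0] != len(self.markers) or self.P.shape[1] != len(self.samples):
            raise ValueError("index lengths do not match tensor shape")
        if np.any(self.P < -1e-12):
            raise ValueError("negative posterior probability")
        s = self.P.sum(axis=2)
        if np.any(np.abs(s - 1.0) > 1e-6):
            raise ValueError("posterior vectors must sum to 1")

    @property
    def ploidy(self) -> int:
        return self.P.shape[2] - 1

    @property
    def n_markers(self) -> int:
        return self.P.shape[0]

    @property
    def n_samples(self) -> int:
        return self.P.shape[1]

    def marker_index(self, name: str) -> int:
        return self.markers.index(name)

    def argmax(self) -> np.ndarray:
        """Most probable dosage per cell (ties toward the lower dosage)."""
        return np.argmax(self.P, axis=2)

    def max_prob(self) -> np.ndarray:
        return np.max(self.P, axis=2)

    def weighted_dosage(self) -> np.ndarray:
        """Posterior expectation of dosage, markers x samples."""
        return self.P @ np.arange(self.ploidy + 1, dtype=float)

    def select_markers(self, names_or_mask) -> "DosagePosteriors":
        if isinstance(names_or_mask, np.ndarray) and names_or_mask.dtype == bool:
            idx = np.flatnonzero(names_or_mask)
        else:
            pos = {m: i for i, m in enumerate(self.markers)}
            idx = np.array([pos[n] for n in names_or_mask], dtype=int)
        meta = self.meta.iloc[idx] if self.meta is not None else None
        return DosagePosteriors(
            self.P[idx], [self.markers[i] for i in idx], list(self.samples), meta
        )

    def select_samples(self, names) -> "DosagePosteriors":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[n] for n in names], dtype=int)
        return DosagePosteriors(
            self.P[:, idx], list(self.markers), [self.samples[i] for i in idx], self.meta
        )

    def marker_posteriors(self, name: str) -> np.ndarray:
        """Samples x (ploidy+1) posterior matrix of one marker."""
        return self.P[self.marker_index(name)]


def _betabinom_logpmf(k, n, a, b):
    """log PMF of the beta-binomial, vectorised (scipy-free hot path)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )


def read_count_loglik(
    alt: np.ndarray, depth: np.ndarray, p: float, rho: float
) -> np.ndarray:
    """Log-likelihood of counted-allele read counts at success probability p.

    Beta-binomial with intra-class correlation ``rho``; binomial at rho = 0.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    if np.any(alt > depth) or np.any(alt < 0):
        raise ValueError("require 0 <= alt <= depth")
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    if rho == 0:
        k = alt.astype(float)
        n = depth.astype(float)
        return (
            gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * np.log(p) + (n - k) * np.log1p(-p)
        )
    kk = (1.0 - rho) / rho
    return _betabinom_logpmf(alt, depth, p * kk, (1.0 - p) * kk)


def call_reads(
    alt: pd.DataFrame,
    depth: pd.DataFrame,
    ploidy: int = 4,
    eps: float = 0.001,
    bias: float = 1.0,
    overdispersion: float = 0.0,
    prior: np.ndarray | None = None,
) -> DosagePosteriors:
    """Bayesian dosage posteriors from read counts.

    P(dosage k | alt, depth) is proportional to prior[k] times the
    beta-binomial likelihood with per-dosage read probability p_k.  Cells
    with zero depth return the prior.

    Parameters
    ----------
    alt, depth : DataFrames, markers x samples.
    prior : length ploidy+1 distribution over dosages; uniform by default.
        An F1 prior from ``expected_segregation`` may be supplied instead.
    """
    A = alt.to_numpy()
    N = depth.to_numpy()
    if A.shape != N.shape:
        raise ValueError("alt and depth shapes differ")
    if prior is None:
        prior = np.full(ploidy + 1, 1.0 / (ploidy + 1))
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (ploidy + 1,) or np.any(prior < 0):
        raise ValueError("invalid prior")
    prior = prior / prior.sum()

    loglik = np.empty(A.shape + (ploidy + 1,))
    for k in range(ploidy + 1):
        p_k = dosage_to_read_prob(k, ploidy, eps, bias)
        loglik[..., k] = read_count_loglik(A, N, float(p_k), overdispersion)
    logprior = np.full_like(prior, -np.inf)
    logprior[prior > 0] = np.log(prior[prior > 0])
    logpost = loglik + logprior
    logpost -= logpost.max(axis=-1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=-1, keepdims=True)
    # zero-depth cells carry no information: posterior equals the prior
    zero = N == 0
    if np.any(zero):
        post[zero] = prior
    return DosagePosteriors(post, list(alt.index), list(alt.columns))


def _parent_offspring_split(samples: list[str], parents: tuple[str, str]):
    try:
        pidx = [samples.index(p) for p in parents]
    except ValueError as e:
        raise ValueError(f"parent column missing: {e}")
    oidx = [i for i in range(len(samples)) if i not in pidx]
    return pidx, oidx


def _f1_family_posterior(
    loglik: np.ndarray, pidx: list[int], oidx: list[int], ploidy: int
) -> np.ndarray:
    """Joint F1 posterior from per-sample class log-likelihoods of one marker.

    The pair of parental dosages (d1, d2) is a latent variable with a
    uniform prior over all (ploidy+1)^2 combinations.  Each combination's
    likelihood multiplies the parents' class likelihoods with every
    offspring's segregation-mixture likelihood
    sum_k seg_k(d1, d2) * lik_k.  Parent posteriors are the marginals of the
    combination posterior; offspring posteriors average the per-combination
    posterior (segregation prior x likelihood) over the combination weights.

    Parameters
    ----------
    loglik : (n_samples, ploidy+1) class log-likelihood matrix.

    Returns the (n_samples, ploidy+1) posterior matrix.
    """
    from .simulate import expected_segregation

    K = ploidy + 1
    combos = [(d1, d2) for d1 in range(K) for d2 in range(K)]
    seg = np.array([expected_segregation(d1, d2, ploidy) for d1, d2 in combos])
    logseg = np.full_like(seg, -np.inf)
    logseg[seg > 0] = np.log(seg[seg > 0])

    L_off = loglik[oidx]                         # (n_off, K)
    # log sum_k seg_k * lik_k per combination and offspring: (C, n_off)
    mix = logseg[:, None, :] + L_off[None, :, :]
    mmax = mix.max(axis=2, keepdims=True)
    M = mmax[..., 0] + np.log(np.exp(mix - mmax).sum(axis=2))
    joint = (
        loglik[pidx[0]][[c[0] for c in combos]]
        + loglik[pidx[1]][[c[1] for c in combos]]
        + M.sum(axis=1)
    )
    joint -= joint.max()
    w = np.exp(joint)
    w /= w.sum()
    P = np.empty_like(loglik)
    # per-combination offspring posterior, then mixture over combinations
    A_czk = np.exp(mix - M[..., None])           # (C, n_off, K), rows sum to 1
    P_off = np.einsum("c,czk->zk", w, A_czk)
    P[oidx] = P_off / P_off.sum(axis=1, keepdims=True)
    for pj, pos in enumerate(pidx):
        marg = np.zeros(K)
        for c, (d1, d2) in enumerate(combos):
            marg[(d1, d2)[pj]] += w[c]
        P[pos] = marg / marg.sum()
    return P


def call_reads_f1(
    alt: pd.DataFrame,
    depth: pd.DataFrame,
    parents: tuple[str, str] = ("P1", "P2"),
    ploidy: int = 4,
    eps: float = 0.001,
    bias: float = 1.0,
    overdispersion: float = 0.0,
) -> DosagePosteriors:
    """Joint F1 dosage posteriors from read counts.

    Applies :func:`_f1_family_posterior` to the beta-binomial class
    log-likelihoods of every marker: parental dosages are inferred jointly
    from the whole family, offspring are called under the inferred
    segregation mixture.  Because the whole family informs the parental
    dosages, parents are called far more confidently than from their own
    reads alone — the standard family-aware calling model for F1 designs.

    Parameters
    ----------
    alt, depth : DataFrames, markers x samples; ``parents`` must name two
        columns, all other columns are offspring.
    """
    A = alt.to_numpy()
    N = depth.to_numpy()
    if A.shape != N.shape:
        raise ValueError("alt and depth shapes differ")
    samples = list(alt.columns)
    pidx, oidx = _parent_offspring_split(samples, parents)

    K = ploidy + 1
    loglik = np.empty(A.shape + (K,))
    for k in range(K):
        p_k = dosage_to_read_prob(k, ploidy, eps, bias)
        loglik[..., k] = read_count_loglik(A, N, float(p_k), overdispersion)
    # zero-depth cells carry no information
    loglik[N == 0] = 0.0

    P = np.empty((A.shape[0], len(samples), K))
    for i in range(A.shape[0]):
        P[i] = _f1_family_posterior(loglik[i], pidx, oidx, ploidy)
    return DosagePosteriors(P, list(alt.index), samples)


def _em_normal_mixture(
    t: np.ndarray,
    mu0: np.ndarray,
    sigma0: float,
    max_iter: int = 300,
    tol: float = 1e-9,
    min_sep: float = 0.05,
    min_sigma: float = 1e-4,
    mean_tether: float = 5.0,
) -> tuple[np.ndarray, bool, dict]:
    """MAP-EM for a K-component normal mixture with shared variance.

    Means are initialised at ``mu0`` and tethered there by a conjugate
    normal prior worth ``mean_tether`` pseudo-observations: the M-step mean
    is (sum of weighted data + tether * mu0_k) / (responsibility + tether).
    The tether preserves the dosage-class geometry — a component whose
    class is absent stays near its canonical position instead of drifting
    onto an occupied cluster — while a well-populated class can still shift
    to its empirical centre (e.g. under allelic bias).  The fit is flagged
    unconverged if EM does not converge or adjacent means end up closer
    than ``min_sep``.
    """
    n = len(t)
    K = len(mu0)
    mu = mu0.astype(float).copy()
    sigma = float(sigma0)
    w = np.full(K, 1.0 / K)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        logp = norm.logpdf(t[:, None], mu[None, :], sigma) + np.log(w)[None, :]
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
        nk = resp.sum(axis=0)
        w = np.maximum(nk, 1e-12) / n
        w /= w.sum()
        S = (resp * t[:, None]).sum(axis=0)
        mu_new = (S + mean_tether * mu0) / (nk + mean_tether)
        var = float(np.sum(resp * (t[:, None] - mu_new[None, :]) ** 2) / n)
        sigma_new = max(np.sqrt(var), min_sigma)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            mu, sigma = mu_new, sigma_new
            converged = True
            break
        mu, sigma = mu_new, sigma_new
        ll_old = ll
    separated = bool(np.all(np.diff(mu) > min_sep))
    ok = converged and separated and bool(np.all(np.diff(mu) > 0))
    logp = norm.logpdf(t[:, None], mu[None, :], sigma) + np.log(w)[None, :]
    m = logp.max(axis=1, keepdims=True)
    p = np.exp(logp - m)
    resp = p / p.sum(axis=1, keepdims=True)
    return resp, ok, {"mu": mu, "sigma": sigma, "w": w}


def call_array(
    ratios: pd.DataFrame,
    ploidy: int = 4,
    transform: str = "asin",
    min_sep: float = 0.05,
    parents: tuple[str, str] | None = None,
) -> DosagePosteriors:
    """Mixture-model dosage posteriors from array signal ratios.

    Per marker a (ploidy+1)-component normal mixture is fitted by EM on
    variance-stabilised ratios (arcsine-square-root by default, logit as an
    alternative).  Markers whose EM fails to converge or whose fitted class
    means collapse are flagged ``converged=False`` in ``meta`` and should be
    excluded downstream (the pipeline does this).  Their posteriors are set
    to the uninformative uniform vector.

    With ``parents`` naming two sample columns, posteriors are computed from
    the fitted class densities through the joint F1 family model
    (:func:`_f1_family_posterior`) instead of the plain mixture
    responsibilities: the mixing proportions then come from the inferred
    parental-dosage combination rather than being free, the model-selection
    step an F1-aware array caller performs.  Without ``parents`` the
    responsibilities are returned unchanged.
    """
    R = ratios.to_numpy(dtype=float)
    if not np.all(np.isfinite(R)) or np.any(R <= 0) or np.any(R >= 1):
        raise ValueError("ratios must be finite and in (0, 1)")
    if transform == "asin":
        f = lambda x: np.arcsin(np.sqrt(x))
    elif transform == "logit":
        f = lambda x: np.log(x / (1.0 - x))
    else:
        raise ValueError(f"unknown transform {transform!r}")
    T = f(R)
    mu0 = f(np.clip(np.arange(ploidy + 1) / ploidy, 1e-4, 1 - 1e-4))
    sigma0 = 0.25 * float(np.min(np.diff(mu0)))

    samples = list(ratios.columns)
    if parents is not None:
        pidx, oidx = _parent_offspring_split(samples, parents)

    n_mark, n_samp = T.shape
    P = np.full((n_mark, n_samp, ploidy + 1), 1.0 / (ploidy + 1))
    flags = np.zeros(n_mark, dtype=bool)
    sigmas = np.full(n_mark, np.nan)
    for i in range(n_mark):
        t = T[i]
        if np.ptp(t) < 1e-12:  # all-identical ratios: degenerate fit
            continue
        resp, ok, par = _em_normal_mixture(t, mu0, sigma0, min_sep=min_sep)
        if ok:
            if parents is not None:
                loglik = norm.logpdf(
                    t[:, None], par["mu"][None, :], par["sigma"]
                )
                P[i] = _f1_family_posterior(loglik, pidx, oidx, ploidy)
            else:
                P[i] = resp
            flags[i] = True
            sigmas[i] = par["sigma"]
    meta = pd.DataFrame(
        {"converged": flags, "sigma": sigmas}, index=list(ratios.index)
    )
    return DosagePosteriors(P, list(ratios.index), list(ratios.columns), meta)


def discretize(post: DosagePosteriors, prob_threshold: float = 0.95) -> pd.DataFrame:
    """Discrete dosages: argmax where the maximum posterior clears the threshold.

    Cells whose maximum posterior is below the threshold become MISSING (-1).
    Ties are broken toward the lower dosage.  The threshold must exceed
    1/(ploidy+1) (below that every cell would trivially pass).
    """
    lo = 1.0 / (post.ploidy + 1)
    if not lo < prob_threshold <= 1.0:
        raise ValueError(f"prob_threshold must be in ({lo:.3f}, 1]")
    calls = post.argmax()
    calls = np.where(post.max_prob() >= prob_threshold, calls, MISSING)
    return pd.DataFrame(calls, index=post.markers, columns=post.samples)


def filter_markers_missing(
    D: pd.DataFrame, max_missing_fraction: float = 0.4
) -> tuple[list[str], pd.Series]:
    """Markers whose missing fraction does not exceed the threshold.

    The rule is strictly greater-than: a marker at exactly the threshold is
    retained.  Returns (retained marker names, per-marker missing rates).
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    rates = (D.to_numpy() == MISSING).mean(axis=1)
    rates = pd.Series(rates, index=D.index, name="missing_rate")
    keep = [m for m, r in rates.items() if r <= max_missing_fraction]
    return keep, rates
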