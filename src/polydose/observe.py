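"""Noisy genotyping observations from true dosages.

Two observation channels are modelled:

* SNP-array allele signal ratios: for a true dosage ``d`` the expected
  counted-allele signal fraction is ``xi_d``; observed ratios are Beta
  distributed around ``xi_d`` with intra-class correlation ``rho``
  ("overdispersion"), so the within-class variance is ``xi(1-xi)rho``.
* Sequencing read counts: the number of counted-allele reads out of the
  read depth is beta-binomial with success probability combining the
  allelic bias ``h`` and the sequencing error rate ``eps``, and the same
  overdispersion parameter ``rho`` (rho = 0 degenerates to binomial).

The bias convention follows the reference/alternative ratio: ``h``
multiplies the non-counted allele, so h = 0.7 inflates the counted-allele
fraction at heterozygous dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TruthSet

#: offset keeping Beta parameters positive for boundary dosages 0 and ploidy
BOUNDARY_DELTA = 1e-4


@dataclass
class ObservationNoiseConfig:
    """Noise parameters for simulated genotyping observations.

    Parameters
    ----------
    overdispersion : float in [0, 1)
        Beta intra-class correlation; extra variance beyond the basic model.
    seq_error : float in [0, 0.5)
        Per-read sequencing error rate (read-count channel only).
    allelic_bias : float > 0
        Reference/alternative bias; 1 = unbiased.
    depth : int or (int, int)
        Fixed read depth, or an inclusive uniform integer range.
    seed : int
    """

    overdispersion: float = 0.0
    seq_error: float = 0.001
    allelic_bias: float = 0.7
    depth: int | tuple[int, int] = (50, 200)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.overdispersion < 1:
            raise ValueError("overdispersion must be in [0, 1)")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.allelic_bias <= 0:
            raise ValueError("allelic_bias must be positive")


def dosage_to_array_ratio_mean(
    d: np.ndarray | int, ploidy: int, bias: float = 1.0
) -> np.ndarray | float:
    """Expected counted-allele signal fraction for dosage ``d``.

    xi_d = f / (h (1 - f) + f) with f = d/ploidy; strictly increasing in d,
    0 at dosage 0 and 1 at dosage ploidy.
    """
    f = np.asarray(d, dtype=float) / ploidy
    xi = f / (bias * (1.0 - f) + f)
    return float(xi) if np.isscalar(d) else xi


def dosage_to_read_prob(
    d: np.ndarray | int, ploidy: int, eps: float = 0.001, bias: float = 1.0
) -> np.ndarray | float:
    """Per-read probability of observing the counted allele.

    Bias is applied before sequencing error: p = xi_d (1-eps) + (1-xi_d) eps.
    """
    xi = np.asarray(dosage_to_array_ratio_mean(d, ploidy, bias))
    p = xi * (1.0 - eps) + (1.0 - xi) * eps
    return float(p) if np.isscalar(d) else p


def _sample_table(truth: TruthSet, include_parents: bool) -> tuple[np.ndarray, list[str]]:
    """True dosages and sample names, optionally prepending the parents."""
    dos = truth.true_dosages
    names = [f"F1_{z + 1:03d}" for z in range(truth.n_individuals)]
    if include_parents:
        pd_dos = truth.parental_dosages()  # markers x 2
        dos = np.vstack([pd_dos.T, dos])
        names = ["P1", "P2"] + names
    return dos, names


def simulate_array_signals(
    truth: TruthSet,
    overdispersion: float,
    bias: float = 1.0,
    seed: int | None = 0,
    include_parents: bool = True,
) -> pd.DataFrame:
    """Simulate SNP-array signal ratios for all samples.

    Ratios are Beta(xi (1-rho)/rho, (1-xi)(1-rho)/rho), i.e. mean xi and
    intra-class correlation rho; at rho = 0 the exact class mean is
    returned.  Boundary class means (dosage 0 and ploidy) are clamped into
    (0, 1) by a small offset so the Beta parameters stay positive.

    Returns a DataFrame (markers x samples) of values in (0, 1).
    """
    if not 0 <= overdispersion < 1:
        raise ValueError("overdispersion must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dos, names = _sample_table(truth, include_parents)
    xi = dosage_to_array_ratio_mean(dos, truth.ploidy, bias)
    xi = np.clip(xi, BOUNDARY_DELTA, 1.0 - BOUNDARY_DELTA)
    if overdispersion == 0:
        ratios = xi.copy()
    else:
        k = (1.0 - overdispersion) / overdispersion
        ratios = rng.beta(xi * k, (1.0 - xi) * k)
        ratios = np.clip(ratios, BOUNDARY_DELTA, 1.0 - BOUNDARY_DELTA)
    return pd.DataFrame(ratios.T, index=truth.marker_names, columns=names)


def _draw_depths(
    depth: int | tuple[int, int], shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    if np.isscalar(depth):
        d = np.full(shape, int(depth), dtype=np.int64)
    else:
        lo, hi = depth
        d = rng.integers(int(lo), int(hi) + 1, size=shape)
    if np.any(d < 1):
        raise ValueError("read depth must be positive")
    return d


def simulate_read_counts(
    truth: TruthSet,
    noise: ObservationNoiseConfig,
    include_parents: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sequencing read counts for all samples.

    Per data point the depth is drawn from the configured depth model and
    the counted-allele read count is beta-binomial with mean probability
    from :func:`dosage_to_read_prob` and overdispersion rho (binomial when
    rho = 0).

    Returns (alt, depth) DataFrames, markers x samples.
    """
    rng = np.random.default_rng(noise.seed)
    dos, names = _sample_table(truth, include_parents)
    p = dosage_to_read_prob(dos, truth.ploidy, noise.seq_error, noise.allelic_bias)
    depth = _draw_depths(noise.depth, dos.shape, rng)
    rho = noise.overdispersion
    if rho == 0:
        alt = rng.binomial(depth, p)
    else:
        k = (1.0 - rho) / rho
        pp = np.clip(p, 1e-12, 1.0 - 1e-12)
        q = rng.beta(pp * k, (1.0 - pp) * k)
        alt = rng.binomial(depth, q)
    idx = truth.marker_names
    return (
        pd.DataFrame(alt.T, index=idx, columns=names),
        pd.DataFrame(depth.T, index=idx, columns=names),
    )
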