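"""Probabilistic data curation before linkage analysis.

Mirrors the pre-mapping filters of discrete-dosage pipelines, generalised to
dosage posteriors: duplicate individuals are detected by correlating
posterior-expected ("weighted") dosages and merged by averaging their
posteriors; poorly scored individuals are flagged from their maximum
posterior profile; each marker's segregation type is taken from the parents'
most probable dosages and tested against the probabilistic offspring
segregation; and markers are converted to their simplest (reflection-
canonical) form before linkage estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

from .calling import DosagePosteriors
from .simulate import all_seg_type_pairs, expected_segregation, seg_type_label

logger = logging.getLogger(__name__)


def weighted_dosage(p_vector: np.ndarray) -> float:
    """Posterior expectation of dosage for one marker x individual cell."""
    p = np.asarray(p_vector, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("posterior vector must be a distribution")
    return float(p @ np.arange(len(p)))


def find_and_merge_duplicates(
    post: DosagePosteriors, corr_threshold: float = 0.95
) -> tuple[DosagePosteriors, list[list[str]]]:
    """Detect and merge duplicate individuals.

    Individuals whose weighted-dosage vectors over all markers have a
    Pearson correlation above the threshold are grouped by transitive
    closure; each group is replaced by a single individual (named after its
    first member) whose posterior is the per-class arithmetic mean,
    renormalised.

    Returns the merged tensor and the list of duplicate groups (sample
    names).  Zero-variance individuals cannot be correlated and are kept
    unmerged (logged).
    """
    if post.n_samples < 2:
        raise ValueError("need at least two individuals")
    X = post.weighted_dosage()  # markers x samples
    sd = X.std(axis=0)
    usable = sd > 0
    if not np.all(usable):
        logger.warning(
            "%d zero-variance individuals excluded from duplicate detection",
            int((~usable).sum()),
        )
    g = nx.Graph()
    g.add_nodes_from(range(post.n_samples))
    idx = np.flatnonzero(usable)
    if len(idx) >= 2:
        C = np.corrcoef(X[:, idx].T)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if C[a, b] > corr_threshold:
                    g.add_edge(idx[a], idx[b])
    groups = [sorted(c) for c in nx.connected_components(g)]
    groups.sort(key=lambda c: c[0])
    newP = np.empty((post.n_markers, len(groups), post.ploidy + 1))
    names, dup_groups = [], []
    for j, comp in enumerate(groups):
        block = post.P[:, comp, :].mean(axis=1)
        newP[:, j, :] = block / block.sum(axis=1, keepdims=True)
        names.append(post.samples[comp[0]])
        if len(comp) > 1:
            dup_groups.append([post.samples[i] for i in comp])
    merged = DosagePosteriors(newP, list(post.markers), names, post.meta)
    return merged, dup_groups


def flag_poor_individuals(
    post: DosagePosteriors, prob: float = 0.6, min_fraction: float = 0.5
) -> list[str]:
    """Individuals where fewer than half the markers are confidently scored.

    An individual is flagged iff the number of markers whose maximum
    posterior exceeds ``prob`` is strictly fewer than ``min_fraction`` of
    all markers.
    """
    good = (post.max_prob() > prob).sum(axis=0)
    flagged = good < min_fraction * post.n_markers
    return [s for s, f in zip(post.samples, flagged) if f]


@dataclass
class SegregationAssignment:
    """Result of segregation-type determination for one marker."""

    marker: str
    d1: int | None
    d2: int | None
    expected: np.ndarray | None
    statistic: float
    p_value: float
    impossible_mass: float
    matches_expected: bool
    monomorphic: bool
    best_alternative: tuple[int, int] | None

    @property
    def seg_type(self) -> tuple[int, int] | None:
        if self.d1 is None or self.d2 is None:
            return None
        return (self.d1, self.d2)

    @property
    def label(self) -> str:
        if self.seg_type is None:
            return "NA"
        return seg_type_label(self.d1, self.d2)


def _multinomial_loglik(totals: np.ndarray, freqs: np.ndarray) -> float:
    ll = 0.0
    for o, f in zip(totals, freqs):
        if o > 1e-9:
            if f <= 0:
                return -np.inf
            ll += o * np.log(f)
    return ll


def assign_segregation_type(
    P_marker: np.ndarray,
    p_parent1: np.ndarray,
    p_parent2: np.ndarray,
    marker: str = "",
    parent_conf_threshold: float = 0.9,
    p_min: float = 1e-3,
    max_impossible: float = 0.05,
    ploidy: int = 4,
) -> SegregationAssignment:
    """Assign and test a marker's segregation type from dosage posteriors.

    The parental dosages are the argmax of the parent posteriors, required
    to clear ``parent_conf_threshold`` (otherwise the marker is rejected as
    unassignable).  The probabilistic offspring class totals
    O'_k = sum_z P[z, k] are tested against N * expected_segregation(d1, d2)
    with a chi-square statistic over the possible classes; posterior mass on
    classes impossible under the type counts against the marker separately
    (``max_impossible``).  The best-fitting alternative type is the
    (d1, d2) pair maximising the multinomial log-likelihood of the totals;
    the marker matches only if the parental type's expected distribution is
    among the best.
    """
    p1 = np.asarray(p_parent1, dtype=float)
    p2 = np.asarray(p_parent2, dtype=float)
    d1 = int(np.argmax(p1)) if p1.max() >= parent_conf_threshold else None
    d2 = int(np.argmax(p2)) if p2.max() >= parent_conf_threshold else None
    if d1 is None or d2 is None:
        return SegregationAssignment(
            marker, d1, d2, None, np.nan, np.nan, np.nan, False, False, None
        )
    f = expected_segregation(d1, d2, ploidy)
    if np.max(f) > 1.0 - 1e-12:  # a single possible class: non-segregating
        return SegregationAssignment(
            marker, d1, d2, f, np.nan, np.nan, np.nan, False, True, None
        )
    P = np.asarray(P_marker, dtype=float)
    N = P.shape[0]
    totals = P.sum(axis=0)  # probabilistic class totals O'_k
    possible = f > 0
    stat = float(
        np.sum((totals[possible] - N * f[possible]) ** 2 / (N * f[possible]))
    )
    df = int(possible.sum()) - 1
    p_value = float(chi2.sf(stat, df)) if df > 0 else 1.0
    impossible_mass = float(totals[~possible].sum() / N)

    best_ll, best_pair, best_f = -np.inf, None, None
    for cand in all_seg_type_pairs(ploidy):
        fc = expected_segregation(*cand, ploidy)
        ll = _multinomial_loglik(totals, fc)
        if ll > best_ll + 1e-9:
            best_ll, best_pair, best_f = ll, cand, fc
    alt_is_same = best_f is not None and np.allclose(best_f, f, atol=1e-12)
    if alt_is_same:
        best_pair = (d1, d2)  # report the parental pair among tied-best types
    matches = (
        p_value >= p_min and impossible_mass <= max_impossible and alt_is_same
    )
    return SegregationAssignment(
        marker, d1, d2, f, stat, p_value, impossible_mass, matches, False, best_pair
    )


def assign_all_segregation_types(
    post: DosagePosteriors,
    parent1: str = "P1",
    parent2: str = "P2",
    **kwargs,
) -> list[SegregationAssignment]:
    """Run :func:`assign_segregation_type` for every marker in the tensor.

    ``parent1``/``parent2`` name the parental samples; all other samples are
    treated as offspring.
    """
    i1 = post.samples.index(parent1)
    i2 = post.samples.index(parent2)
    off = [i for i in range(post.n_samples) if i not in (i1, i2)]
    out = []
    for m, name in enumerate(post.markers):
        out.append(
            assign_segregation_type(
                post.P[m, off, :],
                post.P[m, i1],
                post.P[m, i2],
                marker=name,
                ploidy=post.ploidy,
                **kwargs,
            )
        )
    return out


def to_simplest_form(
    P_marker: np.ndarray, seg: tuple[int, int], ploidy: int = 4
) -> tuple[np.ndarray, tuple[int, int], bool]:
    """Convert a marker to its simplest (reflection-canonical) form.

    If swapping the counted allele — i.e. replacing parental dosages
    (d1, d2) by (ploidy-d1, ploidy-d2) and reversing each posterior vector —
    yields a lexicographically smaller dosage pair, the reflection is
    applied.  Idempotent.

    Returns (posteriors, seg_type, reflected_flag).
    """
    d1, d2 = seg
    refl = (ploidy - d1, ploidy - d2)
    if refl < (d1, d2):
        return np.asarray(P_marker)[..., ::-1].copy(), refl, True
    return np.asarray(P_marker), (d1, d2), False


def segregation_report(assignments: list[SegregationAssignment]) -> pd.DataFrame:
    """Per-marker QC table for the segregation check."""
    return pd.DataFrame(
        {
            "marker": [a.marker for a in assignments],
            "seg_type": [a.label for a in assignments],
            "d1": [a.d1 for a in assignments],
            "d2": [a.d2 for a in assignments],
            "p_value": [a.p_value for a in assignments],
            "impossible_mass": [a.impossible_mass for a in assignments],
            "matches_expected": [a.matches_expected for a in assignments],
            "monomorphic": [a.monomorphic for a in assignments],
            "best_alternative": [
                None if a.best_alternative is None else seg_type_label(*a.best_alternative)
                for a in assignments
            ],
        }
    ).set_index("marker")
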