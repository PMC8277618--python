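"""Evaluation statistics for simulation studies.

All functions are pure: given the same calls/posteriors and the same truth
they return bit-identical results.  They cover genotype-calling accuracy
(fraction of argmax calls equal to the true dosage), summaries of the
maximum posterior split by call correctness, marker retention under
discretisation thresholds, estimated-versus-true regressions (slope and
adjusted R^2) for recombination fractions and map positions, and the
pairwise phase error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import MISSING, DosagePosteriors, discretize, filter_markers_missing


def fraction_correct(
    calls: np.ndarray, truth: np.ndarray, denominator: str = "all"
) -> float:
    """Proportion of dosage calls equal to the truth.

    ``denominator='all'`` counts every cell (missing calls count as wrong),
    matching an argmax-without-threshold evaluation; ``'scored'`` restricts
    to non-missing calls.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("shape mismatch between calls and truth")
    correct = (calls == truth) & (calls != MISSING)
    if denominator == "all":
        return float(correct.mean())
    scored = calls != MISSING
    return float(correct.sum() / scored.sum()) if scored.any() else np.nan


def maxprob_summary(post: DosagePosteriors, truth: np.ndarray) -> pd.DataFrame:
    """Mean and 25%/75% quantiles of the max posterior, by call correctness.

    Computed over all marker x individual cells; an empty group (e.g. no
    incorrect calls) yields NaN rows rather than an error.
    """
    truth = np.asarray(truth)
    mp = post.max_prob().ravel()
    correct = (post.argmax() == truth).ravel()
    rows = {}
    for label, mask in (("correct", correct), ("incorrect", ~correct)):
        vals = mp[mask]
        if len(vals):
            rows[label] = {
                "n": len(vals),
                "mean": float(vals.mean()),
                "q25": float(np.quantile(vals, 0.25)),
                "q75": float(np.quantile(vals, 0.75)),
            }
        else:
            rows[label] = {"n": 0, "mean": np.nan, "q25": np.nan, "q75": np.nan}
    return pd.DataFrame(rows).T


def retention_curve(
    post: DosagePosteriors,
    prob_thresholds: list[float],
    missing_thresholds: list[float],
) -> pd.DataFrame:
    """Marker retention after discretisation + missing-rate filtering.

    For each (probability threshold, max missing fraction) pair, posteriors
    are discretised and markers above the missing threshold removed; the
    retained marker fraction is reported.
    """
    rows = []
    for pt in prob_thresholds:
        D = discretize(post, pt)
        for mt in missing_thresholds:
            keep, _ = filter_markers_missing(D, mt)
            rows.append((pt, mt, len(keep) / post.n_markers))
    return pd.DataFrame(
        rows, columns=["prob_threshold", "missing_threshold", "retained_fraction"]
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    adj_r2: float
    n: int


def regression_eval(
    estimates: np.ndarray, truths: np.ndarray, orient: bool = False
) -> RegressionResult:
    """OLS of estimates on truths: slope and adjusted R^2.

    With a single predictor the adjusted R^2 uses n-2 residual degrees of
    freedom.  ``orient=True`` flips the estimates (map reversal) when their
    correlation with the truth is negative, as a map's global orientation
    is arbitrary.
    """
    y = np.asarray(estimates, dtype=float)
    x = np.asarray(truths, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if x.std() == 0:
        raise ValueError("degenerate truth variance")
    if orient and np.corrcoef(x, y)[0, 1] < 0:
        y = y.max() - y
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    n = len(x)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(float(beta[1]), float(beta[0]), float(adj), n)


def phase_error_rate(
    links: pd.DataFrame, truth, name_to_index: dict[str, int] | None = None
) -> float:
    """Fraction of marker pairs with an incorrectly estimated phase.

    The estimated phase class (overlap counts in both parents) of every
    pair in the linkage table is compared with the truth-set overlap of the
    allele-carrying homolog sets.
    """
    if name_to_index is None:
        name_to_index = {m: i for i, m in enumerate(truth.marker_names)}
    wrong = 0
    total = 0
    for row in links.itertuples(index=False):
        i = name_to_index[row.marker_a]
        j = name_to_index[row.marker_b]
        true_m1 = truth.phase_overlap(i, j, 0)
        true_m2 = truth.phase_overlap(i, j, 1)
        total += 1
        if (row.phase1_overlap, row.phase2_overlap) != (true_m1, true_m2):
            wrong += 1
    return wrong / total if total else np.nan
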