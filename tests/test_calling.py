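import numpy as np
import pandas as pd
import pytest
from scipy.stats import betabinom, binom

from polydose.calling import (
    MISSING,
    DosagePosteriors,
    call_array,
    call_reads,
    call_reads_f1,
    discretize,
    filter_markers_missing,
    read_count_loglik,
)
from polydose.observe import ObservationNoiseConfig, simulate_array_signals, simulate_read_counts

from conftest import full_truth


def test_read_count_loglik_matches_scipy():
    alt = np.array([0, 3, 10, 25])
    dp = np.array([10, 10, 20, 25])
    p = 0.3
    assert np.allclose(
        read_count_loglik(alt, dp, p, 0.0), binom.logpmf(alt, dp, p)
    )
    rho = 0.1
    k = (1 - rho) / rho
    assert np.allclose(
        read_count_loglik(alt, dp, p, rho),
        betabinom.logpmf(alt, dp, p * k, (1 - p) * k),
    )
    with pytest.raises(ValueError):
        read_count_loglik(np.array([5]), np.array([3]), p, 0.0)


def _frames(alt, dp, samples=None):
    samples = samples or [f"s{i}" for i in range(alt.shape[1])]
    idx = [f"m{i}" for i in range(alt.shape[0])]
    return (
        pd.DataFrame(alt, index=idx, columns=samples),
        pd.DataFrame(dp, index=idx, columns=samples),
    )


def test_call_reads_normalised_and_accurate_at_high_depth():
    rng = np.random.default_rng(0)
    truth_d = rng.integers(0, 5, size=(20, 50))
    dp = np.full_like(truth_d, 200)
    p = truth_d / 4 * (1 - 2 * 0.001) + 0.001
    alt = rng.binomial(dp, p)
    post = call_reads(*_frames(alt, dp))
    assert np.allclose(post.P.sum(axis=-1), 1.0)
    assert (post.argmax() == truth_d).mean() > 0.99


def test_call_reads_zero_depth_returns_prior():
    alt, dp = _frames(np.zeros((1, 3), int), np.zeros((1, 3), int))
    prior = np.array([0.4, 0.3, 0.2, 0.05, 0.05])
    post = call_reads(alt, dp, prior=prior)
    assert np.allclose(post.P[0], prior)
    with pytest.raises(ValueError):
        call_reads(alt, dp, prior=np.array([0.5, 0.5]))


def test_call_reads_f1_requires_parent_columns():
    alt, dp = _frames(np.full((2, 4), 5), np.full((2, 4), 10))
    with pytest.raises(ValueError, match="parent column"):
        call_reads_f1(alt, dp)


def test_call_reads_f1_parents_called_confidently(truth_tiny):
    noise = ObservationNoiseConfig(overdispersion=0.0, depth=40, seed=23)
    alt, dp = simulate_read_counts(truth_tiny, noise)
    post = call_reads_f1(alt, dp, bias=0.7)
    assert np.allclose(post.P.sum(axis=-1), 1.0)
    truth = full_truth(truth_tiny)
    calls = post.argmax()
    # family information pins down the parental dosages
    parent_cols = [post.samples.index("P1"), post.samples.index("P2")]
    assert (calls[:, parent_cols] == truth[:, parent_cols]).mean() > 0.95
    assert post.max_prob()[:, parent_cols].mean() > 0.95
    # offspring accuracy at 40x
    assert (calls == truth).mean() > 0.9


def test_call_reads_f1_at_least_as_accurate_as_flat_prior(truth_tiny):
    noise = ObservationNoiseConfig(overdispersion=0.0, depth=15, seed=31)
    alt, dp = simulate_read_counts(truth_tiny, noise)
    truth = full_truth(truth_tiny)
    fam = (call_reads_f1(alt, dp, bias=0.7).argmax() == truth).mean()
    flat = (call_reads(alt, dp, bias=0.7).argmax() == truth).mean()
    assert fam >= flat


def test_call_array_low_noise_recovers_truth(truth_tiny):
    R = simulate_array_signals(truth_tiny, 0.01, seed=41)
    post = call_array(R, parents=("P1", "P2"))
    truth = full_truth(truth_tiny)
    conv = post.meta["converged"].to_numpy()
    assert conv.mean() > 0.8
    acc = (post.argmax()[conv] == truth[conv]).mean()
    assert acc > 0.97


def test_call_array_rejects_invalid_ratios():
    bad = pd.DataFrame([[0.0, 0.5]], index=["m0"], columns=["a", "b"])
    with pytest.raises(ValueError):
        call_array(bad)
    with pytest.raises(ValueError):
        call_array(bad.clip(0.1, 0.9), transform="probit")


def test_call_array_unfit_markers_flagged_uniform():
    # a monomorphic signal cannot be fitted: uniform posterior, converged=False
    R = pd.DataFrame(
        np.full((1, 6), 0.5), index=["m0"], columns=[f"s{i}" for i in range(6)]
    )
    post = call_array(R)
    assert not post.meta["converged"].iloc[0]
    assert np.allclose(post.P[0], 0.2)


def test_discretize_threshold_and_missing():
    P = np.array([[[0.96, 0.04, 0, 0, 0], [0.5, 0.5, 0, 0, 0]]])
    post = DosagePosteriors(P, ["m0"], ["a", "b"])
    D = discretize(post, 0.95)
    assert D.loc["m0", "a"] == 0
    assert D.loc["m0", "b"] == MISSING
    with pytest.raises(ValueError):
        discretize(post, 0.1)


def test_filter_markers_missing_boundary_inclusive():
    D = pd.DataFrame(
        [[0, 1, MISSING, 2], [MISSING, MISSING, 0, 1]],
        index=["m0", "m1"],
        columns=list("abcd"),
    )
    keep, rates = filter_markers_missing(D, 0.25)
    assert keep == ["m0"]  # m0 at exactly 0.25 retained, m1 at 0.5 dropped
    assert rates["m1"] == 0.5
    keep2, _ = filter_markers_missing(D, 0.5)
    assert keep2 == ["m0", "m1"]


def test_posteriors_select_and_accessors():
    P = np.tile(np.array([0.7, 0.3, 0.0, 0.0, 0.0]), (3, 2, 1))
    post = DosagePosteriors(P, ["m0", "m1", "m2"], ["a", "b"])
    sub = post.select_markers(["m2", "m0"])
    assert sub.markers == ["m2", "m0"]
    subs = post.select_samples(["b"])
    assert subs.n_samples == 1
    assert post.marker_index("m1") == 1
    assert np.allclose(post.weighted_dosage(), 0.3)
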