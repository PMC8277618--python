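import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polydose.calling import MISSING, DosagePosteriors
from polydose.linkage import (
    PhaseClass,
    estimate_r,
    expected_offspring_table,
    loglik_discrete,
    loglik_probabilistic,
    pairwise_linkage_scan,
    phase_overlap_range,
    two_locus_gamete_dist,
)
from polydose.simulate import gamete_dosage_dist


def test_phase_overlap_range():
    assert list(phase_overlap_range(1, 1)) == [0, 1]
    assert list(phase_overlap_range(2, 3)) == [1, 2]
    assert list(phase_overlap_range(0, 4)) == [0]


def test_two_locus_gamete_dist_validation():
    with pytest.raises(ValueError):
        two_locus_gamete_dist(1, 1, 0, 0.6)
    with pytest.raises(ValueError):
        two_locus_gamete_dist(1, 1, 2, 0.1)  # overlap 2 impossible for (1,1)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    dA=st.integers(0, 4),
    dB=st.integers(0, 4),
    data=st.data(),
    r=st.floats(0.0, 0.5),
)
def test_two_locus_gamete_dist_marginals(dA, dB, data, r):
    """Joint gamete distribution: valid, with hypergeometric marginals."""
    rng = phase_overlap_range(dA, dB)
    m = data.draw(st.sampled_from(list(rng)))
    J = two_locus_gamete_dist(dA, dB, m, r)
    assert J.shape == (3, 3)
    assert np.all(J >= -1e-12)
    assert J.sum() == pytest.approx(1.0)
    assert np.allclose(J.sum(axis=1), gamete_dosage_dist(dA), atol=1e-12)
    assert np.allclose(J.sum(axis=0), gamete_dosage_dist(dB), atol=1e-12)


def test_gamete_dist_coupling_vs_repulsion_at_zero_r():
    # coupling simplex pair at r=0: alleles co-transmitted
    J = two_locus_gamete_dist(1, 1, 1, 0.0)
    assert J[1, 0] == pytest.approx(0.0)
    assert J[1, 1] == pytest.approx(0.5)
    # repulsion at r=0: never co-transmitted... except via the free bivalent
    Jr = two_locus_gamete_dist(1, 1, 0, 0.0)
    assert Jr[1, 1] < J[1, 1]


def test_expected_offspring_table_is_distribution():
    for r in (0.0, 0.1, 0.5):
        E = expected_offspring_table((1, 2), (2, 1), PhaseClass(1, 1), r)
        assert E.shape == (5, 5)
        assert np.all(E >= -1e-12)
        assert E.sum() == pytest.approx(1.0)


def test_loglik_discrete_impossible_cell():
    E = expected_offspring_table((1, 0), (1, 0), PhaseClass(1, 0), 0.1)
    O = np.zeros((5, 5))
    O[0, 0] = 3
    assert np.isfinite(loglik_discrete(O, E))
    O[4, 4] = 1  # impossible under SNxSN
    assert loglik_discrete(O, E) == -np.inf


def test_probabilistic_equals_discrete_on_onehot():
    rng = np.random.default_rng(1)
    E = expected_offspring_table((1, 1), (1, 1), PhaseClass(1, 0), 0.2)
    dA = rng.integers(0, 3, size=40)
    dB = rng.integers(0, 3, size=40)
    PA = np.zeros((40, 5))
    PB = np.zeros((40, 5))
    PA[np.arange(40), dA] = 1.0
    PB[np.arange(40), dB] = 1.0
    O = np.zeros((5, 5))
    np.add.at(O, (dA, dB), 1.0)
    ld = loglik_discrete(O, E)
    lp = loglik_probabilistic(PA, PB, E)
    if np.isfinite(ld):
        assert lp == pytest.approx(ld, abs=1e-9)
    else:
        assert lp == -np.inf


def _simulate_sn_pair(r, n=400, seed=0):
    """Offspring dosages for an SN/SN coupling pair at true fraction r."""
    rng = np.random.default_rng(seed)
    E = expected_offspring_table((1, 0), (1, 0), PhaseClass(1, 0), r)
    flat = E.ravel()
    draws = rng.choice(len(flat), size=n, p=flat)
    return draws // 5, draws % 5


def test_estimate_r_discrete_recovers_truth_and_phase():
    dA, dB = _simulate_sn_pair(0.1, seed=3)
    res = estimate_r(dA, dB, (1, 0), (1, 0), mode="discrete")
    assert res is not None
    assert res.phase == PhaseClass(1, 0)
    assert abs(res.r_hat - 0.1) < 0.05
    assert res.lod > 10
    assert res.n_informative == 400


def test_estimate_r_probabilistic_on_soft_posteriors():
    dA, dB = _simulate_sn_pair(0.15, seed=5)
    PA = np.full((400, 5), 0.01)
    PB = np.full((400, 5), 0.01)
    PA[np.arange(400), dA] = 0.96
    PB[np.arange(400), dB] = 0.96
    res = estimate_r(PA, PB, (1, 0), (1, 0), mode="probabilistic")
    assert res is not None
    assert abs(res.r_hat - 0.15) < 0.06
    assert res.lod > 5


def test_estimate_r_missing_and_min_informative():
    dA, dB = _simulate_sn_pair(0.1, seed=7)
    dA[:395] = MISSING
    assert estimate_r(dA, dB, (1, 0), (1, 0), mode="discrete") is None


def test_estimate_r_unlinked_pair_near_half():
    rng = np.random.default_rng(11)
    dA = rng.integers(0, 2, size=500)
    dB = rng.integers(0, 2, size=500)
    res = estimate_r(dA, dB, (1, 0), (1, 0), mode="discrete")
    assert res.r_hat > 0.4
    assert res.lod < 2


def test_pairwise_linkage_scan_table(truth_tiny):
    d = truth_tiny.true_dosages.T  # markers x offspring
    names = truth_tiny.marker_names
    P = np.zeros(d.shape + (5,))
    idx = np.indices(d.shape)
    P[idx[0], idx[1], d] = 1.0
    post = DosagePosteriors(P, names, [f"F1_{z}" for z in range(d.shape[1])])
    seg = {
        names[i]: tuple(truth_tiny.parental_dosages()[i])
        for i in range(6)
    }
    links = pairwise_linkage_scan(post, seg, mode="probabilistic")
    assert set(links.columns) >= {
        "marker_a", "marker_b", "r", "LOD", "phase1_overlap", "phase2_overlap"
    }
    assert len(links) == 15
    assert links["r"].between(0, 0.5).all()
    # deterministic
    again = pairwise_linkage_scan(post, seg, mode="probabilistic")
    pd.testing.assert_frame_equal(links, again)


def test_pairwise_scan_explicit_pairs(truth_tiny):
    d = truth_tiny.true_dosages.T
    names = truth_tiny.marker_names
    D = pd.DataFrame(d, index=names, columns=[f"F1_{z}" for z in range(d.shape[1])])
    seg = {
        names[i]: tuple(truth_tiny.parental_dosages()[i]) for i in range(4)
    }
    links = pairwise_linkage_scan(
        D, seg, mode="discrete", pairs=[(names[0], names[1])]
    )
    assert len(links) <= 1
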