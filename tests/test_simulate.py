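import numpy as np
import pytest
from scipy.stats import chisquare

from polydose.simulate import (
    MarkerDef,
    ParentGenome,
    SimPopulationConfig,
    all_seg_type_pairs,
    assign_parent_phases,
    expected_segregation,
    gamete_dosage_dist,
    seg_type_label,
    simulate_f1,
    simulate_meiosis,
)


def test_default_design_has_505_markers():
    cfg = SimPopulationConfig()
    defs = cfg.marker_defs()
    assert len(defs) == 505
    positions = sorted({m.position for m in defs})
    assert positions[0] == 0.0 and positions[-1] == 100.0
    assert len(positions) == 101


def test_marker_spacing_scales_marker_count():
    assert len(SimPopulationConfig(marker_spacing=5.0).marker_defs()) == 105


def test_invalid_population_sizes_rejected():
    with pytest.raises(ValueError):
        SimPopulationConfig(n_individuals=0)
    with pytest.raises(ValueError):
        SimPopulationConfig(ploidy=3)
    with pytest.raises(ValueError):
        SimPopulationConfig(marker_spacing=0.0)


def test_expected_segregation_ratios():
    # SN 1:1 over dosages {0, 1}
    assert np.allclose(expected_segregation(1, 0) * 2, [1, 1, 0, 0, 0])
    # DN 1:4:1
    assert np.allclose(expected_segregation(2, 0) * 6, [1, 4, 1, 0, 0])
    # DD 1:8:18:8:1
    assert np.allclose(expected_segregation(2, 2) * 36, [1, 8, 18, 8, 1])
    # SD 1:5:5:1 (convolution of 1:1 and 1:4:1)
    assert np.allclose(expected_segregation(1, 2) * 12, [1, 5, 5, 1, 0])


def test_gamete_dosage_dist_is_hypergeometric():
    assert np.allclose(gamete_dosage_dist(0), [1, 0, 0])
    assert np.allclose(gamete_dosage_dist(4), [0, 0, 1])
    # simplex: transmit the allele iff its homolog is among the 2 chosen of 4
    assert np.allclose(gamete_dosage_dist(1), [0.5, 0.5, 0])
    # duplex: 1:4:1
    assert np.allclose(gamete_dosage_dist(2) * 6, [1, 4, 1])
    with pytest.raises(ValueError):
        gamete_dosage_dist(5)


def test_seg_type_labels():
    assert seg_type_label(1, 0) == "SN"
    assert seg_type_label(2, 2) == "DD"


def test_simulate_f1_reproducible_and_consistent():
    cfg = SimPopulationConfig(n_individuals=40, marker_spacing=25.0, seed=3)
    t1 = simulate_f1(cfg)
    t2 = simulate_f1(cfg)
    assert np.array_equal(t1.true_dosages, t2.true_dosages)
    t3 = simulate_f1(SimPopulationConfig(n_individuals=40, marker_spacing=25.0, seed=4))
    assert not np.array_equal(t1.true_dosages, t3.true_dosages)
    assert t1.true_dosages.shape == (40, 25)
    assert t1.true_dosages.min() >= 0 and t1.true_dosages.max() <= 4


def test_offspring_dosage_bounded_by_parental_gametes(truth_tiny):
    pd_ = truth_tiny.parental_dosages()
    for i in range(truth_tiny.n_markers):
        d1, d2 = pd_[i]
        lo = max(0, d1 - 2) + max(0, d2 - 2)
        hi = min(2, d1) + min(2, d2)
        col = truth_tiny.true_dosages[:, i]
        assert col.min() >= lo and col.max() <= hi


def test_empirical_segregation_matches_expectation(truth_small):
    """Pooled offspring dosage counts per seg type agree with the model."""
    pd_ = truth_small.parental_dosages()
    for seg in [(1, 0), (1, 1), (1, 2), (2, 0), (2, 2)]:
        cols = [i for i in range(truth_small.n_markers) if tuple(pd_[i]) == seg]
        counts = np.bincount(
            truth_small.true_dosages[:, cols].ravel(), minlength=5
        )
        exp = expected_segregation(*seg) * counts.sum()
        keep = exp > 0
        assert exp[~keep].sum() == 0 and counts[~keep].sum() == 0
        p = chisquare(counts[keep], exp[keep]).pvalue
        assert p > 1e-6, f"seg type {seg}: p={p}"


def test_phase_overlap_range_and_values(truth_tiny):
    pd_ = truth_tiny.parental_dosages()
    for parent in (0, 1):
        m = truth_tiny.phase_overlap(0, 1, parent)
        dA, dB = pd_[0][parent], pd_[1][parent]
        assert max(0, dA + dB - 4) <= m <= min(dA, dB)


def test_simulate_meiosis_shapes_and_recombination_rate():
    positions = np.array([0.0, 50.0])
    parent = ParentGenome(4, [frozenset({0}), frozenset({0})])
    rng = np.random.default_rng(0)
    n, rec = 4000, 0
    for _ in range(n):
        origins, dos = simulate_meiosis(parent, positions, rng)
        assert origins.shape == (2, 2)
        assert dos.shape == (2,)
        # two transmitted chromatids come from different bivalents
        assert origins[0, 0] != origins[1, 0]
        rec += dos[0] != dos[1]
    # Haldane: r = (1 - exp(-1)) / 2 ~ 0.316 at 50 cM
    r_hat = rec / n
    assert abs(r_hat - 0.3161) < 0.025


def test_assign_parent_phases_respects_dosages():
    defs = [MarkerDef("a", 0.0, 3, 1), MarkerDef("b", 1.0, 0, 4)]
    p1, p2 = assign_parent_phases(defs, seed=1)
    assert [len(s) for s in p1.homolog_alleles] == [3, 0]
    assert [len(s) for s in p2.homolog_alleles] == [1, 4]


def test_all_seg_type_pairs_segregating():
    pairs = list(all_seg_type_pairs())
    assert (1, 0) in pairs and (2, 2) in pairs
    assert (0, 0) not in pairs and (4, 4) not in pairs and (0, 4) not in pairs
    assert len(pairs) == 21
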