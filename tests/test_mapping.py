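import numpy as np
import pandas as pd
import pytest

from polydose.mapping import (
    GeneticMap,
    assign_markers,
    cluster_homologs,
    haldane_distance,
    haldane_r,
    mds_order,
    merge_identical_markers,
    nnfit,
    nnfit_filter,
)


def test_haldane_round_trip():
    r = np.array([0.0, 0.05, 0.2, 0.4])
    assert np.allclose(haldane_r(haldane_distance(r)), r)
    assert haldane_distance(0.0) == 0.0
    with pytest.raises(ValueError):
        haldane_distance(0.6)
    with pytest.warns(UserWarning):
        assert np.isfinite(haldane_distance(0.5))


def _chain_links(positions, lod=20.0, m1=1, m2=0, jitter=None, seed=0):
    """All-pairs linkage table from true positions via the Haldane map."""
    rng = np.random.default_rng(seed)
    names = list(positions)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = haldane_r(abs(positions[a] - positions[b]))
            if jitter:
                r = float(np.clip(r + rng.normal(0, jitter), 0.0, 0.49))
            rows.append((a, b, r, lod, m1, m2, "probabilistic", 200))
    return pd.DataFrame(
        rows,
        columns=["marker_a", "marker_b", "r", "LOD",
                 "phase1_overlap", "phase2_overlap", "mode", "n_informative"],
    )


def test_mds_order_recovers_marker_order():
    true = {f"m{i}": 10.0 * i for i in range(11)}
    links = _chain_links(true, jitter=0.01)
    pos = mds_order(links)
    est = pos[list(true)].to_numpy()
    truth = np.array(list(true.values()))
    rho = np.corrcoef(est, truth)[0, 1]
    assert abs(rho) > 0.99
    # total length close to 100 cM
    assert abs(est.max() - est.min() - 100.0) < 15.0


def test_mds_order_two_markers_and_disconnected():
    two = _chain_links({"a": 0.0, "b": 20.0})
    pos = mds_order(two)
    assert pos["a"] == 0.0 and pos["b"] == pytest.approx(20.0, abs=1e-6)
    disc = pd.concat(
        [_chain_links({"a": 0.0, "b": 5.0}), _chain_links({"c": 0.0, "d": 5.0})]
    )
    with pytest.raises(ValueError, match="disconnected"):
        mds_order(disc)


def test_nnfit_flags_displaced_marker():
    true = {f"m{i}": 5.0 * i for i in range(21)}
    links = _chain_links(true)
    pos = pd.Series(true, name="position_cM")
    fit = nnfit(pos, links)
    assert (fit.dropna() < 1e-6).all()
    # displace one marker on the map by 20 cM: its NNfit blows up
    bad = pos.copy()
    bad["m10"] = bad["m10"] + 20.0
    fit_bad = nnfit(bad, links)
    assert fit_bad["m10"] > 5.0
    final, fit_final, removed = nnfit_filter(bad, links, threshold=5.0)
    assert "m10" in removed
    assert (fit_final.drop(removed, errors="ignore").dropna() < 5.0).all()


def test_nnfit_ignores_uninformative_pairs():
    pos = pd.Series({"a": 0.0, "b": 1.0})
    links = _chain_links({"a": 0.0, "b": 1.0}, lod=1.0)
    fit = nnfit(pos, links, lod_informative=3.0)
    assert fit.isna().all()


def test_cluster_homologs_and_assign():
    # two homologs of parent 1, three SN markers each, plus one SS marker
    seg = {f"h1_{i}": (1, 0) for i in range(3)}
    seg.update({f"h2_{i}": (1, 0) for i in range(3)})
    seg["ss"] = (1, 1)
    rows = []
    for i in range(3):
        for j in range(i + 1, 3):
            rows.append((f"h1_{i}", f"h1_{j}", 0.05, 20.0, 1, 0))
            rows.append((f"h2_{i}", f"h2_{j}", 0.05, 20.0, 1, 0))
    for i in range(3):
        for j in range(3):
            rows.append((f"h1_{i}", f"h2_{j}", 0.3, 8.0, 0, 0))  # repulsion
        rows.append((f"h1_{i}", "ss", 0.05, 12.0, 1, 1))
        rows.append((f"h2_{i}", "ss", 0.3, 6.0, 0, 1))
    links = pd.DataFrame(
        rows, columns=["marker_a", "marker_b", "r", "LOD",
                       "phase1_overlap", "phase2_overlap"]
    )
    clusters = cluster_homologs(links, seg, parent=0, lod_min=5.0)
    assert len(clusters) == 2
    assert {frozenset(c) for c in clusters} == {
        frozenset({"h1_0", "h1_1", "h1_2"}), frozenset({"h2_0", "h2_1", "h2_2"})
    }
    assigned, dropped = assign_markers(links, clusters, seg, parent=0)
    assert not dropped
    # the simplex ss marker joins exactly the cluster it couples with
    h1_cluster = next(k for k, c in enumerate(clusters) if "h1_0" in c)
    assert assigned["ss"] == {h1_cluster}


def test_merge_identical_markers():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(3, 50))
    X = np.vstack([base, base[0] + 1e-9 * rng.normal(size=50)])
    wd = pd.DataFrame(X, index=["a", "b", "c", "a2"])
    links = pd.DataFrame(
        {"marker_a": ["a", "a", "b"], "marker_b": ["b", "c", "c"],
         "r": [0.1] * 3, "LOD": [10.0] * 3}
    )
    reps, sat = merge_identical_markers(wd, links, corr_threshold=0.99)
    assert set(reps) == {"a", "b", "c"}
    assert sat == {"a2": "a"}


def test_genetic_map_frame_and_length():
    pos = pd.Series({"a": 0.0, "b": 12.5}, name="position_cM")
    gm = GeneticMap(pos, {"a": {0}}, {"b": {1, 2}}, pd.Series({"a": 0.1, "b": 0.2}), [])
    frame = gm.to_frame()
    assert list(frame.index) == ["a", "b"]
    assert frame.loc["a", "homologs_parent1"] == "1"
    assert frame.loc["b", "homologs_parent2"] == "2,3"
    assert gm.length == 12.5
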