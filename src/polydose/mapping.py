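"""From the pairwise linkage table to genetic maps.

Homolog clustering groups the simplex x nulliplex (SN) markers of one
parent by coupling-phase linkage at high LOD: each connected component is a
candidate homolog.  Remaining markers are assigned to the homolog(s) their
strongest coupling linkages support, and dropped when no SN linkage reaches
the assignment LOD threshold.  Marker ordering uses weighted
multidimensional scaling (SMACOF with LOD^2 weights) of Haldane map
distances in two dimensions, followed by a principal-curve fit whose
arc-length yields the map positions; a single nearest-neighbour-fit pass
(NNfit > threshold removes a marker) is applied and the order re-estimated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

R_CAP = 0.4999


def haldane_distance(r: np.ndarray | float) -> np.ndarray | float:
    """Haldane map distance in cM: d = -50 ln(1 - 2r).

    Fractions at or above R_CAP are clamped (with a warning) so distant
    pairs map to a large but finite distance.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0) or np.any(arr > 0.5):
        raise ValueError("r must be in [0, 0.5]")
    if np.any(arr >= R_CAP):
        warnings.warn("recombination fractions clamped at %.4f" % R_CAP)
        arr = np.minimum(arr, R_CAP)
    d = -50.0 * np.log1p(-2.0 * arr)
    return float(d) if np.isscalar(r) else d


def haldane_r(d: np.ndarray | float) -> np.ndarray | float:
    """Inverse Haldane map function: r = (1 - exp(-d/50)) / 2."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


def _sn_markers(seg_types: dict[str, tuple[int, int]], parent: int, ploidy: int):
    other = 1 - parent
    return [
        m for m, d in seg_types.items()
        if d[parent] == 1 and d[other] == 0
    ]


def cluster_homologs(
    links: pd.DataFrame,
    seg_types: dict[str, tuple[int, int]],
    parent: int = 0,
    lod_min: float = 5.0,
    ploidy: int = 4,
) -> list[set[str]]:
    """Cluster one parent's SN markers into homolog candidates.

    Edges join SN markers in coupling phase (overlap 1 in this parent) with
    LOD at or above ``lod_min``; connected components are the clusters.  In
    a clean single-chromosome dataset at most ``ploidy`` clusters per
    parent are expected.
    """
    sn = set(_sn_markers(seg_types, parent, ploidy))
    g = nx.Graph()
    g.add_nodes_from(sn)
    ocol = f"phase{parent + 1}_overlap"
    for row in links.itertuples(index=False):
        a, b = row.marker_a, row.marker_b
        if a in sn and b in sn and row.LOD >= lod_min and getattr(row, ocol) == 1:
            g.add_edge(a, b)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), sorted(c)[0]))
    return comps


def assign_markers(
    links: pd.DataFrame,
    clusters: list[set[str]],
    seg_types: dict[str, tuple[int, int]],
    parent: int = 0,
    lod_assign: float = 3.0,
    ploidy: int = 4,
) -> tuple[dict[str, set[int]], list[str]]:
    """Assign markers to homolog clusters of one parent by coupling LOD.

    A marker with dosage d in this parent is assigned the (up to) d clusters
    whose SN members show the strongest coupling-phase linkage to it; the
    best supporting linkage must reach ``lod_assign``.  Markers informative
    in this parent with no qualifying SN linkage are dropped and reported.

    Returns (marker -> cluster-index set, dropped markers).
    """
    member_of = {m: k for k, cl in enumerate(clusters) for m in cl}
    ocol = f"phase{parent + 1}_overlap"
    evidence: dict[str, dict[int, float]] = {}
    for row in links.itertuples(index=False):
        for m, sn_m in ((row.marker_a, row.marker_b), (row.marker_b, row.marker_a)):
            if sn_m in member_of and getattr(row, ocol) >= 1:
                k = member_of[sn_m]
                ev = evidence.setdefault(m, {})
                ev[k] = max(ev.get(k, 0.0), row.LOD)
    assigned: dict[str, set[int]] = {}
    dropped: list[str] = []
    for m, seg in seg_types.items():
        d = seg[parent]
        if not 0 < d < ploidy:
            continue  # uninformative in this parent
        if m in member_of:  # SN marker: its own cluster
            assigned[m] = {member_of[m]}
            continue
        ev = evidence.get(m, {})
        good = sorted(
            ((lod, k) for k, lod in ev.items() if lod >= lod_assign), reverse=True
        )
        if not good:
            dropped.append(m)
            continue
        assigned[m] = {k for _, k in good[:d]}
    return assigned, dropped


def merge_identical_markers(
    weighted_dosage: pd.DataFrame,
    links: pd.DataFrame,
    corr_threshold: float = 0.99,
    lod_sig: float = 3.0,
) -> tuple[list[str], dict[str, str]]:
    """Collapse effectively identical markers before ordering.

    Markers whose weighted-dosage rows correlate above ``corr_threshold``
    are grouped transitively; each group keeps the member with the largest
    number of significant linkages (LOD >= lod_sig), ties broken
    alphabetically.  Satellites later inherit the representative's mapped
    position and homologs.

    Parameters
    ----------
    weighted_dosage : DataFrame, markers x individuals.

    Returns (representative markers, satellite -> representative).
    """
    X = weighted_dosage.to_numpy()
    names = list(weighted_dosage.index)
    sd = X.std(axis=1)
    usable = np.flatnonzero(sd > 0)
    g = nx.Graph()
    g.add_nodes_from(names)
    if len(usable) >= 2:
        C = np.corrcoef(X[usable])
        iu, ju = np.triu_indices(len(usable), k=1)
        hits = C[iu, ju] > corr_threshold
        for a, b in zip(iu[hits], ju[hits]):
            g.add_edge(names[usable[a]], names[usable[b]])
    n_sig = {m: 0 for m in names}
    sig = links[links["LOD"] >= lod_sig]
    for col in ("marker_a", "marker_b"):
        for m, c in sig[col].value_counts().items():
            if m in n_sig:
                n_sig[m] += int(c)
    reps: list[str] = []
    satellite: dict[str, str] = {}
    for comp in nx.connected_components(g):
        rep = sorted(comp, key=lambda m: (-n_sig[m], m))[0]
        reps.append(rep)
        for m in comp:
            if m != rep:
                satellite[m] = rep
    reps.sort(key=names.index)
    return reps, satellite


def _weighted_smacof(
    D: np.ndarray, W: np.ndarray, n_components: int = 2,
    n_iter: int = 300, tol: float = 1e-7,
) -> np.ndarray:
    """Weighted metric MDS by iterative stress majorisation (SMACOF)."""
    n = D.shape[0]
    V = -W.copy()
    np.fill_diagonal(V, 0.0)
    np.fill_diagonal(V, -V.sum(axis=1))
    Vp = np.linalg.pinv(V + np.ones((n, n)) / n) - np.ones((n, n)) / n
    # deterministic init: classical MDS on the (weight-agnostic) distances
    J = np.eye(n) - np.ones((n, n)) / n
    B0 = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B0)
    order = np.argsort(vals)[::-1][:n_components]
    X = vecs[:, order] * np.sqrt(np.maximum(vals[order], 1e-12))
    stress_old = np.inf
    for _ in range(n_iter):
        diff = X[:, None, :] - X[None, :, :]
        delta = np.sqrt((diff ** 2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 1e-12, D / delta, 0.0)
        B = -W * ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = Vp @ B @ X
        stress = float((W * (D - delta) ** 2).sum())
        if stress_old - stress < tol * max(stress, 1.0):
            break
        stress_old = stress
    return X


def _lowess_smooth(y: np.ndarray, frac: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.arange(len(y), dtype=float)
    return lowess(y, x, frac=frac, return_sorted=False)


def _principal_curve_positions(
    X: np.ndarray, span: float = 0.3, n_iter: int = 8
) -> np.ndarray:
    """Arc-length positions along a principal curve through a 2D layout.

    The curve parameter starts at the first principal component ordering;
    at each iteration the coordinates are smoothed (lowess) along the
    current order and the parameter is replaced by cumulative arc length of
    the smoothed curve.
    """
    n = X.shape[0]
    if n <= 2:
        lam = np.linalg.norm(X - X[0], axis=1)
        return lam
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = Xc @ Vt[0]
    for _ in range(n_iter):
        order = np.argsort(lam, kind="stable")
        S = np.empty_like(X)
        for d in range(X.shape[1]):
            S[order, d] = _lowess_smooth(X[order, d], span)
        seg = np.linalg.norm(np.diff(S[order], axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        new_lam = np.empty(n)
        new_lam[order] = arc
        if np.allclose(new_lam, lam, atol=1e-9):
            lam = new_lam
            break
        lam = new_lam
    return lam - lam.min()


def mds_order(
    links: pd.DataFrame,
    markers: list[str] | None = None,
    n_components: int = 2,
    span: float = 0.3,
) -> pd.Series:
    """Order markers of one linkage group by weighted MDS.

    Pairwise Haldane distances (from estimated r) enter a weighted SMACOF
    embedding with LOD^2 weights; positions are arc lengths along a
    principal curve through the 2D configuration, rescaled so the map
    distances regress 1:1 (weighted) on the observed pairwise distances.
    A 1D embedding (``n_components=1``) is available as a fallback.

    Raises on a disconnected linkage graph, naming the components.
    """
    if markers is None:
        markers = sorted(set(links["marker_a"]) | set(links["marker_b"]))
    idx = {m: i for i, m in enumerate(markers)}
    n = len(markers)
    if n < 2:
        return pd.Series(np.zeros(n), index=markers, name="position_cM")
    D = np.zeros((n, n))
    W = np.zeros((n, n))
    g = nx.Graph()
    g.add_nodes_from(markers)
    for row in links.itertuples(index=False):
        a, b = row.marker_a, row.marker_b
        if a in idx and b in idx:
            i, j = idx[a], idx[b]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                D[i, j] = D[j, i] = haldane_distance(min(row.r, R_CAP))
            W[i, j] = W[j, i] = row.LOD ** 2
            if row.LOD > 0:
                g.add_edge(a, b)
    if not nx.is_connected(g):
        comps = [sorted(c)[:3] for c in nx.connected_components(g)]
        raise ValueError(f"linkage graph disconnected; components (heads): {comps}")
    if n == 2:
        return pd.Series([0.0, D[0, 1]], index=markers, name="position_cM")
    X = _weighted_smacof(D, W, n_components=max(n_components, 1))
    if n_components == 1:
        lam = X[:, 0] - X[:, 0].min()
    else:
        lam = _principal_curve_positions(X, span=span)
    # rescale so map distances match observed distances (weighted regression)
    dl = np.abs(lam[:, None] - lam[None, :])
    num = float((W * dl * D).sum())
    den = float((W * dl ** 2).sum())
    if den > 0 and num > 0:
        lam = lam * (num / den)
    return pd.Series(lam, index=markers, name="position_cM")


def nnfit(
    positions: pd.Series, links: pd.DataFrame, lod_informative: float = 3.0
) -> pd.Series:
    """Nearest-neighbour fit per marker.

    For each marker, among the markers it has an *informative* linkage
    estimate with (LOD at or above ``lod_informative``), the nearest one on
    the map is located; NNfit is the absolute difference between the
    observed (Haldane) distance to that neighbour and the map-implied
    distance.  Restricting to informative neighbours keeps the diagnostic
    from flagging markers whose nearest map neighbour happens to be a weakly
    informative pair with a noisy estimate.  Markers with no informative
    neighbour get NaN.
    """
    pos = positions.to_dict()
    best: dict[str, tuple[float, float]] = {}
    for row in links.itertuples(index=False):
        a, b = row.marker_a, row.marker_b
        if a not in pos or b not in pos or row.LOD < lod_informative:
            continue
        dmap = abs(pos[a] - pos[b])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dobs = haldane_distance(min(row.r, R_CAP))
        for m in (a, b):
            if m not in best or dmap < best[m][0]:
                best[m] = (dmap, abs(dobs - dmap))
    return pd.Series(
        {m: best.get(m, (np.nan, np.nan))[1] for m in positions.index},
        name="NNfit",
    )


def nnfit_filter(
    positions: pd.Series,
    links: pd.DataFrame,
    threshold: float = 5.0,
    lod_informative: float = 3.0,
    **mds_kwargs,
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Remove ordering outliers (NNfit > threshold) and re-order once.

    Returns (final positions, NNfit of the final map, removed markers).
    """
    fit = nnfit(positions, links, lod_informative)
    removed = [m for m in positions.index if fit[m] > threshold]
    if removed:
        keep = [m for m in positions.index if m not in removed]
        sub = links[
            links["marker_a"].isin(keep) & links["marker_b"].isin(keep)
        ]
        positions = mds_order(sub, markers=keep, **mds_kwargs)
        fit = nnfit(positions, sub, lod_informative)
    return positions, fit, removed


@dataclass
class GeneticMap:
    """An ordered map: positions, homolog assignments and fit diagnostics."""

    positions: pd.Series
    homologs_p1: dict[str, set[int]]
    homologs_p2: dict[str, set[int]]
    nnfit: pd.Series
    removed: list[str]

    def to_frame(self) -> pd.DataFrame:
        mk = list(self.positions.index)
        fmt = lambda hs: ",".join(str(h + 1) for h in sorted(hs)) if hs else ""
        return pd.DataFrame(
            {
                "marker": mk,
                "linkage_group": 1,
                "homologs_parent1": [fmt(self.homologs_p1.get(m, set())) for m in mk],
                "homologs_parent2": [fmt(self.homologs_p2.get(m, set())) for m in mk],
                "position_cM": self.positions.values,
                "NNfit": [self.nnfit.get(m, np.nan) for m in mk],
            }
        ).set_index("marker")

    @property
    def length(self) -> float:
        return float(self.positions.max() - self.positions.min())
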