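"""End-to-end workflows: observations -> posteriors -> QC -> linkage -> map.

Two workflows share every stage except two: the *probabilistic* workflow
feeds dosage posteriors directly into the full two-point likelihood, while
the *discrete* workflow first discretises the posteriors (maximum-posterior
call above a probability threshold, otherwise missing), removes markers
with too many missing values, and uses the count-based likelihood.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from . import qc as qc_mod
from .calling import MISSING, DosagePosteriors, discretize, filter_markers_missing
from .linkage import pairwise_linkage_scan
from .mapping import (
    GeneticMap,
    assign_markers,
    cluster_homologs,
    mds_order,
    merge_identical_markers,
    nnfit_filter,
)

logger = logging.getLogger(__name__)

PARENTS = ("P1", "P2")


def call_simulated_array(truth, overdispersion, seed=0, bias=1.0):
    """Simulate array signal ratios for a TruthSet and call posteriors."""
    from .calling import call_array
    from .observe import simulate_array_signals

    ratios = simulate_array_signals(truth, overdispersion, bias=bias, seed=seed)
    return call_array(ratios, ploidy=truth.ploidy, parents=PARENTS)


def call_simulated_reads(truth, noise, prior="f1"):
    """Simulate read counts for a TruthSet and call posteriors.

    The caller is given the simulation's own error, bias and overdispersion
    (the known-parameter setting of the simulation studies).  With
    ``prior='f1'`` (default) the joint family model of
    :func:`~polydose.calling.call_reads_f1` is applied: parental dosages are
    latent per marker and inferred from the whole family, and offspring are
    called under the resulting segregation mixture.  ``prior='uniform'``
    calls every sample independently under a flat prior; an explicit prior
    array is also accepted.
    """
    from .calling import call_reads, call_reads_f1
    from .observe import simulate_read_counts

    alt, depth = simulate_read_counts(truth, noise)
    kw = dict(
        ploidy=truth.ploidy, eps=noise.seq_error,
        bias=noise.allelic_bias, overdispersion=noise.overdispersion,
    )
    if not isinstance(prior, str):
        return call_reads(alt, depth, prior=prior, **kw)
    if prior == "uniform":
        return call_reads(alt, depth, prior=None, **kw)
    if prior != "f1":
        raise ValueError("prior must be 'f1', 'uniform' or an array")
    return call_reads_f1(alt, depth, parents=PARENTS, **kw)


@dataclass
class PipelineConfig:
    """Thresholds and switches of the mapping pipeline.

    Defaults follow the standard probabilistic workflow: duplicate
    individuals merged above 0.95 weighted-dosage correlation, individuals
    flagged when fewer than half their markers reach max posterior 0.6,
    segregation tested at p >= 1e-3 with parental confidence 0.9,
    discretisation at 0.95 with a 0.1 missing-rate cap (discrete workflow
    only), homolog clustering at LOD 5, marker assignment at LOD 3, and one
    NNfit > 5 removal pass.
    """

    mode: str = "probabilistic"
    ploidy: int = 4
    duplicate_corr: float = 0.95
    poor_prob: float = 0.6
    poor_fraction: float = 0.5
    parent_conf: float = 0.9
    seg_p_min: float = 1e-3
    seg_max_impossible: float = 0.05
    discretize_threshold: float = 0.95
    max_missing: float = 0.1
    lod_cluster: float = 5.0
    lod_assign: float = 3.0
    nnfit_threshold: float = 5.0
    min_informative: int = 10
    merge_identical: bool = False
    identical_corr: float = 0.99
    mds_components: int = 2
    mds_span: float = 0.3
    max_pairs: int | None = None
    pair_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("probabilistic", "discrete"):
            raise ValueError("mode must be 'probabilistic' or 'discrete'")
        for name, lo, hi in (
            ("duplicate_corr", 0, 1), ("poor_prob", 0, 1), ("poor_fraction", 0, 1),
            ("parent_conf", 0, 1), ("max_missing", 0, 1), ("identical_corr", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    posteriors: DosagePosteriors
    seg_report: pd.DataFrame
    seg_types: dict[str, tuple[int, int]]
    links: pd.DataFrame
    genetic_map: GeneticMap | None
    discrete: pd.DataFrame | None
    duplicate_groups: list[list[str]]
    poor_individuals: list[str]
    dropped_assignment: list[str]
    satellites: dict[str, str]
    manifest: dict = field(default_factory=dict)


def _subsample_pairs(markers: list[str], max_pairs: int | None, seed: int):
    pairs = list(itertools.combinations(markers, 2))
    if max_pairs is None or len(pairs) <= max_pairs:
        return None  # scan everything
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=max_pairs, replace=False)
    return [pairs[i] for i in sorted(idx)]


def run_pipeline(
    post: DosagePosteriors,
    cfg: PipelineConfig | None = None,
    build_map: bool = True,
) -> PipelineResult:
    """Run the full workflow on a posterior tensor containing P1/P2 samples.

    Stages: unfit-marker removal -> duplicate merging -> poorly scored
    individuals -> segregation typing and filtering -> simplest-form
    conversion -> (discrete only: discretisation + missing filter) ->
    two-point scan -> homolog clustering and assignment -> MDS ordering ->
    NNfit pass.  The manifest records marker/individual counts per stage.
    """
    cfg = cfg or PipelineConfig()
    manifest: dict = {"mode": cfg.mode, "stages": {}}

    def stage(name, **counts):
        manifest["stages"][name] = counts
        logger.info("%s: %s", name, counts)

    stage("input", markers=post.n_markers, samples=post.n_samples)

    # markers the caller could not fit
    if post.meta is not None and "converged" in post.meta:
        fit_mask = post.meta["converged"].to_numpy(dtype=bool)
        post = post.select_markers(fit_mask)
    stage("caller_fit", markers=post.n_markers)

    # individual-level curation (parents are kept aside)
    offspring = [s for s in post.samples if s not in PARENTS]
    off = post.select_samples(offspring)
    off, dup_groups = qc_mod.find_and_merge_duplicates(off, cfg.duplicate_corr)
    poor = qc_mod.flag_poor_individuals(off, cfg.poor_prob, cfg.poor_fraction)
    keep_samples = [s for s in off.samples if s not in poor]
    off = off.select_samples(keep_samples)
    parents = post.select_samples([p for p in PARENTS if p in post.samples])
    P = np.concatenate([parents.P, off.P], axis=1)
    post = DosagePosteriors(
        P, list(post.markers), list(parents.samples) + list(off.samples), post.meta
    )
    stage("individual_qc", samples=post.n_samples,
          duplicates=len(dup_groups), poor=len(poor))

    # segregation typing on the probabilistic data
    assignments = qc_mod.assign_all_segregation_types(
        post,
        parent_conf_threshold=cfg.parent_conf,
        p_min=cfg.seg_p_min,
        max_impossible=cfg.seg_max_impossible,
    )
    seg_report = qc_mod.segregation_report(assignments)
    ok = [a.marker for a in assignments if a.matches_expected and not a.monomorphic]
    post = post.select_markers(ok)
    seg_types: dict[str, tuple[int, int]] = {}
    newP = post.P.copy()
    for i, m in enumerate(post.markers):
        a = next(x for x in assignments if x.marker == m)
        conv, seg, _ = qc_mod.to_simplest_form(post.P[i], a.seg_type, cfg.ploidy)
        newP[i] = conv
        seg_types[m] = seg
    post = DosagePosteriors(newP, list(post.markers), list(post.samples), post.meta)
    stage("segregation", markers=post.n_markers)

    # discrete workflow: discretise and filter on missing rate
    discrete = None
    if cfg.mode == "discrete":
        D = discretize(post, cfg.discretize_threshold)
        off_cols = [c for c in D.columns if c not in PARENTS]
        keep, _rates = filter_markers_missing(D[off_cols], cfg.max_missing)
        discrete = D.loc[keep, off_cols]
        post = post.select_markers(keep)
        seg_types = {m: seg_types[m] for m in keep}
        stage("missing_filter", markers=len(keep))

    # two-point scan
    scan_markers = list(seg_types)
    pairs = _subsample_pairs(scan_markers, cfg.max_pairs, cfg.pair_seed)
    data = discrete if cfg.mode == "discrete" else post
    links = pairwise_linkage_scan(
        data, seg_types, mode=cfg.mode, pairs=pairs,
        ploidy=cfg.ploidy, min_informative=cfg.min_informative,
    )
    stage("linkage_scan", pairs=len(links))

    satellites: dict[str, str] = {}
    if cfg.merge_identical:
        wd = pd.DataFrame(
            post.weighted_dosage(), index=post.markers, columns=post.samples
        )
        off_cols = [c for c in wd.columns if c not in PARENTS]
        reps, satellites = merge_identical_markers(
            wd[off_cols], links, cfg.identical_corr
        )
        keep = set(reps)
        links = links[
            links["marker_a"].isin(keep) & links["marker_b"].isin(keep)
        ].reset_index(drop=True)
        seg_types = {m: s for m, s in seg_types.items() if m in keep}
        stage("identical_merge", markers=len(keep), satellites=len(satellites))

    result = PipelineResult(
        posteriors=post,
        seg_report=seg_report,
        seg_types=seg_types,
        links=links,
        genetic_map=None,
        discrete=discrete,
        duplicate_groups=dup_groups,
        poor_individuals=poor,
        dropped_assignment=[],
        satellites=satellites,
        manifest=manifest,
    )
    if not build_map or not len(links):
        return result

    # homolog clustering and marker assignment per parent
    homologs: dict[int, dict[str, set[int]]] = {0: {}, 1: {}}
    mapped: set[str] = set()
    candidates: set[str] = set()
    for parent in (0, 1):
        clusters = cluster_homologs(
            links, seg_types, parent, cfg.lod_cluster, cfg.ploidy
        )
        if not clusters or not any(len(c) > 1 for c in clusters):
            continue
        assigned, _dropped = assign_markers(
            links, clusters, seg_types, parent, cfg.lod_assign, cfg.ploidy
        )
        homologs[parent] = assigned
        mapped |= set(assigned)
        candidates |= {
            m for m, s in seg_types.items() if 0 < s[parent] < cfg.ploidy
        }
    dropped_assignment = sorted(candidates - mapped)
    result.dropped_assignment = dropped_assignment
    stage("assignment", mapped=len(mapped), dropped=len(dropped_assignment))
    if len(mapped) < 3:
        return result

    # ordering on the largest connected component of the retained markers
    sub = links[
        links["marker_a"].isin(mapped) & links["marker_b"].isin(mapped)
    ].reset_index(drop=True)
    g = nx.Graph()
    g.add_nodes_from(mapped)
    g.add_edges_from(zip(sub["marker_a"], sub["marker_b"]))
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    group = sorted(comps[0])
    if len(comps) > 1:
        logger.info("ordering largest of %d linkage components", len(comps))
    sub = sub[
        sub["marker_a"].isin(group) & sub["marker_b"].isin(group)
    ].reset_index(drop=True)
    positions = mds_order(
        sub, markers=group, n_components=cfg.mds_components, span=cfg.mds_span
    )
    positions, fit, removed = nnfit_filter(
        positions, sub, cfg.nnfit_threshold,
        n_components=cfg.mds_components, span=cfg.mds_span,
    )
    positions = positions.sort_values()
    result.genetic_map = GeneticMap(
        positions, homologs[0], homologs[1], fit, removed
    )
    stage("ordering", mapped=len(positions), nnfit_removed=len(removed))
    manifest["config"] = asdict(cfg)
    return result
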