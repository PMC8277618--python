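"""File formats: tab-separated, header row, UTF-8, ``NA`` as missing token.

Posterior tables use the long layout common to polyploid callers: one row
per marker x sample with columns ``marker, sample, P0..Pk``.  Matrices
(dosages, signal ratios, read counts) are markers x samples with the marker
name as first column.  All writers round-trip with their readers within
float formatting (12 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import MISSING, DosagePosteriors
from .simulate import MarkerDef, ParentGenome, SimPopulationConfig, TruthSet

NA = "NA"
FLOAT_FMT = "%.12g"


def write_posteriors(post: DosagePosteriors, path: str | Path) -> None:
    k = post.ploidy + 1
    cols = [f"P{i}" for i in range(k)]
    flat = post.P.reshape(-1, k)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "sample", np.tile(post.samples, post.n_markers))
    df.insert(0, "marker", np.repeat(post.markers, post.n_samples))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_posteriors(path: str | Path, renorm_tol: float = 1e-6) -> DosagePosteriors:
    """Read a long-format posterior table.

    Rows with a negative probability are rejected with their line number;
    vectors off normalisation by more than ``renorm_tol`` are renormalised
    with a warning.
    """
    import warnings

    df = pd.read_csv(path, sep="\t")
    pcols = [c for c in df.columns if c.startswith("P") and c[1:].isdigit()]
    pcols.sort(key=lambda c: int(c[1:]))
    P = df[pcols].to_numpy(dtype=float)
    neg = np.flatnonzero((P < 0).any(axis=1))
    if len(neg):
        raise ValueError(f"negative probability at data line {neg[0] + 2} of {path}")
    sums = P.sum(axis=1)
    off = np.abs(sums - 1.0) > renorm_tol
    if off.any():
        warnings.warn(f"{off.sum()} posterior rows renormalised in {path}")
    P = P / sums[:, None]
    markers = list(dict.fromkeys(df["marker"]))
    samples = list(dict.fromkeys(df["sample"]))
    tensor = P.reshape(len(markers), len(samples), len(pcols))
    return DosagePosteriors(tensor, markers, samples)


def write_dosage_matrix(D: pd.DataFrame, path: str | Path) -> None:
    out = D.replace(MISSING, NA)
    out.to_csv(path, sep="\t", index_label="marker", na_rep=NA)


def read_dosage_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="marker", na_values=[NA])
    return df.fillna(MISSING).astype(np.int64)


def write_matrix(M: pd.DataFrame, path: str | Path) -> None:
    M.to_csv(path, sep="\t", index_label="marker", float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="marker")


def _fmt_homologs(s: frozenset[int]) -> str:
    return ",".join(str(h + 1) for h in sorted(s)) if s else ""


def _parse_homologs(s) -> frozenset[int]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return frozenset()
    return frozenset(int(x) - 1 for x in str(s).split(","))


def write_truthset(truth: TruthSet, markers_path: str | Path, dosages_path: str | Path) -> None:
    p1, p2 = truth.parent_genomes
    rows = []
    for i, m in enumerate(truth.marker_defs):
        rows.append(
            (m.name, m.position, m.d1, m.d2,
             _fmt_homologs(p1.homolog_alleles[i]),
             _fmt_homologs(p2.homolog_alleles[i]))
        )
    pd.DataFrame(
        rows,
        columns=["marker", "position_cM", "d1", "d2",
                 "parent1_homologs", "parent2_homologs"],
    ).to_csv(markers_path, sep="\t", index=False, float_format=FLOAT_FMT)
    D = pd.DataFrame(
        truth.true_dosages.T,
        index=truth.marker_names,
        columns=[f"F1_{z + 1:03d}" for z in range(truth.n_individuals)],
    )
    write_dosage_matrix(D, dosages_path)


def read_truthset(
    markers_path: str | Path, dosages_path: str | Path, ploidy: int = 4
) -> TruthSet:
    mdf = pd.read_csv(markers_path, sep="\t", keep_default_na=False, na_values=[])
    defs = [
        MarkerDef(r.marker, float(r.position_cM), int(r.d1), int(r.d2))
        for r in mdf.itertuples(index=False)
    ]
    p1 = ParentGenome(ploidy, [_parse_homologs(s) for s in mdf["parent1_homologs"]])
    p2 = ParentGenome(ploidy, [_parse_homologs(s) for s in mdf["parent2_homologs"]])
    D = read_dosage_matrix(dosages_path)
    return TruthSet(defs, (p1, p2), D.to_numpy().T)


def write_linkage_table(links: pd.DataFrame, path: str | Path) -> None:
    links.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_linkage_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_map(map_frame: pd.DataFrame, path: str | Path) -> None:
    map_frame.to_csv(path, sep="\t", index_label="marker", float_format=FLOAT_FMT, na_rep=NA)


def read_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="marker", na_values=[NA])


def read_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def config_from_file(path: str | Path) -> SimPopulationConfig:
    data = read_config(path)
    known = SimPopulationConfig.__dataclass_fields__.keys()
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seg_types" in data:
        data["seg_types"] = tuple(data["seg_types"])
    return SimPopulationConfig(**data)
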