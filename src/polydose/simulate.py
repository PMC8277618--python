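"""Simulation of autopolyploid F1 populations at the homolog level.

An F1 mapping population derives from a cross of two heterozygous parents.
Each parent carries ``ploidy`` homologous chromosomes; a marker's parental
dosage is the number of homologs carrying the counted allele.  Meiosis is
modelled with strict bivalent pairing: homologs pair two-by-two (the pairing
drawn uniformly from all perfect matchings each meiosis), each bivalent
transmits one chromatid, and crossovers follow a Poisson process at one
crossover per 100 cM per chromatid (no interference), which yields Haldane
map distances.  Double reduction is excluded, so the centromere position has
no effect and is accepted only for interface completeness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

#: Segregation-type labels used throughout: parental dosage pairs
#: (first parent, second parent).  N/S/D/T/Q = dosage 0..4 in a tetraploid.
SEG_TYPES = {
    "SN": (1, 0),
    "SS": (1, 1),
    "SD": (1, 2),
    "DN": (2, 0),
    "DD": (2, 2),
}

DOSAGE_LETTERS = "NSDTQ"


def seg_type_label(d1: int, d2: int) -> str:
    """Human-readable segregation-type label, e.g. (1, 0) -> 'SN'."""
    if max(d1, d2) < len(DOSAGE_LETTERS):
        return DOSAGE_LETTERS[d1] + DOSAGE_LETTERS[d2]
    return f"{d1}x{d2}"


@dataclass(frozen=True)
class MarkerDef:
    """A marker on the simulated chromosome.

    Parameters
    ----------
    name : str
        Unique marker identifier.
    position : float
        Map position in centiMorgan, non-negative.
    d1, d2 : int
        Parental dosages of the counted allele (the segregation type).
    """

    name: str
    position: float
    d1: int
    d2: int

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"negative position for marker {self.name}")

    @property
    def seg_type(self) -> tuple[int, int]:
        return (self.d1, self.d2)


@dataclass
class ParentGenome:
    """Phase assignment of one parent: which homologs carry the counted allele.

    ``homolog_alleles[m]`` is a frozenset of 0-based homolog indices of size
    equal to the parent's dosage at marker ``m``.
    """

    ploidy: int
    homolog_alleles: list[frozenset[int]]

    def allele_matrix(self) -> np.ndarray:
        """Boolean matrix (markers x ploidy): homolog carries the allele."""
        out = np.zeros((len(self.homolog_alleles), self.ploidy), dtype=bool)
        for i, s in enumerate(self.homolog_alleles):
            out[i, list(s)] = True
        return out


@dataclass
class SimPopulationConfig:
    """Design of a simulated F1 population.

    Defaults reproduce the standard study design: 200 tetraploid F1
    individuals, one 100 cM chromosome with the centromere in the middle,
    and the five segregation types SN, SS, SD, DN, DD placed at every
    1 cM position, giving 505 markers.
    """

    n_individuals: int = 200
    ploidy: int = 4
    chromosome_length: float = 100.0
    marker_spacing: float = 1.0
    seg_types: tuple[str, ...] = ("SN", "SS", "SD", "DN", "DD")
    centromere: float | None = None  # inert under bivalent-only meiosis
    seed: int = 0

    def __post_init__(self):
        if self.ploidy % 2 != 0 or self.ploidy < 2:
            raise ValueError("ploidy must be a positive even integer")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.marker_spacing <= 0 or self.chromosome_length <= 0:
            raise ValueError("lengths must be positive")

    def marker_defs(self) -> list[MarkerDef]:
        """All five segregation types at each spacing step (co-located)."""
        defs = []
        positions = np.arange(
            0.0, self.chromosome_length + 1e-9, self.marker_spacing
        )
        for pos in positions:
            for label in self.seg_types:
                d1, d2 = SEG_TYPES[label]
                name = f"M{pos:07.2f}_{label}".replace(".", "p")
                defs.append(MarkerDef(name, float(pos), d1, d2))
        return defs


@dataclass
class TruthSet:
    """A simulated population with full ground truth.

    Attributes
    ----------
    marker_defs : list of MarkerDef
    parent_genomes : (ParentGenome, ParentGenome)
    true_dosages : ndarray, shape (n_individuals, n_markers)
        Integer offspring dosages 0..ploidy.
    homolog_origins : ndarray, shape (n_individuals, 2, ploidy//2, n_markers)
        Per individual, parent, transmitted chromatid: origin homolog index.
    """

    marker_defs: list[MarkerDef]
    parent_genomes: tuple[ParentGenome, ParentGenome]
    true_dosages: np.ndarray
    homolog_origins: np.ndarray = field(repr=False, default=None)

    @property
    def ploidy(self) -> int:
        return self.parent_genomes[0].ploidy

    @property
    def n_individuals(self) -> int:
        return self.true_dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_defs)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.marker_defs]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.marker_defs])

    def parental_dosages(self) -> np.ndarray:
        """(n_markers, 2) array of the two parents' dosages."""
        return np.array([[m.d1, m.d2] for m in self.marker_defs])

    def phase_overlap(self, i: int, j: int, parent: int) -> int:
        """True phase of a marker pair in one parent: |S_i ∩ S_j|.

        The overlap count between the allele-carrying homolog sets fully
        determines the two-locus gamete distribution under random bivalent
        pairing (homologs are exchangeable), so it serves as the phase class:
        maximal overlap = coupling, zero overlap = repulsion.
        """
        g = self.parent_genomes[parent]
        return len(g.homolog_alleles[i] & g.homolog_alleles[j])


def gamete_dosage_dist(parent_dosage: int, ploidy: int = 4) -> np.ndarray:
    """Distribution of the gamete dosage transmitted by one parent.

    Under random bivalent pairing without double reduction, the ploidy/2
    transmitted homolog origins form a uniform draw of ploidy/2 homologs
    out of ploidy, so the gamete dosage is hypergeometric.

    Returns an array of length ploidy/2 + 1.
    """
    if not 0 <= parent_dosage <= ploidy:
        raise ValueError(f"dosage {parent_dosage} out of 0..{ploidy}")
    n = ploidy // 2
    k = np.arange(n + 1)
    return hypergeom.pmf(k, ploidy, parent_dosage, n)


def expected_segregation(d1: int, d2: int, ploidy: int = 4) -> np.ndarray:
    """Expected offspring dosage distribution for parental dosages (d1, d2).

    The convolution of the two parental gamete-dosage distributions; e.g.
    duplex x duplex (DD) in a tetraploid segregates 1:8:18:8:1.

    Returns an array of length ploidy + 1.
    """
    g1 = gamete_dosage_dist(d1, ploidy)
    g2 = gamete_dosage_dist(d2, ploidy)
    return np.convolve(g1, g2)


def assign_parent_phases(
    marker_defs: list[MarkerDef], ploidy: int = 4, seed: int | None = 0
) -> tuple[ParentGenome, ParentGenome]:
    """Assign allele-carrying homolog sets uniformly at random per marker.

    Independent across markers and parents; reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    genomes = []
    for parent in range(2):
        sets = []
        for m in marker_defs:
            d = (m.d1, m.d2)[parent]
            if not 0 <= d <= ploidy:
                raise ValueError(f"dosage {d} out of range for {m.name}")
            chosen = rng.choice(ploidy, size=d, replace=False)
            sets.append(frozenset(int(c) for c in chosen))
        genomes.append(ParentGenome(ploidy, sets))
    return genomes[0], genomes[1]


@lru_cache(maxsize=None)
def _perfect_matchings(ploidy: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All ways to pair ``ploidy`` homologs into bivalents (3 for ploidy 4)."""

    def rec(items):
        if not items:
            yield ()
            return
        first, rest = items[0], items[1:]
        for i, other in enumerate(rest):
            for tail in rec(rest[:i] + rest[i + 1:]):
                yield ((first, other),) + tail

    return tuple(rec(tuple(range(ploidy))))


def simulate_meiosis(
    parent: ParentGenome,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: transmitted chromatid origins and gamete dosages.

    Homologs are paired into ploidy/2 bivalents uniformly over all perfect
    matchings.  Each bivalent transmits one chromatid whose parental origin
    starts at either homolog with probability 1/2 and switches at crossover
    points drawn from a Poisson process at 1 crossover per 100 cM.

    Parameters
    ----------
    positions : array of marker positions in cM, sorted ascending.

    Returns
    -------
    origins : ndarray (ploidy//2, n_markers) of homolog indices.
    dosages : ndarray (n_markers,) gamete dosage at each marker.
    """
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    ploidy = parent.ploidy
    matchings = _perfect_matchings(ploidy)
    matching = matchings[rng.integers(len(matchings))]
    length = positions[-1] if len(positions) else 0.0

    n_biv = ploidy // 2
    origins = np.empty((n_biv, len(positions)), dtype=np.int64)
    for b, (h1, h2) in enumerate(matching):
        start = rng.integers(2)
        n_xo = rng.poisson(length / 100.0)
        xo = np.sort(rng.uniform(0.0, length, size=n_xo)) if n_xo else np.empty(0)
        # parity of crossover count left of each marker flips the origin
        flips = np.searchsorted(xo, positions, side="right") % 2
        which = (start + flips) % 2
        origins[b] = np.where(which == 0, h1, h2)

    allele = parent.allele_matrix()  # markers x ploidy
    dosages = allele[np.arange(len(positions))[None, :], origins].sum(axis=0)
    return origins, dosages


def simulate_f1(config: SimPopulationConfig) -> TruthSet:
    """Simulate a full F1 population under the configured design.

    Returns a TruthSet with true offspring dosages and, for oracle checks,
    the transmitted homolog origins of every gamete.
    """
    rng = np.random.default_rng(config.seed)
    defs = config.marker_defs()
    positions = np.array([m.position for m in defs])
    p1, p2 = assign_parent_phases(
        defs, config.ploidy, seed=rng.integers(2**31)
    )
    n_biv = config.ploidy // 2
    n_mark = len(defs)
    dosages = np.empty((config.n_individuals, n_mark), dtype=np.int64)
    origins = np.empty((config.n_individuals, 2, n_biv, n_mark), dtype=np.int64)
    for z in range(config.n_individuals):
        o1, d1 = simulate_meiosis(p1, positions, rng)
        o2, d2 = simulate_meiosis(p2, positions, rng)
        dosages[z] = d1 + d2
        origins[z, 0] = o1
        origins[z, 1] = o2
    return TruthSet(defs, (p1, p2), dosages, origins)


def all_seg_type_pairs(ploidy: int = 4, segregating_only: bool = True):
    """Enumerate candidate parental dosage pairs (d1, d2).

    With ``segregating_only`` a marker must segregate in the progeny, i.e.
    at least one parent has dosage strictly between 0 and ploidy.
    """
    for d1, d2 in itertools.product(range(ploidy + 1), repeat=2):
        if segregating_only and not (0 < d1 < ploidy or 0 < d2 < ploidy):
            continue
        yield d1, d2
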