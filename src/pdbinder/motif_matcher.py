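"""Three-residue motif enumeration and structural matching.

A *motif triplet* is a set of three residues of one chain whose contact
graph — edges between residues with CA-CA distance strictly below the
neighbour cutoff (7.5 Å by default) — is connected.  Two triplets match when
their residue types can be paired identically (no substitutions) and the
paired representative atoms superpose with an RMSD strictly below the
threshold (0.7 Å by default).

Matching is exact: library triplets are indexed by sorted amino-acid
composition, which only prunes pairs that could never satisfy the
identical-type pairing rule, and every type-consistent permutation of a
candidate pair is tested.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .library_builder import ResidueLibrary
from .structure_model import (DEFAULT_SCHEME, RepresentationScheme,
                              ResidueRecord, ensure_representations)

MOTIF_SIZE = 3


@dataclass(frozen=True)
class ParamConfig:
    """Matching parameters: both cutoffs are strict upper bounds (Å)."""

    rmsd_max: float = 0.7
    neighbor_max: float = 7.5
    motif_size: int = MOTIF_SIZE
    representation: RepresentationScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if self.rmsd_max <= 0 or self.neighbor_max <= 0:
            raise ValueError("rmsd_max and neighbor_max must be positive")
        if self.motif_size != MOTIF_SIZE:
            raise ValueError("only three-residue motifs are supported")


@dataclass
class MotifTriplet:
    """Three residues of one chain in canonical (chain, seq, icode) order."""

    residues: tuple[ResidueRecord, ResidueRecord, ResidueRecord]
    coords: np.ndarray            # concatenated representative coordinates
    splits: tuple[int, int, int]  # representative-atom count per residue

    @property
    def aa_types(self) -> tuple[str, str, str]:
        return tuple(r.aa_type for r in self.residues)  # type: ignore[return-value]

    @property
    def aa_key(self) -> tuple[str, str, str]:
        return tuple(sorted(self.aa_types))  # type: ignore[return-value]

    @property
    def keys(self) -> tuple:
        return tuple(r.key for r in self.residues)

    def coords_in_order(self, order: tuple[int, int, int]) -> np.ndarray:
        offsets = np.concatenate([[0], np.cumsum(self.splits)])
        return np.concatenate([self.coords[offsets[i]:offsets[i + 1]] for i in order])


@dataclass
class Match:
    """An accepted superposition between a query and a library triplet."""

    query_triplet: MotifTriplet
    library_triplet: MotifTriplet
    rmsd: float
    residue_pairing: tuple[tuple[ResidueRecord, ResidueRecord], ...]
    library_chain: str = ""


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between positionally corresponding point sets.

    Optimizes over proper rotations (determinant +1) and translations;
    reflections are never used, so enantiomeric point sets do not superpose
    to zero.  Both inputs must have the same length, at least 3 points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need (n, 3) arrays with n >= 3")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    # Kabsch: SVD of the covariance, with the smallest singular direction
    # flipped when needed to keep the rotation proper (det +1).  The RMSD is
    # evaluated on the explicitly rotated coordinates, which stays accurate
    # to machine precision near zero (unlike residual-trace formulas).
    u, _, vt = np.linalg.svd(bc.T @ ac)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt)
    diff = ac - bc @ rot
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# --------------------------------------------------------------------------
# Triplet enumeration
# --------------------------------------------------------------------------

def _canonical(residues: tuple[ResidueRecord, ...]) -> tuple[ResidueRecord, ...]:
    return tuple(sorted(residues, key=lambda r: r.key))


def make_triplet(residues: tuple[ResidueRecord, ResidueRecord, ResidueRecord]) -> MotifTriplet:
    res = _canonical(residues)
    coords = np.concatenate([r.rep_coords for r in res])
    splits = tuple(len(r.rep_coords) for r in res)
    return MotifTriplet(residues=res, coords=coords, splits=splits)  # type: ignore[arg-type]


def enumerate_triplets(residues: list[ResidueRecord], cfg: ParamConfig = ParamConfig()
                       ) -> list[MotifTriplet]:
    """All three-residue subsets with a connected contact graph.

    Connectivity (not a full clique) is required: a path A-B-C with
    d(A,C) >= neighbor_max is still a valid motif.  Residues lacking a
    representation are skipped.  Output order is deterministic (sorted
    index triples).
    """
    complete, _ = ensure_representations(residues, cfg.representation)
    n = len(complete)
    if n < 3:
        return []
    cas = np.array([r.ca for r in complete])
    pairs = cKDTree(cas).query_pairs(cfg.neighbor_max, output_type="ndarray")
    # strict inequality: drop pairs at exactly the cutoff
    d = np.linalg.norm(cas[pairs[:, 0]] - cas[pairs[:, 1]], axis=1)
    pairs = pairs[d < cfg.neighbor_max]
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in pairs:
        adj[i].add(int(j))
        adj[j].add(int(i))
    # a 3-vertex graph is connected iff it has >= 2 edges: enumerate paths
    # centred on each vertex; triangles are produced once via sorted dedup
    seen: set[tuple[int, int, int]] = set()
    for b in range(n):
        nb = sorted(adj[b])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                seen.add(tuple(sorted((nb[x], b, nb[y]))))  # type: ignore[arg-type]
    return [make_triplet((complete[i], complete[j], complete[k]))
            for i, j, k in sorted(seen)]


# --------------------------------------------------------------------------
# Library triplets (pure binding / pure non-binding only)
# --------------------------------------------------------------------------

def library_triplets(lib: ResidueLibrary, cfg: ParamConfig = ParamConfig()
                     ) -> list[tuple[MotifTriplet, str, str, bool]]:
    """Enumerate library triplets as (triplet, chain_key, cluster, is_binding).

    Triplets never span two source chains, and triplets mixing binding and
    non-binding residues are dropped here: the method scores matches against
    exactly two libraries, so a group of residues must belong wholly to one.
    Results are cached on the library keyed by the matching parameters.
    """
    cache_key = (cfg.neighbor_max, cfg.representation.cache_key())
    cached = lib._triplet_cache.get(cache_key)
    if cached is not None:
        return cached
    out: list[tuple[MotifTriplet, str, str, bool]] = []
    for chain_key, (cluster, residues) in lib.chains().items():
        for t in enumerate_triplets(residues, cfg):
            flags = {r.is_binding for r in t.residues}
            if len(flags) != 1:
                continue  # mixed triplet: excluded from both libraries
            out.append((t, chain_key, cluster, bool(flags.pop())))
    lib._triplet_cache[cache_key] = out
    return out


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------

def _consistent_orders(query_types: tuple[str, ...], lib_types: tuple[str, ...]
                       ) -> list[tuple[int, int, int]]:
    """Permutations of the library residues matching the query types positionally."""
    orders = []
    for perm in permutations(range(3)):
        if tuple(lib_types[i] for i in perm) == query_types:
            orders.append(perm)
    return orders


def match_triplet_pair(qt: MotifTriplet, lt: MotifTriplet, cfg: ParamConfig
                       ) -> tuple[float, tuple[int, int, int]] | None:
    """Best-RMSD identical-type pairing of two triplets, if below threshold."""
    best: tuple[float, tuple[int, int, int]] | None = None
    for order in _consistent_orders(qt.aa_types, lt.aa_types):
        rmsd = kabsch_rmsd(qt.coords, lt.coords_in_order(order))
        if rmsd < cfg.rmsd_max and (best is None or rmsd < best[0]):
            best = (rmsd, order)
    return best


def match_structure(query: list[ResidueRecord], lib: ResidueLibrary,
                    cfg: ParamConfig = ParamConfig(),
                    exclusion: set[str] | frozenset[str] = frozenset(),
                    ) -> list[Match]:
    """All accepted (query triplet, library triplet) superpositions.

    Library triplets from chains whose homology cluster is in ``exclusion``
    are skipped (leave-one-out / homology exclusion).  When a triplet
    contains repeated types every consistent pairing is tried, but each
    (query triplet, library triplet) pair yields at most one match, reported
    with its best-RMSD pairing.
    """
    lib_trips = library_triplets(lib, cfg)
    if not lib_trips:
        warnings.warn("empty motif library: no matches possible", stacklevel=2)
        return []
    index: dict[tuple[str, str, str], list[tuple[MotifTriplet, str, str, bool]]] = {}
    for entry in lib_trips:
        if entry[2] in exclusion:
            continue
        index.setdefault(entry[0].aa_key, []).append(entry)

    matches: list[Match] = []
    for qt in enumerate_triplets(query, cfg):
        for lt, chain_key, _cluster, _binding in index.get(qt.aa_key, ()):
            hit = match_triplet_pair(qt, lt, cfg)
            if hit is None:
                continue
            rmsd, order = hit
            pairing = tuple((qt.residues[i], lt.residues[order[i]]) for i in range(3))
            matches.append(Match(query_triplet=qt, library_triplet=lt,
                                 rmsd=rmsd, residue_pairing=pairing,
                                 library_chain=chain_key))
    return matches


def write_matches_tsv(matches: list[Match], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["query_res1", "query_res2", "query_res3", "library_chain",
                    "lib_res1", "lib_res2", "lib_res3", "rmsd", "lib_binding"])
        for m in matches:
            w.writerow([*(r.label() for r in m.query_triplet.residues),
                        m.library_chain,
                        *(r.label() for r in m.library_triplet.residues),
                        f"{m.rmsd:.4f}",
                        "".join("1" if r.is_binding else "0"
                                for r in m.library_triplet.residues)])
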