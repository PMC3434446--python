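"""Combining predictions with external predictors and ranking cavities.

External energy- or geometry-based predictors are consumed as files, in one
of two dialects: residue lists (cavity/cluster id plus residue identifiers)
or 3-D probe point clouds (x, y, z, cluster id per line).  Probe points are
mapped to residues with the same heavy-atom distance rule used for pocket
definition (< 3.5 Å by default).  Boolean integration (AND/OR) operates on
residue-key sets; cavity ranking orders externally detected surface clefts
by how many predicted binding residues they contain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import StructureRecord

ResidueKey = tuple[str, int, str]

PROBE_CUTOFF = 3.5
STP_ATOM_SCORE_CUTOFF = 70.0


@dataclass
class ExternalPrediction:
    """A set of predicted residues, or probe clusters with ranks."""

    residues: set[ResidueKey] = field(default_factory=set)
    probe_clusters: dict[int, np.ndarray] = field(default_factory=dict)  # rank -> points

    def top_clusters(self, n: int) -> np.ndarray:
        ranks = sorted(self.probe_clusters)
        pts = [self.probe_clusters[r] for r in ranks[:n]]
        return np.concatenate(pts) if pts else np.empty((0, 3))


@dataclass
class Cavity:
    """An externally detected surface cleft."""

    cavity_id: str
    residues: set[ResidueKey] = field(default_factory=set)
    points: np.ndarray | None = None
    size: float | None = None  # point count or provided volume

    def size_proxy(self) -> float:
        if self.size is not None:
            return float(self.size)
        if self.points is not None:
            return float(len(self.points))
        return float(len(self.residues))


def probes_to_residues(points: np.ndarray, struct: StructureRecord,
                       cutoff: float = PROBE_CUTOFF) -> set[ResidueKey]:
    """Residues with any heavy atom strictly closer than ``cutoff`` to any
    probe point."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return set()
    tree = cKDTree(points)
    out: set[ResidueKey] = set()
    for res in struct.iter_residues():
        coords = res.heavy_coords()
        if len(coords) == 0:
            continue
        d, _ = tree.query(coords, k=1)
        if float(np.min(d)) < cutoff:
            out.add(res.key)
    return out


def combine(a: set[ResidueKey], b: set[ResidueKey], mode: str) -> set[ResidueKey]:
    """Boolean integration of two residue-set predictions."""
    if mode.upper() == "AND":
        return set(a) & set(b)
    if mode.upper() == "OR":
        return set(a) | set(b)
    raise ValueError(f"unknown combination mode {mode!r}")


def rank_cavities(cavities: list[Cavity], predicted: set[ResidueKey],
                  struct: StructureRecord | None = None,
                  cutoff: float = PROBE_CUTOFF) -> list[tuple[Cavity, int]]:
    """Cavities ordered by the number of predicted binding residues inside.

    Point-set cavities are first mapped to residues (requires ``struct``).
    Ties are broken by the larger size proxy, then by cavity id; with no
    predictions at all the ordering degenerates to pure size ordering.
    """
    scored = []
    for cav in cavities:
        residues = cav.residues
        if not residues and cav.points is not None:
            if struct is None:
                raise ValueError("point-set cavities require the structure")
            residues = probes_to_residues(cav.points, struct, cutoff)
            cav.residues = residues
        scored.append((cav, len(residues & predicted)))
    scored.sort(key=lambda t: (-t[1], -t[0].size_proxy(), t[0].cavity_id))
    return scored


def topn_success(ranked: list[tuple[Cavity, int]], truth: set[ResidueKey],
                 n: int) -> bool:
    """True iff any of the first ``n`` cavities contains a true binding
    residue."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return any(bool(cav.residues & truth) for cav, _ in ranked[:n])


# --------------------------------------------------------------------------
# File dialects
# --------------------------------------------------------------------------

def read_cavity_residues(path: str | Path) -> list[Cavity]:
    """TSV: cavity_id, chain, seq_num, icode (icode may be empty)."""
    cavities: dict[str, Cavity] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            cid, chain, seq = row[0], row[1], int(row[2])
            icode = row[3] if len(row) > 3 else ""
            cavities.setdefault(cid, Cavity(cavity_id=cid)).residues.add(
                (chain, seq, icode))
    return list(cavities.values())


def read_cavity_points(path: str | Path) -> list[Cavity]:
    """Whitespace-separated point cloud: x y z cavity_id per line."""
    groups: dict[str, list[list[float]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            x, y, z, cid = float(parts[0]), float(parts[1]), float(parts[2]), parts[3]
            groups.setdefault(cid, []).append([x, y, z])
    return [Cavity(cavity_id=cid, points=np.array(pts)) for cid, pts in groups.items()]


def write_ranked_cavities(ranked: list[tuple[Cavity, int]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["rank", "cavity_id", "predicted_residues", "size_proxy"])
        for i, (cav, count) in enumerate(ranked, start=1):
            w.writerow([i, cav.cavity_id, count, cav.size_proxy()])


def stp_residues_from_atom_scores(path: str | Path,
                                  cutoff: float = STP_ATOM_SCORE_CUTOFF
                                  ) -> set[ResidueKey]:
    """Residues with at least one atom scoring strictly above ``cutoff``.

    Expects a TSV of per-atom surface-patch scores: chain, seq_num, icode,
    atom_name, score.
    """
    out: set[ResidueKey] = set()
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            chain, seq, icode, _atom, score = row[0], int(row[1]), row[2], row[3], float(row[4])
            if score > cutoff:
                out.add((chain, seq, icode))
    return out
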