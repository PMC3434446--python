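"""Synthetic structures and planted motif libraries for download-free testing.

The generator emulates exactly the features of real data the pipeline
depends on — chains with ~3.8 Å CA-CA backbone spacing and per-residue
representative atoms, a ligand placed so that a designed residue subset
satisfies the 3.5 Å pocket rule, and a motif library whose binding triplets
are noisy rigid copies of motifs planted in the query pocket.  It does not
attempt physical realism (no rotamers, no packing, no secondary structure).

The planted library gives every query residue a *designed* propensity:

* pocket residues draw their per-triplet binding fraction from
  ``pocket_bind_range`` (default 0.32-0.92, lower bound enforced by
  rounding up),
* background residues from ``background_bind_range`` (default 0.00-0.28,
  enforced by rounding down),
* one pocket residue and one background residue are pinned exactly to the
  band edges (0.32 and 0.28), so the generative decision boundary sits
  sharply at the planted cutoff of 0.30,
* optionally, one spatially isolated background residue per chain (a
  *decoy*) is given a high fraction, creating a false positive that only
  the spatial clustering filter can remove; the counts of the surrounding
  triplets are inflated so the decoy's sequence neighbours stay below the
  boundary.

Amino-acid types within a chain are all distinct (chains of at most 20
residues), so every triplet has a unique composition and matches only its
own noisy copies; across chains, same-composition triplet pairs are
verified at generation time to be farther than the RMSD threshold.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .library_builder import QualityPolicy, ResidueLibrary, define_binding_pocket
from .motif_matcher import MotifTriplet, ParamConfig, enumerate_triplets, kabsch_rmsd
from .structure_model import (STANDARD_AA, AtomRec, LigandRecord,
                              ResidueRecord, StructureRecord,
                              ensure_representations, write_pdb)

PLANTED_CUTOFF = 0.30          # generative decision boundary on Pr
_POCKET_EDGE = 0.32            # pinned lower edge of the pocket Pr band
_BACKGROUND_EDGE = 0.28        # pinned upper edge of the background Pr band
_DECOY_FRACTION = 0.50
_DECOY_MIN_SEPARATION = 12.0   # Å, CA distance from any other designed positive


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cohort; a fixed seed gives byte-identical
    output."""

    n_chains: int = 6
    residues_per_chain: int = 20
    n_planted_binding_motifs: int = 3    # pocket length = motifs + 2 residues
    noise_sigma: float = 0.1             # Å, per-coordinate noise on library copies
    seed: int = 0
    ligand_heavy_atoms: int = 20
    pocket_start: int = 4                # 0-based index of the first pocket residue
    copies_per_triplet: int = 25
    pocket_bind_range: tuple[float, float] = (_POCKET_EDGE, 0.92)
    background_bind_range: tuple[float, float] = (0.0, _BACKGROUND_EDGE)
    n_decoys_per_chain: int = 1

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise GeometryError("noise sigma must be >= 0")
        if self.residues_per_chain > len(STANDARD_AA):
            raise GeometryError("chains longer than 20 residues would repeat "
                                "amino-acid types; keep <= 20")
        pocket_len = self.n_planted_binding_motifs + 2
        if self.pocket_start + pocket_len + 6 > self.residues_per_chain:
            raise GeometryError("pocket does not leave enough background residues")

    @property
    def pocket_indices(self) -> range:
        return range(self.pocket_start,
                     self.pocket_start + self.n_planted_binding_motifs + 2)


# --------------------------------------------------------------------------
# Chain geometry
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _walk(rng: np.random.Generator, n: int) -> np.ndarray:
    """Gently curving 3.8 Å-step walk: extended enough that chain ends are
    far from the middle, curved enough that triplet geometries vary."""
    direction = _unit(rng.normal(size=3))
    pos = np.zeros(3)
    cas = [pos.copy()]
    for _ in range(n - 1):
        axis = rng.normal(size=3)
        axis -= axis.dot(direction) * direction
        axis = _unit(axis)
        angle = math.radians(rng.uniform(6.0, 18.0))
        direction = _unit(direction * math.cos(angle) + axis * math.sin(angle))
        pos = pos + 3.8 * direction
        cas.append(pos.copy())
    return np.array(cas)


def _build_residues(rng: np.random.Generator, spec: FixtureSpec, chain_id: str
                    ) -> list[ResidueRecord]:
    n = spec.residues_per_chain
    cas = _walk(rng, n)

    types = list(rng.permutation(STANDARD_AA)[:n])
    # glycine has no CB: keep it out of the pocket (pocket anchors use CB)
    if "GLY" in types:
        gi = types.index("GLY")
        if gi in spec.pocket_indices:
            for j in range(n):
                if j not in spec.pocket_indices and types[j] != "GLY":
                    types[gi], types[j] = types[j], types[gi]
                    break

    # parallel-transported local frames along the walk
    residues: list[ResidueRecord] = []
    u_prev: np.ndarray | None = None
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        t = _unit(cas[hi] - cas[lo])
        if u_prev is None:
            ref = np.array([0.0, 0.0, 1.0])
            if abs(ref.dot(t)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            u = _unit(ref - ref.dot(t) * t)
        else:
            u = _unit(u_prev - u_prev.dot(t) * t)
        u_prev = u
        v = np.cross(t, u)
        ca = cas[i]
        atoms = [
            AtomRec("N", "N", ca - 1.20 * t + 0.80 * u),
            AtomRec("CA", "C", ca),
            AtomRec("C", "C", ca + 1.20 * t + 0.80 * u),
            AtomRec("O", "O", ca + 1.40 * t + 1.95 * u),
        ]
        if types[i] != "GLY":
            atoms.append(AtomRec("CB", "C", ca - 0.62 * u + 1.41 * v))
        residues.append(ResidueRecord(chain_id=chain_id, seq_num=i + 1,
                                      insertion_code="", aa_type=types[i],
                                      atoms=atoms))
    return residues


def _place_ligand(residues: list[ResidueRecord], spec: FixtureSpec,
                  chain_id: str) -> LigandRecord:
    pocket = list(spec.pocket_indices)
    anchors = []
    for i in pocket:
        res = residues[i]
        cb = res.atom("CB")
        if cb is None:
            raise GeometryError("pocket residue lacks CB")
        w = _unit(cb.coords - res.ca)
        anchors.append(cb.coords + 2.0 * w)
    centroid = np.mean(anchors, axis=0)
    mean_w = _unit(np.mean([_unit(a - residues[i].ca)
                            for a, i in zip(anchors, pocket)], axis=0))
    extra = max(0, spec.ligand_heavy_atoms - len(anchors))
    pts = anchors[:spec.ligand_heavy_atoms] + [
        centroid + mean_w * (2.2 + 1.4 * j) for j in range(extra)]
    atoms = [AtomRec(f"C{k + 1}", "C", p) for k, p in enumerate(pts)]
    return LigandRecord(het_code="LIG", atoms=atoms, chain_id="X", seq_num=901)


def _verify_pocket(struct: StructureRecord, chain_id: str, spec: FixtureSpec) -> bool:
    pocket = define_binding_pocket(struct, struct.ligands[0],
                                   QualityPolicy(min_binding_residues=1))
    designated = {(chain_id, i + 1, "") for i in spec.pocket_indices}
    if pocket != designated:
        return False
    # a clean margin on the negative side keeps the fixture insensitive to
    # coordinate rounding in PDB text
    lig = struct.ligands[0].heavy_coords()
    for res in struct.chains[chain_id]:
        if res.key in designated:
            continue
        d = np.min(np.linalg.norm(
            res.heavy_coords()[:, None, :] - lig[None, :, :], axis=2))
        if d < 3.6:
            return False
    return True


def _synthesize_structure(rng: np.random.Generator, spec: FixtureSpec,
                          chain_id: str) -> StructureRecord:
    for _ in range(40):
        residues = _build_residues(rng, spec, chain_id)
        ligand = _place_ligand(residues, spec, chain_id)
        struct = StructureRecord(pdb_id=f"syn{spec.seed}{chain_id.lower()}",
                                 chains={chain_id: residues}, ligands=[ligand],
                                 resolution=1.80, r_factor=0.180)
        if _verify_pocket(struct, chain_id, spec):
            return struct
    raise GeometryError("could not realize the requested pocket geometry")


def make_structure(spec: FixtureSpec, chain_id: str = "A") -> str:
    """One synthetic complex as fixed-column PDB text (deterministic in the
    seed)."""
    rng = np.random.default_rng([spec.seed, ord(chain_id)])
    return write_pdb(_synthesize_structure(rng, spec, chain_id))


# --------------------------------------------------------------------------
# Planted library cohorts
# --------------------------------------------------------------------------

@dataclass
class PlantedCohort:
    """A cohort of query structures plus the library planted around them."""

    spec: FixtureSpec
    cfg: ParamConfig
    structures: list[StructureRecord]
    query_residues: dict[str, list[ResidueRecord]]
    library: ResidueLibrary
    truth: dict[str, set[tuple[str, int, str]]]
    decoys: dict[str, set[tuple[str, int, str]]]
    expected_pr: dict[str, dict[tuple[str, int, str], float]]
    planted_cutoff: float = PLANTED_CUTOFF

    @property
    def chain_ids(self) -> list[str]:
        return list(self.query_residues)


def _classify_triplets(triplets: list[MotifTriplet], pocket_keys: set
                       ) -> tuple[list[int], list[int]]:
    pure_pocket, pure_bg = [], []
    for idx, t in enumerate(triplets):
        inside = sum(1 for r in t.residues if r.key in pocket_keys)
        if inside == 3:
            pure_pocket.append(idx)
        elif inside == 0:
            pure_bg.append(idx)
    return pure_pocket, pure_bg


def _pick_decoy(residues, triplets, pure_bg: list[int], pocket_keys: set
                ) -> tuple[int, list[int]] | None:
    """The last chain residue, if isolated and covered by pure triplets."""
    bg_sets = [set(triplets[i].keys) for i in pure_bg]
    pocket_cas = np.array([r.ca for r in residues if r.key in pocket_keys])
    for cand in (len(residues) - 1, 0):
        res = residues[cand]
        if res.key in pocket_keys:
            continue
        if np.min(np.linalg.norm(pocket_cas - res.ca, axis=1)) < _DECOY_MIN_SEPARATION:
            continue
        own = [i for i, s in zip(pure_bg, bg_sets) if res.key in s]
        if not own:
            continue
        # every triplet-mate must keep at least one dilution triplet
        mates = {k for i in own for k in triplets[i].keys} - {res.key}
        ok = all(any(m in s and res.key not in s for i, s in zip(pure_bg, bg_sets))
                 for m in mates)
        if ok:
            return cand, own
    return None


def _copy_triplet(rng: np.random.Generator, t: MotifTriplet, sigma: float,
                  rmsd_max: float, chain_key: str) -> list[ResidueRecord]:
    """A rigidly moved, noise-perturbed copy of a triplet as a 3-residue
    chain."""
    centroid = t.coords.mean(axis=0)
    for _ in range(20):
        rot = _random_rotation(rng)
        shift = rng.uniform(-200.0, 200.0, size=3)
        copies: list[ResidueRecord] = []
        offset = 0
        for k, res in enumerate(t.residues):
            n_atoms = t.splits[k]
            block = t.coords[offset:offset + n_atoms]
            offset += n_atoms
            moved = (block - centroid) @ rot.T + shift
            moved = moved + rng.normal(0.0, sigma, size=moved.shape)
            names = [a.name for a in res.atoms if a.name in
                     {"N", "CA", "C", "CB"}][:n_atoms]
            if len(names) != n_atoms:  # fall back to scheme order
                names = ["N", "CA", "C", "CB"][:n_atoms]
            atoms = [AtomRec(nm, nm[0], c) for nm, c in zip(names, moved)]
            copies.append(ResidueRecord(chain_id=chain_key, seq_num=k + 1,
                                        insertion_code="", aa_type=res.aa_type,
                                        atoms=atoms, rep_coords=moved))
        if sigma > rmsd_max / 3:
            return copies
        concat = np.concatenate([c.rep_coords for c in copies])
        if kabsch_rmsd(concat, t.coords) < rmsd_max:
            return copies
    raise GeometryError("noise resampling failed to stay under the RMSD cutoff")


def _min_pairing_rmsd(a: MotifTriplet, b: MotifTriplet) -> float:
    from .motif_matcher import _consistent_orders
    best = np.inf
    for order in _consistent_orders(a.aa_types, b.aa_types):
        best = min(best, kabsch_rmsd(a.coords, b.coords_in_order(order)))
    return best


def _geometrically_separated(new_triplets, old_triplets, margin: float) -> bool:
    by_key: dict[tuple, list[MotifTriplet]] = {}
    for t in old_triplets:
        by_key.setdefault(t.aa_key, []).append(t)
    for t in new_triplets:
        for other in by_key.get(t.aa_key, ()):
            if _min_pairing_rmsd(t, other) < margin:
                return False
    return True


def make_planted_library(spec: FixtureSpec, cfg: ParamConfig = ParamConfig()
                         ) -> PlantedCohort:
    """Build a cohort of queries and the motif library planted around them.

    Every pure (non-boundary) query triplet receives ``copies_per_triplet``
    rigid noisy copies in the library, split between the binding and
    non-binding labels according to the designed per-triplet fraction, so
    the realized per-residue propensities equal the designed ones whenever
    the noise stays below the RMSD threshold.
    """
    chain_ids = list(string.ascii_uppercase[:spec.n_chains])
    structures: list[StructureRecord] = []
    query_residues: dict[str, list[ResidueRecord]] = {}
    truth: dict[str, set] = {}
    decoys: dict[str, set] = {}
    expected: dict[str, dict] = {}
    library = ResidueLibrary()
    all_prev_triplets: list[MotifTriplet] = []
    copy_serial = 0

    for ci, chain_id in enumerate(chain_ids):
        planted = None
        for attempt in range(60):
            rng = np.random.default_rng([spec.seed, ci, attempt])
            try:
                struct = _synthesize_structure(rng, spec, chain_id)
            except GeometryError:
                continue
            residues = struct.chains[chain_id]
            complete, _ = ensure_representations(residues, cfg.representation)
            triplets = enumerate_triplets(complete, cfg)
            pocket_keys = {(chain_id, i + 1, "") for i in spec.pocket_indices}
            pure_pocket, pure_bg = _classify_triplets(triplets, pocket_keys)
            if not pure_pocket or len(pure_bg) < 6:
                continue

            decoy_pick = None
            if spec.n_decoys_per_chain > 0:
                decoy_pick = _pick_decoy(residues, triplets, pure_bg, pocket_keys)
                if decoy_pick is None:
                    continue

            counts = _assign_counts(rng, spec, residues, triplets,
                                    pure_pocket, pure_bg, pocket_keys, decoy_pick)
            if counts is None:
                continue
            if not _geometrically_separated(
                    [triplets[i] for i in sorted(counts)], all_prev_triplets,
                    cfg.rmsd_max + 3 * spec.noise_sigma + 0.1):
                continue
            planted = (struct, residues, triplets, counts, decoy_pick, pocket_keys, rng)
            break
        if planted is None:
            raise GeometryError(f"chain {chain_id}: no admissible planted geometry")

        struct, residues, triplets, counts, decoy_pick, pocket_keys, rng = planted
        structures.append(struct)
        query_residues[chain_id] = residues
        truth[chain_id] = pocket_keys
        decoys[chain_id] = ({residues[decoy_pick[0]].key} if decoy_pick else set())

        per_res_b: dict[tuple, int] = {}
        per_res_t: dict[tuple, int] = {}
        for ti, (n_tot, n_bind) in counts.items():
            t = triplets[ti]
            for r in t.residues:
                per_res_b[r.key] = per_res_b.get(r.key, 0) + n_bind
                per_res_t[r.key] = per_res_t.get(r.key, 0) + n_tot
            for j in range(n_tot):
                chain_key = f"L{copy_serial}"
                copy_serial += 1
                copies = _copy_triplet(rng, t, spec.noise_sigma, cfg.rmsd_max,
                                       chain_key)
                label = j < n_bind
                for c in copies:
                    c.is_binding = label
                library.add_chain(chain_key, chain_key, copies)
        expected[chain_id] = {
            r.key: (per_res_b.get(r.key, 0) / per_res_t[r.key]
                    if per_res_t.get(r.key) else 0.0)
            for r in residues}
        all_prev_triplets.extend(triplets[i] for i in sorted(counts))

    return PlantedCohort(spec=spec, cfg=cfg, structures=structures,
                         query_residues=query_residues, library=library,
                         truth=truth, decoys=decoys, expected_pr=expected)


def _assign_counts(rng, spec: FixtureSpec, residues, triplets,
                   pure_pocket: list[int], pure_bg: list[int],
                   pocket_keys: set, decoy_pick) -> dict[int, tuple[int, int]] | None:
    """Per-triplet (total copies, binding copies); None if the designed Pr
    bands cannot be realized on this geometry."""
    m = spec.copies_per_triplet
    counts: dict[int, tuple[int, int]] = {}

    decoy_key = None
    decoy_triplets: set[int] = set()
    dilution: set[int] = set()
    if decoy_pick is not None:
        decoy_idx, own = decoy_pick
        decoy_key = residues[decoy_idx].key
        decoy_triplets = set(own)
        mates = {k for i in own for k in triplets[i].keys} - {decoy_key}
        dilution = {i for i in pure_bg
                    if i not in decoy_triplets
                    and mates & set(triplets[i].keys)}

    # a background residue pinned at the band edge, away from the decoy zone
    margin_res = None
    protected = decoy_triplets | dilution
    bg_sets = {i: set(triplets[i].keys) for i in pure_bg}
    for res in residues:
        if res.key in pocket_keys or res.key == decoy_key:
            continue
        own_all = [i for i, t in enumerate(triplets) if res.key in t.keys]
        if not own_all or any(i not in bg_sets for i in own_all):
            continue
        if any(i in protected for i in own_all):
            continue
        margin_res = res.key
        margin_triplets = set(own_all)
        break
    if margin_res is None:
        return None

    # pin one edge-of-pocket residue exactly to the band edge: the first
    # pocket residue sits in a single pure pocket triplet on an extended
    # chain, so pinning its triplet pins its Pr
    edge_key = residues[spec.pocket_start].key
    edge_triplets = [i for i in pure_pocket if edge_key in triplets[i].keys]

    for i in pure_pocket:
        if i in edge_triplets:
            counts[i] = (m, int(round(_POCKET_EDGE * m)))
        else:
            f = rng.uniform(*spec.pocket_bind_range)
            counts[i] = (m, math.ceil(f * m - 1e-9))
    for i in pure_bg:
        if i in decoy_triplets:
            counts[i] = (m, int(round(_DECOY_FRACTION * m)))
        elif i in dilution:
            counts[i] = (8 * m, math.floor(0.04 * 8 * m + 1e-9))
        elif i in margin_triplets:
            counts[i] = (m, math.floor(_BACKGROUND_EDGE * m + 1e-9))
        else:
            f = rng.uniform(*spec.background_bind_range)
            counts[i] = (m, math.floor(f * m + 1e-9))

    # verify the designed bands
    per_b: dict[tuple, int] = {}
    per_t: dict[tuple, int] = {}
    for i, (n_tot, n_bind) in counts.items():
        for r in triplets[i].residues:
            per_b[r.key] = per_b.get(r.key, 0) + n_bind
            per_t[r.key] = per_t.get(r.key, 0) + n_tot
    for res in residues:
        tot = per_t.get(res.key, 0)
        pr = per_b.get(res.key, 0) / tot if tot else 0.0
        if res.key in pocket_keys:
            if pr < _POCKET_EDGE - 1e-9:
                return None
        elif res.key == decoy_key:
            if pr < _POCKET_EDGE:
                return None
        elif pr > _BACKGROUND_EDGE + 1e-9:
            return None
    return counts


# --------------------------------------------------------------------------
# Composition-vs-geometry contrast cohort
# --------------------------------------------------------------------------

def make_composition_contrast(spec: FixtureSpec, cfg: ParamConfig = ParamConfig()
                              ) -> PlantedCohort:
    """A cohort where composition carries no signal but geometry carries all.

    Every pure query triplet contributes two library populations of equal
    size and identical amino-acid composition: geometry-matched noisy copies
    carrying the triplet's true label, and geometrically displaced copies
    (verified beyond the RMSD threshold) carrying the opposite label.  The
    composition-only potential is exactly 1/2 for every observed
    composition, while geometric matching still separates pocket from
    background perfectly.
    """
    n_per_side = 10
    chain_ids = list(string.ascii_uppercase[:spec.n_chains])
    structures, query_residues, truth = [], {}, {}
    library = ResidueLibrary()
    all_prev: list[MotifTriplet] = []
    serial = 0

    for ci, chain_id in enumerate(chain_ids):
        chosen = None
        for attempt in range(60):
            rng = np.random.default_rng([spec.seed, 7000 + ci, attempt])
            try:
                struct = _synthesize_structure(rng, spec, chain_id)
            except GeometryError:
                continue
            residues = struct.chains[chain_id]
            complete, _ = ensure_representations(residues, cfg.representation)
            triplets = enumerate_triplets(complete, cfg)
            pocket_keys = {(chain_id, i + 1, "") for i in spec.pocket_indices}
            pure_pocket, pure_bg = _classify_triplets(triplets, pocket_keys)
            if not pure_pocket or not pure_bg:
                continue
            if not _geometrically_separated(
                    [triplets[i] for i in pure_pocket + pure_bg], all_prev,
                    cfg.rmsd_max + 3 * spec.noise_sigma + 0.1):
                continue
            chosen = (struct, residues, triplets, pure_pocket, pure_bg,
                      pocket_keys, rng)
            break
        if chosen is None:
            raise GeometryError(f"chain {chain_id}: no admissible geometry")
        struct, residues, triplets, pure_pocket, pure_bg, pocket_keys, rng = chosen

        structures.append(struct)
        query_residues[chain_id] = residues
        truth[chain_id] = pocket_keys

        for ti in pure_pocket + pure_bg:
            t = triplets[ti]
            true_label = ti in pure_pocket
            for j in range(n_per_side):
                key = f"C{serial}"
                serial += 1
                copies = _copy_triplet(rng, t, spec.noise_sigma, cfg.rmsd_max, key)
                for c in copies:
                    c.is_binding = true_label
                library.add_chain(key, key, copies)
            far = _displaced_triplet(rng, t, cfg)
            for j in range(n_per_side):
                key = f"C{serial}"
                serial += 1
                copies = _copy_triplet(rng, far, spec.noise_sigma, cfg.rmsd_max, key)
                for c in copies:
                    c.is_binding = not true_label
                library.add_chain(key, key, copies)
            all_prev.extend([t, far])

    return PlantedCohort(spec=spec, cfg=cfg, structures=structures,
                         query_residues=query_residues, library=library,
                         truth=truth, decoys={c: set() for c in chain_ids},
                         expected_pr={}, planted_cutoff=0.5)


def _displaced_triplet(rng: np.random.Generator, t: MotifTriplet,
                       cfg: ParamConfig) -> MotifTriplet:
    """Same composition, clearly different geometry, still a connected
    motif."""
    from .motif_matcher import make_triplet
    for _ in range(40):
        shift_dir = _unit(rng.normal(size=3))
        moved_res: list[ResidueRecord] = []
        for k, res in enumerate(t.residues):
            delta = shift_dir * 3.0 if k == 1 else np.zeros(3)
            atoms = [AtomRec(a.name, a.element, a.coords + delta) for a in res.atoms]
            moved_res.append(ResidueRecord(chain_id=res.chain_id,
                                           seq_num=res.seq_num,
                                           insertion_code=res.insertion_code,
                                           aa_type=res.aa_type, atoms=atoms))
        complete, _ = ensure_representations(moved_res, cfg.representation)
        if len(complete) != 3:
            continue
        far = make_triplet(tuple(complete))  # type: ignore[arg-type]
        cas = np.array([r.ca for r in far.residues])
        d01 = np.linalg.norm(cas[0] - cas[1])
        d12 = np.linalg.norm(cas[1] - cas[2])
        connected = sum(d < cfg.neighbor_max for d in
                        (d01, d12, np.linalg.norm(cas[0] - cas[2]))) >= 2
        if connected and _min_pairing_rmsd(far, t) > cfg.rmsd_max + 0.3:
            return far
    raise GeometryError("could not displace triplet beyond the RMSD cutoff")
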