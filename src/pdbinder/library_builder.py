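"""Build the libraries of binding and non-binding residues.

A collection of protein-ligand complexes is reduced to a non-redundant set
of chains through a fixed filter pipeline — structure quality, ligand size
and identity, pocket size, one representative chain per homology cluster —
and every standard residue of the surviving chains is labelled *binding*
(some heavy atom closer than the pocket distance to a heavy atom of a
retained ligand of its chain) or *non-binding* (everything else).

The homology clustering itself is an input (a two-column TSV mapping
``pdbid_chain`` to a cluster identifier), mirroring the use of
externally provided sequence clusters.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, EmptyLibraryError, InvalidLigandError
from .structure_model import LigandRecord, ResidueRecord, StructureRecord

# Elements counted as metals for the bare-metal-ion exclusion.
_METALS = frozenset({
    "LI", "BE", "NA", "MG", "AL", "K", "CA", "SC", "TI", "V", "CR", "MN",
    "FE", "CO", "NI", "CU", "ZN", "GA", "RB", "SR", "Y", "ZR", "NB", "MO",
    "TC", "RU", "RH", "PD", "AG", "CD", "IN", "SN", "CS", "BA", "LA", "CE",
    "PR", "ND", "SM", "EU", "GD", "TB", "DY", "HO", "ER", "TM", "YB", "LU",
    "HF", "TA", "W", "RE", "OS", "IR", "PT", "AU", "HG", "TL", "PB", "BI",
})


def default_excluded_het_codes() -> frozenset[str]:
    """Codes from the packaged buffer/solvent list (user-editable text file)."""
    text = resources.files("pdbinder").joinpath("data/excluded_het_codes.txt").read_text()
    codes = {ln.strip().upper() for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")}
    return frozenset(codes)


@dataclass(frozen=True)
class LigandFilterPolicy:
    """Which hetero groups count as biologically relevant ligands.

    Heavy-atom bounds are inclusive on both sides: the defaults keep ligands
    with 10 to 60 heavy atoms, excluding metal ions and very small molecules
    below and very large ligands above.
    """

    min_heavy: int = 10
    max_heavy: int = 60
    excluded_het_codes: frozenset[str] = field(default_factory=default_excluded_het_codes)
    exclude_metals: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_heavy <= self.max_heavy):
            raise ConfigurationError("need 1 <= min_heavy <= max_heavy")


@dataclass(frozen=True)
class QualityPolicy:
    """Structure-quality and pocket-definition parameters.

    ``pocket_distance`` is the strict upper bound (Å) on the heavy-atom
    distance between a pocket residue and the ligand; resolution and
    R-factor bounds are inclusive.
    """

    max_resolution: float = 2.0
    max_r_factor: float = 0.20
    min_binding_residues: int = 10
    pocket_distance: float = 3.5

    def __post_init__(self) -> None:
        for name in ("max_resolution", "max_r_factor", "min_binding_residues", "pocket_distance"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


class HomologyGroups:
    """Mapping from chain identifier (``pdbid_chain``) to homology cluster id."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    def cluster_of(self, chain_key: str) -> str:
        try:
            return self.mapping[chain_key]
        except KeyError:
            raise ConfigurationError(f"chain {chain_key!r} has no homology cluster") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologyGroups":
        mapping: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                mapping[row[0]] = row[1]
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for k, v in self.mapping.items():
                w.writerow([k, v])


# --------------------------------------------------------------------------
# Individual filter operations
# --------------------------------------------------------------------------

def is_metal_ion(lig: LigandRecord) -> bool:
    heavy = [a for a in lig.atoms if not a.is_hydrogen]
    return len(heavy) == 1 and heavy[0].element.upper() in _METALS


def filter_ligands(struct: StructureRecord, policy: LigandFilterPolicy) -> list[LigandRecord]:
    """Ligands of ``struct`` passing the size/identity filter."""
    kept = []
    for lig in struct.ligands:
        if lig.het_code.upper() in policy.excluded_het_codes:
            continue
        if policy.exclude_metals and is_metal_ion(lig):
            continue
        if policy.min_heavy <= lig.heavy_atom_count <= policy.max_heavy:
            kept.append(lig)
    return kept


def define_binding_pocket(struct: StructureRecord, lig: LigandRecord,
                          policy: QualityPolicy) -> set[tuple[str, int, str]]:
    """Residue keys with a heavy atom strictly closer than ``pocket_distance``
    to any heavy atom of ``lig``."""
    lig_coords = lig.heavy_coords()
    if len(lig_coords) == 0:
        raise InvalidLigandError(f"ligand {lig.het_code} has no heavy atoms")
    tree = cKDTree(lig_coords)
    pocket: set[tuple[str, int, str]] = set()
    for res in struct.iter_residues():
        coords = res.heavy_coords()
        if len(coords) == 0:
            continue
        d, _ = tree.query(coords, k=1)
        if float(np.min(d)) < policy.pocket_distance:
            pocket.add(res.key)
    return pocket


def select_representatives(chains: list[tuple[str, int]], groups: HomologyGroups) -> list[str]:
    """One chain per homology cluster: the one with the most pocket residues.

    ``chains`` is a list of ``(chain_key, pocket_residue_count)``.  Ties are
    broken by the lexicographically smallest chain key.
    """
    best: dict[str, tuple[int, str]] = {}
    for chain_key, count in chains:
        cluster = groups.cluster_of(chain_key)
        cand = (-count, chain_key)
        if cluster not in best or cand < best[cluster]:
            best[cluster] = cand
    return sorted(key for _, key in best.values())


# --------------------------------------------------------------------------
# The residue library
# --------------------------------------------------------------------------

@dataclass
class ResidueLibrary:
    """Labelled residues with per-residue provenance.

    ``residues[i]`` belongs to library chain ``source_chain[i]`` (a
    ``pdbid_chain`` key) in homology cluster ``source_cluster[i]``; its
    ``is_binding`` flag is always set.  Motif triplets are always enumerated
    within a single source chain.
    """

    residues: list[ResidueRecord] = field(default_factory=list)
    source_chain: list[str] = field(default_factory=list)
    source_cluster: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._triplet_cache: dict[tuple, list] = {}

    def add_chain(self, chain_key: str, cluster: str, residues: list[ResidueRecord]) -> None:
        for res in residues:
            if res.is_binding is None:
                raise ConfigurationError(f"library residue {res.key} has no binding label")
            self.residues.append(res)
            self.source_chain.append(chain_key)
            self.source_cluster.append(cluster)
        self._triplet_cache.clear()

    def chains(self) -> dict[str, tuple[str, list[ResidueRecord]]]:
        """chain_key -> (cluster_id, residues), preserving insertion order."""
        out: dict[str, tuple[str, list[ResidueRecord]]] = {}
        for res, ck, cl in zip(self.residues, self.source_chain, self.source_cluster):
            if ck not in out:
                out[ck] = (cl, [])
            out[ck][1].append(res)
        return out

    @property
    def n_binding(self) -> int:
        return sum(1 for r in self.residues if r.is_binding)

    @property
    def n_nonbinding(self) -> int:
        return sum(1 for r in self.residues if r.is_binding is False)

    def __len__(self) -> int:
        return len(self.residues)

    # -- serialization -----------------------------------------------------

    HEADER = ["source_pdb", "chain", "seq_num", "icode", "aa_type",
              "is_binding", "cluster_id", "rep_coords"]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(self.HEADER)
            for res, ck, cl in zip(self.residues, self.source_chain, self.source_cluster):
                coords = res.rep_coords
                if coords is None:
                    coords = np.empty((0, 3))
                packed = ";".join(",".join(f"{x:.3f}" for x in row) for row in coords)
                pdb_id, _, chain = ck.rpartition("_")
                w.writerow([pdb_id, chain or res.chain_id, res.seq_num,
                            res.insertion_code, res.aa_type,
                            int(bool(res.is_binding)), cl, packed])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueLibrary":
        lib = cls()
        by_chain: dict[str, tuple[str, list[ResidueRecord]]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header != cls.HEADER:
                raise ConfigurationError(f"unexpected library header in {path}")
            for row in reader:
                pdb_id, chain, seq_num, icode, aa, binding, cluster, packed = row
                coords = np.array([[float(x) for x in p.split(",")]
                                   for p in packed.split(";") if p]) if packed else None
                # rebuild atoms from the representative coordinates under the
                # default scheme so CA lookup and re-representation work
                atoms = []
                if coords is not None:
                    from .structure_model import DEFAULT_SCHEME, AtomRec
                    names = DEFAULT_SCHEME.atoms_for(aa)
                    if len(names) == len(coords):
                        atoms = [AtomRec(name=n, element=n[0], coords=c)
                                 for n, c in zip(names, coords)]
                res = ResidueRecord(chain_id=chain, seq_num=int(seq_num),
                                    insertion_code=icode, aa_type=aa, atoms=atoms,
                                    rep_coords=coords,
                                    is_binding=bool(int(binding)))
                key = f"{pdb_id}_{chain}" if pdb_id else chain
                by_chain.setdefault(key, (cluster, []))[1].append(res)
        for key, (cluster, residues) in by_chain.items():
            lib.add_chain(key, cluster, residues)
        return lib


@dataclass
class BuildLog:
    """Chain/ligand counts surviving each pipeline stage."""

    n_structures: int = 0
    n_quality_pass: int = 0
    n_ligands_total: int = 0
    n_ligands_kept: int = 0
    chains_with_ligand: int = 0
    chains_min_pocket: int = 0
    chains_representative: int = 0
    incomplete_residues: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def build_library(structs: list[StructureRecord], qpolicy: QualityPolicy,
                  lpolicy: LigandFilterPolicy, groups: HomologyGroups,
                  ) -> tuple[ResidueLibrary, BuildLog]:
    """Run the full filter pipeline and emit the labelled residue library.

    Pipeline order: quality filter -> ligand filter -> pocket definition ->
    minimum-pocket-size filter -> representative selection -> labelling.
    A residue is *binding* if it is in the pocket of any retained ligand of
    its own chain; structures without resolution or R-factor headers fail
    the quality filter.
    """
    log = BuildLog(n_structures=len(structs))

    candidate: dict[str, tuple[StructureRecord, str, set]] = {}
    for st in structs:
        log.n_ligands_total += len(st.ligands)
        if st.resolution is None or st.r_factor is None:
            continue
        if st.resolution > qpolicy.max_resolution or st.r_factor > qpolicy.max_r_factor:
            continue
        log.n_quality_pass += 1
        ligands = filter_ligands(st, lpolicy)
        log.n_ligands_kept += len(ligands)
        if not ligands:
            continue
        pocket_all: set = set()
        for lig in ligands:
            pocket_all |= define_binding_pocket(st, lig, qpolicy)
        for chain_id, residues in st.chains.items():
            chain_keys = {r.key for r in residues}
            pocket = pocket_all & chain_keys
            if pocket:
                log.chains_with_ligand += 1
            if len(pocket) >= qpolicy.min_binding_residues:
                log.chains_min_pocket += 1
                candidate[f"{st.pdb_id}_{chain_id}"] = (st, chain_id, pocket)

    reps = select_representatives(
        [(key, len(p)) for key, (_, _, p) in candidate.items()], groups)
    log.chains_representative = len(reps)

    lib = ResidueLibrary()
    for key in reps:
        st, chain_id, pocket = candidate[key]
        residues = st.chains[chain_id]
        for res in residues:
            res.is_binding = res.key in pocket
        lib.add_chain(key, groups.cluster_of(key), residues)

    if len(lib) == 0:
        raise EmptyLibraryError(
            "no chain survived the filter pipeline; see the build log")
    return lib, log
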