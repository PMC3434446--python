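"""In-memory model of protein structures read from PDB/mmCIF files.

The model is deliberately minimal: chains of standard amino-acid residues
with their heavy-atom coordinates, plus the non-water hetero groups that are
candidate ligands.  Parsing is delegated to :mod:`gemmi`; this module applies
the policies the rest of the pipeline depends on (first model only, one
conformer per atom, waters never ligands, modified amino acids dropped) and
exposes a flat record structure that is cheap to slice and serialize.

Author residue numbering is preserved; all coordinates are in Angstrom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .errors import EmptyStructureError, IncompleteResidueError

# The 20 standard amino acids, three-letter codes.
STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
_STANDARD_AA_SET = frozenset(STANDARD_AA)

_WATER_CODES = frozenset({"HOH", "DOD", "WAT"})
_HYDROGEN_ELEMENTS = frozenset({"H", "D"})


def is_standard_aa(name: str) -> bool:
    return name.upper() in _STANDARD_AA_SET


@dataclass
class AtomRec:
    """A single atom: name, element symbol, coordinates (Å)."""

    name: str
    element: str
    coords: np.ndarray
    is_hetero: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class ResidueRecord:
    """One standard amino-acid residue of a chain.

    ``rep_coords`` holds the ordered representative-atom coordinates used for
    superposition; it is filled in lazily by :func:`residue_representation`.
    ``is_binding`` stays ``None`` until the library builder labels the residue.
    """

    chain_id: str
    seq_num: int
    insertion_code: str
    aa_type: str
    atoms: list[AtomRec] = field(default_factory=list)
    rep_coords: np.ndarray | None = None
    is_binding: bool | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def atom(self, name: str) -> AtomRec | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray:
        a = self.atom("CA")
        if a is None:
            raise IncompleteResidueError(f"residue {self.key} has no CA atom")
        return a.coords

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if not a.is_hydrogen], dtype=float)

    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain_id}{self.seq_num}{icode}"


@dataclass
class LigandRecord:
    """A non-water hetero group that may qualify as a ligand."""

    het_code: str
    atoms: list[AtomRec]
    chain_id: str = ""
    seq_num: int = 0

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if not a.is_hydrogen)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if not a.is_hydrogen], dtype=float)


@dataclass
class StructureRecord:
    """A parsed structure: ordered chains of residues plus candidate ligands."""

    pdb_id: str
    chains: dict[str, list[ResidueRecord]]
    ligands: list[LigandRecord] = field(default_factory=list)
    resolution: float | None = None
    r_factor: float | None = None

    def iter_residues(self) -> Iterator[ResidueRecord]:
        for residues in self.chains.values():
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())


# --------------------------------------------------------------------------
# Representation schemes
# --------------------------------------------------------------------------

class RepresentationScheme:
    """Which atoms represent a residue in superpositions, in fixed order.

    The default uses the backbone plus the side-chain direction,
    ``{N, CA, C, CB}`` (``{N, CA, C}`` for glycine): these atoms exist in
    nearly every residue and make identical-type pairing well defined.
    """

    def __init__(self, default_atoms: tuple[str, ...] = ("N", "CA", "C", "CB"),
                 overrides: dict[str, tuple[str, ...]] | None = None) -> None:
        self.default_atoms = tuple(default_atoms)
        self.overrides = dict(overrides or {"GLY": ("N", "CA", "C")})

    def atoms_for(self, aa_type: str) -> tuple[str, ...]:
        return self.overrides.get(aa_type.upper(), self.default_atoms)

    def size_for(self, aa_type: str) -> int:
        return len(self.atoms_for(aa_type))

    def cache_key(self) -> tuple:
        return (self.default_atoms, tuple(sorted(self.overrides.items())))


DEFAULT_SCHEME = RepresentationScheme()


def residue_representation(res: ResidueRecord, scheme: RepresentationScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Ordered representative coordinates of ``res`` under ``scheme``.

    Raises :class:`IncompleteResidueError` if a required atom is missing; the
    caller is expected to exclude such residues from matching.
    """
    coords = []
    for name in scheme.atoms_for(res.aa_type):
        a = res.atom(name)
        if a is None:
            raise IncompleteResidueError(
                f"residue {res.key} ({res.aa_type}) lacks required atom {name}")
        coords.append(a.coords)
    return np.array(coords, dtype=float)


def ensure_representations(residues: Iterable[ResidueRecord],
                           scheme: RepresentationScheme = DEFAULT_SCHEME,
                           ) -> tuple[list[ResidueRecord], list[ResidueRecord]]:
    """Fill ``rep_coords`` for every residue; return (complete, incomplete)."""
    complete: list[ResidueRecord] = []
    incomplete: list[ResidueRecord] = []
    for res in residues:
        try:
            res.rep_coords = residue_representation(res, scheme)
            complete.append(res)
        except IncompleteResidueError:
            incomplete.append(res)
    return complete, incomplete


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

_RFACTOR_RE = re.compile(
    r"REMARK\s+3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # Highest occupancy wins; ties broken by altloc character order.
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def _is_modified_aa(res: gemmi.Residue) -> bool:
    # HETATM group with a peptide backbone => chemically modified amino acid.
    names = {a.name for a in res}
    return {"N", "CA", "C"}.issubset(names)


def parse_pdb(path: str | Path, model_policy: str = "first_model") -> StructureRecord:
    """Parse a PDB (or mmCIF) file into a :class:`StructureRecord`.

    Policies applied: only the first model is kept; for alternate locations
    the highest-occupancy conformer is retained (ties by altloc character);
    waters are never ligands; modified amino acids (HETATM groups with a
    peptide backbone) are dropped entirely.
    """
    if model_policy != "first_model":
        raise ValueError(f"unknown model policy {model_policy!r}")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read structure from {path}: {exc}") from exc

    r_factor: float | None = None
    if path.suffix.lower() not in {".cif", ".mmcif"}:
        m = _RFACTOR_RE.search(path.read_text(errors="replace"))
        if m:
            r_factor = float(m.group(1))

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate models")
    model = st[0]

    chains: dict[str, list[ResidueRecord]] = {}
    ligands: list[LigandRecord] = []
    for chain in model:
        for res in chain:
            name = res.name.upper()
            # collapse altlocs: group by atom name, keep one conformer each
            by_name: dict[str, list[gemmi.Atom]] = {}
            for a in res:
                by_name.setdefault(a.name, []).append(a)
            picked = [_pick_altloc(v) for v in by_name.values()]
            atoms = [
                AtomRec(
                    name=a.name,
                    element=a.element.name or "X",
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    is_hetero=res.het_flag == "H",
                    altloc=a.altloc or "",
                )
                for a in picked
            ]
            if name in _WATER_CODES:
                continue
            if is_standard_aa(name) and res.het_flag != "H":
                rec = ResidueRecord(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip() or "",
                    aa_type=name,
                    atoms=atoms,
                )
                chains.setdefault(chain.name, []).append(rec)
            elif res.het_flag == "H" and _is_modified_aa(res):
                continue  # modified amino acid: neither residue nor ligand
            else:
                ligands.append(LigandRecord(
                    het_code=name, atoms=atoms,
                    chain_id=chain.name, seq_num=res.seqid.num))

    if not chains:
        raise EmptyStructureError(f"{path}: no standard protein residues")

    return StructureRecord(
        pdb_id=(st.name or path.stem).lower(),
        chains=chains,
        ligands=ligands,
        resolution=resolution,
        r_factor=r_factor,
    )


# --------------------------------------------------------------------------
# Writing (fixed-column PDB)
# --------------------------------------------------------------------------

def _atom_line(serial: int, record: str, atom: AtomRec, res_name: str,
               chain_id: str, seq_num: int, icode: str) -> str:
    name = atom.name
    # PDB atom-name column convention: 1-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.coords
    return (f"{record:<6}{serial:>5} {name:<4}{'':1}{res_name:<3} {chain_id:1}"
            f"{seq_num:>4}{icode or ' ':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{20.00:6.2f}          {atom.element:>2}")


def write_pdb(struct: StructureRecord) -> str:
    """Serialize a :class:`StructureRecord` as fixed-column PDB text."""
    lines: list[str] = []
    if struct.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {struct.resolution:.2f} ANGSTROMS.")
    if struct.r_factor is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : {struct.r_factor:.3f}")
    serial = 1
    for chain_id, residues in struct.chains.items():
        for res in residues:
            for atom in res.atoms:
                lines.append(_atom_line(serial, "ATOM", atom, res.aa_type,
                                        chain_id, res.seq_num, res.insertion_code))
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    for lig in struct.ligands:
        for atom in lig.atoms:
            lines.append(_atom_line(serial, "HETATM", atom, lig.het_code,
                                    lig.chain_id or "X", lig.seq_num or 1, ""))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
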