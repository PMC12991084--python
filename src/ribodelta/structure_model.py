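"""Hierarchical coordinate model and PDB/mmCIF I/O.

The in-memory representation is deliberately small: a :class:`StructureModel`
holds chains, chains hold residues ordered by author numbering, residues hold
atoms. Entity classes (``rna`` / ``protein`` / ``other``) are inferred from
residue vocabulary at parse time, with modified nucleotides normalised to
their parent base for alignment and substitution calling.

Residues are addressed throughout the package by author numbering
``(chain_id, seq_id, icode)`` — the convention structural biologists use when
they write "A1492" — never by sequential label numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Address of a residue in author numbering.
ResidueAddress = tuple[str, int, str]

# Canonical residue vocabularies. DNA names are grouped with RNA: both are
# nucleic acids and the contact categories only distinguish nucleic vs protein.
RNA_NAMES = {"A", "C", "G", "U", "I", "N", "DA", "DC", "DG", "DT", "DU", "DI"}
AA_NAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
ION_NAMES = {"MG", "K", "NA", "ZN", "CL", "CA", "MN", "FE", "CD", "NI", "CO"}

# Modified nucleotides mapped to their parent base identity. Covers the
# modifications commonly modelled in bacterial rRNA.
MODIFIED_NUCLEOTIDES: dict[str, str] = {
    "PSU": "U", "5MU": "U", "4SU": "U", "H2U": "U", "OMU": "U", "UR3": "U",
    "3MU": "U", "70U": "U", "2MA": "A", "1MA": "A", "6MA": "A", "MA6": "A",
    "A2M": "A", "T6A": "A", "MIA": "A", "2MG": "G", "7MG": "G", "M2G": "G",
    "OMG": "G", "1MG": "G", "G7M": "G", "YG": "G", "QUO": "G", "5MC": "C",
    "OMC": "C", "4OC": "C", "M4C": "C", "4AC": "C", "CCC": "C",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


class EmptyModelError(ValueError):
    """Raised when a coordinate file contains no polymer (RNA/protein) chain."""


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class Atom:
    """A single atom: name, element, position (Å), occupancy, B-factor."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    temp_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1]")
        if not self.element:
            raise ValueError(f"atom {self.name} has empty element")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def is_polar(self) -> bool:
        return self.element.upper() in ("N", "O", "S")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    entity_class: str = "other"  # resolved at parse time
    label_seq_id: int | None = None  # mmCIF sequential numbering, metadata only

    @property
    def address(self) -> ResidueAddress:
        return (self.chain_id, self.seq_id, self.icode)

    @property
    def parent_name(self) -> str:
        """Residue name with modified nucleotides mapped to the parent base."""
        return MODIFIED_NUCLEOTIDES.get(self.name, self.name)

    @property
    def one_letter(self) -> str:
        name = self.parent_name
        if name in RNA_NAMES and len(name) <= 2:
            return name[-1]  # DA -> A etc.
        return THREE_TO_ONE.get(name, "X")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    entity_class: str = "other"
    residues: list[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class StructureModel:
    label: str
    chains: list[Chain] = field(default_factory=list)
    source_path: str = ""

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.entity_class in ("rna", "protein")]

    def get_chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def get_residue(self, address: ResidueAddress) -> Residue | None:
        chain = self.get_chain(address[0])
        if chain is None:
            return None
        for r in chain.residues:
            if (r.seq_id, r.icode) == (address[1], address[2]):
                return r
        return None

    def iter_residues(self, polymer_only: bool = True) -> Iterator[Residue]:
        for chain in self.chains:
            if polymer_only and chain.entity_class not in ("rna", "protein"):
                continue
            for res in chain.residues:
                if polymer_only and res.entity_class not in ("rna", "protein"):
                    continue
                yield res

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def _classify_residue_name(name: str) -> str:
    name = name.strip().upper()
    if name in WATER_NAMES or name in ION_NAMES:
        return "other"
    if name in RNA_NAMES or name in MODIFIED_NUCLEOTIDES:
        return "rna"
    if name in AA_NAMES:
        return "protein"
    return "unknown"


def _reduce_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def read_structure(path: str | Path, label: str = "") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is read. Alternate locations are
    reduced to the highest-occupancy conformer (ties broken by altloc label).
    Hydrogens are retained (they are excluded later, at contact time). Each
    polymer chain receives an entity class by majority vote over residues with
    recognised names; residues with unrecognised names inherit the chain class.

    Raises
    ------
    StructureParseError
        If the file cannot be parsed as PDB or mmCIF.
    EmptyModelError
        If no RNA or protein chain is present (e.g. a waters-only file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no coordinate model found")

    model = StructureModel(label=label or path.stem, source_path=str(path))
    gmodel = st[0]
    for gchain in gmodel:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            atoms = []
            for ga in gres:
                altloc = ga.altloc if ga.altloc != "\x00" else ""
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name or "X",
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        temp_factor=ga.b_iso,
                        altloc=altloc,
                    )
                )
            atoms = _reduce_altlocs(atoms)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            res = Residue(
                chain_id=gchain.name,
                seq_id=gres.seqid.num,
                icode=icode,
                name=gres.name.strip().upper(),
                atoms=atoms,
                label_seq_id=gres.label_seq,
            )
            res.entity_class = _classify_residue_name(res.name)
            chain.residues.append(res)
        if not chain.residues:
            continue
        chain.residues.sort(key=lambda r: (r.seq_id, r.icode))
        # Majority vote over recognised residues decides the chain class;
        # unknown residues then inherit it.
        votes: dict[str, int] = {}
        for r in chain.residues:
            if r.entity_class in ("rna", "protein"):
                votes[r.entity_class] = votes.get(r.entity_class, 0) + 1
        if votes:
            chain.entity_class = max(sorted(votes), key=votes.get)
            for r in chain.residues:
                if r.entity_class == "unknown":
                    r.entity_class = chain.entity_class
        else:
            chain.entity_class = "other"
            for r in chain.residues:
                if r.entity_class == "unknown":
                    r.entity_class = "other"
        model.chains.append(chain)

    if not model.polymer_chains():
        raise EmptyModelError(f"{path}: no RNA or protein chain found")
    seen = [c.chain_id for c in model.chains]
    if len(seen) != len(set(seen)):
        # Merge duplicate chain ids (gemmi usually handles this, but PDB
        # files with reused ids after TER can produce them).
        merged: dict[str, Chain] = {}
        for c in model.chains:
            if c.chain_id in merged:
                merged[c.chain_id].residues.extend(c.residues)
                merged[c.chain_id].residues.sort(key=lambda r: (r.seq_id, r.icode))
            else:
                merged[c.chain_id] = c
        model.chains = list(merged.values())
    return model


# PDB fixed-width temperature-factor field bounds (columns 61-66, %6.2f).
BFACTOR_MIN = -99.99
BFACTOR_MAX = 999.99


def _format_atom_record(serial: int, atom: Atom, res: Residue, het: bool) -> str:
    name = atom.name
    # Standard PDB alignment: 1-letter elements start in column 14.
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    record = "HETATM" if het else "ATOM  "
    x, y, z = atom.position
    return (
        f"{record}{min(serial, 99999):5d} {name:<4s}{'':1s}{res.name:>3s} "
        f"{res.chain_id[:1]:1s}{res.seq_id:4d}{res.icode[:1]:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
        f"{np.clip(atom.temp_factor, BFACTOR_MIN, BFACTOR_MAX):6.2f}"
        f"          {atom.element:>2s}\n"
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a PDB file (ATOM/HETATM/TER records, one model)."""
    path = Path(path)
    lines: list[str] = []
    serial = 0
    for chain in model.chains:
        het = chain.entity_class not in ("rna", "protein")
        for res in chain.residues:
            res_het = het or res.entity_class not in ("rna", "protein")
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_record(serial, atom, res, res_het))
        serial += 1
        lines.append(f"TER   {min(serial, 99999):5d}\n")
    lines.append("END\n")
    path.write_text("".join(lines))


def write_bfactor_encoded(
    model: StructureModel,
    scores: Mapping[ResidueAddress, float],
    path: str | Path,
) -> int:
    """Write a PDB with per-residue scores in the temperature-factor column.

    Every atom of a scored residue carries that residue's score, clipped to the
    fixed-width field range [-99.99, 999.99]; unscored residues carry 0.00.
    Score keys absent from the model are skipped with a logged count.

    Returns the number of skipped score keys.
    """
    present = {r.address for c in model.chains for r in c.residues}
    skipped = sum(1 for key in scores if key not in present)
    if skipped:
        logger.warning("write_bfactor_encoded: %d score keys not in model, skipped", skipped)

    encoded = StructureModel(label=model.label, source_path=model.source_path)
    for chain in model.chains:
        new_chain = Chain(chain_id=chain.chain_id, entity_class=chain.entity_class)
        for res in chain.residues:
            score = float(np.clip(scores.get(res.address, 0.0), BFACTOR_MIN, BFACTOR_MAX))
            new_res = Residue(
                chain_id=res.chain_id, seq_id=res.seq_id, icode=res.icode,
                name=res.name, entity_class=res.entity_class,
            )
            new_res.atoms = [
                Atom(a.name, a.element, a.position.copy(), a.occupancy, score, a.altloc)
                for a in res.atoms
            ]
            new_chain.residues.append(new_res)
        encoded.chains.append(new_chain)
    write_pdb(encoded, path)
    return skipped
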