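"""Heavy-atom contact detection and residue-pair contact matrices.

A contact is a pair of heavy atoms from two *different* residues within a
distance cutoff (4.0 Å by default); self-contacts within one residue are
excluded. Contacts are categorised as rna-rna, rna-protein or protein-protein
from the entity classes of the residues involved; waters, ions and ligands
belong to no category. Detection uses a k-d tree whose output is identical to
the all-pairs scan (closed cutoff, plain double-precision comparison).

"Contact frequency" of a residue pair means the heavy-atom pair count, not a
binary indicator — difference maps sum gains and losses and percent-change
statements need magnitudes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Atom, Residue, ResidueAddress, StructureModel

CATEGORIES = ("rna-rna", "rna-protein", "protein-protein")

#: Unordered residue-address pair.
PairKey = tuple[ResidueAddress, ResidueAddress]


def pair_key(a: ResidueAddress, b: ResidueAddress) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Contact:
    chain_a: str
    res_a: ResidueAddress
    atom_a: str
    chain_b: str
    res_b: ResidueAddress
    atom_b: str
    distance: float
    category: str


@dataclass
class ContactMatrix:
    """Sparse symmetric residue-pair contact counts for one category."""

    category: str
    counts: dict[PairKey, int] = field(default_factory=dict)
    cutoff: float = 4.0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, a: ResidueAddress, b: ResidueAddress) -> int:
        return self.counts.get(pair_key(a, b), 0)


def _heavy_atom_table(
    model: StructureModel,
) -> tuple[np.ndarray, list[tuple[ResidueAddress, str, str, str]]]:
    """Flat coordinate array plus (address, atom name, element, entity) rows."""
    coords = []
    meta = []
    for res in model.iter_residues(polymer_only=True):
        for atom in res.atoms:
            if not atom.is_heavy:
                continue
            coords.append(atom.position)
            meta.append((res.address, atom.name, atom.element, res.entity_class))
    if not coords:
        return np.empty((0, 3)), []
    return np.asarray(coords, dtype=float), meta


def _categorise(entity_a: str, entity_b: str) -> str | None:
    pair = frozenset((entity_a, entity_b))
    if pair == {"rna"}:
        return "rna-rna"
    if pair == {"rna", "protein"}:
        return "rna-protein"
    if pair == {"protein"}:
        return "protein-protein"
    return None


def find_contacts(model: StructureModel, cutoff: float = 4.0) -> list[Contact]:
    """All heavy-atom pairs from distinct polymer residues within ``cutoff`` Å.

    The comparison is a closed inequality (distance ≤ cutoff) on double
    precision, so results are exactly those of a brute-force all-pairs scan.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords, meta = _heavy_atom_table(model)
    contacts: list[Contact] = []
    if len(coords) == 0:
        return contacts
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff, output_type="ndarray"):
        addr_i, name_i, _el_i, ent_i = meta[i]
        addr_j, name_j, _el_j, ent_j = meta[j]
        if addr_i == addr_j:
            continue  # self-contacts excluded
        category = _categorise(ent_i, ent_j)
        if category is None:
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        a_first = addr_i <= addr_j
        contacts.append(
            Contact(
                chain_a=addr_i[0] if a_first else addr_j[0],
                res_a=addr_i if a_first else addr_j,
                atom_a=name_i if a_first else name_j,
                chain_b=addr_j[0] if a_first else addr_i[0],
                res_b=addr_j if a_first else addr_i,
                atom_b=name_j if a_first else name_i,
                distance=dist,
                category=category,
            )
        )
    contacts.sort(key=lambda c: (c.res_a, c.res_b, c.atom_a, c.atom_b))
    return contacts


def contact_matrix(
    contacts: Iterable[Contact], category: str, cutoff: float = 4.0
) -> ContactMatrix:
    """Count qualifying heavy-atom pairs per unordered residue pair."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    counter: Counter[PairKey] = Counter()
    for c in contacts:
        if c.category == category:
            counter[pair_key(c.res_a, c.res_b)] += 1
    return ContactMatrix(category=category, counts=dict(counter), cutoff=cutoff)


def contact_matrices(
    model: StructureModel, cutoff: float = 4.0
) -> dict[str, ContactMatrix]:
    """Per-category contact matrices from a single contact pass."""
    contacts = find_contacts(model, cutoff)
    out = {}
    for category in CATEGORIES:
        counter: Counter[PairKey] = Counter()
        for c in contacts:
            if c.category == category:
                counter[pair_key(c.res_a, c.res_b)] += 1
        out[category] = ContactMatrix(category=category, counts=dict(counter), cutoff=cutoff)
    return out


def _selection_atoms(
    model: StructureModel, selection: Iterable[str] | Iterable[ResidueAddress]
) -> tuple[np.ndarray, list[ResidueAddress]]:
    """Resolve a selection (chain ids, or residue addresses) to heavy atoms."""
    sel = set(selection)
    chain_ids = {s for s in sel if isinstance(s, str)}
    addresses = {s for s in sel if isinstance(s, tuple)}
    coords, meta = [], []
    for res in model.iter_residues(polymer_only=True):
        if res.chain_id in chain_ids or res.address in addresses:
            for atom in res.heavy_atoms():
                coords.append(atom.position)
                meta.append(res.address)
    return (np.asarray(coords, dtype=float) if coords else np.empty((0, 3))), meta


def count_interface_contacts(
    model: StructureModel,
    group_a: Iterable[str] | Iterable[ResidueAddress],
    group_b: Iterable[str] | Iterable[ResidueAddress],
    cutoff: float = 4.0,
    convention: str = "atom_pairs",
) -> int:
    """Number of cross-group heavy-atom contacts at ``cutoff`` Å.

    Conventions:

    - ``atom_pairs`` (default): count (a, b) pairs with distance ≤ cutoff —
      consistent with the contact-matrix counting used in difference maps.
    - ``unique_atoms``: count group-A atoms having ≥ 1 group-B partner.
    - ``residue_pairs``: count distinct residue pairs in contact.

    Selections may be chain ids or residue addresses and must be disjoint.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("interface selections must be disjoint")
    coords_a, meta_a = _selection_atoms(model, set_a)
    coords_b, meta_b = _selection_atoms(model, set_b)
    shared = {m for m in meta_a} & {m for m in meta_b}
    if shared:
        raise ValueError(f"selections overlap on residues: {sorted(shared)[:3]}")
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0
    tree_b = cKDTree(coords_b)
    neighbours = tree_b.query_ball_point(coords_a, cutoff)
    if convention == "atom_pairs":
        return int(sum(len(nb) for nb in neighbours))
    if convention == "unique_atoms":
        return int(sum(1 for nb in neighbours if nb))
    if convention == "residue_pairs":
        pairs = {
            pair_key(meta_a[i], meta_b[j])
            for i, nb in enumerate(neighbours)
            for j in nb
        }
        return len(pairs)
    raise ValueError(f"unknown convention {convention!r}")


def detect_polar_proximities(model: StructureModel, dmax: float = 3.5) -> list[Contact]:
    """N/O/S atom pairs within ``dmax`` Å — a distance-only hydrogen-bond proxy.

    No donor–H–acceptor angle term is applied; treat the output as candidate
    polar interactions, not verified hydrogen bonds.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    polar = ("N", "O", "S")
    out = []
    for c in find_contacts(model, dmax):
        res_a = model.get_residue(c.res_a)
        res_b = model.get_residue(c.res_b)
        el_a = next(a.element.upper() for a in res_a.atoms if a.name == c.atom_a)
        el_b = next(a.element.upper() for a in res_b.atoms if a.name == c.atom_b)
        if el_a in polar and el_b in polar:
            out.append(c)
    return out


def contacts_to_tsv(contacts: Iterable[Contact], path) -> None:
    import pandas as pd

    rows = [
        {
            "chain_a": c.res_a[0],
            "res_a": f"{c.res_a[1]}{c.res_a[2]}",
            "atom_a": c.atom_a,
            "chain_b": c.res_b[0],
            "res_b": f"{c.res_b[1]}{c.res_b[2]}",
            "atom_b": c.atom_b,
            "distance": f"{c.distance:.3f}",
            "category": c.category,
        }
        for c in contacts
    ]
    pd.DataFrame(
        rows,
        columns=["chain_a", "res_a", "atom_a", "chain_b", "res_b", "atom_b", "distance", "category"],
    ).to_csv(path, sep="\t", index=False)
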