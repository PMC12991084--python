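"""Superposition, RMSD, displacement flags and center-of-mass distances.

Superposition is least-squares optimal rigid fitting (Kabsch, SVD with
reflection correction). Per-residue displacements are measured between
representative atoms after fitting: P for RNA, CA for proteins, with a
center-of-mass fallback — stable to side-chain and base rearrangements.
The nucleotide center-of-mass distance is the decoding-site open/closed
metric: the distance between the mass-weighted heavy-atom centers of the
two monitoring adenosines reports whether the site is open or closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .residue_mapping import ResidueMap
from .structure_model import Residue, ResidueAddress, StructureModel

_cfg_default = None  # resolved lazily to avoid an import cycle


@dataclass
class RigidTransform:
    """Proper rotation + translation: x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation matrix determinant is not +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def to_matrix_text(self) -> str:
        """3×4 [R | t] matrix, one row per line."""
        rows = []
        for i in range(3):
            vals = list(self.rotation[i]) + [self.translation[i]]
            rows.append(" ".join(f"{v: .9f}" for v in vals))
        return "\n".join(rows) + "\n"


@dataclass
class DisplacementReport:
    """Per-residue post-superposition displacement magnitudes and flags."""

    magnitudes: dict[ResidueAddress, float] = field(default_factory=dict)
    flagged: set[ResidueAddress] = field(default_factory=set)
    threshold: float = 1.0
    rmsd: float = 0.0

    def to_tsv(self, path) -> None:
        import pandas as pd

        recs = [
            {
                "chain": addr[0],
                "seq_id": addr[1],
                "icode": addr[2] or "-",
                "magnitude": f"{mag:.3f}",
                "flagged": addr in self.flagged,
            }
            for addr, mag in sorted(self.magnitudes.items())
        ]
        pd.DataFrame(
            recs, columns=["chain", "seq_id", "icode", "magnitude", "flagged"]
        ).to_csv(path, sep="\t", index=False)


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of A onto B (Kabsch) and the post-fit RMSD.

    Returns the transform T minimising ‖T(A) − B‖ and the RMSD after applying
    it. Reflections are corrected so the rotation is always proper.
    """
    P = np.asarray(coords_a, dtype=float)
    Q = np.asarray(coords_b, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must be matched N×3")
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry")
    H = P0.T @ Q0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(rotation=R, translation=t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return transform, rmsd


def _representative_atom(res: Residue, selection: str) -> np.ndarray | None:
    """Coordinate of the residue's representative atom for ``selection``.

    ``P``: P for RNA, CA for proteins; ``C1'``: C1' for RNA, CA for proteins;
    ``heavy``: handled by the caller (all shared heavy atoms). Falls back to
    the heavy-atom center of mass when the named atom is missing.
    """
    if res.entity_class == "rna":
        name = "P" if selection == "P" else "C1'"
    else:
        name = "CA"
    atom = res.get_atom(name)
    if atom is not None and atom.is_heavy:
        return atom.position
    heavy = res.heavy_atoms()
    if not heavy:
        return None
    return residue_com(res)


def _matched_coordinates(
    model_a: StructureModel,
    model_b: StructureModel,
    rmap: ResidueMap,
    atom_selection: str,
) -> tuple[np.ndarray, np.ndarray, list[ResidueAddress]]:
    xs, ys, addrs = [], [], []
    for addr_a, addr_b in sorted(rmap.mapping.items()):
        res_a = model_a.get_residue(addr_a)
        res_b = model_b.get_residue(addr_b)
        if res_a is None or res_b is None:
            continue
        if atom_selection == "heavy":
            names_a = {a.name for a in res_a.heavy_atoms()}
            names_b = {a.name for a in res_b.heavy_atoms()}
            for name in sorted(names_a & names_b):
                xs.append(res_a.get_atom(name).position)
                ys.append(res_b.get_atom(name).position)
                addrs.append(addr_a)
        else:
            pa = _representative_atom(res_a, atom_selection)
            pb = _representative_atom(res_b, atom_selection)
            if pa is None or pb is None:
                continue
            xs.append(pa)
            ys.append(pb)
            addrs.append(addr_a)
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} matched atoms under selection {atom_selection!r}; need >= 3"
        )
    return np.asarray(xs), np.asarray(ys), addrs


def chain_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    rmap: ResidueMap,
    atom_selection: str = "P",
) -> tuple[float, int]:
    """Post-superposition RMSD over mapped residues and the atom count used.

    ``atom_selection`` is one of ``P`` (phosphates for RNA, CA for proteins —
    the default, standard rRNA practice), ``C1'``, or ``heavy`` (all heavy
    atoms with matching names).
    """
    xs, ys, _ = _matched_coordinates(model_a, model_b, rmap, atom_selection)
    _, rmsd = superpose(xs, ys)
    return rmsd, len(xs)


# Standard atomic weights via gemmi's element table.
def _mass(element: str) -> float:
    el = gemmi.Element(element.capitalize())
    if el.weight <= 0:
        raise ValueError(f"unknown element {element!r}")
    return float(el.weight)


def residue_com(res: Residue) -> np.ndarray:
    """Mass-weighted mean position of the residue's heavy atoms (Å)."""
    heavy = res.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {res.address} has no heavy atoms")
    masses = np.array([_mass(a.element) for a in heavy])
    coords = np.array([a.position for a in heavy])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def residue_centroid(res: Residue) -> np.ndarray:
    """Unweighted heavy-atom centroid — the geometric-mean variant."""
    heavy = res.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {res.address} has no heavy atoms")
    return np.array([a.position for a in heavy]).mean(axis=0)


def com_distance(
    model: StructureModel,
    addr_a: ResidueAddress,
    addr_b: ResidueAddress,
    weighted: bool = True,
) -> float:
    """Distance between the centers of mass of two residues (Å)."""
    res_a = model.get_residue(addr_a)
    if res_a is None:
        raise ValueError(f"residue {addr_a} not found in {model.label}")
    res_b = model.get_residue(addr_b)
    if res_b is None:
        raise ValueError(f"residue {addr_b} not found in {model.label}")
    fn = residue_com if weighted else residue_centroid
    return float(np.linalg.norm(fn(res_a) - fn(res_b)))


def displacement_report(
    model_a: StructureModel,
    model_b: StructureModel,
    rmap: ResidueMap,
    cfg=None,
    atom_selection: str = "P",
) -> DisplacementReport:
    """Per-residue representative-atom displacements after global superposition.

    Residues shifting by more than the threshold (1 Å by default) are flagged
    as sites of significant structural change.
    """
    from .delta_contact import AnalysisConfig

    cfg = cfg or AnalysisConfig()
    xs, ys, addrs = _matched_coordinates(model_a, model_b, rmap, atom_selection)
    transform, rmsd = superpose(xs, ys)
    moved = transform.apply(xs)
    dists = np.linalg.norm(moved - ys, axis=1)
    report = DisplacementReport(threshold=cfg.shift_threshold, rmsd=rmsd)
    for addr, d in zip(addrs, dists):
        mag = float(d)
        prev = report.magnitudes.get(addr)
        if prev is None or mag > prev:
            report.magnitudes[addr] = mag
    report.flagged = {
        addr for addr, mag in report.magnitudes.items() if mag > cfg.shift_threshold
    }
    return report
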