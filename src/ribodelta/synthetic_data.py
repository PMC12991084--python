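"""Paired toy ribonucleoprotein models with planted, recomputed ground truth.

The generator builds a coarse RNA helix (P / O3' / C1' backbone plus 2–4
inward-pointing base atoms per nucleotide) and a protein backbone trace with
1–3 side-chain atoms placed against the RNA so a 4 Å interface exists by
construction. The geometry is controlled, not chemically realistic: real
element symbols and standard masses are used so center-of-mass and polar
proximity operations behave as on real structures, but no base pairing,
sugar pucker or peptide geometry is modelled.

:func:`perturb` applies a :class:`PerturbationPlan` — substitutions, whole-
residue displacements, contact gains/losses driven to a requested magnitude,
an optional global rigid move, and coordinate jitter — and returns the
perturbed model together with a :class:`GroundTruth` holding the *recomputed*
(not requested) contact deltas, so tests compare against what actually exists
in the coordinates.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contact_analysis import CATEGORIES, PairKey, contact_matrices, pair_key
from .delta_contact import QualityTable
from .geometry import RigidTransform, residue_com
from .structure_model import Atom, Chain, Residue, ResidueAddress, StructureModel

RNA_HELIX_RADIUS = 9.0
RNA_RISE = 2.8
RNA_TWIST = 0.6  # radians per nucleotide

# Base atom layouts: (atom name, element, radial offset inward from C1').
_PURINE_ATOMS = [("N9", "N", 1.2), ("C8", "C", 2.0), ("N7", "N", 2.8), ("C5", "C", 3.5)]
_PYRIMIDINE_ATOMS = [("N1", "N", 1.2), ("C2", "C", 2.0), ("O2", "O", 2.8)]

_PROTEIN_SIDECHAINS = {
    "ALA": [("CB", "C")],
    "SER": [("CB", "C"), ("OG", "O")],
    "LYS": [("CB", "C"), ("CG", "C"), ("NZ", "N")],
    "ASP": [("CB", "C"), ("CG", "C"), ("OD1", "O")],
    "GLN": [("CB", "C"), ("CG", "C"), ("NE2", "N")],
    "VAL": [("CB", "C"), ("CG1", "C")],
}


@dataclass
class PerturbationPlan:
    """Edits to apply when deriving a variant model from a base model."""

    substitutions: list[tuple[ResidueAddress, str]] = field(default_factory=list)
    displaced: list[tuple[ResidueAddress, tuple[float, float, float]]] = field(default_factory=list)
    contact_edits: list[tuple[ResidueAddress, ResidueAddress, int, int]] = field(default_factory=list)
    global_transform: RigidTransform | None = None
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class GroundTruth:
    """What the perturbation actually realised, recomputed from coordinates."""

    substitutions: list[tuple[str, int, str]] = field(default_factory=list)
    displacements: dict[ResidueAddress, float] = field(default_factory=dict)
    contact_deltas: dict[str, dict[PairKey, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "substitutions": [list(s) for s in self.substitutions],
            "displacements": [
                [list(addr), mag] for addr, mag in sorted(self.displacements.items())
            ],
            "contact_deltas": {
                cat: [[list(k[0]), list(k[1]), v] for k, v in sorted(d.items())]
                for cat, d in self.contact_deltas.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _base_atoms_for(name: str) -> list[tuple[str, str, float]]:
    return _PURINE_ATOMS if name in ("A", "G") else _PYRIMIDINE_ATOMS


def generate_toy_complex(n_rna: int, n_protein: int, seed: int) -> StructureModel:
    """Deterministic toy RNA helix (chain A) + protein trace (chain B).

    The RNA backbone guarantees consecutive-residue RNA-RNA contacts (the O3'
    atom sits midway to the next phosphate); each protein residue's innermost
    side-chain atom is placed 3.5 Å from its nearest RNA phosphate, so an
    RNA-protein interface at 4.0 Å exists whenever ``n_protein >= 1``.
    """
    if n_rna < 4:
        raise ValueError("n_rna must be >= 4")
    if n_protein < 0:
        raise ValueError("n_protein must be >= 0")
    rng = np.random.default_rng(seed)
    model = StructureModel(label=f"toy-{seed}")

    bases = rng.choice(["A", "C", "G", "U"], size=n_rna)
    p_positions = []
    for i in range(n_rna):
        phi = i * RNA_TWIST
        p_positions.append(
            np.array([RNA_HELIX_RADIUS * np.cos(phi), RNA_HELIX_RADIUS * np.sin(phi), i * RNA_RISE])
        )

    rna = Chain(chain_id="A", entity_class="rna")
    for i in range(n_rna):
        name = str(bases[i])
        p = p_positions[i]
        nxt = p_positions[i + 1] if i + 1 < n_rna else p + np.array([0.0, 0.0, RNA_RISE])
        inward = -np.array([p[0], p[1], 0.0])
        inward /= np.linalg.norm(inward)
        atoms = [
            Atom("P", "P", p.copy()),
            Atom("O3'", "O", (p + nxt) / 2.0),
            Atom("C1'", "C", p + inward * 2.2 + np.array([0, 0, 0.4])),
        ]
        c1 = atoms[2].position
        for atom_name, element, offset in _base_atoms_for(name):
            atoms.append(Atom(atom_name, element, c1 + inward * offset))
        # Small seeded jitter keeps the geometry generic (no exact symmetries).
        for a in atoms:
            a.position = a.position + rng.normal(0.0, 0.03, size=3)
        rna.residues.append(
            Residue(chain_id="A", seq_id=i + 1, icode="", name=name, atoms=atoms, entity_class="rna")
        )
    model.chains.append(rna)

    if n_protein > 0:
        aa_names = rng.choice(sorted(_PROTEIN_SIDECHAINS), size=n_protein)
        prot = Chain(chain_id="B", entity_class="protein")
        # Face protein residue j at RNA residue k, centred along the helix.
        offset = max((n_rna - n_protein) // 2, 0)
        ca_positions = []
        for j in range(n_protein):
            k = min(offset + j, n_rna - 1)
            p = p_positions[k]
            outward = np.array([p[0], p[1], 0.0])
            outward /= np.linalg.norm(outward)
            ca_positions.append(p + outward * 7.0 + np.array([0.0, 0.0, 0.6]))
        for j in range(n_protein):
            k = min(offset + j, n_rna - 1)
            p = p_positions[k]
            outward = np.array([p[0], p[1], 0.0])
            outward /= np.linalg.norm(outward)
            tip = p + outward * 3.5  # innermost side-chain atom: contact by construction
            ca = ca_positions[j]
            nxt_ca = ca_positions[j + 1] if j + 1 < n_protein else ca + np.array([0.0, 0.0, 3.0])
            name = str(aa_names[j])
            sidechain = _PROTEIN_SIDECHAINS[name]
            # Two bridge atoms toward the next CA guarantee protein-protein
            # contacts along the trace (CA spacing exceeds the 4 A cutoff).
            atoms = [
                Atom("CA", "C", ca.copy()),
                Atom("C", "C", ca + (nxt_ca - ca) / 3.0),
                Atom("O", "O", ca + 2.0 * (nxt_ca - ca) / 3.0),
            ]
            n_side = len(sidechain)
            for s, (atom_name, element) in enumerate(sidechain):
                frac = (s + 1) / n_side
                atoms.append(Atom(atom_name, element, ca + (tip - ca) * frac))
            for a in atoms[:-1]:  # keep the tip exact so the contact is guaranteed
                a.position = a.position + rng.normal(0.0, 0.03, size=3)
            prot.residues.append(
                Residue(chain_id="B", seq_id=j + 1, icode="", name=name, atoms=atoms, entity_class="protein")
            )
        model.chains.append(prot)
    return model


def _replace_base_atoms(res: Residue, new_name: str) -> None:
    backbone = {"P", "O3'", "C1'"}
    kept = [a for a in res.atoms if a.name in backbone]
    p = next(a for a in kept if a.name == "P").position
    c1 = next(a for a in kept if a.name == "C1'").position
    inward = c1 - p
    inward = inward / np.linalg.norm(inward)
    for atom_name, element, offset in _base_atoms_for(new_name):
        kept.append(Atom(atom_name, element, c1 + inward * offset))
    res.atoms = kept
    res.name = new_name


def _pair_contact_count(res_a: Residue, res_b: Residue, cutoff: float = 4.0) -> int:
    ca = np.array([a.position for a in res_a.heavy_atoms()])
    cb = np.array([a.position for a in res_b.heavy_atoms()])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    return int((d <= cutoff).sum())


def _drive_contact_edit(
    model: StructureModel,
    addr_r: ResidueAddress,
    addr_s: ResidueAddress,
    sign: int,
    magnitude: int,
    base_count: int,
    max_steps: int = 80,
) -> None:
    """Translate residue r along the r–s axis until the pair delta suffices."""
    res_r = model.get_residue(addr_r)
    res_s = model.get_residue(addr_s)
    if res_r is None or res_s is None:
        raise ValueError(f"contact edit references missing residue {addr_r} or {addr_s}")
    direction = residue_com(res_r) - residue_com(res_s)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    step = direction * (0.4 if sign < 0 else -0.25)
    for _ in range(max_steps):
        count = _pair_contact_count(res_r, res_s)
        delta = count - base_count
        if sign < 0 and delta <= -magnitude:
            return
        if sign > 0 and delta >= magnitude:
            return
        for a in res_r.atoms:
            a.position = a.position + step
    raise ValueError(
        f"contact edit unsatisfiable for pair {addr_r} ~ {addr_s} "
        f"(sign {sign:+d}, magnitude {magnitude})"
    )


def perturb(model: StructureModel, plan: PerturbationPlan) -> tuple[StructureModel, GroundTruth]:
    """Apply a perturbation plan; return the variant and its ground truth.

    Contact deltas in the ground truth are recomputed per category from the
    noiseless construction (variant − base), so they are exact integers; the
    global transform and jitter are applied after that, as pure observation
    noise. With an empty plan and zero jitter the output coordinates equal
    the input's.
    """
    variant = copy.deepcopy(model)
    variant.label = model.label + "-variant"
    truth = GroundTruth()

    for addr, new_name in plan.substitutions:
        res = variant.get_residue(addr)
        if res is None:
            raise ValueError(f"substitution site {addr} not in model")
        if res.entity_class != "rna":
            raise ValueError(f"substitutions are planted on RNA residues; {addr} is not RNA")
        old = res.one_letter
        _replace_base_atoms(res, new_name)
        truth.substitutions.append((old, addr[1], new_name))

    for addr, shift in plan.displaced:
        res = variant.get_residue(addr)
        if res is None:
            raise ValueError(f"displaced residue {addr} not in model")
        vec = np.asarray(shift, dtype=float)
        for a in res.atoms:
            a.position = a.position + vec
        truth.displacements[addr] = float(np.linalg.norm(vec))

    if plan.contact_edits:
        for addr_r, addr_s, sign, magnitude in plan.contact_edits:
            base_r = model.get_residue(addr_r)
            base_s = model.get_residue(addr_s)
            if base_r is None or base_s is None:
                raise ValueError(f"contact edit references missing residue {addr_r} or {addr_s}")
            base_count = _pair_contact_count(base_r, base_s)
            if sign < 0 and base_count < magnitude:
                raise ValueError(
                    f"cannot plant a loss of {magnitude} at {addr_r} ~ {addr_s}: "
                    f"only {base_count} contacts exist"
                )
            _drive_contact_edit(variant, addr_r, addr_s, sign, magnitude, base_count)

    # Exact ground-truth deltas from the noiseless construction.
    mats_base = contact_matrices(model)
    mats_var = contact_matrices(variant)
    for cat in CATEGORIES:
        deltas: dict[PairKey, int] = {}
        keys = set(mats_var[cat].counts) | set(mats_base[cat].counts)
        for key in keys:
            d = mats_var[cat].counts.get(key, 0) - mats_base[cat].counts.get(key, 0)
            if d != 0:
                deltas[key] = d
        truth.contact_deltas[cat] = deltas

    if plan.global_transform is not None:
        for chain in variant.chains:
            for res in chain.residues:
                for a in res.atoms:
                    a.position = plan.global_transform.apply(a.position)

    if plan.jitter_sigma > 0:
        rng = np.random.default_rng(plan.seed)
        for chain in variant.chains:
            for res in chain.residues:
                for a in res.atoms:
                    a.position = a.position + rng.normal(0.0, plan.jitter_sigma, size=3)

    return variant, truth


def generate_quality_table(
    model: StructureModel,
    base_q: float = 0.8,
    bad_residues: list[ResidueAddress] | None = None,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> QualityTable:
    """Per-residue Q-scores around ``base_q`` with planted sub-0.4 residues.

    Local resolution follows a center-to-periphery gradient (2.0 Å at the
    model center, degrading outwards), emulating the peripheral resolution
    drop-off of single-particle reconstructions.
    """
    if not 0.0 <= base_q <= 1.0:
        raise ValueError("base_q must be in [0, 1]")
    bad = set(bad_residues or [])
    rng = np.random.default_rng(seed)

    coms = {}
    for res in model.iter_residues(polymer_only=True):
        coms[res.address] = residue_com(res)
    center = np.mean(list(coms.values()), axis=0)
    dists = {addr: float(np.linalg.norm(c - center)) for addr, c in coms.items()}
    dmax = max(dists.values()) or 1.0

    rows = {}
    for addr in sorted(coms):
        if addr in bad:
            q = float(rng.uniform(0.10, 0.39))
        else:
            q = float(np.clip(base_q + rng.normal(0.0, noise_sd), -1.0, 1.0))
        locres = 2.0 + 2.0 * dists[addr] / dmax
        rows[addr] = (q, round(locres, 3))
    return QualityTable(rows=rows)
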