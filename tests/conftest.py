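"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's implementation paths:
contact detection is checked against a dense all-pairs distance scan,
global alignment against memoised exhaustive recursion, and Kabsch
superposition against the quaternion (Horn) method.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

import ribodelta as rd

# ---------------------------------------------------------------------------
# Minimal hand-written coordinate fixtures (identical content, two dialects).

MINIMAL_PDB = """\
ATOM      1  P     G A  10      11.000  22.000  33.000  1.00 10.00           P
ATOM      2  C1'   G A  10      12.500  22.000  33.000  1.00 10.00           C
ATOM      3  N9    G A  10      13.700  22.500  33.100  1.00 10.00           N
TER       4
END
"""

MINIMAL_CIF = """\
data_minimal
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
ATOM 1 P P   . G A 1 1 ? 11.000 22.000 33.000 1.00 10.00 10 A
ATOM 2 C "C1'" . G A 1 1 ? 12.500 22.000 33.000 1.00 10.00 10 A
ATOM 3 N N9  . G A 1 1 ? 13.700 22.500 33.100 1.00 10.00 10 A
"""

WATERS_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def minimal_cif(tmp_path):
    path = tmp_path / "minimal.cif"
    path.write_text(MINIMAL_CIF)
    return path


@pytest.fixture
def waters_only_pdb(tmp_path):
    path = tmp_path / "waters.pdb"
    path.write_text(WATERS_ONLY_PDB)
    return path


@pytest.fixture(scope="session")
def toy_model():
    return rd.generate_toy_complex(30, 10, seed=1)


@pytest.fixture
def toy_pair(toy_model):
    """Base model plus a noiseless variant with one of each planted change."""
    plan = rd.PerturbationPlan(
        substitutions=[(("A", 5, ""), "C")],
        displaced=[(("A", 12, ""), (1.5, 1.0, 0.8))],
        contact_edits=[(("A", 15, ""), ("B", 5, ""), -1, 1)],
        jitter_sigma=0.0,
        seed=7,
    )
    variant, truth = rd.perturb(toy_model, plan)
    return toy_model, variant, truth


# ---------------------------------------------------------------------------
# Independent oracles.

def brute_force_contacts(model, cutoff=4.0, polar_only=False):
    """All-pairs heavy-atom contact scan; returns a set of unordered keys."""
    atoms = []
    for res in model.iter_residues(polymer_only=True):
        for atom in res.atoms:
            if not atom.is_heavy:
                continue
            if polar_only and atom.element.upper() not in ("N", "O", "S"):
                continue
            atoms.append((res.address, res.entity_class, atom.name, atom.position))
    found = set()
    for (addr_i, ent_i, name_i, pos_i), (addr_j, ent_j, name_j, pos_j) in itertools.combinations(atoms, 2):
        if addr_i == addr_j:
            continue
        if {ent_i, ent_j} - {"rna", "protein"}:
            continue
        if np.linalg.norm(pos_i - pos_j) <= cutoff:
            found.add(frozenset(((addr_i, name_i), (addr_j, name_j))))
    return found


def contact_set(contacts):
    return {frozenset(((c.res_a, c.atom_a), (c.res_b, c.atom_b))) for c in contacts}


def brute_force_align_score(seq_a: str, seq_b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Best global alignment score by exhaustive (memoised) recursion."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i == len(seq_a) and j == len(seq_b):
            return 0
        options = []
        if i < len(seq_a) and j < len(seq_b):
            options.append(
                (match if seq_a[i] == seq_b[j] else mismatch) + best(i + 1, j + 1)
            )
        if i < len(seq_a):
            options.append(gap + best(i + 1, j))
        if j < len(seq_b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def quaternion_superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal rigid-fit RMSD via Horn's quaternion method."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (P0**2).sum() + (Q0**2).sum()
    return float(np.sqrt(max(e0 - 2.0 * lam, 0.0) / len(P)))
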