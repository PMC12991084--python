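"""Residue correspondence between homologous models.

Chain pairing uses global sequence alignment (Needleman–Wunsch, match +1,
mismatch −1, gap −2) restricted to chains of the same entity class; aligned
non-gap columns then become the residue-level partial bijection. Substitutions
are enumerated where mapped residues differ in parent-base-normalised name,
reported in the reference (first) model's author numbering — the convention
in which variants like A412C are named.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_model import Chain, ResidueAddress, StructureModel

logger = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -1
GAP = -2

#: Minimum fraction identity for a chain pair to be accepted. Rejects
#: accidental pairing of non-homologous RNAs (e.g. 16S vs 23S) while keeping
#: inter-species 16S homologues.
IDENTITY_THRESHOLD = 0.30


@dataclass
class Alignment:
    """Global alignment as ordered (indexA | None, indexB | None) pairs."""

    pairs: list[tuple[int | None, int | None]]
    score: int

    def matched_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in self.pairs if i is not None and j is not None]

    def identity(self, seq_a: str, seq_b: str) -> float:
        matched = self.matched_pairs()
        if not matched:
            return 0.0
        same = sum(1 for i, j in matched if seq_a[i] == seq_b[j])
        return same / max(len(seq_a), len(seq_b))


@dataclass
class ChainPairing:
    matches: list[tuple[str, str, int, float]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.matches)


@dataclass
class ResidueMap:
    """Partial bijection between residue addresses of two models."""

    mapping: dict[ResidueAddress, ResidueAddress] = field(default_factory=dict)
    unmapped_a: set[ResidueAddress] = field(default_factory=set)
    unmapped_b: set[ResidueAddress] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.mapping)

    def inverse(self) -> "ResidueMap":
        return ResidueMap(
            mapping={v: k for k, v in self.mapping.items()},
            unmapped_a=set(self.unmapped_b),
            unmapped_b=set(self.unmapped_a),
        )


@dataclass
class SubstitutionList:
    """Planted or observed residue identity changes, reference numbering."""

    entries: list[tuple[str, int, str]] = field(default_factory=list)
    addresses: list[tuple[ResidueAddress, ResidueAddress]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        """Human-readable labels such as ``A412C``."""
        return [f"{ref}{seq}{alt}" for ref, seq, alt in self.entries]

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for (ref, seq, alt), (addr_a, addr_b) in zip(self.entries, self.addresses):
            rows.append(
                {
                    "ref_name": ref,
                    "ref_seq_id": seq,
                    "alt_name": alt,
                    "chain_a": addr_a[0],
                    "chain_b": addr_b[0],
                }
            )
        pd.DataFrame(
            rows, columns=["ref_name", "ref_seq_id", "alt_name", "chain_a", "chain_b"]
        ).to_csv(path, sep="\t", index=False)


def global_align(seq_a: str, seq_b: str) -> Alignment:
    """Needleman–Wunsch global alignment, match +1 / mismatch −1 / gap −2.

    Traceback ties prefer match/mismatch over a gap in A (consuming B only)
    over a gap in B, making the alignment deterministic.
    """
    if not seq_a or not seq_b:
        raise ValueError("global_align requires two non-empty sequences")
    n, m = len(seq_a), len(seq_b)
    a = np.frombuffer(seq_a.encode("latin1"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("latin1"), dtype=np.uint8)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = GAP * np.arange(m + 1)
    score[:, 0] = GAP * np.arange(n + 1)
    sub = np.where(a[:, None] == b[None, :], MATCH, MISMATCH).astype(np.int32)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP
        row = score[i]
        prev = row[0]
        # The left-dependency is sequential within the row.
        dm = np.maximum(diag, up)
        for j in range(1, m + 1):
            prev = max(dm[j - 1], prev + GAP)
            row[j] = prev

    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif j > 0 and score[i, j] == score[i, j - 1] + GAP:  # gap in A
            pairs.append((None, j - 1))
            j -= 1
        else:  # gap in B
            pairs.append((i - 1, None))
            i -= 1
    pairs.reverse()
    return Alignment(pairs=pairs, score=int(score[n, m]))


def pair_chains(model_a: StructureModel, model_b: StructureModel) -> ChainPairing:
    """Greedy best-score matching of same-entity-class polymer chains.

    Candidate pairs are ranked by alignment score; pairs falling below 30%
    fraction identity are dropped (logged). Each chain is used at most once.
    """
    chains_a = model_a.polymer_chains()
    chains_b = model_b.polymer_chains()
    if not chains_a or not chains_b:
        raise ValueError("both models must have at least one polymer chain")

    candidates: list[tuple[int, float, str, str]] = []
    for ca in chains_a:
        for cb in chains_b:
            if ca.entity_class != cb.entity_class:
                continue
            seq_a, seq_b = ca.sequence(), cb.sequence()
            if not seq_a or not seq_b:
                continue
            aln = global_align(seq_a, seq_b)
            ident = aln.identity(seq_a, seq_b)
            candidates.append((aln.score, ident, ca.chain_id, cb.chain_id))

    candidates.sort(key=lambda t: (-t[0], t[2], t[3]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairing = ChainPairing()
    for score, ident, ida, idb in candidates:
        if ida in used_a or idb in used_b:
            continue
        if ident < IDENTITY_THRESHOLD:
            logger.info(
                "pair_chains: dropping %s~%s (identity %.2f < %.2f)",
                ida, idb, ident, IDENTITY_THRESHOLD,
            )
            continue
        pairing.matches.append((ida, idb, score, ident))
        used_a.add(ida)
        used_b.add(idb)
    if not pairing.matches:
        logger.warning("pair_chains: no chain pair above identity threshold")
    return pairing


def build_residue_map(
    pairing: ChainPairing, model_a: StructureModel, model_b: StructureModel
) -> ResidueMap:
    """Turn aligned columns of each paired chain into a residue bijection.

    Gap columns populate the unmapped sets — residues absent from either
    structure are thereby excluded from all downstream difference analyses.
    """
    if not pairing:
        raise ValueError("build_residue_map requires a non-empty chain pairing")
    rmap = ResidueMap()
    paired_a = {m[0] for m in pairing.matches}
    paired_b = {m[1] for m in pairing.matches}
    for ida, idb, _score, _ident in pairing.matches:
        ca = model_a.get_chain(ida)
        cb = model_b.get_chain(idb)
        aln = global_align(ca.sequence(), cb.sequence())
        for i, j in aln.pairs:
            if i is not None and j is not None:
                rmap.mapping[ca.residues[i].address] = cb.residues[j].address
            elif i is not None:
                rmap.unmapped_a.add(ca.residues[i].address)
            else:
                rmap.unmapped_b.add(cb.residues[j].address)
    # Residues of unpaired chains are unmapped too.
    for chain in model_a.polymer_chains():
        if chain.chain_id not in paired_a:
            rmap.unmapped_a.update(r.address for r in chain.residues)
    for chain in model_b.polymer_chains():
        if chain.chain_id not in paired_b:
            rmap.unmapped_b.update(r.address for r in chain.residues)
    return rmap


def list_substitutions(
    rmap: ResidueMap, model_a: StructureModel, model_b: StructureModel
) -> SubstitutionList:
    """Enumerate mapped residue pairs whose parent-base names differ.

    Entries are reported in the reference (A) numbering and sorted by
    (chain, seq_id); names are parent-base-normalised so a modified
    nucleotide never shows up as a spurious substitution.
    """
    if not rmap.mapping:
        raise ValueError("list_substitutions requires a non-empty residue map")
    out = SubstitutionList()
    items = sorted(rmap.mapping.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    for addr_a, addr_b in items:
        res_a = model_a.get_residue(addr_a)
        res_b = model_b.get_residue(addr_b)
        if res_a is None or res_b is None:
            continue
        if res_a.parent_name != res_b.parent_name:
            out.entries.append((res_a.one_letter, res_a.seq_id, res_b.one_letter))
            out.addresses.append((addr_a, addr_b))
    return out
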