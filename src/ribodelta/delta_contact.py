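"""Δ-contact matrices, quality-based exclusions, Δ-scores and filters.

The core comparison: for two residue-mapped structures A (variant) and B
(baseline), the Δ-contact matrix holds per mapped residue pair the signed
difference countA − countB of heavy-atom contact counts, one matrix per
interaction category. Pairs touching a residue that is absent from either
structure, or whose per-residue map-model Q-score falls below 0.4 in either
structure, are excluded for model reliability. Residue-resolved Δ-scores sum
gains and losses across all interaction partners per residue: negative net
means net contact loss (destabilisation, rendered red), positive net contact
gain (stabilisation, blue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .contact_analysis import ContactMatrix, PairKey, pair_key
from .residue_mapping import ResidueMap, SubstitutionList
from .structure_model import (
    ResidueAddress,
    StructureModel,
    write_bfactor_encoded,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Every numeric threshold of the analysis, in one place.

    Attributes
    ----------
    contact_cutoff, interface_cutoff:
        Heavy-atom distance cutoffs, Å.
    q_exclude:
        Residues with Q-score below this value are excluded from Δ analysis.
    q_change_frac:
        Relative Q-score change (vs. baseline) flagging a significant site.
    locres_change:
        Absolute local-resolution change (Å) flagging a significant site.
    neighborhood_radius:
        Heavy-atom radius (Å) defining a mutation's structural neighborhood.
    min_local_resolution:
        Local-resolution value (Å) a residue must be at or below (i.e. better
        than) to count as well-resolved in neighborhood reports.
    shift_threshold:
        Post-superposition per-residue displacement (Å) above which a residue
        is flagged as significantly shifted.
    """

    contact_cutoff: float = 4.0
    interface_cutoff: float = 4.0
    q_exclude: float = 0.4
    q_change_frac: float = 0.10
    locres_change: float = 0.5
    neighborhood_radius: float = 10.0
    min_local_resolution: float = 3.0
    shift_threshold: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class QualityTable:
    """Per-residue Q-score and optional local resolution (Å)."""

    rows: dict[ResidueAddress, tuple[float, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for addr, (q, locres) in self.rows.items():
            if not -1.0 <= q <= 1.0:
                raise ValueError(f"q_score {q} at {addr} outside [-1, 1]")
            if locres is not None and locres <= 0:
                raise ValueError(f"local_resolution {locres} at {addr} not positive")

    def q_score(self, addr: ResidueAddress) -> float | None:
        row = self.rows.get(addr)
        return row[0] if row else None

    def local_resolution(self, addr: ResidueAddress) -> float | None:
        row = self.rows.get(addr)
        return row[1] if row else None

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QualityTable":
        df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str})
        rows: dict[ResidueAddress, tuple[float, float | None]] = {}
        for rec in df.itertuples(index=False):
            icode = "" if pd.isna(rec.icode) or rec.icode == "-" else str(rec.icode)
            locres = None if pd.isna(rec.local_resolution) else float(rec.local_resolution)
            rows[(str(rec.chain), int(rec.seq_id), icode)] = (float(rec.q_score), locres)
        return cls(rows=rows)

    def to_tsv(self, path: str | Path) -> None:
        recs = [
            {
                "chain": addr[0],
                "seq_id": addr[1],
                "icode": addr[2] or "-",
                "q_score": f"{q:.4f}",
                "local_resolution": "" if locres is None else f"{locres:.3f}",
            }
            for addr, (q, locres) in sorted(self.rows.items())
        ]
        pd.DataFrame(
            recs, columns=["chain", "seq_id", "icode", "q_score", "local_resolution"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DeltaMatrix:
    """Signed contact-count differences on mapped residue pairs (A numbering)."""

    category: str
    delta: dict[PairKey, int] = field(default_factory=dict)
    excluded: dict[ResidueAddress, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.delta.values())

    @property
    def total_gain(self) -> int:
        return sum(v for v in self.delta.values() if v > 0)

    @property
    def total_loss(self) -> int:
        return sum(-v for v in self.delta.values() if v < 0)

    def to_tsv(self, path: str | Path) -> None:
        recs = [
            {
                "chain_a": k[0][0],
                "res_a": f"{k[0][1]}{k[0][2]}",
                "chain_b": k[1][0],
                "res_b": f"{k[1][1]}{k[1][2]}",
                "category": self.category,
                "delta": v,
            }
            for k, v in sorted(self.delta.items())
        ]
        pd.DataFrame(
            recs, columns=["chain_a", "res_a", "chain_b", "res_b", "category", "delta"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ResidueDeltaScore:
    """Per-residue (net, gains, losses) with net = gains − losses."""

    scores: dict[ResidueAddress, tuple[int, int, int]] = field(default_factory=dict)

    def net(self, addr: ResidueAddress) -> int:
        return self.scores.get(addr, (0, 0, 0))[0]

    def nets(self) -> dict[ResidueAddress, int]:
        return {addr: s[0] for addr, s in self.scores.items()}

    def to_tsv(self, path: str | Path) -> None:
        recs = [
            {
                "chain": addr[0],
                "seq_id": addr[1],
                "icode": addr[2] or "-",
                "net": net,
                "gains": gains,
                "losses": losses,
            }
            for addr, (net, gains, losses) in sorted(self.scores.items())
        ]
        pd.DataFrame(
            recs, columns=["chain", "seq_id", "icode", "net", "gains", "losses"]
        ).to_csv(path, sep="\t", index=False)


def _excluded_residues(
    residues: set[ResidueAddress],
    rmap: ResidueMap,
    qual_a: QualityTable | None,
    qual_b: QualityTable | None,
    cfg: AnalysisConfig,
) -> dict[ResidueAddress, str]:
    """Exclusion reasons for A-numbered residues: unmapped or low Q either side.

    Residues without a quality row pass the Q filter but are merely
    unassessed — reference models routinely lack Q tables.
    """
    out: dict[ResidueAddress, str] = {}
    for addr in residues:
        if addr not in rmap.mapping:
            out[addr] = "unmapped"
            continue
        q_a = qual_a.q_score(addr) if qual_a else None
        q_b = qual_b.q_score(rmap.mapping[addr]) if qual_b else None
        if (q_a is not None and q_a < cfg.q_exclude) or (
            q_b is not None and q_b < cfg.q_exclude
        ):
            out[addr] = "q_below_threshold"
    return out


def delta_matrix(
    mat_a: ContactMatrix,
    mat_b: ContactMatrix,
    rmap: ResidueMap,
    qual_a: QualityTable | None = None,
    qual_b: QualityTable | None = None,
    cfg: AnalysisConfig | None = None,
) -> DeltaMatrix:
    """Δ = countA − countB per mapped residue pair, after exclusions.

    B-side pairs are translated into A numbering through the residue map;
    missing entries count as zero, so a pair present only in B contributes a
    negative delta. Pairs touching an unmapped or low-Q residue are excluded
    before any summing, with the reason recorded per residue.
    """
    cfg = cfg or AnalysisConfig()
    if mat_a.category != mat_b.category:
        raise ValueError(f"category mismatch: {mat_a.category} vs {mat_b.category}")
    if abs(mat_a.cutoff - mat_b.cutoff) > 1e-9:
        raise ValueError(f"cutoff mismatch: {mat_a.cutoff} vs {mat_b.cutoff}")

    inv = {v: k for k, v in rmap.mapping.items()}

    # Translate B counts to A numbering; unmapped B residues are excluded.
    b_in_a: dict[PairKey, int] = {}
    excluded: dict[ResidueAddress, str] = {}
    for (r1, r2), count in mat_b.counts.items():
        a1, a2 = inv.get(r1), inv.get(r2)
        if a1 is None or a2 is None:
            for r, a in ((r1, a1), (r2, a2)):
                if a is None:
                    excluded[r] = "unmapped_in_reference"
            continue
        b_in_a[pair_key(a1, a2)] = count

    touched = {r for k in mat_a.counts for r in k} | {r for k in b_in_a for r in k}
    excluded.update(_excluded_residues(touched, rmap, qual_a, qual_b, cfg))
    bad = {addr for addr, reason in excluded.items() if reason != "unmapped_in_reference"}

    delta: dict[PairKey, int] = {}
    for key in set(mat_a.counts) | set(b_in_a):
        if key[0] in bad or key[1] in bad:
            continue
        d = mat_a.counts.get(key, 0) - b_in_a.get(key, 0)
        if d != 0:
            delta[key] = d

    n_excl = sum(1 for k in set(mat_a.counts) | set(b_in_a) if k[0] in bad or k[1] in bad)
    if n_excl:
        logger.info(
            "delta_matrix[%s]: excluded %d pairs via %d residues",
            mat_a.category, n_excl, len(bad),
        )
    return DeltaMatrix(category=mat_a.category, delta=delta, excluded=excluded)


def residue_delta_scores(*matrices: DeltaMatrix) -> ResidueDeltaScore:
    """Sum gains and losses across all interaction partners per residue.

    Each pair contributes its delta to both member residues. Several
    Δ-matrices (e.g. all three categories) may be combined in one call.
    """
    gains: dict[ResidueAddress, int] = {}
    losses: dict[ResidueAddress, int] = {}
    for dm in matrices:
        for (r1, r2), d in dm.delta.items():
            for r in (r1, r2):
                if d > 0:
                    gains[r] = gains.get(r, 0) + d
                else:
                    losses[r] = losses.get(r, 0) - d
    out = ResidueDeltaScore()
    for r in set(gains) | set(losses):
        g = gains.get(r, 0)
        l = losses.get(r, 0)
        out.scores[r] = (g - l, g, l)
    return out


def aggregate_scores(
    scores: ResidueDeltaScore, model: StructureModel, mode: str
) -> dict:
    """Aggregate Δ-scores per nucleotide (RNA) or per chain (proteins).

    ``per_nucleotide`` returns RNA residue scores unchanged; ``per_chain``
    sums (net, gains, losses) over each protein chain's residues.
    """
    if mode == "per_nucleotide":
        out = {}
        for res in model.iter_residues(polymer_only=True):
            if res.entity_class == "rna" and res.address in scores.scores:
                out[res.address] = scores.scores[res.address]
        return out
    if mode == "per_chain":
        out = {}
        for chain in model.polymer_chains():
            if chain.entity_class != "protein":
                continue
            net = g = l = 0
            for res in chain.residues:
                s = scores.scores.get(res.address)
                if s:
                    net += s[0]
                    g += s[1]
                    l += s[2]
            out[chain.chain_id] = (net, g, l)
        return out
    raise ValueError(f"unknown aggregation mode {mode!r}")


def flag_significant_sites(
    qual_a: QualityTable,
    qual_b: QualityTable,
    rmap: ResidueMap,
    cfg: AnalysisConfig | None = None,
) -> dict[ResidueAddress, list[str]]:
    """Mapped residues with >10% Q-score change or >0.5 Å local-resolution change.

    The relative Q change uses the baseline (B) value in the denominator.
    Residues not covered by both tables are skipped (logged). Each flag
    records which criterion fired: ``q_change`` and/or ``locres_change``.
    """
    cfg = cfg or AnalysisConfig()
    eps = 1e-9
    flagged: dict[ResidueAddress, list[str]] = {}
    skipped = 0
    for addr_a, addr_b in rmap.mapping.items():
        q_a, q_b = qual_a.q_score(addr_a), qual_b.q_score(addr_b)
        lr_a = qual_a.local_resolution(addr_a)
        lr_b = qual_b.local_resolution(addr_b)
        if q_a is None or q_b is None:
            skipped += 1
            continue
        reasons = []
        if abs(q_a - q_b) / max(abs(q_b), eps) > cfg.q_change_frac:
            reasons.append("q_change")
        if lr_a is not None and lr_b is not None and abs(lr_a - lr_b) > cfg.locres_change:
            reasons.append("locres_change")
        if reasons:
            flagged[addr_a] = reasons
    if skipped:
        logger.info("flag_significant_sites: %d mapped residues lacked quality rows", skipped)
    return flagged


def mutation_neighborhood(
    model: StructureModel,
    sites: SubstitutionList,
    qual: QualityTable | None = None,
    cfg: AnalysisConfig | None = None,
) -> dict[ResidueAddress, set[ResidueAddress]]:
    """Residues with any heavy atom within 10 Å of each mutation site.

    Where the quality table provides a local resolution, neighbors resolved
    worse than ``cfg.min_local_resolution`` (numeric value above it) are
    dropped; the site residue itself is always included.
    """
    import numpy as np
    from scipy.spatial import cKDTree

    cfg = cfg or AnalysisConfig()
    coords, addrs = [], []
    for res in model.iter_residues(polymer_only=True):
        for atom in res.heavy_atoms():
            coords.append(atom.position)
            addrs.append(res.address)
    tree = cKDTree(np.asarray(coords))

    out: dict[ResidueAddress, set[ResidueAddress]] = {}
    for (addr_a, _addr_b), (_ref, _seq, _alt) in zip(sites.addresses, sites.entries):
        site_res = model.get_residue(addr_a)
        if site_res is None:
            raise ValueError(f"mutation site {addr_a} not found in model {model.label}")
        site_coords = np.asarray([a.position for a in site_res.heavy_atoms()])
        hit: set[ResidueAddress] = set()
        for idxs in tree.query_ball_point(site_coords, cfg.neighborhood_radius):
            hit.update(addrs[i] for i in idxs)
        kept = set()
        for addr in hit:
            if addr == addr_a:
                kept.add(addr)
                continue
            locres = qual.local_resolution(addr) if qual else None
            if locres is not None and locres > cfg.min_local_resolution:
                continue
            kept.add(addr)
        kept.add(addr_a)
        out[addr_a] = kept
    return out


def encode_delta_pdb(
    model: StructureModel, scores: ResidueDeltaScore, path: str | Path
) -> int:
    """Write the model with net Δ-scores in the B-factor column.

    Net contact loss is negative (red end of a red-white-blue spectrum), net
    gain positive (blue); viewers colouring by B-factor reproduce the map.
    """
    return write_bfactor_encoded(model, scores.nets(), path)
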