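"""Δ-matrices, quality exclusions, Δ-scores, aggregation, filters."""

import numpy as np
import pytest

import ribodelta as rd
from ribodelta.contact_analysis import pair_key
from ribodelta.delta_contact import DeltaMatrix


def identity_map(model):
    return rd.build_residue_map(rd.pair_chains(model, model), model, model)


def full_quality(model, q=0.8, locres=2.5, override=None):
    rows = {}
    for res in model.iter_residues():
        rows[res.address] = (q, locres)
    if override:
        rows.update(override)
    return rd.QualityTable(rows=rows)


class TestDeltaMatrix:
    def test_self_difference_is_zero(self, toy_model):
        rmap = identity_map(toy_model)
        mats = rd.contact_matrices(toy_model)
        for cat, mat in mats.items():
            dm = rd.delta_matrix(mat, mat, rmap)
            assert dm.delta == {}
            assert dm.total == 0

    def test_planted_deltas_match_ground_truth(self, toy_pair):
        base, variant, truth = toy_pair
        rmap = rd.build_residue_map(rd.pair_chains(variant, base), variant, base)
        mats_v = rd.contact_matrices(variant)
        mats_b = rd.contact_matrices(base)
        for cat in ("rna-rna", "rna-protein", "protein-protein"):
            dm = rd.delta_matrix(mats_v[cat], mats_b[cat], rmap)
            assert dm.delta == truth.contact_deltas[cat]

    def test_low_q_residue_excluded_with_reason(self, toy_model):
        rmap = identity_map(toy_model)
        mats = rd.contact_matrices(toy_model)
        bad = ("A", 15, "")
        qual_b = full_quality(toy_model, override={bad: (0.39, 2.5)})
        qual_a = full_quality(toy_model)
        dm = rd.delta_matrix(mats["rna-rna"], mats["rna-rna"], rmap, qual_a, qual_b)
        assert dm.excluded[bad] == "q_below_threshold"
        assert all(bad not in key for key in dm.delta)

    def test_q_just_above_threshold_retained(self, toy_model):
        rmap = identity_map(toy_model)
        mats = rd.contact_matrices(toy_model)
        ok = ("A", 15, "")
        qual = full_quality(toy_model, override={ok: (0.41, 2.5)})
        dm = rd.delta_matrix(mats["rna-rna"], mats["rna-rna"], rmap, qual, qual)
        assert ok not in dm.excluded

    def test_antisymmetry(self, toy_pair):
        base, variant, _ = toy_pair
        fwd_map = rd.build_residue_map(rd.pair_chains(variant, base), variant, base)
        rev_map = rd.build_residue_map(rd.pair_chains(base, variant), base, variant)
        mats_v = rd.contact_matrices(variant)
        mats_b = rd.contact_matrices(base)
        fwd = rd.delta_matrix(mats_v["rna-rna"], mats_b["rna-rna"], fwd_map)
        rev = rd.delta_matrix(mats_b["rna-rna"], mats_v["rna-rna"], rev_map)
        # Addresses coincide here (no renumbering), so entries must negate.
        assert fwd.delta == {k: -v for k, v in rev.delta.items()}

    def test_category_mismatch_errors(self, toy_model):
        rmap = identity_map(toy_model)
        mats = rd.contact_matrices(toy_model)
        with pytest.raises(ValueError):
            rd.delta_matrix(mats["rna-rna"], mats["rna-protein"], rmap)


class TestResidueDeltaScores:
    def test_simple_arithmetic(self):
        r, s, t = ("A", 1, ""), ("A", 5, ""), ("A", 9, "")
        dm = DeltaMatrix(category="rna-rna", delta={pair_key(r, s): 2, pair_key(r, t): -5})
        scores = rd.residue_delta_scores(dm)
        assert scores.scores[r] == (-3, 2, 5)
        assert scores.scores[s] == (2, 2, 0)
        assert scores.scores[t] == (-5, 0, 5)

    def test_all_zero_delta_gives_no_scores(self):
        scores = rd.residue_delta_scores(DeltaMatrix(category="rna-rna"))
        assert scores.scores == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_identity(self, seed):
        rng = np.random.default_rng(seed)
        addrs = [("A", int(i), "") for i in range(1, 30)]
        delta = {}
        for _ in range(40):
            i, j = rng.choice(len(addrs), size=2, replace=False)
            d = int(rng.integers(-6, 7))
            if d:
                delta[pair_key(addrs[i], addrs[j])] = d
        dm = DeltaMatrix(category="rna-rna", delta=delta)
        scores = rd.residue_delta_scores(dm)
        assert sum(s[0] for s in scores.scores.values()) == 2 * sum(delta.values())


class TestAggregation:
    def test_per_chain_sums_protein_residues(self, toy_model):
        prot = toy_model.get_chain("B")
        r1, r2 = prot.residues[0].address, prot.residues[1].address
        scores = rd.ResidueDeltaScore(scores={r1: (1, 1, 0), r2: (-4, 0, 4)})
        agg = rd.aggregate_scores(scores, toy_model, "per_chain")
        assert agg["B"] == (-3, 1, 4)

    def test_per_chain_on_rna_only_model_is_empty(self):
        model = rd.generate_toy_complex(6, 0, seed=0)
        scores = rd.ResidueDeltaScore(scores={("A", 1, ""): (2, 2, 0)})
        assert rd.aggregate_scores(scores, model, "per_chain") == {}

    def test_per_nucleotide_passes_rna_scores_through(self, toy_model):
        rna_addr = ("A", 3, "")
        prot_addr = ("B", 3, "")
        scores = rd.ResidueDeltaScore(scores={rna_addr: (1, 1, 0), prot_addr: (5, 5, 0)})
        agg = rd.aggregate_scores(scores, toy_model, "per_nucleotide")
        assert agg == {rna_addr: (1, 1, 0)}

    def test_per_chain_equals_brute_force_regrouping(self, toy_pair):
        base, variant, _ = toy_pair
        rmap = rd.build_residue_map(rd.pair_chains(variant, base), variant, base)
        mats_v, mats_b = rd.contact_matrices(variant), rd.contact_matrices(base)
        dms = [
            rd.delta_matrix(mats_v[c], mats_b[c], rmap)
            for c in ("rna-rna", "rna-protein", "protein-protein")
        ]
        scores = rd.residue_delta_scores(*dms)
        agg = rd.aggregate_scores(scores, variant, "per_chain")
        for chain in variant.polymer_chains():
            if chain.entity_class != "protein":
                continue
            expected = sum(
                scores.scores.get(r.address, (0, 0, 0))[0] for r in chain.residues
            )
            assert agg[chain.chain_id][0] == expected


class TestSignificanceFlags:
    def make_map_and_tables(self, qa, qb, lra=2.8, lrb=2.8):
        addr = ("A", 1, "")
        rmap = rd.ResidueMap(mapping={addr: addr})
        qual_a = rd.QualityTable(rows={addr: (qa, lra)})
        qual_b = rd.QualityTable(rows={addr: (qb, lrb)})
        return addr, rmap, qual_a, qual_b

    def test_q_change_above_ten_percent_flagged(self):
        addr, rmap, qa, qb = self.make_map_and_tables(0.70, 0.80)
        flags = rd.flag_significant_sites(qa, qb, rmap)
        assert flags == {addr: ["q_change"]}

    def test_q_change_below_ten_percent_not_flagged(self):
        _, rmap, qa, qb = self.make_map_and_tables(0.74, 0.80)
        assert rd.flag_significant_sites(qa, qb, rmap) == {}

    def test_locres_change_above_half_angstrom_flagged(self):
        addr, rmap, qa, qb = self.make_map_and_tables(0.80, 0.80, lra=3.5, lrb=2.9)
        flags = rd.flag_significant_sites(qa, qb, rmap)
        assert flags == {addr: ["locres_change"]}

    def test_locres_change_below_half_angstrom_not_flagged(self):
        _, rmap, qa, qb = self.make_map_and_tables(0.80, 0.80, lra=3.2, lrb=2.8)
        assert rd.flag_significant_sites(qa, qb, rmap) == {}

    def test_no_flags_on_identical_tables(self, toy_model):
        rmap = identity_map(toy_model)
        qual = full_quality(toy_model)
        assert rd.flag_significant_sites(qual, qual, rmap) == {}


class TestMutationNeighborhood:
    def site_list(self, addr):
        return rd.SubstitutionList(entries=[("A", addr[1], "C")], addresses=[(addr, addr)])

    def test_isolated_residue_is_its_own_neighborhood(self):
        model = rd.generate_toy_complex(6, 0, seed=0)
        lone = model.get_chain("A").residues[0]
        for a in lone.atoms:
            a.position = a.position + np.array([200.0, 0.0, 0.0])
        hoods = rd.mutation_neighborhood(model, self.site_list(lone.address))
        assert hoods[lone.address] == {lone.address}

    def test_neighborhood_equals_brute_force_scan(self, toy_model):
        site = ("A", 10, "")
        hoods = rd.mutation_neighborhood(toy_model, self.site_list(site))
        site_res = toy_model.get_residue(site)
        site_xyz = np.array([a.position for a in site_res.heavy_atoms()])
        expected = set()
        for res in toy_model.iter_residues():
            xyz = np.array([a.position for a in res.heavy_atoms()])
            d = np.linalg.norm(site_xyz[:, None, :] - xyz[None, :, :], axis=2)
            if (d <= 10.0).any():
                expected.add(res.address)
        assert hoods[site] == expected

    def test_poorly_resolved_neighbor_excluded(self, toy_model):
        site = ("A", 10, "")
        neighbor = ("A", 11, "")
        qual = full_quality(toy_model, locres=2.5, override={neighbor: (0.8, 3.4)})
        hoods = rd.mutation_neighborhood(toy_model, self.site_list(site), qual)
        assert neighbor not in hoods[site]
        assert site in hoods[site]

    def test_missing_site_errors(self, toy_model):
        with pytest.raises(ValueError, match="Z"):
            rd.mutation_neighborhood(toy_model, self.site_list(("Z", 1, "")))


class TestEncodeDeltaPdb:
    def test_roundtrip_recovers_nets(self, toy_model, tmp_path):
        scores = rd.ResidueDeltaScore(
            scores={("A", 1, ""): (-3, 0, 3), ("A", 2, ""): (7, 7, 0), ("B", 1, ""): (-99, 0, 99)}
        )
        path = tmp_path / "delta.pdb"
        rd.encode_delta_pdb(toy_model, scores, path)
        reread = rd.read_structure(path)
        for addr, (net, _, _) in scores.scores.items():
            res = reread.get_residue(addr)
            assert all(a.temp_factor == pytest.approx(net, abs=0.005) for a in res.atoms)


class TestQualityTableIO:
    def test_tsv_roundtrip(self, toy_model, tmp_path):
        table = rd.generate_quality_table(toy_model, seed=4)
        path = tmp_path / "qual.tsv"
        table.to_tsv(path)
        back = rd.QualityTable.from_tsv(path)
        assert set(back.rows) == set(table.rows)
        for addr in table.rows:
            assert back.q_score(addr) == pytest.approx(table.q_score(addr), abs=1e-4)
            assert back.local_resolution(addr) == pytest.approx(
                table.local_resolution(addr), abs=1e-3
            )

    def test_q_score_range_enforced(self):
        with pytest.raises(ValueError):
            rd.QualityTable(rows={("A", 1, ""): (1.5, 2.0)})
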