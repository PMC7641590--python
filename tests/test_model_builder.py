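import numpy as np
import pytest

from domainfold.model_builder import (
    ContactRecord,
    ContactSet,
    ModelBuildError,
    PDBParseError,
    assign_charges,
    build_contacts,
    build_dual_basin,
    classify_contacts,
    coarse_grain,
    parse_pdb,
)
from domainfold.synthetic_data import (
    ToySpec,
    _partner_chain_entries,
    _partner_rail,
    _protein_chain_entries,
    make_toy_multidomain,
    write_pdb,
)

THREE_RES_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00
ATOM      3  C   GLY A   1       2.000   0.500   0.000  1.00  0.00
ATOM      4  N   ALA A   2       3.000   1.000   0.000  1.00  0.00
ATOM      5  CA  ALA A   2       3.800   1.200   0.400  1.00  0.00
ATOM      6  C   ALA A   2       4.500   2.000   0.900  1.00  0.00
ATOM      7  CA  SER A   3       7.600   2.400   1.100  1.00  0.00
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY A   1       1.000   0.000   0.000  0.30  0.00
ATOM      2  CA BGLY A   1       2.000   0.000   0.000  0.70  0.00
ATOM      3  CA  GLY A   2       5.000   0.000   0.000  1.00  0.00
END
"""


class TestParsePDB:
    def test_three_residue_fixture(self):
        st = parse_pdb(THREE_RES_PDB)
        assert st.n_residues == 3
        cas = [r.atom("CA").pos for c in st.chains for r in c.residues]
        np.testing.assert_allclose(cas[0], [0.1, 0.0, 0.0])
        np.testing.assert_allclose(cas[1], [0.38, 0.12, 0.04])

    def test_altloc_resolved_to_highest_occupancy(self):
        st = parse_pdb(ALTLOC_PDB)
        res = st.chains[0].residues[0]
        assert len(res.atoms) == 1
        np.testing.assert_allclose(res.atoms[0].pos, [0.2, 0.0, 0.0])

    def test_protein_and_nucleic_chains_recognized(self):
        rail = _partner_rail(3)
        names = ["GLY", "ARG", "GLY", "GLY"]
        pos = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0], [1.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        text = write_pdb([
            ("A", _protein_chain_entries(names, pos)),
            ("B", _partner_chain_entries(rail)),
        ])
        st = parse_pdb(text)
        assert len(st.chains) == 2
        assert all(not r.is_nucleic for r in st.chains[0].residues)
        assert all(r.is_nucleic for r in st.chains[1].residues)
        assert len(st.chains[1].residues) == 3

    def test_waters_excluded(self):
        text = THREE_RES_PDB.replace(
            "END", "HETATM  9 O    HOH A 101       0.000   9.000   0.000  1.00  0.00\nEND"
        )
        assert parse_pdb(text).n_residues == 3

    def test_malformed_record_names_line(self):
        bad = "ATOM      1  CA  GLY A   1       xxx\nEND\n"
        with pytest.raises(PDBParseError, match="line 1"):
            parse_pdb(bad)

    def test_empty_structure_rejected(self):
        with pytest.raises(PDBParseError):
            parse_pdb("END\n")


class TestCoarseGrain:
    def test_polymerase_domain_definition_sizes(self):
        # finger 11-77, palm 1-10 + 78-166, thumb 167-229, linker 230-244,
        # little finger 245-341
        n = 341
        pos = np.zeros((n, 3))
        pos[:, 0] = 0.38 * np.arange(n)
        names = ["GLY"] * n
        text = write_pdb([("A", _protein_chain_entries(names, pos))])
        model = coarse_grain(
            parse_pdb(text),
            {
                "F": [(11, 77)],
                "P": [(1, 10), (78, 166)],
                "T": [(167, 229)],
                "linker": [(230, 244)],
                "LF": [(245, 341)],
            },
        )
        assert model.domain_sizes() == {
            "F": 67, "P": 99, "T": 63, "linker": 15, "LF": 97,
        }

    def test_chain_topology_combinatorics(self):
        pos = np.cumsum(np.tile([[0.3, 0.2, 0.1]], (10, 1)), axis=0)
        text = write_pdb([("A", _protein_chain_entries(["GLY"] * 10, pos))])
        model = coarse_grain(parse_pdb(text))
        assert len(model.bonds) == 9
        assert len(model.angles) == 8
        assert len(model.dihedrals) == 7

    def test_two_nucleotide_dna_gives_six_beads(self):
        text = write_pdb([("B", _partner_chain_entries(_partner_rail(2)))])
        model = coarse_grain(parse_pdb(text))
        assert model.n_beads == 6
        assert model.kinds == ["phosphate", "sugar", "base"] * 2
        assert model.frozen.all()

    def test_uncovered_residue_rejected(self):
        pos = np.cumsum(np.tile([[0.3, 0.2, 0.1]], (5, 1)), axis=0)
        text = write_pdb([("A", _protein_chain_entries(["GLY"] * 5, pos))])
        with pytest.raises(ModelBuildError, match="not covered"):
            coarse_grain(parse_pdb(text), {"A": [(1, 3)]})


class TestCharges:
    def test_charge_rule(self):
        names = ["ARG", "LYS", "ASP", "GLU", "GLY"]
        pos = np.cumsum(np.tile([[0.38, 0.0, 0.0]], (5, 1)), axis=0)
        model = coarse_grain(
            parse_pdb(write_pdb([("A", _protein_chain_entries(names, pos))]))
        )
        np.testing.assert_array_equal(model.charges, [1, 1, -1, -1, 0])

    def test_poly_gly_neutral(self):
        pos = np.cumsum(np.tile([[0.38, 0.0, 0.0]], (6, 1)), axis=0)
        model = coarse_grain(
            parse_pdb(write_pdb([("A", _protein_chain_entries(["GLY"] * 6, pos))]))
        )
        assert not model.charges.any()

    def test_dna_one_negative_phosphate_per_nucleotide(self):
        model = coarse_grain(
            parse_pdb(write_pdb([("B", _partner_chain_entries(_partner_rail(3)))]))
        )
        assert (model.charges == -1).sum() == 3
        assert all(
            model.kinds[i] == "phosphate"
            for i in np.nonzero(model.charges == -1)[0]
        )


def brute_force_contacts(structure, model, cutoff, min_separation):
    """Independent O(N^2) residue-pair scan."""
    residues = []
    for chain in structure.chains:
        for order, res in enumerate(chain.residues):
            residues.append((chain.name, order, res))
    pairs = set()
    bead_of = {}
    for k in range(model.n_beads):
        bead_of.setdefault((model.chain_ids[k], int(model.res_ids[k])), []).append(k)
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            ch_a, o_a, ra = residues[a]
            ch_b, o_b, rb = residues[b]
            if ra.is_nucleic and rb.is_nucleic:
                continue
            if ch_a == ch_b and not ra.is_nucleic and abs(o_a - o_b) < min_separation:
                continue
            dmin = min(
                np.linalg.norm(x.pos - y.pos)
                for x in ra.atoms for y in rb.atoms
            )
            if dmin < cutoff:
                beads_a = bead_of[(ch_a, ra.seqid)]
                beads_b = bead_of[(ch_b, rb.seqid)]
                best = min(
                    ((np.linalg.norm(model.positions[i] - model.positions[j]), i, j)
                     for i in beads_a for j in beads_b),
                )
                pairs.add((min(best[1], best[2]), max(best[1], best[2])))
    return pairs


class TestContacts:
    def test_threshold_and_separation_rules(self):
        # residues 1 and 6 at 0.40 nm: contact; residues 1 and 3 close but
        # below the separation minimum: no contact
        pos = np.array([
            [0.0, 0.0, 0.0], [0.5, 0.0, 0.0], [0.5, 0.5, 0.0],
            [1.2, 0.5, 0.0], [1.2, 0.0, 0.0], [0.0, 0.4, 0.0],
        ])
        text = write_pdb([("A", _protein_chain_entries(["GLY"] * 6, pos))])
        st = parse_pdb(text)
        model = coarse_grain(st)
        cs = build_contacts(st, model, cutoff=0.45, min_separation=4)
        assert {(r.i, r.j) for r in cs} == {(0, 5)}

    def test_cutoff_must_be_positive(self, fold_toy):
        st = parse_pdb(fold_toy.pdb_text)
        with pytest.raises(ValueError):
            build_contacts(st, fold_toy.model, cutoff=-1.0)

    def test_brute_force_oracle_equivalence(self, fold_toy, binding_toy):
        for toy in (fold_toy, binding_toy):
            st = parse_pdb(toy.pdb_text)
            cs = build_contacts(st, toy.model, cutoff=0.75, min_separation=3)
            expected = brute_force_contacts(st, toy.model, 0.75, 3)
            assert {(r.i, r.j) for r in cs} == expected

    def test_classification_matches_interval_oracle(self, fold_toy):
        model = fold_toy.model
        intervals = model.domain_map
        def label(res_id):
            for name, ivs in intervals.items():
                for lo, hi in ivs:
                    if lo <= res_id <= hi:
                        return name
            raise AssertionError
        for r in fold_toy.contacts:
            la = label(int(model.res_ids[r.i]))
            lb = label(int(model.res_ids[r.j]))
            if "linker" in (la, lb):
                assert r.contact_class == "linker"
            elif la == lb:
                assert r.contact_class == f"intra:{la}"
            else:
                assert r.contact_class == "inter:" + "|".join(sorted((la, lb)))

    def test_class_counts_sum_to_total(self, fold_toy, binding_toy):
        for toy in (fold_toy, binding_toy):
            totals = toy.contacts.class_totals()
            assert sum(totals.values()) == len(toy.contacts)

    def test_serialization_deterministic_and_round_trips(self, fold_toy):
        a = make_toy_multidomain()
        b = make_toy_multidomain()
        assert a.contacts.to_csv() == b.contacts.to_csv()
        rt = ContactSet.from_csv(a.contacts.to_csv())
        assert rt.to_csv() == a.contacts.to_csv()

    def test_duplicate_contacts_rejected(self):
        recs = [
            ContactRecord(0, 1, 0.5, "intra:A"),
            ContactRecord(0, 1, 0.6, "intra:A"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            ContactSet(recs)


class TestDualBasin:
    def test_merge_is_apo_plus_binary_difference(self, dual_basin_toy):
        cs = dual_basin_toy.contacts
        apo = {(r.i, r.j) for r in cs if r.basin == "apo"}
        binary = {
            (r.i, r.j) for r in cs
            if r.basin == "binary" and r.contact_class != "binding"
        }
        assert apo and binary
        assert not apo & binary

    def test_apo_set_preserved_by_merge(self):
        apo = ContactSet([ContactRecord(0, 5, 0.5, "intra:A")])
        binary = ContactSet([
            ContactRecord(0, 5, 0.52, "intra:A"),
            ContactRecord(2, 9, 0.6, "inter:A|B"),
        ])
        merged = build_dual_basin(apo, binary)
        kept = [r for r in merged if (r.i, r.j) == (0, 5)]
        assert len(kept) == 1 and kept[0].sigma == 0.5 and kept[0].basin == "apo"
        assert any(r.basin == "binary" for r in merged)

    def test_binding_contact_count_matches_interchain_scan(self, binding_toy):
        st = parse_pdb(binding_toy.pdb_text)
        expected = brute_force_contacts(st, binding_toy.model, 0.75, 3)
        kinds = binding_toy.model.kinds
        inter_chain = {
            (i, j) for i, j in expected
            if (kinds[i] == "CA") != (kinds[j] == "CA")
        }
        got = {(r.i, r.j) for r in binding_toy.contacts.by_class("binding")}
        assert got == inter_chain
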