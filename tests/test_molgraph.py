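"""Molecular graphs, atom typing, distances and pair fingerprints."""

import itertools

import numpy as np
import pytest

from qsardnn.molgraph import (
    Atom,
    Bond,
    BPCategory,
    FingerprintVector,
    MolecularGraph,
    PairDescriptorKey,
    ap_atom_type,
    bp_atom_type,
    generate_fingerprint,
    graph_from_rdkit,
    merge_fingerprints,
    read_sdf,
    topological_distances,
)
from qsardnn.synthetic import EXPECTED_AP_FINGERPRINTS

from _oracles import brute_force_fingerprint, random_graph


class TestGraphInvariants:
    def test_needs_at_least_one_atom(self):
        with pytest.raises(ValueError):
            MolecularGraph(atoms=[])

    def test_rejects_explicit_hydrogen(self):
        with pytest.raises(ValueError):
            Atom("H")

    def test_rejects_self_bond_and_duplicates(self):
        with pytest.raises(ValueError):
            Bond(1, 1)
        atoms = [Atom("C"), Atom("C")]
        with pytest.raises(ValueError, match="duplicate"):
            MolecularGraph(atoms, [Bond(0, 1), Bond(1, 0)])

    def test_rejects_out_of_range_bond(self):
        with pytest.raises(ValueError, match="out of range"):
            MolecularGraph([Atom("C")], [Bond(0, 1)])


class TestAtomTyping:
    @pytest.mark.parametrize(
        "name, index, expected",
        [
            ("propane", 0, "C(1,0)"),  # terminal carbon
            ("propane", 1, "C(2,0)"),  # central carbon
            ("methane", 0, "C(0,0)"),  # lone heavy atom
            ("benzene", 0, "C(2,2)"),  # two aromatic bonds -> 2 pi electrons
            ("ethanol", 2, "O(1,0)"),
        ],
    )
    def test_ap_types(self, toys, name, index, expected):
        assert str(ap_atom_type(toys[name], index)) == expected

    def test_ap_type_round_trips(self, toys):
        from qsardnn.molgraph import APAtomType

        t = ap_atom_type(toys["propane"], 1)
        assert APAtomType.from_text(str(t)) == t

    def test_pi_electron_convention(self):
        # C=C: 1 pi each; C#N: 2 pi each
        ene = MolecularGraph([Atom("C", attached_hydrogens=2)] * 2, [Bond(0, 1, "double")])
        assert ene.pi_electrons(0) == ene.pi_electrons(1) == 1
        nitrile = MolecularGraph([Atom("C"), Atom("N")], [Bond(0, 1, "triple")])
        assert nitrile.pi_electrons(0) == 2

    @pytest.mark.parametrize(
        "name, index, expected",
        [
            ("propane", 1, BPCategory.HYDROPHOBIC),  # sp3 C, no heteroatoms
            ("ethanol", 2, BPCategory.POLAR),  # hydroxyl O: donor + acceptor
        ],
    )
    def test_bp_types(self, toys, name, index, expected):
        assert bp_atom_type(toys[name], index) == expected

    def test_charged_nitrogen_is_cation(self):
        g = MolecularGraph([Atom("N", formal_charge=1, attached_hydrogens=0)])
        assert bp_atom_type(g, 0) == BPCategory.CATION

    def test_carboxylate_oxygen_is_anion(self):
        g = MolecularGraph([Atom("O", formal_charge=-1)])
        assert bp_atom_type(g, 0) == BPCategory.ANION

    def test_pyridine_nitrogen_is_acceptor_pyrrole_is_donor(self):
        ring = [Atom("C", attached_hydrogens=1)] * 5
        pyridine = MolecularGraph(
            [*ring, Atom("N")],
            [Bond(i, (i + 1) % 6, "aromatic") for i in range(6)],
        )
        assert bp_atom_type(pyridine, 5) == BPCategory.NEUTRAL_ACCEPTOR
        pyrrole = MolecularGraph(
            [Atom("C", attached_hydrogens=1)] * 4 + [Atom("N", attached_hydrogens=1)],
            [Bond(i, (i + 1) % 5, "aromatic") for i in range(5)],
        )
        assert bp_atom_type(pyrrole, 4) == BPCategory.NEUTRAL_DONOR

    def test_sulfur_is_other(self):
        g = MolecularGraph([Atom("S")])
        assert bp_atom_type(g, 0) == BPCategory.OTHER

    def test_exactly_one_category_per_atom(self, rng):
        for _ in range(50):
            g = random_graph(rng)
            for i in range(g.n_atoms):
                assert bp_atom_type(g, i) in BPCategory

    def test_index_out_of_range(self, toys):
        with pytest.raises(IndexError):
            ap_atom_type(toys["propane"], 3)
        with pytest.raises(IndexError):
            bp_atom_type(toys["propane"], -1)


class TestTopologicalDistances:
    def test_bonded_pair_distance_one(self):
        g = MolecularGraph([Atom("C"), Atom("C")], [Bond(0, 1)])
        d = topological_distances(g)
        assert d[0, 1] == 1 and d[1, 0] == 1 and d[0, 0] == 0

    def test_benzene_opposite_atoms(self, toys):
        d = topological_distances(toys["benzene"])
        assert d[0, 3] == 3  # ring diameter

    def test_disconnected_pair_infinite(self, toys):
        d = topological_distances(toys["ethane_plus_methane"])
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 2])

    def test_symmetry_zero_diagonal_triangle_inequality(self, rng):
        for _ in range(30):
            g = random_graph(rng)
            d = topological_distances(g)
            assert np.array_equal(d, d.T)
            assert np.all(np.diag(d) == 0)
            finite = np.isfinite(d)
            for i, j, k in itertools.permutations(range(g.n_atoms), 3):
                if finite[i, j] and finite[j, k]:
                    assert d[i, k] <= d[i, j] + d[j, k]
            if g.n_atoms > 6:
                break  # keep the O(n^3) loop cheap


class TestFingerprints:
    def test_propane_ap_example(self, toys):
        fp = generate_fingerprint(toys["propane"], "AP", 7)
        assert fp.to_text_counts() == {
            "AP|C(1,0)|1|C(2,0)": 2,
            "AP|C(1,0)|2|C(1,0)": 1,
        }

    def test_single_atom_empty(self, toys):
        assert len(generate_fingerprint(toys["methane"], "AP", 7)) == 0
        assert len(generate_fingerprint(toys["methane"], "BP", 7)) == 0

    def test_ethanol_distance_one_only(self, toys):
        fp = generate_fingerprint(toys["ethanol"], "AP", 1)
        assert fp.to_text_counts() == {
            "AP|C(1,0)|1|C(2,0)": 1,
            "AP|C(2,0)|1|O(1,0)": 1,
        }

    @pytest.mark.parametrize("name", sorted(EXPECTED_AP_FINGERPRINTS))
    def test_fixture_fingerprints(self, toys, name):
        fp = generate_fingerprint(toys[name], "AP", 7)
        assert fp.to_text_counts() == EXPECTED_AP_FINGERPRINTS[name]

    @pytest.mark.parametrize("scheme", ["AP", "BP"])
    def test_matches_brute_force_oracle(self, rng, scheme):
        for _ in range(60):
            g = random_graph(rng)
            fp = generate_fingerprint(g, scheme, 7)
            assert fp.to_text_counts() == brute_force_fingerprint(g, scheme, 7)

    def test_total_counts_pair_bound(self, rng):
        """Sum of counts is n(n-1)/2 when the cutoff covers the diameter."""
        for _ in range(40):
            g = random_graph(rng)
            n = g.n_atoms
            fp = generate_fingerprint(g, "AP", max_distance=max(1, n))
            d = topological_distances(g)
            if np.all(np.isfinite(d)):
                assert fp.total() == n * (n - 1) // 2
            else:
                assert fp.total() <= n * (n - 1) // 2

    def test_invariant_under_atom_relabeling(self, rng):
        for _ in range(25):
            g = random_graph(rng)
            perm = rng.permutation(g.n_atoms)
            mapping = {old: new for new, old in enumerate(perm)}
            relabeled = MolecularGraph(
                atoms=[g.atoms[old] for old in perm],
                bonds=[Bond(mapping[b.i], mapping[b.j], b.order) for b in g.bonds],
            )
            for scheme in ("AP", "BP"):
                assert generate_fingerprint(g, scheme, 7) == generate_fingerprint(
                    relabeled, scheme, 7
                )

    def test_invalid_arguments(self, toys):
        with pytest.raises(ValueError):
            generate_fingerprint(toys["propane"], "XX", 7)
        with pytest.raises(ValueError):
            generate_fingerprint(toys["propane"], "AP", 0)


class TestMergeAndKeys:
    def test_merge_is_disjoint_union_with_additive_totals(self, toys):
        ap = generate_fingerprint(toys["propane"], "AP", 7)
        bp = generate_fingerprint(toys["propane"], "BP", 7)
        merged = merge_fingerprints(ap, bp)
        assert merged.total() == ap.total() + bp.total()
        assert len(merged) == len(ap) + len(bp)
        for k in ap:
            assert merged[k] == ap[k]

    def test_merge_empty(self):
        assert merge_fingerprints(FingerprintVector(), FingerprintVector()).total() == 0

    def test_merge_scheme_mismatch(self, toys):
        bp = generate_fingerprint(toys["propane"], "BP", 7)
        with pytest.raises(ValueError):
            merge_fingerprints(bp, bp)

    def test_key_canonicalization_and_round_trip(self):
        k = PairDescriptorKey(scheme="AP", type_a="O(1,0)", distance=2, type_b="C(1,0)")
        assert (k.type_a, k.type_b) == ("C(1,0)", "O(1,0)")
        assert PairDescriptorKey.from_text(k.to_text()) == k
        with pytest.raises(ValueError):
            PairDescriptorKey(scheme="AP", type_a="C", distance=0, type_b="C")


class TestRDKitBridge:
    def test_smiles_ethanol_matches_toy(self, toys):
        from rdkit import Chem

        g = graph_from_rdkit(Chem.MolFromSmiles("CCO"))
        assert generate_fingerprint(g, "AP", 7) == generate_fingerprint(
            toys["ethanol"], "AP", 7
        )

    def test_sdf_round_trip(self, tmp_path, toys):
        from rdkit import Chem

        mol = Chem.MolFromSmiles("c1ccccc1")
        path = tmp_path / "benzene.sdf"
        with Chem.SDWriter(str(path)) as w:
            w.write(mol)
        (graph,) = read_sdf(path)
        assert generate_fingerprint(graph, "AP", 7) == generate_fingerprint(
            toys["benzene"], "AP", 7
        )
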