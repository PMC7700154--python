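"""Fragment enumeration: hand-counted examples, closed forms, brute-force oracle."""

from collections import Counter
from itertools import combinations, permutations

import numpy as np
import pytest

from movscreen.fragments import (
    DescriptorTable,
    FragmentConfig,
    MolecularGraph,
    build_descriptor_table,
    enumerate_atom_centered_fragments,
    enumerate_sequence_fragments,
    enumerate_triplet_fragments,
)


def _propane():
    return MolecularGraph.from_smiles("CCC")


# ---------------------------------------------------------------------------
# independent oracles (permutation-based, not DFS)


def _oracle_sequences(g, min_len, max_len):
    """Count simple paths by checking every atom permutation of each size."""
    counts = Counter()
    bond = {}
    for i, j, order in g.bonds:
        sym = {1: "-", 2: "=", 3: "#", "ar": "~"}[order]
        bond[(i, j)] = bond[(j, i)] = sym
    for k in range(min_len, max_len + 1):
        for perm in permutations(range(g.n_atoms), k):
            if any((perm[t], perm[t + 1]) not in bond for t in range(k - 1)):
                continue
            parts = [g.atom_symbol(perm[0])]
            for t in range(k - 1):
                parts += [bond[(perm[t], perm[t + 1])], g.atom_symbol(perm[t + 1])]
            s = "".join(parts)
            counts[min(s, "".join(reversed(parts)))] += 1
    return Counter({lab: c // 2 for lab, c in counts.items()})


def _oracle_triplets(g):
    """Count triples via explicit Floyd-Warshall distances."""
    n = g.n_atoms
    INF = 10**6
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for i, j, _ in g.bonds:
        d[i][j] = d[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i][j] = min(d[i][j], d[i][k] + d[k][j])
    counts = Counter()
    for i, j, k in combinations(range(n), 3):
        trio = (d[i][j], d[i][k], d[j][k])
        if max(trio) >= INF:
            continue
        syms = sorted((g.atom_symbol(i), g.atom_symbol(j), g.atom_symbol(k)))
        counts[",".join(syms) + ";" + ",".join(map(str, sorted(trio)))] += 1
    return counts


class TestSequences:
    def test_propane_hand_count(self):
        counts = enumerate_sequence_fragments(_propane())
        assert counts == Counter({"C-C": 2, "C-C-C": 1})

    def test_single_atom_is_empty(self):
        g = MolecularGraph.from_smiles("C")
        assert enumerate_sequence_fragments(g) == Counter()

    def test_benzene_two_atom_paths_collapse(self):
        g = MolecularGraph.from_smiles("c1ccccc1")
        counts = enumerate_sequence_fragments(g, 2, 2)
        assert counts == Counter({"Ca~Ca": 6})

    @pytest.mark.parametrize("n", range(2, 9))
    def test_linear_alkane_closed_form(self, n):
        """A path graph of n atoms has n-k+1 simple paths of k atoms."""
        g = MolecularGraph.from_smiles("C" * n)
        counts = enumerate_sequence_fragments(g, 2, 8)
        for k in range(2, n + 1):
            label = "-".join(["C"] * k)
            assert counts[label] == n - k + 1

    def test_relabeling_invariance(self):
        g = MolecularGraph.from_smiles("CC(O)C=O")
        perm = [3, 1, 4, 0, 2]
        inv = {old: new for new, old in enumerate(perm)}
        shuffled = MolecularGraph(
            atoms=tuple(g.atoms[i] for i in perm),
            bonds=tuple((inv[i], inv[j], o) for i, j, o in g.bonds),
        )
        assert enumerate_sequence_fragments(g) == enumerate_sequence_fragments(shuffled)
        assert enumerate_triplet_fragments(g) == enumerate_triplet_fragments(shuffled)


class TestAtomCentered:
    def test_isolated_atom_encodes_center_only(self):
        g = MolecularGraph.from_smiles("C")
        assert enumerate_atom_centered_fragments(g) == Counter({"C()": 1})

    def test_propane_fixed_length_two(self):
        counts = enumerate_atom_centered_fragments(_propane(), fixed_length=2)
        # central atom: two C-C branches; terminals: one each (isomorphic)
        assert counts == Counter({"C(-C|-C)": 1, "C(-C)": 2})

    def test_terminal_atoms_isomorphic(self):
        counts = enumerate_atom_centered_fragments(_propane(), max_len=8)
        # both terminal atoms must map to the same label
        assert max(counts.values()) == 2

    def test_fixed_length_bounds(self):
        with pytest.raises(ValueError):
            enumerate_atom_centered_fragments(_propane(), fixed_length=9)


class TestTriplets:
    def test_propane_single_triple(self):
        counts = enumerate_triplet_fragments(_propane())
        assert counts == Counter({"C,C,C;1,1,2": 1})

    def test_two_atoms_empty(self):
        assert enumerate_triplet_fragments(MolecularGraph.from_smiles("CC")) == Counter()

    def test_benzene_three_distance_classes(self):
        counts = enumerate_triplet_fragments(MolecularGraph.from_smiles("c1ccccc1"))
        assert sum(counts.values()) == 20  # C(6,3)
        assert len(counts) == 3  # {1,1,2}, {1,2,3}, {2,2,2}

    def test_disconnected_triples_skipped(self):
        g = MolecularGraph.from_smiles("CC.O")
        assert enumerate_triplet_fragments(g) == Counter()


class TestOracleEquivalence:
    def test_twenty_small_molecules(self, small_library):
        """DFS counts equal exhaustive permutation enumeration on molecules
        of at most 10 heavy atoms."""
        from rdkit import Chem

        mols = [s for _, s in small_library
                if Chem.MolFromSmiles(s).GetNumHeavyAtoms() <= 10][:17]
        mols += ["c1ccccc1", "CC(C)C(=O)O", "C1CC1CO"]  # ring/branch coverage
        assert len(mols) >= 20
        for smi in mols:
            g = MolecularGraph.from_smiles(smi)
            assert enumerate_sequence_fragments(g, 2, 6) == _oracle_sequences(g, 2, 6), smi
            assert enumerate_triplet_fragments(g) == _oracle_triplets(g), smi


class TestDescriptorTable:
    def test_duplicate_molecules_identical_rows(self):
        table = build_descriptor_table([("a", "CCO"), ("b", "CCO")])
        assert np.array_equal(
            table.matrix[0].toarray(), table.matrix[1].toarray()
        )

    def test_empty_compound_list(self):
        table = build_descriptor_table([])
        assert table.shape == (0, 0)

    def test_disjoint_chemistries_share_no_sequence_columns(self):
        cfg = FragmentConfig(atom_centered=False, triplets=False)
        alkane = build_descriptor_table([("a", "CCCC")], cfg)
        aromatic = build_descriptor_table([("b", "c1ccccc1")], cfg)
        assert not set(alkane.labels) & set(aromatic.labels)

    def test_column_order_lexicographic(self, small_library):
        table = build_descriptor_table(small_library[:10])
        assert table.labels == sorted(table.labels)

    def test_dense_for_imputes_missing_as_zero(self):
        table = build_descriptor_table([("a", "CCO")])
        dense = table.dense_for(["S|C-C", "S|nonexistent"])
        assert dense[0, 1] == 0.0 and dense[0, 0] > 0

    def test_mtx_round_trip(self, tmp_path, small_library):
        table = build_descriptor_table(small_library[:5])
        table.save(tmp_path / "tbl")
        back = DescriptorTable.load(tmp_path / "tbl")
        assert back.ids == table.ids and back.labels == table.labels
        assert (back.matrix != table.matrix).nnz == 0
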