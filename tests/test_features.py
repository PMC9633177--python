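"""Fragment enumeration, Z-score statistics, pruning and group profiling."""

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from bbbqsar import features, synthdata
from bbbqsar.features import (
    FeatureMatrix,
    Fragment,
    PruneConfig,
    ScaffoldConfig,
    build_feature_matrix,
    enumerate_linear_fragments,
    enumerate_scaffolds,
    feature_statistics,
    functional_group_profile,
    molecule_path_labels,
    prune_features,
)


def mol(smiles):
    m = Chem.MolFromSmiles(smiles)
    assert m is not None
    return m


def brute_force_path_labels(m, min_atoms, max_atoms):
    """Independent oracle: all simple paths via networkx, labelled by hand."""
    bond_sym = {
        Chem.BondType.SINGLE: "-",
        Chem.BondType.DOUBLE: "=",
        Chem.BondType.TRIPLE: "#",
        Chem.BondType.AROMATIC: ":",
    }

    def label_atom(a):
        s = a.GetSymbol()
        if a.GetIsAromatic():
            return s.lower()
        return s + "R" if a.IsInRing() else s

    g = nx.Graph()
    for a in m.GetAtoms():
        g.add_node(a.GetIdx())
    for b in m.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    labels = set()
    nodes = list(g.nodes)
    for i in nodes:
        for j in nodes:
            if i >= j:
                continue
            for path in nx.all_simple_paths(g, i, j, cutoff=max_atoms - 1):
                if not (min_atoms <= len(path) <= max_atoms):
                    continue
                atoms = [label_atom(m.GetAtomWithIdx(k)) for k in path]
                bonds = [
                    bond_sym[m.GetBondBetweenAtoms(a, b).GetBondType()]
                    for a, b in zip(path, path[1:])
                ]
                fwd = atoms[0] + "".join(s + a for s, a in zip(bonds, atoms[1:]))
                rev_atoms = atoms[::-1]
                rev_bonds = bonds[::-1]
                bwd = rev_atoms[0] + "".join(s + a for s, a in zip(rev_bonds, rev_atoms[1:]))
                labels.add(min(fwd, bwd))
    return labels


class TestLinearFragments:
    def test_ethanol_paths(self):
        got = {f.fragment_id for f in enumerate_linear_fragments(mol("CCO"), 2, 3)}
        assert got == {"C-C", "C-O", "C-C-O"}

    def test_methane_has_no_paths(self):
        assert enumerate_linear_fragments(mol("C"), 2, 3) == set()

    def test_benzene_three_paths_collapse_by_symmetry(self):
        got = {f.fragment_id for f in enumerate_linear_fragments(mol("c1ccccc1"), 3, 3)}
        assert got == {"c:c:c"}

    def test_cyclic_vs_acyclic_environment_distinguished(self):
        cyclic = {f.fragment_id for f in enumerate_linear_fragments(mol("C1CCNCC1"), 2, 2)}
        acyclic = {f.fragment_id for f in enumerate_linear_fragments(mol("CCNCC"), 2, 2)}
        assert "CR-NR" in cyclic
        assert "C-N" in acyclic
        assert cyclic.isdisjoint(acyclic)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            enumerate_linear_fragments(mol("CCO"), 1, 3)

    @pytest.mark.parametrize(
        "smiles",
        ["CCO", "c1ccccc1", "C1CCNCC1", "CC(=O)O", "c1ccc2[nH]ccc2c1", "CS(N)(=O)=O",
         "OCc1ccccc1", "C1COCCN1", "N#Cc1ccco1"],
    )
    def test_matches_brute_force_oracle(self, smiles):
        m = mol(smiles)
        assert m.GetNumHeavyAtoms() <= 12
        got = {f.fragment_id for f in enumerate_linear_fragments(m, 2, 7)}
        assert got == brute_force_path_labels(m, 2, 7)

    def test_atom_order_permutation_invariance(self):
        m = mol("CC(=O)Nc1ccc(O)cc1")
        base = molecule_path_labels(m, 2, 7)
        rng = np.random.default_rng(0)
        for _ in range(5):
            order = rng.permutation(m.GetNumAtoms()).tolist()
            shuffled = Chem.RenumberAtoms(m, order)
            assert molecule_path_labels(shuffled, 2, 7) == base


class TestScaffolds:
    def test_indole_scaffold_emitted_with_three_carriers(self):
        mols = [mol(s) for s in [
            "c1ccc2[nH]ccc2c1", "Cc1ccc2[nH]ccc2c1", "OCc1ccc2[nH]ccc2c1",
            "CCO", "CCN",
        ]]
        labels = [1, 1, 1, 0, 0]
        got = {f.fragment_id for f in enumerate_scaffolds(mols, labels)}
        indole = Chem.MolToSmiles(mol("c1ccc2[nH]ccc2c1"))
        assert indole in got

    def test_two_carrier_scaffold_not_emitted(self):
        mols = [mol(s) for s in ["c1ccc2[nH]ccc2c1", "Cc1ccc2[nH]ccc2c1", "CCO", "CCN", "CCC"]]
        labels = [1, 1, 0, 0, 0]
        got = {f.fragment_id for f in enumerate_scaffolds(mols, labels)}
        assert Chem.MolToSmiles(mol("c1ccc2[nH]ccc2c1")) not in got

    def test_small_ring_system_fails_size_constraint(self):
        mols = [mol("C1CCCC1"), mol("CC1CCCC1"), mol("OC1CCCC1"), mol("CCO"), mol("CCN")]
        labels = [1, 1, 1, 0, 0]
        got = {f.fragment_id for f in enumerate_scaffolds(mols, labels)}
        assert Chem.MolToSmiles(mol("C1CCCC1")) not in got  # 5 atoms < 6

    def test_weak_z_scaffold_not_emitted(self):
        # benzene carried equally by both classes: |z| ~ 0
        mols = [mol(s) for s in ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1"]]
        labels = [1, 0, 1, 0]
        got = enumerate_scaffolds(mols, labels, ScaffoldConfig(min_compounds=3, min_atoms=6))
        assert got == set()


class TestFeatureMatrix:
    def test_substructure_membership(self):
        frags = [Fragment("c:c:c", "linear_path", 3)]
        m = build_feature_matrix([mol("Cc1ccccc1"), mol("CCO")], frags)
        assert m.values[0, 0] and not m.values[1, 0]

    def test_shape_and_binary(self, small_dataset):
        _, mols, _ = small_dataset
        frags = [Fragment("C-C", "linear_path", 2), Fragment("O-C=O", "linear_path", 3)]
        m = build_feature_matrix(mols[:50], frags)
        assert m.values.shape == (50, 2)
        assert m.values.dtype == bool

    def test_column_sums_equal_per_molecule_counts(self):
        mols = [mol(s) for s in ["CCO", "CCN", "CCC"]]
        frags = [Fragment(x, "linear_path", 2) for x in ["C-C", "C-O", "C-N"]]
        m = build_feature_matrix(mols, frags)
        assert m.values.sum(axis=0).sum() == m.values.sum(axis=1).sum()


class TestFeatureStatistics:
    def _matrix(self, column):
        return FeatureMatrix(
            compound_ids=[f"c{i}" for i in range(len(column))],
            fragments=[Fragment("X", "linear_path", 2)],
            values=np.array(column, dtype=bool).reshape(-1, 1),
        )

    def test_worked_proportion_example(self):
        # 100 compounds at base rate 0.5; feature in 16 of them, 12 positive
        labels = np.zeros(100, dtype=int)
        labels[:50] = 1
        col = np.zeros(100, dtype=bool)
        col[:12] = True      # positives carrying the feature
        col[50:54] = True    # negatives carrying the feature
        (s,) = feature_statistics(self._matrix(col), labels)
        assert s.frequency == 16 and s.n_positive == 12
        assert s.z_raw == pytest.approx(0.25)
        assert s.z_std == pytest.approx(2.0)
        assert s.precision == pytest.approx(0.75)

    def test_ubiquitous_feature_has_zero_z(self):
        labels = [1, 0, 1, 0]
        (s,) = feature_statistics(self._matrix([1, 1, 1, 1]), labels)
        assert s.z_raw == 0.0 and s.z_std == 0.0

    def test_all_positive_small_subset(self):
        # feature in 4 compounds, all positive, base rate 0.5 -> z_std 2.0
        labels = np.zeros(8, dtype=int)
        labels[:4] = 1
        (s,) = feature_statistics(self._matrix([1, 1, 1, 1, 0, 0, 0, 0]), labels)
        assert s.z_raw == pytest.approx(0.5)
        assert s.z_std == pytest.approx(2.0)

    def test_z_scales_with_sqrt_frequency(self):
        # same rate difference, 4x frequency -> 2x z_std
        labels = np.array([1] * 32 + [0] * 32)
        small = np.zeros(64, dtype=bool)
        small[:4] = True
        big = np.zeros(64, dtype=bool)
        big[:16] = True
        (s1,) = feature_statistics(self._matrix(small), labels)
        (s2,) = feature_statistics(self._matrix(big), labels)
        assert s2.z_std == pytest.approx(2 * s1.z_std)


class TestPruning:
    def _setup(self, cols, z_stats=None, labels=None):
        n = len(cols[0])
        labels = labels if labels is not None else np.array([1, 0] * (n // 2))
        frags = [Fragment(f"F{i}", "linear_path", 2 + i) for i in range(len(cols))]
        matrix = FeatureMatrix(
            compound_ids=[f"c{i}" for i in range(n)],
            fragments=frags,
            values=np.array(cols, dtype=bool).T,
        )
        return matrix, feature_statistics(matrix, labels), labels

    def test_identical_columns_keep_exactly_one(self):
        col = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0])
        matrix, stats, _ = self._setup([col, col], labels=labels)
        kept = prune_features(stats, matrix, PruneConfig(min_count=1, min_abs_z=0.0))
        assert len(kept) == 1

    def test_low_z_removed(self):
        strong = [1, 1, 1, 1, 0, 0, 0, 0]
        weak = [1, 0, 1, 0, 1, 0, 1, 0]
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        matrix, stats, _ = self._setup([strong, weak], labels=labels)
        kept = prune_features(stats, matrix, PruneConfig(min_count=1, min_abs_z=1.0))
        assert kept == ["F0"]

    def test_all_pruned_raises_actionable_error(self):
        col = [1, 0, 1, 0]
        matrix, stats, _ = self._setup([col])
        with pytest.raises(ValueError, match="relax"):
            prune_features(stats, matrix, PruneConfig(min_count=10, min_abs_z=5.0))

    def test_tie_prefers_smaller_fragment(self):
        col = [1, 1, 1, 0, 0, 0, 1, 0]
        labels = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        matrix, stats, _ = self._setup([col, col], labels=labels)  # F0 has 2 atoms, F1 has 3
        kept = prune_features(stats, matrix, PruneConfig(min_count=1, min_abs_z=0.0))
        assert kept == ["F0"]


class TestFunctionalGroups:
    def test_acid_matches_and_benzene_does_not(self):
        df = functional_group_profile(
            [mol("CC(=O)O"), mol("c1ccccc1")],
            {"carboxylic_acid": "[CX3](=O)[OX2H1]"},
            labels=[0, 1],
        )
        row = df.iloc[0]
        assert row.n_total == 1 and row.n_positive == 0

    def test_invalid_pattern_names_group(self):
        with pytest.raises(ValueError, match="broken"):
            functional_group_profile([mol("CCO")], {"broken": "[[["})

    def test_default_library_counts_acids_in_synthetic_set(self, small_dataset):
        records, mols, labels = small_dataset
        df = functional_group_profile(mols, labels=labels).set_index("group")
        acid = df.loc["carboxylic_acid"]
        carriers = sum("carboxylic_acid" in r.planted_fragments for r in records)
        assert acid.n_total == carriers
        # planted -2.5 logit effect: acids overwhelmingly negative
        assert acid.n_positive < 0.25 * acid.n_total
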