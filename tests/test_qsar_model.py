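"""Fitting, domain rules, classification and serialization of both model styles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from bbbqsar import descriptors, qsar_model, synthdata
from bbbqsar.features import FeatureMatrix, Fragment
from bbbqsar.qsar_model import (
    Call,
    CallValue,
    CUConfig,
    LSConfig,
    LSModel,
    applicability_domain_cu,
    applicability_domain_ls,
    classify,
    fit_cu_style,
    fit_ls_style,
    model_from_json,
    model_to_json,
    predict,
    prepare_ls_features,
    select_threshold,
    tanimoto,
)


def mol(smiles):
    m = Chem.MolFromSmiles(smiles)
    assert m is not None
    return m


class TestClassify:
    @pytest.mark.parametrize(
        "p,pos,neg,expected",
        [
            (0.61, 0.6, 0.4, CallValue.POSITIVE),
            (0.50, 0.6, 0.4, CallValue.EQUIVOCAL),
            (0.60, 0.6, 0.4, CallValue.EQUIVOCAL),  # boundary is equivocal
            (0.40, 0.6, 0.4, CallValue.EQUIVOCAL),
            (0.39, 0.6, 0.4, CallValue.NEGATIVE),
            (0.55, 0.65, 0.45, CallValue.EQUIVOCAL),  # CU band around 0.55
            (0.44, 0.65, 0.45, CallValue.NEGATIVE),
            (0.66, 0.65, 0.45, CallValue.POSITIVE),
        ],
    )
    def test_bands(self, p, pos, neg, expected):
        assert classify(p, pos, neg) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2, 0.6, 0.4)

    @settings(derandomize=True, max_examples=100)
    @given(p1=st.floats(0, 1), p2=st.floats(0, 1))
    def test_monotone_no_inversion(self, p1, p2):
        order = {CallValue.NEGATIVE: 0, CallValue.EQUIVOCAL: 1, CallValue.POSITIVE: 2}
        if p1 >= p2:
            assert order[classify(p1, 0.6, 0.4)] >= order[classify(p2, 0.6, 0.4)]


class TestTanimoto:
    def test_identity_disjoint_symmetry(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        b = np.array([0, 0, 1, 1], dtype=bool)
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, b) == 0.0
        assert tanimoto(a, b) == tanimoto(b, a)

    def test_partial_overlap(self):
        a = np.array([1, 1, 1, 0], dtype=bool)
        b = np.array([1, 0, 0, 1], dtype=bool)
        assert tanimoto(a, b) == pytest.approx(1 / 4)


class TestSelectThreshold:
    def test_perfect_separation(self):
        t = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < t < 0.8
        # sens = spec = 1 at that threshold
        s = np.array([0.1, 0.2, 0.8, 0.9]) > t
        assert s.tolist() == [False, False, True, True]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.9], [1, 1])

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.5, 0.5, 0.5], [0, 1, 0])

    def test_balance_optimal_against_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = (rng.random(200) < scores).astype(int)
        t = select_threshold(scores, labels)

        def balance(th):
            pred = scores > th
            return abs(pred[labels == 1].mean() - (~pred[labels == 0]).mean())

        uniq = np.unique(scores)
        candidates = (uniq[:-1] + uniq[1:]) / 2
        assert balance(t) <= min(balance(c) for c in candidates) + 1e-12


class TestLSFit:
    def _toy(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        col = y.astype(bool)  # one perfectly separating feature
        matrix = FeatureMatrix(
            compound_ids=[f"c{i}" for i in range(n)],
            fragments=[Fragment("SEP", "linear_path", 2)],
            values=col.reshape(-1, 1),
        )
        D = rng.normal(size=(n, 8))
        return matrix, D, y

    def test_separating_feature_gets_positive_weight(self):
        matrix, D, y = self._toy()
        model = fit_ls_style(matrix, D, y)
        assert model.feature_weights[0] > 0
        probs = [model.probability(matrix.values[i], D[i]) for i in range(len(y))]
        assert all(p > model.pos_cutoff for p, label in zip(probs, y) if label == 1)
        assert all(p < model.neg_cutoff for p, label in zip(probs, y) if label == 0)

    def test_single_class_rejected(self):
        matrix, D, y = self._toy()
        with pytest.raises(ValueError):
            fit_ls_style(matrix, D, np.ones_like(y))

    def test_deterministic_given_seed(self):
        matrix, D, y = self._toy()
        m1 = fit_ls_style(matrix, D, y, LSConfig(seed=5))
        m2 = fit_ls_style(matrix, D, y, LSConfig(seed=5))
        assert np.array_equal(m1.feature_weights, m2.feature_weights)
        assert np.array_equal(m1.descriptor_weights, m2.descriptor_weights)
        assert m1.intercept == m2.intercept

    def test_logistic_alternative_method(self):
        matrix, D, y = self._toy()
        model = fit_ls_style(matrix, D, y, LSConfig(method="logistic"))
        assert model.feature_weights[0] > 0


@pytest.fixture(scope="module")
def ls_model(small_dataset):
    _, mols, y = small_dataset
    matrix = prepare_ls_features(mols, y)
    return fit_ls_style(matrix, descriptors.descriptor_matrix(mols), y), mols


@pytest.fixture(scope="module")
def cu_model(small_dataset):
    _, mols, y = small_dataset
    return fit_cu_style(mols, y), mols, y


class TestLSDomain:
    def test_training_compound_in_domain(self, ls_model):
        model, mols = ls_model
        ok, reason = applicability_domain_ls(model, mols[0])
        assert ok and "1.000" in reason  # self-similarity

    def test_featureless_molecule_out_of_domain(self, ls_model):
        model, _ = ls_model
        call = predict(model, mol("C"))  # methane matches nothing
        assert call.value is CallValue.OUT_OF_DOMAIN
        assert call.probability is None

    def test_similarity_rule_strict_below_threshold(self):
        # hand-built fingerprints: query matches 3 model features
        frags = [Fragment("C-C", "linear_path", 2), Fragment("C-O", "linear_path", 2),
                 Fragment("C-C-O", "linear_path", 3)]
        frags += [Fragment(f"Z{i}", "linear_path", 2) for i in range(7)]
        scaler = descriptors.DescriptorScaler(mean=(0.0,) * 8, sd=(1.0,) * 8)
        fp_far = np.zeros(10, dtype=bool)
        fp_far[3:] = True  # Tanimoto with ethanol bits = 0/10
        fp_border = np.zeros(10, dtype=bool)
        fp_border[:10] = True  # Tanimoto = 3/10 = 0.30, not below threshold
        common = dict(
            feature_weights=np.zeros(10),
            descriptor_weights=np.zeros(8),
            intercept=0.0,
            descriptor_scaler=scaler,
            pos_cutoff=0.6,
            neg_cutoff=0.4,
            similarity_threshold=0.30,
        )
        far = LSModel(fragments=frags, training_fingerprints=fp_far.reshape(1, -1), **common)
        border = LSModel(fragments=frags, training_fingerprints=fp_border.reshape(1, -1), **common)
        assert applicability_domain_ls(far, mol("CCO"))[0] is False
        assert applicability_domain_ls(border, mol("CCO"))[0] is True


class TestCUFit:
    def test_planted_alert_and_deactivator_signs(self, cu_model):
        model, _, _ = cu_model
        truth = synthdata.planted_truth(synthdata.SynthConfig())
        ids = [f.fragment_id for f in model.fragments]
        naphthalene = truth["fused_bicyclic_aromatic"].canonical_label
        acid = truth["carboxylic_acid"].canonical_label
        assert naphthalene in model.alert_ids
        assert model.weights[ids.index(naphthalene)] > 0
        assert acid in model.deactivator_ids
        assert model.weights[ids.index(acid)] < 0

    def test_scores_bounded(self, cu_model):
        model, mols, _ = cu_model
        from bbbqsar.features import molecule_feature_bits

        for m in mols[:25]:
            p = model.probability(molecule_feature_bits(m, model.fragments))
            assert 0.0 <= p <= 1.0

    def test_single_class_rejected(self, small_dataset):
        _, mols, y = small_dataset
        with pytest.raises(ValueError):
            fit_cu_style(mols[:40], np.zeros(40, dtype=int))

    def test_unknown_triplet_weak_score_is_ood(self, cu_model):
        model, _, _ = cu_model
        call = predict(model, mol("CCP"))  # phosphorus absent from the grammar
        assert call.value is CallValue.OUT_OF_DOMAIN

    def test_known_triplets_in_domain(self, cu_model):
        model, mols, _ = cu_model
        ok, _ = applicability_domain_cu(model, mols[3])
        assert ok

    def test_prediction_permutation_invariant(self, cu_model):
        model, mols, _ = cu_model
        m = mols[10]
        base = predict(model, m)
        order = list(reversed(range(m.GetNumAtoms())))
        again = predict(model, Chem.RenumberAtoms(m, order))
        assert again.value is base.value
        assert again.probability == pytest.approx(base.probability)


class TestSerialization:
    def test_ls_roundtrip(self, small_dataset):
        _, mols, y = small_dataset
        matrix = prepare_ls_features(mols[:100], y[:100])
        model = fit_ls_style(matrix, descriptors.descriptor_matrix(mols[:100]), y[:100])
        back = model_from_json(model_to_json(model))
        probe = mols[5]
        assert predict(model, probe).probability == pytest.approx(
            predict(back, probe).probability
        )

    def test_cu_roundtrip(self, small_dataset):
        _, mols, y = small_dataset
        model = fit_cu_style(mols, y)
        back = model_from_json(model_to_json(model))
        assert back.alert_ids == model.alert_ids
        assert np.allclose(back.weights, model.weights)
        probe = mols[7]
        assert predict(back, probe).probability == pytest.approx(
            predict(model, probe).probability
        )

    def test_call_invariant_enforced(self):
        with pytest.raises(ValueError):
            Call(value=CallValue.OUT_OF_DOMAIN, probability=0.5)
        with pytest.raises(ValueError):
            Call(value=CallValue.POSITIVE, probability=None)
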