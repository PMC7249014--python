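"""Compound descriptors, Lipinski gating, clogP banding, BBB SVM, and the
triage ranking."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litmine.synthetic import BBBSpec, make_bbb_dataset
from litmine.triage import (
    BBBModel,
    CompoundRecord,
    DescriptorSet,
    LipinskiRuleConfig,
    TriageError,
    clogp_band,
    compute_descriptors,
    count_hba,
    count_hbd,
    crippen_atom_contributions,
    crippen_clogp,
    fingerprint,
    lipinski_violations,
    load_bbb_model,
    molecular_weight,
    parse_smiles,
    predict_bbb,
    predict_bbb_from_bits,
    rotatable_bonds,
    save_bbb_model,
    tpsa,
    train_bbb_svm,
    triage,
)
ZILEUTON_SMILES = "CC(c1cc2ccccc2s1)N(O)C(N)=O"
TCDD_SMILES = "O1c2cc(Cl)c(Cl)cc2Oc2cc(Cl)c(Cl)cc12"


class TestParseSmiles:
    def test_methane(self):
        mol = parse_smiles("C")
        assert mol.GetNumAtoms() == 1
        assert mol.GetAtomWithIdx(0).GetTotalNumHs() == 4

    def test_benzene_aromatic_ring(self):
        mol = parse_smiles("c1ccccc1")
        assert mol.GetNumAtoms() == 6
        assert all(a.GetIsAromatic() for a in mol.GetAtoms())
        assert mol.GetRingInfo().NumRings() == 1

    def test_syntax_error(self):
        with pytest.raises(TriageError, match="unparseable"):
            parse_smiles("C(")

    def test_empty_smiles(self):
        with pytest.raises(TriageError, match="empty"):
            parse_smiles("")


class TestMolecularWeight:
    @pytest.mark.parametrize(
        "smiles,expected",
        [("C", 16.043), ("O", 18.015)],  # 12.011 + 4*1.008; 15.999 + 2*1.008
    )
    def test_small_molecules(self, smiles, expected):
        assert molecular_weight(parse_smiles(smiles)) == pytest.approx(expected, abs=1e-3)

    def test_zileuton_rounds_to_236(self):
        """C11H12N2O2S from the systematic name gives MW ~ 236 Da."""
        assert round(molecular_weight(parse_smiles(ZILEUTON_SMILES))) == 236

    def test_additivity_over_disconnected_fragments(self):
        """MW of a two-fragment record equals the sum of the fragments."""
        a, b = "CCO", "c1ccccc1"
        combined = molecular_weight(parse_smiles(f"{a}.{b}"))
        assert combined == pytest.approx(
            molecular_weight(parse_smiles(a)) + molecular_weight(parse_smiles(b)), abs=1e-6
        )


class TestHBondCounts:
    @pytest.mark.parametrize(
        "smiles,hbd,hba",
        [
            ("O", 1, 1),  # water: one O with H
            ("CCO", 1, 1),  # ethanol hydroxyl
            ("NC(N)=O", 2, 3),  # urea: two NH2 donate; 2 N + 1 O accept
        ],
    )
    def test_lipinski_counting_conventions(self, smiles, hbd, hba):
        mol = parse_smiles(smiles)
        assert count_hbd(mol) == hbd
        assert count_hba(mol) == hba


class TestTPSA:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("c1ccccc1", 0.0),  # no polar atoms
            ("CCOCC", 9.23),  # single ether-oxygen fragment value
            ("c1ccncc1", 12.89),  # single aromatic-N fragment value
        ],
    )
    def test_published_fragment_values(self, smiles, expected):
        assert tpsa(parse_smiles(smiles)) == pytest.approx(expected, abs=0.01)


class TestRotatableBonds:
    @pytest.mark.parametrize(
        "smiles,expected", [("CC", 0), ("CCCC", 1), ("c1ccccc1", 0)]
    )
    def test_strict_counting(self, smiles, expected):
        assert rotatable_bonds(parse_smiles(smiles)) == expected

    def test_amide_bond_excluded(self):
        # N-methylacetamide: only the C-N amide bond is a candidate; excluded
        assert rotatable_bonds(parse_smiles("CC(=O)NC")) == 0


class TestClogP:
    def test_methane_from_published_table(self):
        """Methane = one aliphatic-C entry (0.1441) + four hydrocarbon-H
        entries (0.1230 each)."""
        assert crippen_clogp(parse_smiles("C")) == pytest.approx(
            0.1441 + 4 * 0.1230, abs=1e-6
        )

    def test_atom_contributions_sum_to_total(self):
        """The Wildman-Crippen scheme is atom-additive: explicit-H per-atom
        contributions must sum to the aggregate value."""
        for smiles in (ZILEUTON_SMILES, TCDD_SMILES, "CCO", "c1ccncc1"):
            mol = parse_smiles(smiles)
            assert sum(crippen_atom_contributions(mol)) == pytest.approx(
                crippen_clogp(mol), abs=1e-6
            )

    def test_zileuton_below_optimal_bound(self):
        assert crippen_clogp(parse_smiles(ZILEUTON_SMILES)) <= 5.0

    def test_tcdd_more_lipophilic_than_zileuton(self):
        assert crippen_clogp(parse_smiles(TCDD_SMILES)) > crippen_clogp(
            parse_smiles(ZILEUTON_SMILES)
        )


class TestClogpBand:
    @pytest.mark.parametrize(
        "value,band",
        [(-1.1, "aqueous"), (6.12, "high"), (0.0, "optimal"), (4.99, "optimal"), (5.0, "high")],
    )
    def test_banding(self, value, band):
        assert clogp_band(value) == band

    def test_non_finite_rejected(self):
        with pytest.raises(TriageError):
            clogp_band(float("nan"))


class TestLipinski:
    def test_violation_free_compound(self):
        d = DescriptorSet(mw=236.3, hbd=2, hba=4, tpsa=66.6, rotatable_bonds=2, clogp=2.7)
        assert lipinski_violations(d) == 0

    def test_mw_bound_is_strict(self):
        base = dict(hbd=0, hba=0, tpsa=0.0, rotatable_bonds=0, clogp=1.0)
        assert lipinski_violations(DescriptorSet(mw=499.99, **base)) == 0
        assert lipinski_violations(DescriptorSet(mw=500.0, **base)) == 1

    def test_other_bounds_inclusive(self):
        d = DescriptorSet(mw=100.0, hbd=5, hba=10, tpsa=140.0, rotatable_bonds=10, clogp=1.0)
        assert lipinski_violations(d) == 0

    @settings(max_examples=1000, deadline=None)
    @given(
        st.floats(10, 1000),
        st.integers(0, 12),
        st.integers(0, 20),
        st.floats(0, 300),
        st.integers(0, 20),
    )
    def test_matches_brute_force_rule_check(self, mw, hbd, hba, tpsa_val, rotb):
        """Violation count equals an independent recount of the five rules."""
        d = DescriptorSet(mw=mw, hbd=hbd, hba=hba, tpsa=tpsa_val, rotatable_bonds=rotb, clogp=1.0)
        cfg = LipinskiRuleConfig()
        expected = 0
        if not (mw < cfg.mw_max):
            expected += 1
        if not (hbd <= cfg.hbd_max):
            expected += 1
        if not (hba <= cfg.hba_max):
            expected += 1
        if not (tpsa_val <= cfg.tpsa_max):
            expected += 1
        if not (rotb <= cfg.rotb_max):
            expected += 1
        assert lipinski_violations(d, cfg) == expected


class TestFingerprint:
    def test_deterministic(self):
        mol = parse_smiles(ZILEUTON_SMILES)
        assert np.array_equal(fingerprint(mol), fingerprint(mol))

    def test_distinct_molecules_distinct_bits(self):
        assert not np.array_equal(
            fingerprint(parse_smiles("C")), fingerprint(parse_smiles("c1ccccc1"))
        )

    def test_never_all_zero(self):
        for smiles in ("C", "O", "CCO", ZILEUTON_SMILES):
            assert fingerprint(parse_smiles(smiles)).sum() >= 1


class TestBBBSVM:
    def test_separable_pair(self):
        X = np.zeros((2, 8))
        X[0, 0] = 1.0
        X[1, 1] = 1.0
        model = train_bbb_svm(X, np.array([1, -1]), n_bits=8)
        for x, y in zip(X, (1, -1)):
            score, crossing = predict_bbb_from_bits(x, model)
            assert crossing == (y == 1)

    def test_single_class_rejected(self):
        with pytest.raises(TriageError, match="both classes"):
            train_bbb_svm(np.eye(4), np.array([1, 1, 1, 1]), n_bits=4)

    def test_training_is_deterministic(self):
        X, y, _ = make_bbb_dataset(BBBSpec(n_samples=60, n_bits=16, seed=5))
        m1 = train_bbb_svm(X, y, n_bits=16, seed=5)
        m2 = train_bbb_svm(X, y, n_bits=16, seed=5)
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias

    def test_heldout_accuracy_on_synthetic_set(self, bbb_recovery_accuracy):
        """Parameter recovery: accuracy vs the generating rule >= 0.90 on
        the seed-3 set (flip_rate 0.05), 75/25 split, C by cross-validation."""
        assert bbb_recovery_accuracy >= 0.90

    def test_zero_weight_model_scores_bias(self):
        model = BBBModel(weights=np.zeros(8), bias=0.5, n_bits=8)
        score, crossing = predict_bbb_from_bits(np.ones(8), model)
        assert score == 0.5 and crossing

    def test_score_monotone_in_positive_weight_bit(self):
        weights = np.zeros(8)
        weights[3] = 2.0
        model = BBBModel(weights=weights, bias=-1.0, n_bits=8)
        off, _ = predict_bbb_from_bits(np.zeros(8), model)
        bits = np.zeros(8)
        bits[3] = 1.0
        on, crossing = predict_bbb_from_bits(bits, model)
        assert on > off and crossing

    def test_fingerprint_size_mismatch(self):
        model = BBBModel(weights=np.zeros(8), bias=0.0, n_bits=8)
        with pytest.raises(TriageError, match="n_bits"):
            predict_bbb_from_bits(np.zeros(16), model)

    def test_model_round_trip(self, tmp_path):
        model = BBBModel(weights=np.arange(8.0), bias=-0.25, n_bits=8, radius=2, seed=1)
        path = tmp_path / "bbb.json"
        save_bbb_model(model, path)
        loaded = load_bbb_model(path)
        assert np.array_equal(loaded.weights, model.weights)
        assert loaded.bias == model.bias and loaded.n_bits == 8


class TestTriage:
    def _records(self):
        return [
            CompoundRecord("gooddrug", ZILEUTON_SMILES),  # all gates pass
            CompoundRecord("toolipophilic", TCDD_SMILES),  # clogp band high
            CompoundRecord("aqueousone", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
            CompoundRecord(
                "rulebreaker",  # methotrexate-like: 2 violations -> poor oral
                "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)N[C@@H](CCC(=O)O)C(=O)O",
            ),
            CompoundRecord("badsmiles", "C(("),
        ]

    def test_gates_and_exclusions(self, panel_bbb_model, caplog):
        with caplog.at_level("WARNING"):
            verdicts = triage(self._records(), bbb_model=panel_bbb_model)
        names = {v.name: v for v in verdicts}
        assert "badsmiles" not in names and "badsmiles" in caplog.text
        assert names["gooddrug"].suitable
        assert names["toolipophilic"].clogp_band == "high" and not names["toolipophilic"].suitable
        assert names["aqueousone"].clogp_band == "aqueous" and not names["aqueousone"].suitable
        assert names["rulebreaker"].violations >= 2 and names["rulebreaker"].poor_oral

    def test_poor_oral_iff_two_violations(self, panel_bbb_model):
        verdicts = triage(self._records()[:4], bbb_model=panel_bbb_model)
        for v in verdicts:
            assert v.poor_oral == (v.violations >= 2)

    def test_suitable_invariant(self, panel_bbb_model):
        for v in triage(self._records()[:4], bbb_model=panel_bbb_model):
            assert v.suitable == (
                (not v.poor_oral) and v.bbb_crossing and v.clogp_band == "optimal"
            )

    def test_ordering_is_total_and_permutation_invariant(self, panel_bbb_model, rng):
        records = self._records()[:4]
        baseline = [v.name for v in triage(records, bbb_model=panel_bbb_model)]
        for _ in range(5):
            perm = [records[i] for i in rng.permutation(len(records))]
            assert [v.name for v in triage(perm, bbb_model=panel_bbb_model)] == baseline

    def test_without_bbb_model_nothing_suitable(self):
        verdicts = triage(self._records()[:2])
        assert all(not v.suitable for v in verdicts)


def test_compute_descriptors_consistency():
    d = compute_descriptors(parse_smiles(ZILEUTON_SMILES))
    mol = parse_smiles(ZILEUTON_SMILES)
    assert d.mw == molecular_weight(mol)
    assert d.hbd == count_hbd(mol) and d.hba == count_hba(mol)
    assert d.clogp == crippen_clogp(mol)
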