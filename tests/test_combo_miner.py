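"""Clinical SL pair identification, drug rearrangement and toxicity filtering."""

from __future__ import annotations

import numpy as np
import pytest

from slcombo.combo_miner import (
    TOX_CYTOSTATIC,
    TOX_LOW,
    CandidateDrugPair,
    DrugRecord,
    TreatmentCombination,
    enumerate_candidate_pairs,
    existing_drug_pairs,
    filter_low_toxicity,
    identify_clinical_sl_pairs,
)
from slcombo.synthetic_data import rearrangement_fixture, clinical_practice_fixture

from .oracles import brute_candidates, brute_clinical_pairs


def combo(cid, drugs, source="practice", indication="Breast Neoplasms"):
    return TreatmentCombination(cid, indication, frozenset(drugs), source)


def random_instance(seed, n_drugs=30):
    rng = np.random.default_rng(seed)
    drugs = [f"d{i}" for i in range(n_drugs)]
    genes = [f"g{i}".upper() for i in range(20)]
    targets = {
        d: frozenset(rng.choice(genes, size=rng.integers(1, 4), replace=False))
        for d in drugs
    }
    combos = []
    for c in range(10):
        members = rng.choice(drugs, size=rng.integers(2, 5), replace=False)
        combos.append(
            combo(
                f"c{c}",
                members,
                source="practice" if rng.uniform() < 0.5 else "trial",
                indication="IndA" if rng.uniform() < 0.7 else "IndB",
            )
        )
    sl = {
        tuple(sorted(rng.choice(genes, size=2, replace=False))) for _ in range(12)
    }
    return combos, targets, sorted(sl)


class TestClinicalSLPairs:
    def test_clinical_practice_scenario_yields_six_pairs(self):
        combos, targets, sl = clinical_practice_fixture()
        pairs = identify_clinical_sl_pairs(combos, targets, sl)
        rows = {(p.drug_a, p.drug_b, p.target_pairs[0]) for p in pairs}
        assert rows == {
            ("bevacizumab", "docetaxel", ("BCL2", "VEGFA")),
            ("bevacizumab", "paclitaxel", ("BCL2", "VEGFA")),
            ("docetaxel", "gemcitabine", ("BCL2", "RRM1")),
            ("gemcitabine", "paclitaxel", ("BCL2", "RRM1")),
            ("docetaxel", "trastuzumab", ("BCL2", "ERBB2")),
            ("paclitaxel", "trastuzumab", ("BCL2", "ERBB2")),
        }

    def test_empty_sl_set_gives_empty_output(self):
        combos, targets, _ = clinical_practice_fixture()
        assert identify_clinical_sl_pairs(combos, targets, []) == []

    def test_pair_must_span_the_sl_pair(self):
        # both drugs hit only BCL2: never spans an SL pair containing BCL2
        combos = [combo("c1", ["docetaxel", "paclitaxel"])]
        targets = {"docetaxel": {"BCL2"}, "paclitaxel": {"BCL2"}}
        assert identify_clinical_sl_pairs(combos, targets, [("VEGFA", "BCL2")]) == []

    def test_drug_without_targets_is_skipped_with_warning(self):
        combos = [combo("c1", ["a", "b", "mystery"])]
        targets = {"a": {"G1"}, "b": {"G2"}}
        with pytest.warns(UserWarning, match="mystery"):
            pairs = identify_clinical_sl_pairs(combos, targets, [("G1", "G2")])
        assert [(p.drug_a, p.drug_b) for p in pairs] == [("a", "b")]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_double_loop(self, seed):
        combos, targets, sl = random_instance(seed)
        got = {
            (p.drug_a, p.drug_b): set(p.target_pairs)
            for p in identify_clinical_sl_pairs(combos, targets, sl)
        }
        assert got == brute_clinical_pairs(combos, targets, sl)


class TestEnumerateCandidatePairs:
    def test_rearrangement_recovers_the_known_novel_pair(self):
        combos, targets, sl = rearrangement_fixture()
        cands = enumerate_candidate_pairs(combos, targets, sl)
        assert [(c.drug_a, c.drug_b) for c in cands] == [("iniparib", "zoledronic_acid")]
        assert cands[0].supporting_sl_pairs == (("FDPS", "PARP1"),)
        existing = existing_drug_pairs(combos)
        for c in cands:
            assert frozenset((c.drug_a, c.drug_b)) not in existing

    def test_existing_combination_excluded(self):
        combos = [combo("c1", ["a", "b"], "trial"), combo("c2", ["a", "b"], "trial")]
        targets = {"a": {"G1"}, "b": {"G2"}}
        assert enumerate_candidate_pairs(combos, targets, [("G1", "G2")]) == []

    def test_same_drug_in_both_combos_excluded(self):
        combos = [combo("c1", ["a", "x"], "trial"), combo("c2", ["a", "y"], "trial")]
        targets = {"a": {"G1"}, "x": {"G9"}, "y": {"G8"}}
        got = enumerate_candidate_pairs(combos, targets, [("G1", "G1")])
        assert got == []

    def test_indication_scoping(self):
        combos = [
            combo("c1", ["a", "x"], "trial", indication="IndA"),
            combo("c2", ["b", "y"], "trial", indication="IndB"),
        ]
        targets = {"a": {"G1"}, "b": {"G2"}, "x": {"G9"}, "y": {"G8"}}
        sl = [("G1", "G2")]
        assert enumerate_candidate_pairs(combos, targets, sl, same_indication=True) == []
        cross = enumerate_candidate_pairs(combos, targets, sl, same_indication=False)
        assert [(c.drug_a, c.drug_b) for c in cross] == [("a", "b")]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_double_loop(self, seed):
        combos, targets, sl = random_instance(seed + 50)
        got = {
            (c.drug_a, c.drug_b): set(c.supporting_sl_pairs)
            for c in enumerate_candidate_pairs(combos, targets, sl)
        }
        assert got == brute_candidates(combos, targets, sl)

    @pytest.mark.parametrize("seed", range(3))
    def test_no_candidate_duplicates_an_existing_combination(self, seed):
        combos, targets, sl = random_instance(seed + 80)
        existing = existing_drug_pairs(combos)
        for c in enumerate_candidate_pairs(combos, targets, sl):
            assert frozenset((c.drug_a, c.drug_b)) not in existing

    def test_invariant_to_input_row_order(self):
        combos, targets, sl = random_instance(9)
        a = enumerate_candidate_pairs(combos, targets, sl)
        b = enumerate_candidate_pairs(combos[::-1], targets, sl)
        assert {(c.drug_a, c.drug_b) for c in a} == {(c.drug_a, c.drug_b) for c in b}


class TestFilterLowToxicity:
    def drugs(self):
        return [
            DrugRecord("cel", "celecoxib", "cox2_inhibitor", TOX_LOW),
            DrugRecord("zol", "zoledronic acid", "bisphosphonate", TOX_LOW),
            DrugRecord("doc", "docetaxel", "taxane", TOX_CYTOSTATIC),
        ]

    def cand(self, a, b):
        return CandidateDrugPair(a, b, (("G1", "G2"),), (("c1", "c2"),), "Breast Neoplasms")

    def test_both_low_toxicity_kept(self):
        kept = filter_low_toxicity([self.cand("cel", "zol")], self.drugs())
        assert len(kept) == 1

    def test_one_cytostatic_member_dropped(self):
        assert filter_low_toxicity([self.cand("doc", "zol")], self.drugs()) == []

    def test_empty_input(self):
        assert filter_low_toxicity([], self.drugs()) == []

    def test_subset_and_idempotent(self):
        cands = [self.cand("cel", "zol"), self.cand("doc", "zol")]
        once = filter_low_toxicity(cands, self.drugs())
        assert set(once) <= set(cands)
        assert filter_low_toxicity(once, self.drugs()) == once

    def test_missing_annotation_policies(self):
        cands = [self.cand("cel", "unknown")]
        with pytest.raises(KeyError, match="unknown"):
            filter_low_toxicity(cands, self.drugs(), on_missing="strict")
        with pytest.warns(UserWarning, match="unknown"):
            assert filter_low_toxicity(cands, self.drugs(), on_missing="lenient") == []
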