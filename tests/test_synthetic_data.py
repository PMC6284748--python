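"""Planted-structure generators: determinism and recoverable signal."""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pytest

from slcombo.gi_orthology import filter_negative_interactions, interactions_from_dataframe
from slcombo.combo_miner import (
    enumerate_candidate_pairs,
    filter_low_toxicity,
    identify_clinical_sl_pairs,
)
from slcombo.pair_features import dice_coefficient
from slcombo.synthetic_data import (
    ConfigError,
    GeneratorConfig,
    gen_annotations_and_graph,
    gen_dose_response,
    gen_drug_universe,
    gen_gi_screen,
    gen_orthology,
    write_all_inputs,
)
from slcombo.synergy import fit_median_effect, synergy_report


def kept_pairs(df, eps=-0.08, p=0.05):
    sl = filter_negative_interactions(interactions_from_dataframe(df), eps, p)
    return {frozenset(x.key) for x in sl}


class TestGIScreen:
    def test_noise_free_config_is_perfectly_separable(self):
        cfg = GeneratorConfig(seed=0, epsilon_sd=0.0, epsilon_sd_null=0.0)
        df, truth = gen_gi_screen(cfg)
        assert kept_pairs(df) == truth

    def test_fixed_seed_reproduces_identical_table(self):
        a, _ = gen_gi_screen(GeneratorConfig(seed=5))
        b, _ = gen_gi_screen(GeneratorConfig(seed=5))
        assert a.equals(b)

    def test_recall_under_stated_noise(self):
        """epsilon ~ N(-0.3, 0.05) leaves negligible mass above -0.08, so the
        standard cutoff recovers nearly every planted pair in every seed."""
        recalls = []
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=seed, n_interactions=1000, sl_fraction=0.1,
                epsilon_mean_neg=-0.3, epsilon_sd=0.05,
            )
            df, truth = gen_gi_screen(cfg)
            kept = kept_pairs(df)
            recalls.append(len(kept & truth) / len(truth))
        assert min(recalls) >= 0.99

    def test_unrecoverable_config_rejected(self):
        with pytest.raises(ConfigError, match="recoverable"):
            gen_gi_screen(GeneratorConfig(epsilon_mean_neg=-0.1, epsilon_sd=0.05))

    def test_empty_planted_class_rejected(self):
        with pytest.raises(ConfigError, match="planted"):
            gen_gi_screen(GeneratorConfig(sl_fraction=1e-6))


class TestAnnotationsAndGraph:
    def test_signal_raises_dice_of_sl_pairs(self):
        cfg = GeneratorConfig(seed=3, dice_signal_strength=1.0)
        genes = [f"H{i:04d}" for i in range(1, 101)]
        sl = [(genes[2 * i], genes[2 * i + 1]) for i in range(20)]
        null = [(genes[2 * i], genes[2 * i + 41]) for i in range(20)]
        corpora, _ = gen_annotations_and_graph(cfg, sl, genes)
        c = corpora[0]

        def mean_dice(pairs):
            return np.mean([dice_coefficient(c.terms(a), c.terms(b)) for a, b in pairs])

        assert mean_dice(sl) > mean_dice(null)

    def test_signal_pairs_get_direct_edges(self):
        cfg = GeneratorConfig(seed=4, dice_signal_strength=1.0)
        genes = [f"H{i:04d}" for i in range(1, 51)]
        sl = [(genes[0], genes[1]), (genes[2], genes[3])]
        _, graph = gen_annotations_and_graph(cfg, sl, genes)
        for a, b in sl:
            assert graph.has_edge(a, b)

    def test_all_genes_are_nodes(self):
        cfg = GeneratorConfig(seed=5)
        genes = [f"H{i:04d}" for i in range(1, 31)]
        _, graph = gen_annotations_and_graph(cfg, [], genes)
        assert set(graph.nodes()) == set(genes)


class TestOrthology:
    def test_truth_matches_records(self):
        records, truth = gen_orthology(GeneratorConfig(seed=6))
        derived: dict[str, set[str]] = {}
        for r in records:
            derived.setdefault(r.yeast_gene.id, set()).add(r.human_gene.id)
        assert {k: frozenset(v) for k, v in derived.items()} == truth

    def test_coverage_parameter_respected(self):
        _, truth = gen_orthology(GeneratorConfig(seed=7, orthology_coverage=1.0))
        assert len(truth) == GeneratorConfig().n_yeast_genes


class TestDrugUniverse:
    SL = [(f"H{2 * i + 1:04d}", f"H{2 * i + 2:04d}") for i in range(20)]

    def test_planted_answers_close_the_loop(self):
        u = gen_drug_universe(GeneratorConfig(seed=8), self.SL)
        clinical = {
            frozenset((p.drug_a, p.drug_b))
            for p in identify_clinical_sl_pairs(u.combos, u.targets, self.SL)
        }
        assert clinical == u.clinical_pairs
        cands = enumerate_candidate_pairs(u.combos, u.targets, self.SL)
        assert {frozenset((c.drug_a, c.drug_b)) for c in cands} == u.candidate_pairs
        low = filter_low_toxicity(cands, u.drugs)
        assert {
            frozenset((c.drug_a, c.drug_b)) for c in low
        } == u.low_tox_candidate_pairs

    def test_insufficient_sl_pairs_rejected(self):
        with pytest.raises(ConfigError, match="disjoint"):
            gen_drug_universe(GeneratorConfig(seed=9), self.SL[:3])


class TestDoseResponse:
    def test_noiseless_plates_recover_truth_exactly(self):
        cfg = GeneratorConfig(seed=10, plate_noise_sd=0.0)
        s1, s2, _, truth = gen_dose_response(cfg)
        f1, f2 = fit_median_effect(s1), fit_median_effect(s2)
        assert f1.dm == pytest.approx(truth.dm1, rel=1e-9)
        assert f1.m == pytest.approx(truth.m1, rel=1e-9)
        assert f2.dm == pytest.approx(truth.dm2, rel=1e-9)
        assert f2.m == pytest.approx(truth.m2, rel=1e-9)

    @pytest.mark.parametrize(
        "scenario,factor", [("additive", 1.0), ("synergy", 0.5), ("synergy", 0.25)]
    )
    def test_combination_scenario_hits_expected_ci(self, scenario, factor):
        cfg = GeneratorConfig(seed=11, plate_noise_sd=0.0)
        s1, s2, combo, truth = gen_dose_response(
            cfg, scenario=scenario, synergy_factor=factor
        )
        expected = factor if scenario == "synergy" else 1.0
        assert truth.expected_ci == expected
        rep = synergy_report(s1, s2, combo)
        for r in rep.results:
            assert r.ci == pytest.approx(truth.expected_ci, abs=1e-6)


class TestWriteAllInputs:
    def test_two_runs_are_byte_identical(self, tmp_path: Path):
        cfg = GeneratorConfig(seed=12)
        p1 = write_all_inputs(cfg, tmp_path / "run1")
        p2 = write_all_inputs(cfg, tmp_path / "run2")
        assert p1.keys() == p2.keys()
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path: Path):
        p1 = write_all_inputs(GeneratorConfig(seed=1), tmp_path / "a")
        p2 = write_all_inputs(GeneratorConfig(seed=2), tmp_path / "b")
        assert not filecmp.cmp(p1["gi_screen"], p2["gi_screen"], shallow=False)
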