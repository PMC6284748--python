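"""End-to-end driver: simulate -> filter -> map -> featurize -> train -> predict -> rearrange -> synergy.

Chains the module operations over one :class:`~slcombo.synthetic_data.GeneratorConfig`
and writes every intermediate table under an output directory.  All stages are
seeded from the config, so two runs with the same config produce byte-identical
output trees — the property the determinism checks assert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import combo_miner, io as sio, sl_classifier, synergy
from .gi_orthology import (
    filter_negative_interactions,
    interactions_from_dataframe,
    translate_pairs,
)
from .synthetic_data import GeneratorConfig, gen_classifier_corpus, write_all_inputs


@dataclass
class PipelineResult:
    """Key objects computed by one full pipeline run."""

    outdir: Path
    n_sl_yeast: int
    n_sl_human: int
    untranslatable: int
    report: sl_classifier.EvaluationReport
    n_clinical_pairs: int
    n_candidates: int
    n_low_tox_candidates: int
    synergy: synergy.SynergyReport


def run_full_pipeline(config: GeneratorConfig, outdir: str | Path) -> PipelineResult:
    outdir = Path(outdir)
    inputs = write_all_inputs(config, outdir / "inputs")

    # 1. screen -> yeast SL pairs
    interactions = interactions_from_dataframe(sio.read_gi_table(inputs["gi_screen"]))
    sl_yeast = filter_negative_interactions(interactions)
    sio.write_sl_pairs(sl_yeast, outdir / "sl_yeast.tsv")

    # 2. orthologue translation
    orthology = sio.read_orthology(inputs["orthology"])
    translated = translate_pairs(sl_yeast, orthology, mode="union")
    sio.write_sl_pairs(translated.pairs, outdir / "sl_human.tsv")

    # 3. features + classifier on the planted corpus
    features, labels, manifest = gen_classifier_corpus(config)
    features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    model, report = sl_classifier.train_and_validate(
        features, labels, manifest, seed=config.seed
    )
    (outdir / "report.json").write_text(json.dumps(report.__dict__, indent=2))
    predictions = sl_classifier.predict_pairs(model, features)
    predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)

    # 4. drug-combination mining against the simulated universe
    combos = sio.read_combinations(inputs["combinations"])
    targets = sio.read_drug_targets(inputs["drug_targets"])
    drugs = sio.read_drugs(inputs["drugs"])
    sl_set = sio.read_gene_pairs(inputs["sl_pairs_human"])
    clinical = combo_miner.identify_clinical_sl_pairs(combos, targets, sl_set)
    combo_miner.clinical_pairs_to_frame(clinical).to_csv(
        outdir / "clinical_sl_pairs.tsv", sep="\t", index=False
    )
    candidates = combo_miner.enumerate_candidate_pairs(combos, targets, sl_set)
    combo_miner.candidates_to_frame(candidates).to_csv(
        outdir / "candidates.tsv", sep="\t", index=False
    )
    low_tox = combo_miner.filter_low_toxicity(candidates, drugs)
    combo_miner.candidates_to_frame(low_tox).to_csv(
        outdir / "candidates_low_toxicity.tsv", sep="\t", index=False
    )

    # 5. synergy quantification of the simulated plates
    singles = sio.read_single_agent_plate(inputs["plate_singles"])
    combo_plate = sio.read_combo_plate(inputs["plate_combo"])
    rep = synergy.synergy_report(singles[0], singles[1], combo_plate)
    rep.to_frame().to_csv(outdir / "synergy_report.tsv", sep="\t", index=False)
    (outdir / "synergy_report.json").write_text(json.dumps(rep.to_dict(), indent=2))

    return PipelineResult(
        outdir=outdir,
        n_sl_yeast=len(sl_yeast),
        n_sl_human=len(translated.pairs),
        untranslatable=translated.untranslatable,
        report=report,
        n_clinical_pairs=len(clinical),
        n_candidates=len(candidates),
        n_low_tox_candidates=len(low_tox),
        synergy=rep,
    )
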