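"""Planted-structure generators for every pipeline input.

The pipeline's real inputs are exports from external resources (an SGA
genetic-interaction screen, orthology databases, annotation corpora, a drug
database, mined treatment combinations, viability plates).  These generators
emulate each one with parameterised, *planted* structure, and return the
planted truth alongside the data so every downstream stage can be scored
end-to-end without any external download.

The generators are structural, not biological: score distributions, term
assignments and the interactome are simple parametric models (Gaussian
epsilon mixture, uniform term draws, Erdős–Rényi graph), chosen so that the
planted signal — not distributional realism — drives the tests.

Each generator draws from its own pseudo-random stream derived from the
master seed and a fixed per-generator offset, so regenerating one input never
perturbs the others.  With a fixed config every generator is a pure function:
identical tables, byte for byte, on every run.

Two small clinically anchored fixtures ship with the package (under
``fixtures/``): a five-drug practice scenario whose target map spans three SL
gene pairs in six known ways, and a two-combination rearrangement scenario in
which one novel low-toxicity pair (iniparib + zoledronic acid) spans the SL
pair (FDPS, PARP1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import io as sio
from .combo_miner import (
    TOX_CYTOSTATIC,
    TOX_LOW,
    DrugRecord,
    TreatmentCombination,
)
from .gi_orthology import (
    HUMAN,
    ORTHOLOGY_SOURCES,
    YEAST,
    GeneRef,
    OrthologyRecord,
)
from .pair_features import AnnotationCorpus, build_feature_vectors
from .synergy import CombinationMeasurement, DoseResponseSeries, MedianEffectFit

# fixed per-generator stream offsets
_STREAM_GI = 11
_STREAM_ORTHOLOGY = 23
_STREAM_ANNOTATIONS = 37
_STREAM_DRUGS = 53
_STREAM_PLATES = 71

_NAMESPACE_NAMES = (
    "pathway_kegg",
    "pathway_panther",
    "ontology_go",
    "disease_mesh",
    "drug_target",
    "drug_enzyme",
    "drug_transporter",
    "drug_carrier",
)


class ConfigError(ValueError):
    """Raised when a generator config cannot produce the requested structure."""


@dataclass
class GeneratorConfig:
    """All knobs for the synthetic inputs; the defaults are the study conditions.

    GI screen: a mixture of planted synthetic-lethal pairs (strongly negative
    epsilon, small p) and null pairs (epsilon near zero, uniform p), sized so
    the SGA-style cutoff (-0.08, 0.05) separates the classes almost
    perfectly.  Orthology: most yeast genes map to one human gene, a minority
    to several, each assignment supported by a random subset of five sources.
    Annotations/network: with probability ``dice_signal_strength`` an SL
    pair's genes share extra terms in every namespace and a direct network
    edge.  Drug universe: a fixed number of clinical SL pairs and rearrangeable
    candidate pairs are planted among filler drugs and combinations.  Plates:
    median-effect truth with plate noise on single agents.
    """

    seed: int = 0

    # GI screen
    n_yeast_genes: int = 80
    n_interactions: int = 1200
    sl_fraction: float = 0.10
    epsilon_mean_neg: float = -0.30
    epsilon_sd: float = 0.05
    epsilon_sd_null: float = 0.03
    p_max_sl: float = 0.05

    # orthology
    n_human_genes: int = 200
    orthology_coverage: float = 0.85
    orthology_extra_mean: float = 0.3  # Poisson mean of orthologues beyond the first
    orthology_source_prob: float = 0.6  # per-source support probability

    # annotations + interactome
    n_namespaces: int = 4
    terms_per_namespace: int = 50
    baseline_terms_per_gene: int = 4
    shared_terms_per_pair: int = 5
    dice_signal_strength: float = 0.9
    edge_probability: float = 0.03

    # classifier corpus
    n_classifier_pairs: int = 400

    # drug universe
    n_drugs: int = 30
    n_combos: int = 14
    indication: str = "Breast Neoplasms"
    low_toxicity_fraction: float = 0.5
    n_planted_clinical: int = 3
    n_planted_candidates: int = 4
    n_low_tox_candidates: int = 2

    # dose-response truth
    dm1: float = 1.0
    m1: float = 1.0
    dm2: float = 4.0
    m2: float = 1.5
    plate_noise_sd: float = 0.02
    n_replicates: int = 3

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(offset)])


def _yeast_genes(n: int) -> list[str]:
    return [f"Y{i:04d}" for i in range(1, n + 1)]


def _human_genes(n: int) -> list[str]:
    return [f"H{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# GI screen


def gen_gi_screen(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, frozenset[frozenset[str]]]:
    """Emulate an SGA screen export with planted negative interactions.

    Planted pairs draw epsilon ~ N(mean_neg, sd) and p ~ U(0, p_max_sl); null
    pairs draw epsilon ~ N(0, sd_null) and p ~ U(0, 1).  The config must keep
    the planted epsilon distribution at least two standard deviations below
    the -0.08 cutoff so the planted class is recoverable.  Returns the screen
    table and the planted truth set (never re-derived from the table).
    """
    if config.epsilon_mean_neg > -0.08 - 2.0 * config.epsilon_sd:
        raise ConfigError(
            "epsilon_mean_neg must sit <= -0.08 - 2*epsilon_sd for a "
            "recoverable planted class"
        )
    genes = _yeast_genes(config.n_yeast_genes)
    all_pairs = list(combinations(genes, 2))
    if config.n_interactions > len(all_pairs):
        raise ConfigError("n_interactions exceeds the number of distinct pairs")
    n_sl = round(config.sl_fraction * config.n_interactions)
    if n_sl < 1:
        raise ConfigError("sl_fraction yields no planted pairs")
    rng = config.rng(_STREAM_GI)
    idx = rng.choice(len(all_pairs), size=config.n_interactions, replace=False)
    chosen = [all_pairs[i] for i in idx]
    sl_pairs = chosen[:n_sl]
    null_pairs = chosen[n_sl:]
    rows = []
    for a, b in sl_pairs:
        rows.append(
            (
                a,
                b,
                rng.normal(config.epsilon_mean_neg, config.epsilon_sd),
                rng.uniform(0.0, config.p_max_sl),
            )
        )
    for a, b in null_pairs:
        rows.append((a, b, rng.normal(0.0, config.epsilon_sd_null), rng.uniform()))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score", "p_value"])
    df = df.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)
    truth = frozenset(frozenset(p) for p in sl_pairs)
    return df, truth


# ---------------------------------------------------------------------------
# orthology


def gen_orthology(
    config: GeneratorConfig,
) -> tuple[list[OrthologyRecord], dict[str, frozenset[str]]]:
    """Emulate multi-source yeast->human orthology exports.

    Each yeast gene is covered with probability ``orthology_coverage``; a
    covered gene maps to ``1 + Poisson(orthology_extra_mean)`` human genes,
    and each yeast->human assignment is supported by a random subset of the
    five sources (at least one).  Returns the records plus the per-yeast-gene
    truth map of human orthologue sets (union over sources).
    """
    rng = config.rng(_STREAM_ORTHOLOGY)
    ygenes = _yeast_genes(config.n_yeast_genes)
    hgenes = _human_genes(config.n_human_genes)
    records: list[OrthologyRecord] = []
    truth: dict[str, frozenset[str]] = {}
    for yg in ygenes:
        if rng.uniform() > config.orthology_coverage:
            continue
        k = 1 + rng.poisson(config.orthology_extra_mean)
        hs = rng.choice(len(hgenes), size=min(k, len(hgenes)), replace=False)
        mapped = []
        for hi in hs:
            hg = hgenes[hi]
            support = [
                s for s in ORTHOLOGY_SOURCES if rng.uniform() < config.orthology_source_prob
            ]
            if not support:
                support = [ORTHOLOGY_SOURCES[int(rng.integers(len(ORTHOLOGY_SOURCES)))]]
            mapped.append(hg)
            for s in support:
                records.append(
                    OrthologyRecord(GeneRef(YEAST, yg), GeneRef(HUMAN, hg), s)
                )
        truth[yg] = frozenset(mapped)
    records.sort(key=lambda r: (r.yeast_gene.id, r.human_gene.id, r.source))
    return records, truth


# ---------------------------------------------------------------------------
# annotations + interactome


def gen_annotations_and_graph(
    config: GeneratorConfig,
    sl_truth: Sequence[tuple[str, str]],
    genes: Sequence[str],
) -> tuple[list[AnnotationCorpus], nx.Graph]:
    """Annotation corpora and an interactome with planted pair-level signal.

    Every gene receives ``baseline_terms_per_gene`` uniform terms per
    namespace on top of an Erdős–Rényi interactome.  With probability
    ``dice_signal_strength`` an SL pair additionally shares
    ``shared_terms_per_pair`` terms in every namespace (raising its Dice
    coefficients) and a direct network edge (shortening its path).  With
    signal strength 0 SL and null pairs are exchangeable.
    """
    rng = config.rng(_STREAM_ANNOTATIONS)
    namespaces = [
        _NAMESPACE_NAMES[i] if i < len(_NAMESPACE_NAMES) else f"namespace_{i}"
        for i in range(config.n_namespaces)
    ]
    assignments: dict[str, dict[str, set[str]]] = {
        ns: {g: set() for g in genes} for ns in namespaces
    }
    for ns in namespaces:
        for g in genes:
            terms = rng.choice(
                config.terms_per_namespace,
                size=min(config.baseline_terms_per_gene, config.terms_per_namespace),
                replace=False,
            )
            assignments[ns][g].update(f"{ns}:t{t:03d}" for t in terms)
    graph = nx.fast_gnp_random_graph(
        len(genes),
        config.edge_probability,
        seed=int(rng.integers(2**31)),
    )
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))
    for a, b in sl_truth:
        if rng.uniform() >= config.dice_signal_strength:
            continue
        for ns in namespaces:
            shared = rng.choice(
                config.terms_per_namespace,
                size=min(config.shared_terms_per_pair, config.terms_per_namespace),
                replace=False,
            )
            for t in shared:
                assignments[ns][a].add(f"{ns}:t{t:03d}")
                assignments[ns][b].add(f"{ns}:t{t:03d}")
        graph.add_edge(a, b)
    corpora = [
        AnnotationCorpus(ns, {g: frozenset(t) for g, t in assignments[ns].items()})
        for ns in namespaces
    ]
    return corpora, graph


def gen_classifier_corpus(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """A labelled pair corpus with planted annotation/network signal.

    Draws ``n_classifier_pairs // 2`` SL pairs and as many disjoint null
    pairs over the human gene universe, plants signal for the SL pairs via
    :func:`gen_annotations_and_graph`, and assembles the feature table.
    Returns ``(features, labels, manifest)`` with labels "SL"/"non-SL"
    aligned to the feature rows.
    """
    rng = config.rng(_STREAM_ANNOTATIONS + 1)
    genes = _human_genes(config.n_human_genes)
    n_pos = config.n_classifier_pairs // 2
    n_neg = config.n_classifier_pairs - n_pos
    all_pairs = list(combinations(genes, 2))
    idx = rng.choice(len(all_pairs), size=n_pos + n_neg, replace=False)
    pos = [all_pairs[i] for i in idx[:n_pos]]
    neg = [all_pairs[i] for i in idx[n_pos:]]
    corpora, graph = gen_annotations_and_graph(config, pos, genes)
    features, manifest = build_feature_vectors(pos + neg, corpora, graph)
    labels = ["SL"] * n_pos + ["non-SL"] * n_neg
    return features, labels, manifest


# ---------------------------------------------------------------------------
# drug universe


@dataclass
class DrugUniverse:
    drugs: list[DrugRecord]
    targets: dict[str, frozenset[str]]
    combos: list[TreatmentCombination]
    #: planted truth, returned alongside the data, never re-derived from it
    clinical_pairs: frozenset[frozenset[str]]
    candidate_pairs: frozenset[frozenset[str]]
    low_tox_candidate_pairs: frozenset[frozenset[str]]


def gen_drug_universe(
    config: GeneratorConfig, sl_human: Sequence[tuple[str, str]]
) -> DrugUniverse:
    """Drugs, targets and combinations with planted rearrangement answers.

    Plants, over gene-disjoint SL pairs: ``n_planted_clinical`` practice
    combinations whose two drugs span an SL pair (the clinical-SL truth), and
    ``n_planted_candidates`` drug pairs split across two different trial
    combinations so that rearrangement recovers exactly them (the candidate
    truth), of which ``n_low_tox_candidates`` have both members annotated
    low-toxicity (the funnel truth).  Filler drugs target only non-SL genes,
    so no unplanted pair can span an SL pair.
    """
    needed = config.n_planted_clinical + config.n_planted_candidates
    disjoint: list[tuple[str, str]] = []
    used: set[str] = set()
    for a, b in sl_human:
        if a in used or b in used or a == b:
            continue
        disjoint.append((a, b))
        used.update((a, b))
        if len(disjoint) == needed:
            break
    if len(disjoint) < needed:
        raise ConfigError(
            f"need {needed} gene-disjoint SL pairs, found {len(disjoint)}"
        )
    if config.n_low_tox_candidates > config.n_planted_candidates:
        raise ConfigError("n_low_tox_candidates exceeds n_planted_candidates")
    rng = config.rng(_STREAM_DRUGS)
    drugs: list[DrugRecord] = []
    targets: dict[str, frozenset[str]] = {}
    combos: list[TreatmentCombination] = []
    filler_genes = [f"NG{i:04d}" for i in range(1, 200)]

    def add_drug(drug_id: str, tox: str, genes: Sequence[str]) -> None:
        drugs.append(DrugRecord(drug_id, drug_id.replace("_", " "), "synthetic_class", tox))
        targets[drug_id] = frozenset(g.upper() for g in genes)

    def filler_gene() -> str:
        return filler_genes[int(rng.integers(len(filler_genes)))]

    clinical_truth = set()
    for i in range(config.n_planted_clinical):
        ga, gb = disjoint[i]
        da, db = f"clin{i}a", f"clin{i}b"
        add_drug(da, TOX_CYTOSTATIC, [ga])
        add_drug(db, TOX_CYTOSTATIC, [gb])
        combos.append(
            TreatmentCombination(
                combo_id=f"P{i + 1:03d}",
                indication=config.indication,
                drugs=frozenset((da, db)),
                source="practice",
            )
        )
        clinical_truth.add(frozenset((da, db)))

    candidate_truth = set()
    low_tox_truth = set()
    combo_no = 100
    for j in range(config.n_planted_candidates):
        ga, gb = disjoint[config.n_planted_clinical + j]
        low = j < config.n_low_tox_candidates
        tox = TOX_LOW if low else TOX_CYTOSTATIC
        da, db = f"cand{j}a", f"cand{j}b"
        fa, fb = f"fill{j}a", f"fill{j}b"
        add_drug(da, tox, [ga])
        add_drug(db, tox, [gb])
        add_drug(fa, TOX_CYTOSTATIC, [filler_gene()])
        add_drug(fb, TOX_CYTOSTATIC, [filler_gene()])
        combos.append(
            TreatmentCombination(
                combo_id=f"T{combo_no}",
                indication=config.indication,
                drugs=frozenset((da, fa)),
                source="trial",
            )
        )
        combos.append(
            TreatmentCombination(
                combo_id=f"T{combo_no + 1}",
                indication=config.indication,
                drugs=frozenset((db, fb)),
                source="trial",
            )
        )
        combo_no += 2
        candidate_truth.add(frozenset((da, db)))
        if low:
            low_tox_truth.add(frozenset((da, db)))

    # pad with filler drugs/combos targeting non-SL genes only
    i = 0
    while len(drugs) < config.n_drugs:
        tox = TOX_LOW if rng.uniform() < config.low_toxicity_fraction else TOX_CYTOSTATIC
        add_drug(f"extra{i}", tox, [filler_gene()])
        i += 1
    extra_ids = [d.drug_id for d in drugs if d.drug_id.startswith("extra")]
    while len(combos) < config.n_combos and len(extra_ids) >= 2:
        pick = rng.choice(len(extra_ids), size=2, replace=False)
        combos.append(
            TreatmentCombination(
                combo_id=f"T{combo_no}",
                indication=config.indication,
                drugs=frozenset(extra_ids[p] for p in pick),
                source="trial",
            )
        )
        combo_no += 1
    return DrugUniverse(
        drugs=drugs,
        targets=targets,
        combos=combos,
        clinical_pairs=frozenset(clinical_truth),
        candidate_pairs=frozenset(candidate_truth),
        low_tox_candidate_pairs=frozenset(low_tox_truth),
    )


# ---------------------------------------------------------------------------
# viability plates


@dataclass
class PlateTruth:
    dm1: float
    m1: float
    dm2: float
    m2: float
    expected_ci: float


def gen_dose_response(
    config: GeneratorConfig,
    scenario: str = "additive",
    synergy_factor: float = 0.5,
    fa_levels: Sequence[float] = (0.2, 0.35, 0.5, 0.65, 0.8),
    dose_split: float = 0.5,
) -> tuple[DoseResponseSeries, DoseResponseSeries, list[CombinationMeasurement], PlateTruth]:
    """Single-agent plates plus combination points under a stated interaction.

    Single-agent viability is ``1 - fa`` from the median-effect model at a
    two-fold dose ladder around each drug's Dm, in ``n_replicates`` replicates
    with Gaussian plate noise, clipped to [0, 1].  Combination points are
    constructed on the CI identity: at each target ``fa`` level the doses are
    ``d1 = c * split * Dx1(fa)`` and ``d2 = c * (1-split) * Dx2(fa)`` with
    ``c = 1`` for the additive scenario and ``c = synergy_factor < 1`` for the
    synergistic one — by construction the two-term combination index at those
    points equals ``c`` exactly.
    """
    if scenario not in ("additive", "synergy"):
        raise ConfigError(f"unknown combination scenario: {scenario!r}")
    if config.dm1 <= 0 or config.dm2 <= 0 or config.m1 <= 0 or config.m2 <= 0:
        raise ConfigError("dose-response truth requires Dm, m > 0")
    rng = config.rng(_STREAM_PLATES)
    ladder = 2.0 ** np.arange(-3, 4)

    def single(drug_id: str, dm: float, m: float) -> DoseResponseSeries:
        doses, via = [], []
        for mult in ladder:
            d = dm * mult
            ratio = (d / dm) ** m
            fa = ratio / (1.0 + ratio)
            for _ in range(config.n_replicates):
                v = 1.0 - fa + rng.normal(0.0, config.plate_noise_sd)
                doses.append(d)
                via.append(float(np.clip(v, 0.0, 1.0)))
        return DoseResponseSeries(drug_id=drug_id, doses=doses, viability=via)

    s1 = single("drug1", config.dm1, config.m1)
    s2 = single("drug2", config.dm2, config.m2)
    c = 1.0 if scenario == "additive" else synergy_factor
    fit1 = MedianEffectFit("drug1", config.dm1, config.m1, r=1.0, n_points=len(ladder))
    fit2 = MedianEffectFit("drug2", config.dm2, config.m2, r=1.0, n_points=len(ladder))
    combo = [
        CombinationMeasurement(
            d1=c * dose_split * fit1.dose_for_fa(fa),
            d2=c * (1.0 - dose_split) * fit2.dose_for_fa(fa),
            fa=fa,
        )
        for fa in fa_levels
    ]
    truth = PlateTruth(config.dm1, config.m1, config.dm2, config.m2, expected_ci=c)
    return s1, s2, combo, truth


# ---------------------------------------------------------------------------
# clinically anchored built-in fixtures


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("slcombo").joinpath("fixtures", name)))


def clinical_practice_fixture() -> tuple[
    list[TreatmentCombination], dict[str, frozenset[str]], list[tuple[str, str]]
]:
    """Five breast-cancer practice drugs spanning three SL pairs in six ways.

    Bevacizumab, gemcitabine and trastuzumab (targeting VEGFA, RRM1, ERBB2)
    are each co-administered in practice with both taxanes (off-target BCL2);
    the SL set pairs each of the three genes with BCL2, yielding exactly six
    clinical drug pairs.
    """
    combos = sio.read_combinations(_fixture_path("clinical_practice_combinations.tsv"))
    targets = sio.read_drug_targets(_fixture_path("clinical_practice_targets.tsv"))
    sl = sio.read_gene_pairs(_fixture_path("clinical_practice_sl_pairs.tsv"))
    return combos, targets, sl


def rearrangement_fixture() -> tuple[
    list[TreatmentCombination], dict[str, frozenset[str]], list[tuple[str, str]]
]:
    """The two-trial rearrangement scenario around combinations #388 and #390.

    Combination #390 pairs docetaxel (TUBB) with zoledronic acid (FDPS);
    #388 pairs iniparib (PARP1) with gemcitabine (RRM1, TYMS).  With the SL
    pair (FDPS, PARP1), rearrangement proposes exactly the novel pair
    iniparib + zoledronic acid.
    """
    combos = sio.read_combinations(_fixture_path("rearrangement_combinations.tsv"))
    targets = sio.read_drug_targets(_fixture_path("rearrangement_targets.tsv"))
    sl = sio.read_gene_pairs(_fixture_path("rearrangement_sl_pairs.tsv"))
    return combos, targets, sl


# ---------------------------------------------------------------------------
# bulk writer used by the CLI / analysis drivers


def write_all_inputs(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; truth under ``outdir/truth``.

    Returns a name -> path map of everything written.  Deterministic for a
    fixed config.
    """
    outdir = Path(outdir)
    truth_dir = outdir / "truth"
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    gi, sl_truth = gen_gi_screen(config)
    paths["gi_screen"] = outdir / "gi_screen.tsv"
    sio.write_gi_table(gi, paths["gi_screen"])
    truth_rows = sorted(tuple(sorted(p)) for p in sl_truth)
    paths["sl_truth"] = truth_dir / "sl_truth.tsv"
    pd.DataFrame(truth_rows, columns=["gene_a", "gene_b"]).to_csv(
        paths["sl_truth"], sep="\t", index=False
    )

    orthology, _ = gen_orthology(config)
    paths["orthology"] = outdir / "orthology.tsv"
    sio.write_orthology(orthology, paths["orthology"])

    genes = _human_genes(config.n_human_genes)
    sl_pairs_h = [
        (genes[2 * i], genes[2 * i + 1]) for i in range(min(40, len(genes) // 2))
    ]
    corpora, graph = gen_annotations_and_graph(config, sl_pairs_h, genes)
    paths["annotations"] = outdir / "annotations.gmt"
    sio.write_gmt(corpora, paths["annotations"])
    paths["network"] = outdir / "network.tsv"
    sio.write_edge_list(graph, paths["network"])

    universe = gen_drug_universe(config, sl_pairs_h)
    paths["drugs"] = outdir / "drugs.tsv"
    sio.write_drugs(universe.drugs, paths["drugs"])
    paths["drug_targets"] = outdir / "drug_targets.tsv"
    sio.write_drug_targets(universe.targets, paths["drug_targets"])
    paths["combinations"] = outdir / "combinations.tsv"
    sio.write_combinations(universe.combos, paths["combinations"])
    paths["sl_pairs_human"] = outdir / "sl_pairs_human.tsv"
    pd.DataFrame(sl_pairs_h, columns=["gene_a", "gene_b"]).to_csv(
        paths["sl_pairs_human"], sep="\t", index=False
    )
    for name, pairs in (
        ("clinical_pairs", universe.clinical_pairs),
        ("candidate_pairs", universe.candidate_pairs),
        ("low_tox_candidate_pairs", universe.low_tox_candidate_pairs),
    ):
        rows = sorted(tuple(sorted(p)) for p in pairs)
        paths[name] = truth_dir / f"{name}.tsv"
        pd.DataFrame(rows, columns=["drug_a", "drug_b"]).to_csv(
            paths[name], sep="\t", index=False
        )

    s1, s2, combo, truth = gen_dose_response(config, scenario="synergy")
    paths["plate_singles"] = outdir / "plate_singles.csv"
    sio.write_single_agent_plate([s1, s2], paths["plate_singles"])
    paths["plate_combo"] = outdir / "plate_combo.csv"
    sio.write_combo_plate(combo, paths["plate_combo"])
    paths["plate_truth"] = truth_dir / "plate_truth.tsv"
    pd.DataFrame(
        [
            ("dm1", truth.dm1),
            ("m1", truth.m1),
            ("dm2", truth.dm2),
            ("m2", truth.m2),
            ("expected_ci", truth.expected_ci),
        ],
        columns=["parameter", "value"],
    ).to_csv(paths["plate_truth"], sep="\t", index=False)
    return paths
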