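"""Readers and writers for the pipeline's plain-text exchange formats.

All tables are TSV (plates are CSV); ``#`` lines are comments.  Formats:

* GI screen: ``gene_a  gene_b  score  p_value``
* orthology: ``yeast_gene  human_gene  source``
* SL pairs: ``gene_a  gene_b  origin  provenance`` (provenance ";"-joined)
* gene sets, GMT-style: ``term  namespace  gene1  gene2 ...`` or the inverted
  per-gene form ``gene  namespace  term``
* interaction network: 2-column edge list
* drugs: ``drug_id  name  drug_class  toxicity_class``
* drug targets: ``drug_id  gene``
* combinations: ``combo_id  indication  source  drugs`` (drugs ";"-joined)
* plates: ``drug_id,dose_uM,viability`` (singles) and
  ``dose1_uM,dose2_uM,viability`` (combinations)
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .combo_miner import DrugRecord, TreatmentCombination
from .gi_orthology import (
    HUMAN,
    YEAST,
    GeneRef,
    OrthologyRecord,
    SLPair,
)
from .pair_features import AnnotationCorpus
from .synergy import CombinationMeasurement, DoseResponseSeries


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_gi_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_gi_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_orthology(path: str | Path) -> list[OrthologyRecord]:
    df = _read_tsv(path)
    return [
        OrthologyRecord(
            GeneRef(YEAST, str(r.yeast_gene)),
            GeneRef(HUMAN, str(r.human_gene)),
            str(r.source),
        )
        for r in df.itertuples(index=False)
    ]


def write_orthology(records: Iterable[OrthologyRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "yeast_gene": [r.yeast_gene.id for r in records],
            "human_gene": [r.human_gene.id for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sl_pairs(path: str | Path, namespace: str = HUMAN) -> list[SLPair]:
    df = _read_tsv(path)
    origin = "origin" in df.columns
    prov = "provenance" in df.columns
    return [
        SLPair(
            GeneRef(namespace, str(r.gene_a)),
            GeneRef(namespace, str(r.gene_b)),
            origin=str(r.origin) if origin else "yeast_screen",
            provenance=tuple(str(r.provenance).split(";")) if prov and str(r.provenance) else (),
        )
        for r in df.itertuples(index=False)
    ]


def write_sl_pairs(pairs: Sequence[SLPair], path: str | Path) -> None:
    from .gi_orthology import sl_pairs_to_frame

    sl_pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_gene_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = _read_tsv(path)
    return [(str(r.gene_a), str(r.gene_b)) for r in df.itertuples(index=False)]


def read_gmt(path: str | Path) -> list[AnnotationCorpus]:
    """GMT-style gene sets: ``term<TAB>namespace<TAB>gene1<TAB>gene2...``."""
    per_ns: dict[str, dict[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, namespace, *genes = line.rstrip("\n").split("\t")
        ns = per_ns.setdefault(namespace, {})
        for g in genes:
            if g:
                ns.setdefault(g.upper(), set()).add(term)
    return [
        AnnotationCorpus(ns, {g: frozenset(t) for g, t in gmap.items()})
        for ns, gmap in sorted(per_ns.items())
    ]


def write_gmt(corpora: Sequence[AnnotationCorpus], path: str | Path) -> None:
    lines = []
    for corpus in sorted(corpora, key=lambda c: c.namespace):
        terms: dict[str, list[str]] = {}
        for gene, ts in corpus.assignments.items():
            for t in ts:
                terms.setdefault(t, []).append(gene)
        for term in sorted(terms):
            genes = "\t".join(sorted(terms[term]))
            lines.append(f"{term}\t{corpus.namespace}\t{genes}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_term_table(path: str | Path) -> list[AnnotationCorpus]:
    """Inverted per-gene form: ``gene<TAB>namespace<TAB>term``."""
    df = _read_tsv(path)
    per_ns: dict[str, dict[str, set[str]]] = {}
    for r in df.itertuples(index=False):
        per_ns.setdefault(str(r.namespace), {}).setdefault(
            str(r.gene).upper(), set()
        ).add(str(r.term))
    return [
        AnnotationCorpus(ns, {g: frozenset(t) for g, t in gmap.items()})
        for ns, gmap in sorted(per_ns.items())
    ]


def read_edge_list(path: str | Path) -> nx.Graph:
    df = _read_tsv(path, header=None, names=["a", "b"])
    graph = nx.Graph()
    for r in df.itertuples(index=False):
        a, b = str(r.a).upper(), str(r.b).upper()
        if a != b:
            graph.add_edge(a, b)
        else:
            # self-referential row encodes an isolated node
            graph.add_node(a)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    lines = [f"{min(a, b)}\t{max(a, b)}" for a, b in graph.edges()]
    # isolated nodes round-trip as self-referential rows
    lines += [f"{n}\t{n}" for n in graph.nodes() if graph.degree(n) == 0]
    Path(path).write_text("\n".join(sorted(lines)) + "\n")


def read_drugs(path: str | Path) -> list[DrugRecord]:
    df = _read_tsv(path)
    return [
        DrugRecord(str(r.drug_id), str(r.name), str(r.drug_class), str(r.toxicity_class))
        for r in df.itertuples(index=False)
    ]


def write_drugs(drugs: Sequence[DrugRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in drugs],
            "name": [d.name for d in drugs],
            "drug_class": [d.drug_class for d in drugs],
            "toxicity_class": [d.toxicity_class for d in drugs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_drug_targets(path: str | Path) -> dict[str, frozenset[str]]:
    df = _read_tsv(path)
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.drug_id), set()).add(str(r.gene).upper())
    return {d: frozenset(g) for d, g in out.items()}


def write_drug_targets(targets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [(d, g) for d in sorted(targets) for g in sorted(targets[d])]
    pd.DataFrame(rows, columns=["drug_id", "gene"]).to_csv(path, sep="\t", index=False)


def read_combinations(path: str | Path) -> list[TreatmentCombination]:
    df = _read_tsv(path)
    return [
        TreatmentCombination(
            combo_id=str(r.combo_id),
            indication=str(r.indication),
            drugs=frozenset(str(r.drugs).split(";")),
            source=str(r.source),
        )
        for r in df.itertuples(index=False)
    ]


def write_combinations(
    combos: Sequence[TreatmentCombination], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "combo_id": [c.combo_id for c in combos],
            "indication": [c.indication for c in combos],
            "source": [c.source for c in combos],
            "drugs": [";".join(sorted(c.drugs)) for c in combos],
        }
    ).to_csv(path, sep="\t", index=False)


def read_single_agent_plate(path: str | Path) -> list[DoseResponseSeries]:
    df = pd.read_csv(path, comment="#")
    return [
        DoseResponseSeries(
            drug_id=str(drug),
            doses=sub["dose_uM"].tolist(),
            viability=sub["viability"].tolist(),
        )
        for drug, sub in df.groupby("drug_id", sort=True)
    ]


def write_single_agent_plate(
    series: Sequence[DoseResponseSeries], path: str | Path
) -> None:
    rows = [
        (s.drug_id, d, v)
        for s in series
        for d, v in zip(s.doses, s.viability)
    ]
    pd.DataFrame(rows, columns=["drug_id", "dose_uM", "viability"]).to_csv(
        path, index=False
    )


def read_combo_plate(path: str | Path) -> list[CombinationMeasurement]:
    df = pd.read_csv(path, comment="#")
    return [
        CombinationMeasurement(
            d1=float(r.dose1_uM), d2=float(r.dose2_uM), fa=1.0 - float(r.viability)
        )
        for r in df.itertuples(index=False)
    ]


def write_combo_plate(
    combo: Sequence[CombinationMeasurement], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "dose1_uM": [c.d1 for c in combo],
            "dose2_uM": [c.d2 for c in combo],
            "viability": [1.0 - c.fa for c in combo],
        }
    ).to_csv(path, index=False)
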