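"""Drug-combination mining and rearrangement against a predicted SL set.

Starting from a table of existing treatment combinations (clinical trials and
clinical practice, each tagged with a MeSH indication), a drug->target map and
a set of predicted synthetic-lethal human gene pairs, this module

* finds **clinical SL pairs**: drug pairs already co-administered in clinical
  practice whose targets span a predicted SL gene pair (one drug hits one
  side, the other drug the other side);
* **rearranges** drugs across combinations into novel candidate pairs — one
  drug from each of two different combinations (same indication by default)
  that never co-occur in any existing combination — keeping a pair iff its
  targets span at least one SL pair;
* filters candidates down to pairs where both members carry a non-cytostatic,
  low-toxicity annotation, the criterion used to nominate pairs for in-vitro
  testing.

Toxicity is an explicit per-drug annotation supplied with the drug table; it
is never inferred.  All outputs are canonically ordered and deduplicated, so
they are invariant to input row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

TOX_LOW = "non_cytostatic_low_toxicity"
TOX_CYTOSTATIC = "cytostatic"


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    drug_class: str
    toxicity_class: str


@dataclass(frozen=True)
class TreatmentCombination:
    """An indication-tagged drug set from a trial or clinical practice."""

    combo_id: str
    indication: str
    drugs: frozenset[str]
    source: str  # "trial" | "practice"

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(f"combination {self.combo_id} has no drugs")
        if self.source not in ("trial", "practice"):
            raise ValueError(f"unknown combination source: {self.source!r}")


@dataclass(frozen=True)
class ClinicalSLPair:
    """A practice drug pair whose targets span >= 1 predicted SL gene pair."""

    drug_a: str
    drug_b: str
    target_pairs: tuple[tuple[str, str], ...]
    combo_ids: tuple[str, ...]


@dataclass(frozen=True)
class CandidateDrugPair:
    """A rearranged (novel) drug pair with its supporting SL target pairs."""

    drug_a: str
    drug_b: str
    supporting_sl_pairs: tuple[tuple[str, str], ...]
    provenance: tuple[tuple[str, str], ...]  # (combo of drug_a, combo of drug_b)
    indication: str


def normalize_sl_set(pairs: Iterable[Sequence[str]]) -> frozenset[frozenset[str]]:
    """Canonicalise an iterable of gene pairs into a set of unordered pairs."""
    out = set()
    for a, b in pairs:
        a, b = a.upper(), b.upper()
        if a != b:
            out.add(frozenset((a, b)))
    return frozenset(out)


def _spanning_target_pairs(
    targets_a: frozenset[str],
    targets_b: frozenset[str],
    sl_pairs: frozenset[frozenset[str]],
) -> tuple[tuple[str, str], ...]:
    """SL pairs (ta, tb) with ta hit by drug A and tb hit by drug B (or swapped).

    Both drugs hitting the same gene does not count: the pair must span the
    two sides of an SL interaction.
    """
    found = set()
    for ta in targets_a:
        for tb in targets_b:
            if ta != tb and frozenset((ta, tb)) in sl_pairs:
                found.add(tuple(sorted((ta, tb))))
    return tuple(sorted(found))


def _clean_targets(
    targets: Mapping[str, Iterable[str]],
) -> dict[str, frozenset[str]]:
    return {d: frozenset(g.upper() for g in gs) for d, gs in targets.items()}


def identify_clinical_sl_pairs(
    combos: Sequence[TreatmentCombination],
    targets: Mapping[str, Iterable[str]],
    sl_pairs: Iterable[Sequence[str]] | frozenset[frozenset[str]],
) -> list[ClinicalSLPair]:
    """Drug pairs co-occurring in clinical practice whose targets span an SL pair.

    Only ``source == "practice"`` combinations are examined.  Drugs without a
    target assignment are skipped with a warning.  One record is emitted per
    drug pair, listing every supporting target pair and every practice
    combination in which the pair co-occurs; output order is canonical.
    """
    sl = (
        sl_pairs
        if isinstance(sl_pairs, frozenset)
        else normalize_sl_set(sl_pairs)  # type: ignore[arg-type]
    )
    tmap = _clean_targets(targets)
    seen: dict[tuple[str, str], set[str]] = {}
    for combo in combos:
        if combo.source != "practice":
            continue
        known = []
        for d in sorted(combo.drugs):
            if d in tmap:
                known.append(d)
            else:
                warnings.warn(f"drug {d!r} has no target assignment; skipped", stacklevel=2)
        for da, db in combinations(known, 2):
            seen.setdefault((da, db), set()).add(combo.combo_id)
    out = []
    for (da, db), combo_ids in sorted(seen.items()):
        spans = _spanning_target_pairs(tmap[da], tmap[db], sl)
        if spans:
            out.append(
                ClinicalSLPair(
                    drug_a=da,
                    drug_b=db,
                    target_pairs=spans,
                    combo_ids=tuple(sorted(combo_ids)),
                )
            )
    return out


def existing_drug_pairs(
    combos: Sequence[TreatmentCombination],
) -> frozenset[frozenset[str]]:
    """All unordered drug pairs co-occurring in any combination (trial or practice)."""
    pairs = set()
    for combo in combos:
        for da, db in combinations(sorted(combo.drugs), 2):
            pairs.add(frozenset((da, db)))
    return frozenset(pairs)


def enumerate_candidate_pairs(
    combos: Sequence[TreatmentCombination],
    targets: Mapping[str, Iterable[str]],
    sl_pairs: Iterable[Sequence[str]] | frozenset[frozenset[str]],
    same_indication: bool = True,
) -> list[CandidateDrugPair]:
    """Rearrange drugs across combinations into novel SL-targeting pairs.

    Considers unordered pairs (d_a from combination X, d_b from combination Y,
    X != Y; same indication when ``same_indication``) that do not already
    co-occur in any existing combination, and keeps a pair iff its target sets
    span at least one predicted SL gene pair.  Every member of a multi-drug
    regimen is an eligible donor.  Duplicates across provenance merge, with
    the full provenance list retained; output order is canonical by
    (indication, drug pair).
    """
    sl = (
        sl_pairs
        if isinstance(sl_pairs, frozenset)
        else normalize_sl_set(sl_pairs)  # type: ignore[arg-type]
    )
    tmap = _clean_targets(targets)
    existing = existing_drug_pairs(combos)
    found: dict[tuple[str, tuple[str, str]], dict] = {}
    for x, y in combinations(range(len(combos)), 2):
        cx, cy = combos[x], combos[y]
        if same_indication and cx.indication != cy.indication:
            continue
        indication = cx.indication if same_indication else "*"
        for da in sorted(cx.drugs):
            for db in sorted(cy.drugs):
                if da == db or da not in tmap or db not in tmap:
                    continue
                key_pair = tuple(sorted((da, db)))
                if frozenset(key_pair) in existing:
                    continue
                spans = _spanning_target_pairs(tmap[da], tmap[db], sl)
                if not spans:
                    continue
                entry = found.setdefault(
                    (indication, key_pair), {"spans": set(), "prov": set()}
                )
                entry["spans"].update(spans)
                # provenance ordered as (donor combo of drug_a, donor of drug_b)
                # under the canonical drug order
                if key_pair == (da, db):
                    entry["prov"].add((cx.combo_id, cy.combo_id))
                else:
                    entry["prov"].add((cy.combo_id, cx.combo_id))
    out = []
    for (indication, (da, db)), entry in sorted(found.items()):
        out.append(
            CandidateDrugPair(
                drug_a=da,
                drug_b=db,
                supporting_sl_pairs=tuple(sorted(entry["spans"])),
                provenance=tuple(sorted(entry["prov"])),
                indication=indication,
            )
        )
    return out


def filter_low_toxicity(
    candidates: Sequence[CandidateDrugPair],
    drugs: Sequence[DrugRecord] | Mapping[str, DrugRecord],
    on_missing: str = "strict",
) -> list[CandidateDrugPair]:
    """Keep candidate pairs where BOTH drugs are non-cytostatic low-toxicity.

    ``on_missing`` controls behaviour for drugs without a toxicity annotation:
    ``"strict"`` raises, ``"lenient"`` drops the pair with a warning.
    """
    if on_missing not in ("strict", "lenient"):
        raise ValueError(f"unknown on_missing policy: {on_missing!r}")
    if not isinstance(drugs, Mapping):
        drugs = {d.drug_id: d for d in drugs}
    out = []
    for cand in candidates:
        tox = []
        missing = [d for d in (cand.drug_a, cand.drug_b) if d not in drugs]
        if missing:
            if on_missing == "strict":
                raise KeyError(f"no toxicity annotation for drugs: {missing}")
            warnings.warn(
                f"dropping pair ({cand.drug_a}, {cand.drug_b}): missing "
                f"toxicity annotation for {missing}",
                stacklevel=2,
            )
            continue
        tox = [drugs[cand.drug_a].toxicity_class, drugs[cand.drug_b].toxicity_class]
        if all(t == TOX_LOW for t in tox):
            out.append(cand)
    return out


def clinical_pairs_to_frame(pairs: Sequence[ClinicalSLPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_a": [p.drug_a for p in pairs],
            "drug_b": [p.drug_b for p in pairs],
            "target_pairs": [
                ";".join(f"{a}-{b}" for a, b in p.target_pairs) for p in pairs
            ],
            "combo_ids": [";".join(p.combo_ids) for p in pairs],
        }
    )


def candidates_to_frame(cands: Sequence[CandidateDrugPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_a": [c.drug_a for c in cands],
            "drug_b": [c.drug_b for c in cands],
            "indication": [c.indication for c in cands],
            "supporting_sl_pairs": [
                ";".join(f"{a}-{b}" for a, b in c.supporting_sl_pairs) for c in cands
            ],
            "provenance": [
                ";".join(f"{x}+{y}" for x, y in c.provenance) for c in cands
            ],
        }
    )
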