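"""Yeast genetic-interaction filtering and yeast-to-human orthologue translation.

A synthetic genetic array (SGA) screen reports, for each yeast gene pair, a
quantitative genetic-interaction score ``epsilon`` (the deviation of the double
mutant's fitness from the multiplicative expectation of the two singles) and a
p-value.  Strongly negative ``epsilon`` marks synthetic-lethal or
synthetic-sick pairs.  This module

* filters a screen down to synthetic-lethal (SL) pairs with inclusive cutoffs
  ``epsilon <= epsilon_cutoff`` and ``p <= p_cutoff`` (defaults -0.08 / 0.05),
* translates the surviving yeast pairs into human gene pairs through one or
  more orthology maps, either accepting any single source (``union``) or
  requiring a minimum number of concordant sources (``min_sources``).

One-to-many orthology expands combinatorially: a yeast pair maps to every
human pair in the Cartesian product of the two orthologue sets, with
self-pairs removed and duplicates merged.  Gene identifiers are normalised to
upper case throughout; unordered pairs are stored in lexicographic order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

YEAST = "yeast"
HUMAN = "human"

#: default SGA cutoffs for calling a negative interaction synthetic lethal
DEFAULT_EPSILON_CUTOFF = -0.08
DEFAULT_P_CUTOFF = 0.05

#: the orthology resources whose exports the translation step understands
ORTHOLOGY_SOURCES = ("roundup", "oma", "ensembl", "inparanoid", "homologene")


class ValidationError(ValueError):
    """Raised when input records violate the screen's value contracts."""


@dataclass(frozen=True, order=True)
class GeneRef:
    """A namespaced gene identifier; ids are upper-cased on construction."""

    namespace: str
    id: str

    def __post_init__(self) -> None:
        norm = self.id.strip().upper()
        if not norm:
            raise ValidationError("gene id must be non-empty")
        object.__setattr__(self, "id", norm)


def _canonical(a: GeneRef, b: GeneRef) -> tuple[GeneRef, GeneRef]:
    if a.namespace != b.namespace:
        raise ValidationError(f"pair spans namespaces: {a.namespace}/{b.namespace}")
    if a.id == b.id:
        raise ValidationError(f"self-pair not allowed: {a.id}")
    return (a, b) if a.id <= b.id else (b, a)


@dataclass(frozen=True)
class GeneticInteraction:
    """One screen edge: a yeast gene pair with score epsilon and p-value."""

    gene_a: GeneRef
    gene_b: GeneRef
    epsilon: float
    p_value: float

    def __post_init__(self) -> None:
        a, b = _canonical(self.gene_a, self.gene_b)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a.id, self.gene_b.id)


@dataclass(frozen=True)
class SLPair:
    """An unordered synthetic-lethal gene pair with provenance.

    ``origin`` records which pipeline stage produced the call:
    ``yeast_screen``, ``orthologue_translation`` or ``classifier_inference``.
    """

    gene_a: GeneRef
    gene_b: GeneRef
    origin: str
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        a, b = _canonical(self.gene_a, self.gene_b)
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a.id, self.gene_b.id)


@dataclass(frozen=True)
class OrthologyRecord:
    yeast_gene: GeneRef
    human_gene: GeneRef
    source: str


@dataclass
class TranslationResult:
    """Human SL pairs plus the tally of yeast pairs that could not be mapped."""

    pairs: list[SLPair]
    untranslatable: int


def interactions_from_dataframe(df: pd.DataFrame) -> list[GeneticInteraction]:
    """Build interaction records from a screen table.

    Expects columns ``gene_a, gene_b, score, p_value``.  Rows whose p-value
    falls outside [0, 1] are collected and reported together in a single
    :class:`ValidationError` naming the offending row numbers.
    """
    bad_rows = [
        i for i, p in enumerate(df["p_value"]) if not (0.0 <= float(p) <= 1.0)
    ]
    if bad_rows:
        raise ValidationError(f"p_value outside [0,1] in rows: {bad_rows}")
    return [
        GeneticInteraction(
            GeneRef(YEAST, str(r.gene_a)),
            GeneRef(YEAST, str(r.gene_b)),
            float(r.score),
            float(r.p_value),
        )
        for r in df.itertuples(index=False)
    ]


def filter_negative_interactions(
    interactions: Iterable[GeneticInteraction],
    epsilon_cutoff: float = DEFAULT_EPSILON_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> list[SLPair]:
    """Keep pairs with ``epsilon <= epsilon_cutoff`` and ``p <= p_cutoff``.

    Both cutoffs are inclusive.  Duplicate pairs (including reversed order)
    collapse to a single :class:`SLPair` whose provenance concatenates the
    contributing screen rows.  Output is sorted by canonical pair key, so the
    result is deterministic regardless of input order.
    """
    for c in (epsilon_cutoff, p_cutoff):
        if not (c == c and abs(c) != float("inf")):
            raise ValidationError("cutoffs must be finite")
    if epsilon_cutoff >= 0:
        warnings.warn(
            "epsilon_cutoff is non-negative; synthetic-lethal screens use a "
            "negative score cutoff",
            stacklevel=2,
        )
    merged: dict[tuple[str, str], list] = {}
    for gi in interactions:
        if not (0.0 <= gi.p_value <= 1.0):
            raise ValidationError(f"p_value outside [0,1]: {gi.p_value!r}")
        if gi.epsilon <= epsilon_cutoff and gi.p_value <= p_cutoff:
            tag = f"gi:eps={gi.epsilon:g},p={gi.p_value:g}"
            merged.setdefault(gi.key, [gi.gene_a, gi.gene_b, []])[2].append(tag)
    return [
        SLPair(a, b, origin="yeast_screen", provenance=tuple(tags))
        for (a, b, tags) in (merged[k] for k in sorted(merged))
    ]


def _orthologue_sets(
    orthology: Iterable[OrthologyRecord],
    mode: str,
    min_sources: int,
) -> Mapping[str, dict[str, frozenset[str]]]:
    by_yeast: dict[str, dict[str, set[str]]] = {}
    for rec in orthology:
        by_yeast.setdefault(rec.yeast_gene.id, {}).setdefault(
            rec.human_gene.id, set()
        ).add(rec.source)
    out: dict[str, dict[str, frozenset[str]]] = {}
    for ygene, humans in by_yeast.items():
        kept = {
            h: frozenset(srcs)
            for h, srcs in humans.items()
            if mode == "union" or len(srcs) >= min_sources
        }
        if kept:
            out[ygene] = kept
    return out


def translate_pairs(
    sl_pairs: Sequence[SLPair],
    orthology: Iterable[OrthologyRecord],
    mode: str = "union",
    min_sources: int = 2,
) -> TranslationResult:
    """Expand yeast SL pairs into human orthologue pairs.

    Each yeast pair maps to the Cartesian product of its two genes' human
    orthologue sets.  In ``union`` mode one supporting source suffices for an
    orthologue call; in ``min_sources`` mode the yeast->human assignment must
    be present in at least ``min_sources`` of the configured resources.

    Self-pairs (both yeast genes mapping onto the same human gene) are
    discarded.  A yeast pair with no admissible orthologue on either side is
    dropped and counted in the returned ``untranslatable`` tally.  Duplicate
    human pairs arising from different yeast pairs merge, concatenating
    provenance.  The operation is idempotent in content: translating the same
    input twice yields the same set of human pairs.
    """
    if mode not in ("union", "min_sources"):
        raise ValidationError(f"unknown orthology mode: {mode!r}")
    orth = _orthologue_sets(orthology, mode, min_sources)
    merged: dict[tuple[str, str], list] = {}
    untranslatable = 0
    for pair in sl_pairs:
        ya, yb = pair.key
        ha_set, hb_set = orth.get(ya), orth.get(yb)
        if not ha_set or not hb_set:
            untranslatable += 1
            continue
        expanded = False
        for ha, ha_src in ha_set.items():
            for hb, hb_src in hb_set.items():
                if ha == hb:
                    continue
                expanded = True
                tag = (
                    f"{ya}-{yb}|{ya}->{ha}[{';'.join(sorted(ha_src))}]"
                    f"|{yb}->{hb}[{';'.join(sorted(hb_src))}]"
                )
                key = tuple(sorted((ha, hb)))
                merged.setdefault(
                    key, [GeneRef(HUMAN, key[0]), GeneRef(HUMAN, key[1]), []]
                )[2].append(tag)
        if not expanded:
            # all candidate human pairs were self-pairs
            untranslatable += 1
    pairs = [
        SLPair(a, b, origin="orthologue_translation", provenance=tuple(sorted(tags)))
        for (a, b, tags) in (merged[k] for k in sorted(merged))
    ]
    return TranslationResult(pairs=pairs, untranslatable=untranslatable)


def sl_pairs_to_frame(pairs: Sequence[SLPair]) -> pd.DataFrame:
    """Tabulate SL pairs as ``gene_a, gene_b, origin, provenance`` (";"-joined)."""
    return pd.DataFrame(
        {
            "gene_a": [p.gene_a.id for p in pairs],
            "gene_b": [p.gene_b.id for p in pairs],
            "origin": [p.origin for p in pairs],
            "provenance": [";".join(p.provenance) for p in pairs],
        }
    )
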