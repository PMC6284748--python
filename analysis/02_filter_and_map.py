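#!/usr/bin/env python
"""Filter the simulated screen to SL pairs and translate them to human orthologues.

Applies the SGA cutoffs (epsilon <= -0.08, p <= 0.05), scores recovery of the
planted synthetic-lethal set, then expands the yeast pairs through the
multi-source orthology map (union mode).  Writes results/sl_yeast.tsv and
results/sl_human.tsv.
"""

from pathlib import Path

import pandas as pd

from slcombo import io as sio
from slcombo.gi_orthology import (
    filter_negative_interactions,
    interactions_from_dataframe,
    translate_pairs,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    interactions = interactions_from_dataframe(
        sio.read_gi_table(ROOT / "sim" / "gi_screen.tsv")
    )
    sl_yeast = filter_negative_interactions(interactions)
    sio.write_sl_pairs(sl_yeast, ROOT / "sl_yeast.tsv")

    truth = {
        frozenset(t)
        for t in pd.read_csv(ROOT / "sim" / "truth" / "sl_truth.tsv", sep="\t")
        .itertuples(index=False)
    }
    kept = {frozenset(p.key) for p in sl_yeast}
    recall = len(kept & truth) / len(truth)
    precision = len(kept & truth) / len(kept)
    print(
        f"screen: {len(interactions)} interactions -> {len(sl_yeast)} SL pairs "
        f"(recall {recall:.3f}, precision {precision:.3f} vs planted truth)"
    )

    orthology = sio.read_orthology(ROOT / "sim" / "orthology.tsv")
    translated = translate_pairs(sl_yeast, orthology, mode="union")
    sio.write_sl_pairs(translated.pairs, ROOT / "sl_human.tsv")
    print(
        f"orthology: {len(translated.pairs)} human pairs; "
        f"{translated.untranslatable} yeast pairs untranslatable"
    )


if __name__ == "__main__":
    main()
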