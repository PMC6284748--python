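#!/usr/bin/env python
"""Generate all pipeline inputs with planted structure under results/sim/.

Emulates the external resources the pipeline normally consumes — an SGA
genetic-interaction screen, multi-source orthology exports, annotation
corpora, an interactome, a drug/target/combination universe, and viability
plates — and writes the planted truth under results/sim/truth/ for scoring
by the later stages.
"""

from pathlib import Path

from slcombo.synthetic_data import GeneratorConfig, write_all_inputs

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    config = GeneratorConfig(seed=SEED)
    paths = write_all_inputs(config, OUT)
    print(f"seed {SEED}: wrote {len(paths)} files")
    for name, path in sorted(paths.items()):
        print(f"  {name:24s} {path.relative_to(OUT.parent)}")


if __name__ == "__main__":
    main()
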