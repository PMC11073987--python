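"""Generate the synthetic study bundle (counts, annotation, peptides, cohort).

Writes the full input bundle under results/data/ in the same plain-text
formats the readers accept, so every later script — and the CLI — can run
from files. The planted truth (which features respond, how strongly, and the
latent cohort autophagy activity) is reproducible from the seed alone.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from ereflow.synthetic import SimConfig, write_experiment_bundle


def main() -> None:
    config = SimConfig(seed=SEED)
    paths = write_experiment_bundle(RESULTS / "data", config)
    print(f"simulated study bundle (seed {SEED}):")
    for name, path in paths.items():
        print(f"  {name:12s} {path}")


if __name__ == "__main__":
    main()
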