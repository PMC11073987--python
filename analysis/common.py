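"""Shared configuration for the numbered analysis scripts.

All scripts simulate the same study (seed 7, default desk-scale conditions:
four treated-vs-control cell lines at 3 + 3 replicates, a 500-protein
immunopeptidome and a 437-patient cohort) and write their tables under
results/.
"""

from pathlib import Path

from ereflow.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def run_config() -> RunConfig:
    return RunConfig(seed=SEED, outdir=str(RESULTS))
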