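"""Peptide-to-RNA integration: candidate database, concordance, rphm screen.

Builds the three-frame candidate peptide database from expressed transcripts,
classes every differential peptide by its best-supported source's RNA
behaviour (most changes are RNA-unchanged — the post-translational fraction),
compares source-RNA fold-changes between up- and down-DEMs, and screens
peptide RNA support (rphm) against the 8.55 expression threshold.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED

from ereflow.differential import moderated_test, peptide_differential
from ereflow.integration import (
    build_candidate_db,
    concordance,
    concordance_counts,
    peptide_rphm,
    source_fold_change_test,
    tissue_screen,
)
from ereflow.synthetic import SimConfig, simulate_experiment, simulate_immunopeptidome, \
    simulate_proteome


def main() -> None:
    outdir = RESULTS / "tables"
    outdir.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(seed=SEED)
    cm, annotation, truth = simulate_experiment(sim)
    proteins, prot_truth = simulate_proteome(sim)
    peptides, _ = simulate_immunopeptidome(sim, proteins, prot_truth, truth)

    deg = moderated_test(cm.log2_cpm(), cm.groups, order=("AZA", "CT"))
    dem = peptide_differential(peptides, peptides.attrs["condition_columns"],
                               "AZA", "CT")

    expr = cm.cpm()[cm.samples_of("AZA")].mean(axis=1)
    db = build_candidate_db(
        prot_truth.transcripts,
        expr.reindex(list(prot_truth.transcripts)).fillna(0.0), min_cpm=1.0)
    print(f"candidate database: {len(db)} unique 8-11-mers")
    db.to_frame().to_csv(outdir / "candidate_db.tsv", sep="\t", index=False)

    reads = cm.counts[cm.samples_of("AZA")].sum(axis=1)
    total = float(cm.counts[cm.samples_of("AZA")].sum().sum())
    classes = concordance(dem, deg, db, reads)
    classes.to_csv(outdir / "concordance.tsv", sep="\t")
    print(concordance_counts(classes).to_string(index=False))
    fc = source_fold_change_test(classes)
    print(f"source-RNA log2FC, up vs down DEMs: "
          f"{fc['mean_up']:+.2f} vs {fc['mean_down']:+.2f} (p = {fc['p']:.4f})")

    profile = pd.DataFrame(
        {"treated": [peptide_rphm(p, db, reads, total)[0] for p in dem.index]},
        index=dem.index)
    flags, lowly = tissue_screen(profile)
    print(f"rphm screen at 8.55: {int(flags.values.sum())} peptide-context "
          f"cells flagged, {int(lowly.sum())} peptides lowly or not expressed")


if __name__ == "__main__":
    main()
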