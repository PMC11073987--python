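"""Candidate databases, rphm quantification, concordance and the tissue screen."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ereflow.differential import moderated_test, peptide_differential
from ereflow.integration import (
    build_candidate_db,
    concordance,
    peptide_rphm,
    rphm,
    tissue_screen,
    translate_three_frames,
)
from ereflow.synthetic import SimConfig, simulate_experiment, simulate_immunopeptidome, \
    simulate_proteome


class TestTranslation:
    def test_three_frames_of_a_hexamer(self):
        assert translate_three_frames("ATGGCC") == [["MA"], ["W"], ["G"]]

    def test_lone_stop_codon_yields_empty_frame(self):
        assert translate_three_frames("TAA")[0] == []

    def test_translation_is_deterministic(self):
        seq = "ATGGCCAAATTTGGGCCCTAG"
        assert translate_three_frames(seq) == translate_three_frames(seq)

    def test_n_codons_break_fragments_like_stops(self):
        # frame 1: ATG GNC AAA -> M, X, K: the X splits M from K
        frames = translate_three_frames("ATGGNCAAA")
        assert frames[0] == ["M", "K"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            translate_three_frames("")

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            translate_three_frames("ATGQ")


def _codons(protein):
    table = {"M": "ATG", "A": "GCT", "K": "AAA", "F": "TTT", "G": "GGT",
             "L": "CTT", "P": "CCT", "S": "TCT", "T": "ACT", "V": "GTT"}
    return "".join(table[aa] for aa in protein)


class TestCandidateDb:
    # frame 1 translates to the 10-mer SIMGYKSLLT; frames 2/3 only contain
    # fragments shorter than 8 residues, so they emit nothing
    TEN_MER_TX = "AGTATAATGGGATATAAGAGTCTTCTGACTTAA"

    def test_window_counts_for_a_ten_residue_fragment(self):
        # 10-aa frame-1 fragment: 3 8-mers + 2 9-mers + 1 10-mer = 6 peptides
        db = build_candidate_db({"T1": self.TEN_MER_TX}, {"T1": 10.0}, min_cpm=1.0)
        assert len(db) == 6
        assert "SIMGYKSL" in db and "SIMGYKSLLT" in db

    def test_below_min_cpm_contributes_nothing(self):
        tx = {"T1": _codons("MAKFGLPSTV")}
        db = build_candidate_db(tx, {"T1": 0.5}, min_cpm=1.0)
        assert len(db) == 0

    def test_shared_peptide_lists_both_sources(self):
        tx = {"T1": _codons("MAKFGLPSTV"), "T2": _codons("AMAKFGLPST")}
        db = build_candidate_db(tx, {"T1": 5.0, "T2": 5.0}, min_cpm=1.0)
        assert db.source_transcripts("MAKFGLPS") == {"T1", "T2"}

    def test_missing_expression_rejected(self):
        with pytest.raises(ValueError, match="T1"):
            build_candidate_db({"T1": "ATG"}, {}, 0.0)

    def test_every_emitted_peptide_is_refindable_in_its_translation(self):
        rng = np.random.default_rng(5)
        tx = {f"T{i}": "".join(rng.choice(list("ACGT"), size=90)) for i in range(8)}
        db = build_candidate_db(tx, {t: 10.0 for t in tx}, min_cpm=0.0)
        for pep, sources in db.peptides.items():
            for src in sources:
                frames = translate_three_frames(tx[src.transcript_id])
                assert any(pep in frag for frag in frames[src.frame])

    @settings(deadline=None, max_examples=20)
    @given(length=st.integers(min_value=1, max_value=40))
    def test_db_size_formula_over_all_fragments(self, length):
        """db size equals sum over every stop-free fragment F (all frames) of
        sum_{k=8}^{min(11,|F|)} (|F| - k + 1), deduplicated."""
        protein = ("MAKFGLPSTV" * 5)[:length]
        tx = {"T": _codons(protein) + "TAA"}
        db = build_candidate_db(tx, {"T": 1.0}, min_cpm=0.0)
        expected = set()
        for fragments in translate_three_frames(tx["T"]):
            for frag in fragments:
                for k in range(8, min(11, len(frag)) + 1):
                    for i in range(len(frag) - k + 1):
                        expected.add(frag[i : i + k])
        assert set(db.peptides) == expected


class TestRphm:
    def test_hand_value_at_threshold(self):
        assert rphm(171, 2e9) == pytest.approx(8.55)

    def test_zero_support_is_zero(self):
        assert rphm(0, 1e9) == 0.0

    def test_linear_in_reads_and_scale_invariant(self):
        assert rphm(342, 2e9) == pytest.approx(2 * rphm(171, 2e9))
        assert rphm(171 * 7, 2e9 * 7) == pytest.approx(rphm(171, 2e9))

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            rphm(1, 0)
        with pytest.raises(ValueError):
            rphm(-1, 10)

    def test_absent_peptide_flagged_rna_absent(self):
        tx = {"T1": _codons("MAKFGLPSTV")}
        db = build_candidate_db(tx, {"T1": 5.0}, min_cpm=0.0)
        value, absent = peptide_rphm("WWWWWWWW", db, {"T1": 100}, 1e8)
        assert value == 0.0 and absent

    def test_present_peptide_sums_source_reads(self):
        tx = {"T1": _codons("MAKFGLPSTV")}
        db = build_candidate_db(tx, {"T1": 5.0}, min_cpm=0.0)
        value, absent = peptide_rphm("MAKFGLPS", db, {"T1": 171}, 2e9)
        assert value == pytest.approx(8.55) and not absent


class TestTissueScreen:
    def test_strictly_above_threshold_rule(self):
        profile = pd.DataFrame({"tissue": [8.6, 8.55, 0.0]},
                               index=["hot", "edge", "cold"])
        flags, lowly = tissue_screen(profile)
        assert bool(flags.loc["hot", "tissue"])
        assert not bool(flags.loc["edge", "tissue"])  # 8.55 itself not flagged
        assert bool(lowly["edge"]) and bool(lowly["cold"]) and not bool(lowly["hot"])

    def test_all_zero_row_summarised_not_expressed(self):
        profile = pd.DataFrame(np.zeros((1, 4)), index=["pep"],
                               columns=list("abcd"))
        _, lowly = tissue_screen(profile)
        assert bool(lowly["pep"])


class TestConcordance:
    def _tables(self):
        dems = pd.DataFrame({"direction": ["up", "up", "down", "up"]},
                            index=["MAKFGLPS", "AKFGLPST", "KFGLPSTV", "WWWWWWWW"])
        degs = pd.DataFrame({"direction": ["up", "ns"], "log2FC": [2.0, 0.1]},
                            index=["T1", "T2"])
        tx = {"T1": _codons("MAKFGLPSTV"), "T2": _codons("AKFGLPSTVM")}
        db = build_candidate_db(tx, {"T1": 5.0, "T2": 5.0}, min_cpm=0.0)
        return dems, degs, db

    def test_classes_follow_best_source_direction(self):
        dems, degs, db = self._tables()
        # reads favour T1 for shared peptides
        out = concordance(dems, degs, db, {"T1": 100, "T2": 10})
        assert out.loc["MAKFGLPS", "rna_class"] == "rna_up"
        assert out.loc["WWWWWWWW", "rna_class"] == "rna_absent"

    def test_ns_source_is_rna_unchanged(self):
        dems, degs, db = self._tables()
        out = concordance(dems, degs, db, {"T1": 1, "T2": 100})
        assert out.loc["AKFGLPST", "rna_class"] == "rna_unchanged"  # T2 wins, ns

    def test_full_rna_drive_recovers_rna_up_classes(self):
        """With peptide fold-changes fully RNA-driven, nearly every up-DEM's
        best source is itself called up at the RNA level."""
        cfg = SimConfig(seed=1, n_genes=400, n_ere=100, n_cta=40, n_gene_up=60,
                        n_gene_down=20, n_proteins=300, n_peptides=1500,
                        rna_drive=1.0, pep_noise_sd=0.05, frac_pep_ere=0.0,
                        lfc_mean=2.5, lfc_sd=0.3, dispersion=0.02,
                        detect_dropout_scale=0.0)
        _, annotation, truth = simulate_experiment(cfg)
        proteins, prot_truth = simulate_proteome(cfg)
        peptides, _ = simulate_immunopeptidome(cfg, proteins, prot_truth, truth)
        cm, _, _ = simulate_experiment(cfg, truth=truth, annotation=annotation,
                                       seed=77)
        degs = moderated_test(cm.log2_cpm(), cm.groups, order=("AZA", "CT"))
        dems = peptide_differential(peptides, peptides.attrs["condition_columns"],
                                    "AZA", "CT")
        expr = cm.cpm().mean(axis=1)
        db = build_candidate_db(prot_truth.transcripts,
                                expr.reindex(list(prot_truth.transcripts)).fillna(0),
                                min_cpm=0.0)
        reads = cm.counts.sum(axis=1)
        out = concordance(dems, degs, db, reads)
        up = out[out["dem_direction"] == "up"]
        assert len(up) >= 50
        assert (up["rna_class"] == "rna_up").mean() >= 0.95

    def test_zero_rna_drive_matches_deg_base_rate(self):
        """With a = 0 the rna_up share of up-DEMs is indistinguishable from
        the overall DEG-up base rate among candidate sources."""
        from scipy.stats import fisher_exact

        cfg = SimConfig(seed=2, n_genes=400, n_ere=100, n_cta=40, n_gene_up=60,
                        n_gene_down=20, n_proteins=300, n_peptides=1500,
                        rna_drive=0.0, frac_pep_ere=0.0, dispersion=0.02,
                        detect_dropout_scale=0.2)
        _, annotation, truth = simulate_experiment(cfg)
        proteins, prot_truth = simulate_proteome(cfg)
        peptides, _ = simulate_immunopeptidome(cfg, proteins, prot_truth, truth)
        cm, _, _ = simulate_experiment(cfg, truth=truth, annotation=annotation,
                                       seed=78)
        degs = moderated_test(cm.log2_cpm(), cm.groups, order=("AZA", "CT"))
        dems = peptide_differential(peptides, peptides.attrs["condition_columns"],
                                    "AZA", "CT")
        expr = cm.cpm().mean(axis=1)
        db = build_candidate_db(prot_truth.transcripts,
                                expr.reindex(list(prot_truth.transcripts)).fillna(0),
                                min_cpm=0.0)
        out = concordance(dems, degs, db, cm.counts.sum(axis=1))
        up = out[out["dem_direction"] == "up"]
        rest = out[out["dem_direction"] != "up"]
        table = [[(up["rna_class"] == "rna_up").sum(),
                  (up["rna_class"] != "rna_up").sum()],
                 [(rest["rna_class"] == "rna_up").sum(),
                  (rest["rna_class"] != "rna_up").sum()]]
        assert fisher_exact(table)[1] > 0.01
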