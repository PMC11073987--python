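"""End-to-end orchestration: simulate -> differential -> ERE metrics ->
peptidome features -> peptide/RNA integration -> cohort analysis -> report.

A run is fully specified by a :class:`RunConfig` (thresholds + a SimConfig);
all randomness flows from the single root seed, expanded per stage with fixed
offsets inside the generators, so identical config + seed produces an
identical report byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import correlate_sets, gsea_preranked, ssgsea_matrix, stratify
from .differential import (
    call_condition_specific,
    common_elements,
    dem_deg_correlation,
    direction_counts,
    moderated_test,
    peptide_differential,
)
from .ere import class_enrichment, cumulative_ere_cpm, he_ere_count, median_split
from .integration import RPHM_THRESHOLD, build_candidate_db, concordance, \
    concordance_counts, rphm, source_fold_change_test, tissue_screen
from .peptidome import (
    cterm_association,
    composition_correlation,
    dem_count_group_test,
    gravy,
    polar_fraction,
    protein_feature_table,
)
from .synthetic import (
    SimConfig,
    line_truth,
    random_gene_set_collection,
    simulate_cohort,
    simulate_experiment,
    simulate_immunopeptidome,
    simulate_proteome,
)


@dataclass
class RunConfig:
    """Thresholds and simulation directives for an end-to-end run."""

    seed: int = 0
    tau_lfc: float = 1.0
    tau_fdr: float = 0.05
    theta_rphm: float = RPHM_THRESHOLD
    min_cpm: float = 1.0
    n_cell_lines: int = 4
    n_perm: int = 499
    outdir: str = "results"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if not 0.0 < self.tau_fdr <= 1.0:
            raise ValueError(f"tau_fdr must lie in (0, 1] (got {self.tau_fdr})")
        if self.tau_lfc < 0:
            raise ValueError("tau_lfc must be >= 0")
        if self.n_cell_lines < 1:
            raise ValueError("n_cell_lines must be >= 1")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def ere_map_fraction(
    detected_biotypes: Mapping[str, Sequence[str]]
) -> dict:
    """Fraction of detected MAPs with ERE biotype, per condition, plus ratio.

    ``detected_biotypes`` maps condition -> the biotype of every MAP detected
    in that condition. The ratio divides the first condition's fraction by
    the second's (0 when the denominator's numerator count is 0).
    """
    out: dict = {"fractions": {}, "counts": {}}
    for cond, biotypes in detected_biotypes.items():
        biotypes = list(biotypes)
        if not biotypes:
            raise ValueError(f"no detected MAPs in condition {cond!r}")
        n_ere = sum(b == "ERE" for b in biotypes)
        out["counts"][cond] = {"ERE": n_ere, "total": len(biotypes)}
        out["fractions"][cond] = n_ere / len(biotypes)
    conds = list(detected_biotypes)
    if len(conds) >= 2:
        fa, fb = out["fractions"][conds[0]], out["fractions"][conds[1]]
        out["ratio"] = fa / fb if fb > 0 else 0.0
    return out


def _feature_biotype(fid: str, cta_ids: set[str], coding_ids: set[str]) -> str:
    if fid.startswith("ERE"):
        return "ERE"
    if fid in cta_ids:
        return "CTA"
    if fid in coding_ids:
        return "canonical"
    return "other-noncanonical"


def run_end_to_end(config: RunConfig) -> dict:
    """Execute every stage in dependency order and return the report dict."""
    sim = config.sim
    report: dict = {
        "provenance": {"config_hash": config.hash(), "seed": config.seed,
                       "version": __version__},
    }

    # --- stage 1: simulated cell-line experiments sharing one planted truth,
    # each responding on a nested sensitivity-dependent feature subset
    cm0, annotation, truth = simulate_experiment(sim)
    sens = list(sim.line_sensitivity)
    if len(sens) < config.n_cell_lines:
        sens += [sens[-1]] * (config.n_cell_lines - len(sens))
    line_truths = [line_truth(truth, sens[k], seed=sim.seed + 50)
                   for k in range(config.n_cell_lines)]
    lines = []
    for k in range(config.n_cell_lines):
        cm_k, _, _ = simulate_experiment(sim, truth=line_truths[k],
                                         annotation=annotation,
                                         seed=sim.seed + 100 + k)
        lines.append(cm_k)
    genes, loci = annotation
    cta_ids = {g.gene_id for g in genes if g.is_cta}
    coding_ids = {g.gene_id for g in genes if g.biotype == "protein_coding"}

    # --- stage 2: RNA differential expression per line
    deg_tables = []
    for cm in lines:
        table = moderated_test(cm.log2_cpm(), cm.groups, order=("AZA", "CT"),
                               tau_lfc=config.tau_lfc, tau_fdr=config.tau_fdr)
        deg_tables.append(table)
    deg_counts = [direction_counts(t) for t in deg_tables]
    up_all = direction_counts(deg_tables[0])
    report["deg"] = {
        "per_line": deg_counts,
        "up_fraction_line1": up_all["up"] / max(up_all["up"] + up_all["down"], 1),
    }

    common_up = common_elements(deg_tables, "up")
    common_up_ere = sorted(i for i in common_up if i.startswith("ERE"))
    report["common_up"] = {
        "n_features": len(common_up),
        "n_ere": len(common_up_ere),
        "biotype_composition": pd.Series(
            [_feature_biotype(i, cta_ids, coding_ids) for i in common_up]
        ).value_counts(normalize=True).to_dict() if common_up else {},
    }

    # --- stage 3: ERE class enrichment of the commonly induced loci
    if common_up_ere:
        enr = class_enrichment(common_up_ere, loci)
        report["class_enrichment"] = {
            k: {"ratio": float(enr.loc[k, "ratio"]), "p": float(enr.loc[k, "p"])}
            for k in enr.index
        }

    # --- stage 4: immunopeptidome differential abundance per line
    proteins, prot_truth = simulate_proteome(sim)
    dem_tables, pep_tables = [], []
    for k in range(config.n_cell_lines):
        sim_k = replace(sim, frac_pep_affected=sim.frac_pep_affected * sens[k])
        peptides, _ = simulate_immunopeptidome(sim_k, proteins, prot_truth,
                                               line_truths[k],
                                               seed=sim.seed + 200 + k)
        cond_cols = peptides.attrs["condition_columns"]
        dem = peptide_differential(peptides, cond_cols, "AZA", "CT",
                                   tau_lfc=config.tau_lfc, tau_fdr=config.tau_fdr)
        pep_tables.append(peptides)
        dem_tables.append(dem)
    dem_counts = [direction_counts(t) for t in dem_tables]
    report["dem"] = {"per_line": dem_counts}

    n_dems = [c["up"] + c["down"] for c in dem_counts]
    n_degs = [c["up"] + c["down"] for c in deg_counts]
    r, p = dem_deg_correlation(n_dems, n_degs)
    report["dem_deg_correlation"] = {"r": r, "p": p}

    peptides, dem = pep_tables[0], dem_tables[0]
    cond_cols = peptides.attrs["condition_columns"]
    specific = call_condition_specific(peptides, cond_cols, "AZA", "CT")
    up_dem = dem.index[dem["direction"] == "up"]
    report["condition_specific"] = {
        "n": int(specific.sum()),
        "fraction_of_up": float(specific.reindex(up_dem).fillna(False).mean())
        if len(up_dem) else 0.0,
    }

    # ERE-MAP fraction of the detected immunopeptidome, per condition
    from .differential import detection_matrix

    det = detection_matrix(peptides[cond_cols["AZA"] + cond_cols["CT"]])
    biotype = peptides["source"].map(
        lambda s: _feature_biotype(s, cta_ids, coding_ids)
    )
    detected = {
        cond: list(biotype[det[list(cols)].any(axis=1)])
        for cond, cols in (("AZA", cond_cols["AZA"]), ("CT", cond_cols["CT"]))
    }
    report["ere_map_fraction"] = ere_map_fraction(detected)

    # --- stage 5: peptidome sequence features of up vs down DEMs
    up_seqs = [s for s in dem.index[dem["direction"] == "up"]]
    down_seqs = [s for s in dem.index[dem["direction"] == "down"]]
    if up_seqs and down_seqs:
        fisher = cterm_association(up_seqs, down_seqs)
        n_up_per_protein = peptides.loc[
            peptides.index.intersection(up_seqs), "source"].value_counts()
        n_down_per_protein = peptides.loc[
            peptides.index.intersection(down_seqs), "source"].value_counts()
        feats = protein_feature_table(proteins, n_up_per_protein, n_down_per_protein)
        comp = composition_correlation(feats[list("ACDEFGHIKLMNPQRSTVWY")],
                                       feats["n_up"])
        top = comp.sort_values("rho", ascending=False).head(3)
        try:
            dgv_test = dem_count_group_test(feats)
        except ValueError:
            dgv_test = None
        report["peptidome_features"] = {
            "mean_gravy_up": float(np.mean([gravy(s) for s in up_seqs])),
            "mean_gravy_down": float(np.mean([gravy(s) for s in down_seqs])),
            "mean_polar_up": float(np.mean([polar_fraction(s) for s in up_seqs])),
            "mean_polar_down": float(np.mean([polar_fraction(s) for s in down_seqs])),
            "cterm_fisher": {"odds_ratio": fisher["odds_ratio"], "p": fisher["p"]},
            "top_composition_residues": list(top.index),
            "dgv_group_test": dgv_test,
        }

    # --- stage 6: peptide-to-RNA integration (candidate db, concordance, rphm)
    cm = lines[0]
    expr_cpm = cm.cpm()[cm.samples_of("AZA")].mean(axis=1)
    transcripts = prot_truth.transcripts
    db = build_candidate_db(transcripts, expr_cpm.reindex(list(transcripts)).fillna(0.0),
                            min_cpm=config.min_cpm)
    read_support = cm.counts[cm.samples_of("AZA")].sum(axis=1)
    total_reads = float(cm.counts[cm.samples_of("AZA")].sum().sum())
    classes = concordance(dem, deg_tables[0], db, read_support)
    report["concordance"] = {
        "counts": concordance_counts(classes).to_dict(orient="records"),
        "fold_change_test": source_fold_change_test(classes),
    }
    dem_rphm = pd.DataFrame({
        "treated": [
            rphm(float(sum(read_support.get(t, 0.0)
                           for t in db.source_transcripts(pep))), total_reads)
            if pep in db else 0.0
            for pep in dem.index
        ]}, index=dem.index)
    flags, lowly = tissue_screen(dem_rphm, threshold=config.theta_rphm)
    report["rphm_screen"] = {
        "n_flagged": int(flags.to_numpy().sum()),
        "n_lowly_or_not_expressed": int(lowly.sum()),
        "threshold": config.theta_rphm,
    }

    # --- stage 7: cohort analysis
    cohort, cohort_truth = simulate_cohort(sim)
    gene_rows = [f for f in cohort.cpm.index if not f.startswith("ERE")]
    ere_set = list(cohort_truth.induced_ere_ids)
    e_p = cumulative_ere_cpm(cohort.cpm, ere_set)
    h_p = he_ere_count(cohort.cpm, ere_set)
    split = median_split(e_p)
    collection = random_gene_set_collection(
        [g for g in gene_rows if g not in ("CD8A", "CD8B")],
        n_sets=50, seed=sim.seed + 4,
        include={"AUTOPHAGY": cohort_truth.autophagy_genes},
    )
    scores = ssgsea_matrix(cohort.cpm.loc[gene_rows], collection)
    ranking = correlate_sets(scores, e_p, tail="negative")
    strata = stratify(cohort.cpm, ere_set, ere_axis="he_ere")
    high = strata.index[strata["ere_label"] == "high"]
    cd8_groups = strata.loc[high, "cd8_label"]
    gene_expr = np.log2(cohort.cpm.loc[gene_rows, high] + 1.0)
    cd8_de = moderated_test(gene_expr, cd8_groups, order=("high", "low"))
    gsea = gsea_preranked(cd8_de["t"], cohort_truth.autophagy_genes,
                          n_perm=config.n_perm, seed=config.seed,
                          set_name="AUTOPHAGY")
    report["cohort"] = {
        "n_samples": cohort.n_samples,
        "split_sizes": split.value_counts().to_dict(),
        "autophagy_rho": float(ranking.loc["AUTOPHAGY", "rho"]),
        "autophagy_rank": float(ranking.loc["AUTOPHAGY", "rank"]),
        "autophagy_top_decile": bool(ranking.loc["AUTOPHAGY", "top_decile"]),
        "strata_sizes": strata["stratum"].value_counts().to_dict(),
        "autophagy_nes_cd8_high_vs_low_in_ere_high": gsea.nes,
        "autophagy_gsea_p": gsea.p,
    }
    return report


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, outdir: str | Path) -> tuple[Path, Path]:
    """Emit the machine-readable JSON and a human-readable text mirror."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    text_path = outdir / "report.txt"
    payload = _to_jsonable(report)
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(text_path, "w") as fh:
        fh.write(_render_text(payload))
    return json_path, text_path


def _render_text(report: dict, indent: int = 0) -> str:
    lines = []
    pad = "  " * indent
    for key, value in report.items():
        if isinstance(value, dict):
            lines.append(f"{pad}{key}:")
            lines.append(_render_text(value, indent + 1))
        elif isinstance(value, list):
            lines.append(f"{pad}{key}: {json.dumps(value)}")
        else:
            if isinstance(value, float):
                value = f"{value:.6g}"
            lines.append(f"{pad}{key}: {value}")
    return "\n".join(line for line in lines if line) + ("\n" if indent == 0 else "")
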