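"""Synthetic study data with planted, recoverable effect structure.

Everything downstream of raw sequencing/MS is testable against this module:
it emulates (i) negative-binomial RNA-seq counts for genes and ERE loci where
treatment-induced upregulation concentrates in LINE/LTR classes and in a
cancer-testis (CTA) gene subset while SINEs receive no planted effect;
(ii) a proteome whose residue frequencies follow a Dirichlet, with a subset
enriched in Asp/Gly/Val that preferentially yields upregulated peptides;
(iii) an MHC-I peptide table whose log2 fold-changes are a mixture of an
RNA-driven component and an independent (post-transcriptional) component,
with log-normal intensities and missing-not-at-random detection dropout; and
(iv) a patient cohort in which a latent per-sample autophagy activity A_p
drives autophagy-gene expression up and induced-ERE expression down.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a fixed
seed gives bit-identical output across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .differential import CountMatrix
from .ere import CohortFrame
from .io import (
    EreLocus,
    GeneModel,
    GeneSetCollection,
    GenomicInterval,
    write_counts,
    write_ere_bed,
    write_fasta,
    write_gmt,
    write_gtf_genes,
    write_id_list,
    write_peptides,
)
from .peptidome import AMINO_ACIDS, POLAR

_MEAN_POLAR = len(POLAR) / len(AMINO_ACIDS)  # expected polar fraction, uniform residues

# codons per residue for reverse-translating simulated proteins into CDS
_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_ERE_FAMILIES = {"LINE": "L1", "SINE": "Alu", "LTR": "ERVL", "Other": "SVA"}


@dataclass
class SimConfig:
    """All simulation knobs; defaults are the desk-scale study conditions."""

    seed: int = 0
    # experiment (per cell line)
    n_genes: int = 2000
    n_ere: int = 3000
    class_mix: dict = field(
        default_factory=lambda: {"LINE": 0.35, "SINE": 0.45, "LTR": 0.15, "Other": 0.05}
    )
    n_cta: int = 100
    frac_ere_up: float = 0.3
    n_gene_up: int = 150
    n_gene_down: int = 50
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    dispersion: float = 0.1
    n_reps_per_group: int = 3
    # per-cell-line sensitivity: fraction of planted features responding in
    # each line (nested, so a common responsive core exists across lines)
    line_sensitivity: tuple = (1.0, 0.75, 0.55, 0.4)
    # proteome / immunopeptidome
    n_proteins: int = 500
    protein_length: int = 300
    dgv_enrichment: float = 3.0
    frac_dgv_enriched: float = 0.2
    n_peptides: int = 2000
    rna_drive: float = 0.3
    frac_pep_affected: float = 0.25
    pep_lfc_sd: float = 2.0
    pep_noise_sd: float = 0.3
    polar_coupling: float = 4.0  # log2FC per unit excess polar fraction
    frac_pep_ere: float = 0.01
    detect_dropout_scale: float = 1.0
    dropout_mid: float = 10.0  # log2-intensity at which dropout is half its max
    # cohort
    cohort_n: int = 437
    cohort_n_genes: int = 1500
    cohort_n_ere: int = 800
    n_induced_ere: int = 500
    n_autophagy: int = 50
    beta_autophagy: float = 1.0
    beta_cd8: float = 1.0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        for name in ("frac_ere_up", "rna_drive", "frac_pep_affected",
                     "frac_dgv_enriched", "frac_pep_ere"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (got {v})")
        if self.cohort_n < 4:
            raise ValueError("cohort_n must be >= 4")
        if self.beta_autophagy < 0:
            raise ValueError("beta_autophagy must be >= 0")
        if self.detect_dropout_scale < 0:
            raise ValueError("detect_dropout_scale must be >= 0")
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SimTruth:
    """Ground truth planted by the generators (what recovery tests check)."""

    feature_lfc: pd.Series | None = None  # per gene/ERE true log2FC
    feature_mean: pd.Series | None = None  # baseline NB means (shared across lines)
    dgv_enriched: tuple[str, ...] = ()  # proteins with planted D/G/V enrichment
    transcripts: dict[str, str] = field(default_factory=dict)  # CDS per protein
    peptide_lfc: pd.Series | None = None
    peptide_rna_driven: pd.Series | None = None
    autophagy_activity: pd.Series | None = None  # latent A_p per cohort sample
    autophagy_genes: tuple[str, ...] = ()
    induced_ere_ids: tuple[str, ...] = ()


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean^2) via gamma-Poisson mixing."""
    mean = np.maximum(np.asarray(mean, float), 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _make_annotation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[EreLocus]]:
    genes = []
    for i in range(config.n_genes):
        gene_id = f"GENE{i + 1:05d}"
        biotype = "protein_coding" if i < int(0.85 * config.n_genes) else (
            "lncRNA" if i % 2 == 0 else "ncRNA"
        )
        start = 1000 * (i + 1)
        iv = GenomicInterval("chr1", start, start + 500, "+" if i % 2 == 0 else "-")
        genes.append(GeneModel(gene_id, biotype, is_cta=i < config.n_cta, intervals=(iv,)))
    classes = rng.choice(
        list(config.class_mix), size=config.n_ere, p=list(config.class_mix.values())
    )
    loci = []
    for i, klass in enumerate(classes):
        start = 500 * (i + 1)
        iv = GenomicInterval("chr2", start, start + 300, "+" if i % 3 else "-")
        loci.append(EreLocus(f"ERE{i + 1:05d}", iv, str(klass), _ERE_FAMILIES[str(klass)]))
    return genes, loci


def _plant_truth(
    config: SimConfig,
    genes: list[GeneModel],
    loci: list[EreLocus],
    rng: np.random.Generator,
) -> SimTruth:
    ids = [g.gene_id for g in genes] + [l.locus_id for l in loci]
    lfc = pd.Series(0.0, index=ids)
    mean = pd.Series(rng.lognormal(np.log(60.0), 1.2, size=len(ids)), index=ids)

    cta_ids = [g.gene_id for g in genes if g.is_cta]
    non_cta = [g.gene_id for g in genes if not g.is_cta]
    up_genes = list(rng.choice(non_cta, size=min(config.n_gene_up, len(non_cta)),
                               replace=False))
    remaining = [g for g in non_cta if g not in set(up_genes)]
    down_genes = list(rng.choice(remaining, size=min(config.n_gene_down, len(remaining)),
                                 replace=False))
    line_ltr = [l.locus_id for l in loci if l.ere_class in ("LINE", "LTR")]
    n_ere_up = int(round(config.frac_ere_up * len(line_ltr)))
    up_eres = list(rng.choice(line_ltr, size=n_ere_up, replace=False))

    for group, sign in ((cta_ids, +1), (up_genes, +1), (up_eres, +1), (down_genes, -1)):
        if group:
            lfc[group] = sign * rng.normal(config.lfc_mean, config.lfc_sd, size=len(group))
    return SimTruth(feature_lfc=lfc, feature_mean=mean)


def line_truth(truth: SimTruth, sensitivity: float, seed: int) -> SimTruth:
    """Restrict planted effects to a nested responding subset of features.

    Cell lines differ in how broadly they respond; a line with sensitivity s
    keeps the planted fold-change on the first ceil(s * n_planted) features
    of a fixed (seed-determined) ordering, so lower-sensitivity lines respond
    on nested subsets and a common responsive core exists across lines.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must lie in [0, 1]")
    planted = truth.feature_lfc.index[truth.feature_lfc != 0]
    order = np.random.default_rng(seed).permutation(np.asarray(planted))
    keep = set(order[: int(np.ceil(sensitivity * len(order)))])
    lfc = truth.feature_lfc.copy()
    lfc[[i for i in planted if i not in keep]] = 0.0
    return SimTruth(feature_lfc=lfc, feature_mean=truth.feature_mean)


def simulate_experiment(
    config: SimConfig,
    truth: SimTruth | None = None,
    annotation: tuple[list[GeneModel], list[EreLocus]] | None = None,
    seed: int | None = None,
) -> tuple[CountMatrix, tuple[list[GeneModel], list[EreLocus]], SimTruth]:
    """One treated-vs-control RNA-seq experiment with planted effects.

    Passing an existing ``truth`` (and its annotation) reuses the planted
    fold-changes and baseline means but draws fresh counts — this is how
    several "cell lines" sharing the same induced features are simulated.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if annotation is None:
        annotation = _make_annotation(config, rng)
    genes, loci = annotation
    if truth is None:
        truth = _plant_truth(config, genes, loci, rng)
    n = config.n_reps_per_group
    samples = [f"CT_{i + 1}" for i in range(n)] + [f"AZA_{i + 1}" for i in range(n)]
    groups = pd.Series(["CT"] * n + ["AZA"] * n, index=samples)
    base = truth.feature_mean.to_numpy()[:, None]
    fold = 2.0 ** truth.feature_lfc.to_numpy()[:, None]
    mean = np.hstack([np.repeat(base, n, axis=1), np.repeat(base * fold, n, axis=1)])
    counts = _nb_counts(rng, mean, config.dispersion)
    cm = CountMatrix(pd.DataFrame(counts, index=truth.feature_lfc.index, columns=samples),
                     groups)
    return cm, annotation, truth


def simulate_proteome(
    config: SimConfig, seed: int | None = None
) -> tuple[dict[str, str], SimTruth]:
    """Proteins with Dirichlet residue frequencies; a subset enriched in D/G/V.

    Protein ids coincide with the first ``n_proteins`` gene ids so peptides
    can be traced back to transcripts; the CDS obtained by reverse
    translation is stored in the truth for candidate-database construction.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    if config.n_proteins > config.n_genes:
        raise ValueError("n_proteins cannot exceed n_genes")
    base_alpha = np.full(len(AMINO_ACIDS), 2.5)
    dg_idx = [AMINO_ACIDS.index(a) for a in "DG"]
    v_idx = AMINO_ACIDS.index("V")
    n_enriched = int(round(config.frac_dgv_enriched * config.n_proteins))
    ids = [f"GENE{i + 1:05d}" for i in range(config.n_proteins)]
    enriched = set(rng.choice(ids, size=n_enriched, replace=False))
    proteins: dict[str, str] = {}
    transcripts: dict[str, str] = {}
    for pid in ids:
        alpha = base_alpha.copy()
        if pid in enriched:
            # Asp/Gly carry the full planted enrichment; Val (the third
            # DNMT2-target residue) half of it, mirroring the weaker Val signal
            alpha[dg_idx] *= config.dgv_enrichment
            alpha[v_idx] *= 1.0 + (config.dgv_enrichment - 1.0) / 2.0
        probs = rng.dirichlet(alpha)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=config.protein_length, p=probs))
        proteins[pid] = seq
        transcripts[pid] = "".join(_CODONS[aa] for aa in seq)
    truth = SimTruth(dgv_enriched=tuple(sorted(enriched)), transcripts=transcripts)
    return proteins, truth


def simulate_immunopeptidome(
    config: SimConfig,
    proteome: Mapping[str, str],
    proteome_truth: SimTruth,
    experiment_truth: SimTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """An MHC-I peptide intensity table coupled to the RNA ground truth.

    Each peptide's true log2FC is a * (source RNA log2FC) + (1 - a) * e, with
    a = ``rna_drive`` and e an independent effect drawn for an "affected"
    subset (peptides from D/G/V-enriched proteins are affected more often and
    with positive sign, emulating aggregation-driven presentation).
    Intensities are log-normal; detection is missing-not-at-random with
    dropout probability clip(detect_dropout_scale, 0, 1) * logistic(mid - x)
    in log2-intensity x, so the knob's zero limit switches dropout off.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    protein_ids = list(proteome)
    enriched = set(proteome_truth.dgv_enriched)
    ere_ids = [fid for fid in experiment_truth.feature_lfc.index if fid.startswith("ERE")]
    a = config.rna_drive

    rows = []
    seen: set[str] = set()
    n_target = config.n_peptides
    while len(rows) < n_target:
        from_ere = rng.random() < config.frac_pep_ere
        if from_ere and ere_ids:
            source = str(rng.choice(ere_ids))
            length = int(rng.integers(8, 12))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            src_is_enriched = False
        else:
            source = str(rng.choice(protein_ids))
            prot = proteome[source]
            length = int(rng.integers(8, min(12, len(prot) + 1)))
            start = int(rng.integers(0, len(prot) - length + 1))
            seq = prot[start : start + length]
            src_is_enriched = source in enriched
        assert 8 <= len(seq) <= 11
        if seq in seen:
            continue
        seen.add(seq)
        rna_lfc = float(experiment_truth.feature_lfc.get(source, 0.0))
        p_aff = min(1.0, 3.0 * config.frac_pep_affected) if src_is_enriched \
            else config.frac_pep_affected
        if rng.random() < p_aff:
            if src_is_enriched:
                indep = float(rng.normal(config.lfc_mean, config.lfc_sd))
            else:
                # post-transcriptional effect skewed towards polar peptides
                polar = sum(aa in POLAR for aa in seq) / len(seq)
                shift = config.polar_coupling * (polar - _MEAN_POLAR)
                indep = float(rng.normal(shift, config.pep_lfc_sd))
        else:
            indep = 0.0
        true_lfc = a * rna_lfc + (1.0 - a) * indep
        rows.append({"sequence": seq, "source": source, "true_lfc": true_lfc,
                     "rna_driven": a > 0 and rna_lfc != 0.0})

    n = config.n_reps_per_group
    ct_cols = [f"CT_{i + 1}" for i in range(n)]
    aza_cols = [f"AZA_{i + 1}" for i in range(n)]
    table = pd.DataFrame(index=[r["sequence"] for r in rows])
    table.index.name = "sequence"
    table["source"] = [r["source"] for r in rows]
    base_log2 = rng.normal(12.0, 2.0, size=len(rows))
    true_lfc = np.array([r["true_lfc"] for r in rows])
    for cols, shift in ((ct_cols, 0.0), (aza_cols, 1.0)):
        for col in cols:
            log2_i = base_log2 + shift * true_lfc + rng.normal(0.0, config.pep_noise_sd,
                                                               size=len(rows))
            intensity = 2.0 ** log2_i
            p_miss = min(config.detect_dropout_scale, 1.0) / (
                1.0 + np.exp(log2_i - config.dropout_mid)
            )
            missing = rng.random(len(rows)) < p_miss
            table[col] = np.where(missing, np.nan, intensity)
    truth = SimTruth(
        peptide_lfc=pd.Series(true_lfc, index=table.index),
        peptide_rna_driven=pd.Series([r["rna_driven"] for r in rows], index=table.index),
    )
    table.attrs["condition_columns"] = {"CT": ct_cols, "AZA": aza_cols}
    return table, truth


def simulate_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[CohortFrame, SimTruth]:
    """A patient cohort with a latent autophagy activity A_p ~ N(0, 1).

    ``beta_autophagy`` is the single coupling strength: autophagy-set genes
    scale as 2^(+beta_autophagy * A_p), the induced-ERE loci as
    2^(-beta_autophagy * A_p), and the CD8 markers as 2^(-beta_cd8 * A_p);
    all other features are uncoupled. Expression is returned as cpm with a
    vanishing continuous jitter so per-sample cumulative scores are almost
    surely distinct.
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    samples = [f"P{i + 1:04d}" for i in range(config.cohort_n)]
    A = rng.normal(0.0, 1.0, size=config.cohort_n)

    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.cohort_n_genes)]
    autophagy = tuple(
        sorted(rng.choice(gene_ids, size=config.n_autophagy, replace=False))
    )
    ere_ids = [f"ERE{i + 1:05d}" for i in range(config.cohort_n_ere)]
    induced = tuple(
        sorted(rng.choice(ere_ids, size=min(config.n_induced_ere, len(ere_ids)),
                          replace=False))
    )
    markers = ["CD8A", "CD8B"]
    feature_ids = gene_ids + markers + ere_ids

    base = rng.lognormal(np.log(60.0), 1.2, size=len(feature_ids))
    coupling = np.zeros(len(feature_ids))
    index = {fid: i for i, fid in enumerate(feature_ids)}
    for g in autophagy:
        coupling[index[g]] = config.beta_autophagy
    for e in induced:
        coupling[index[e]] = -config.beta_autophagy
    for m in markers:
        coupling[index[m]] = -config.beta_cd8

    mean = base[:, None] * 2.0 ** (coupling[:, None] * A[None, :])
    counts = _nb_counts(rng, mean, config.dispersion)
    counts_df = pd.DataFrame(counts, index=feature_ids, columns=samples)
    lib = counts_df.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("cohort sample with zero library size; increase feature counts")
    cpm = counts_df * 1e6 / lib
    cpm += rng.uniform(0.0, 1e-9, size=cpm.shape)  # tie-break jitter

    frame = CohortFrame(cpm=cpm, ere_ids=tuple(ere_ids))
    truth = SimTruth(
        autophagy_activity=pd.Series(A, index=samples),
        autophagy_genes=autophagy,
        induced_ere_ids=induced,
    )
    return frame, truth


def random_gene_set_collection(
    universe: list[str],
    n_sets: int,
    seed: int,
    size_range: tuple[int, int] = (20, 60),
    include: Mapping[str, tuple[str, ...]] | None = None,
) -> GeneSetCollection:
    """Random gene sets over a universe, optionally including named true sets."""
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset[str]] = {}
    if include:
        for name, members in include.items():
            sets[name] = frozenset(members)
    for i in range(n_sets - len(sets)):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"RANDOM_SET_{i + 1:04d}"] = frozenset(
            rng.choice(universe, size=min(size, len(universe)), replace=False)
        )
    return GeneSetCollection(sets=sets, source="synthetic")


def write_experiment_bundle(
    outdir: str | Path, config: SimConfig
) -> dict[str, Path]:
    """Simulate everything once and write the io-format bundle to ``outdir``.

    Emits counts TSV, gene GTF, ERE BED6+2, CTA id list, protein and
    transcript FASTA, peptide CSV, a cohort matrix TSV and a GMT collection —
    the same formats the readers in :mod:`ereflow.io` accept, so the CLI can
    run end-to-end from files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, (genes, loci), truth = simulate_experiment(config)
    proteins, prot_truth = simulate_proteome(config)
    peptides, pep_truth = simulate_immunopeptidome(config, proteins, prot_truth, truth)
    cohort, cohort_truth = simulate_cohort(config)
    collection = random_gene_set_collection(
        [f"GENE{i + 1:05d}" for i in range(config.cohort_n_genes)],
        n_sets=50, seed=config.seed + 4,
        include={"AUTOPHAGY": cohort_truth.autophagy_genes},
    )
    paths = {
        "counts": outdir / "counts.tsv",
        "gtf": outdir / "genes.gtf",
        "ere_bed": outdir / "ere_loci.bed",
        "cta": outdir / "cta_ids.txt",
        "proteins": outdir / "proteins.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "peptides": outdir / "peptides.csv",
        "cohort": outdir / "cohort_cpm.tsv",
        "gmt": outdir / "gene_sets.gmt",
        "groups": outdir / "groups.tsv",
        "config": outdir / "sim_config.yaml",
    }
    write_counts(cm.counts, paths["counts"])
    write_gtf_genes(genes, paths["gtf"])
    write_ere_bed(loci, paths["ere_bed"])
    write_id_list([g.gene_id for g in genes if g.is_cta], paths["cta"])
    write_fasta(proteins, paths["proteins"])
    write_fasta(prot_truth.transcripts, paths["transcripts"])
    write_peptides(peptides, paths["peptides"])
    cohort.cpm.to_csv(paths["cohort"], sep="\t", index_label="feature_id")
    write_gmt(collection, paths["gmt"])
    cm.groups.rename("group").to_csv(paths["groups"], sep="\t", index_label="sample")
    config.to_yaml(paths["config"])
    return paths


def null_config(**overrides) -> SimConfig:
    """A configuration with no planted effects anywhere (all true lfc = 0)."""
    base = dict(lfc_mean=0.0, lfc_sd=0.0, frac_ere_up=0.0, n_gene_up=0,
                n_gene_down=0, n_cta=0, frac_pep_affected=0.0,
                beta_autophagy=0.0, beta_cd8=0.0)
    base.update(overrides)
    return SimConfig(**base)
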