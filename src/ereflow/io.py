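"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are normalised at this boundary to a single internal
convention: 0-based, half-open. GTF input (1-based, inclusive) is converted on
read and back on write; the BED-like ERE annotation is already 0-based
half-open. Every reader validates eagerly and raises :class:`FormatError`
naming the offending line or field, so downstream code can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ERE_CLASSES = ("LINE", "SINE", "LTR", "Other")
GENE_BIOTYPES = ("protein_coding", "lncRNA", "ncRNA")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EreLocus:
    """A single endogenous-retroelement locus with its class (LINE/SINE/LTR)."""

    locus_id: str
    interval: GenomicInterval
    ere_class: str
    family: str = ""

    def __post_init__(self):
        if self.ere_class not in ERE_CLASSES:
            raise FormatError(
                f"unknown ERE class {self.ere_class!r} for locus "
                f"{self.locus_id!r}; allowed: {', '.join(ERE_CLASSES)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with biotype, optional cancer-testis-antigen status and exons."""

    gene_id: str
    biotype: str
    is_cta: bool = False
    intervals: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if self.biotype not in GENE_BIOTYPES:
            raise FormatError(
                f"unknown biotype {self.biotype!r} for gene {self.gene_id!r}; "
                f"allowed: {', '.join(GENE_BIOTYPES)}"
            )
        if len(self.intervals) < 1:
            raise FormatError(f"gene {self.gene_id!r} has no intervals")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT currency) for ORA / ssGSEA / GSEA."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# annotation: GTF (genes) + BED6+2 (ERE loci)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf_genes(path: str | Path, cta_ids: Iterable[str] = ()) -> list[GeneModel]:
    """Parse gene models from a GTF file.

    Exon lines, when present, provide the intervals; genes without exon lines
    fall back to their gene-line span. GTF 1-based inclusive coordinates are
    converted to the internal 0-based half-open convention here and nowhere
    else.
    """
    cta = set(cta_ids)
    spans: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            try:
                start_i, end_i = int(start) - 1, int(end)  # 1-based incl -> 0-based half-open
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 0 or start_i >= end_i:
                raise FormatError(f"{path}:{lineno}: start >= end")
            iv = GenomicInterval(chrom, start_i, end_i, strand if strand in "+-" else ".")
            if feature == "gene":
                biotype = attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding"))
                spans[gene_id] = {"interval": iv, "biotype": biotype}
            else:
                exons.setdefault(gene_id, []).append(iv)
    genes = []
    for gene_id, info in spans.items():
        ivs = tuple(exons.get(gene_id, [info["interval"]]))
        genes.append(
            GeneModel(gene_id, info["biotype"], is_cta=gene_id in cta, intervals=ivs)
        )
    return genes


_ERE_BED_COLS = ("chrom", "start", "end", "locus_id", "score", "strand", "ere_class", "family")


def read_ere_bed(path: str | Path) -> list[EreLocus]:
    """Parse the BED6+2 ERE annotation (columns: BED6 + ere_class, family)."""
    loci: list[EreLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected 8 BED6+2 columns")
            chrom, start, end, locus_id, _score, strand, ere_class, family = fields[:8]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i >= end_i:
                raise FormatError(f"{path}:{lineno}: start >= end ({start_i} >= {end_i})")
            if ere_class not in ERE_CLASSES:
                raise FormatError(
                    f"{path}:{lineno}: unknown ERE class {ere_class!r}; "
                    f"allowed: {', '.join(ERE_CLASSES)}"
                )
            if locus_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate locus_id {locus_id!r}")
            seen.add(locus_id)
            loci.append(
                EreLocus(locus_id, GenomicInterval(chrom, start_i, end_i, strand), ere_class, family)
            )
    return loci


def read_annotation(
    gtf_path: str | Path, ere_bed_path: str | Path, cta_ids: Iterable[str] = ()
) -> tuple[list[GeneModel], list[EreLocus]]:
    """Read the gene GTF and ERE BED6+2 annotations together."""
    return read_gtf_genes(gtf_path, cta_ids), read_ere_bed(ere_bed_path)


def write_ere_bed(loci: Iterable[EreLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            fh.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), locus.locus_id, "0",
                     iv.strand, locus.ere_class, locus.family]
                )
                + "\n"
            )


def write_gtf_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GTF (gene + exon lines, 1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            chrom = gene.intervals[0].chrom
            strand = gene.intervals[0].strand
            start = min(iv.start for iv in gene.intervals)
            end = max(iv.end for iv in gene.intervals)
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write(
                f"{chrom}\tereflow\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
            for iv in gene.intervals:
                fh.write(
                    f"{iv.chrom}\tereflow\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )


def repeatmasker_to_ere_bed(rm_out_path: str | Path, bed_path: str | Path) -> int:
    """Convenience converter from RepeatMasker .out to the BED6+2 dialect.

    The .out dialect varies between releases; this converter handles the
    common whitespace-delimited layout and maps repeat classes onto
    LINE/SINE/LTR/Other by prefix. Returns the number of loci written.
    """
    n = 0
    with open(rm_out_path) as fh, open(bed_path, "w") as out:
        for line in fh:
            fields = line.split()
            if len(fields) < 11 or not fields[0].isdigit():
                continue  # header / blank lines
            chrom, start, end = fields[4], int(fields[5]) - 1, int(fields[6])
            strand = "+" if fields[8] == "+" else "-"
            family, rm_class = fields[9], fields[10]
            base = rm_class.split("/")[0]
            ere_class = base if base in ("LINE", "SINE", "LTR") else "Other"
            n += 1
            out.write(
                f"{chrom}\t{start}\t{end}\t{family}_{n}\t0\t{strand}\t{ere_class}\t{family}\n"
            )
    return n


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then >=1 member per line."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member ({len(fields)} fields found)"
                )
            name = fields[0]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.source or 'ereflow'}\t{members}\n")


# ---------------------------------------------------------------------------
# count matrices and plain tables
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    annotation: tuple[list[GeneModel], list[EreLocus]] | None = None,
) -> pd.DataFrame:
    """Read a feature-by-sample TSV of integer counts.

    When an annotation is supplied every feature id must resolve to a gene or
    an ERE locus; unresolvable ids are reported together in the error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no features")
    for col in df.columns:
        series = df[col]
        bad = series[(series != series.round()) | (series < 0) | series.isna()]
        if len(bad):
            row = bad.index[0]
            raise FormatError(
                f"{path}: negative or non-integer count at row {row!r}, column {col!r}"
            )
    df = df.astype(int)
    if annotation is not None:
        genes, loci = annotation
        known = {g.gene_id for g in genes} | {l.locus_id for l in loci}
        missing = [fid for fid in df.index if fid not in known]
        if missing:
            shown = ", ".join(repr(m) for m in missing[:10])
            raise FormatError(
                f"{path}: {len(missing)} feature id(s) absent from annotation: {shown}"
            )
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0)


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text id list, one id per line (CTA catalog, markers...)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


# ---------------------------------------------------------------------------
# FASTA and peptide tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (order preserved)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_peptides(path: str | Path) -> pd.DataFrame:
    """Read a peptide CSV: sequence, sources, biotype + intensity columns.

    Intensity columns are every column not in the reserved set; empty cells
    are missing values (peptide not detected in that replicate).
    """
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise FormatError(f"{path}: peptide table needs a 'sequence' column")
    bad = df["sequence"].str.len().pipe(lambda s: df.loc[(s < 8) | (s > 11), "sequence"])
    if len(bad):
        raise FormatError(
            f"{path}: peptide length outside 8-11 for {bad.iloc[0]!r}"
        )
    return df.set_index("sequence")


def write_peptides(peptides: pd.DataFrame, path: str | Path) -> None:
    peptides.to_csv(path, index_label="sequence")


def roundtrip_identical(write, read, obj, path) -> bool:
    """Write ``obj`` with ``write``, read it back, report equality (test aid)."""
    write(obj, path)
    return read(path) == obj
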