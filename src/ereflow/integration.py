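"""Linking MHC-I peptides to the transcripts that can encode them.

A candidate database enumerates every 8-11-mer in the three-frame translation
of expressed transcripts (transcripts are stranded, so three frames suffice).
A peptide's RNA support is expressed in reads per hundred million (rphm):
r_total * 1e8 / T, where r_total sums the reads over the peptide's source
regions and T is the total reads of the context. The normal-tissue screen
flags contexts with rphm strictly above a threshold (default 8.55); peptides
with no flagged context are "lowly or not expressed" — candidates free of
central tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

MIN_LEN, MAX_LEN = 8, 11
RPHM_THRESHOLD = 8.55


def translate_three_frames(sequence: str) -> list[list[str]]:
    """Translate a transcript in frames 0/1/2, splitting at stop codons.

    Trailing partial codons are dropped; codons containing N translate to X
    and break fragments the same way stops do. Returns one fragment list per
    frame (a lone stop yields an empty list).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide character(s): {sorted(bad)}")
    frames: list[list[str]] = []
    for offset in range(3):
        sub = seq[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            frames.append([])
            continue
        aa = str(Seq(sub).translate())
        fragments = [f for f in aa.replace("X", "*").split("*") if f]
        frames.append(fragments)
    return frames


@dataclass(frozen=True)
class PeptideSource:
    transcript_id: str
    frame: int  # 0, 1, 2
    offset: int  # residue offset within the frame's translation


@dataclass
class CandidateDb:
    """Peptide sequence -> the transcript sources that encode it."""

    peptides: dict[str, set[PeptideSource]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    def sources(self, peptide: str) -> set[PeptideSource]:
        return self.peptides.get(peptide, set())

    def source_transcripts(self, peptide: str) -> set[str]:
        return {s.transcript_id for s in self.sources(peptide)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"peptide": pep, "transcript_id": s.transcript_id,
             "frame": s.frame, "offset": s.offset}
            for pep, sources in sorted(self.peptides.items())
            for s in sorted(sources, key=lambda s: (s.transcript_id, s.frame, s.offset))
        ]
        return pd.DataFrame(rows, columns=["peptide", "transcript_id", "frame", "offset"])


def build_candidate_db(
    transcripts: Mapping[str, str],
    expression: Mapping[str, float] | pd.Series,
    min_cpm: float = 0.0,
) -> CandidateDb:
    """Enumerate all 8-11-mers of three-frame translations of expressed
    transcripts (cpm >= min_cpm), keyed by peptide with all sources kept."""
    expression = pd.Series(expression)
    missing = [t for t in transcripts if t not in expression.index]
    if missing:
        raise ValueError(f"no expression value for transcript(s): {missing[:10]}")
    db = CandidateDb()
    for tid, seq in transcripts.items():
        if expression[tid] < min_cpm:
            continue
        for frame, fragments in enumerate(translate_three_frames(seq)):
            pos = 0  # residue offset within the frame translation, stops included
            for fragment in fragments:
                for k in range(MIN_LEN, MAX_LEN + 1):
                    for i in range(len(fragment) - k + 1):
                        pep = fragment[i : i + k]
                        assert MIN_LEN <= len(pep) <= MAX_LEN
                        db.peptides.setdefault(pep, set()).add(
                            PeptideSource(tid, frame, pos + i)
                        )
                pos += len(fragment) + 1
    return db


def rphm(r_total: float, total_reads: float) -> float:
    """Reads per hundred million: r_total * 1e8 / T."""
    if total_reads <= 0:
        raise ValueError("total reads must be > 0")
    if r_total < 0:
        raise ValueError("read support must be >= 0")
    return r_total * 1e8 / total_reads


def peptide_rphm(
    peptide: str,
    db: CandidateDb,
    read_support: Mapping[str, float] | pd.Series,
    total_reads: float,
) -> tuple[float, bool]:
    """rphm of a peptide from the summed reads of its source transcripts.

    Returns (rphm, rna_absent): a peptide missing from the database has no
    RNA support and is flagged rna_absent with rphm 0.
    """
    if peptide not in db:
        return 0.0, True
    support = pd.Series(read_support)
    r_total = float(sum(support.get(t, 0.0) for t in db.source_transcripts(peptide)))
    return rphm(r_total, total_reads), False


# biotype priority used to break read-support ties between candidate sources
_PRIORITY = {"canonical": 0, "CTA": 1, "ERE": 2, "other-noncanonical": 3}


def best_source(
    peptide: str,
    db: CandidateDb,
    read_support: Mapping[str, float] | pd.Series,
    biotype_of: Mapping[str, str] | None = None,
) -> str | None:
    """The source transcript with maximal read support; ties broken by
    biotype priority (canonical > CTA > ERE > other), then lexicographic id."""
    candidates = db.source_transcripts(peptide)
    if not candidates:
        return None
    support = pd.Series(read_support)

    def key(tid: str):
        prio = _PRIORITY.get((biotype_of or {}).get(tid, "other-noncanonical"), 3)
        return (-float(support.get(tid, 0.0)), prio, tid)

    return sorted(candidates, key=key)[0]


def concordance(
    dems: pd.DataFrame,
    degs: pd.DataFrame,
    db: CandidateDb,
    read_support: Mapping[str, float] | pd.Series,
    biotype_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Class each differential peptide by its best source's RNA behaviour.

    ``dems``/``degs`` are differential tables (index = peptide sequence /
    transcript id) with a ``direction`` column. Classes: rna_up, rna_down,
    rna_unchanged (source tested but ns — the post-translational fraction),
    rna_absent (no database source). Adds the per-peptide source id and its
    RNA log2FC for downstream fold-change comparisons.
    """
    rows = []
    for pep, rec in dems.iterrows():
        src = best_source(pep, db, read_support, biotype_of)
        if src is None or src not in degs.index:
            rna_class, rna_lfc = "rna_absent", np.nan
        else:
            direction = degs.loc[src, "direction"]
            rna_class = {"up": "rna_up", "down": "rna_down"}.get(direction, "rna_unchanged")
            rna_lfc = float(degs.loc[src, "log2FC"])
        rows.append(
            {"peptide": pep, "dem_direction": rec["direction"],
             "source": src, "rna_class": rna_class, "rna_log2FC": rna_lfc}
        )
    return pd.DataFrame(rows).set_index("peptide")


def concordance_counts(classes: pd.DataFrame) -> pd.DataFrame:
    """Counts per (DEM direction x RNA class)."""
    return (
        classes.groupby(["dem_direction", "rna_class"]).size().rename("n").reset_index()
    )


def source_fold_change_test(classes: pd.DataFrame) -> dict:
    """Rank-sum comparison of source-RNA log2FC between up- and down-DEMs."""
    from .peptidome import group_compare

    up = classes.loc[(classes["dem_direction"] == "up") & classes["rna_log2FC"].notna(),
                     "rna_log2FC"]
    down = classes.loc[(classes["dem_direction"] == "down") & classes["rna_log2FC"].notna(),
                       "rna_log2FC"]
    if up.empty or down.empty:
        return {"U": np.nan, "p": np.nan, "mean_up": np.nan, "mean_down": np.nan}
    u, p = group_compare(up, down)
    return {"U": u, "p": p, "mean_up": float(up.mean()), "mean_down": float(down.mean())}


def tissue_screen(
    profile: pd.DataFrame, threshold: float = RPHM_THRESHOLD
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag peptide x context cells with rphm strictly above the threshold.

    Returns (flags, lowly_expressed) where ``lowly_expressed`` is True for
    peptides with no flagged context — i.e. lowly or not expressed across the
    normal-tissue panel.
    """
    flags = profile > threshold
    lowly = ~flags.any(axis=1)
    return flags, lowly.rename("lowly_or_not_expressed")
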