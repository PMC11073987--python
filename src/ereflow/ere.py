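"""ERE biotype assignment, class-level enrichment and cohort ERE metrics.

The cohort metrics mirror how AML patient cohorts are stratified by
retroelement activity: a per-sample cumulative cpm over a fixed set of
treatment-induced ERE loci (E_p), a count of highly-expressed EREs (H_p: the
number of loci expressed strictly above that locus' median across samples
with non-zero expression), and a median split into high/low groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import EreLocus, GeneModel

logger = logging.getLogger(__name__)

BIOTYPES = ("canonical", "CTA", "ERE", "other-noncanonical")


@dataclass
class CohortFrame:
    """A patient cohort: cpm expression (features x samples) plus metadata.

    ``ere_ids`` names the rows that are ERE loci; remaining rows are genes.
    Derived per-sample scores and strata labels are filled by the analysis
    functions below.
    """

    cpm: pd.DataFrame
    ere_ids: tuple[str, ...]
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        missing = [e for e in self.ere_ids if e not in self.cpm.index]
        if missing:
            raise ValueError(f"ERE rows absent from cohort matrix: {missing[:10]}")
        if self.scores.empty:
            self.scores = pd.DataFrame(index=self.cpm.columns)

    @property
    def n_samples(self) -> int:
        return self.cpm.shape[1]


def assign_biotype(
    sources: Iterable[str],
    gene_models: Mapping[str, GeneModel],
    ere_loci: Mapping[str, EreLocus] | Iterable[str],
    cta_ids: Iterable[str],
) -> str:
    """Biotype of a feature or peptide from its source ids.

    Priority: canonical (a protein-coding, non-CTA gene source exists) >
    CTA > ERE > other-noncanonical. A peptide is only called ERE-derived when
    no conventional coding source explains it — conservative, so the ERE
    class is never inflated by multi-mapping peptides.
    """
    cta = set(cta_ids)
    ere_ids = set(ere_loci.keys()) if isinstance(ere_loci, Mapping) else set(ere_loci)
    seen = {"canonical": False, "CTA": False, "ERE": False, "other": False}
    sources = list(sources)
    if not sources:
        raise ValueError("no sources supplied")
    for src in sources:
        if src in gene_models:
            gene = gene_models[src]
            if src in cta or gene.is_cta:
                seen["CTA"] = True
            elif gene.biotype == "protein_coding":
                seen["canonical"] = True
            else:
                seen["other"] = True
        elif src in ere_ids:
            seen["ERE"] = True
        else:
            raise ValueError(f"unresolvable source id {src!r}")
    if seen["canonical"]:
        return "canonical"
    if seen["CTA"]:
        return "CTA"
    if seen["ERE"]:
        return "ERE"
    return "other-noncanonical"


def class_enrichment(
    up_ere_ids: Iterable[str], ere_annotation: Sequence[EreLocus]
) -> pd.DataFrame:
    """Per-class enrichment of an ERE id set against the genomic background.

    Background fractions b_k come from the full annotation; for each class
    the expected count is e_k = b_k * n, the ratio o_k / e_k, and a two-sided
    exact binomial p by the tail-doubling rule (2 * min tail, capped at 1).
    """
    up = set(up_ere_ids)
    if not up:
        raise ValueError("nothing to test: empty up-regulated ERE set")
    class_of = {l.locus_id: l.ere_class for l in ere_annotation}
    unknown = up - set(class_of)
    if unknown:
        raise ValueError(f"ids absent from annotation: {sorted(unknown)[:10]}")
    bg = pd.Series([l.ere_class for l in ere_annotation]).value_counts(normalize=True)
    obs = pd.Series([class_of[i] for i in up]).value_counts()
    n = int(obs.sum())
    rows = []
    for klass in bg.index:
        b_k = float(bg[klass])
        o_k = int(obs.get(klass, 0))
        e_k = b_k * n
        lower = stats.binom.cdf(o_k, n, b_k)
        upper = stats.binom.sf(o_k - 1, n, b_k)
        p = min(1.0, 2.0 * min(lower, upper))
        rows.append(
            {"ere_class": klass, "observed": o_k, "background_fraction": b_k,
             "expected": e_k, "ratio": o_k / e_k if e_k > 0 else np.nan, "p": p}
        )
    return pd.DataFrame(rows).set_index("ere_class")


def cumulative_ere_cpm(cohort_cpm: pd.DataFrame, ere_set: Iterable[str]) -> pd.Series:
    """E_p: per-sample summed cpm over a fixed ERE set."""
    ere_set = list(dict.fromkeys(ere_set))
    if not ere_set:
        raise ValueError("empty ERE set")
    missing = [e for e in ere_set if e not in cohort_cpm.index]
    if missing:
        raise ValueError(f"ERE rows missing from expression matrix: {missing[:10]}")
    return cohort_cpm.loc[ere_set].sum(axis=0).rename("E_p")


def he_ere_count(cohort_cpm: pd.DataFrame, ere_set: Iterable[str]) -> pd.Series:
    """H_p: number of set EREs expressed strictly above their non-null median.

    For each ERE the reference m_e is the median cpm over samples where the
    ERE has non-zero expression; a sample scores a point for every ERE with
    cpm strictly above m_e. EREs with zero expression everywhere contribute
    nothing (logged).
    """
    if cohort_cpm.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    ere_set = list(dict.fromkeys(ere_set))
    missing = [e for e in ere_set if e not in cohort_cpm.index]
    if missing:
        raise ValueError(f"ERE rows missing from expression matrix: {missing[:10]}")
    sub = cohort_cpm.loc[ere_set]
    counts = pd.Series(0, index=cohort_cpm.columns, name="H_p")
    n_silent = 0
    for ere, row in sub.iterrows():
        nonzero = row[row > 0]
        if nonzero.empty:
            n_silent += 1
            continue
        m_e = nonzero.median()
        counts += (row > m_e).astype(int)
    if n_silent:
        logger.info("he_ere_count: %d ERE(s) with zero expression everywhere", n_silent)
    return counts


def median_split(scores: pd.Series) -> pd.Series:
    """Label each sample high/low around the median score.

    The median is the middle order statistic (odd n) or the mean of the two
    middle values (even n); samples at or above the median are "high", so 437
    distinct scores split 219 high / 218 low. Constant scores label everything
    high with a warning.
    """
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to split")
    if scores.nunique() == 1:
        warnings.warn("all scores identical; labelling every sample 'high'")
        return pd.Series("high", index=scores.index, name="label")
    med = float(scores.median())
    return pd.Series(np.where(scores >= med, "high", "low"),
                     index=scores.index, name="label")
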