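"""Gene-set machinery and cohort stratification.

ssGSEA (single-sample enrichment): genes are ranked by decreasing expression
within a sample; the enrichment score is the sum over all ranked positions of
the difference between the normalised running weight of in-set genes
(weights |rank|^alpha, alpha = 0.25 by default, rank n for the highest
expressed gene) and the running fraction of out-of-set genes. The score is
rank-based, hence invariant under strictly monotone transforms of expression.

Pre-ranked GSEA: classical weighted (exponent 1) running-sum enrichment score
(maximal-magnitude deviation), null by gene-label permutation, NES = ES
divided by the mean magnitude of same-sign null scores, two-sided permutation
p = (1 + #{|null| >= |ES|}) / (n_perm + 1).

Over-representation: hypergeometric upper tail with BH across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .ere import cumulative_ere_cpm, he_ere_count, median_split
from .io import GeneSetCollection


def ssgsea(expression: pd.Series, gene_set: Iterable[str], alpha: float = 0.25) -> float:
    """Single-sample enrichment score of a gene set in one expression vector."""
    gene_set = frozenset(gene_set)
    genes = expression.index
    in_set = genes.isin(gene_set)
    n = len(genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the measured genes")
    if n_in == n:
        raise ValueError("gene set equals the measured universe (empty complement)")
    order = np.argsort(-expression.to_numpy(), kind="stable")
    in_sorted = in_set[order]
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets rank n
    weights = np.where(in_sorted, ranks**alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expression: pd.DataFrame,
    collection: GeneSetCollection | Mapping[str, Iterable[str]],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """ssGSEA scores for every set x sample; rows = sets, columns = samples.

    Vectorised over sets within each sample (one sort per sample).
    """
    sets = dict(collection.items()) if hasattr(collection, "items") else dict(collection)
    genes = expression.index
    n = len(genes)
    masks = {}
    for name, members in sets.items():
        mask = np.asarray(genes.isin(frozenset(members)))
        k = int(mask.sum())
        if k == 0 or k == n:
            raise ValueError(f"gene set {name!r} has empty intersection or complement")
        masks[name] = mask
    ranks = np.arange(n, 0, -1, dtype=float) ** alpha
    out = pd.DataFrame(index=list(sets), columns=expression.columns, dtype=float)
    for sample in expression.columns:
        order = np.argsort(-expression[sample].to_numpy(), kind="stable")
        for name, mask in masks.items():
            in_sorted = mask[order]
            weights = np.where(in_sorted, ranks, 0.0)
            p_in = np.cumsum(weights) / weights.sum()
            p_out = np.cumsum(~in_sorted) / (n - in_sorted.sum())
            out.loc[name, sample] = np.sum(p_in - p_out)
    return out


def correlate_sets(
    scores: pd.DataFrame, covariate: pd.Series, tail: str = "negative"
) -> pd.DataFrame:
    """Spearman correlation of per-set scores with a per-sample covariate.

    Sets are ranked on the chosen tail (rank 1 = most negative rho for
    ``tail='negative'``); the top-decile flag marks rank <= ceil(0.1 * n).
    Constant score rows are excluded with a warning (NA rho, no rank).
    """
    covariate = covariate.reindex(scores.columns)
    if scores.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    if covariate.nunique() <= 1:
        warnings.warn("constant covariate; all correlations undefined")
        return pd.DataFrame(
            {"rho": np.nan, "p": np.nan, "rank": np.nan, "top_decile": False},
            index=scores.index,
        )
    rows = {}
    for name, row in scores.iterrows():
        if row.nunique() <= 1:
            warnings.warn(f"constant scores for set {name!r}; excluded from ranking")
            rows[name] = (np.nan, np.nan)
            continue
        rho, p = stats.spearmanr(row.to_numpy(), covariate.to_numpy())
        rows[name] = (float(rho), float(p))
    out = pd.DataFrame(rows, index=["rho", "p"]).T
    valid = out["rho"].notna()
    ascending = tail == "negative"
    ranks = out.loc[valid, "rho"].rank(method="first", ascending=ascending)
    out["rank"] = ranks
    cutoff = int(np.ceil(0.1 * valid.sum()))
    out["top_decile"] = out["rank"] <= cutoff
    return out


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    n_perm: int
    seed: int

    def __post_init__(self):
        if self.es != 0 and np.isfinite(self.nes) and np.sign(self.nes) != np.sign(self.es):
            raise ValueError("NES sign must match ES sign")


def _running_es(in_set_sorted: np.ndarray, weights_sorted: np.ndarray) -> float:
    """Signed maximal deviation of the weighted GSEA running sum.

    ``in_set_sorted`` is boolean over positions (2-D allowed: perms x n);
    ``weights_sorted`` the |statistic| values in ranked order.
    """
    hit_w = np.where(in_set_sorted, weights_sorted, 0.0)
    denom = hit_w.sum(axis=-1, keepdims=True)
    p_hit = np.cumsum(hit_w, axis=-1) / denom
    n = in_set_sorted.shape[-1]
    k = in_set_sorted.sum(axis=-1, keepdims=True)
    p_miss = np.cumsum(~in_set_sorted, axis=-1) / (n - k)
    dev = p_hit - p_miss
    idx = np.argmax(np.abs(dev), axis=-1)
    return np.take_along_axis(dev, np.expand_dims(idx, -1), axis=-1).squeeze(-1)


def gsea_preranked(
    statistic: pd.Series,
    gene_set: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
    set_name: str = "",
) -> GseaResult:
    """Classical pre-ranked GSEA with a gene-label permutation null."""
    if statistic.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranked statistic")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    gene_set = frozenset(gene_set)
    order = np.argsort(-statistic.to_numpy(), kind="stable")
    genes = statistic.index.to_numpy()[order]
    weights = np.abs(statistic.to_numpy(float)[order])
    in_set = np.isin(genes, list(gene_set))
    k = int(in_set.sum())
    n = len(genes)
    if k < 2:
        raise ValueError("gene set intersects fewer than 2 ranked genes")
    if k == n:
        raise ValueError("gene set equals the ranked universe")
    es = float(_running_es(in_set, weights))

    rng = np.random.default_rng(seed)
    null_masks = np.zeros((n_perm, n), dtype=bool)
    for b in range(n_perm):
        null_masks[b, rng.choice(n, size=k, replace=False)] = True
    null_es = np.atleast_1d(_running_es(null_masks, weights))

    p = (1.0 + np.sum(np.abs(null_es) >= abs(es))) / (n_perm + 1.0)
    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
    nes = es / denom if denom and np.isfinite(denom) else np.nan
    return GseaResult(set_name=set_name, es=es, nes=float(nes), p=float(p),
                      n_perm=n_perm, seed=seed)


def overrepresentation(
    gene_list: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection | Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    p is the upper tail P(X >= overlap); fold enrichment is the overlap over
    its expectation under random draws; q is BH across sets.
    """
    gene_list = set(gene_list)
    universe = set(universe)
    if not gene_list:
        raise ValueError("empty gene list")
    if not gene_list <= universe:
        raise ValueError("gene list must be a subset of the universe")
    items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    n_u = len(universe)
    n_l = len(gene_list)
    rows = []
    for name, members in items:
        members = set(members) & universe
        k = len(gene_list & members)
        m = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_u, m, n_l))
        expected = m * n_l / n_u
        rows.append(
            {"set": name, "overlap": k, "set_size": m, "expected": expected,
             "fold_enrichment": (k / expected) if expected > 0 else np.nan, "p": p}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p")


def cd8_score(cohort_cpm: pd.DataFrame, markers: Sequence[str] = ("CD8A", "CD8B")) -> pd.Series:
    """Mean log2(cpm + 1) of the CD8 marker transcripts, per sample."""
    missing = [m for m in markers if m not in cohort_cpm.index]
    if missing:
        raise ValueError(f"marker row(s) missing from cohort matrix: {missing}")
    return np.log2(cohort_cpm.loc[list(markers)] + 1.0).mean(axis=0).rename("cd8_score")


def stratify(
    cohort_cpm: pd.DataFrame,
    ere_set: Iterable[str],
    markers: Sequence[str] = ("CD8A", "CD8B"),
    ere_axis: str = "he_ere",
) -> pd.DataFrame:
    """2x2 stratification of a cohort: ERE axis x CD8 axis, both median-split.

    The ERE axis is the HE-ERE count H_p by default (``ere_axis='he_ere'``)
    or the cumulative cpm E_p (``ere_axis='cumulative'``). Returns per-sample
    scores, high/low labels and the combined stratum name.
    """
    ere_set = list(ere_set)
    if ere_axis == "he_ere":
        ere_score = he_ere_count(cohort_cpm, ere_set)
    elif ere_axis == "cumulative":
        ere_score = cumulative_ere_cpm(cohort_cpm, ere_set)
    else:
        raise ValueError(f"unknown ERE axis {ere_axis!r}")
    cd8 = cd8_score(cohort_cpm, markers)
    ere_label = median_split(ere_score)
    cd8_label = median_split(cd8)
    out = pd.DataFrame(
        {"ere_score": ere_score, "cd8_score": cd8,
         "ere_label": ere_label, "cd8_label": cd8_label}
    )
    out["stratum"] = "ERE-" + out["ere_label"] + "/CD8-" + out["cd8_label"]
    return out
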