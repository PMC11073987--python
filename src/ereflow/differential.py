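"""Differential expression / abundance with empirical-Bayes variance shrinkage.

The engine is a moderated two-sample t on log2(cpm + 1) for transcript counts
and log2(intensity + 1) for peptide intensities. Per-feature sample variances
s^2 (pooled, d = n1 + n2 - 2 df) are shrunk towards a prior (d0, s0^2):

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t = (mean1 - mean2) / (s_tilde * sqrt(1/n1 + 1/n2)),   df = d0 + d

When the prior is not supplied it is fit by method of moments on the
distribution of s^2 under the scaled-F model s^2 ~ s0^2 * F(d, d0) (the
hierarchical model behind limma-style moderation). Multiple testing is
Benjamini-Hochberg throughout. Direction calls use log2FC and BH q against
configurable thresholds (defaults |log2FC| > 1, q < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_MAX_DF = 1e6  # stands in for an infinite prior df


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with group labels and cpm."""

    counts: pd.DataFrame
    groups: pd.Series  # sample -> group label

    def __post_init__(self):
        self.counts = self.counts.astype(int)
        self.groups = pd.Series(self.groups).reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.groups[self.groups.isna()].index)
            raise ValueError(f"samples without group label: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        return cpm(self.counts)

    def size_factors(self) -> pd.Series:
        """Median-of-ratios size factors on the cpm scale.

        For each sample, the median over features of cpm / geometric-mean
        cpm (features expressed everywhere). Corrects the compositional bias
        a large asymmetric induced fraction exerts on plain library-size
        normalisation.
        """
        c = self.cpm()
        positive = c[(c > 0).all(axis=1)]
        if positive.empty:
            return pd.Series(1.0, index=c.columns)
        ref = np.exp(np.log(positive).mean(axis=1))
        return positive.div(ref, axis=0).median(axis=0)

    def log2_cpm(self, normalized: bool = True) -> pd.DataFrame:
        """log2(cpm + 1); by default cpm rescaled by median-of-ratios factors."""
        c = self.cpm()
        if normalized:
            c = c / self.size_factors()
        return np.log2(c + 1.0)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups[self.groups == group].index)


@dataclass
class ShrinkageModel:
    """Prior degrees of freedom and prior variance for moderation."""

    d0: float
    s02: float
    method: str = "fixed"

    def __post_init__(self):
        if self.d0 < 0:
            raise ValueError("prior df d0 must be >= 0")
        if self.s02 <= 0:
            raise ValueError("prior variance s0^2 must be > 0")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; every column sums to 1e6."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts * 1e6 / lib


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    from scipy.special import polygamma

    if y <= 0:
        return float("inf")
    x = 0.5 + 1.0 / y
    for _ in range(60):
        f = float(polygamma(1, x)) - y
        fprime = float(polygamma(2, x))
        step = f / fprime
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < 1e-10 * (1 + abs(x)):
            break
    return x


def fit_shrinkage(s2: np.ndarray, d: int) -> ShrinkageModel:
    """Method-of-moments fit of (d0, s0^2) on the log variance scale.

    Under the hierarchical model s^2 ~ s0^2 F(d, d0), log s^2 has variance
    trigamma(d/2) + trigamma(d0/2) and a mean offset expressible through
    digamma terms; matching both moments gives (d0, s0^2). Fitting on the
    log scale keeps the prior finite and sensible when a minority of
    features (e.g. imputed peptides) carry very large variances. When the
    observed spread of log s^2 does not exceed pure chi^2 sampling noise the
    prior df is effectively infinite and every feature shrinks to the common
    variance.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size == 0 or s2.max() <= 0:
        raise ValueError("all pooled variances are zero; nothing to moderate")
    z = np.log(np.maximum(s2, 1e-12))
    # centre of log chi^2_d / d
    e_chi = float(digamma(d / 2.0)) - np.log(d / 2.0)
    var_z = z.var(ddof=1)
    excess = var_z - float(polygamma(1, d / 2.0))
    if excess <= 0:
        return ShrinkageModel(d0=_MAX_DF, s02=float(np.exp(z.mean() - e_chi)),
                              method="moments")
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s02 = z.mean() - e_chi + float(digamma(d0 / 2.0)) - np.log(d0 / 2.0)
    return ShrinkageModel(d0=float(d0), s02=float(np.exp(log_s02)), method="moments")


def moderated_test(
    values: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    model: ShrinkageModel | str = "fit",
    tau_lfc: float = 1.0,
    tau_fdr: float = 0.05,
    order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Moderated two-group test on a log2-scale matrix (features x samples).

    ``groups`` maps sample -> one of exactly two labels. log2FC is
    mean(order[0]) - mean(order[1]); when ``order`` is omitted the labels are
    taken in column order, so pass ``order=(treated, control)`` to fix the
    fold-change orientation. Returns a table with columns log2FC, t, p, q,
    direction.
    """
    groups = pd.Series(groups).reindex(values.columns)
    labels = list(order) if order is not None else list(dict.fromkeys(groups.dropna()))
    if len(labels) != 2 or not set(labels) == set(groups.dropna()):
        raise ValueError(f"need exactly two group labels, got {labels}")
    g1 = [s for s in values.columns if groups[s] == labels[0]]
    g2 = [s for s in values.columns if groups[s] == labels[1]]
    n1, n2 = len(g1), len(g2)
    if min(n1, n2) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {labels[0]}:{n1}, {labels[1]}:{n2})"
        )
    x1 = values[g1].to_numpy(float)
    x2 = values[g2].to_numpy(float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    if model == "fit":
        model = fit_shrinkage(s2, d)
    elif not isinstance(model, ShrinkageModel):
        raise TypeError("model must be 'fit' or a ShrinkageModel")
    if model.d0 == 0:
        s2_tilde = s2
        df = float(d)
    else:
        s2_tilde = (model.d0 * model.s02 + d * s2) / (model.d0 + d)
        df = min(model.d0 + d, _MAX_DF)
    lfc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    t = np.where(lfc == 0, 0.0, t)  # 0/0 at identical means
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    table = pd.DataFrame(
        {"log2FC": lfc, "t": t, "p": p}, index=values.index
    )
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["direction"] = call_de(table, tau_lfc=tau_lfc, tau_fdr=tau_fdr)
    table.attrs["model"] = model
    table.attrs["groups"] = (labels[0], labels[1])
    return table


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, tau_lfc: float = 1.0, tau_fdr: float = 0.05) -> pd.Series:
    """Direction flags: up iff log2FC > tau_lfc and q < tau_fdr; down symmetric."""
    up = (table["log2FC"] > tau_lfc) & (table["q"] < tau_fdr)
    down = (table["log2FC"] < -tau_lfc) & (table["q"] < tau_fdr)
    out = pd.Series("ns", index=table.index, name="direction")
    out[up] = "up"
    out[down] = "down"
    return out


def direction_counts(table: pd.DataFrame) -> dict[str, int]:
    c = table["direction"].value_counts()
    return {"up": int(c.get("up", 0)), "down": int(c.get("down", 0)), "ns": int(c.get("ns", 0))}


# ---------------------------------------------------------------------------
# peptide intensity handling
# ---------------------------------------------------------------------------

def detection_matrix(intensities: pd.DataFrame) -> pd.DataFrame:
    """Boolean detection pattern: a peptide is detected where intensity is present."""
    return intensities.notna() & (intensities > 0)


def filter_and_impute(
    intensities: pd.DataFrame, condition_columns: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Label-free missing-value policy ahead of testing.

    Keep peptides detected in >= 2 replicates of at least one condition; then
    impute remaining missing cells with half the minimum observed intensity of
    that replicate column (missing-not-at-random floor imputation).
    """
    det = detection_matrix(intensities)
    keep = pd.Series(False, index=intensities.index)
    for cond, cols in condition_columns.items():
        keep |= det[list(cols)].sum(axis=1) >= 2
    out = intensities.loc[keep].copy()
    for col in out.columns:
        observed = out[col].dropna()
        floor = observed.min() / 2.0 if len(observed) else 0.0
        out[col] = out[col].fillna(floor)
    return out


def peptide_differential(
    peptides: pd.DataFrame,
    condition_columns: Mapping[str, Sequence[str]],
    treated: str,
    control: str,
    model: ShrinkageModel | str = "fit",
    tau_lfc: float = 1.0,
    tau_fdr: float = 0.05,
) -> pd.DataFrame:
    """Moderated test on log2(intensity + 1) after filtering and imputation."""
    cols = list(condition_columns[treated]) + list(condition_columns[control])
    filled = filter_and_impute(peptides[cols], {treated: condition_columns[treated],
                                                control: condition_columns[control]})
    logged = np.log2(filled + 1.0)
    groups = pd.Series(
        {c: treated for c in condition_columns[treated]}
        | {c: control for c in condition_columns[control]}
    )
    return moderated_test(logged, groups, model=model, tau_lfc=tau_lfc,
                          tau_fdr=tau_fdr, order=(treated, control))


def call_condition_specific(
    peptides: pd.DataFrame,
    condition_columns: Mapping[str, Sequence[str]],
    treated: str,
    control: str,
) -> pd.Series:
    """Treatment-specific peptides: detected in every treated replicate and in
    no control replicate."""
    for cond in (treated, control):
        if cond not in condition_columns:
            raise ValueError(f"condition {cond!r} absent from table")
    det = detection_matrix(peptides[list(condition_columns[treated]) +
                                    list(condition_columns[control])])
    in_all_treated = det[list(condition_columns[treated])].all(axis=1)
    in_no_control = ~det[list(condition_columns[control])].any(axis=1)
    return (in_all_treated & in_no_control).rename("condition_specific")


# ---------------------------------------------------------------------------
# cross-analysis summaries
# ---------------------------------------------------------------------------

def common_elements(tables: Iterable[pd.DataFrame], direction: str = "up") -> set[str]:
    """Feature ids called with the given direction in every analysis."""
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need >= 2 differential tables to intersect")
    sets = [set(t.index[t["direction"] == direction]) for t in tables]
    return set.intersection(*sets)


def dem_deg_correlation(
    n_dems: Sequence[float], n_degs: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between per-analysis DEM and DEG counts.

    Returns (r, p); (nan, nan) when either vector has zero variance.
    """
    x = np.asarray(n_dems, float)
    y = np.asarray(n_degs, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired analyses")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
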