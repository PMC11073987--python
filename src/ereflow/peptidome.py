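"""Physicochemical sequence features of MHC-I peptides and source proteins.

These statistics characterise immunopeptidome changes that RNA abundance does
not explain: hydropathy (GRAVY, Kyte-Doolittle), aromaticity (F/W/Y), the
fraction of DNMT2-target residues (D/G/V, whose tRNAs lose methylation when
DNMT2 is inhibited), polar-residue content, protease-specificity of the
C-terminal residue (tryptic K/R vs chymotryptic-like F/W/Y/L/M, Fisher exact),
and the residue-composition correlation with per-protein peptide counts.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import stats

from .differential import bh_fdr

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
AROMATIC = frozenset("FWY")
DNMT2_TARGETS = frozenset("DGV")  # Asp, Gly, Val
POLAR = frozenset("STNQCYHKRDE")
TRYPTIC = frozenset("KR")
CHYMOTRYPTIC = frozenset("FWYLM")


def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in {sequence!r}")
    return sequence


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    _validate(sequence)
    return sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


def _fraction(sequence: str, residues: frozenset[str]) -> float:
    _validate(sequence)
    return sum(aa in residues for aa in sequence) / len(sequence)


def aromaticity(sequence: str) -> float:
    """Fraction of aromatic residues (Phe, Trp, Tyr)."""
    return _fraction(sequence, AROMATIC)


def dnmt2_fraction(sequence: str) -> float:
    """Fraction of DNMT2-target residues (Asp, Gly, Val)."""
    return _fraction(sequence, DNMT2_TARGETS)


def polar_fraction(sequence: str, polar_set: Iterable[str] = POLAR) -> float:
    """Fraction of polar residues (default set S,T,N,Q,C,Y,H,K,R,D,E)."""
    return _fraction(sequence, frozenset(polar_set))


def residue_frequencies(sequence: str) -> pd.Series:
    """Per-residue frequency vector over the 20 canonical amino acids."""
    _validate(sequence)
    counts = pd.Series(0.0, index=list(AMINO_ACIDS))
    for aa in sequence:
        counts[aa] += 1
    return counts / len(sequence)


def cterm_class(
    peptide: str,
    tryptic: Iterable[str] = TRYPTIC,
    chymotryptic: Iterable[str] = CHYMOTRYPTIC,
) -> str:
    """Protease class of a peptide from its C-terminal residue."""
    t, c = frozenset(tryptic), frozenset(chymotryptic)
    if t & c:
        raise ValueError("tryptic and chymotryptic residue sets overlap")
    last = _validate(peptide)[-1]
    if last in t:
        return "tryptic"
    if last in c:
        return "chymotryptic"
    return "other"


def cterm_association(
    up_peptides: Iterable[str],
    down_peptides: Iterable[str],
    tryptic: Iterable[str] = TRYPTIC,
    chymotryptic: Iterable[str] = CHYMOTRYPTIC,
) -> dict:
    """2x2 Fisher exact test of C-terminal protease class vs DEM direction.

    Rows are {up, down}, columns {tryptic, chymotryptic}; peptides whose
    C-terminus falls in neither set are excluded. A zero margin makes the
    test degenerate: p = 1 with a warning flag.
    """
    def counts(peps):
        classes = [cterm_class(p, tryptic, chymotryptic) for p in peps]
        return (classes.count("tryptic"), classes.count("chymotryptic"))

    table = np.array([counts(up_peptides), counts(down_peptides)], dtype=int)
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        return {"table": table, "odds_ratio": np.nan, "p": 1.0, "degenerate": True}
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p": float(p), "degenerate": False}


def composition_correlation(
    frequencies: pd.DataFrame, n_up: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of each residue's frequency with up-DEM counts.

    ``frequencies`` is proteins x 20 residues; ``n_up`` the per-protein count
    of upregulated peptides. Residues with constant frequency across proteins
    yield NA rows; p-values are BH-adjusted across the 20 residues.
    """
    common = frequencies.index.intersection(n_up.index)
    if len(common) < 10:
        raise ValueError("need >= 10 proteins with DEM counts")
    freqs = frequencies.loc[common]
    y = n_up.loc[common].astype(float)
    rows = []
    for aa in AMINO_ACIDS:
        f = freqs[aa]
        if f.nunique() <= 1 or y.nunique() <= 1:
            rows.append({"residue": aa, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(f, y)
        rows.append({"residue": aa, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows).set_index("residue")
    ok = out["p"].notna()
    q = pd.Series(np.nan, index=out.index)
    if ok.any():
        q[ok] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out


def group_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (two-sided): exact for min group size <= 8 and no ties,
    otherwise normal approximation with tie correction. Returns (U, p)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def protein_feature_table(
    proteins: Mapping[str, str],
    n_up: Mapping[str, int] | pd.Series | None = None,
    n_down: Mapping[str, int] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-protein feature table: GRAVY, aromaticity, D/G/V fraction, residue
    frequencies and (optional) up/down DEM counts."""
    rows = {}
    for pid, seq in proteins.items():
        feats = residue_frequencies(seq).to_dict()
        feats.update(
            gravy=gravy(seq),
            aromaticity=aromaticity(seq),
            dnmt2_fraction=dnmt2_fraction(seq),
            polar_fraction=polar_fraction(seq),
            length=len(seq),
        )
        rows[pid] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "protein_id"
    table["n_up"] = pd.Series(n_up, dtype=float).reindex(table.index).fillna(0).astype(int) \
        if n_up is not None else 0
    table["n_down"] = pd.Series(n_down, dtype=float).reindex(table.index).fillna(0).astype(int) \
        if n_down is not None else 0
    return table


def dem_count_group_test(
    features: pd.DataFrame, column: str = "dnmt2_fraction", threshold: int = 3
) -> dict:
    """Compare a protein feature between proteins generating > ``threshold``
    upregulated peptides and all other peptide-generating proteins."""
    generating = features[(features["n_up"] + features["n_down"]) > 0]
    high = generating[generating["n_up"] > threshold][column]
    rest = generating[generating["n_up"] <= threshold][column]
    if high.empty or rest.empty:
        raise ValueError("one of the comparison groups is empty")
    u, p = group_compare(high, rest)
    return {
        "U": u, "p": p, "n_high": len(high), "n_rest": len(rest),
        "mean_high": float(high.mean()), "mean_rest": float(rest.mean()),
    }
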