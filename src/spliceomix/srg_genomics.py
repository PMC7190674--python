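"""Genomic-alteration landscape statistics for a gene catalog.

Works on a patients x genes matrix of exclusive calls in {amp, del, mut,
none} (cBioPortal-style multi-track exports are flattened on read with
precedence amp > del > mut).  Provides per-gene and cumulative alteration
frequencies, top-altered rankings, one-sided Fisher co-occurrence tests,
copy-number-to-expression association, and Gleason-grade association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CALLS = ("amp", "del", "mut", "none")
_PRECEDENCE = {"amp": 0, "del": 1, "mut": 2, "none": 3}


def alteration_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Validate (and return) a patients x genes call matrix."""
    bad = set(np.unique(calls.to_numpy().astype(str))) - set(CALLS)
    if bad:
        raise ValueError(f"invalid alteration calls: {sorted(bad)}")
    if calls.index.has_duplicates or calls.columns.has_duplicates:
        raise ValueError("duplicate patient or gene ids")
    return calls


def flatten_long_calls(long: pd.DataFrame, patients: Sequence[str],
                       genes: Sequence[str]) -> pd.DataFrame:
    """Flatten a long (patient, gene, call) table to one call per cell.

    Multiple calls for one patient/gene collapse by precedence
    amp > del > mut; absent pairs become "none".
    """
    long = long.copy()
    long["rank"] = long["call"].map(_PRECEDENCE)
    if long["rank"].isna().any():
        raise ValueError("invalid call in long table")
    best = (long.sort_values("rank", kind="mergesort")
            .drop_duplicates(["patient", "gene"]))
    matrix = best.pivot(index="patient", columns="gene", values="call")
    matrix = matrix.reindex(index=list(patients), columns=list(genes))
    return alteration_matrix(matrix.fillna("none"))


def gene_alteration_freq(matrix: pd.DataFrame, gene: str) -> dict[str, float]:
    """Per-type and any-alteration frequency of one gene."""
    if gene not in matrix.columns:
        raise KeyError(f"gene {gene!r} absent from matrix")
    col = matrix[gene]
    n = len(col)
    out = {call: float((col == call).sum()) / n for call in ("amp", "del", "mut")}
    out["any"] = float((col != "none").sum()) / n
    return out


def alteration_freq_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Frequencies for every gene (columns amp, del, mut, any)."""
    n = len(matrix)
    vals = matrix.to_numpy()
    out = pd.DataFrame({call: (vals == call).sum(axis=0) / n
                        for call in ("amp", "del", "mut")},
                       index=matrix.columns)
    out["any"] = (vals != "none").sum(axis=0) / n
    return out


def cumulative_freq(matrix: pd.DataFrame, gene_set: Sequence[str],
                    types: Sequence[str] = ("amp", "del", "mut")) -> float:
    """Fraction of patients with >= 1 alteration among the gene set.

    Each patient is counted once regardless of how many set genes are
    altered.
    """
    gene_set = [g for g in gene_set]
    if not gene_set:
        warnings.warn("empty gene set: cumulative frequency is 0")
        return 0.0
    missing = set(gene_set) - set(matrix.columns)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
    sub = matrix[gene_set].isin(list(types))
    return float(sub.any(axis=1).mean())


def top_altered(matrix: pd.DataFrame, n: int = 15,
                by: str = "any") -> pd.DataFrame:
    """Genes ranked by alteration frequency; ties broken alphabetically."""
    if by not in ("amp", "del", "mut", "any"):
        raise ValueError(f"unknown ranking key {by!r}")
    freqs = alteration_freq_table(matrix)
    freqs = freqs.sort_values([by, freqs.index.name or "index"],
                              ascending=[False, True], kind="mergesort") \
        if freqs.index.name else \
        freqs.assign(_g=freqs.index).sort_values([by, "_g"],
                                                 ascending=[False, True],
                                                 kind="mergesort").drop(columns="_g")
    return freqs.head(min(n, len(freqs)))


@dataclass(frozen=True)
class CoocResult:
    """2x2 co-occurrence result with a one-sided Fisher exact p."""

    both: int
    a_only: int
    b_only: int
    neither: int
    p_value: float
    odds_ratio: float  # np.inf / 0.0 for zero cells

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.both, self.a_only],
                         [self.b_only, self.neither]])


def cooccurrence(matrix: pd.DataFrame, gene_a: str, gene_b: str,
                 types: Sequence[str] = ("amp", "del", "mut")) -> CoocResult:
    """One-sided (co-occurrence enrichment) Fisher exact test.

    p = P(X >= both) under the hypergeometric null given the margins.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.columns:
            raise KeyError(f"gene {g!r} absent from matrix")
    a = matrix[gene_a].isin(list(types)).to_numpy()
    b = matrix[gene_b].isin(list(types)).to_numpy()
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    table = [[both, a_only], [b_only, neither]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return CoocResult(both, a_only, b_only, neither,
                      p_value=float(p), odds_ratio=float(odds))


def expression_by_cnv(expr: pd.DataFrame, matrix: pd.DataFrame, gene: str,
                      min_group: int = 3) -> pd.DataFrame:
    """amp-vs-neutral and del-vs-neutral expression comparison for a gene.

    Two-sided rank-sum p per contrast; groups below ``min_group`` patients
    are flagged and reported as NA.
    """
    if gene not in matrix.columns:
        raise KeyError(f"gene {gene!r} absent from alteration matrix")
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    calls = matrix[gene]
    values = expr.loc[gene, matrix.index]
    rows = []
    neutral = values[calls == "none"].to_numpy(dtype=float)
    for alt in ("amp", "del"):
        grp = values[calls == alt].to_numpy(dtype=float)
        row = dict(contrast=f"{alt}_vs_neutral", n_alt=len(grp),
                   n_neutral=len(neutral),
                   mean_alt=float(grp.mean()) if len(grp) else np.nan,
                   mean_neutral=float(neutral.mean()) if len(neutral) else np.nan)
        if len(grp) < min_group or len(neutral) < min_group:
            row.update(p_value=np.nan, flag="group_too_small")
        else:
            res = stats.mannwhitneyu(grp, neutral, alternative="two-sided")
            row.update(p_value=float(res.pvalue), flag="")
        rows.append(row)
    return pd.DataFrame(rows).set_index("contrast")


def grade_association(in_group, gleason) -> dict[str, float]:
    """Mann-Whitney comparison of Gleason grades between two groups."""
    mask = np.asarray(in_group, dtype=bool)
    grades = np.asarray(gleason, dtype=float)
    a, b = grades[mask], grades[~mask]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 patients")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return dict(p_value=float(res.pvalue), statistic=float(res.statistic),
                median_in=float(np.median(a)), median_out=float(np.median(b)))
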