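"""Gene-set overlap and expression-shift statistics.

Covers the chi-square enrichment of one gene set in another over an
explicit universe (e.g. intron-retention-bearing genes vs NMD targets),
the two-tailed paired t-test on per-gene Z-score shifts between
conditions, the removal of genes with both up- and downregulated IR
events, and a plain fold-change + Welch-t DEG caller used on synthetic
expression data (it deliberately does not reimplement a negative-binomial
shrinkage model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .splicing_quant import bh_fdr


@dataclass(frozen=True)
class OverlapTable:
    """2x2 membership table over a stated universe with a chi-square test."""

    in_both: int
    a_only: int
    b_only: int
    neither: int
    chi2: float
    p_value: float
    overlap_fraction: float  # |A & B| / |A|

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.in_both, self.a_only],
                         [self.b_only, self.neither]])


def set_overlap_chi2(set_a: Iterable, set_b: Iterable, universe: Iterable,
                     yates: bool = False) -> OverlapTable:
    """Pearson chi-square (1 df, two-tailed) on set membership."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    in_both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(universe) - in_both - a_only - b_only
    table = np.array([[in_both, a_only], [b_only, neither]])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    frac = in_both / len(a) if a else np.nan
    return OverlapTable(in_both, a_only, b_only, neither,
                        chi2=float(chi2), p_value=float(p),
                        overlap_fraction=float(frac))


def paired_shift_test(z1: pd.Series, z2: pd.Series,
                      genes: Sequence[str] | None = None
                      ) -> tuple[float, float]:
    """Two-tailed paired t on per-gene Z differences between conditions."""
    if genes is not None:
        z1, z2 = z1.loc[list(genes)], z2.loc[list(genes)]
    if not z1.index.equals(z2.index):
        raise ValueError("mismatched gene sets between conditions")
    if len(z1) < 3:
        raise ValueError("need at least 3 paired genes")
    t, p = stats.ttest_rel(z2.to_numpy(dtype=float), z1.to_numpy(dtype=float))
    return float(t), float(p)


def filter_bidirectional_ir_genes(ir_events: pd.DataFrame,
                                  gene_col: str = "gene_id",
                                  direction_col: str = "direction"
                                  ) -> list[str]:
    """Genes whose significant IR events are all one direction."""
    n_dirs = ir_events.groupby(gene_col)[direction_col].nunique()
    return sorted(n_dirs.index[n_dirs == 1])


def deg_call(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
             fc_threshold: float = 2.0, q_threshold: float = 0.05,
             min_mean: float = 10.0) -> pd.DataFrame:
    """Fold-change + Welch-t differential-expression caller.

    Inputs are genes x replicates matrices on the log2(count + 1) scale.
    log2FC is the group-B minus group-A mean; the abundance filter applies
    to the linear-scale base mean across all replicates.  A gene is called
    iff |FC| >= fc_threshold, BH q < q_threshold and base mean >= min_mean.
    """
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("need at least 2 replicates per group")
    if not expr_a.index.equals(expr_b.index):
        raise ValueError("gene sets differ between groups")
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical genes
    q = bh_fdr(p)
    base_mean = np.concatenate([2.0 ** a - 1.0, 2.0 ** b - 1.0],
                               axis=1).mean(axis=1)
    out = pd.DataFrame({
        "log2_fc": log2fc, "t": t, "p_value": p, "q_value": q,
        "base_mean": base_mean,
    }, index=expr_a.index)
    out["called"] = (np.abs(out["log2_fc"]) >= np.log2(fc_threshold)) \
        & (out["q_value"] < q_threshold) & (out["base_mean"] >= min_mean)
    return out
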