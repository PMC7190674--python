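"""PSI quantification and differential splicing-event (DSE) calling.

Percent spliced in for one event in one sample is computed from inclusion
and skipping junction counts, length-normalized:

    psi = (I / lI) / (I / lI + S / lS)

Group differences are tested with a binomial likelihood-ratio test on the
pooled per-group counts (one shared inclusion proportion vs two group
proportions, 1 df chi-square asymptotics), delta-PSI is the difference of
replicate-mean PSI (group B minus group A), and events are called
differentially spliced when |dPSI| > 0.1 and the Benjamini-Hochberg q-value
is < 0.1.  This is a deliberately transparent caller, not a reimplementation
of rMATS or SUPPA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import JunctionCounts

logger = logging.getLogger(__name__)

AS_TYPES = ("SE", "A5", "A3", "MX", "IR")

DPSI_THRESHOLD = 0.1
Q_THRESHOLD = 0.1


@dataclass(frozen=True)
class SpliceEvent:
    """One AS event; coordinates 0-based half-open, lengths in bp."""

    event_id: str
    as_type: str
    gene_id: str
    l_inc: float = 1.0
    l_skp: float = 1.0

    def __post_init__(self) -> None:
        if self.as_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.as_type!r}")
        if self.l_inc < 1 or self.l_skp < 1:
            raise ValueError("effective lengths must be >= 1")


def compute_psi(inclusion, skipping, l_inc=1.0, l_skp=1.0):
    """PSI from inclusion/skipping counts; NaN where I + S = 0.

    Accepts scalars or arrays; arrays broadcast elementwise.
    """
    i = np.asarray(inclusion, dtype=float)
    s = np.asarray(skipping, dtype=float)
    if np.any(i < 0) or np.any(s < 0):
        raise ValueError("counts must be non-negative")
    num = i / l_inc
    den = num + s / l_skp
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(den > 0, num / den, np.nan)
    return float(psi) if psi.ndim == 0 else psi


def _binom_ll(i: np.ndarray, s: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel with the 0*log(0) = 0 convention."""
    from scipy.special import xlogy
    return xlogy(i, p) + xlogy(s, 1.0 - p)


def binomial_lrt(inc_a, skp_a, inc_b, skp_b):
    """Likelihood-ratio test of one shared vs two group inclusion rates.

    Operates on pooled per-group counts; vectorized over events.
    Returns (statistic, p) with p from chi-square(1).
    """
    ia, sa = np.asarray(inc_a, float), np.asarray(skp_a, float)
    ib, sb = np.asarray(inc_b, float), np.asarray(skp_b, float)
    na, nb = ia + sa, ib + sb
    with np.errstate(invalid="ignore"):
        pa = np.where(na > 0, ia / na, 0.5)
        pb = np.where(nb > 0, ib / nb, 0.5)
        p0 = np.where(na + nb > 0, (ia + ib) / (na + nb), 0.5)
    stat = 2.0 * (_binom_ll(ia, sa, pa) + _binom_ll(ib, sb, pb)
                  - _binom_ll(ia, sa, p0) - _binom_ll(ib, sb, p0))
    stat = np.maximum(stat, 0.0)  # guard tiny negative round-off
    p = stats.chi2.sf(stat, df=1)
    if stat.ndim == 0:
        return float(stat), float(p)
    return stat, p


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DifferentialResult:
    """Per-event differential splicing summary for one event."""

    event_id: str
    psi: pd.Series          # per-sample PSI (NaN where not quantifiable)
    psi_bar_a: float
    psi_bar_b: float
    delta_psi: float
    statistic: float
    p_value: float
    q_value: float | None = None
    direction: str = ""


def differential_table(counts: JunctionCounts, group_a: str = "A",
                       group_b: str = "B",
                       lengths: pd.DataFrame | None = None) -> pd.DataFrame:
    """Differential splicing over every event in a count table.

    ``lengths``, if given, is an event-indexed frame with columns
    ``l_inc``/``l_skp`` used for PSI length normalization (default 1).
    Events with no quantifiable replicate in a group are dropped and logged.
    Returns a frame with per-group mean PSI, delta_psi (B minus A), the LRT
    statistic, p and BH q, and the direction of change in group B.
    """
    samples_a = counts.groups.index[counts.groups == group_a]
    samples_b = counts.groups.index[counts.groups == group_b]
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")

    inc, skp = counts.inclusion, counts.skipping
    l_inc = l_skp = 1.0
    if lengths is not None:
        l_inc = lengths["l_inc"].reindex(inc.index).to_numpy()[:, None]
        l_skp = lengths["l_skp"].reindex(inc.index).to_numpy()[:, None]

    psi_a = compute_psi(inc[samples_a].to_numpy(), skp[samples_a].to_numpy(),
                        l_inc, l_skp)
    psi_b = compute_psi(inc[samples_b].to_numpy(), skp[samples_b].to_numpy(),
                        l_inc, l_skp)
    quantifiable = ~(np.isnan(psi_a).all(axis=1) | np.isnan(psi_b).all(axis=1))
    n_dropped = int((~quantifiable).sum())
    if n_dropped:
        logger.warning("%d events with no quantifiable replicate in a group "
                       "were skipped", n_dropped)

    with np.errstate(invalid="ignore"):
        bar_a = np.nanmean(psi_a, axis=1)
        bar_b = np.nanmean(psi_b, axis=1)
    stat, p = binomial_lrt(
        inc[samples_a].sum(axis=1).to_numpy(), skp[samples_a].sum(axis=1).to_numpy(),
        inc[samples_b].sum(axis=1).to_numpy(), skp[samples_b].sum(axis=1).to_numpy())

    out = pd.DataFrame({
        "psi_bar_a": bar_a, "psi_bar_b": bar_b,
        "delta_psi": bar_b - bar_a,
        "statistic": stat, "p_value": p,
    }, index=inc.index)
    out = out[quantifiable]
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["direction"] = np.where(out["delta_psi"] >= 0, "up", "down")
    return out


def differential_event(counts: JunctionCounts, event_id: str,
                       group_a: str = "A", group_b: str = "B",
                       lengths: pd.DataFrame | None = None) -> DifferentialResult:
    """Single-event wrapper around :func:`differential_table`."""
    table = differential_table(counts, group_a, group_b, lengths)
    if event_id not in table.index:
        raise KeyError(f"event {event_id!r} not quantifiable or unknown")
    row = table.loc[event_id]
    psi = pd.Series(
        compute_psi(counts.inclusion.loc[event_id].to_numpy(),
                    counts.skipping.loc[event_id].to_numpy()),
        index=counts.inclusion.columns)
    return DifferentialResult(
        event_id=event_id, psi=psi,
        psi_bar_a=float(row["psi_bar_a"]), psi_bar_b=float(row["psi_bar_b"]),
        delta_psi=float(row["delta_psi"]), statistic=float(row["statistic"]),
        p_value=float(row["p_value"]), q_value=float(row["q_value"]),
        direction=str(row["direction"]))


def call_dse(results: pd.DataFrame, dpsi_threshold: float = DPSI_THRESHOLD,
             q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Flag differentially spliced events: |dPSI| > 0.1 AND q < 0.1."""
    out = results.copy()
    out["called"] = (out["delta_psi"].abs() > dpsi_threshold) \
        & (out["q_value"] < q_threshold)
    return out


def partition_dse(called: pd.DataFrame,
                  event_types: pd.Series) -> pd.DataFrame:
    """Counts of called events per AS type and direction."""
    sig = called[called["called"]]
    types = event_types.reindex(sig.index)
    table = (pd.crosstab(types, sig["direction"])
             .reindex(index=list(AS_TYPES), fill_value=0))
    table.index.name = "as_type"
    for col in ("up", "down"):
        if col not in table.columns:
            table[col] = 0
    table["total"] = table[["up", "down"]].sum(axis=1)
    return table[["up", "down", "total"]]


def landscape_summary(comparisons: dict[str, pd.DataFrame],
                      event_types: dict[str, pd.Series],
                      reference: str,
                      gene_ids: dict[str, pd.Series] | None = None
                      ) -> pd.DataFrame:
    """Per-type DSE counts across comparisons with fold changes vs a
    reference comparison; optionally also gene-collapsed counts.

    Counts are event counts; when ``gene_ids`` maps events to genes, the
    number of distinct affected genes is reported alongside.
    """
    if reference not in comparisons:
        raise KeyError(f"reference comparison {reference!r} absent")
    rows = []
    for name, res in comparisons.items():
        part = partition_dse(res, event_types[name])
        row = {f"{t}": int(part.loc[t, "total"]) for t in AS_TYPES}
        row["total"] = int(part["total"].sum())
        row["comparison"] = name
        if gene_ids is not None:
            sig = res[res["called"]]
            row["n_genes"] = int(gene_ids[name].reindex(sig.index).nunique())
        rows.append(row)
    table = pd.DataFrame(rows).set_index("comparison")
    ref = table.loc[reference]
    for t in list(AS_TYPES) + ["total"]:
        with np.errstate(divide="ignore", invalid="ignore"):
            table[f"fc_{t}"] = np.where(ref[t] > 0, table[t] / ref[t], np.nan)
    return table
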