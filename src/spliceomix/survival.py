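"""Kaplan-Meier estimation, two-group log-rank, and best-cutoff stratification.

The product-limit estimator and the standard two-group log-rank test (with
hypergeometric variance, chi-square(1) reference) are implemented directly
so that per-group observed/expected event counts, a vectorizable cutoff
scan, and a permutation-based p-value are all available; lifelines serves
as an independent cross-check in the test suite.

Best-cutoff stratification splits a continuous score at every candidate
threshold within quantile bounds and keeps the threshold with the lowest
log-rank p.  Minimal-p selection inflates type-I error; the report records
this and can attach a permutation-adjusted p (off by default).

Convention: subjects censored exactly at an event time are still at risk
for that event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no survival records")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    if t.shape != e.shape:
        raise ValueError("times and events differ in length")
    return t, e


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(time=self.event_times, at_risk=self.at_risk,
                                 events=self.n_events, survival=self.survival))


def km_curve(times, events) -> KMCurve:
    t, e = _clean(times, events)
    ts = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in ts], dtype=float)
    deaths = np.array([((t == u) & (e == 1)).sum() for u in ts], dtype=float)
    surv = np.cumprod(1.0 - deaths / at_risk) if ts.size else np.array([])
    return KMCurve(event_times=ts, survival=surv, at_risk=at_risk,
                   n_events=deaths, n=t.size)


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]   # (group A, group B)
    expected: tuple[float, float]
    n: tuple[int, int]
    permutation_p: float | None = None


def _logrank_core(t: np.ndarray, e: np.ndarray, in_a: np.ndarray
                  ) -> tuple[float, float, float]:
    """(O_A - E_A, Var, O_A) over the pooled distinct event times."""
    ts = np.unique(t[e == 1])
    o_minus_e = var = obs_a = 0.0
    for u in ts:
        at_risk = t >= u
        n_tot = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((t == u) & (e == 1)).sum()
        d_a = ((t == u) & (e == 1) & in_a).sum()
        e_a = d * n_a / n_tot
        obs_a += d_a
        o_minus_e += d_a - e_a
        if n_tot > 1:
            var += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
    return o_minus_e, var, obs_a


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance."""
    ta, ea = _clean(times_a, events_a)
    tb, eb = _clean(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    if e.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    in_a = np.zeros(t.size, dtype=bool)
    in_a[:ta.size] = True
    o_minus_e, var, obs_a = _logrank_core(t, e, in_a)
    total_events = float(e.sum())
    exp_a = obs_a - o_minus_e
    if var <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e ** 2 / var
        p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(statistic=float(stat), p_value=p,
                         observed=(float(obs_a), total_events - obs_a),
                         expected=(float(exp_a), total_events - exp_a),
                         n=(int(ta.size), int(tb.size)))


def permutation_logrank(times_a, events_a, times_b, events_b,
                        n_permutations: int = 10_000,
                        seed: int = 0) -> LogRankResult:
    """Log-rank with a group-label permutation p attached."""
    result = logrank(times_a, events_a, times_b, events_b)
    ta, ea = _clean(times_a, events_a)
    tb, eb = _clean(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    rng = np.random.default_rng(seed)
    n_a = ta.size
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(t.size)
        in_a = np.zeros(t.size, dtype=bool)
        in_a[perm[:n_a]] = True
        o_minus_e, var, _ = _logrank_core(t, e, in_a)
        stat = o_minus_e ** 2 / var if var > 0 else 0.0
        if stat >= result.statistic - 1e-12:
            hits += 1
    result.permutation_p = (hits + 1) / (n_permutations + 1)
    return result


@dataclass
class CutoffScan:
    candidates: np.ndarray
    p_values: np.ndarray
    chosen_cutoff: float
    chosen_p: float
    note: str = ("minimal-p cutoff selection inflates type-I error; the "
                 "unadjusted p is reported as-is")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(cutoff=self.candidates, p_value=self.p_values))


def best_cutoff(scores, times, events,
                quantile_bounds: tuple[float, float] = (0.10, 0.90)
                ) -> CutoffScan:
    """Scan unique score values within quantile bounds for the lowest
    log-rank p; ties resolved toward the smaller threshold."""
    s = np.asarray(scores, dtype=float)
    t, e = _clean(times, events)
    if s.size != t.size:
        raise ValueError("scores and records differ in length")
    if np.unique(s).size < 2:
        raise ValueError("all scores equal: no cutoff possible")
    lo, hi = np.quantile(s, quantile_bounds)
    candidates = np.unique(s)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    cands, ps = [], []
    for c in candidates:
        high = s > c
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        if e[high].sum() + e[~high].sum() == 0:
            continue
        try:
            res = logrank(t[high], e[high], t[~high], e[~high])
        except ValueError:
            continue
        cands.append(c)
        ps.append(res.p_value)
    if not cands:
        raise ValueError("no candidate cutoff yields two valid groups")
    cands = np.array(cands)
    ps = np.array(ps)
    best = int(np.flatnonzero(ps == ps.min())[0])  # smallest c among ties
    return CutoffScan(candidates=cands, p_values=ps,
                      chosen_cutoff=float(cands[best]),
                      chosen_p=float(ps[best]))


@dataclass
class SurvivalReport:
    split: str
    cutoff: float
    high_curve: KMCurve
    low_curve: KMCurve
    logrank: LogRankResult
    direction: str                      # unfavorable | favorable
    cutoff_scan: CutoffScan | None = None
    permutation_adjusted_p: float | None = None


def signature_survival_report(scores: pd.Series, clinical: pd.DataFrame,
                              split: str = "best-cutoff",
                              permutation_adjust: bool = False,
                              n_permutations: int = 1000,
                              seed: int = 0) -> SurvivalReport:
    """KM curves + log-rank for a score-stratified cohort.

    ``clinical`` must carry ``time`` and ``event`` columns indexed like
    ``scores``.  The direction label is "unfavorable" when the high-score
    group's KM curve is lower at the last common follow-up time.
    With ``permutation_adjust``, the whole cutoff selection is re-run on
    score-permuted cohorts to attach a selection-adjusted p.
    """
    clinical = clinical.loc[scores.index]
    t = clinical["time"].to_numpy(dtype=float)
    e = clinical["event"].to_numpy(dtype=int)
    s = scores.to_numpy(dtype=float)

    scan = None
    if split == "best-cutoff":
        scan = best_cutoff(s, t, e)
        cutoff = scan.chosen_cutoff
    elif split == "median":
        cutoff = float(np.median(s))
    else:
        raise ValueError(f"unknown split {split!r}")
    high = s > cutoff
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("a group has fewer than 2 subjects after the split")

    lr = logrank(t[high], e[high], t[~high], e[~high])
    hc = km_curve(t[high], e[high])
    lc = km_curve(t[~high], e[~high])
    t_common = min(t[high].max(), t[~high].max())
    direction = ("unfavorable" if hc.survival_at(t_common)
                 < lc.survival_at(t_common) else "favorable")

    adj_p = None
    if permutation_adjust:
        rng = np.random.default_rng(seed)
        observed = scan.chosen_p if scan is not None else lr.p_value
        hits = 0
        for _ in range(n_permutations):
            sp = rng.permutation(s)
            try:
                if split == "best-cutoff":
                    p = best_cutoff(sp, t, e).chosen_p
                else:
                    h = sp > np.median(sp)
                    p = logrank(t[h], e[h], t[~h], e[~h]).p_value
            except ValueError:
                continue
            if p <= observed:
                hits += 1
        adj_p = (hits + 1) / (n_permutations + 1)

    return SurvivalReport(split=split, cutoff=float(cutoff), high_curve=hc,
                          low_curve=lc, logrank=lr, direction=direction,
                          cutoff_scan=scan, permutation_adjusted_p=adj_p)


def km_plot(curves: dict[str, KMCurve], path=None, title: str = ""):
    """Step plot of one or more KM curves (matplotlib, Agg-safe)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        x = np.concatenate([[0.0], curve.event_times])
        y = np.concatenate([[1.0], curve.survival])
        ax.step(x, y, where="post", label=f"{label} (n={curve.n})")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
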