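"""Intron splicing-code features and maximum-entropy splice-site scoring.

Retained vs constitutively spliced introns are characterized by length,
GC content and donor/acceptor splice-site strength.  Constitutive introns
are the n events nearest the center of the delta-PSI-sorted event list
among those with delta-PSI exactly 0.  Site strength is scored with a
retrainable maximum-entropy model over fixed-length windows:

* donor: 9-mer, 3 terminal exonic bases + 6 initial intronic bases;
* acceptor: 21-mer, 20 terminal intronic bases + 1 initial exonic base
  (a 23-mer variant with 3 exonic bases is available via ``acceptor_exonic``).

The model is the maximum-entropy distribution subject to positional
marginals (order 0) or positional + adjacent-pair marginals (order 1),
fitted by iterative proportional fitting; the score of a window is
log2 P_signal / P_background in bits.  Order-1 fitting uses a chain
factorization with exact marginals from forward-backward sweeps, which
keeps the 21-mer acceptor space tractable (a dense 4^21 table is not).

Group comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 1

IPF_TOL = 1e-6
IPF_MAX_ITER = 10_000

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def intron_features(seq: str) -> tuple[int, float]:
    """(length, GC fraction); N bases excluded from the GC computation."""
    if not seq:
        raise ValueError("empty sequence")
    counted = [b for b in seq.upper() if b in "ACGT"]
    if not counted:
        raise ValueError("sequence has no unambiguous bases")
    gc = sum(b in "GC" for b in counted) / len(counted)
    return len(seq), gc


# ---------------------------------------------------------------------------
# constitutive intron selection
# ---------------------------------------------------------------------------

def select_constitutive_introns(events: pd.DataFrame, n: int = 300,
                                dpsi_col: str = "delta_psi") -> pd.DataFrame:
    """The n zero-delta-PSI events nearest the center of the sorted list.

    Events are sorted by delta-PSI (stable); among those with delta-PSI
    exactly 0 the n whose positions are nearest the list center are kept,
    ties resolved toward the lower index.  Fewer than n zeros returns all
    of them with a warning.
    """
    order = events[dpsi_col].to_numpy().argsort(kind="mergesort")
    sorted_events = events.iloc[order]
    positions = np.flatnonzero(sorted_events[dpsi_col].to_numpy() == 0.0)
    if positions.size == 0:
        raise ValueError("no events with delta-PSI = 0")
    if positions.size < n:
        warnings.warn(f"only {positions.size} zero-delta-PSI events available "
                      f"(requested {n}); returning all of them")
        chosen = positions
    else:
        center = (len(sorted_events) - 1) / 2.0
        key = np.lexsort((positions, np.abs(positions - center)))
        chosen = np.sort(positions[key[:n]])
    return sorted_events.iloc[chosen]


# ---------------------------------------------------------------------------
# splice-site window extraction
# ---------------------------------------------------------------------------

def extract_site_windows(chrom_seq: str, start: int, end: int, strand: str,
                         intron_id: str = "",
                         donor_exonic: int = DONOR_EXONIC,
                         donor_intronic: int = DONOR_INTRONIC,
                         acceptor_intronic: int = ACCEPTOR_INTRONIC,
                         acceptor_exonic: int = ACCEPTOR_EXONIC
                         ) -> tuple[str, str]:
    """Donor and acceptor windows of one intron, 5'->3' on the sense strand.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    intron; minus-strand windows are reverse-complemented.
    """
    label = intron_id or f"{start}-{end}({strand})"
    if strand == "+":
        d_lo, d_hi = start - donor_exonic, start + donor_intronic
        a_lo, a_hi = end - acceptor_intronic, end + acceptor_exonic
        if d_lo < 0 or a_hi > len(chrom_seq):
            raise ValueError(f"site window out of bounds for intron {label}")
        return chrom_seq[d_lo:d_hi].upper(), chrom_seq[a_lo:a_hi].upper()
    if strand == "-":
        d_lo, d_hi = end - donor_intronic, end + donor_exonic
        a_lo, a_hi = start - acceptor_exonic, start + acceptor_intronic
        if a_lo < 0 or d_hi > len(chrom_seq):
            raise ValueError(f"site window out of bounds for intron {label}")
        return (reverse_complement(chrom_seq[d_lo:d_hi]).upper(),
                reverse_complement(chrom_seq[a_lo:a_hi]).upper())
    raise ValueError(f"invalid strand {strand!r} for intron {label}")


def extract_all_windows(introns: pd.DataFrame, genome: dict[str, str],
                        **geometry) -> pd.DataFrame:
    """Donor/acceptor windows for an intron table (intron_id-indexed)."""
    rows = {}
    for row in introns.itertuples():
        donor, acceptor = extract_site_windows(
            genome[row.chrom], row.start, row.end, row.strand,
            intron_id=row.intron_id, **geometry)
        rows[row.intron_id] = (donor, acceptor)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["donor", "acceptor"])


# ---------------------------------------------------------------------------
# maximum-entropy splice-site model
# ---------------------------------------------------------------------------

def _encode(windows, length: int | None = None) -> np.ndarray:
    arr = []
    for w in windows:
        w = w.upper()
        if length is not None and len(w) != length:
            raise ValueError(f"window {w!r} has length {len(w)}, "
                             f"expected {length}")
        try:
            arr.append([_ENC[b] for b in w])
        except KeyError:
            raise ValueError(f"window {w!r} contains an ambiguous base")
    out = np.asarray(arr, dtype=np.int64)
    if out.ndim != 2 or len({len(w) for w in windows}) > 1:
        raise ValueError("inconsistent window lengths")
    return out


@dataclass
class ChainMaxEnt:
    """Max-entropy distribution over fixed-length windows.

    Order 0 stores positional marginals (the product distribution).
    Order 1 stores adjacent-pair factors of a chain together with the
    normalizer; both satisfy the empirical marginal constraints.
    """

    length: int
    order: int
    positional: np.ndarray               # (length, 4)
    pair_factors: list | None = None     # (length-1) arrays (4, 4)
    log_z: float = 0.0
    max_marginal_dev: float = 0.0
    n_iter: int = 0

    def log2_prob(self, window: str) -> float:
        x = _encode([window], self.length)[0]
        if self.order == 0:
            probs = self.positional[np.arange(self.length), x]
            if np.any(probs <= 0.0):
                return -np.inf
            return float(np.log2(probs).sum())
        total = 0.0
        for k, psi in enumerate(self.pair_factors):
            v = psi[x[k], x[k + 1]]
            if v <= 0.0:
                return -np.inf
            total += np.log(v)
        return float((total - self.log_z) / np.log(2.0))

    # --- exact marginals of the fitted chain -----------------------------
    def _forward_backward(self):
        w = self.length
        alpha = [np.ones(4)]
        for k in range(w - 1):
            alpha.append(alpha[k] @ self.pair_factors[k])
        beta = [None] * w
        beta[w - 1] = np.ones(4)
        for k in range(w - 2, -1, -1):
            beta[k] = self.pair_factors[k] @ beta[k + 1]
        z = float(alpha[-1].sum())
        return alpha, beta, z

    def pair_marginals(self) -> np.ndarray:
        alpha, beta, z = self._forward_backward()
        out = np.empty((self.length - 1, 4, 4))
        for k in range(self.length - 1):
            out[k] = np.outer(alpha[k], beta[k + 1]) * self.pair_factors[k] / z
        return out

    def fitted_positional_marginals(self) -> np.ndarray:
        if self.order == 0:
            return self.positional.copy()
        pm = self.pair_marginals()
        out = np.empty((self.length, 4))
        out[:-1] = pm.sum(axis=2)
        out[-1] = pm[-1].sum(axis=0)
        return out


def _empirical_marginals(x: np.ndarray, pseudocount: float):
    n, w = x.shape
    pos = np.zeros((w, 4))
    for i in range(w):
        pos[i] = np.bincount(x[:, i], minlength=4) + pseudocount
    pos /= pos.sum(axis=1, keepdims=True)
    pair = np.zeros((w - 1, 4, 4))
    for k in range(w - 1):
        np.add.at(pair[k], (x[:, k], x[:, k + 1]), 1.0)
        pair[k] += pseudocount
        pair[k] /= pair[k].sum()
    return pos, pair


def fit_chain_maxent(windows, order: int = 0, tol: float = IPF_TOL,
                     max_iter: int = IPF_MAX_ITER,
                     pseudocount: float = 0.0) -> ChainMaxEnt:
    """Fit one max-entropy distribution to a set of site windows."""
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    x = _encode(windows)
    length = x.shape[1]
    pos, pair = _empirical_marginals(x, pseudocount)
    if order == 0:
        return ChainMaxEnt(length=length, order=0, positional=pos,
                           max_marginal_dev=0.0, n_iter=1)
    model = ChainMaxEnt(length=length, order=1, positional=pos,
                        pair_factors=[pair[k].copy() for k in range(length - 1)])
    dev = np.inf
    for it in range(1, max_iter + 1):
        for k in range(length - 1):
            current = model.pair_marginals()[k]
            psi = model.pair_factors[k]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(current > 0, pair[k] / current, 0.0)
            psi *= ratio
            psi[pair[k] == 0.0] = 0.0
            s = psi.sum()
            if s <= 0:
                raise RuntimeError("IPF degenerated: empty factor support")
            psi /= s
        dev = float(np.abs(model.pair_marginals() - pair).max())
        if dev < tol:
            model.max_marginal_dev = dev
            model.n_iter = it
            break
    else:
        raise RuntimeError(
            f"IPF did not converge in {max_iter} iterations "
            f"(max marginal deviation {dev:.3e}, tolerance {tol:.1e})")
    _, _, z = model._forward_backward()
    model.log_z = float(np.log(z))
    return model


@dataclass
class MaxEntModel:
    """Signal + background max-entropy pair for log-odds site scoring."""

    window_length: int
    order: int
    signal: ChainMaxEnt
    background: ChainMaxEnt
    diagnostics: dict = field(default_factory=dict)


def fit_maxent(signal_windows, background_windows, order: int = 0,
               tol: float = IPF_TOL, max_iter: int = IPF_MAX_ITER,
               pseudocount: float = 0.0,
               min_signal: int = 50) -> MaxEntModel:
    """Fit signal and background distributions with shared geometry."""
    if len(signal_windows) < min_signal:
        raise ValueError(f"need at least {min_signal} signal windows, "
                         f"got {len(signal_windows)}")
    signal = fit_chain_maxent(signal_windows, order, tol, max_iter, pseudocount)
    background = fit_chain_maxent(background_windows, order, tol, max_iter,
                                  pseudocount)
    if signal.length != background.length:
        raise ValueError("signal and background window lengths differ")
    return MaxEntModel(
        window_length=signal.length, order=order, signal=signal,
        background=background,
        diagnostics=dict(
            max_marginal_dev=max(signal.max_marginal_dev,
                                 background.max_marginal_dev),
            n_iter=max(signal.n_iter, background.n_iter)))


def score_site(model: MaxEntModel, window: str) -> float:
    """log2(P_signal / P_background) in bits for one window.

    Raises on a wrong-length window or an ambiguous base; batch scoring
    with per-window flags is provided by :func:`score_sites`.
    """
    if len(window) != model.window_length:
        raise ValueError(f"window length {len(window)} != model length "
                         f"{model.window_length}")
    ls = model.signal.log2_prob(window)
    lb = model.background.log2_prob(window)
    if np.isinf(ls) and np.isinf(lb):
        return np.nan
    return ls - lb


def score_sites(model: MaxEntModel, windows) -> pd.DataFrame:
    """Score a window collection; N-containing windows are flagged, not scored."""
    items = windows.items() if isinstance(windows, pd.Series) \
        else enumerate(windows)
    rows = []
    for key, w in items:
        if len(w) != model.window_length:
            rows.append((key, np.nan, "wrong_length"))
        elif any(b not in "ACGT" for b in w.upper()):
            rows.append((key, np.nan, "ambiguous_base"))
        else:
            rows.append((key, score_site(model, w), ""))
    out = pd.DataFrame(rows, columns=["window_id", "score", "flag"])
    return out.set_index("window_id")


# ---------------------------------------------------------------------------
# feature tables and group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntronRecord:
    """One intron: sense-strand sequence, features and site scores."""

    intron_id: str
    sequence: str
    length: int
    gc: float
    donor: str
    acceptor: str
    s5: float = np.nan
    s3: float = np.nan


def intron_feature_frame(introns: pd.DataFrame, genome: dict[str, str],
                         donor_model: MaxEntModel | None = None,
                         acceptor_model: MaxEntModel | None = None,
                         **geometry) -> pd.DataFrame:
    """L, GC and (when models are given) S5/S3 for every intron."""
    windows = extract_all_windows(introns, genome, **geometry)
    rows = {}
    for row in introns.itertuples():
        raw = genome[row.chrom][row.start:row.end]
        seq = raw if row.strand == "+" else reverse_complement(raw)
        length, gc = intron_features(seq)
        rows[row.intron_id] = dict(L=length, GC=gc)
    feats = pd.DataFrame.from_dict(rows, orient="index")
    if donor_model is not None:
        feats["S5"] = score_sites(donor_model, windows["donor"])["score"]
    if acceptor_model is not None:
        feats["S3"] = score_sites(acceptor_model, windows["acceptor"])["score"]
    return feats


def compare_intron_groups(features_a: pd.DataFrame, features_b: pd.DataFrame,
                          features: tuple[str, ...] = ("L", "GC", "S5", "S3")
                          ) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per feature, with group medians."""
    rows = []
    for feat in features:
        if feat not in features_a.columns or feat not in features_b.columns:
            continue
        a = features_a[feat].dropna().to_numpy()
        b = features_b[feat].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"group size < 3 for feature {feat!r}")
        # exact null distribution at small n, normal approximation otherwise
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(dict(feature=feat, median_a=float(np.median(a)),
                         median_b=float(np.median(b)),
                         statistic=float(res.statistic),
                         p_value=float(res.pvalue)))
    return pd.DataFrame(rows).set_index("feature")
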