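"""RNA-binding-protein consensus-motif scanning and binding scores.

Intron sequence groups (e.g. retained vs constitutive) are scanned for
IUPAC consensus motifs.  For each RBP the binding frequency f (fraction of
sequences with at least one match), the mean appearance count c within
matching sequences, and the binding score B = f * c are computed; a
shortlist is then formed by filtering on f and ranking by B.

Scanning is strand-agnostic on the provided sense-strand sequence: no
reverse-complement scan is performed, matching protein binding to the
single-stranded transcript.  Overlapping matches are all counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# U and T are interchangeable: motifs may be given in RNA or DNA alphabet.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RBPMotif:
    rbp_name: str
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) < 3:
            raise ValueError(f"{self.rbp_name}: motif shorter than 3")
        for ch in self.motif.upper():
            if ch not in IUPAC:
                raise ValueError(f"{self.rbp_name}: invalid IUPAC code {ch!r}")


@dataclass(frozen=True)
class MotifStats:
    """f = binding frequency, c_bar = mean count per matching sequence."""

    rbp_name: str
    f: float
    c_bar: float
    B: float
    n_sequences: int


def motif_regex(motif: str) -> re.Pattern:
    """Overlap-counting regex (lookahead) for an IUPAC motif, DNA alphabet."""
    parts = []
    for ch in motif.upper():
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?={''.join(parts)})")


def iupac_match_positions(motif: str, seq: str) -> list[int]:
    """Start positions of every (overlapping) match of the motif."""
    pattern = motif_regex(motif)
    return [m.start() for m in pattern.finditer(seq.upper().replace("U", "T"))]


def iupac_match_count(motif: str | RBPMotif, seq: str) -> int:
    if not seq:
        raise ValueError("empty sequence")
    m = motif.motif if isinstance(motif, RBPMotif) else motif
    return len(iupac_match_positions(m, seq))


def realize_iupac(motif: str, rng: np.random.Generator) -> str:
    """One concrete DNA word drawn uniformly from the motif's options."""
    return "".join(IUPAC[ch][rng.integers(len(IUPAC[ch]))]
                   for ch in motif.upper())


def motif_group_stats(motif: RBPMotif, seqs: Mapping[str, str] | Sequence[str],
                      count_mode: str = "matching") -> MotifStats:
    """Binding statistics of one motif over a sequence group.

    ``count_mode='matching'`` averages the appearance count over sequences
    with at least one match (absence is already captured by f);
    ``count_mode='all'`` averages over every sequence.
    """
    values = list(seqs.values()) if isinstance(seqs, Mapping) else list(seqs)
    if not values:
        raise ValueError("empty sequence group")
    if count_mode not in ("matching", "all"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    counts = np.array([iupac_match_count(motif, s) for s in values])
    hit = counts > 0
    f = float(hit.mean())
    if count_mode == "matching":
        c_bar = float(counts[hit].mean()) if hit.any() else 0.0
    else:
        c_bar = float(counts.mean())
    return MotifStats(motif.rbp_name, f=f, c_bar=c_bar, B=f * c_bar,
                      n_sequences=len(values))


def scan_motif_table(motifs: Sequence[RBPMotif] | pd.DataFrame,
                     seqs: Mapping[str, str] | Sequence[str],
                     count_mode: str = "matching") -> pd.DataFrame:
    """Per-RBP stats table (columns f, c_bar, B) over one sequence group."""
    if isinstance(motifs, pd.DataFrame):
        motifs = [RBPMotif(r.rbp_name, r.motif) for r in motifs.itertuples()]
    rows = [motif_group_stats(m, seqs, count_mode=count_mode) for m in motifs]
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("rbp_name")
    return out[["f", "c_bar", "B", "n_sequences"]]


def rank_rbps(stats: pd.DataFrame, f_min: float = 0.70,
              top_n: int = 20) -> pd.DataFrame:
    """Filter on binding frequency, then rank by binding score.

    Keeps RBPs with f > f_min, sorts by B descending (ties broken by f
    descending then name ascending) and returns the top ``top_n``.
    """
    kept = stats[stats["f"] > f_min].copy()
    kept = kept.sort_values(["B", "f", kept.index.name or "rbp_name"],
                            ascending=[False, False, True],
                            kind="mergesort")
    kept = kept.head(top_n)
    kept["rank"] = np.arange(1, len(kept) + 1)
    return kept


def differential_binding(stats_a: pd.DataFrame,
                         stats_b: pd.DataFrame) -> pd.DataFrame:
    """Join per-RBP binding scores of two groups and compare.

    Group A is conventionally the retained-intron group; the output is
    sorted by its binding score.  A motif matched only in group A gets an
    infinite ratio flagged ``A-exclusive``.
    """
    if set(stats_a.index) != set(stats_b.index):
        raise ValueError("the two groups use different motif sets")
    b = stats_b.loc[stats_a.index]
    out = pd.DataFrame({
        "B_a": stats_a["B"], "B_b": b["B"],
        "f_a": stats_a["f"], "f_b": b["f"],
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = out["B_a"] / out["B_b"]
    out["difference"] = out["B_a"] - out["B_b"]
    out["flag"] = ""
    out.loc[(out["B_b"] == 0) & (out["B_a"] > 0), "flag"] = "A-exclusive"
    out.loc[(out["B_a"] == 0) & (out["B_b"] > 0), "flag"] = "B-exclusive"
    out.loc[(out["B_a"] == 0) & (out["B_b"] == 0), "ratio"] = np.nan
    return out.sort_values("B_a", ascending=False, kind="mergesort")


def read_motif_table(path) -> list[RBPMotif]:
    """Read a motif TSV with columns rbp_name, motif."""
    df = pd.read_csv(path, sep="\t")
    return [RBPMotif(str(r.rbp_name), str(r.motif)) for r in df.itertuples()]
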