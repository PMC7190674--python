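"""Z-score standardization and composite gene-signature scoring.

Expression (log2 scale) is standardized per gene against a reference
sample set — Z = (x - mean_ref) / sd_ref — or against the whole cohort
when no reference exists.  A signature score for a sample is the SUM of
Z-scores over the signature's detected member genes; the sum scale is what
makes the +/-7 fractionation cutoff of the 20-gene androgen-receptor (AR)
activity signature meaningful.  Cohorts are stratified by inclusive
+/-7 fractionation (AR activity), by median split (ties to the low group),
or by top/bottom-k extremes.

Shipped signatures: the 20 AR transcriptional targets, and the 13-gene
unfavorable and favorable prognostic splicing-regulatory-gene signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]
    direction: str = "neutral"  # unfavorable | favorable | neutral

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty signature")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")


def _load_gene_list(filename: str) -> tuple[str, ...]:
    text = resources.files("spliceomix.data").joinpath(filename).read_text()
    return tuple(line.strip() for line in text.splitlines()
                 if line.strip() and not line.startswith("#"))


def ar_targets() -> GeneSignature:
    """The 20 androgen-induced AR transcriptional target genes."""
    return GeneSignature("AR_activity", _load_gene_list("ar_targets.txt"))


def unfavorable_signature() -> GeneSignature:
    return GeneSignature("unfavorable_SRG",
                         _load_gene_list("signature_unfavorable.txt"),
                         direction="unfavorable")


def favorable_signature() -> GeneSignature:
    return GeneSignature("favorable_SRG",
                         _load_gene_list("signature_favorable.txt"),
                         direction="favorable")


@dataclass
class ZMatrix:
    """Genes x samples Z-scores plus the reference statistics used."""

    z: pd.DataFrame
    ref_mean: pd.Series
    ref_sd: pd.Series
    reference_samples: tuple[str, ...]
    excluded_genes: tuple[str, ...]


def zscore_vs_reference(expr: pd.DataFrame,
                        reference_samples=None) -> ZMatrix:
    """Standardize each gene against reference samples (or the cohort).

    Zero-variance genes are excluded and listed.  Reference mean/SD use
    the sample SD (ddof=1), so the reference samples themselves have mean
    0 and SD 1 under their own standardization.
    """
    if reference_samples is None:
        reference_samples = list(expr.columns)
    else:
        reference_samples = list(reference_samples)
        missing = set(reference_samples) - set(expr.columns)
        if missing:
            raise KeyError(f"reference samples not in matrix: {sorted(missing)}")
        if len(reference_samples) < 3:
            raise ValueError("need at least 3 reference samples")
    ref = expr[reference_samples]
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > 0
    excluded = tuple(expr.index[~keep])
    if excluded:
        warnings.warn(f"{len(excluded)} zero-variance genes excluded "
                      f"from Z-matrix: {list(excluded)[:5]}...")
    z = expr[keep.to_numpy()].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return ZMatrix(z=z, ref_mean=mean[keep], ref_sd=sd[keep],
                   reference_samples=tuple(reference_samples),
                   excluded_genes=excluded)


def composite_score(z: ZMatrix | pd.DataFrame,
                    signature: GeneSignature) -> tuple[pd.Series, int]:
    """Per-sample sum of member-gene Z-scores and the detected-gene count."""
    zm = z.z if isinstance(z, ZMatrix) else z
    detected = [g for g in signature.genes if g in zm.index]
    if not detected:
        raise ValueError(f"no genes of signature {signature.name!r} detected")
    score = zm.loc[detected].sum(axis=0)
    score.name = signature.name
    return score, len(detected)


def ar_activity_fractionate(scores: pd.Series, hi: float = 7.0,
                            lo: float = -7.0, inclusive: bool = True
                            ) -> tuple[pd.Index, pd.Index, pd.Index]:
    """(high, low, unassigned) sample sets by score thresholds.

    Inclusive comparison (score >= hi / <= lo) by default; ``inclusive=
    False`` switches to strict inequalities.
    """
    if inclusive:
        high = scores.index[scores >= hi]
        low = scores.index[scores <= lo]
    else:
        high = scores.index[scores > hi]
        low = scores.index[scores < lo]
    rest = scores.index.difference(high.union(low), sort=False)
    if len(high) == 0 and len(low) == 0:
        warnings.warn("no samples beyond either fractionation threshold")
    return high, low, rest


def median_split(scores: pd.Series) -> tuple[pd.Index, pd.Index]:
    """(high, low) split at the median; ties go to the low group."""
    if len(scores) < 4:
        raise ValueError("median split needs at least 4 samples")
    med = scores.median()
    high = scores.index[scores > med]
    low = scores.index[scores <= med]
    if len(high) == 0:
        warnings.warn("all scores equal: every sample assigned to low group")
    return high, low


def select_extremes(scores: pd.Series, k: int = 20
                    ) -> tuple[pd.Index, pd.Index]:
    """Top-k and bottom-k samples by score; boundary ties by sample id."""
    n = len(scores)
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds sample count {n}")
    df = scores.rename("score").rename_axis("sample").reset_index()
    top = df.sort_values(["score", "sample"], ascending=[False, True],
                         kind="mergesort").head(k)["sample"]
    bottom = df.sort_values(["score", "sample"], ascending=[True, True],
                            kind="mergesort").head(k)["sample"]
    return pd.Index(top), pd.Index(bottom)
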