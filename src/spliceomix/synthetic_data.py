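"""Synthetic data generation with planted ground truth.

Everything downstream of this module — PSI quantification, the intron
splicing-code features, RBP motif scoring, signature survival analysis and
alteration statistics — is exercised on cohorts produced here, where every
planted parameter (group PSI values, motif positions, copy-number states,
hazard coefficients) is recorded in a truth object so that recovery can be
checked against it.

Count model: per event and sample the total informative read count is
Poisson(depth) and the inclusion count is Binomial(total, psi) at the
group's true PSI.  Survival: exponential baseline proportional-hazards with
the log hazard proportional to the standardized composite signature score,
and independent uniform administrative censoring calibrated to the requested
censoring fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rbp_motifs import iupac_match_positions, realize_iupac

AS_TYPES = ("SE", "A5", "A3", "MX", "IR")

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EventDesign:
    """One block of AS events sharing a type and true group PSI values."""

    as_type: str
    n_events: int
    psi_a: float
    psi_b: float

    def __post_init__(self) -> None:
        if self.as_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.as_type!r}")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        for psi in (self.psi_a, self.psi_b):
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"PSI {psi} outside [0, 1]")

    @property
    def is_null(self) -> bool:
        return self.psi_a == self.psi_b


@dataclass
class CohortDesign:
    """Patient-cohort generative parameters.

    ``effect_size`` is the mean log2-expression shift added for an amplified
    gene and subtracted for a deleted one.  ``log_hazard_coef`` is the log
    hazard ratio per standard deviation of the composite signature score.
    """

    n_patients: int = 200
    p_amp: float = 0.05
    p_del: float = 0.05
    p_mut: float = 0.02
    effect_size: float = 2.0
    baseline_hazard: float = 0.1
    log_hazard_coef: float = float(np.log(3.0))
    censoring_fraction: float = 0.30
    gleason_amp_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for p in (self.p_amp, self.p_del, self.p_mut):
            if not 0.0 <= p <= 1.0:
                raise ValueError("alteration probabilities must be in [0, 1]")
        if self.p_amp + self.p_del + self.p_mut > 1.0:
            raise ValueError("alteration probabilities sum above 1")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


def default_event_design() -> list[EventDesign]:
    """900 null + 100 alternative events at |dPSI| = 0.3, mixed types."""
    design = []
    for as_type, n_null, n_alt in (
        ("SE", 400, 40), ("IR", 250, 30), ("A3", 100, 10),
        ("A5", 100, 10), ("MX", 50, 10),
    ):
        design.append(EventDesign(as_type, n_null, 0.5, 0.5))
        design.append(EventDesign(as_type, n_alt, 0.3, 0.6))
    return design


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (150, 1200)
    gc_target: float = 0.45
    event_design: list[EventDesign] = field(default_factory=default_event_design)
    depth: int = 100
    n_replicates: int = 3
    cohort: CohortDesign = field(default_factory=CohortDesign)

    def __post_init__(self) -> None:
        lo, hi = self.exons_per_gene
        if lo < 2:
            raise ValueError("genes must have at least 2 exons to carry introns")
        if hi < lo:
            raise ValueError("exons_per_gene range inverted")
        for name, (a, b) in (("exon_len", self.exon_len), ("intron_len", self.intron_len)):
            if a <= 0 or b < a:
                raise ValueError(f"invalid {name} range")
        if self.intron_len[0] < 30:
            raise ValueError("introns shorter than 30 bp cannot carry site windows")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Planted parameters; each generated record is covered exactly once."""

    events: pd.DataFrame | None = None          # event_id -> type, psi_a, psi_b
    motifs: dict[str, list[int]] | None = None  # seq_id -> planted match starts
    cohort: pd.DataFrame | None = None          # patient-level true states

    def to_json(self, path: str | Path) -> None:
        payload = {}
        if self.events is not None:
            payload["events"] = self.events.reset_index().to_dict(orient="list")
        if self.motifs is not None:
            payload["motifs"] = self.motifs
        if self.cohort is not None:
            payload["cohort"] = self.cohort.reset_index().to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """Multi-exon gene models with one chromosome per gene.

    Coordinates are 0-based half-open internally and converted to the
    1-based inclusive GTF convention only at serialization.
    """

    exons: pd.DataFrame    # gene_id, transcript_id, chrom, start, end, strand
    introns: pd.DataFrame  # intron_id, gene_id, chrom, start, end, strand
    genome: dict[str, str]

    def write_gtf(self, path: str | Path) -> None:
        lines = []
        for row in self.exons.itertuples():
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}";'
            lines.append(
                f"{row.chrom}\tspliceomix\texon\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in self.genome.items()]
        SeqIO.write(records, str(path), "fasta")


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def gc_content(seq: str) -> float:
    counted = [b for b in seq.upper() if b in "ACGT"]
    if not counted:
        raise ValueError("sequence has no unambiguous bases")
    return sum(b in "GC" for b in counted) / len(counted)


def generate_annotation(config: SimConfig) -> Annotation:
    """Generate gene models and genome sequence with GT..AG introns."""
    rng = np.random.default_rng(config.seed)
    exon_rows, intron_rows, genome = [], [], {}
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        chrom = f"chr_{gene_id}"
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pieces, pos = [], 100  # leading pad keeps windows inside bounds
        pad = random_sequence(rng, 100, config.gc_target)
        pieces.append(pad)
        for e in range(n_exons):
            elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            exon_rows.append(dict(gene_id=gene_id, transcript_id=gene_id + ".t1",
                                  chrom=chrom, start=pos, end=pos + elen,
                                  strand=strand))
            pieces.append(random_sequence(rng, elen, config.gc_target))
            pos += elen
            if e < n_exons - 1:
                ilen = int(rng.integers(config.intron_len[0],
                                        config.intron_len[1] + 1))
                iseq = random_sequence(rng, ilen, config.gc_target)
                # canonical boundaries in genomic orientation of the strand
                if strand == "+":
                    iseq = "GT" + iseq[2:-2] + "AG"
                else:
                    iseq = "CT" + iseq[2:-2] + "AC"  # revcomp of GT..AG
                intron_rows.append(dict(
                    intron_id=f"{gene_id}.i{e + 1}", gene_id=gene_id,
                    chrom=chrom, start=pos, end=pos + ilen, strand=strand))
                pieces.append(iseq)
                pos += ilen
        pieces.append(random_sequence(rng, 100, config.gc_target))
        genome[chrom] = "".join(pieces)
    return Annotation(exons=pd.DataFrame(exon_rows),
                      introns=pd.DataFrame(intron_rows), genome=genome)


def intron_sequences(annotation: Annotation) -> pd.Series:
    """Sense-strand (5'->3') sequence of every annotated intron."""
    from .intron_code import reverse_complement

    seqs = {}
    for row in annotation.introns.itertuples():
        s = annotation.genome[row.chrom][row.start:row.end]
        seqs[row.intron_id] = s if row.strand == "+" else reverse_complement(s)
    return pd.Series(seqs, name="sequence")


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

@dataclass
class JunctionCounts:
    """Inclusion/skipping counts, events x samples, plus group labels."""

    inclusion: pd.DataFrame
    skipping: pd.DataFrame
    groups: pd.Series  # sample -> group label

    def write_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.inclusion.to_csv(directory / "inclusion.tsv", sep="\t")
        self.skipping.to_csv(directory / "skipping.tsv", sep="\t")
        self.groups.rename("group").to_csv(directory / "groups.tsv", sep="\t")


def event_truth(design: Sequence[EventDesign]) -> TruthSet:
    rows = []
    for block in design:
        for _ in range(block.n_events):
            rows.append(dict(as_type=block.as_type, psi_a=block.psi_a,
                             psi_b=block.psi_b,
                             delta_psi=block.psi_b - block.psi_a,
                             is_null=block.is_null))
    events = pd.DataFrame(rows)
    events.index = [f"EV{i + 1:05d}" for i in range(len(events))]
    events.index.name = "event_id"
    return TruthSet(events=events)


def simulate_junction_counts(truth: TruthSet, depth: int, n_replicates: int,
                             seed: int) -> JunctionCounts:
    """Binomial inclusion counts given Poisson event totals, per sample."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    events = truth.events
    if events is None:
        raise ValueError("truth carries no event table")
    rng = np.random.default_rng(seed)
    n_ev = len(events)
    samples, groups = [], {}
    inc_cols, skp_cols = [], []
    for group, psi_col in (("A", "psi_a"), ("B", "psi_b")):
        psi = events[psi_col].to_numpy()
        for r in range(n_replicates):
            name = f"{group}{r + 1}"
            total = rng.poisson(depth, size=n_ev)
            inc = rng.binomial(total, psi)
            inc_cols.append(inc)
            skp_cols.append(total - inc)
            samples.append(name)
            groups[name] = group
    inclusion = pd.DataFrame(np.column_stack(inc_cols), index=events.index,
                             columns=samples)
    skipping = pd.DataFrame(np.column_stack(skp_cols), index=events.index,
                            columns=samples)
    return JunctionCounts(inclusion=inclusion, skipping=skipping,
                          groups=pd.Series(groups))


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def random_sequences(n: int, length: int, gc: float, seed: int,
                     avoid_motif: str | None = None,
                     max_tries: int = 200) -> dict[str, str]:
    """Random sequences; with ``avoid_motif``, rejection-sampled motif-free."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        for _ in range(max_tries):
            seq = random_sequence(rng, length, gc)
            if avoid_motif is None or not iupac_match_positions(avoid_motif, seq):
                break
        else:
            raise RuntimeError(f"could not generate motif-free sequence "
                               f"of length {length} avoiding {avoid_motif!r}")
        out[f"S{i + 1:04d}"] = seq
    return out


def plant_motifs(seqs: Mapping[str, str], motif: str, seed: int,
                 frac_seqs: float = 1.0,
                 per_seq: int = 1) -> tuple[dict[str, str], TruthSet]:
    """Overwrite random concrete realizations of ``motif`` into sequences.

    ``frac_seqs`` of the sequences (chosen at random) each receive
    ``per_seq`` non-overlapping occurrences.  Truth records, per sequence,
    every match start found by rescanning the edited sequence, so planted
    and incidental occurrences are both covered.
    """
    if per_seq < 0 or not 0.0 <= frac_seqs <= 1.0:
        raise ValueError("invalid occurrence design")
    rng = np.random.default_rng(seed)
    ids = list(seqs)
    n_plant = int(round(frac_seqs * len(ids)))
    chosen = set(rng.choice(ids, size=n_plant, replace=False)) if n_plant else set()
    mlen = len(motif)
    edited, truth = {}, {}
    for sid in ids:
        seq = seqs[sid]
        if sid in chosen and per_seq > 0:
            if mlen > len(seq):
                raise ValueError(f"motif longer than sequence {sid}")
            taken: list[int] = []
            for _ in range(per_seq):
                for _ in range(200):
                    pos = int(rng.integers(0, len(seq) - mlen + 1))
                    if all(abs(pos - t) >= mlen for t in taken):
                        break
                else:
                    raise RuntimeError(f"no room for {per_seq} occurrences in {sid}")
                word = realize_iupac(motif, rng)
                seq = seq[:pos] + word + seq[pos + mlen:]
                taken.append(pos)
        edited[sid] = seq
        truth[sid] = iupac_match_positions(motif, seq)
    return edited, TruthSet(motifs=truth)


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Patients x {expression, alteration calls, Gleason, survival}."""

    expression: pd.DataFrame   # genes x patients, log2 scale
    alterations: pd.DataFrame  # patients x genes in {amp, del, mut, none}
    clinical: pd.DataFrame     # patient -> time, event, gleason

    def write_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.expression.to_csv(directory / "expression.tsv", sep="\t")
        self.alterations.to_csv(directory / "alterations.tsv", sep="\t")
        self.clinical.to_csv(directory / "clinical.tsv", sep="\t")


def _censoring_horizon(hazards: np.ndarray, fraction: float) -> float:
    """Uniform(0, tau) horizon giving the requested expected censoring."""
    def frac_at(tau: float) -> float:
        lt = hazards * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    # frac_at decreases from 1 (tau -> 0) to 0 (tau -> inf)
    lo, hi = 1e-9, 1.0 / hazards.min()
    while frac_at(hi) > fraction:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_at(mid) > fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimConfig, signature_genes: Sequence[str],
                    extra_genes: Sequence[str] = (),
                    seed: int | None = None) -> tuple[CohortTable, TruthSet]:
    """Cohort with CNV-coupled expression and signature-dependent hazards."""
    design = config.cohort
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = list(dict.fromkeys(list(signature_genes) + list(extra_genes)))
    if not genes:
        raise ValueError("no genes to simulate")
    n, g = design.n_patients, len(genes)
    patients = [f"P{i + 1:04d}" for i in range(n)]

    # alteration calls: one per gene per patient
    u = rng.random((n, g))
    calls = np.full((n, g), "none", dtype=object)
    calls[u < design.p_amp] = "amp"
    calls[(u >= design.p_amp) & (u < design.p_amp + design.p_del)] = "del"
    calls[(u >= design.p_amp + design.p_del)
          & (u < design.p_amp + design.p_del + design.p_mut)] = "mut"
    alterations = pd.DataFrame(calls, index=patients, columns=genes)

    baseline = rng.normal(5.0, 1.0, size=g)
    expr = baseline[None, :] + rng.normal(0.0, 1.0, size=(n, g))
    expr = expr + design.effect_size * ((calls == "amp").astype(float)
                                        - (calls == "del").astype(float))
    expression = pd.DataFrame(expr.T, index=genes, columns=patients)

    # composite signature score from cohort-standardized member genes
    sig = [gn for gn in signature_genes if gn in expression.index]
    z = expression.loc[sig]
    z = z.sub(z.mean(axis=1), axis=0).div(z.std(axis=1, ddof=1), axis=0)
    score = z.sum(axis=0)
    u_score = (score - score.mean()) / score.std(ddof=1)

    hazards = design.baseline_hazard * np.exp(
        design.log_hazard_coef * u_score.to_numpy())
    t_true = rng.exponential(1.0 / hazards)
    if design.censoring_fraction > 0:
        tau = _censoring_horizon(hazards, design.censoring_fraction)
        c = rng.uniform(0.0, tau, size=n)
        time = np.minimum(t_true, c)
        event = (t_true <= c).astype(int)
    else:
        time, event = t_true, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)

    any_amp = (calls == "amp").any(axis=1)
    gleason = np.clip(np.round(
        rng.normal(7.0, 1.0, size=n)
        + design.gleason_amp_shift * any_amp), 6, 10).astype(int)

    clinical = pd.DataFrame(dict(time=time, event=event, gleason=gleason),
                            index=patients)
    truth = TruthSet(cohort=pd.DataFrame(
        dict(true_hazard=hazards, true_time=t_true, true_score=score,
             any_amp=any_amp), index=patients))
    return CohortTable(expression, alterations, clinical), truth
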