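"""Configuration-driven end-to-end runs with a machine-readable report.

Pipeline: simulate -> quantify -> characterize introns -> score motifs ->
signature scoring -> survival -> report.  Every stage is deterministic
given the configured seed, writes its outputs under the run directory,
and contributes one section to the JSON report.  The recovery suite
re-estimates each planted generator parameter from the generated data and
tabulates planted value, recovered value, tolerance and verdict.
"""

from __future__ import annotations

import difflib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from . import intron_code, rbp_motifs, signatures, splicing_quant, srg_genomics
from . import survival as surv
from .synthetic_data import (Annotation, CohortDesign, EventDesign, SimConfig,
                             event_truth, generate_annotation, gc_content,
                             intron_sequences, simulate_cohort,
                             simulate_junction_counts)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration schema (strict: unknown keys rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThresholdBlock(_Strict):
    dpsi: float = Field(0.1, ge=0.0, le=1.0)
    fdr: float = Field(0.1, gt=0.0, le=1.0)


class EventBlock(_Strict):
    as_type: str
    n_events: int = Field(ge=0)
    psi_a: float = Field(ge=0.0, le=1.0)
    psi_b: float = Field(ge=0.0, le=1.0)


class CohortBlock(_Strict):
    n_patients: int = Field(200, ge=4)
    p_amp: float = Field(0.05, ge=0.0, le=1.0)
    p_del: float = Field(0.05, ge=0.0, le=1.0)
    p_mut: float = Field(0.02, ge=0.0, le=1.0)
    effect_size: float = 2.0
    baseline_hazard: float = Field(0.1, gt=0.0)
    log_hazard_coef: float = float(np.log(3.0))
    censoring_fraction: float = Field(0.30, ge=0.0, lt=1.0)


class SimulationBlock(_Strict):
    n_genes: int = Field(30, ge=1)
    exons_min: int = Field(3, ge=2)
    exons_max: int = Field(6, ge=2)
    gc_target: float = Field(0.45, gt=0.0, lt=1.0)
    depth: int = Field(100, gt=0)
    n_replicates: int = Field(3, ge=1)
    event_design: list[EventBlock] | None = None
    cohort: CohortBlock = Field(default_factory=CohortBlock)


class RunConfig(_Strict):
    scenario: str = "run"
    seed: int = 0
    out_dir: str = "spliceomix_run"
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    thresholds: ThresholdBlock = Field(default_factory=ThresholdBlock)


def _format_errors(exc: ValidationError) -> str:
    known: set[str] = set()
    for model in (RunConfig, SimulationBlock, CohortBlock, ThresholdBlock,
                  EventBlock):
        known |= set(model.model_fields)
    items = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        msg = f"{loc}: {err['msg']}"
        if err["type"] == "extra_forbidden":
            key = str(err["loc"][-1])
            close = difflib.get_close_matches(key, known, n=1)
            if close:
                msg += f" (did you mean {close[0]!r}?)"
        items.append(msg)
    return "invalid configuration:\n  " + "\n  ".join(items)


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        raise ValueError(_format_errors(exc)) from exc


def _sim_config(cfg: RunConfig) -> SimConfig:
    sim = cfg.simulation
    design = None
    if sim.event_design is not None:
        design = [EventDesign(e.as_type, e.n_events, e.psi_a, e.psi_b)
                  for e in sim.event_design]
    kwargs = dict(seed=cfg.seed, n_genes=sim.n_genes,
                  exons_per_gene=(sim.exons_min, sim.exons_max),
                  gc_target=sim.gc_target, depth=sim.depth,
                  n_replicates=sim.n_replicates,
                  cohort=CohortDesign(**sim.cohort.model_dump()))
    if design is not None:
        kwargs["event_design"] = design
    return SimConfig(**kwargs)


SMOKE_CONFIG = RunConfig(
    scenario="smoke", seed=7, out_dir="spliceomix_smoke",
    simulation=SimulationBlock(
        n_genes=20, depth=100, n_replicates=3,
        event_design=[
            EventBlock(as_type="SE", n_events=60, psi_a=0.5, psi_b=0.5),
            EventBlock(as_type="IR", n_events=60, psi_a=0.5, psi_b=0.5),
            EventBlock(as_type="IR", n_events=20, psi_a=0.3, psi_b=0.6),
            EventBlock(as_type="SE", n_events=20, psi_a=0.6, psi_b=0.3),
            EventBlock(as_type="A3", n_events=20, psi_a=0.5, psi_b=0.5),
            EventBlock(as_type="A5", n_events=20, psi_a=0.5, psi_b=0.5),
        ],
        cohort=CohortBlock(n_patients=40)))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _shuffled_windows(windows, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    out = []
    for w in windows:
        chars = list(w)
        rng.shuffle(chars)
        out.append("".join(chars))
    return out


def _stage(report: dict, name: str, payload: dict, t0: float) -> None:
    payload = dict(payload)
    payload["elapsed_s"] = round(time.perf_counter() - t0, 3)
    report["stages"][name] = payload
    logger.info("stage %-12s %s", name, payload)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and write) the run report."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "scenario": config.scenario, "seed": config.seed,
        "version": __version__,
        "parameters": config.model_dump(), "stages": {},
    }
    sim = _sim_config(config)

    # -- simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    annotation = generate_annotation(sim)
    truth = event_truth(sim.event_design)
    counts = simulate_junction_counts(truth, sim.depth, sim.n_replicates,
                                      seed=sim.seed + 1)
    annotation.write_gtf(out / "annotation.gtf")
    annotation.write_fasta(out / "genome.fa")
    counts.write_tsv(out)
    truth.to_json(out / "truth_events.json")
    _stage(report, "simulate", dict(
        n_genes=sim.n_genes, n_events=len(truth.events),
        n_introns=len(annotation.introns),
        n_samples=len(counts.groups)), t0)

    # -- quantify ----------------------------------------------------------
    t0 = time.perf_counter()
    results = splicing_quant.differential_table(counts)
    called = splicing_quant.call_dse(results, config.thresholds.dpsi,
                                     config.thresholds.fdr)
    called.to_csv(out / "splicing_results.tsv", sep="\t")
    truth_aligned = truth.events.loc[called.index]
    is_alt = ~truth_aligned["is_null"]
    n_called = int(called["called"].sum())
    sensitivity = float(called.loc[is_alt, "called"].mean()) if is_alt.any() else np.nan
    fdp = (float((~is_alt[called["called"]]).mean()) if n_called else 0.0)
    part = splicing_quant.partition_dse(called, truth_aligned["as_type"])
    _stage(report, "quantify", dict(
        n_called=n_called, sensitivity=sensitivity, fdp=fdp,
        per_type=part["total"].to_dict()), t0)

    # -- intron splicing code ----------------------------------------------
    t0 = time.perf_counter()
    introns = annotation.introns
    seqs = intron_sequences(annotation)
    windows = intron_code.extract_all_windows(introns, annotation.genome)
    donor_model = intron_code.fit_maxent(
        list(windows["donor"]), _shuffled_windows(windows["donor"], sim.seed + 2),
        order=0, min_signal=min(50, len(windows)))
    acceptor_model = intron_code.fit_maxent(
        list(windows["acceptor"]),
        _shuffled_windows(windows["acceptor"], sim.seed + 3),
        order=0, min_signal=min(50, len(windows)))
    feats = intron_code.intron_feature_frame(introns, annotation.genome,
                                             donor_model, acceptor_model)
    feats.to_csv(out / "intron_features.tsv", sep="\t")

    # retained = introns standing in for the called up-regulated IR events;
    # constitutive = central zero-delta-PSI events of the generator's list
    ir_truth = truth.events[truth.events["as_type"] == "IR"]
    intron_of_event = pd.Series(
        [introns["intron_id"].iloc[i % len(introns)]
         for i in range(len(ir_truth))], index=ir_truth.index)
    ir_called = called.reindex(ir_truth.index)
    retained_ids = intron_of_event[(ir_called["called"] == True)  # noqa: E712
                                   & (ir_called["direction"] == "up")]
    n_const = min(300, int((ir_truth["delta_psi"] == 0).sum()))
    const_events = intron_code.select_constitutive_introns(ir_truth, n=n_const)
    const_ids = intron_of_event[const_events.index]
    comparison = None
    if len(retained_ids) >= 3 and len(const_ids) >= 3:
        comparison = intron_code.compare_intron_groups(
            feats.loc[retained_ids.unique()], feats.loc[const_ids.unique()])
        comparison.to_csv(out / "intron_group_comparison.tsv", sep="\t")
    _stage(report, "intron_code", dict(
        n_retained=int(len(retained_ids)), n_constitutive=int(len(const_ids)),
        maxent_max_dev=donor_model.diagnostics["max_marginal_dev"],
        comparison={} if comparison is None
        else comparison["p_value"].round(6).to_dict()), t0)

    # -- RBP motifs ----------------------------------------------------------
    t0 = time.perf_counter()
    from importlib import resources
    motif_path = resources.files("spliceomix.data") / "synthetic_motifs.tsv"
    motifs = rbp_motifs.read_motif_table(str(motif_path))
    grp_a = {i: seqs[i] for i in retained_ids.unique()} or dict(seqs.head(5))
    grp_b = {i: seqs[i] for i in const_ids.unique()} or dict(seqs.tail(5))
    stats_a = rbp_motifs.scan_motif_table(motifs, grp_a)
    stats_b = rbp_motifs.scan_motif_table(motifs, grp_b)
    shortlist = rbp_motifs.rank_rbps(stats_a)
    diff = rbp_motifs.differential_binding(stats_a, stats_b)
    diff.to_csv(out / "rbp_binding.tsv", sep="\t")
    _stage(report, "rbp_motifs", dict(
        n_motifs=len(motifs), n_shortlisted=len(shortlist),
        top_rbp=(shortlist.index[0] if len(shortlist) else None)), t0)

    # -- cohort, signatures, survival, alterations ---------------------------
    t0 = time.perf_counter()
    signature = signatures.unfavorable_signature()
    extra = [f"FILLER{i:02d}" for i in range(10)]
    cohort, cohort_truth = simulate_cohort(sim, signature.genes,
                                           extra_genes=extra,
                                           seed=sim.seed + 4)
    cohort.write_tsv(out)
    zmat = signatures.zscore_vs_reference(cohort.expression)
    score, n_detected = signatures.composite_score(zmat, signature)
    high, low = signatures.median_split(score)
    surv_report = surv.signature_survival_report(score, cohort.clinical,
                                                 split="median")
    surv.km_plot({"high": surv_report.high_curve,
                  "low": surv_report.low_curve},
                 path=out / "km_signature.png",
                 title=f"{signature.name} (median split)")
    freq = srg_genomics.alteration_freq_table(cohort.alterations)
    freq.to_csv(out / "alteration_freq.tsv", sep="\t")
    cum = srg_genomics.cumulative_freq(cohort.alterations,
                                       cohort.alterations.columns)
    grade = srg_genomics.grade_association(
        cohort_truth.cohort["any_amp"], cohort.clinical["gleason"])
    _stage(report, "signatures_survival", dict(
        n_patients=len(score), n_detected_genes=n_detected,
        n_high=len(high), n_low=len(low),
        logrank_p=surv_report.logrank.p_value,
        direction=surv_report.direction,
        cumulative_alteration_freq=cum,
        grade_p=grade["p_value"]), t0)

    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                default=str))
    return report


# ---------------------------------------------------------------------------
# parameter-recovery suite
# ---------------------------------------------------------------------------

def recovery_suite(config: RunConfig) -> pd.DataFrame:
    """Re-estimate every planted generator parameter from generated data."""
    sim = _sim_config(config)
    if sim.n_replicates < 1:
        raise ValueError("recovery suite needs at least one replicate")
    rows = []

    def check(name, planted, recovered, tol):
        rows.append(dict(check=name, planted=float(planted),
                         recovered=float(recovered), tolerance=float(tol),
                         verdict="pass" if abs(recovered - planted) <= tol
                         else "FAIL"))

    annotation = generate_annotation(sim)
    seqs = intron_sequences(annotation)
    mean_gc = float(np.mean([gc_content(s) for s in seqs]))
    check("intron_gc", sim.gc_target, mean_gc, 0.05)

    truth = event_truth(sim.event_design)
    counts = simulate_junction_counts(truth, sim.depth, sim.n_replicates,
                                      seed=sim.seed + 1)
    results = splicing_quant.differential_table(counts)
    t = truth.events.loc[results.index]
    err = np.abs(np.concatenate([
        results["psi_bar_a"] - t["psi_a"], results["psi_bar_b"] - t["psi_b"]]))
    check("psi_recovery_mae", 0.0, float(np.nanmean(err)), 0.03)

    called = splicing_quant.call_dse(results, config.thresholds.dpsi,
                                     config.thresholds.fdr)
    is_alt = ~t["is_null"]
    if is_alt.any():
        check("dse_sensitivity", 1.0,
              float(called.loc[is_alt, "called"].mean()), 0.15)
    n_called = int(called["called"].sum())
    fdp = float((t["is_null"] & called["called"]).sum() / n_called) \
        if n_called else 0.0
    check("dse_fdp", 0.0, fdp, 0.15)

    cohort, cohort_truth = simulate_cohort(
        sim, signatures.unfavorable_signature().genes, seed=sim.seed + 4)
    gene = (cohort.alterations == "amp").sum(axis=0).idxmax()
    amp = cohort.alterations[gene] == "amp"
    none = cohort.alterations[gene] == "none"
    if amp.sum() >= 3:
        diff = (cohort.expression.loc[gene, amp.index[amp]].mean()
                - cohort.expression.loc[gene, none.index[none]].mean())
        check("cnv_expression_shift", sim.cohort.effect_size, diff, 0.8)
    freq = srg_genomics.alteration_freq_table(cohort.alterations)["amp"].mean()
    check("amp_frequency", sim.cohort.p_amp, float(freq), 0.03)

    return pd.DataFrame(rows)
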