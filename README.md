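# spliceomix

A toolkit for studying the alternative-splicing landscape of tumor cohorts —
differential splicing quantification, the sequence "code" of retained introns,
RNA-binding-protein (RBP) motif enrichment, gene-signature scoring, and
survival stratification — together with fully synthetic data generators that
plant a known ground truth so every analysis step can be validated end to end.

## Scientific problem

Aggressive cancers, prostate cancer in particular, rewire pre-mRNA splicing:
intron retention increases, splicing-regulatory genes (SRGs) are recurrently
amplified, deleted or mis-expressed, and composite expression signatures of
these genes stratify patient survival. Analyzing this involves a chain of
quantitative steps, each with subtle statistical conventions:

1. **PSI quantification.** For each alternative-splicing event, the percent
   spliced in is estimated from inclusion (I) and skipping (S) junction reads,
   ψ = (I/lI) / (I/lI + S/lS), with effective lengths lI, lS. A differentially
   spliced event (DSE) requires both |Δψ| > 0.1 and Benjamini–Hochberg
   q < 0.1, where Δψ is group B minus group A and the p-value comes from a
   binomial likelihood-ratio test on pooled per-group counts.
2. **The intron splicing code.** Retained introns are compared against
   constitutively spliced introns (the central zero-Δψ events of a Δψ-sorted
   list) in length, GC content, and donor/acceptor splice-site strength. Site
   strength is scored in bits, log2 P(signal)/P(background), under a
   trainable maximum-entropy model over the 9-base donor window (3 exonic +
   6 intronic) and the 21-base acceptor window (20 intronic + 1 exonic).
3. **RBP motif enrichment.** IUPAC consensus motifs are scanned over sequence
   groups; a motif's binding frequency f (fraction of sequences with ≥ 1
   match) and mean occurrence count c̄ combine into a binding score
   B = f · c̄. Motifs are filtered at f > 0.70 and the top 20 by B retained.
4. **Signatures and survival.** Per-gene Z-scores against a reference sample
   set are summed into composite signature scores (e.g., a 20-gene androgen
   receptor activity score fractionated at ±7); cohorts are split at the
   median or at the best cutoff (lowest log-rank p over candidate
   thresholds), and compared with Kaplan–Meier curves and the log-rank test.
5. **SRG genomics.** Alteration frequencies, cumulative altered fraction of a
   gene set, one-sided Fisher co-occurrence tests, copy-number-to-expression
   shifts, and Gleason-grade associations.

Real cohort results depend on large controlled-access datasets. This package
instead ships generators that simulate annotations, junction counts, and
clinical cohorts **with the planted truth recorded**, so the statistical
machinery itself is testable: planted Δψ must be recovered, null p-values
must be uniform, planted hazard ratios must produce the expected log-rank
rejections, and every closed-form oracle must agree to numerical precision.

## Worked example

Simulate 200 events (180 null, 20 with a planted Δψ = +0.3 intron-retention
shift), quantify, and call DSEs:

```python
from spliceomix.synthetic_data import (EventDesign, event_truth,
                                       simulate_junction_counts)
from spliceomix.splicing_quant import differential_table, call_dse

design = [EventDesign("SE", 180, 0.5, 0.5),   # null background
          EventDesign("IR", 20, 0.3, 0.6)]    # planted delta-PSI = +0.3
truth = event_truth(design)
counts = simulate_junction_counts(truth, depth=100, n_replicates=3, seed=11)
results = call_dse(differential_table(counts))
print(f"{int(results['called'].sum())} of {len(results)} events called")
cols = ["psi_bar_a", "psi_bar_b", "delta_psi", "q_value", "direction"]
print(results.loc[results["called"], cols].head(3).round(4))
```

Output:

```
21 of 200 events called
          psi_bar_a  psi_bar_b  delta_psi  q_value direction
event_id
EV00074      0.4322     0.5696     0.1374   0.0052        up
EV00181      0.2792     0.5859     0.3067   0.0000        up
EV00182      0.2711     0.6269     0.3558   0.0000        up
```

(The 20 planted events are EV00181–EV00200; at these settings all 20 are
recovered, plus one borderline null event — an empirical FDP of 1/21.)

Score the bundled 13-gene unfavorable SRG signature on a simulated cohort
whose hazards are coupled to the signature (hazard ratio 3 per score SD,
30 % censoring), then stratify survival at the median:

```python
from spliceomix.synthetic_data import SimConfig, CohortDesign, simulate_cohort
from spliceomix.signatures import (unfavorable_signature, zscore_vs_reference,
                                   composite_score)
from spliceomix.survival import signature_survival_report

sig = unfavorable_signature()
cfg = SimConfig(seed=21, cohort=CohortDesign(n_patients=200,
                                             censoring_fraction=0.30))
cohort, _ = simulate_cohort(cfg, sig.genes)
score, n_detected = composite_score(zscore_vs_reference(cohort.expression), sig)
report = signature_survival_report(score, cohort.clinical, split="median")
print(f"signature: {sig.name} ({n_detected} genes detected)")
print(f"log-rank chi2 = {report.logrank.statistic:.2f}, "
      f"p = {report.logrank.p_value:.2e}, direction = {report.direction}")
```

Output:

```
signature: unfavorable_SRG (13 genes detected)
log-rank chi2 = 53.59, p = 2.47e-13, direction = unfavorable
```

## Command-line interface

The `spliceomix` command exposes the same functionality:

```
spliceomix simulate     --config cfg.yaml --out run/
spliceomix splice-call  --inclusion inc.tsv --skipping skp.tsv \
                        --groups groups.tsv --dpsi 0.1 --fdr 0.1 --out res.tsv
spliceomix rbp-score    --motifs motifs.tsv --group-a retained.fa --out rbp.tsv
spliceomix signature    --expression expr.tsv --signature unfavorable --out s.tsv
spliceomix survive      --clinical clin.tsv --scores s.tsv --split median --out r.json
spliceomix pipeline run --config cfg.yaml
spliceomix pipeline smoke
spliceomix pipeline recover
```

`pipeline recover` re-estimates every planted generator parameter from
freshly generated data and prints a verdict table:

```
               check  planted  recovered  tolerance verdict
           intron_gc     0.45   0.448883       0.05    pass
    psi_recovery_mae     0.00   0.021875       0.03    pass
     dse_sensitivity     1.00   1.000000       0.15    pass
             dse_fdp     0.00   0.069767       0.15    pass
cnv_expression_shift     2.00   2.343712       0.80    pass
       amp_frequency     0.05   0.065385       0.03    pass
```

## Package layout

| Module | Contents |
| --- | --- |
| `synthetic_data` | Annotation/genome, junction-count, motif-planting and cohort generators with recorded truth |
| `splicing_quant` | PSI, binomial LRT, BH FDR, DSE calling, landscape summaries |
| `intron_code` | Intron features, constitutive-intron selection, splice-site windows, max-entropy scoring, group comparisons |
| `rbp_motifs` | IUPAC scanning, binding statistics, filter-and-rank, differential binding |
| `signatures` | Z-scoring vs reference, composite scores, ±7 fractionation, median/extreme splits |
| `survival` | Kaplan–Meier, log-rank (+ permutation), best-cutoff scans, reports and plots |
| `srg_genomics` | Alteration matrices, frequencies, Fisher co-occurrence, CNV→expression, grade association |
| `overlap_stats` | Set-overlap χ², paired shift tests, IR-direction filters, a simple DEG caller |
| `orchestrator` | Validated YAML configs, the end-to-end pipeline, the parameter-recovery suite |

See `docs/methods.md` for the statistical conventions, default parameters and
their rationale, and known limitations.

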