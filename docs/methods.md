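# Methods

This note records the statistical conventions, the generator models, the
default parameters and their rationale, and the numerical choices made in
`spliceomix`. Problem sizes and tolerances quoted here are the package's own
validation choices.

## 1. PSI quantification and differential splicing

**Definition.** For an event with inclusion count I, skipping count S and
effective lengths lI, lS:

ψ = (I/lI) / (I/lI + S/lS).

Defaults lI = lS = 1 (raw-count ratio) unless annotation-derived lengths are
supplied; with equal lengths ψ is the binomial proportion I/(I+S). An event
with I + S = 0 in a sample is not quantifiable there (ψ = NaN); events not
quantifiable in an entire group are dropped from differential tables and
logged.

**Test.** Counts are pooled within each group and compared with a binomial
likelihood-ratio test: under H0 a single inclusion probability generates both
groups, under H1 each group has its own; 2·ΔlogL is referred to χ²(1). This
is a deliberately transparent stand-in for junction-count DSE tools — it is
oracle-checkable (it agrees with the Pearson χ² on the pooled 2×2 table
asymptotically) and calibrated on the package's own null simulations
(Kolmogorov–Smirnov test against Uniform(0,1) on 2000 null events does not
reject; the fraction of p < 0.05 sits in [0.03, 0.07]). It ignores
between-replicate overdispersion; see Limitations.

**Calling.** A differentially spliced event requires |Δψ| > 0.1 **and**
Benjamini–Hochberg q < 0.1, with Δψ = ψ̄(B) − ψ̄(A) (group order from the
configuration). BH is implemented directly as the step-up
q(i) = min over j ≥ i of min(1, p(j)·m/j) on the sorted p-values, because it
is itself a specified operation with a brute-force oracle in the tests;
`statsmodels.multipletests` serves as an independent cross-check.

## 2. The intron splicing code

**Constitutive introns.** From a Δψ-sorted event list, the events with
Δψ = 0 nearest the center of the list are selected (default n = 300, ties to
the lower index). Fewer than n zeros returns all of them with a warning.

**Site windows.** Donor: 9 bases — 3 exonic + 6 intronic at the 5′ splice
site. Acceptor: 21 bases — 20 intronic + 1 exonic at the 3′ splice site (a
23-base variant with 3 exonic bases is available via `acceptor_exonic=3`).
Windows are reported 5′→3′ on the sense strand; minus-strand introns are
reverse-complemented. Out-of-bounds windows raise an error naming the
intron.

**Features.** L = sequence length; GC = (#G + #C)/(#A + #C + #G + #T), N
bases excluded from both numerator and denominator of GC but counted in L.

**Maximum-entropy model.** Order 0 constrains positional marginals; the
maximum-entropy solution is exactly the product of positional empirical
frequencies. Order 1 adds adjacent-pair marginals; the solution is fitted by
iterative proportional fitting (IPF) on a chain factorization
ψ₁(x₁,x₂)·ψ₂(x₂,x₃)·…, with exact pairwise marginals computed by a
forward–backward pass. A dense table over 4²¹ acceptor states is infeasible;
the chain factorization is exact for the adjacent-pair constraint set, so no
approximation is introduced. Convergence: max marginal deviation < 1e-6,
iteration cap 10 000 (non-convergence raises with diagnostics; in practice
the chain IPF converges in one sweep). Scores are
log2 P(signal)/P(background) in bits; training frequencies use a
pseudocount (default 0.5) so unseen bases do not produce infinities.
Windows containing N or of the wrong length are flagged, not scored.

**Group comparisons.** Feature distributions (L, GC, S5, S3) between
retained and constitutive introns use the two-sided Mann–Whitney test,
exact enumeration when both group sizes are ≤ 8 (so identical tiny groups
give p = 1 exactly), asymptotic otherwise; groups of fewer than 3 are
refused.

## 3. RBP motif statistics

IUPAC consensus motifs are compiled to regular expressions with a lookahead
(`(?=...)`) so overlapping occurrences are counted; U ≡ T. Per motif and
sequence group: f = fraction of sequences with ≥ 1 match; c̄ = mean match
count **over matching sequences** (the default; `count_mode="all"` averages
over all sequences); B = f · c̄. Ranking first filters at f strictly
greater than 0.70, then keeps the top 20 by B; ties break by higher f, then
by motif name. Differential binding reports the ratio of B between groups,
flagging group-exclusive motifs rather than dividing by zero.

## 4. Signatures

Per-gene Z-scores: Z = (x − mean_ref)/sd_ref with the sample SD (ddof = 1),
reference = a designated sample set (≥ 3 samples) or the whole cohort when
none is given. Zero-variance genes are excluded with a warning. A composite
signature score is the **sum** of member-gene Z-scores over detected genes —
the sum scale is what makes the ±7 fractionation cutoff of the 20-gene AR
activity signature meaningful. Fractionation uses inclusive comparisons
(≥ 7 / ≤ −7) by default. Median splits send ties to the low group; top/
bottom-k extreme selection breaks boundary ties by sample id for
determinism.

## 5. Survival

The Kaplan–Meier product-limit estimator and the two-group log-rank test
(hypergeometric variance, χ²(1) reference) are implemented directly so that
per-group observed/expected counts, a vectorizable cutoff scan and a
permutation p-value are all available; `lifelines` is used as an independent
cross-check in the tests, not as a dependency of the computation. Subjects
censored exactly at an event time are still at risk for that event time.
The permutation p uses the add-one estimator (hits+1)/(n+1) and therefore
never returns 0.

**Best cutoff.** Candidates are the unique score values within the 10th–90th
percentile; each splits the cohort at score > c; the cutoff with the lowest
log-rank p wins, ties resolved toward the smaller threshold. Minimal-p
selection inflates type-I error; the scan records this caveat and an
optional permutation adjustment re-runs the entire selection on
score-permuted cohorts. The direction label ("unfavorable" vs "favorable")
compares the two KM curves at the last follow-up time common to both groups.

## 6. SRG genomics and overlap statistics

Alteration calls are exclusive per patient and gene in {amp, del, mut,
none}; multi-track long tables are flattened with precedence
amp > del > mut. Cumulative frequency counts each patient once regardless of
how many set genes are altered. Co-occurrence uses the one-sided Fisher
exact test (upper hypergeometric tail, via `scipy.stats.fisher_exact`,
verified against exact rational enumeration for all 2×2 tables with
n ≤ 20). Set-overlap enrichment uses the Pearson χ² without Yates
correction by default (a flag enables it). The DEG caller is a plain
log2-fold-change + Welch-t + BH procedure on log2(count+1) matrices with a
linear-scale base-mean filter — deliberately not a negative-binomial
shrinkage model.

## 7. Synthetic-data generators

Generator defaults are the package's study conditions and are never tuned
to make validations pass.

- **Annotation.** Per gene one chromosome (`chr_G####`), 3–6 exons, 100-bp
  pads; intron bases drawn with P(G or C) = `gc_target` (default 0.45,
  an intron-like composition); canonical GT..AG boundaries on the sense
  strand (CT..AC genomic for minus strand).
- **Junction counts.** Per event, sample and replicate: total ~
  Poisson(depth) (default depth 100, 3 replicates/group), inclusion ~
  Binomial(total, ψ). The default event design plants 900 null events and
  100 with Δψ = 0.3 — large enough to measure sensitivity and an empirical
  false-discovery proportion.
- **Motif planting.** Occurrences are placed non-overlapping at random
  positions; the recorded truth is a **re-scan** of the edited sequence, so
  incidental background matches are covered. Backgrounds can be generated
  motif-free by rejection sampling.
- **Cohort.** Alterations: one call per gene and patient with
  p_amp = p_del = 0.05, p_mut = 0.02; amp/del shift log2 expression by
  ±effect_size (default 2.0). Survival: exponential baseline with log-hazard
  = `log_hazard_coef` × standardized signature score (default log 3, i.e. a
  hazard ratio of 3 per score SD); censoring times are Uniform(0, τ) with τ
  solved by bisection so the expected censored fraction matches the target
  (default 0.30) — the censoring probability E[(1−e^{−λτ})/(λτ)] is
  decreasing in τ, and the solver brackets accordingly. Gleason grades are
  drawn around 7 with an upward shift for amplified patients.

## 8. Validation strategy

Three layers, all seeded and reproducible:

1. **Unit oracles** — closed forms (PSI formula, BH brute force, exact
   Fisher enumeration, hand KM/log-rank tables, order-0 max-entropy product
   form, rank-sum enumeration) and independent implementations
   (statsmodels, lifelines, scipy) at tolerances 1e-10–1e-12.
2. **Property-based tests** (hypothesis) — e.g. ψ complement symmetry,
   monotonicity in I, GC invariance under reverse complement.
3. **Recovery tests** — planted truths re-estimated from generated data:
   PSI mean absolute error < 0.03 at depth 200; DSE sensitivity ≥ 0.85 and
   FDP ≤ 0.15 over 20 seeds; null calibration; hazard-ratio-3 cohorts
   rejecting at p < 0.01 in ≥ 90 % of 100 simulations with the
   "unfavorable" label in ≥ 95 %; null-hazard rejection near the nominal
   α; cumulative frequency matching 1 − (1 − p)^G.

`tests/test_acceptance.py` encodes these as assertions;
`scripts/acceptance.py` recomputes the same quantities at any seed.

## 9. Limitations

- The binomial LRT ignores biological overdispersion between replicates;
  on real data it would be anti-conservative relative to rMATS/SUPPA-class
  models. It is calibrated for the Poisson–binomial generator used here.
- Pooling replicates discards within-group variance information.
- The max-entropy fitter trains on the user's windows; it does not ship a
  pretrained human splice-site model, and order 1 captures only adjacent
  dependencies.
- The DEG caller is intentionally simple (no shrinkage, no normalization
  beyond log2(count+1)).
- The generators simulate independent events, independent alterations and
  exponential survival; they do not emulate read alignment, isoform
  deconvolution, linkage between events in a gene, or subclonal structure.
- Best-cutoff survival p-values are reported unadjusted by default (with a
  recorded caveat); the permutation adjustment is available but off.

## 10. Conventions

- Coordinates are 0-based half-open internally; GTF output converts to
  1-based inclusive.
- Δψ sign: group B minus group A; "up" means higher inclusion in B.
- All tie-breaks are deterministic (documented per function above).
- Every stochastic routine takes an explicit seed; derived seeds stay below
  2³¹.
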