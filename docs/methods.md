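# Methods

## Scope and model

`markerconcord` compares three measurement routes for ER, PR and Ki-67 in
breast-cancer biopsies — relative mRNA quantification (RT-qPCR, 40-ΔΔCq
scale), digital image analysis of IHC slides (qIHC, percent positive
nuclei) and visual IHC scoring (vIHC) — and evaluates the proliferation
readouts as predictors of pathological complete response (pCR, defined as
ypT0 ypN0). The statistical machinery is deterministic given its inputs;
the only stochastic component is the synthetic-cohort generator.

## Quantification (40-ΔΔCq)

Per sample and gene the triplicate median Cq is used; undetected wells are
excluded rather than imputed at the 40-cycle ceiling (imputation would bias
upward-censored genes), two detected replicates contribute their mean
(equal to their median), and a single replicate is kept but flagged.
Target genes are normalized against the unweighted mean of the B2M and
CALM2 medians, then against the same contrast on the run's calibrator
sample:

    40-ΔΔCq[g]_S = 40 − ((Cq[g]_S − meanCq[REF]_S) − (Cq[g]_PC − meanCq[REF]_PC))

Two exact algebraic properties follow and are enforced by tests: adding a
constant to every Cq of a sample leaves all values unchanged
(within-sample normalization), and a gene-specific offset applied to both
sample and calibrator wells of a run cancels (inter-run correction).
Lowering a target median by δ raises its value by exactly δ.

QC defaults — mean reference Cq ≤ 32 cycles, replicate spread ≤ 1 cycle,
≥ 2 detected replicates per panel gene — are this package's
operationalization of vendor acceptance criteria that are not public.
They are configurable, echoed into every report, and QC-invalid samples
carry a reason string instead of values.

## Agreement statistics

Binary agreement uses PPA/NPA/OPA on the 2×2 cross-classification with
complete-case pairing (dropped pairs are counted and logged); undefined
ratios (empty margin) are reported as missing rather than 0 or 100.
Continuous agreement uses the tie-corrected Spearman coefficient; its
two-sided p-value comes from the t approximation for n > 9 and from full
permutation enumeration for n ≤ 9. Fisher's exact test follows the
probability-mass two-sided convention (sum of margin-fixed tables whose
point probability does not exceed the observed one); 2×2 tables are
delegated to `scipy.stats.fisher_exact`, r×c tables use a hand-written
Freeman–Halton enumeration validated against R's `fisher.test`. A zero
row or column margin yields p = 1 by convention, flagged.

## ROC and the constrained cutoff

Candidate thresholds are the midpoints between consecutive distinct
observed values plus sentinels below the minimum and above the maximum;
a sample is test-positive when its value is at or above the threshold.
Midpoints make the derived cutoff classifier-stable: no observed value
sits on a boundary, and re-classifying at the returned cutoff reproduces
the reported sensitivity and specificity exactly. The operating point
fixes one axis at a required level (default: sensitivity at 100%, the
"detect all responders" prerequisite) and maximizes the other, breaking
ties toward the larger cutoff. Both axes are selectable because the two
natural conventions (fix sensitivity vs fix specificity) serve different
clinical aims; the default reflects the neoadjuvant use case of sparing
non-responders.

AUC is computed through the rank-sum identity (favorable responder/non-
responder pairs, ties counted half) and tested against 0.5 with the
tie-corrected normal approximation of the Mann-Whitney statistic, without
continuity correction; the standalone two-group Mann-Whitney test uses
the exact distribution for n₁+n₂ ≤ 16 without ties and otherwise the
tie- and continuity-corrected normal approximation. Degenerate all-tied
inputs return AUC 0.5 with p = 1.

For externally supplied cutoffs, dichotomization is inclusive
(value ≥ cutoff → high), so a responder sitting exactly at a published
cutoff is kept test-positive. Hormone-receptor mRNA positivity cutoffs
have no package default — no published value exists to anchor one — and
must be supplied; the demo pipeline configuration uses ESR1 33.5 and
PGR 30.0, the quantiles of the simulated mRNA marginals matching the
simulated hormone-negative fractions (~16–17%).

## Synthetic cohorts

Each marker has a trivariate Gaussian copula over the (mRNA, qIHC, vIHC)
latent scores. Target rank correlations are converted to the latent
Pearson scale by r = 2·sin(π·ρ_s/6) so the *empirical Spearman*
correlation converges to the configured target under the monotone marginal
transforms; the converted 3×3 matrix must be positive semi-definite, which
is validated at configuration time with a diagnostic naming the marker.
Defaults encode the study conditions this analysis is designed around:
n = 101 biopsies, assay-failure rate 18/101, pCR prevalence 12/83, and
inter-layer rank correlations 0.82/0.85/0.88 (ER), 0.86/0.88/0.90 (PR),
0.50/0.56/0.80 (Ki-67).

Marginals: the mRNA layer is linear on the 40-ΔΔCq scale (Ki-67:
mean 37.0, SD 1.5, matching a cohort median near 37; ER 36.0 ± 2.5 and
PR 33.0 ± 3.0 chosen as realistic hormone-receptor levels with adequate
headroom below the detection ceiling). Protein layers map the latent
score through a logistic curve into [0, 100]%, parametrized by the median
percent at z = 0 and a logit-scale spread; Ki-67 medians are 23.4%
(qIHC) and 35.0% (vIHC), and the steep hormone-receptor spreads (6 for
ER, 5 for PR) produce the near-bimodal percent distributions typical of
ER/PR staining, with ~16–17% of samples below the 1% positivity bar.
The Remmele score is intensity (0–3, sampled conditionally on the
percentage) times the percentage category (0; <10; 10–50; 51–80; >80 →
0–4), so the IRS identity holds by construction; Ki-67 carries no IRS.

The pCR outcome is Bernoulli with logit(p) = a + b·z, where z is the
Ki-67 mRNA-layer latent score (standard normal). The slope default
b = 1.2 makes the model-implied AUC of the mRNA readout 0.78 (computed by
numerical integration), the study condition for that assay; the intercept
is solved by Gauss–Hermite quadrature so the marginal prevalence equals
the configured value. Because the protein layers see proliferation only
through their 0.5/0.56 correlation with the mRNA layer, the protein
assays are, by design, weaker predictors — the qualitative contrast the
end-to-end test measures.

Cq plates are emitted in triplicate for all six genes plus a per-run
calibrator plate. Target-gene wells are constructed by inverting the
40-ΔΔCq formula around the sample's reference-gene draws, so
quantification recovers the generator's true expression exactly at zero
replicate noise; per-run gene offsets (SD 0.3 cycles) are applied
identically to sample and calibrator wells and therefore cancel.
Replicate noise defaults to 0.15 cycles. Constructed Cq values above the
40-cycle ceiling are emitted as undetected — very low expression is
upward-censored exactly as in a real plate, so exact round-trip
statements apply to the detectable range. Assay failure (insufficient
RNA) is sampled independently of biology and implemented as a +10-cycle
shift of the failed sample's reference genes, which the QC stage flags
as low RNA yield; this routes attrition through the same accounting as
real data.

Randomness derives from one master seed via fixed labeled sub-streams
(latent scores, outcome draws, failure flags, run offsets, replicate
noise, ...), so emitted tables are byte-identical across re-runs and
independent of call order.

### What the generator does and does not emulate

It reproduces the joint rank-correlation structure, marginal locations,
outcome link, triplicate noise, run effects, detection censoring and
assay failure. It does not model spatial tumor heterogeneity, hot-spot
scoring, inter-observer variability beyond the configured vIHC layer,
HER2-driven subtype structure, or any dependence of assay failure on
biology. Passing tests therefore demonstrate that the analysis machinery
is correct and that the pipeline's qualitative contrasts follow from the
configured structure — not that any particular clinical cohort would
reproduce them.

## Numerical choices and problem sizes

Exact-test oracles in the test suite enumerate all 2×2 tables with
n ≤ 30 (Fisher), all rank assignments for n₁+n₂ ≤ 10 (Mann-Whitney) and
all responder/non-responder pairs for n₁·n₂ ≤ 400 (AUC). Copula
fidelity (±0.04 on each pairwise Spearman), prevalence (3 binomial SE)
and outcome-link recovery (±15% on the slope, via a statsmodels logistic
fit on the latent score) are checked at n = 5000. The end-to-end
contrast uses 200 seeded replicates at the study scale n = 101. Ties in
the cutoff search are resolved toward the larger threshold; floating
comparisons in the search use a 1e-12 guard; the round-trip tolerance at
zero noise is 1e-9 cycles.

## Known limitations

- Hormone mRNA cutoffs must be user-supplied; concordance involving
  hormone mRNA status is skipped (and logged) without them.
- The Freeman–Halton enumeration is exponential in table size; it is
  intended for cohort-scale category counts (a few hundred tables), not
  large sparse tables.
- The Mann-Whitney "exact" route switches to the asymptotic
  approximation whenever ties are present, as is conventional.
- QC thresholds are package defaults, not vendor criteria.
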