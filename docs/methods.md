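# Methods

## Preprocessing

Abundance matrices are samples × proteins in arbitrary relative units with
per-sample class labels (`ascites`, `oc_plasma`, `n_plasma`). Plasma
samples diluted 1:2 during preparation are corrected by multiplying their
units by 2 **before** any threshold is computed, so that corrected units
are the analysis units throughout. The low-signal filter removes probes
that never *strictly* exceed a threshold in any sample; with
`threshold="auto"` the threshold is the median over all sample × probe
values of the (dilution-corrected) matrix. Whether that median should be
taken over ascites only or ascites + plasma is not settled; the package
computes it over whatever matrix it is given, so either convention is one
`subset_classes` call away. Missing values are a validation error: the
emulated assays report complete probe panels, and silent zero-imputation
would corrupt every quantile downstream.

Survivor classification at cutoff `c = 24` months: *short* iff the relapse
event was observed and RFS < c; *long* iff RFS ≥ c regardless of event
status; *indeterminate* iff censored before c. Indeterminate patients still
contribute to Kaplan–Meier and logrank computations (censoring handles
them) but are excluded from signature sensitivity/specificity accounting,
where their class is unknowable.

## Per-protein association

For each protein the patients are split at the empirical q-quantile of its
abundance for each q in the grid (default {0.3, 0.4, 0.5, 0.6, 0.7}, the
values observed in practice for this analysis style; configurable). "High"
means strictly greater than the threshold; ties go to the low group,
consistent with the strict `>` of the signal filter. The split minimizing
the two-group logrank p is reported together with its threshold, the
univariate Cox hazard ratio of high vs. low, and each group's KM median
RFS. Ties on the minimal p are broken toward the most balanced split
(q closest to 0.5), then the smaller q.

The best-fit p is the minimum of five highly dependent tests and is
therefore anti-conservative: on effect-free data the fixed median split
rejects at the nominal 5% while the scan rejects at ~15%. Following the
source analysis, p-values are reported nominal and uncorrected; the
inflation is *measured* (it is one of the quantities the acceptance script
reports) rather than corrected.

### Numerical implementation

The scan needs the logrank statistic for thousands of candidate group
labelings of one survival sample (5 quantiles × all probes × replicates ×
split-half repetitions), which rules out per-call statistics objects on one
CPU. `ascsig._stats.SurvivalScan` precomputes the risk-set structure once
and evaluates whole indicator matrices with cumulative sums and
`reduceat`; the single-binary-covariate Cox model is fitted by a vectorized
1-D Newton iteration on the partial likelihood with Breslow tie handling
(|log HR| capped at 15; beyond the cap the fit is flagged non-converged and
reported as an `inf`/`0.0` sentinel — complete separation). The KM median
is the smallest time where the product-limit curve reaches 0.5, `inf` when
never reached. All three are validated in the test suite against
lifelines — the standard survival stack for this analysis, and the
independent oracle here: logrank p agrees to 1e-10, Cox log-HR to 5e-3
(lifelines defaults to Efron ties; on untied data agreement is 1e-4), KM
medians exactly.

Differential abundance between sample classes is the two-sided
equal-variance t-test (scipy) with Benjamini–Hochberg adjustment
(statsmodels); fold change is the plain ratio of arithmetic means of
corrected units, `inf` when the denominator mean is zero. The 2-cluster
ascites utility is Ward agglomerative clustering (scikit-learn) on
log-transformed, per-protein standardized values; it exists to define the
groups fed into differential abundance, not as a clustering study.

## Split-half robustness

Each repetition bisects the patients uniformly at random into halves of
⌊n/2⌋ and ⌈n/2⌉; 25 repetitions yield 50 simulated cohorts. Markers are
dichotomized in each half at their **full-cohort** best-fit threshold: the
simulation probes the stability of an already-selected marker definition,
and refitting inside halves would change what is being tested
(`refit_per_half=True` is available for comparison). Halves where a
marker's dichotomization leaves a single group record p = 1 with a flag.
Two aggregation rules are both computed because both appear in the
analysis tradition this package reproduces: the class label follows the
"≥ 50% of repetitions significant in both halves with concordant HR
direction" rule; the "median p < α" criterion is reported as a separate
flag. HR direction per half is taken as the sign of the logrank
observed-minus-expected statistic, which matches the sign of the Cox
estimate and costs nothing extra.

## Signatures

A signature is an ordered protein list with one threshold and one risk
direction per protein. The indicator for a patient is 1 when the value
lies on the protein's poor-prognosis side: strictly above the threshold
for direction +1 (HR > 1), at-or-below for −1 (HR < 1). The score is the
indicator fraction; score > ½ predicts short RFS for both signature types.

**Scoring direction.** The verbatim description of this scoring in the
source tradition ("1 below the threshold") cannot be reconciled with its
own decision rule ("high score predicts short RFS") once adverse markers
(high level = risk) are in the signature. The package scores the risk side
and keeps the decision rule; `literal_below=True` implements the verbatim
below-threshold indicator for side-by-side comparison. No intent is
guessed: both modes exist, the risk-side mode is the default because it is
the only one under which the documented decision rule is coherent.

**Core search.** Exhaustive over all 3-subsets of the candidate pool
(default: the nominally significant proteins). The objective maximizes the
*sum* of the two class rates (balanced accuracy), ties toward the higher
target-class rate, then the smaller summed logrank p. A target-first
lexicographic core objective was tried and rejected: it is maximized by
conservative triples that simply never call the non-target class (100%
target rate, 0% other rate) and the greedy extension then climbs a
degenerate ridge. The balanced core plus target-first extension reproduces
the qualitative behavior expected of this analysis (an informative core
below 100% target, extensions that reach 100% target while improving the
other class).

**Greedy extension.** At each step the single candidate (step = 1) or
candidate pair (step = 2; the default, matching the pairwise additions
described for this analysis style) that maximizes the lexicographic
objective (target-class rate, other-class rate) is appended; extension
stops at `max_len` (default 9) or when no addition strictly improves the
class-rate pair. Members are never removed, so the objective is monotone
along the chain.

**Pool construction and pairing.** How the original analysis enumerated
its candidate signature pairs is not described ("random marker
combinations"); `build_signature_pool` therefore combines the
deterministic greedy chain (both step sizes, several target lengths) with
optional randomized cores discovered on random subsets of the candidate
pool. Every type-1 × type-2 pair is evaluated; pairs with zero false
predictions on the training cohort are retained and ranked by the fraction
of classifiable patients correctly predicted, ties toward the shorter
pair. Note that if both signatures reach 100% target-class rate on
training, zero training false calls follow automatically: every error
becomes a disagreement (abstention) or a within-half-score call.

**Combined predictor.** Consistency means both signatures make the same
short/long call; inconsistent patients are "prediction not possible". For
consistent patients the summed risk counts against the summed lengths
decide; an exact tie at half the maximum also abstains, since "above" and
"below" 50% are both strict in the decision rule and a tie satisfies
neither.

**Bootstrap.** Patients are resampled with replacement (same n, 500
resamples by default); the signatures are fixed — the procedure quantifies
sampling stability of a given pair, not selection optimism, which is why
the README points to held-out cohorts for honest error estimates. The 95%
interval is the 2.5/97.5 percentile interval; resamples with zero
classifiable patients are recorded as missing and excluded with a warning.

## Synthetic cohorts

`generate_cohort` draws per-protein log-baselines μ_p ~ N(abundance_log_mean,
protein_level_log_sd) and ascites log-abundances μ_p + ε with ε ~ N(0,
abundance_log_sd). A random block of `cluster_block_fraction` of the probes
is shifted up by `cluster_log_shift` in a `cluster_fraction` subset of
samples (the latent 2-cluster structure); plasma samples get a global
`plasma_log_shift`. Defaults mirror the emulated study: 70 ascites
patients, 20 + 10 plasma samples, 1,305 probes, baseline median RFS 18
months (relapse typically within two years), 30% censoring.

Planted survival effects act through threshold exceedance. Each planted
marker carries a latent binary trait: the marker's log-abundance sits in a
low or high mode separated by `planted_separation_sd` (default 5)
within-mode log-sds, and the true threshold is the inter-mode midpoint. In
the default `independent` mode each marker's trait is drawn separately
with the exceedance count fixed to round((1−q)·n); in `shared` mode one
latent binary risk factor drives all planted markers — adverse markers
exceed for risk-positive patients, favorable markers for risk-negative
ones, each flipped independently with `trait_flip_rate` — emulating the
two anti-correlated marker blocks (metastasis-linked vs. immune-linked)
that oppose each other in RFS direction in real ascites data. The bimodal
design makes exceedance a stable patient property: any threshold inside
the gap yields the same indicator, so threshold-estimation noise does not
leak into signature evaluation. A unimodal design was tried first and
rejected — empirical-quantile thresholds on unimodal markers mislabel a
few percent of patients per marker by pure sampling noise, which no
downstream method can undo.

The hazard multiplier is exp(Σ_j β·s_j) with β = `effect_log_hr` and
s_j = ±1 for exceedance/non-exceedance (sign flipped for favorable
markers); survival times are exponential around a baseline median, and
censoring is independent uniform administrative censoring whose upper
bound is solved by bisection so the *expected* censored fraction equals
`censoring_rate` given the realized hazards (exact, not post-hoc).
Note the high-vs-low contrast of one marker is exp(2β), and the marginal
association of one marker is attenuated by the "frailty" contributed by
the other planted markers — with many planted markers each marker alone
looks much weaker than its conditional effect.

`generate_cohort(cfg, patient_seed=...)` separates the study design
(protein baselines, planted identities, thresholds, cluster block — a
function of `cfg.seed`) from patient-level sampling, so held-out cohorts
share ground truth with a training cohort. All sub-generators run on
spawned seed sequences; identical inputs give bit-identical cohorts.

The second platform applies a per-protein strictly increasing affine map
on the log scale plus N(0, (rank_noise·σ_p)²) noise; rank_noise = 0 gives
per-marker Spearman ρ = 1, and `calibrate_rank_noise` bisects the noise to
hit a requested median ρ (Monte-Carlo, default tolerance 0.01). EV
fixtures inject a latent per-sample EV load into designated probes and
emit an MS-style (protein, LFQ) table with a configured panel overlap.

### What the generator does and does not emulate

It reproduces the *statistical geometry* the pipeline relies on:
log-normal-like abundances, dataset-wide-median filtering, threshold-acting
effects with censored exponential survival, anti-correlated marker blocks,
rank-noise between platforms. It does not emulate assay chemistry
(dilution-bin saturation, plate effects, probe cross-reactivity), epitope
effects, correlated censoring, non-proportional hazards, or real
protein-protein abundance correlation beyond the planted blocks. Passing
the recovery tests therefore shows the pipeline is implemented correctly
and is well-calibrated under its own assumptions — not that the published
signatures would validate in a new patient cohort.

## Validation scenarios (`ascsig.scenarios`)

* `recovery` — n = 300 patients, 200 probes, 10 + 10 planted at β = ln 3,
  30% censoring. Measured over 50 replicates: ≈ 95–96% of planted markers
  flagged at nominal p < 0.05 with the correct HR direction; the null-probe
  false-positive rate matches the empirically estimated grid-inflated null
  (~15%).
* `null` — n = 100, 2,000 effect-free probes: fixed median split rejects at
  5% ± 1.5 points; the best-fit scan's inflation (~15%) is reported.
* `robustness` — n = 300, 2 + 2 planted at β = ln 8: every planted marker
  classified robust with all 50 half-cohort p-values < 0.05; null markers
  essentially never robust.
* `end_to_end` — n = 80 + 80 held-out, 60 probes, 3 + 3 planted in `shared`
  mode at β = ln 4 with 1% trait flips: the discovered pair classifies
  ≥ 70% of held-out patients with zero false calls in ~90% of replicates.
  These problem sizes keep each scenario to seconds–tens of seconds while
  leaving the Monte-Carlo error well below the margins being asserted.

## Known limitations

* Cox ties use Breslow, not Efron; with heavily tied survival times HRs
  can differ from lifelines in the third decimal.
* The quantile-grid scan's selected q is noisy between adjacent grid
  points when a marker is strong at several quantiles; only the indicator
  behavior, not the label q itself, is guaranteed stable.
* Marker identifiers are matched by exact string; probe-to-assay aliasing
  across platforms is out of scope.
* The candidate pool for signature search is the nominally significant
  set; with very large panels this pool inherits the scan's
  anti-conservativeness, which is by design (it mirrors the emulated
  analysis) but means pool membership is itself noisy.
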