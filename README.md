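# ascsig

Prognostic threshold-indicator signatures from ascites affinity proteomics.

High-grade serous ovarian carcinoma (HGSC) sheds tumor and immune cells —
and their secreted and vesicle-encapsulated proteins — into the peritoneal
fluid (ascites). Relative protein abundances measured there by multiplexed
affinity assays (aptamer-based panels of ~1,300 probes, antibody-based
proximity-extension panels) carry prognostic information about relapse-free
survival (RFS) after first-line surgery, but no single protein separates
short-term from long-term relapse-free survivors. `ascsig` implements, as a
reusable and tested pipeline, the analysis strategy built around that
observation:

1. **Preprocessing** — undo the 1:2 plasma dilution (×2), drop probes that
   never exceed the dataset-wide median signal, and classify patients by the
   24-month RFS cutoff into *short* (relapse observed before 24 months),
   *long* (RFS ≥ 24 months, censored or not) and *indeterminate* (censored
   before 24 months).
2. **Per-protein association** — for each protein, scan a quantile grid
   *q* ∈ {0.3, 0.4, 0.5, 0.6, 0.7}, split patients at each quantile of the
   abundance distribution, and keep the *best-fit* split minimizing the
   logrank p. Each protein is reported with (q, p, HR, per-group median
   RFS), where HR is the univariate Cox hazard ratio of the high vs. low
   group (HR > 1: adverse; HR < 1: favorable).
3. **Split-half robustness** — repeatedly bisect the cohort at random
   (25 repetitions → 50 simulated cohorts), re-test each selected marker at
   its full-cohort threshold in both halves, and call a marker robust when
   at least half the repetitions are significant in both halves with a
   concordant HR direction.
4. **Signature discovery** — a *signature* is a set of proteins with
   per-protein thresholds and risk directions. A patient's score is the
   fraction of proteins on their poor-prognosis side; score > ½ predicts a
   short RFS. Type-1 signatures are tuned to identify all long-term
   survivors, type-2 all short-term survivors: an exhaustive scan finds a
   3-marker core, greedy forward selection (singly or in pairs) extends it
   up to 9 markers.
5. **Combined predictor with abstention** — a type-1/type-2 pair predicts
   per patient only when the two signatures agree; disagreement (or an
   exact tie of the combined score at half its maximum) is "prediction not
   possible". Pairs with zero false predictions are ranked by the fraction
   of patients correctly classified, and validated by bootstrap resampling
   of patients (500 resamples, signatures not re-trained).
6. **Cross-platform concordance** — per-marker Spearman ρ between two
   platforms on matched samples, plus extracellular-vesicle (EV) marker
   correlation and EV-proteome/panel intersection utilities.

Because the patient-level cohort behind the original analysis is not
public, the package ships a first-class synthetic-cohort generator
(`ascsig.synthetic_cohort`) that emulates the study's structure — log-normal
abundances over a ~1,300-probe panel, ~70 ascites + 30 plasma samples, two
latent ascites clusters, planted threshold-acting survival effects,
right-censoring, and a tunable-noise second-platform replicate — with full
ground truth for recovery testing.

## Worked example

Discover a signature pair on a synthetic training cohort with two strong
complementary marker blocks, then validate on freshly generated held-out
patients:

```python
import numpy as np
from ascsig import generate_cohort, associate_all
from ascsig.scenarios import end_to_end_scenario
from ascsig.signature_engine import (
    build_signature_pool, search_signature_pairs, combine_signatures,
    bootstrap_performance, evaluate_signature,
)

cfg = end_to_end_scenario(seed=2)
train, truth = generate_cohort(cfg)
held_out, _ = generate_cohort(cfg, patient_seed=1002)

assoc = associate_all(train)
print(f"{int(assoc.significant.sum())} of {len(assoc)} proteins at nominal logrank p < 0.05")
print(assoc.nsmallest(3, "p")[["q", "p", "hr", "direction"]])

pool1 = build_signature_pool(assoc, train, sig_type=1, n_random_cores=8, seed=2)
pool2 = build_signature_pool(assoc, train, sig_type=2, n_random_cores=8, seed=3)
pairs = search_signature_pairs(pool1, pool2, train)
sig1, sig2 = pairs[0]["sig1"], pairs[0]["sig2"]

perf1 = evaluate_signature(sig1, train)
print(f"type 1 signature {sig1.proteins}: "
      f"{perf1.sensitivity_target_class:.1f}% long-term / {perf1.rate_other_class:.1f}% short-term correct")
s = pairs[0]["summary"]
print(f"training: {s['n_correct']}/{s['n_classifiable']} correct, "
      f"{s['n_false']} false, {s['n_abstain']} abstained")

_, held = combine_signatures(sig1, sig2, held_out)
print(f"held-out: {held['n_correct']}/{held['n_classifiable']} correct, "
      f"{held['n_false']} false, {held['n_abstain']} abstained")

boot = bootstrap_performance(sig1, sig2, train, n_boot=500, seed=7)
print(f"bootstrap (500 resamples): median {100*boot.median_correct_fraction:.0f}% correct, "
      f"95% CI [{100*boot.ci_low:.0f}, {100*boot.ci_high:.0f}]%")
```

which prints:

```
12 of 60 proteins at nominal logrank p < 0.05
           q             p         hr  direction
protein
P0032    0.5  1.041443e-22        inf    adverse
P0037    0.5  1.041443e-22   0.000000  favorable
P0027    0.5  2.612538e-22  93.437011  adverse
type 1 signature ['P0027', 'P0032', 'P0037']: 100.0% long-term / 100.0% short-term correct
training: 80/80 correct, 0 false, 0 abstained
held-out: 80/80 correct, 0 false, 0 abstained
bootstrap (500 resamples): median 100% correct, 95% CI [100, 100]%
```

Reading the output: the association table lists each protein's best-fit
quantile `q`, nominal logrank `p` and hazard ratio `hr` (`inf`/`0.0` are
sentinels for complete separation, where the Cox fit diverges — here the
planted markers split survival perfectly). The discovered pair classifies
every held-out patient correctly with no abstentions; under noisier planted
structure the combined predictor abstains on patients where the two
signatures disagree rather than risking a false call. Signatures trained
and evaluated on the same cohort are optimistic — the bootstrap resamples
patients but does **not** re-train the signatures, so it quantifies
sampling stability, not selection bias; held-out cohorts are the honest
yardstick.

A command-line interface mirrors the library
(`ascsig simulate | preprocess | associate | diffabund | robustness |
discover | combine | bootstrap | concord | evcorr`); every command writes a
JSON provenance record beside its outputs.

## Limitations

The generator is a structural emulation, not a re-release of the original
cohort: probe identities, abundance scales and effect sizes are synthetic,
so the pipeline's published headline numbers on the real cohort are not
reproducible here — see `docs/methods.md` for exactly what the synthetic
scenarios do and do not establish.
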