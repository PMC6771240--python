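"""Signature scoring, discovery, combination with abstention, bootstrap."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ascsig import SyntheticConfig, associate_all, generate_cohort
from ascsig.core_data import SHORT, LONG
from ascsig.signature_engine import (
    SignatureDefinition,
    bootstrap_performance,
    build_signature_pool,
    combine_signatures,
    discover_core,
    evaluate_signature,
    extend_signature,
    score_signature,
    search_signature_pairs,
    signatures_from_association,
)


def _sig(n, sig_type=1, directions=None, thresholds=None):
    proteins = [f"P{i}" for i in range(n)]
    thr = thresholds or {p: 10.0 for p in proteins}
    dirs = directions or {p: +1 for p in proteins}
    return SignatureDefinition(sig_type, proteins, thr, dirs)


class TestScoreSignature:
    def test_seven_of_nine_predicts_short(self):
        sig = _sig(9)
        values = {f"P{i}": (20.0 if i < 7 else 5.0) for i in range(9)}
        score = score_signature(sig, values, patient_id="X")
        assert score.risk_count == 7
        assert score.fraction == pytest.approx(7 / 9)
        assert score.predicts_short

    def test_zero_indicators(self):
        sig = _sig(4)
        score = score_signature(sig, {f"P{i}": 1.0 for i in range(4)})
        assert score.fraction == 0.0 and not score.predicts_short

    def test_two_of_three_predicts_short(self):
        sig = _sig(3)
        values = {"P0": 20.0, "P1": 20.0, "P2": 1.0}
        assert score_signature(sig, values).predicts_short

    def test_value_at_threshold_is_low_side(self):
        sig = _sig(1)
        assert score_signature(sig, {"P0": 10.0}).risk_count == 0

    def test_favorable_direction_scores_low_side(self):
        sig = _sig(2, directions={"P0": -1, "P1": -1})
        score = score_signature(sig, {"P0": 5.0, "P1": 10.0})
        assert score.risk_count == 2  # at-or-below threshold counts for -1

    def test_literal_below_mode(self):
        sig = _sig(2, directions={"P0": +1, "P1": -1})
        score = score_signature(
            sig, {"P0": 5.0, "P1": 5.0}, literal_below=True
        )
        assert score.risk_count == 2  # both strictly below the threshold

    def test_missing_protein_named(self):
        sig = _sig(2)
        with pytest.raises(KeyError, match="P1"):
            score_signature(sig, {"P0": 5.0})


def _tiny_cohort(seed=13, **kw):
    base = dict(
        n_patients=70,
        n_proteins=25,
        n_adverse=3,
        n_favorable=3,
        effect_log_hr=np.log(4),
        planted_trait_mode="shared",
        trait_flip_rate=0.02,
        n_oc_plasma=0,
        n_n_plasma=0,
        seed=seed,
    )
    base.update(kw)
    cohort, truth = generate_cohort(SyntheticConfig(**base))
    return cohort, truth, associate_all(cohort)


def _brute_force_core(association, cohort, sig_type, core_size=3, candidates=None):
    """Independent plain-python enumeration of the core search."""
    if candidates is None:
        candidates = list(association.index[association["significant"]])
    thresholds, directions = signatures_from_association(association)
    pv = cohort.patient_values()
    classes = cohort.clinical.survivor_class.reindex(pv.index)
    keep = classes.isin([SHORT, LONG])
    pv, classes = pv[keep.to_numpy()], classes[keep.to_numpy()]
    target = LONG if sig_type == 1 else SHORT
    best = None
    best_combo = None
    for combo in combinations(candidates, core_size):
        n_t_ok = n_o_ok = n_t = n_o = 0
        for pid in pv.index:
            count = 0
            for p in combo:
                v = pv.loc[pid, p]
                hit = v > thresholds[p] if directions[p] == 1 else v <= thresholds[p]
                count += hit
            predicts_short = count / core_size > 0.5
            if classes[pid] == target:
                n_t += 1
                n_t_ok += (predicts_short == (target == SHORT))
            else:
                n_o += 1
                n_o_ok += (predicts_short != (target == SHORT))
        r_t, r_o = n_t_ok / n_t, n_o_ok / n_o
        sum_p = sum(association.loc[p, "p"] for p in combo)
        key = (r_t + r_o, r_t, -sum_p)
        if best is None or key > best:
            best, best_combo = key, combo
    return list(best_combo)


class TestDiscoverCore:
    def test_matches_brute_force_enumeration(self):
        for seed in (13, 14, 15):
            cohort, _, assoc = _tiny_cohort(seed=seed)
            cands = list(assoc.index[assoc["significant"]])[:10]
            if len(cands) < 3:
                continue
            for sig_type in (1, 2):
                core = discover_core(assoc, cohort, sig_type, candidates=cands)
                oracle = _brute_force_core(assoc, cohort, sig_type, candidates=cands)
                assert core.proteins == oracle

    def test_single_perfect_marker_always_included(self):
        cohort, truth, assoc = _tiny_cohort(seed=16, trait_flip_rate=0.0)
        # a planted marker with zero flip noise classifies almost perfectly
        planted = truth.adverse_ids[0]
        nulls = [p for p in assoc.index if p not in truth.adverse_ids + truth.favorable_ids]
        core = discover_core(assoc, cohort, 2, candidates=[planted] + nulls[:9])
        assert planted in core.proteins

    def test_pool_too_small_rejected(self, small_cohort, small_association):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="core_size"):
            discover_core(small_association, cohort, 1, candidates=["nope"])


class TestExtendSignature:
    def test_monotone_objective_and_stop_rule(self):
        cohort, truth, assoc = _tiny_cohort(seed=17)
        core = discover_core(assoc, cohort, 1)
        ext = extend_signature(core, assoc, cohort, max_len=9, step=2)
        assert set(core.proteins) <= set(ext.proteins)
        assert len(ext) <= 9
        perf_core = evaluate_signature(core, cohort)
        perf_ext = evaluate_signature(ext, cohort)
        assert (
            perf_ext.sensitivity_target_class,
            perf_ext.rate_other_class,
        ) >= (perf_core.sensitivity_target_class, perf_core.rate_other_class)

    def test_pure_noise_candidates_leave_core_unchanged(self):
        cohort, truth, assoc = _tiny_cohort(seed=18, trait_flip_rate=0.0)
        planted = truth.adverse_ids + truth.favorable_ids
        core = discover_core(assoc, cohort, 1, candidates=planted)
        perf = evaluate_signature(core, cohort)
        if perf.sensitivity_target_class < 100 or perf.rate_other_class < 100:
            pytest.skip("core not already optimal in this draw")
        nulls = [p for p in assoc.index if p not in planted][:6]
        ext = extend_signature(core, assoc, cohort, max_len=9, candidates=nulls)
        assert ext.proteins == core.proteins


class TestEvaluateSignature:
    def test_constant_short_classifier(self, small_cohort):
        cohort, _ = small_cohort
        p = cohort.abundance.protein_ids[0]
        sig = SignatureDefinition(2, [p], {p: 0.0}, {p: +1})  # everything > 0
        perf = evaluate_signature(sig, cohort)
        assert perf.sensitivity_target_class == 100.0
        assert perf.rate_other_class == 0.0

    def test_constructed_perfect_signature(self):
        cohort, truth, assoc = _tiny_cohort(seed=19, trait_flip_rate=0.0)
        planted = truth.adverse_ids + truth.favorable_ids
        thr = {p: truth.true_thresholds[p] for p in planted}
        dirs = {p: +1 for p in truth.adverse_ids}
        dirs.update({p: -1 for p in truth.favorable_ids})
        sig = SignatureDefinition(1, planted, thr, dirs)
        perf = evaluate_signature(sig, cohort)
        assert perf.sensitivity_target_class >= 95.0
        assert perf.rate_other_class >= 95.0


class TestCombineSignatures:
    def _cohort_and_sigs(self):
        cohort, truth, assoc = _tiny_cohort(seed=20)
        thresholds, directions = signatures_from_association(assoc)
        planted = truth.adverse_ids + truth.favorable_ids
        s1 = SignatureDefinition(
            1, planted, {p: thresholds[p] for p in planted},
            {p: directions[p] for p in planted},
        )
        s2 = SignatureDefinition(
            2, planted, {p: thresholds[p] for p in planted},
            {p: directions[p] for p in planted},
        )
        return cohort, s1, s2

    def test_counts_partition_classifiable_patients(self):
        cohort, s1, s2 = self._cohort_and_sigs()
        _, summary = combine_signatures(s1, s2, cohort)
        assert (
            summary["n_correct"] + summary["n_false"] + summary["n_abstain"]
            == summary["n_classifiable"]
        )

    def test_disagreement_abstains(self):
        # sig1 says short (1/1 above), sig2 says long (0/1 above)
        values = pd.DataFrame({"A": [20.0], "B": [1.0]}, index=["S1"])
        cohort = _manual_cohort(values, rfs=[10.0], event=[True])
        s1 = SignatureDefinition(1, ["A"], {"A": 10.0}, {"A": +1})
        s2 = SignatureDefinition(2, ["B"], {"B": 10.0}, {"B": +1})
        preds, _ = combine_signatures(s1, s2, cohort)
        assert preds[0].prediction == "not_possible" and not preds[0].consistent

    def test_majority_combined_score_predicts_short(self):
        # 9+9 proteins, 14 of 18 indicators set -> 14 > 9 -> short
        values = pd.DataFrame(
            [[20.0] * 14 + [1.0] * 4], index=["S1"],
            columns=[f"P{i}" for i in range(18)],
        )
        cohort = _manual_cohort(values, rfs=[10.0], event=[True])
        s1 = _sig(9)
        s1 = SignatureDefinition(
            1, [f"P{i}" for i in range(9)],
            {f"P{i}": 10.0 for i in range(9)}, {f"P{i}": +1 for i in range(9)},
        )
        s2 = SignatureDefinition(
            2, [f"P{i}" for i in range(9, 18)],
            {f"P{i}": 10.0 for i in range(9, 18)}, {f"P{i}": +1 for i in range(9, 18)},
        )
        preds, summary = combine_signatures(s1, s2, cohort)
        assert preds[0].combined_score == 14
        assert preds[0].prediction == SHORT
        assert summary["n_correct"] == 1

    def test_exact_tie_abstains(self):
        # two length-4 signatures, 2 indicators each: both call "long"
        # (2/4 is not > 0.5) yet the combined score 4 is exactly half the
        # maximum of 8 -> the tie rule abstains
        values = pd.DataFrame(
            [[20.0, 20.0, 1.0, 1.0] * 2], index=["S1"],
            columns=[f"P{i}" for i in range(8)],
        )
        cohort = _manual_cohort(values, rfs=[10.0], event=[True])
        s1 = SignatureDefinition(
            1, [f"P{i}" for i in range(4)],
            {f"P{i}": 10.0 for i in range(4)}, {f"P{i}": +1 for i in range(4)},
        )
        s2 = SignatureDefinition(
            2, [f"P{i}" for i in range(4, 8)],
            {f"P{i}": 10.0 for i in range(4, 8)}, {f"P{i}": +1 for i in range(4, 8)},
        )
        preds, _ = combine_signatures(s1, s2, cohort)
        assert preds[0].consistent
        assert preds[0].combined_score == 4 and preds[0].max_score == 8
        assert preds[0].prediction == "not_possible"


class TestPairSearchAndBootstrap:
    def test_every_returned_pair_has_zero_false(self):
        cohort, truth, assoc = _tiny_cohort(seed=22)
        p1 = build_signature_pool(assoc, cohort, 1, n_random_cores=3, seed=1)
        p2 = build_signature_pool(assoc, cohort, 2, n_random_cores=3, seed=2)
        pairs = search_signature_pairs(p1, p2, cohort)
        assert pairs, "expected at least one zero-false pair"
        for pair in pairs:
            _, summary = combine_signatures(pair["sig1"], pair["sig2"], cohort)
            assert summary["n_false"] == 0
        fracs = [p["summary"]["correct_fraction"] for p in pairs]
        assert fracs == sorted(fracs, reverse=True)

    def test_bootstrap_counts_and_determinism(self):
        cohort, truth, assoc = _tiny_cohort(seed=23)
        p1 = build_signature_pool(assoc, cohort, 1)
        p2 = build_signature_pool(assoc, cohort, 2)
        pairs = search_signature_pairs(p1, p2, cohort)
        s1, s2 = pairs[0]["sig1"], pairs[0]["sig2"]
        a = bootstrap_performance(s1, s2, cohort, n_boot=200, seed=5)
        b = bootstrap_performance(s1, s2, cohort, n_boot=200, seed=5)
        assert len(a.values) == 200
        assert a.median_correct_fraction == b.median_correct_fraction
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.median_correct_fraction <= a.ci_high

    def test_bootstrap_degenerate_all_correct(self):
        values = pd.DataFrame(
            [[20.0, 20.0], [1.0, 1.0]], index=["S1", "S2"], columns=["A", "B"]
        )
        cohort = _manual_cohort(values, rfs=[5.0, 40.0], event=[True, True])
        s1 = SignatureDefinition(1, ["A"], {"A": 10.0}, {"A": +1})
        s2 = SignatureDefinition(2, ["B"], {"B": 10.0}, {"B": +1})
        res = bootstrap_performance(s1, s2, cohort, n_boot=100, seed=1)
        assert res.median_correct_fraction == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)


def _manual_cohort(values, rfs, event):
    from ascsig.core_data import (
        AbundanceMatrix,
        ClinicalTable,
        CohortDataset,
    )

    classes = pd.Series("ascites", index=values.index)
    patients = [f"PT_{s}" for s in values.index]
    clinical = ClinicalTable(
        pd.DataFrame(
            {"rfs_months": rfs, "event": event},
            index=pd.Index(patients, name="patient_id"),
        )
    )
    return CohortDataset(
        AbundanceMatrix(values, classes),
        clinical,
        dict(zip(values.index, patients)),
    )


class TestSignatureDefinition:
    def test_json_round_trip(self):
        sig = _sig(3, sig_type=2, directions={"P0": +1, "P1": -1, "P2": +1})
        back = SignatureDefinition.from_json(sig.to_json())
        assert back.proteins == sig.proteins
        assert back.risk_direction == sig.risk_direction
        assert back.sig_type == 2

    def test_duplicate_proteins_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SignatureDefinition(1, ["A", "A"], {"A": 1.0}, {"A": 1})
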