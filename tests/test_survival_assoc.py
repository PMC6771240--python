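"""Best-fit dichotomization, trichotomization, differential abundance and
the 2-cluster utility."""

import numpy as np
import pandas as pd
import pytest

from ascsig import SyntheticConfig, generate_cohort
from ascsig._stats import SurvivalScan
from ascsig.core_data import AbundanceMatrix
from ascsig.survival_assoc import (
    DEFAULT_QUANTILE_GRID,
    associate_all,
    best_fit_dichotomize,
    cluster_ascites,
    differential_abundance,
    trichotomize,
)


class TestBestFitDichotomize:
    def test_perfect_separator_picks_median_split(self):
        # all short-RFS patients above the median, all long below
        rng = np.random.default_rng(0)
        n = 40
        values = np.r_[rng.uniform(10, 20, 20), rng.uniform(100, 200, 20)]
        times = np.r_[rng.uniform(40, 80, 20), rng.uniform(1, 10, 20)]
        events = np.ones(n, bool)
        res = best_fit_dichotomize(values, times, events)
        assert res.best_quantile == 0.5
        assert res.hr > 1
        # returned p is the exhaustive-scan minimum over the grid
        scan = SurvivalScan(times, events)
        ps = []
        for q in DEFAULT_QUANTILE_GRID:
            thr = np.quantile(values, q)
            ps.append(scan.logrank(values > thr)[0])
        assert res.logrank_p == pytest.approx(min(ps))

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            best_fit_dichotomize(
                np.full(10, 3.0), np.arange(1.0, 11.0), np.ones(10, bool)
            )

    def test_null_scan_is_anticonservative(self):
        # min over 5 dependent tests rejects more often than 5%
        rng = np.random.default_rng(1)
        n_rej = 0
        reps = 400
        times = rng.exponential(20, 60)
        events = np.ones(60, bool)
        scan = SurvivalScan(times, events)
        for _ in range(reps):
            v = rng.normal(size=60)
            ps = [
                scan.logrank(v > np.quantile(v, q))[0] for q in DEFAULT_QUANTILE_GRID
            ]
            n_rej += min(ps) < 0.05
        assert n_rej / reps > 0.08

    def test_hr_direction_agrees_with_median_rfs_ordering(self, small_cohort):
        cohort, _ = small_cohort
        table = associate_all(cohort)
        both = table[
            np.isfinite(table["median_rfs_high"]) & np.isfinite(table["median_rfs_low"])
        ]
        strong = both[(both["hr"] > 1.5) | (both["hr"] < 1 / 1.5)]
        adverse = strong[strong["hr"] > 1]
        favorable = strong[strong["hr"] < 1]
        assert (adverse["median_rfs_high"] <= adverse["median_rfs_low"]).all()
        assert (favorable["median_rfs_high"] >= favorable["median_rfs_low"]).all()


class TestAssociateAll:
    def test_one_row_per_protein_with_flags(self, small_cohort, small_association):
        cohort, _ = small_cohort
        table = small_association
        assert len(table) == cohort.abundance.shape[1]
        assert set(table["direction"]) <= {"adverse", "favorable"}
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()
        assert (table["q"].isin(DEFAULT_QUANTILE_GRID)).all()

    def test_planted_markers_flagged_with_direction(self, small_cohort, small_association):
        _, truth = small_cohort
        table = small_association
        planted = truth.adverse_ids + truth.favorable_ids
        sub = table.loc[planted]
        want = ["adverse"] * len(truth.adverse_ids) + ["favorable"] * len(
            truth.favorable_ids
        )
        good = (sub["significant"] & (sub["direction"].to_numpy() == np.array(want))).sum()
        assert good >= len(planted) - 1

    def test_constant_protein_skipped_with_warning(self, small_cohort):
        cohort, _ = small_cohort
        values = cohort.abundance.values.copy()
        values["FLAT"] = 100.0
        m = AbundanceMatrix(values, cohort.abundance.sample_class)
        from ascsig.core_data import CohortDataset

        c2 = CohortDataset(m, cohort.clinical, dict(cohort.sample_to_patient))
        with pytest.warns(UserWarning, match="constant"):
            table = associate_all(c2)
        assert "FLAT" not in table.index


class TestTrichotomize:
    def test_partition_and_membership(self, small_cohort, small_association):
        cohort, _ = small_cohort
        top3 = list(small_association.nsmallest(3, "p").index)
        thr = small_association.loc[top3, "threshold"].to_dict()
        res = trichotomize(cohort, top3, thr)
        sizes = res["sizes"]
        assert sum(sizes.values()) == len(cohort.patient_values())
        pv = cohort.patient_values()
        for pid in res["groups"]["all_high"]:
            assert all(pv.loc[pid, p] > thr[p] for p in top3)
        for pid in res["groups"]["all_low"]:
            assert all(pv.loc[pid, p] <= thr[p] for p in top3)

    def test_requires_three_thresholds(self, small_cohort, small_association):
        cohort, _ = small_cohort
        top3 = list(small_association.nsmallest(3, "p").index)
        with pytest.raises(ValueError, match="no threshold"):
            trichotomize(cohort, top3, {top3[0]: 1.0})


class TestDifferentialAbundance:
    def _two_group_matrix(self, ratio, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(100, 1000, 6)
        a = base * ratio * (1 + noise * rng.standard_normal((8, 6)))
        b = base * (1 + noise * rng.standard_normal((8, 6)))
        values = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"S{i}" for i in range(16)],
            columns=[f"P{i}" for i in range(6)],
        )
        classes = pd.Series(["ascites"] * 8 + ["oc_plasma"] * 8, index=values.index)
        return AbundanceMatrix(values, classes)

    def test_sixfold_ratio_retained_at_fc5(self):
        m = self._two_group_matrix(6.0)
        table = differential_abundance(m, "ascites", "oc_plasma", fc_min=5)
        assert len(table) == 6
        np.testing.assert_allclose(table["fold_change"], 6.0, rtol=0.05)

    def test_fc_just_below_cutoff_excluded(self):
        m = self._two_group_matrix(4.9, noise=0.001)
        table = differential_abundance(m, "ascites", "oc_plasma", fc_min=5)
        assert len(table) == 0  # significant but FC <= 5 (strict filter)

    def test_adjusted_p_at_least_raw(self, mixed_matrix):
        table = differential_abundance(
            mixed_matrix, "ascites", "oc_plasma", fc_min=0, filter=False
        )
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()

    def test_bh_step_up_formula(self):
        # classic worked example: all four adjusted to 0.04
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(adj, 0.04)


class TestClusterAscites:
    def test_planted_blocks_recovered(self):
        cfg = SyntheticConfig(
            n_patients=60,
            n_proteins=100,
            n_adverse=0,
            n_favorable=0,
            cluster_log_shift=3.0,
            cluster_block_fraction=0.2,
            n_oc_plasma=0,
            n_n_plasma=0,
            seed=3,
        )
        cohort, truth = generate_cohort(cfg)
        labels = cluster_ascites(cohort.abundance, k=2)
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(
            truth.cluster_labels.values, labels.reindex(truth.cluster_labels.index)
        )
        assert ari >= 0.95

    def test_k_one_single_label(self, mixed_matrix):
        labels = cluster_ascites(mixed_matrix, k=1)
        assert labels.nunique() == 1

    def test_duplicated_samples_cluster_together(self):
        rng = np.random.default_rng(2)
        row = rng.uniform(10, 100, 8)
        other = rng.uniform(1000, 5000, 8)
        values = pd.DataFrame(
            [row, row, other, other],
            index=["A1", "A2", "B1", "B2"],
            columns=[f"P{i}" for i in range(8)],
        )
        m = AbundanceMatrix(values, pd.Series("ascites", index=values.index))
        labels = cluster_ascites(m, k=2)
        assert labels["A1"] == labels["A2"] and labels["B1"] == labels["B2"]

    def test_k_exceeding_samples_rejected(self, mixed_matrix):
        with pytest.raises(ValueError):
            cluster_ascites(mixed_matrix, k=10)
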