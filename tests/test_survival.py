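import numpy as np
import pandas as pd
import pytest

from switchnet import (
    ClinicalTable,
    generate_modular_expression,
    generate_paired_tumor_normal,
    generate_survival,
    km_estimate,
    logrank_test,
    rank_switch_genes_by_survival,
    stratify_by_expression,
)
from conftest import make_expression
from oracles import logrank_chi2, permutation_logrank_p


def clinical_from(times, events, patients=None):
    patients = patients or [f"p{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {"time_days": times, "event": events},
            index=pd.Index(patients, name="patient_id"),
        )
    )


def tumor_em(expr_by_patient):
    """One tumor sample per patient with the given expression of gene 'g'."""
    patients = list(expr_by_patient)
    return make_expression(
        np.array([[expr_by_patient[p] for p in patients]]),
        genes=["g"],
        samples=[f"{p}_T" for p in patients],
        conditions=["tumor"] * len(patients),
        patients=patients,
    )


class TestStratify:
    def test_quartile_counts_with_distinct_values(self):
        em = tumor_em({f"p{i}": float(i + 1) for i in range(8)})
        clin = clinical_from([100] * 8, [True] * 8)
        low, high = stratify_by_expression(em, clin, "g")
        assert len(low) == 2 and len(high) == 2
        assert set(low["patient_id"]) == {"p0", "p1"}
        assert set(high["patient_id"]) == {"p6", "p7"}

    def test_constant_expression_skipped(self):
        em = tumor_em({f"p{i}": 3.0 for i in range(6)})
        clin = clinical_from([50] * 6, [True] * 6)
        with pytest.warns(UserWarning, match="empty"):
            assert stratify_by_expression(em, clin, "g") is None

    def test_ties_at_quartile_are_excluded(self):
        # values [1,2,2,2,5,6,7,8]: Q1 = 2, so the tied patients fall in the
        # excluded middle and only the value-1 patient is 'low'
        em = tumor_em(dict(zip([f"p{i}" for i in range(8)], [1, 2, 2, 2, 5, 6, 7, 8])))
        clin = clinical_from([30] * 8, [True] * 8)
        low, high = stratify_by_expression(em, clin, "g")
        assert set(low["patient_id"]) == {"p0"}
        assert not {"p1", "p2", "p3"} & set(low["patient_id"])

    def test_unknown_gene(self):
        em = tumor_em({"p0": 1.0, "p1": 2.0})
        with pytest.raises(KeyError):
            stratify_by_expression(em, clinical_from([1, 2], [1, 1]), "nope")


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(
            pd.DataFrame({"time_days": [5, 8, 9], "event": [False] * 3})
        )
        assert np.allclose(curve.survival, 1.0)

    def test_two_events_stepwise(self):
        curve = km_estimate(pd.DataFrame({"time_days": [1, 2], "event": [True, True]}))
        steps = dict(zip(curve.times, curve.survival))
        assert steps[1.0] == pytest.approx(0.5)
        assert steps[2.0] == pytest.approx(0.0)

    def test_mixed_censoring_matches_hand_product_limit(self):
        # times (1E, 2C, 3E, 4E, 4C, 6E): hand product-limit values
        cohort = pd.DataFrame(
            {"time_days": [1, 2, 3, 4, 4, 6], "event": [1, 0, 1, 1, 0, 1]}
        )
        curve = km_estimate(cohort)
        steps = dict(zip(curve.times, curve.survival))
        assert steps[1.0] == pytest.approx(5 / 6)
        assert steps[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert steps[4.0] == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert steps[6.0] == pytest.approx(0.0)

    def test_pooled_event_count_equals_group_sum(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(100, 30).round(1)
        events = rng.random(30) < 0.7
        groups = rng.random(30) < 0.5
        pooled = events.sum()
        assert events[groups].sum() + events[~groups].sum() == pooled


class TestLogrank:
    def test_identical_cohorts_give_null_result(self):
        a = pd.DataFrame({"time_days": [1, 2, 3, 4], "event": [1, 1, 0, 1]})
        chi2, p = logrank_test(a, a.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame({"time_days": rng.exponential(50, 15), "event": rng.random(15) < 0.8})
        b = pd.DataFrame({"time_days": rng.exponential(90, 15), "event": rng.random(15) < 0.8})
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_zero_events_warns_p_one(self):
        a = pd.DataFrame({"time_days": [1, 2], "event": [False, False]})
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test(a, a.copy())
        assert (chi2, p) == (0.0, 1.0)

    def test_separated_cohorts_significant(self):
        early = pd.DataFrame({"time_days": np.arange(1, 21), "event": [True] * 20})
        late = pd.DataFrame({"time_days": np.arange(100, 120), "event": [True] * 20})
        _, p = logrank_test(early, late)
        assert p < 0.05

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(11)
        times = np.concatenate([rng.exponential(60, 20), rng.exponential(120, 20)])
        events = rng.random(40) < 0.75
        a_mask = np.arange(40) < 20
        a = pd.DataFrame({"time_days": times[a_mask], "event": events[a_mask]})
        b = pd.DataFrame({"time_days": times[~a_mask], "event": events[~a_mask]})
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(logrank_chi2(times, events, a_mask), rel=1e-9)
        p_perm = permutation_logrank_p(times, events, a_mask, n_perm=2000, seed=5)
        assert abs(p - p_perm) < 0.05


class TestRanking:
    @pytest.fixture(scope="class")
    def survival_setup(self):
        em, truth = generate_modular_expression(
            n_modules=3, genes_per_module=10, n_samples=60, n_switch=3, seed=21
        )
        paired = generate_paired_tumor_normal(em, truth.switch_genes, seed=22)
        clin = generate_survival(paired, "SW01", beta=2.0, seed=23)
        return paired, clin, truth

    def test_single_gene_single_row(self, survival_setup):
        paired, clin, _ = survival_setup
        table, skipped = rank_switch_genes_by_survival(paired, clin, ["SW01"])
        assert len(table) == 1 and not skipped

    def test_driver_outranks_null_genes(self, survival_setup):
        paired, clin, truth = survival_setup
        null_genes = [g for g in paired.gene_ids if g.startswith("M1")][:9]
        table, _ = rank_switch_genes_by_survival(paired, clin, ["SW01"] + null_genes)
        assert table.iloc[0]["gene"] == "SW01"

    def test_rerun_identical(self, survival_setup):
        paired, clin, truth = survival_setup
        t1, _ = rank_switch_genes_by_survival(paired, clin, truth.switch_genes)
        t2, _ = rank_switch_genes_by_survival(paired, clin, truth.switch_genes)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_gene_list_raises(self, survival_setup):
        paired, clin, _ = survival_setup
        with pytest.raises(ValueError, match="empty"):
            rank_switch_genes_by_survival(paired, clin, [])
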