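import numpy as np
import pandas as pd
import pytest

from methet import (
    CohortSpec,
    burden,
    burden_score,
    call_probes,
    cancer_pattern,
    classify_epimut,
    em_fit_1d,
    four_categories,
    km_curve,
    logrank,
    low_epimut_purity_exclusion,
    normal_reference,
    recurrence_filter,
    synth_cohort,
    synth_survival,
)
from methet.purity_window import PurityWindow


class TestEmFit1d:
    def test_separated_clusters_split_at_gap(self):
        fit = em_fit_1d([0, 0, 0, 100, 100, 100])
        assert fit.labels.tolist() == ["low"] * 3 + ["high"] * 3
        assert fit.means[0] == pytest.approx(np.log10(1), abs=1e-6)
        assert fit.means[1] == pytest.approx(np.log10(101), abs=1e-6)

    def test_identical_values_degenerate(self):
        fit = em_fit_1d([5, 5, 5, 5])
        assert fit.degenerate and not fit.converged
        assert fit.labels.nunique() == 1

    def test_mixture_parameter_recovery(self):
        r = np.random.default_rng(42)
        x = np.concatenate([r.normal(0, 1, 100), r.normal(5, 1, 100)])
        truth = np.array(["low"] * 100 + ["high"] * 100)
        fit = em_fit_1d(x, transform=None)
        assert fit.means[0] == pytest.approx(0, abs=0.3)
        assert fit.means[1] == pytest.approx(5, abs=0.3)
        assert (fit.labels.to_numpy() == truth).mean() > 0.95

    def test_loglik_trace_monotone(self):
        r = np.random.default_rng(1)
        fit = em_fit_1d(r.exponential(50, 200))
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-8 * np.maximum(1, np.abs(trace[:-1]))).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            em_fit_1d([1, 2, 3])


class TestFourCategories:
    def fit_for(self, values):
        return em_fit_1d(pd.Series(values, index=list("abcd")))

    @pytest.mark.parametrize(
        "hyper, hypo, expected",
        [
            ("high", "low", "hyper"),
            ("low", "high", "hypo"),
            ("high", "high", "intermediate"),
            ("low", "low", "control"),
        ],
    )
    def test_mapping(self, hyper, hypo, expected):
        from methet.stratify import FOUR_CATEGORY

        assert FOUR_CATEGORY[(hyper, hypo)] == expected

    def test_partition_and_index_alignment(self):
        em_a = self.fit_for([0, 0, 500, 500])
        em_b = self.fit_for([0, 400, 0, 400])
        cats = four_categories(em_a, em_b)
        assert len(cats) == 4
        assert cats.tolist() == ["control", "hypo", "hyper", "intermediate"]

    def test_sample_mismatch_rejected(self):
        em_a = self.fit_for([0, 0, 500, 500])
        em_b = em_fit_1d(pd.Series([0, 400, 0, 400], index=list("wxyz")))
        with pytest.raises(ValueError):
            four_categories(em_a, em_b)


class TestClassifyEpimut:
    def test_rank_frac_counts_and_tiebreak(self):
        burdens = pd.DataFrame(
            {"N_hyper": [10] * 10, "N_hypo": [0, 0, 0, 1, 1, 2, 3, 4, 5, 6]},
            index=[f"s{i}" for i in range(10)],
        )
        labels = classify_epimut(burdens, "rank_frac", frac=0.7, k_hypo=4)
        assert (labels == "LowEpiMut").sum() == 7
        # the three tied-lowest scores are taken first, then lexicographic id
        assert labels["s0"] == labels["s1"] == labels["s2"] == "LowEpiMut"
        assert labels["s9"] == labels["s8"] == labels["s7"] == "HighEpiMut"

    def test_burden_score_arithmetic(self):
        b = pd.DataFrame({"N_hyper": [100], "N_hypo": [50]}, index=["s"])
        assert burden_score(b, 4).iloc[0] == 300
        assert burden_score(b, 2).iloc[0] == 200

    def test_missing_params_rejected(self):
        b = pd.DataFrame({"N_hyper": [1], "N_hypo": [1]})
        with pytest.raises(ValueError):
            classify_epimut(b, "rank_frac")
        with pytest.raises(ValueError):
            classify_epimut(b, "fixed_thresholds")
        with pytest.raises(ValueError):
            classify_epimut(b, "quantile")

    def test_em_total_recovers_latent_subtype(self):
        spec = CohortSpec(
            n_tumor=120, n_normal=10, n_probes=1000,
            effect_hyper=0.5, effect_hypo=0.5,
            purity_dist=(0.5, 1.0), burden_pattern="N2",
            noise_sd=0.02, seed=17,
        )
        tumors, normals, samples, _ = synth_cohort(spec)
        calls = recurrence_filter(call_probes(tumors, normal_reference(normals)), 0.05)
        labels = classify_epimut(burden(calls), "em_total")
        truth = samples["subtype"].map({"high": "HighEpiMut", "low": "LowEpiMut"})
        assert (labels == truth).mean() > 0.9


class TestCancerPattern:
    @pytest.mark.parametrize(
        "frac, pattern",
        [(0.85, "N1"), (0.60, "N2"), (0.39, "N3"), (0.8, "N1"), (0.4, "N2"), (0.0, "N3")],
    )
    def test_thresholds(self, frac, pattern):
        assert cancer_pattern(frac) == pattern


class TestPurityExclusion:
    WINDOW = PurityWindow(lo=0.5, hi=0.7, n_inside=2)

    def test_rules(self):
        labels = pd.Series(
            ["LowEpiMut", "LowEpiMut", "HighEpiMut"], index=["a", "b", "c"]
        )
        samples = pd.DataFrame({"purity": [0.2, 0.5, 0.2]}, index=["a", "b", "c"])
        out = low_epimut_purity_exclusion(labels, samples, self.WINDOW)
        assert "a" not in out.index          # low purity LowEpiMut dropped
        assert out["b"] == "LowEpiMut"       # at the bound: retained
        assert out["c"] == "HighEpiMut"      # high-burden untouched


class TestSurvival:
    def test_km_no_events_stays_at_one(self):
        km = km_curve([5, 8, 13], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_km_product_limit_by_hand(self):
        km = km_curve([1, 2], [1, 1]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(0.5)
        assert km.loc[2.0] == pytest.approx(0.0)

    def test_km_censoring_shrinks_risk_set_only(self):
        km = km_curve([1, 2, 3], [1, 0, 1]).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(2 / 3)  # censoring does not drop S
        assert km.loc[3.0] == pytest.approx(0.0)    # risk set of one at t=3

    def test_km_nonincreasing(self, rng):
        km = km_curve(rng.exponential(10, 50), rng.integers(0, 2, 50))
        assert (np.diff(km["survival"]) <= 1e-12).all()
        assert km["survival"].iloc[0] == 1.0

    def test_km_empty_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])

    def test_logrank_identical_groups_null(self):
        times = [1, 2, 3, 4] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["A"] * 4 + ["B"] * 4
        chi2, p = logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_logrank_hand_computed_table(self):
        # O_A = 2, E_A = 5/6, V = 0.25 + 2/9 -> chi2 = (2 - 5/6)^2 / (17/36)
        chi2, p = logrank([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        expected = (2 - 5 / 6) ** 2 / (0.25 + 2 / 9)
        assert chi2 == pytest.approx(expected, rel=1e-6)

    def test_logrank_symmetric_in_labels(self):
        r = np.random.default_rng(3)
        times = r.exponential(10, 40)
        events = r.integers(0, 2, 40)
        groups = np.array(["A"] * 20 + ["B"] * 20)
        chi2_a, p_a = logrank(times, events, groups)
        swapped = np.where(groups == "A", "B", "A")
        chi2_b, p_b = logrank(times, events, swapped)
        assert chi2_a == pytest.approx(chi2_b)
        assert p_a == pytest.approx(p_b)

    def test_logrank_group_validation(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [1, 1], ["A", "A"])
        with pytest.raises(ValueError):
            logrank([1, 2, 3], [1, 1, 1], ["A", "B", "C"])

    def test_survival_differs_between_burden_groups(self):
        labels = pd.Series(["HighEpiMut"] * 150 + ["LowEpiMut"] * 150)
        df = synth_survival(labels.tolist(), hazard_ratio=2.5, censor_rate=2e-4, seed=23)
        chi2, p = logrank(df["time"], df["event"], labels.to_numpy())
        assert p < 0.001
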