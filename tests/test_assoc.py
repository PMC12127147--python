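import numpy as np
import pandas as pd
import pytest

from methet import (
    BetaMatrix,
    assess_markers,
    auc,
    combined_panel_score,
    correlate,
    panel_mean,
    partial_r2,
    signature_score,
    synth_cfdna,
)


def orthogonalize(v, against):
    """Component of v orthogonal to against (both centered)."""
    v = v - v.mean()
    against = against - against.mean()
    return v - against * (v @ against) / (against @ against)


def marker_with_exact_r(g, r, noise, scale=0.1, base=0.5):
    """Construct a vector whose Pearson correlation with g is exactly r."""
    gs = (g - g.mean()) / g.std()
    e = orthogonalize(noise, g)
    e = e / e.std()
    return base + scale * (r * gs + np.sqrt(1 - r**2) * e)


class TestCorrelate:
    def test_perfect_pearson(self):
        assert correlate([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        res = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)

    def test_spearman_monotone(self):
        res = correlate([1, 2, 3], [10, 100, 1000], method="spearman")
        assert res.r == pytest.approx(1.0)

    def test_pairwise_missing_removal(self):
        res = correlate([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert res.n == 3 and res.r == pytest.approx(1.0)

    def test_zero_variance_flagged_not_raised(self):
        res = correlate([1, 1, 1], [1, 2, 3])
        assert not res.defined and np.isnan(res.r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, np.nan], [1, 2])


class TestSignatureScore:
    def test_single_gene_sample_sd_z(self):
        expr = pd.DataFrame([[0.0, 10.0]], index=["G1"], columns=["s1", "s2"])
        score = signature_score(expr, ["G1"])
        assert score.tolist() == pytest.approx([-0.7071, 0.7071], abs=1e-4)

    def test_fully_absent_list_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            signature_score(expr, ["G9"])

    def test_duplicated_gene_equals_single(self, rng):
        row = rng.normal(size=6)
        expr = pd.DataFrame([row, row], index=["G1", "G2"],
                            columns=[f"s{i}" for i in range(6)])
        pd.testing.assert_series_equal(
            signature_score(expr, ["G1", "G2"]), signature_score(expr, ["G1"])
        )

    def test_zero_variance_gene_dropped(self, rng):
        expr = pd.DataFrame(
            [rng.normal(size=4), np.full(4, 3.0)],
            index=["G1", "G2"], columns=[f"s{i}" for i in range(4)],
        )
        pd.testing.assert_series_equal(
            signature_score(expr, ["G1", "G2"]), signature_score(expr, ["G1"])
        )


def nested_ols_oracle(y, X_full, X_red):
    """Normal-equations nested OLS, independent of the implementation path."""
    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return r @ r

    s_red, s_full = sse(X_red), sse(X_full)
    return (s_red - s_full) / s_red


class TestPartialR2:
    def test_exact_fit_tends_to_one(self, rng):
        cov = pd.DataFrame({"f": rng.normal(size=200), "g": rng.normal(size=200)})
        y = 2 * cov["f"]
        assert partial_r2(y, cov, "f") >= 0.99

    def test_independent_focal_near_zero(self, rng):
        cov = pd.DataFrame({"f": rng.normal(size=200), "g": rng.normal(size=200)})
        y = cov["g"] + 0.5 * rng.normal(size=200)
        assert partial_r2(y, cov, "f") < 0.05

    def test_equals_nested_ols_oracle(self, rng):
        for _ in range(10):
            n, p = 30, 4
            cov = pd.DataFrame(rng.normal(size=(n, p)),
                               columns=[f"c{i}" for i in range(p)])
            y = rng.normal(size=n) + cov["c1"]
            got = partial_r2(y, cov, "c1")
            X_full = np.column_stack([np.ones(n), cov.to_numpy()])
            X_red = np.column_stack([np.ones(n), cov.drop(columns="c1").to_numpy()])
            assert got == pytest.approx(nested_ols_oracle(y.to_numpy(), X_full, X_red),
                                        abs=1e-10)

    def test_equals_squared_partial_correlation(self, rng):
        n = 50
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = cov["a"] + 0.3 * cov["b"] + rng.normal(size=n)
        # partial correlation: correlate residuals of y and focal on the others
        others = np.column_stack([np.ones(n), cov[["b", "c"]].to_numpy()])
        def resid(v):
            beta = np.linalg.solve(others.T @ others, others.T @ v)
            return v - others @ beta
        r = np.corrcoef(resid(y.to_numpy()), resid(cov["a"].to_numpy()))[0, 1]
        assert partial_r2(y, cov, "a") == pytest.approx(r**2, abs=1e-8)

    def test_rank_deficiency_named(self, rng):
        cov = pd.DataFrame({"f": rng.normal(size=50)})
        cov["g"] = 2 * cov["f"]
        with pytest.raises(ValueError, match="collinear"):
            partial_r2(rng.normal(size=50), cov, "f")


class TestAssessMarkers:
    def build(self, rng, rs, n=200):
        g = rng.normal(size=n)
        rows = {
            f"m{i}": marker_with_exact_r(g, r, rng.normal(size=n))
            for i, r in enumerate(rs)
        }
        data = pd.DataFrame(rows).T
        data.columns = [f"s{i}" for i in range(n)]
        bm = BetaMatrix(data.clip(0, 1))
        return bm, pd.Series(g, index=data.columns)

    def test_classification_rules(self, rng):
        bm, g = self.build(rng, [-0.5, 0.0, -0.2])
        out = assess_markers(bm, g)
        assert out.loc["m0", "class"] == "affected"       # r < -0.3, p tiny
        assert out.loc["m1", "class"] == "not_affected"   # r > -0.1
        assert out.loc["m2", "class"] == "intermediate"   # -0.3 <= r <= -0.1, p < .05

    def test_recovers_maintenance_coupled_markers(self, rng):
        """Markers coupled to global hypomethylation separate from uncoupled ones."""
        sens = spec = []
        sens_vals, spec_vals = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            bm, g = self.build(r, [-0.6] * 20 + [0.0] * 20)
            out = assess_markers(bm, g)
            coupled = out.index.str.replace("m", "").astype(int) < 20
            sens_vals.append((out.loc[coupled, "class"] == "affected").mean())
            spec_vals.append((out.loc[~coupled, "class"] == "not_affected").mean())
        assert np.mean(sens_vals) >= 0.9
        assert np.mean(spec_vals) >= 0.9


class TestPanels:
    def test_row_mean(self):
        sig = pd.DataFrame({"a": [0.2], "b": [0.4]}, index=["s1"])
        assert panel_mean(sig, ["a", "b"]).iloc[0] == pytest.approx(0.3)

    def test_missing_marker_skipped_per_sample(self):
        sig = pd.DataFrame({"a": [0.2, np.nan], "b": [0.4, 0.6]}, index=["s1", "s2"])
        scores = panel_mean(sig, ["a", "b"])
        assert scores["s2"] == pytest.approx(0.6)

    def test_all_missing_sample_gets_missing_score(self):
        sig = pd.DataFrame({"a": [np.nan], "b": [np.nan]}, index=["s1"])
        assert np.isnan(panel_mean(sig, ["a", "b"]).iloc[0])

    def test_empty_panel_rejected(self):
        sig = pd.DataFrame({"a": [0.2]})
        with pytest.raises(ValueError):
            panel_mean(sig, ["zzz"])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_all_pairs_enumeration(self):
        # concordant pairs: (3,2), (3,0), (1,0); discordant: (1,2) -> 3/4
        assert auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_complement_and_monotone_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        a = auc(scores, labels)
        assert a + auc(-scores, labels) == pytest.approx(1.0)
        assert auc(np.exp(scores), labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])


class TestCombinedPanel:
    def test_combined_beats_single_panels_under_maintenance_loss(self):
        """When some tumors lose hyper signal, hyper+hypo combination dominates."""
        aucs = {"hyper": [], "hypo": [], "combined": []}
        for seed in range(20):
            sig, labels, panels = synth_cfdna(
                60, 60, 20, 20, tumor_fraction_dist=(0.02, 0.1), noise_sd=0.02,
                seed=seed, frac_high_maintenance_loss=0.4, hyper_attenuation=0.9,
            )
            aucs["hyper"].append(auc(panel_mean(sig, panels["hyper"]), labels))
            aucs["hypo"].append(auc(-panel_mean(sig, panels["hypo"]), labels))
            aucs["combined"].append(
                auc(combined_panel_score(sig, panels["hyper"], panels["hypo"]), labels)
            )
        combined = np.mean(aucs["combined"])
        assert combined >= np.mean(aucs["hyper"])
        assert combined >= np.mean(aucs["hypo"])
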