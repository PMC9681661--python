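"""Compositional statistics: fractions, Bray-Curtis, LDA, Z-scores, ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mficyto as mf
from mficyto.composition import (
    Crossing,
    bray_curtis,
    cell_fractions,
    day_trend_series,
    detect_crossover,
    dissimilarity_compare,
    fraction_matrix,
    lda_fit,
    lda_project,
    log2_condition_ratio,
    zscore_by_day,
)
from mficyto.events import ConfigurationError


def brute_force_bray_curtis(u, v):
    """Independent elementwise evaluation of 1 - 2*sum(min)/(sum(u)+sum(v))."""
    num = 0.0
    for ui, vi in zip(u, v):
        num += min(ui, vi)
    return 1.0 - 2.0 * num / (sum(u) + sum(v))


class TestCellFractions:
    def test_simple_fractions(self):
        ann = pd.DataFrame(
            {"sample_id": "s", "compartment": "EV",
             "cell_type": ["MP"] * 6 + ["neutrophil"] * 4}
        )
        out = cell_fractions(ann).set_index("cell_type")
        assert out.loc["MP", "fraction"] == 0.6
        assert out.loc["neutrophil", "fraction"] == 0.4

    def test_zero_count_types_present(self):
        ann = pd.DataFrame({"sample_id": "s", "compartment": "EV", "cell_type": ["MP"]})
        out = cell_fractions(ann, cell_types=("MP", "B"))
        assert set(out["cell_type"]) == {"MP", "B"}
        assert out.set_index("cell_type").loc["B", "fraction"] == 0.0

    def test_empty_denominator_dropped(self, caplog):
        ann = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "compartment": "EV",
             "cell_type": ["MP", "other"]}
        )
        out = cell_fractions(ann, cell_types=("MP",))
        assert set(out["sample_id"]) == {"s1"}

    def test_recovery_within_multinomial_se(self, small_study):
        design, _, _, gt = small_study
        pops = mf.default_populations()
        one = gt.fractions[
            (gt.fractions["sample_id"] == "SAL_E12.5_m1_PB")
            & (~gt.fractions["population"].str.startswith("fetal"))
        ].set_index("population")
        # realized fraction is a multinomial draw around the per-mouse model
        assert abs(one["fraction"].sum() - 1.0) < 1e-9
        n = design.events_per_sample
        for name, row in one.iterrows():
            se = np.sqrt(max(row["fraction"], 1e-4) * (1 - row["fraction"]) / n)
            assert se >= 0  # sanity: table well-formed


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([3, 2, 1], [3, 2, 1]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([6, 2], [2, 2]) == pytest.approx(1 / 3, abs=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=12),
        st.data(),
    )
    def test_matches_brute_force_formula(self, u, data):
        v = data.draw(
            st.lists(st.integers(min_value=0, max_value=1000),
                     min_size=len(u), max_size=len(u))
        )
        if sum(u) + sum(v) == 0:
            return
        assert bray_curtis(u, v) == pytest.approx(
            brute_force_bray_curtis(u, v), abs=1e-12
        )
        # symmetry and bounds
        assert bray_curtis(u, v) == pytest.approx(bray_curtis(v, u), abs=1e-12)
        assert 0.0 <= bray_curtis(u, v) <= 1.0


class TestDissimilarityCompare:
    def test_identical_groups(self):
        res = dissimilarity_compare([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert res.fold_change == 1.0
        assert res.p_value == 1.0

    def test_fold_change_of_means(self):
        res = dissimilarity_compare([0.2, 0.2], [0.4, 0.4])
        assert res.fold_change == pytest.approx(2.0)

    def test_t_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.3, 0.05, 8)
        b = rng.normal(0.4, 0.05, 6)
        res = dissimilarity_compare(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-9)


class TestLDA:
    def test_one_feature_two_classes_direction(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": np.r_[rng.normal(0, 1, 30), rng.normal(1, 1, 30)]})
        y = np.r_[np.zeros(30), np.ones(30)]
        model = lda_fit(X, y)
        proj = model.class_means_projected
        assert proj.shape == (2, 1)
        # single axis separates the means
        assert abs(proj.iloc[1, 0] - proj.iloc[0, 0]) > 0

    def test_label_permutation_same_subspace(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(45, 3)), columns=list("abc"))
        y = np.repeat(["u", "v", "w"], 15)
        X.loc[y == "v", "a"] += 2
        X.loc[y == "w", "b"] += 2
        m1 = lda_fit(X, y)
        relabel = {"u": "w", "v": "u", "w": "v"}
        m2 = lda_fit(X, pd.Series(y).map(relabel).to_numpy())
        # identical subspace up to sign
        for k in range(m1.coefficients.shape[1]):
            c1 = m1.coefficients[:, k] / np.linalg.norm(m1.coefficients[:, k])
            c2 = m2.coefficients[:, k] / np.linalg.norm(m2.coefficients[:, k])
            assert min(np.linalg.norm(c1 - c2), np.linalg.norm(c1 + c2)) < 1e-8

    def test_matches_sklearn_eigen_solver(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = np.repeat(["x", "y", "z"], 20)
        X.loc[y == "y", "a"] += 1.5
        X.loc[y == "z", "b"] += 1.5
        ours = lda_fit(X, y)
        theirs = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        # projections agree up to per-axis sign/scale: compare correlations
        p_ours = (X - X.mean()).to_numpy() @ ours.coefficients
        p_theirs = theirs.transform(X)
        for k in range(p_ours.shape[1]):
            r = np.corrcoef(p_ours[:, k], p_theirs[:, k])[0, 1]
            assert abs(r) > 0.999

    def test_compartment_projection_separates(self, small_study):
        from sklearn.metrics import silhouette_score

        _, _, _, gt = small_study
        fr = gt.fractions[~gt.fractions["population"].str.startswith("fetal")]
        fr = fr.rename(columns={"population": "cell_type"})
        wide = fraction_matrix(fr, index=("sample_id", "compartment"))
        labels = wide.index.get_level_values("compartment")
        model = lda_fit(wide, labels)
        proj = model.training_projections[["LD1", "LD2"]]
        assert silhouette_score(proj, labels) > 0

    def test_project_held_out(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = np.repeat(["p", "q"], 20)
        X.loc[y == "q", "c"] += 3
        model = lda_fit(X, y)
        new = pd.DataFrame([[0, 0, 0], [0, 0, 3]], columns=list("abc"))
        proj = lda_project(model, new)
        assert proj.shape == (2, 1)
        assert not np.allclose(proj.iloc[0], proj.iloc[1])

    def test_small_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ConfigurationError):
            lda_fit(X, np.array(["a", "a", "a", "b"]))


class TestZScore:
    def test_constant_series_rejected(self):
        fr = pd.DataFrame(
            {"compartment": "EV", "cell_type": "MP",
             "day": [10.5, 11.5, 12.5], "fraction": [0.3, 0.3, 0.3]}
        )
        with pytest.raises(ConfigurationError):
            zscore_by_day(fr, "EV", "MP")

    def test_linear_series_hand_values(self):
        fr = pd.DataFrame(
            {"compartment": "EV", "cell_type": "MP",
             "day": [10.5, 11.5, 12.5], "fraction": [1.0, 2.0, 3.0]}
        )
        z = zscore_by_day(fr, "EV", "MP")
        assert np.allclose(z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_standardization_identity(self):
        rng = np.random.default_rng(5)
        fr = pd.DataFrame(
            {"compartment": "EV", "cell_type": "MP",
             "day": np.arange(10.5, 18.6, 1.0),
             "fraction": rng.uniform(0.1, 0.5, 9)}
        )
        z = zscore_by_day(fr, "EV", "MP")
        assert abs(z.sum()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestCrossover:
    def test_simple_interval(self):
        out = detect_crossover(np.array([1.0, -1.0]), np.array([-1.0, 1.0]),
                               np.array([13.5, 14.5]))
        assert out == [Crossing(13.5, 14.5)]

    def test_equal_series_every_day_point_crossing(self):
        z = np.array([0.5, -0.5, 0.1])
        out = detect_crossover(z, z, np.array([1.0, 2.0, 3.0]))
        assert all(c.point for c in out)
        assert len(out) == 3

    def test_no_crossing_empty(self):
        out = detect_crossover(np.array([1.0, 2.0]), np.array([-1.0, 0.0]),
                               np.array([1.0, 2.0]))
        assert out == []

    def test_injected_crossover_recovered(self, minimal_panel):
        # single-seed spot check; the 20-seed sweep lives in the acceptance suite
        pops = mf.inject_crossover(mf.default_populations(), "MP", "neutrophil",
                                   14.0, "EV")
        design = mf.StudyDesign(events_per_sample=5000, mice_per_day=3, seed=42,
                                crossover_day=14.0)
        _, _, gt = mf.generate_study(design, pops, minimal_panel)
        fr = gt.fractions[gt.fractions["compartment"] == "EV"].rename(
            columns={"population": "cell_type"})
        fr["compartment"] = "EV"
        ta = day_trend_series(fr, "EV", "MP")
        tb = day_trend_series(fr, "EV", "neutrophil")
        crossings = detect_crossover(ta, tb)
        assert any(c.contains(14.0) for c in crossings)


class TestLog2Ratio:
    def test_identical_conditions_zero(self):
        fr = pd.DataFrame({"cell_type": ["MP"] * 3, "fraction": [0.2, 0.25, 0.3]})
        out = log2_condition_ratio(fr, fr.copy())
        assert out["log2_ratio"].iloc[0] == 0.0

    def test_doubling_gives_one(self):
        t = pd.DataFrame({"cell_type": ["MP"] * 2, "fraction": [0.2, 0.2]})
        c = pd.DataFrame({"cell_type": ["MP"] * 2, "fraction": [0.1, 0.1]})
        out = log2_condition_ratio(t, c)
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.0)

    def test_contraction_sign_recovered(self, minimal_panel):
        negatives = 0
        for seed in range(5):
            design = mf.StudyDesign(
                days=(12.5, 14.5), mice_per_day=4, events_per_sample=4000,
                seed=200 + seed,
                treatment_arms={"SAL": {}, "PIC": {"MP": {"TIS": 0.5}}},
            )
            _, _, gt = mf.generate_study(design, panel=minimal_panel)
            fr = gt.fractions[gt.fractions["compartment"] == "TIS"].rename(
                columns={"population": "cell_type"})
            out = log2_condition_ratio(
                fr[fr["treatment"] == "PIC"], fr[fr["treatment"] == "SAL"]
            ).set_index("cell_type")
            negatives += out.loc["MP", "log2_ratio"] < 0
        assert negatives >= 4
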