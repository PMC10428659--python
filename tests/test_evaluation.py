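"""Splitting, AUC, rating bands, contributions, jackknife, response curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tickdist.evaluation import (
    EvalError,
    SplitSpec,
    auc,
    jackknife_importance,
    percent_contribution,
    permutation_importance,
    rate_auc,
    response_curve,
    split_presences,
)
from tickdist.maxent import FeatureSet, FitConfig, fit_maxent, fit_from_tables
from tickdist.occurrences import OccurrenceRecord, OccurrenceSet


def occ_of(n):
    return OccurrenceSet(
        species="t",
        records=[OccurrenceRecord("t", 100 + 0.1 * i, 40 + 0.05 * i) for i in range(n)],
    )


class TestSplit:
    @pytest.mark.parametrize("n,n_train,n_test", [(104, 78, 26), (4, 3, 1), (8, 6, 2)])
    def test_75_25_rounding(self, n, n_train, n_test):
        train, test = split_presences(occ_of(n), SplitSpec(seed=0))
        assert len(train) == n_train and len(test) == n_test

    def test_disjoint_and_exhaustive(self):
        o = occ_of(20)
        train, test = split_presences(o, SplitSpec(seed=3, replicate_id=2))
        got = {(r.lon, r.lat) for r in train} | {(r.lon, r.lat) for r in test}
        assert got == {(r.lon, r.lat) for r in o}
        assert not ({(r.lon, r.lat) for r in train} & {(r.lon, r.lat) for r in test})

    def test_reproducible_per_seed_and_replicate(self):
        o = occ_of(30)
        a = split_presences(o, SplitSpec(seed=5, replicate_id=1))
        b = split_presences(o, SplitSpec(seed=5, replicate_id=1))
        c = split_presences(o, SplitSpec(seed=5, replicate_id=2))
        assert [r.lon for r in a[0]] == [r.lon for r in b[0]]
        assert [r.lon for r in a[0]] != [r.lon for r in c[0]]

    def test_too_small_fatal(self):
        with pytest.raises(EvalError):
            split_presences(occ_of(3), SplitSpec())


def pair_count_auc(p, b):
    """Exhaustive pair-counting oracle."""
    wins = sum((x > y) + 0.5 * (x == y) for x in p for y in b)
    return wins / (len(p) * len(b))


class TestAuc:
    def test_hand_example(self):
        assert auc([0.9, 0.8, 0.4], [0.5, 0.3, 0.2]) == pytest.approx(8 / 9)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_identical_scores_half(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_empty_fatal(self):
        with pytest.raises(EvalError):
            auc([], [0.1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=15),
        st.lists(st.integers(0, 10), min_size=1, max_size=15),
    )
    def test_matches_pair_count_oracle(self, p, b):
        # integer scores force plenty of ties
        assert auc(p, b) == pytest.approx(pair_count_auc(p, b))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=12),
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=12),
    )
    def test_invariant_under_monotone_transform(self, p, b):
        base = auc(p, b)
        for f in (np.log, lambda x: np.asarray(x) ** 3, lambda x: 5 * np.asarray(x) - 2):
            assert auc(f(np.asarray(p)), f(np.asarray(b))) == pytest.approx(base)


class TestRating:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.960, "excellent"),  # the band the study's own models fall in
            (0.85, "good"),
            (0.60, "poor"),  # boundary belongs to the upper band
            (0.55, "failure"),
            (0.75, "fair"),
            (0.9, "excellent"),
            (1.0, "excellent"),
            (0.3, "worse than random"),
        ],
    )
    def test_bands(self, value, label):
        assert rate_auc(value) == label

    def test_bands_partition_upper_half(self):
        # no gaps, no overlaps on [0.5, 1.0]
        grid = np.linspace(0.5, 1.0, 2001)
        labels = [rate_auc(v) for v in grid]
        assert set(labels) == {"failure", "poor", "fair", "good", "excellent"}
        # labels change monotonically through the band order
        order = {"failure": 0, "poor": 1, "fair": 2, "good": 3, "excellent": 4}
        codes = [order[l] for l in labels]
        assert codes == sorted(codes)

    def test_out_of_range_fatal(self):
        with pytest.raises(EvalError):
            rate_auc(1.2)


class TestContribution:
    def test_single_variable_gets_everything(self, make_table):
        x = np.linspace(0, 1, 30)
        bg = make_table(x=x)
        pres = make_table(x=[0.7, 0.8, 0.85, 0.9, 1.0])
        model = fit_from_tables(pres, bg, FitConfig(feature_classes=("linear",)))
        contrib = percent_contribution(model)
        assert contrib["x"] == pytest.approx(100.0)

    def test_sums_to_100(self, small_model):
        contrib = percent_contribution(small_model)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.1)

    def test_noise_variable_contributes_less(self, make_table):
        rng = np.random.default_rng(0)
        medians = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 1, 200)
            noise = r.uniform(0, 1, 200)
            bg = make_table(x=x, noise=noise)
            # presence concentrated at high x, independent of noise
            keep = r.uniform(0, 1, 200) < x**2
            pres = bg[keep]
            if keep.sum() < 5:
                continue
            model = fit_from_tables(
                pres, bg, FitConfig(feature_classes=("linear", "quadratic")))
            c = percent_contribution(model)
            medians.append(c["x"] - c["noise"])
        assert np.median(medians) > 0

    def test_permutation_importance_prefers_informative(self, small_model, small_tables):
        presence, background = small_tables
        imp = permutation_importance(small_model, presence, background, seed=0)
        assert imp["Bio4"] == max(imp.values())


class TestJackknife:
    def small_problem(self, seed=0, extra=None):
        r = np.random.default_rng(seed)
        n = 300
        x = r.uniform(0, 1, n)
        z = r.uniform(0, 1, n)
        cols = {"x": x, "z": z}
        if extra:
            cols.update(extra(r, n, cols))
        bg = pd.DataFrame(cols)
        keep = r.uniform(0, 1, n) < np.exp(3 * (x - 1))
        return bg[keep], bg

    def test_duplicated_variable_is_redundant(self):
        pres, bg = self.small_problem(
            seed=1, extra=lambda r, n, c: {"x_copy": c["x"]})
        cfg = FitConfig(feature_classes=("linear", "quadratic"))
        jk = jackknife_importance(pres, bg, ["x", "x_copy", "z"], cfg)
        # dropping the duplicate costs nothing
        assert jk["x_copy"]["gain_without"] == pytest.approx(
            jk["x_copy"]["gain_full"], abs=1e-3)

    def test_noise_variable_gain_only_near_zero(self):
        gains = []
        for seed in range(10):
            pres, bg = self.small_problem(seed=seed)
            cfg = FitConfig(feature_classes=("linear", "quadratic"))
            jk = jackknife_importance(pres, bg, ["x", "z"], cfg,
                                      include_without=False)
            gains.append(jk["z"]["gain_only"])
        assert np.median(gains) <= 0.05

    def test_gain_only_bounded_by_full(self, small_tables, small_stack):
        presence, background = small_tables
        cfg = FitConfig(feature_classes=("linear", "quadratic"), hinge_knots=3)
        jk = jackknife_importance(presence, background, small_stack.names[:3], cfg)
        for v, entry in jk.items():
            assert entry["gain_only"] <= entry["gain_full"] + 1e-6

    def test_single_variable_warns(self, small_tables):
        presence, background = small_tables
        cfg = FitConfig(feature_classes=("linear",))
        with pytest.warns(UserWarning, match="single variable"):
            jk = jackknife_importance(presence, background, ["Bio4"], cfg)
        assert "gain_without" not in jk["Bio4"]


class TestResponseCurve:
    def test_sweep_covers_training_range(self, small_model):
        v = small_model.features.variables[0]
        curve = response_curve(small_model, v, n_points=50)
        lo, hi = small_model.features.bounds[v]
        assert curve[v].iloc[0] == pytest.approx(lo)
        assert curve[v].iloc[-1] == pytest.approx(hi)

    def test_positive_linear_model_is_monotone(self, make_table):
        x = np.linspace(0, 1, 30)
        bg = make_table(x=x)
        pres = make_table(x=[0.7, 0.8, 0.85, 0.9, 1.0])
        model = fit_from_tables(pres, bg, FitConfig(feature_classes=("linear",)))
        assert model.beta[0] > 0
        curve = response_curve(model, "x")
        assert np.all(np.diff(curve["suitability"]) >= -1e-12)

    def test_cloglog_codomain(self, small_model):
        curve = response_curve(small_model, "Bio4", transform="cloglog")
        assert ((curve["suitability"] > 0) & (curve["suitability"] < 1)).all()

    def test_unknown_variable_fatal(self, small_model):
        with pytest.raises(EvalError, match="Bio99"):
            response_curve(small_model, "Bio99")
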