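import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollenscale.biomes import (
    BiomeScore,
    DifferenceAxis,
    binary_filter,
    difference_axis,
    mean_score,
    project_scores,
    quantile_groups,
    recent_assemblages,
    typical_assemblage,
)
from pollenscale.errors import EmptySelectionError, InsufficientDataError
from pollenscale.ordination import ScoreSeries
from pollenscale.records import PollenRecord


def surface_record(site_id, counts, ages=None, cls="forest"):
    counts = np.atleast_2d(counts)
    if ages is None:
        ages = 100.0 + 50.0 * np.arange(counts.shape[0])
    return PollenRecord(
        site_id=site_id, lat=50.0, lon=10.0, times=np.asarray(ages, float),
        taxa=[f"t{i}" for i in range(counts.shape[1])], counts=counts,
        class_labels={"intersection_class": cls},
    )


def ta(biome_id, weights: dict):
    from pollenscale.biomes import TypicalAssemblage
    return TypicalAssemblage(biome_id=biome_id, weights=pd.Series(weights),
                             n_source_records=1, class_selection=[biome_id])


class TestRecentAssemblages:
    def test_single_sample_is_sqrt_of_proportions(self):
        rec = surface_record("a", [[3, 1]])
        asm, meta = recent_assemblages([rec])
        assert np.allclose(asm.loc["a"].to_numpy(), [np.sqrt(0.75), np.sqrt(0.25)])
        assert meta.loc["a", "intersection_class"] == "forest"

    def test_two_identical_samples_same_as_one(self):
        one = recent_assemblages([surface_record("a", [[3, 1]])])[0]
        two = recent_assemblages([surface_record("a", [[3, 1], [3, 1]])])[0]
        assert np.allclose(one.to_numpy(), two.to_numpy())

    def test_transform_orders_match_hand_computation(self):
        rec = surface_record("a", [[3, 1], [1, 3]])
        mean_first = recent_assemblages([rec], transform_order="mean_then_sqrt")[0]
        sqrt_first = recent_assemblages([rec], transform_order="sqrt_then_mean")[0]
        assert np.allclose(mean_first.loc["a"], np.sqrt([0.5, 0.5]))
        expected = (np.sqrt([0.75, 0.25]) + np.sqrt([0.25, 0.75])) / 2
        assert np.allclose(sqrt_first.loc["a"], expected)

    def test_records_without_recent_samples_excluded(self):
        old = surface_record("old", [[2, 2]], ages=[3000.0])
        asm, _ = recent_assemblages([old, surface_record("new", [[2, 2]])])
        assert list(asm.index) == ["new"]


class TestTypicalAssemblage:
    def test_identical_records_mean_is_member(self):
        recs = [surface_record(f"s{i}", [[4, 1]]) for i in range(3)]
        asm, meta = recent_assemblages(recs)
        t = typical_assemblage(asm, meta["intersection_class"], "Fo", ["forest"])
        assert np.allclose(t.weights.to_numpy(), asm.iloc[0].to_numpy())
        assert t.n_source_records == 3

    def test_group_weights_override_group_sizes(self):
        # 4:1 imbalance with equal weights -> plain mean of the two group means
        evergreen = [surface_record(f"e{i}", [[9, 1]], cls="Be") for i in range(4)]
        deciduous = [surface_record("d0", [[1, 9]], cls="Bd")]
        asm, meta = recent_assemblages(evergreen + deciduous)
        lbl = meta["intersection_class"]
        weighted = typical_assemblage(asm, lbl, "Bo", ["Be", "Bd"],
                                      group_weights={"Be": 0.5, "Bd": 0.5})
        mean_e = asm.loc[[f"e{i}" for i in range(4)]].mean()
        mean_d = asm.loc[["d0"]].mean()
        assert np.allclose(weighted.weights, (mean_e + mean_d) / 2)
        unweighted = typical_assemblage(asm, lbl, "Bo", ["Be", "Bd"])
        assert not np.allclose(weighted.weights, unweighted.weights)

    def test_equal_group_sizes_match_unweighted(self):
        recs = [surface_record(f"e{i}", [[9, 1]], cls="Be") for i in range(2)] + \
               [surface_record(f"d{i}", [[1, 9]], cls="Bd") for i in range(2)]
        asm, meta = recent_assemblages(recs)
        lbl = meta["intersection_class"]
        w = typical_assemblage(asm, lbl, "Bo", ["Be", "Bd"],
                               group_weights={"Be": 0.5, "Bd": 0.5})
        u = typical_assemblage(asm, lbl, "Bo", ["Be", "Bd"])
        assert np.allclose(w.weights, u.weights)

    def test_empty_selection_names_classes(self):
        asm, meta = recent_assemblages([surface_record("a", [[1, 1]])])
        with pytest.raises(EmptySelectionError, match="tundra"):
            typical_assemblage(asm, meta["intersection_class"], "Op", ["tundra"])


class TestDifferenceAxis:
    def test_self_difference_is_zero(self):
        a = ta("Fo", {"Pinus": 0.6, "Betula": 0.3})
        axis = difference_axis(a, a)
        assert np.allclose(axis.values, 0.0)

    def test_toy_arithmetic(self):
        axis = difference_axis(ta("i", {"a": 0.6, "b": 0.2}),
                               ta("j", {"a": 0.1, "b": 0.5}))
        assert axis.values["a"] == pytest.approx(0.5)
        assert axis.values["b"] == pytest.approx(-0.3)

    def test_shared_dominant_cancels(self):
        axis = difference_axis(ta("Bo", {"Pinus": 0.7, "Larix": 0.2}),
                               ta("Tc", {"Pinus": 0.7, "Tsuga": 0.2}))
        assert axis.values["Pinus"] == pytest.approx(0.0)
        assert set(axis.display_taxa().index) == {"Larix", "Tsuga"}

    def test_antisymmetry_and_score_negation(self):
        a = ta("i", {"a": 0.6, "b": 0.1})
        b = ta("j", {"a": 0.1, "b": 0.7, "c": 0.2})
        ij, ji = difference_axis(a, b), difference_axis(b, a)
        assert np.allclose(ij.values, -ji.values.reindex(ij.values.index))
        rec = surface_record("r", [[3, 1, 1], [1, 4, 2]])
        rec.taxa = ["a", "b", "c"]
        s_ij = project_scores(rec, ij)
        s_ji = project_scores(rec, ji)
        assert np.allclose(s_ij.values, -s_ji.values)


class TestProjection:
    def test_sign_points_to_matching_biome(self):
        axis = DifferenceAxis("i,j", pd.Series({"a": 0.8, "b": -0.8}))
        rec_i = surface_record("ri", [[95, 5]])
        rec_i.taxa = ["a", "b"]
        rec_j = surface_record("rj", [[5, 95]])
        rec_j.taxa = ["a", "b"]
        assert project_scores(rec_i, axis).values[0] > 0
        assert project_scores(rec_j, axis).values[0] < 0

    def test_zero_axis_zero_scores(self):
        axis = DifferenceAxis("i,j", pd.Series({"t0": 0.0, "t1": 0.0}))
        s = project_scores(surface_record("r", [[3, 2]]), axis)
        assert np.allclose(s.values, 0.0)

    def test_projection_linearity(self):
        rec = surface_record("r", [[3, 2, 5], [1, 1, 8]])
        a = pd.Series({"t0": 0.5, "t1": 0.2, "t2": 0.1})
        b = pd.Series({"t0": 0.1, "t1": 0.4, "t2": 0.3})
        s_ab = project_scores(rec, DifferenceAxis("a,b", a - b))
        s_a = project_scores(rec, DifferenceAxis("a,0", a))
        s_b = project_scores(rec, DifferenceAxis("b,0", b))
        assert np.allclose(s_ab.values, s_a.values - s_b.values, atol=1e-12)

    def test_disjoint_taxa_rejected(self):
        axis = DifferenceAxis("i,j", pd.Series({"x": 1.0}))
        with pytest.raises(EmptySelectionError):
            project_scores(surface_record("r", [[1, 1]]), axis)


class TestMeanScoreAndGroups:
    def test_mean_score_examples(self):
        s = ScoreSeries(np.array([2500.0, 3500.0]), np.array([0.3, 0.3]), "i,j")
        assert mean_score(s).u_bar == pytest.approx(0.3)
        s2 = ScoreSeries(np.array([2500.0, 3500.0]), np.array([-1.0, 1.0]), "i,j")
        assert mean_score(s2).u_bar == pytest.approx(0.0)

    def test_empty_window_flagged(self):
        s = ScoreSeries(np.array([100.0, 200.0]), np.array([1.0, 2.0]), "i,j")
        bs = mean_score(s, window=(2000, 8000))
        assert bs.n_samples_in_window == 0
        assert np.isnan(bs.u_bar)

    def test_quantile_groups_equal_split(self):
        g = quantile_groups(pd.Series(np.arange(10.0)), k=5)
        assert sorted(g.value_counts().tolist()) == [2] * 5

    def test_quantile_groups_monotone(self):
        scores = pd.Series(np.arange(1, 101, dtype=float),
                           index=[f"s{i}" for i in range(100)])
        g = quantile_groups(scores, k=5)
        assert set(scores[g == 1]) == set(range(1, 21))
        assert set(scores[g == 5]) == set(range(81, 101))

    def test_group_sizes_differ_by_at_most_one(self):
        g = quantile_groups(pd.Series(np.random.default_rng(0).normal(size=23)), k=5)
        counts = g.value_counts()
        assert counts.max() - counts.min() <= 1

    def test_too_few_sites_rejected(self):
        with pytest.raises(InsufficientDataError):
            quantile_groups(pd.Series([1.0, 2.0]), k=5)

    def test_groupwise_aggregation_matches_naive_loop(self):
        rng = np.random.default_rng(7)
        scores = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        g = quantile_groups(scores, k=5)
        for grp in range(1, 6):
            member_mean = scores[g == grp].mean()
            naive = np.mean([scores[s] for s in scores.index if g[s] == grp])
            assert member_mean == pytest.approx(naive)


class TestBinaryFilter:
    def test_positive_rule_strict(self):
        s = pd.Series({"a": -1.0, "b": 0.5, "c": 2.0, "d": 0.0})
        assert set(binary_filter(s, "positive")) == {"b", "c"}

    def test_upper_quantile_counts(self):
        s = pd.Series(np.arange(100.0), index=[f"s{i}" for i in range(100)])
        sel = binary_filter(s, ("upper_q", 0.4))
        assert len(sel) == 40
        assert set(sel) == {f"s{i}" for i in range(60, 100)}

    def test_region_rule(self):
        s = pd.Series({"a": 1.0, "b": 2.0})
        regions = pd.Series({"a": "W_Eurasia", "b": "E_Eurasia"})
        assert binary_filter(s, ("region", "E_Eurasia"), regions=regions) == ["b"]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            binary_filter(pd.Series({"a": 1.0}), "bogus")


class TestEndToEnd:
    def test_disjoint_classes_fully_separated(self, surface_world):
        asm, meta = recent_assemblages(surface_world)
        lbl = meta["intersection_class"]
        a_fo = typical_assemblage(asm, lbl, "Fo", ["forest"])
        a_op = typical_assemblage(asm, lbl, "Op", ["open_land"])
        axis = difference_axis(a_fo, a_op)
        correct = 0
        for rec in surface_world:
            u = mean_score(project_scores(rec, axis), window=(-60, 500),
                           site_id=rec.site_id).u_bar
            truth = rec.class_labels["intersection_class"]
            correct += (u > 0) == (truth == "forest")
        assert correct == len(surface_world)

    def test_mixture_sign_accuracy_and_monotonicity(self, fossil_world, surface_world):
        asm, meta = recent_assemblages(surface_world)
        lbl = meta["intersection_class"]
        axis = difference_axis(
            typical_assemblage(asm, lbl, "Fo", ["forest"]),
            typical_assemblage(asm, lbl, "Op", ["open_land"]),
        )
        u_bars, mixtures = [], []
        for rec in fossil_world:
            u = mean_score(project_scores(rec, axis), site_id=rec.site_id).u_bar
            u_bars.append(u)
            mixtures.append(rec.meta["mixture"])
        u_bars, mixtures = np.array(u_bars), np.array(mixtures)
        forestish = mixtures > 0.5
        assert np.mean(u_bars[forestish] > 0) >= 0.95
        rho = stats.spearmanr(mixtures, u_bars).statistic
        assert rho >= 0.9


def test_biome_score_dataclass_roundtrip():
    bs = BiomeScore(site_id="s", axis_id="Fo,Op", u_bar=0.1, n_samples_in_window=4)
    assert bs.axis_id == "Fo,Op"
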