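"""Group comparisons: PERMANOVA, rank tests, ANCOVA, SIMPER, ordination, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu

from epialleles import (
    adjust_fdr,
    composition_matrix,
    diffmodel,
    diffstat,
    driver_species,
    epistat,
    ordinate,
    pairtest,
    permanova,
    significant_regions,
)
from epialleles.groupstats import pseudo_f, rank_sum_test


def long_counts(per_sample, window_id="w1"):
    """Long-format count frame from {sample: {epiallele: count}}."""
    rows = [
        (window_id, s, "*", epi, n)
        for s, tab in per_sample.items()
        for epi, n in tab.items()
    ]
    return pd.DataFrame(rows, columns=["window_id", "sample_id", "strand", "epiallele", "count"])


def meta(groups):
    return pd.DataFrame(
        [(s, g) for s, g in groups.items()], columns=["sample_id", "group"]
    )


def mixture_counts(rng, mixture, total=50):
    keys = sorted(mixture)
    draw = rng.multinomial(total, [mixture[k] for k in keys])
    return {k: int(n) for k, n in zip(keys, draw) if n > 0}


class TestCompositionMatrix:
    def test_identical_compositions_identical_rows(self):
        m = composition_matrix(long_counts({"s1": {"00": 5, "11": 5}, "s2": {"00": 5, "11": 5}}))
        assert np.allclose(m.loc["s1"], m.loc["s2"])

    def test_disjoint_species_one_hot(self):
        m = composition_matrix(long_counts({"a": {"0": 10}, "b": {"1": 10}}))
        assert list(m.columns) == ["0", "1"]
        assert m.loc["a"].tolist() == [1.0, 0.0]
        assert m.loc["b"].tolist() == [0.0, 1.0]

    def test_scale_invariance(self):
        m = composition_matrix(long_counts({"a": {"0": 2, "1": 2}, "b": {"0": 1, "1": 1}}))
        assert np.allclose(m.loc["a"], m.loc["b"])


class TestPermanova:
    def test_pseudo_f_matches_skbio(self):
        """Independent oracle: scikit-bio's PERMANOVA statistic."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(4), size=8)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        d = squareform(pdist(x, "braycurtis"))
        f_mine, _ = pseudo_f(d**2, labels)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        sk = sk_permanova(dm, grouping=labels, permutations=0)
        assert f_mine == pytest.approx(float(sk["test statistic"]), rel=1e-10)

    def test_three_group_pseudo_f_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(3), size=9)
        labels = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        d = squareform(pdist(x, "braycurtis"))
        f_mine, _ = pseudo_f(d**2, labels)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(9)])
        sk = sk_permanova(dm, grouping=labels, permutations=0)
        assert f_mine == pytest.approx(float(sk["test statistic"]), rel=1e-10)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """n=3+3: MC p agrees with the 20-partition exact p within 2 SE."""
        rng = np.random.default_rng(3)
        x = rng.dirichlet(np.ones(3), size=6)
        labels = ["A"] * 3 + ["B"] * 3
        freq = pd.DataFrame(x)
        _, _, p_exact = permanova(freq, labels, method="exact")
        _, _, p_mc = permanova(freq, labels, n_perm=999, seed=42)
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p_mc - p_exact) <= 2 * se + 1 / 1000

    def test_p_never_zero(self):
        freq = pd.DataFrame([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        _, _, p = permanova(freq, ["A", "A", "B", "B"], n_perm=999, seed=0)
        assert p >= 1 / 1000

    def test_invariant_to_row_and_column_order(self):
        per_sample = {"s1": {"00": 30, "11": 10}, "s2": {"00": 25, "11": 15},
                      "s3": {"11": 30, "00": 10}, "s4": {"11": 28, "00": 12}}
        counts = long_counts(per_sample)
        m = meta({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        r1 = epistat(counts, m, min_per_group=2, n_perm=199, seed=7)
        shuffled = counts.sample(frac=1.0, random_state=5).reset_index(drop=True)
        r2 = epistat(shuffled, m, min_per_group=2, n_perm=199, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_invariant_to_count_scaling(self):
        per_sample = {"s1": {"00": 30, "11": 10}, "s2": {"00": 25, "11": 15},
                      "s3": {"11": 30, "00": 10}, "s4": {"11": 28, "00": 12}}
        scaled = {s: {k: v * 7 for k, v in tab.items()} for s, tab in per_sample.items()}
        m = meta({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        r1 = epistat(long_counts(per_sample), m, min_per_group=2, n_perm=199, seed=7)
        r2 = epistat(long_counts(scaled), m, min_per_group=2, n_perm=199, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_seeded_runs_are_reproducible(self):
        rng = np.random.default_rng(8)
        freq = pd.DataFrame(rng.dirichlet(np.ones(4), size=8))
        labels = ["A"] * 4 + ["B"] * 4
        assert permanova(freq, labels, seed=3) == permanova(freq, labels, seed=3)

    def test_single_group_rejected(self):
        counts = long_counts({"s1": {"0": 5}, "s2": {"0": 5}})
        with pytest.raises(ValueError, match="single group"):
            epistat(counts, meta({"s1": "A", "s2": "A"}))

    def test_underpowered_windows_reported_untested(self):
        counts = long_counts({"s1": {"0": 5}, "s2": {"0": 5}, "s3": {"1": 5}})
        m = meta({"s1": "A", "s2": "A", "s3": "B"})
        res = epistat(counts, m, min_per_group=2)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p"].iloc[0])


class TestPairtest:
    def three_group_data(self, seed=0):
        rng = np.random.default_rng(seed)
        mix_ab = {"00": 0.5, "11": 0.5}
        mix_c = {"01": 0.9, "11": 0.1}
        per_sample, groups = {}, {}
        for g, mix in (("A", mix_ab), ("B", mix_ab), ("C", mix_c)):
            for i in range(4):
                s = f"{g}{i}"
                per_sample[s] = mixture_counts(rng, mix, 60)
                groups[s] = g
        return long_counts(per_sample), meta(groups)

    def test_divergent_group_flagged_in_pairs(self):
        counts, m = self.three_group_data(1)
        res = pairtest(counts, m, "w1", n_perm=999, seed=2)
        res = res.set_index(["group1", "group2"])
        assert res.loc[("A", "C"), "p"] <= 0.05
        assert res.loc[("B", "C"), "p"] <= 0.05
        assert res.loc[("A", "B"), "p"] > 0.1

    def test_adjusted_p_at_least_raw(self):
        counts, m = self.three_group_data(2)
        res = pairtest(counts, m, "w1", n_perm=199, seed=3)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_two_groups_pointed_to_epistat(self):
        counts = long_counts({"s1": {"0": 5}, "s2": {"1": 5}})
        with pytest.raises(ValueError, match="epistat"):
            pairtest(counts, meta({"s1": "A", "s2": "B"}), "w1")


class TestDriverSpecies:
    def test_single_differing_species_dominates(self):
        per_sample = {"a1": {"00": 50, "11": 50}, "a2": {"00": 50, "11": 50},
                      "b1": {"00": 50, "11": 25, "01": 25}, "b2": {"00": 50, "11": 25, "01": 25}}
        counts = long_counts(per_sample)
        m = meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = driver_species(counts, m, "w1")
        assert res.iloc[0]["epiallele"] in ("01", "11")

    def test_identical_groups_zero_contributions(self):
        per_sample = {"a1": {"00": 5, "11": 5}, "b1": {"00": 5, "11": 5}}
        counts = long_counts(per_sample)
        res = driver_species(counts, meta({"a1": "A", "b1": "B"}), "w1")
        assert np.allclose(res["contribution"], 0.0)

    def test_contributions_sum_to_mean_bray_curtis(self):
        rng = np.random.default_rng(11)
        per_sample = {f"a{i}": mixture_counts(rng, {"00": 0.6, "01": 0.2, "11": 0.2})
                      for i in range(3)}
        per_sample.update({f"b{i}": mixture_counts(rng, {"00": 0.2, "01": 0.2, "11": 0.6})
                           for i in range(3)})
        groups = {s: s[0].upper() for s in per_sample}
        counts = long_counts(per_sample)
        res = driver_species(counts, meta(groups), "w1")
        freq = composition_matrix(counts)
        bc = []
        for sa in [s for s in freq.index if s.startswith("a")]:
            for sb in [s for s in freq.index if s.startswith("b")]:
                bc.append(pdist(freq.loc[[sa, sb]], "braycurtis")[0])
        assert res["contribution"].sum() == pytest.approx(np.mean(bc), abs=1e-12)


def summaries_frame(values_by_sample, statistic="shannon", window_id="w1"):
    rows = [(window_id, s, v) for s, v in values_by_sample.items()]
    return pd.DataFrame(rows, columns=["window_id", "sample_id", statistic])


class TestDiffstat:
    def test_identical_groups_p_one(self):
        vals = {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 1.0, "b2": 2.0, "b3": 3.0}
        m = meta({s: s[0].upper() for s in vals})
        res = diffstat(summaries_frame(vals), m, "shannon")
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_exact_p(self):
        """Fully separated 4+4 design: exact two-sided rank-sum p = 2/70."""
        vals = {f"a{i}": 0.0 for i in range(4)} | {f"b{i}": 2.0 for i in range(4)}
        m = meta({s: s[0].upper() for s in vals})
        res = diffstat(summaries_frame(vals), m, "shannon", min_per_group=3)
        assert res["p"].iloc[0] == pytest.approx(2 / 70, abs=1e-12)
        assert res["test"].iloc[0] == "wilcoxon"
        assert res["median_A"].iloc[0] == 0.0 and res["median_B"].iloc[0] == 2.0

    def test_matches_scipy_exact_on_random_data(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x, y = rng.normal(size=6), rng.normal(size=6)
            u, p = rank_sum_test(x, y)
            ref = mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert abs(p - ref.pvalue) < 1e-8
            assert abs(u - ref.statistic) < 1e-8

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(1.0, size=15)
        u, p = rank_sum_test(x, y)
        ref = mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_three_groups_use_kruskal_wallis(self):
        vals = ({f"a{i}": float(i) for i in range(3)}
                | {f"b{i}": float(i) + 5 for i in range(3)}
                | {f"c{i}": float(i) + 10 for i in range(3)})
        m = meta({s: s[0].upper() for s in vals})
        res = diffstat(summaries_frame(vals), m, "shannon")
        assert res["test"].iloc[0] == "kruskal-wallis"
        ref_stat, ref_p = kruskal([0, 1, 2], [5, 6, 7], [10, 11, 12])
        assert res["statistic"].iloc[0] == pytest.approx(ref_stat)
        assert res["p"].iloc[0] == pytest.approx(ref_p)

    def test_constant_window_flagged_degenerate(self):
        vals = {s: 1.5 for s in ("a1", "a2", "a3", "b1", "b2", "b3")}
        m = meta({s: s[0].upper() for s in vals})
        res = diffstat(summaries_frame(vals), m, "shannon")
        assert res["degenerate"].iloc[0]
        assert res["p"].iloc[0] == 1.0

    def test_missing_statistic_rejected(self):
        with pytest.raises(ValueError, match="not in the summary table"):
            diffstat(summaries_frame({"a1": 1.0}), meta({"a1": "A"}), "nope")


class TestDiffmodel:
    def simulate(self, slope_b_offset, seed=0, n_per_group=12, noise=0.05, n_windows=1):
        rng = np.random.default_rng(seed)
        rows, mrows = [], []
        for g, slope in (("A", 0.5), ("B", 0.5 + slope_b_offset)):
            for i in range(n_per_group):
                s = f"{g}{i}"
                t = float(i % 4)
                for w in range(n_windows):
                    value = 1.0 + (0.3 if g == "B" else 0.0) + slope * t + rng.normal(0, noise)
                    rows.append((f"w{w}", s, value))
                mrows.append((s, g, t))
        summaries = pd.DataFrame(rows, columns=["window_id", "sample_id", "shannon"])
        metadata = pd.DataFrame(mrows, columns=["sample_id", "group", "time"])
        return summaries, metadata

    def test_equal_slopes_distinct_intercepts(self):
        """With no interaction planted, the interaction term rejects at roughly
        the nominal rate while the group effect is detected throughout."""
        summaries, metadata = self.simulate(0.0, seed=1, n_windows=40)
        res = diffmodel(summaries, metadata, "shannon", covariate_col="time")
        assert (res["p_interaction"] < 0.05).mean() <= 0.2
        assert (res["p_group"] < 0.01).all()

    def test_planted_slopes_recovered(self):
        summaries, metadata = self.simulate(0.4, seed=2)
        res = diffmodel(summaries, metadata, "shannon", covariate_col="time")
        assert res["slope_A"].iloc[0] == pytest.approx(0.5, abs=0.1)
        assert res["slope_B"].iloc[0] == pytest.approx(0.9, abs=0.1)
        assert res["p_interaction"].iloc[0] < 0.01

    def test_rank_deficient_window_skipped(self):
        summaries, metadata = self.simulate(0.0, seed=3)
        metadata["time"] = 1.0  # covariate constant: no slope identifiable
        res = diffmodel(summaries, metadata, "shannon", covariate_col="time")
        assert not res["tested"].iloc[0]


class TestOrdination:
    def two_group_counts(self, seed=0):
        rng = np.random.default_rng(seed)
        per_sample = {f"a{i}": mixture_counts(rng, {"00": 0.9, "11": 0.1}) for i in range(4)}
        per_sample |= {f"b{i}": mixture_counts(rng, {"11": 0.9, "00": 0.1}) for i in range(4)}
        groups = {s: s[0].upper() for s in per_sample}
        return long_counts(per_sample), meta(groups)

    def test_pca_first_axis_separates_groups(self):
        counts, m = self.two_group_counts(1)
        scores, explained = ordinate(counts, m, "w1", method="PCA")
        a = scores.loc[[s for s in scores.index if s.startswith("a")], "PC1"]
        b = scores.loc[[s for s in scores.index if s.startswith("b")], "PC1"]
        assert (a.max() < b.min()) or (b.max() < a.min())
        assert explained[0] > 0.5

    def test_identical_samples_collapse_to_origin(self):
        counts = long_counts({f"s{i}": {"00": 10, "11": 10} for i in range(4)})
        m = meta({f"s{i}": "A" for i in range(4)})
        scores, _ = ordinate(counts, m, "w1", method="PCA")
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_cca_constrained_inertia_bounded(self):
        counts, m = self.two_group_counts(2)
        scores, explained = ordinate(counts, m, "w1", method="CCA")
        assert scores.shape[1] <= 1  # 2 groups -> at most 1 constrained axis
        assert 0 <= explained.sum() <= 1 + 1e-12

    def test_unknown_method_rejected(self):
        counts, m = self.two_group_counts(3)
        with pytest.raises(ValueError, match="PCA or CCA"):
            ordinate(counts, m, "w1", method="tSNE")


class TestAdjustFdr:
    def test_hand_computed_example(self):
        assert np.allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_dominates_raw(self, p):
        """Adjusted values respect the raw ordering, never fall below raw p,
        never exceed 1, and the step-up monotonization is stable."""
        q = adjust_fdr(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1 + 1e-12)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        # re-monotonizing the sorted adjusted values changes nothing
        q_sorted = q[order]
        assert np.allclose(np.minimum.accumulate(q_sorted[::-1])[::-1], q_sorted)


class TestSignificantRegions:
    def test_combined_filter(self):
        diff = pd.DataFrame({
            "window_id": ["w1", "w2", "w3"],
            "p": [0.01, 0.01, 0.2],
            "median_A": [1.0, 1.0, 1.0],
            "median_B": [1.5, 1.05, 1.5],
        })
        comp = pd.DataFrame({"window_id": ["w1", "w2", "w3"], "p": [0.02, 0.02, 0.02]})
        res = significant_regions(diff, comp, groups=("A", "B"))
        assert list(res["window_id"]) == ["w1"]  # w2 fails |dH|, w3 fails p
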