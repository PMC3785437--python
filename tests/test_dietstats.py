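from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from preydiet.assign import AssignmentResult
from preydiet.dietstats import (
    DietMatrix,
    anova_richness,
    amplicon_proportions,
    build_diet_matrix,
    occurrence,
    permanova,
)

from .oracles import anova_ss


def result(species, counts, status="assigned", amp_id="amp"):
    return AssignmentResult(
        amp_id, "ACGT", sum(counts.values()), counts, status, species, 1e-20, None
    )


def matrix_from(counts: dict[str, dict[str, int]], ages: dict[str, str]) -> DietMatrix:
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    df = df.sort_index()
    return DietMatrix(df, pd.Series(ages).loc[df.index].rename("age_class"))


class TestBuildDietMatrix:
    META = {"s1": "adult", "s2": "juvenile", "s3": "adult"}

    def test_negative_sample_retained_and_flagged(self):
        res = [result("spA", {"s1": 4}), result("spB", {"s2": 2})]
        m = build_diet_matrix(res, self.META, species=["spA", "spB"])
        assert list(m.negative_samples) == ["s3"]
        assert set(m.counts.index) == {"s1", "s2", "s3"}

    def test_presence_thresholds_at_one_amplicon(self):
        res = [result("spA", {"s1": 4}), result("spB", {"s1": 1})]
        m = build_diet_matrix(res, self.META, species=["spA", "spB"])
        assert m.presence.loc["s1"].tolist() == [True, True]

    def test_unknown_sample_is_an_error(self):
        with pytest.raises(ValueError, match="unknown sample"):
            build_diet_matrix([result("spA", {"sX": 1})], self.META)

    def test_zero_columns_kept_and_novel_species_added(self):
        res = [result("novel1", {"s1": 7}, status="novel")]
        m = build_diet_matrix(res, self.META, species=["spA", "spB"])
        assert list(m.counts.columns) == ["spA", "spB", "novel1"]
        assert m.counts["spA"].sum() == 0

    def test_unassigned_amplicons_ignored(self):
        res = [result(None, {"s1": 9}, status="unassigned")]
        m = build_diet_matrix(res, self.META, species=["spA"])
        assert m.counts.to_numpy().sum() == 0


class TestOccurrence:
    def test_fraction_over_positive_samples(self):
        m = matrix_from(
            {"s1": {"spA": 1}, "s2": {"spA": 2, "spB": 1}, "s3": {"spB": 3},
             "s4": {"spB": 1}, "s5": {}},
            dict.fromkeys([f"s{i}" for i in range(1, 6)], "adult"),
        )
        occ = occurrence(m)
        assert occ.n_positive == 4
        assert occ.occurrence["spA"] == 0.5
        assert occ.occurrence["spB"] == 0.75

    def test_absent_species_zero(self):
        m = matrix_from(
            {"s1": {"spA": 1, "spB": 0}, "s2": {"spA": 2, "spB": 0}},
            {"s1": "adult", "s2": "adult"},
        )
        assert occurrence(m).occurrence["spB"] == 0.0

    def test_richness_mean_and_se_hand_computed(self):
        # richness vector (2,3,4,5): mean 3.5, sd sqrt(5/3), se sd/2
        counts = {
            "s1": {f"sp{i}": 1 for i in range(2)},
            "s2": {f"sp{i}": 1 for i in range(3)},
            "s3": {f"sp{i}": 1 for i in range(4)},
            "s4": {f"sp{i}": 1 for i in range(5)},
        }
        m = matrix_from(counts, dict.fromkeys(counts, "adult"))
        occ = occurrence(m)
        assert occ.mean_richness == pytest.approx(3.5)
        assert occ.richness_se == pytest.approx(math.sqrt(5 / 3) / 2, abs=1e-4)
        assert occ.richness_se == pytest.approx(0.6455, abs=1e-4)

    def test_no_positive_samples_is_an_error(self):
        m = matrix_from({"s1": {"spA": 0}}, {"s1": "adult"})
        with pytest.raises(ValueError, match="no positive samples"):
            occurrence(m)

    def test_all_samples_denominator_matches_planted_probs(self):
        # ground-truth Bernoulli matrix at n=200: occurrence within binomial error
        rng = np.random.default_rng(123)
        probs = {"spA": 0.9, "spB": 0.5, "spC": 0.15}
        n = 200
        counts = {
            f"s{i}": {sp: int(rng.random() < p) for sp, p in probs.items()}
            for i in range(n)
        }
        m = matrix_from(counts, dict.fromkeys(counts, "adult"))
        occ = occurrence(m, denominator="all")
        for sp, p in probs.items():
            half_ci = 1.96 * math.sqrt(p * (1 - p) / n)
            assert abs(occ.occurrence[sp] - p) <= half_ci + 1e-9


class TestAnovaRichness:
    @staticmethod
    def matrix_with_richness(groups: dict[str, list[int]]) -> DietMatrix:
        counts, ages = {}, {}
        k = 0
        for age, richnesses in groups.items():
            for r in richnesses:
                sid = f"s{k:03d}"
                counts[sid] = {f"sp{i}": 1 for i in range(r)}
                ages[sid] = age
                k += 1
        return matrix_from(counts, ages)

    def test_identical_groups_give_f_zero_p_one(self):
        m = self.matrix_with_richness({"adult": [1, 2, 3], "juvenile": [1, 2, 3]})
        res = anova_richness(m)
        assert (res.f, res.p) == (0.0, 1.0)

    def test_zero_within_variance_flagged_degenerate(self):
        m = self.matrix_with_richness({"adult": [2, 2, 2], "juvenile": [4, 4, 4]})
        res = anova_richness(m)
        assert res.degenerate and res.p == 0.0 and math.isinf(res.f)

    def test_matches_sum_of_squares_and_scipy(self):
        groups = {"a": [3, 1, 2, 4], "b": [5, 4, 4, 6], "c": [2, 2, 3, 1]}
        m = self.matrix_with_richness(groups)
        res = anova_richness(m)
        f_oracle, df1, df2 = anova_ss(list(groups.values()))
        assert res.f == pytest.approx(f_oracle)
        assert (res.df1, res.df2) == (df1, df2)
        f_scipy, p_scipy = stats.f_oneway(*map(np.asarray, groups.values()))
        assert res.f == pytest.approx(f_scipy)
        assert res.p == pytest.approx(p_scipy)

    def test_two_group_f_equals_t_squared(self):
        g1, g2 = [2, 4, 3, 5, 1], [4, 6, 5, 7]
        m = self.matrix_with_richness({"a": g1, "b": g2})
        res = anova_richness(m)
        t, p_t = stats.ttest_ind(g1, g2)
        assert res.f == pytest.approx(t**2)
        assert res.p == pytest.approx(p_t)


def random_matrix(rng, n_per_group=12, n_species=8, shift=0.0):
    counts, ages = {}, {}
    for g, age in enumerate(["juvenile", "adult"]):
        base = 0.4 + shift * g
        for i in range(n_per_group):
            sid = f"s{g}_{i:02d}"
            row = {f"sp{j}": int(rng.random() < base) for j in range(n_species)}
            if not any(row.values()):
                row["sp0"] = 1
            counts[sid] = row
            ages[sid] = age
    return matrix_from(counts, ages)


class TestPermanova:
    def test_p_floor_when_observed_exceeds_all_permutations(self):
        # groups occupy disjoint species sets: maximal separation
        counts, ages = {}, {}
        for g, age in enumerate(["juvenile", "adult"]):
            for i in range(10):
                counts[f"s{g}_{i:02d}"] = {
                    f"sp{j}": int(j // 4 == g and j % 4 <= i % 3 + 1)
                    for j in range(8)
                }
                ages[f"s{g}_{i:02d}"] = age
        m = matrix_from(counts, ages)
        res = permanova(m, permutations=99, seed=1)
        assert res.p == pytest.approx(0.01)

    def test_reproducible_and_sample_order_invariant(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng)
        r1 = permanova(m, permutations=199, seed=42)
        r2 = permanova(m, permutations=199, seed=42)
        shuffled_idx = list(m.counts.index)[::-1]
        m_shuffled = DietMatrix(
            m.counts.loc[shuffled_idx], m.age_class.loc[shuffled_idx]
        )
        r3 = permanova(m_shuffled, permutations=199, seed=42)
        assert r1.p == r2.p == r3.p
        assert r1.pseudo_f == pytest.approx(r3.pseudo_f)

    def test_pseudo_f_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(9)
        m = random_matrix(rng, n_per_group=9)
        res = permanova(m, permutations=99, seed=0)
        dm = skbio_stats.DistanceMatrix(
            squareform(pdist(m.presence.loc[sorted(m.counts.index)].to_numpy(bool),
                             "jaccard")),
            ids=sorted(m.counts.index),
        )
        ref = skbio_stats.permanova(
            dm, grouping=m.age_class.loc[sorted(m.counts.index)].to_list(),
            permutations=99,
        )
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_identical_composition_groups_not_significant(self):
        # the two groups hold the same multiset of compositions
        rows = [
            {"spA": 1, "spB": 0, "spC": 1},
            {"spA": 1, "spB": 1, "spC": 0},
            {"spA": 0, "spB": 1, "spC": 1},
            {"spA": 1, "spB": 1, "spC": 1},
        ]
        counts, ages = {}, {}
        k = 0
        for age in ("juvenile", "adult"):
            for row in rows:
                counts[f"s{k}"] = dict(row)
                ages[f"s{k}"] = age
                k += 1
        m = matrix_from(counts, ages)
        res = permanova(m, permutations=199, seed=3)
        assert res.p > 0.05

    def test_empty_or_single_group_is_an_error(self):
        m = matrix_from(
            {"s1": {"spA": 1}, "s2": {"spA": 1}}, {"s1": "adult", "s2": "adult"}
        )
        with pytest.raises(ValueError, match="two groups"):
            permanova(m, permutations=99)


class TestAmpliconProportions:
    def test_fractions_sum_to_one(self):
        m = matrix_from(
            {"s1": {"spA": 40, "spB": 10}, "s2": {"spA": 40, "spB": 10}},
            {"s1": "adult", "s2": "adult"},
        )
        props = amplicon_proportions(m)
        assert props.sum() == pytest.approx(1.0)
        assert props["spA"] == pytest.approx(0.8)
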