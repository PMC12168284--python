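"""CLR geometry, diversity, PERMANOVA and effect sizes against
independent oracles (hand evaluation, exhaustive enumeration, scikit-bio)."""

import itertools

import numpy as np
import pandas as pd
import pytest

import plaquestab as ps
from plaquestab.composition import DistanceMatrix

from conftest import random_table


class TestClr:
    def test_equal_composition_maps_to_zero(self):
        table = ps.FeatureTable(
            pd.DataFrame([[1, 1, 1, 1]], index=["s"], columns=list("abcd"))
        )
        clr = ps.clr_transform(table, pseudocount=0.37)
        np.testing.assert_allclose(clr.values, 0.0, atol=1e-12)

    def test_two_part_composition_matches_hand_formula(self):
        # row (1, 4): clr = (log1 - m, log4 - m), m = (log1+log4)/2 → ±log2
        table = ps.FeatureTable(pd.DataFrame([[1, 4]], index=["s"], columns=["a", "b"]))
        clr = ps.clr_transform(table, pseudocount=1e-9)
        np.testing.assert_allclose(
            clr.values[0], [-np.log(2), np.log(2)], atol=1e-6
        )

    def test_scale_invariance_in_small_pseudocount_limit(self):
        base = pd.DataFrame([[2, 8, 10]], index=["s"], columns=list("abc"))
        a = ps.clr_transform(ps.FeatureTable(base), 1e-10)
        b = ps.clr_transform(ps.FeatureTable(base * 7), 1e-10)
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        clr = ps.clr_transform(random_table(rng, 6, 9))
        np.testing.assert_allclose(clr.values.sum(axis=1), 0.0, atol=1e-9)

    def test_nonpositive_pseudocount_rejected(self, toy_table):
        with pytest.raises(ValueError, match="pseudocount"):
            ps.clr_transform(toy_table, 0.0)


class TestAitchison:
    def test_identical_rows_zero_distance(self):
        table = ps.FeatureTable(
            pd.DataFrame([[3, 5], [3, 5]], index=["a", "b"], columns=["x", "y"])
        )
        dist = ps.aitchison_distance(ps.clr_transform(table))
        assert dist.get("a", "b") == 0.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            clr = ps.clr_transform(random_table(rng))
            dist = ps.aitchison_distance(clr)
            v = clr.values
            for i in range(len(v)):
                for j in range(len(v)):
                    oracle = np.sqrt(sum((v[i, k] - v[j, k]) ** 2 for k in range(v.shape[1])))
                    assert abs(dist.values[i, j] - oracle) < 1e-10

    def test_taxon_permutation_invariance(self):
        rng = np.random.default_rng(2)
        table = random_table(rng)
        shuffled = ps.FeatureTable(table.data[list(reversed(table.taxon_ids))])
        d1 = ps.aitchison_distance(ps.clr_transform(table))
        d2 = ps.aitchison_distance(ps.clr_transform(shuffled))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)


class TestAlphaDiversity:
    def test_observed_counts_nonzero_taxa(self):
        table = ps.FeatureTable(
            pd.DataFrame([[5, 5, 0, 0]], index=["s"], columns=list("abcd"))
        )
        assert ps.alpha_diversity(table, "observed").loc["s"] == 2

    def test_shannon_uniform_two_part_is_log2(self):
        table = ps.FeatureTable(
            pd.DataFrame([[5, 5, 0, 0]], index=["s"], columns=list("abcd"))
        )
        assert ps.alpha_diversity(table, "shannon").loc["s"] == pytest.approx(np.log(2))

    def test_shannon_single_taxon_is_zero(self):
        table = ps.FeatureTable(
            pd.DataFrame([[10, 0, 0, 0]], index=["s"], columns=list("abcd"))
        )
        assert ps.alpha_diversity(table, "shannon").loc["s"] == 0.0

    def test_all_zero_sample_warns_and_scores_zero(self):
        table = ps.FeatureTable(
            pd.DataFrame([[0, 0]], index=["s"], columns=["a", "b"])
        )
        with pytest.warns(UserWarning, match="all-zero"):
            assert ps.alpha_diversity(table, "observed").loc["s"] == 0


def _toy_distance(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(ids, d)


def _oracle_exhaustive_p(dist, labels):
    """Independent brute force: pseudo-F over all label permutations."""

    def pseudo_f(lab):
        lab = np.asarray(lab)
        n = len(lab)
        uniq = sorted(set(lab))
        d2 = dist.values**2
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            ss_w += sum(d2[i, j] for i, j in itertools.combinations(idx, 2)) / len(idx)
        ss_b = ss_t - ss_w
        return (ss_b / (len(uniq) - 1)) / (ss_w / (n - len(uniq)))

    f_obs = pseudo_f(labels)
    perms = set(itertools.permutations(labels))
    ge = sum(1 for p in perms if pseudo_f(p) >= f_obs - 1e-12)
    return ge / len(perms), f_obs


class TestPermanova:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
        dist = _toy_distance(pts)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = ps.permanova(dist, labels, exhaustive=True)
        p_oracle, f_oracle = _oracle_exhaustive_p(dist, labels)
        assert res.n_perm == 20
        assert res.p == pytest.approx(p_oracle, abs=0)
        assert res.pseudo_F == pytest.approx(f_oracle, rel=1e-12)

    def test_pseudo_f_matches_scikit_bio(self):
        skbio_dist = pytest.importorskip("skbio").DistanceMatrix
        skbio_permanova = pytest.importorskip("skbio.stats.distance").permanova
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 4))
        labels = ["a"] * 6 + ["b"] * 6
        dist = _toy_distance(pts)
        ours = ps.permanova(dist, labels, n_perm=99, seed=0)
        theirs = skbio_permanova(
            skbio_dist(dist.values, ids=dist.ids), grouping=list(labels), permutations=99
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_copied_groups_give_negligible_r2(self):
        pts = np.random.default_rng(5).normal(size=(6, 3))
        dist = _toy_distance(np.vstack([pts, pts]))
        res = ps.permanova(dist, ["a"] * 6 + ["b"] * 6, exhaustive=True)
        assert res.R2 == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.9

    def test_separated_clusters_reach_minimum_p(self):
        pts = np.vstack(
            [np.random.default_rng(6).normal(0, 0.1, (8, 2)),
             np.random.default_rng(7).normal(50, 0.1, (8, 2))]
        )
        res = ps.permanova(_toy_distance(pts), ["a"] * 8 + ["b"] * 8, n_perm=99, seed=1)
        assert res.p == pytest.approx(1 / 100)

    def test_singleton_group_rejected(self):
        pts = np.random.default_rng(8).normal(size=(5, 2))
        with pytest.raises(ValueError, match="singleton"):
            ps.permanova(_toy_distance(pts), ["a", "a", "a", "a", "b"])

    def test_r2_plus_within_fraction_is_one(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        dist = _toy_distance(pts)
        res = ps.permanova(dist, labels, n_perm=9, seed=0)
        d2 = dist.values**2
        n = 10
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = sum(
            d2[np.ix_(idx, idx)][np.triu_indices(5, 1)].sum() / 5
            for idx in (range(5), range(5, 10))
        )
        assert res.R2 + ss_w / ss_t == pytest.approx(1.0, abs=1e-12)

    def test_unit_permutation_requires_consistent_labels(self):
        pts = np.random.default_rng(10).normal(size=(6, 2))
        dist = _toy_distance(pts)
        with pytest.raises(ValueError, match="mixes group labels"):
            ps.permanova(
                dist, ["a", "b", "a", "a", "b", "b"],
                units=["u1", "u1", "u2", "u2", "u3", "u3"], n_perm=9,
            )

    def test_unit_permutation_keeps_repeated_measures_together(self):
        # two samples per unit; exhaustive over units = exhaustive over 3v3
        rng = np.random.default_rng(11)
        unit_pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(2, 1, (3, 2))])
        pts = np.repeat(unit_pts, 2, axis=0) + rng.normal(0, 0.01, (12, 2))
        labels = ["a"] * 6 + ["b"] * 6
        units = [f"u{i // 2}" for i in range(12)]
        res = ps.permanova(_toy_distance(pts), labels, units=units, exhaustive=True)
        assert res.n_perm == 20  # C(6,3) unit assignments, not C(12,6)


class TestEffectSizes:
    def test_identical_groups_d_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        es = ps.cohens_d(x, x + 1e-9)
        assert es.cohens_d == pytest.approx(0.0, abs=1e-6)
        assert es.ci_low <= es.cohens_d <= es.ci_high

    def test_constant_shift_matches_closed_form(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 2.0, 500)
        c = 1.3
        es = ps.cohens_d(x + c, x)
        assert es.cohens_d == pytest.approx(c / x.std(ddof=1), rel=1e-9)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            ps.cohens_d([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_kruskal_on_identical_groups_is_nonsignificant(self):
        vals = np.array([1.0, 2.0, 3.0] * 3)
        labels = np.repeat(["a", "b", "c"], 3)
        assert ps.group_test(vals, labels) > 0.9

    def test_two_group_shift_detected(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 40)
        y = rng.normal(3, 1, 40)
        labels = np.array(["x"] * 40 + ["y"] * 40)
        assert ps.group_test(np.concatenate([x, y]), labels) < 1e-6


def test_rescaling_invariance_improves_with_depth():
    """Aitchison distance under per-sample rescaling: deviation shrinks as
    depth grows (pseudocount fixed at the default)."""
    rng = np.random.default_rng(14)
    base = rng.dirichlet(np.ones(12) * 2, size=6)
    deviations = []
    for depth in (100, 1000, 10000):
        counts = np.round(base * depth).astype(int)
        t1 = ps.FeatureTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(6)],
                         columns=[f"t{j}" for j in range(12)])
        )
        t2 = ps.FeatureTable(t1.data * 3)
        d1 = ps.aitchison_distance(ps.clr_transform(t1))
        d2 = ps.aitchison_distance(ps.clr_transform(t2))
        deviations.append(np.abs(d1.values - d2.values).max())
    assert deviations[0] >= deviations[1] >= deviations[2]
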