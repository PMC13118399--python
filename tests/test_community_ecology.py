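"""Rarefaction, dominance filtering, Bray-Curtis/PCoA and PERMANOVA against
independent oracles (hypergeometric expectation, hand formulas, scikit-bio,
exhaustive permutation)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aggrekey import StudyDesign
from aggrekey.community_ecology import (AbundanceTable, bray_curtis,
                                        dominant_genera, pcoa, permanova,
                                        rarefy, remove_amf_from_its)


def table(matrix, samples=None, kingdom="bacteria", **kw):
    matrix = np.asarray(matrix)
    genera = [f"B_g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return AbundanceTable(pd.DataFrame(matrix, index=genera, columns=samples),
                         kingdom=kingdom, **kw)


class TestAMFRemoval:
    def test_flagged_genera_removed_and_relabelled(self):
        t = table(np.ones((5, 3)), kingdom="nonamf")
        tax = {"B_g0": "Glomeromycota", "B_g3": "glomeromycota",
               "B_g1": "Ascomycota"}
        out = remove_amf_from_its(t, tax)
        assert out.genera == ["B_g1", "B_g2", "B_g4"]
        assert out.kingdom == "nonamf"

    def test_no_amf_is_identity(self):
        t = table(np.arange(6).reshape(3, 2) + 1, kingdom="nonamf")
        out = remove_amf_from_its(t, {"B_g0": "Ascomycota"})
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_matches_independent_set_difference(self, rng):
        t = table(rng.integers(0, 9, size=(20, 4)), kingdom="nonamf")
        tax = {g: ("Glomeromycota" if rng.random() < 0.3 else "Other")
               for g in t.genera}
        out = remove_amf_from_its(t, tax)
        expected = [g for g in t.genera if tax[g] != "Glomeromycota"]
        assert out.genera == expected


class TestRarefy:
    def test_column_sums_hit_depth_and_zeros_preserved(self, rng):
        counts = rng.integers(0, 50, size=(30, 5))
        counts[5] = 0
        t = table(counts)
        depth = int(counts.sum(axis=0).min())
        out = rarefy(t, "min", seed=3)
        assert (out.data.sum(axis=0) == depth).all()
        assert (out.data.loc["B_g5"] == 0).all()

    def test_identity_at_full_depth(self):
        t = table([[4, 7], [6, 3]])
        out = rarefy(t, 10, seed=0)
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_forced_subsample(self):
        t = table([[10, 10], [0, 10]])
        out = rarefy(t, 5, seed=0)
        assert out.data.iloc[1, 0] == 0 and out.data.iloc[0, 0] == 5

    def test_depth_above_total_rejected(self):
        with pytest.raises(ValueError):
            rarefy(table([[3], [4]]), 100)

    def test_expectation_matches_hypergeometric(self):
        """Mean rarefied count over many draws approaches depth*c/T, the
        hypergeometric mean (3-SE band)."""
        counts = np.array([[60], [25], [10], [5]])
        t = table(counts)
        depth, n_rep = 40, 400
        acc = np.zeros(4)
        for s in range(n_rep):
            acc += rarefy(t, depth, seed=s).data.to_numpy()[:, 0]
        mean = acc / n_rep
        total = counts.sum()
        expected = depth * counts[:, 0] / total
        var = (depth * (counts[:, 0] / total) * (1 - counts[:, 0] / total)
               * (total - depth) / (total - 1))
        se = np.sqrt(var / n_rep)
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-9)


class TestDominantGenera:
    def test_strict_boundary(self):
        t = table([[1.0], [999.0]]).to_relative()
        # genus 0 sits exactly at 0.1% of the community
        assert dominant_genera(t, cutoff=0.001) == ["B_g1"]

    def test_all_above_cutoff_retained(self):
        t = table(np.full((4, 3), 5.0)).to_relative()
        assert dominant_genera(t, 0.001) == t.genera

    def test_matches_brute_force_mean_filter(self, rng):
        t = table(rng.uniform(0, 5, size=(40, 6))).to_relative()
        cutoff = 0.02
        expected = [g for g in t.genera
                    if t.data.loc[g].mean() > cutoff]
        assert dominant_genera(t, cutoff) == expected


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        t = table([[3, 3, 5, 0], [1, 1, 0, 2], [2, 2, 0, 7]])
        d = bray_curtis(t)
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[2, 3] == pytest.approx(1.0)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_three_sample_hand_computation(self):
        t = table([[6, 1, 0], [2, 3, 4]])
        d = bray_curtis(t)
        assert d.iloc[0, 1] == pytest.approx((5 + 1) / (8 + 4))
        assert d.iloc[0, 2] == pytest.approx((6 + 2) / (6 + 6))
        assert d.iloc[1, 2] == pytest.approx((1 + 1) / (1 + 7))

    def test_bounded_and_genus_order_invariant(self, rng):
        m = rng.uniform(0, 10, size=(12, 6))
        d1 = bray_curtis(table(m))
        d2 = bray_curtis(table(m[::-1]))
        assert np.allclose(d1, d2)
        assert (d1.to_numpy() >= 0).all() and (d1.to_numpy() <= 1).all()


class TestPCoA:
    def test_recovers_points_on_a_line(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]))
        res = pcoa(d)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        r = np.corrcoef(axis1, x)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_distances_give_zero_coordinates(self):
        res = pcoa(pd.DataFrame(np.zeros((4, 4))))
        assert np.allclose(res.coordinates, 0)

    def test_positive_eigenvalue_fractions_sum_to_one(self, rng):
        m = rng.uniform(0, 10, size=(10, 5))
        res = pcoa(bray_curtis(table(m)))
        pos = res.proportion_explained[res.eigenvalues > 0]
        assert pos.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        m = rng.uniform(0, 10, size=(15, 7))
        d = bray_curtis(table(m))
        mine = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            method="eigh")
        ref_e = np.sort(ref.eigvals.to_numpy())[::-1]
        assert mine.eigenvalues == pytest.approx(ref_e, abs=1e-8)
        assert np.abs(mine.coordinates.iloc[:, 0].to_numpy()) == pytest.approx(
            np.abs(ref.samples.iloc[:, 0].to_numpy()), abs=1e-8)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            pcoa(d)


def _brute_force_pseudo_f(d, labels):
    """Independent PERMANOVA statistic from first principles."""
    d = np.asarray(d)
    n = len(labels)
    groups = sorted(set(labels))
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_w += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    a = len(groups)
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    @pytest.fixture
    def toy(self, rng):
        design = StudyDesign.balanced(["A", "B"], 3)
        m = rng.uniform(0, 10, size=(8, 6))
        t = AbundanceTable(pd.DataFrame(
            m, index=[f"B_g{i}" for i in range(8)], columns=design.samples),
            kingdom="bacteria")
        return bray_curtis(t), design

    def test_exact_p_equals_exhaustive_enumeration(self, toy):
        d, design = toy
        f, p = permanova(d, design, n_perm="exact")
        labels = design.treatment_of(d.index).to_numpy()
        f_ref = _brute_force_pseudo_f(d, labels)
        assert f == pytest.approx(f_ref)
        hits = sum(
            _brute_force_pseudo_f(d, labels[list(perm)]) >= f - 1e-12
            for perm in itertools.permutations(range(6)))
        assert p == pytest.approx(hits / 720)

    def test_separated_clusters_saturate_p(self):
        """Perfectly separated clusters give the smallest attainable p.

        Permutations preserving the two-cluster partition reproduce the
        observed pseudo-F exactly and are counted as ties (the conservative
        >= convention), so the floor is the partition-preserving
        permutation probability (2*4!*4!/8! ~ 2.9%), not 1/(1+n_perm)."""
        design = StudyDesign.balanced(["A", "B"], 4)
        x = np.array([0.0, 0.1, 0.2, 0.3, 10.0, 10.1, 10.2, 10.3])
        d = pd.DataFrame(np.abs(x[:, None] - x[None, :]),
                         index=design.samples, columns=design.samples)
        f, p = permanova(d, design, n_perm=999, seed=5)
        tie_rate = 2 * 24 * 24 / 40320
        assert p < 0.05
        assert p == pytest.approx(tie_rate, abs=0.02)

    def test_statistic_matches_scikit_bio(self, toy):
        skbio = pytest.importorskip("skbio")
        d, design = toy
        f, _ = permanova(d, design, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=design.treatment_of(d.index).to_numpy(), permutations=9)
        assert f == pytest.approx(ref["test statistic"])

    def test_seeded_reproducibility(self, toy):
        d, design = toy
        assert permanova(d, design, 199, seed=11) == \
            permanova(d, design, 199, seed=11)

    def test_single_group_rejected(self, toy):
        d, _ = toy
        design = StudyDesign.balanced(["A"], 6)
        d = d.set_axis(design.samples).set_axis(design.samples, axis=1)
        with pytest.raises(ValueError):
            permanova(d, design, 99)
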