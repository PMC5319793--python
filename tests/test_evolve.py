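"""Divergence metrics, neighbour joining, dating, clustering."""

import io as _io

import numpy as np
import pandas as pd
import pytest

from editevol import evolve


class TestDivergence:
    def test_identical_is_zero(self):
        a = [0.1, 0.4, 0.2, 0.7]
        assert evolve.editing_divergence(a, a) == pytest.approx(0.0)

    def test_reversed_ranks_is_two(self):
        assert evolve.editing_divergence([1, 2, 3, 4], [4, 3, 2, 1]) == \
            pytest.approx(2.0)

    def test_worked_three_site_example(self):
        # d^2 = (0, 1, 1) -> rho = 1 - 6*2/(3*8) = 0.5
        d = evolve.editing_divergence([0.1, 0.3, 0.2], [0.1, 0.2, 0.3])
        assert d == pytest.approx(0.5)

    def test_undefined_below_three_sites(self):
        assert np.isnan(evolve.editing_divergence([0.1, np.nan, 0.2],
                                                  [0.3, 0.4, np.nan]))

    def test_symmetry(self, rng):
        a = rng.uniform(size=20)
        b = rng.uniform(size=20)
        assert evolve.editing_divergence(a, b) == \
            pytest.approx(evolve.editing_divergence(b, a))


def _tree_distances(newick):
    from skbio import TreeNode
    t = TreeNode.read(_io.StringIO(newick))
    tips = list(t.tips())
    names = [x.name for x in tips]
    d = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            d.loc[a.name, b.name] = d.loc[b.name, a.name] = a.distance(b)
    return d


def _splits(tree):
    leaves = frozenset(x.name for x in tree.tips())
    out = set()
    for n in tree.non_tips(include_self=False):
        s = frozenset(x.name for x in n.tips())
        if 1 < len(s) < len(leaves) - 1:
            out.add(frozenset([s, leaves - s]))
    return out


class TestNeighborJoining:
    def test_additive_four_taxon_matrix(self):
        d = _tree_distances("((A:1,B:2):1,(C:3,D:4):1);")
        tree = evolve.build_nj_tree(d)
        assert _splits(tree) == _splits(
            __import__("skbio").TreeNode.read(
                _io.StringIO("((A:1,B:2):1,(C:3,D:4):1);")))
        # path lengths are reproduced exactly on additive input
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    ta = tree.find(a)
                    assert ta.distance(tree.find(b)) == pytest.approx(
                        d.loc[a, b])

    def test_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = evolve.build_nj_tree(d)
        # three-point solution: a = (3+4-5)/2 = 1, b = 2, c = 3
        lens = {t.name: t.length for t in tree.tips()}
        assert lens["A"] == pytest.approx(1.0)
        assert lens["B"] == pytest.approx(2.0)
        assert lens["C"] == pytest.approx(3.0)

    def test_random_additive_matrices_recovered(self, rng):
        from skbio import TreeNode
        for _ in range(20):
            bl = rng.uniform(0.5, 3.0, size=9)
            nwk = (f"((A:{bl[0]},B:{bl[1]}):{bl[2]},(C:{bl[3]},D:{bl[4]}):"
                   f"{bl[5]},(E:{bl[6]},F:{bl[7]}):{bl[8]});")
            d = _tree_distances(nwk)
            tree = evolve.build_nj_tree(d)
            assert _splits(tree) == _splits(TreeNode.read(_io.StringIO(nwk)))

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError):
            evolve.build_nj_tree(d)


class TestRegression:
    def test_perfectly_linear(self):
        t = np.array([5, 10, 30, 45, 60], dtype=float)
        d = 0.01 * t
        slope, intercept, rho = evolve.divergence_time_regression(d, t)
        assert slope == pytest.approx(0.01)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert rho == pytest.approx(1.0)

    def test_constant_time_undefined(self):
        with pytest.raises(ValueError):
            evolve.divergence_time_regression([0.1, 0.2, 0.3], [5, 5, 5])

    def test_permuted_pairing_kills_correlation(self, rng):
        rhos = []
        for _ in range(30):
            t = rng.uniform(1, 60, 12)
            d = rng.permutation(0.01 * t)
            rhos.append(evolve.divergence_time_regression(d, t)[2])
        assert abs(np.mean(rhos)) < 0.2


class TestEditingStatus:
    def test_edited(self):
        assert evolve.call_editing_status([0.025], [100]) == "edited"

    def test_unedited_needs_coverage_everywhere(self):
        assert evolve.call_editing_status([0.01, 0.0], [50, 30]) == "unedited"
        assert evolve.call_editing_status([0.01], [15]) == "undefined"

    def test_non_a_dna_is_unedited(self):
        assert evolve.call_editing_status([0.5], [100], dna_base="G") == \
            "unedited"


class TestAssignAge:
    ORDER = ["mel", "sim", "yak", "ana", "pse", "vir"]

    def test_most_distant_edited_species(self):
        status = {"mel": "edited", "sim": "edited", "yak": "unedited",
                  "ana": "unedited", "pse": "unedited", "vir": "undefined"}
        age = evolve.assign_age("s1", status, self.ORDER)
        assert age.dated and age.age_class == "sim"

    def test_intervening_losses_allowed(self):
        status = {"mel": "edited", "sim": "unedited", "yak": "unedited",
                  "ana": "unedited", "pse": "edited", "vir": "unedited"}
        age = evolve.assign_age("s1", status, self.ORDER)
        assert age.age_class == "pse"

    def test_undated_below_five_defined(self):
        status = {"mel": "edited", "sim": "edited", "yak": "unedited",
                  "ana": "undefined", "pse": "undefined", "vir": "undefined"}
        age = evolve.assign_age("s1", status, self.ORDER)
        assert not age.dated and age.age_class is None

    def test_unedited_anchor_is_error(self):
        status = {sp: "unedited" for sp in self.ORDER}
        with pytest.raises(ValueError):
            evolve.assign_age("s1", status, self.ORDER)


class TestClustering:
    def test_worked_example(self):
        frac, sd = evolve.cluster_fraction([100, 120, 500], max_dist=30, rng=0)
        assert frac == pytest.approx(2 / 3)
        assert sd > 0

    def test_single_site_unclustered(self):
        assert evolve.cluster_fraction([42])[0] == 0.0

    def test_all_close(self):
        frac, _ = evolve.cluster_fraction([10, 15, 20, 25], max_dist=10, rng=0)
        assert frac == 1.0


class TestLevelDifference:
    def test_equal_levels(self):
        m = evolve.level_difference_metrics(0.4, 0.4)
        assert m["normalized_diff"] == 0.0
        assert m["conservation"] == 1.0

    def test_total_loss(self):
        m = evolve.level_difference_metrics(0.4, 0.0)
        assert m["normalized_diff"] == pytest.approx(2.0)
        assert m["conservation"] == pytest.approx(0.0)

    def test_worked_example(self):
        m = evolve.level_difference_metrics(0.3, 0.1)
        assert m["normalized_diff"] == pytest.approx(1.0)
        assert m["conservation"] == pytest.approx(0.5)
        # identity: conservation = 1 - normalized_diff / 2
        assert m["conservation"] == pytest.approx(1 - m["normalized_diff"] / 2)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            evolve.level_difference_metrics(0.0, 0.0)
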