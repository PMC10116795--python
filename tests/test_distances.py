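import io

import numpy as np
import pytest
import skbio

from krv.datatypes import CountTable, ValidationError
from krv.distances import (
    TreeIndex,
    bray_curtis,
    clr_transform,
    philr_basis,
    philr_transform,
    rarefy,
    unifrac,
)


# --------------------------------------------------------------------------
# rarefaction
# --------------------------------------------------------------------------

def test_rarefy_totals_and_determinism(random_table):
    depth = int(random_table.counts.sum(axis=1).min())
    r1 = rarefy(random_table, depth, seed=3)
    r2 = rarefy(random_table, depth, seed=3)
    assert np.array_equal(r1.counts, r2.counts)
    assert np.all(r1.counts.sum(axis=1) == depth)
    assert np.all(r1.counts <= random_table.counts)


def test_rarefy_row_order_invariance(random_table):
    depth = int(random_table.counts.sum(axis=1).min())
    perm = np.arange(random_table.n_samples)[::-1]
    direct = rarefy(random_table, depth, seed=5)
    shuffled = rarefy(random_table.subset(perm), depth, seed=5)
    assert np.array_equal(direct.counts[perm], shuffled.counts)


def test_rarefy_errors_on_shallow_samples(small_table):
    with pytest.raises(ValidationError, match="fewer than"):
        rarefy(small_table, 5, seed=0)


# --------------------------------------------------------------------------
# Bray-Curtis
# --------------------------------------------------------------------------

def test_bray_curtis_hand_value():
    # x=(6,2), y=(2,2): sum|x-y| = 4, sum(x+y) = 12 -> 1/3
    t = CountTable(["x", "y"], ["a", "b"], [[6, 2], [2, 2]])
    D = bray_curtis(t)
    assert D["x", "y"] == pytest.approx(1 / 3)


def test_bray_curtis_identical_samples_zero():
    t = CountTable(["x", "y"], ["a", "b"], [[3, 1], [3, 1]])
    assert bray_curtis(t)["x", "y"] == 0.0


# --------------------------------------------------------------------------
# UniFrac (hand-computed on the 3-leaf tree)
# --------------------------------------------------------------------------

def test_unweighted_unifrac_hand_values(small_table, small_tree):
    D = unifrac(small_table, small_tree, variant="unweighted")
    # s1={A,AB}, s2={C}: no shared branch -> 1
    assert D["s1", "s2"] == pytest.approx(1.0)
    # s1={A,AB} (len 2), s3={A,B,AB} (len 3): shared 2, union 3 -> 1/3
    assert D["s1", "s3"] == pytest.approx(1 / 3)


def test_weighted_unifrac_hand_value(small_table, small_tree):
    D = unifrac(small_table, small_tree, variant="weighted_normalized")
    # s1: p_A=1, p_AB=1; s3: p_A=.5, p_B=.5, p_AB=1
    # num = 1*.5 + 1*.5 + 1*0 = 1;  den = (1+1) + (.5+.5+1) = 4 -> 0.25
    assert D["s1", "s3"] == pytest.approx(0.25)
    # disjoint supports -> 1
    assert D["s1", "s2"] == pytest.approx(1.0)


def test_generalized_unifrac_alpha_one_equals_weighted(random_table, rng):
    from krv.simulate import random_bifurcating_tree

    tree = random_bifurcating_tree(random_table.taxon_ids, seed=8)
    Dg = unifrac(random_table, tree, variant="generalized", alpha=1.0)
    Dw = unifrac(random_table, tree, variant="weighted_normalized")
    assert np.allclose(Dg.data, Dw.data, atol=1e-12)


def test_unifrac_matches_skbio(random_table):
    from krv.simulate import random_bifurcating_tree
    from skbio.diversity import beta_diversity

    tree = random_bifurcating_tree(random_table.taxon_ids, seed=4)
    ids = [str(s) for s in random_table.sample_ids]
    taxa = [str(t) for t in random_table.taxon_ids]
    for variant, metric in (("unweighted", "unweighted_unifrac"),
                            ("weighted_normalized", "weighted_unifrac")):
        ours = unifrac(random_table, tree, variant=variant)
        kw = {"normalized": True} if variant.startswith("weighted") else {}
        ref = beta_diversity(metric, random_table.counts.astype(int), ids=ids,
                             taxa=taxa, tree=tree, validate=True, **kw)
        assert np.allclose(ours.data, ref.data, atol=1e-10), variant


def test_tree_index_rejects_missing_taxa(small_tree):
    t = CountTable(["s"], ["A", "Z"], [[1, 1]])
    with pytest.raises(ValidationError, match="absent"):
        TreeIndex(small_tree, t.taxon_ids)


# --------------------------------------------------------------------------
# CLR / PhILR
# --------------------------------------------------------------------------

def test_clr_hand_value():
    # counts (1,3), pseudo 1 -> log(2), log(4); clr = -/+ log(2)/2 = -/+0.346574
    t = CountTable(["s"], ["a", "b"], [[1, 3]])
    z = clr_transform(t)
    assert z.counts[0, 0] == pytest.approx(-np.log(2) / 2)
    assert z.counts[0, 1] == pytest.approx(np.log(2) / 2)
    assert z.counts.sum(axis=1) == pytest.approx(0.0)


def test_philr_uniform_basis_is_orthonormal():
    from krv.simulate import random_bifurcating_tree

    taxa = [f"t{i}" for i in range(9)]
    tree = random_bifurcating_tree(taxa, seed=2)
    V, labels = philr_basis(tree, taxa, weighting="uniform")
    assert V.shape == (9, 8)
    assert np.allclose(V.T @ V, np.eye(8), atol=1e-10)
    # every balance contrast is orthogonal to the constant vector
    assert np.allclose(V.sum(axis=0), 0.0, atol=1e-10)


def test_philr_blw_scales_uniform_columns():
    from krv.simulate import random_bifurcating_tree

    taxa = [f"t{i}" for i in range(7)]
    tree = random_bifurcating_tree(taxa, seed=3)
    Vu, _ = philr_basis(tree, taxa, weighting="uniform")
    Vb, _ = philr_basis(tree, taxa, weighting="blw")
    # each blw column is a positive multiple of the uniform column
    for k in range(Vu.shape[1]):
        nz = Vu[:, k] != 0
        ratios = Vb[nz, k] / Vu[nz, k]
        assert np.allclose(ratios, ratios[0])
        assert ratios[0] > 0


def test_philr_transform_shapes(random_table):
    from krv.simulate import random_bifurcating_tree

    tree = random_bifurcating_tree(random_table.taxon_ids, seed=5)
    out = philr_transform(random_table, tree)
    assert out.is_transformed
    assert out.counts.shape == (random_table.n_samples, random_table.n_taxa - 1)
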