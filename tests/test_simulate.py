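import numpy as np
import pytest

from krv.datatypes import CountTable, ValidationError
from krv.distances import TreeIndex, rarefy
from krv.simulate import (
    DMParams,
    SimulationConfig,
    ancestry_covariate,
    apply_confounding,
    apply_genetic_effect,
    estimate_dm_params,
    random_bifurcating_tree,
    run_type1_experiment,
    select_causal_variant,
    select_effect_clade,
    simulate_genotypes,
    simulate_otu_counts,
    synthesize_dm_params,
)


def test_dm_params_validation():
    with pytest.raises(ValidationError):
        DMParams(np.array([0.5, 0.6]), 0.01)  # does not sum to 1
    with pytest.raises(ValidationError):
        DMParams(np.array([0.5, 0.5]), 1.5)
    p = DMParams(np.array([0.25, 0.75]), 0.2)
    assert np.allclose(p.concentration, np.array([0.25, 0.75]) * 4.0)


def test_estimate_dm_params_recovers_truth():
    true = DMParams(synthesize_dm_params(n_taxa=50, theta=0.02).pi, 0.02)
    rng = np.random.default_rng(10)
    table = simulate_otu_counts(true, 2000, 1000, rng)
    est = estimate_dm_params(table)
    assert est.theta == pytest.approx(true.theta, rel=0.2)
    assert np.corrcoef(est.pi, true.pi)[0, 1] > 0.999
    assert np.max(np.abs(est.pi - true.pi)) < 0.01


def test_simulate_genotypes_structure():
    cfg = SimulationConfig(n_per_pop=40, n_variants=60, seed=0)
    G, labels = simulate_genotypes(cfg, np.random.default_rng(1))
    assert G.dosages.shape == (80, 60)
    assert set(np.unique(G.dosages)) <= {0.0, 1.0, 2.0}
    assert list(labels[:40]) == ["A"] * 40 and list(labels[40:]) == ["B"] * 40
    lo, hi = cfg.subregion_window
    pos = G.variants["pos"].to_numpy(int)
    assert ((pos >= lo) & (pos <= hi)).sum() >= cfg.n_subregion_variants
    assert np.all(np.diff(pos) >= 0)  # sorted positions


def test_ancestry_covariate_separates_populations():
    cfg = SimulationConfig(n_per_pop=60, n_variants=200, fst=0.1)
    G, labels = simulate_genotypes(cfg, np.random.default_rng(2))
    X = ancestry_covariate(G)
    pc = X.X[:, 1]
    assert pc.mean() == pytest.approx(0.0, abs=1e-10)
    assert pc.std() == pytest.approx(1.0)
    gap = abs(pc[labels == "A"].mean() - pc[labels == "B"].mean())
    assert gap > 1.0  # the leading PC captures the population split


def test_select_causal_variant_common_and_in_window():
    cfg = SimulationConfig(n_per_pop=50, n_variants=100)
    G, _ = simulate_genotypes(cfg, np.random.default_rng(3))
    idx = select_causal_variant(G, cfg)
    lo, hi = cfg.subregion_window
    assert lo <= int(G.variants["pos"].iloc[idx]) <= hi
    assert G.maf()[idx] >= cfg.maf_min


def _small_counts(n=8, q=30, depth=500, seed=4):
    params = synthesize_dm_params(n_taxa=q, theta=0.02)
    table = simulate_otu_counts(params, n, depth, np.random.default_rng(seed))
    return params, table


def test_confounding_t1_only_changes_top10_in_pop_a():
    params, table = _small_counts()
    labels = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
    out = apply_confounding(table, labels, "T1", params.pi,
                            np.random.default_rng(5))
    top10 = np.argsort(params.pi)[::-1][:10]
    mask = np.zeros(table.n_taxa, bool)
    mask[top10] = True
    # population B rows and non-top-10 columns are untouched
    assert np.array_equal(out.counts[4:], table.counts[4:])
    assert np.array_equal(out.counts[:4][:, ~mask], table.counts[:4][:, ~mask])
    # a 10% increase with stochastic rounding never decreases a count
    assert np.all(out.counts[:4][:, mask] >= table.counts[:4][:, mask])


def test_confounding_t2_adds_one_to_ten_rare_taxa():
    params, table = _small_counts()
    labels = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
    out = apply_confounding(table, labels, "T2", params.pi,
                            np.random.default_rng(6))
    diff = out.counts - table.counts
    assert np.array_equal(diff[4:], np.zeros_like(diff[4:]))
    changed = np.where(diff[:4].any(axis=0))[0]
    assert len(changed) == 10
    rare40 = set(np.argsort(params.pi)[:40].tolist())
    assert set(changed.tolist()) <= rare40
    assert np.all(diff[:4][:, changed] == 1)


def test_confounding_rarefies_when_depth_given():
    params, table = _small_counts(depth=600)
    labels = np.array(["A"] * 4 + ["B"] * 4, dtype=object)
    out = apply_confounding(table, labels, "T1", params.pi,
                            np.random.default_rng(7), depth=500, seed_rarefy=1)
    assert np.all(out.counts.sum(axis=1) == 500)
    with pytest.raises(ValidationError):
        apply_confounding(table, labels, "T1", params.pi,
                          np.random.default_rng(7), depth=500)


def test_genetic_effect_p1_multiplicative_carriers_only():
    params, table = _small_counts()
    g = np.array([0, 0, 2, 1, 0, 2, 0, 1], dtype=float)
    out = apply_genetic_effect(table, g, "P1", 0.5, params.pi,
                               np.random.default_rng(8))
    targets = np.argsort(params.pi)[::-1][10:20]
    noncarrier = g == 0
    assert np.array_equal(out.counts[noncarrier], table.counts[noncarrier])
    # carriers: multiplied then stochastically rounded, so within 1 of exact
    exact = table.counts[2, targets] * (1 + 0.5 * 2)
    assert np.all(np.abs(out.counts[2, targets] - exact) <= 1)


def test_genetic_effect_p3_additive_integer():
    params, table = _small_counts()
    g = np.array([0, 1, 2, 0, 0, 0, 1, 0], dtype=float)
    out = apply_genetic_effect(table, g, "P3", 1.0, params.pi,
                               np.random.default_rng(9))
    diff = out.counts - table.counts
    assert np.array_equal(diff[g == 0], np.zeros_like(diff[g == 0]))
    changed = np.where(diff.any(axis=0))[0]
    assert len(changed) == 5
    assert set(changed.tolist()) <= set(np.argsort(params.pi)[:40].tolist())
    # integer effect size: additive exactly c3 * g
    assert np.array_equal(diff[:, changed], np.outer(g, np.ones(5)).astype(int))


def test_random_tree_is_binary_with_all_leaves():
    taxa = [f"t{i}" for i in range(17)]
    tree = random_bifurcating_tree(taxa, seed=11)
    tips = sorted(leaf.name for leaf in tree.tips())
    assert tips == sorted(taxa)
    for node in tree.non_tips(include_self=True):
        assert len(node.children) == 2
    for node in tree.traverse(include_self=False):
        assert node.length >= 0


def test_select_effect_clade_within_bounds():
    params = synthesize_dm_params(n_taxa=80, theta=0.01)
    taxa = [f"t{j + 1:04d}" for j in range(80)]
    tree = random_bifurcating_tree(taxa, seed=12)
    index = TreeIndex(tree, np.array(taxa, dtype=object))
    clade = select_effect_clade(index, params.pi)
    total = params.pi[clade].sum()
    assert 0.05 <= total <= 0.20
    assert 2 <= len(clade) < 80


def test_run_type1_experiment_smoke_and_determinism():
    cfg = SimulationConfig(n_per_pop=15, n_variants=40, n_taxa=40,
                           depth=200, n_replicates=3, seed=77)
    res1 = run_type1_experiment(cfg, kernels=("bray_curtis",))
    res2 = run_type1_experiment(cfg, kernels=("bray_curtis",))
    assert res1.n_failed == 0
    assert res1.pvalues.equals(res2.pvalues)
    table = res1.rejection_table()
    assert set(table["method"]) == {"adjusted", "unadjusted"}
    assert ((res1.pvalues["p_value"] >= 0) & (res1.pvalues["p_value"] <= 1)).all()


def test_simulate_otu_counts_depth_and_shape():
    params = synthesize_dm_params(n_taxa=25, theta=0.05)
    table = simulate_otu_counts(params, 6, 300, np.random.default_rng(13))
    assert table.counts.shape == (6, 25)
    assert np.all(table.counts.sum(axis=1) == 300)
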