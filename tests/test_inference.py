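import itertools

import numpy as np
import pytest

from krv.datatypes import CovariateDesign, KernelMatrix
from krv.inference import (
    DegenerateKernelError,
    adjust_kernel,
    adjusted_krv,
    kernel_pca,
    krv_pvalue,
    krv_statistic,
    matrix_invariants,
    moments_from_invariants,
    permutation_pvalue,
    pvalue_from_W,
)


def _centered_psd(rng, n, q):
    Z = rng.standard_normal((n, q))
    Zc = Z - Z.mean(axis=0)
    K = Zc @ Zc.T
    K -= K.mean(axis=0, keepdims=True)
    K -= K.mean(axis=1, keepdims=True)
    return (K + K.T) / 2


def test_moments_match_exhaustive_enumeration(rng):
    """Closed-form first three permutation moments vs all n! permutations."""
    n = 7
    W1 = _centered_psd(rng, n, 3)
    W2 = _centered_psd(rng, n, 4)
    scale = np.sqrt(np.sum(W1 * W1) * np.sum(W2 * W2))
    stats = []
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        stats.append(np.sum(W1 * W2[np.ix_(p, p)]) / scale)
    stats = np.asarray(stats)
    mean, var, skew = moments_from_invariants(
        n, matrix_invariants(W1), matrix_invariants(W2))
    emp_var = stats.var()
    emp_skew = ((stats - stats.mean()) ** 3).mean() / emp_var ** 1.5
    assert mean == pytest.approx(stats.mean(), rel=1e-10)
    assert var == pytest.approx(emp_var, rel=1e-10)
    assert skew == pytest.approx(emp_skew, rel=1e-8)


def test_pearson3_close_to_enumerated_tail(rng):
    n = 7
    W1 = _centered_psd(rng, n, 2)
    W2 = _centered_psd(rng, n, 3)
    res = pvalue_from_W(W1, W2)
    obs = np.sum(W1 * W2)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        count += np.sum(W1 * W2[np.ix_(p, p)]) >= obs - 1e-12
        total += 1
    exact = count / total
    assert res.p_value == pytest.approx(exact, abs=0.02)


def test_krv_statistic_range_and_self_similarity(rng):
    W = _centered_psd(rng, 10, 4)
    K = KernelMatrix(np.arange(10), W, centered=True)
    assert krv_statistic(K, K) == pytest.approx(1.0)
    other = KernelMatrix(np.arange(10), _centered_psd(rng, 10, 5), centered=True)
    s = krv_statistic(K, other)
    assert 0.0 <= s <= 1.0


def test_intercept_only_adjustment_equals_unadjusted(rng):
    n = 12
    ids = np.arange(n)
    K = KernelMatrix(ids, _centered_psd(rng, n, 3), centered=True)
    L = KernelMatrix(ids, _centered_psd(rng, n, 5), centered=True)
    X0 = CovariateDesign.intercept_only(ids)
    plain = krv_pvalue(K, L)
    adj = krv_pvalue(K, L, X0)
    assert adj.statistic == pytest.approx(plain.statistic, rel=1e-12)
    assert adj.p_value == pytest.approx(plain.p_value, rel=1e-10)
    assert adjusted_krv(K, L, X0) == pytest.approx(krv_statistic(K, L), rel=1e-12)


def test_linear_kernel_adjustment_equals_residual_approach(rng):
    n = 20
    ids = np.arange(n)
    X = CovariateDesign(ids, np.column_stack([np.ones(n), rng.standard_normal((n, 2))]))
    Z = rng.standard_normal((n, 4))
    Y = rng.standard_normal((n, 6))
    K = KernelMatrix(ids, Z @ Z.T)
    L = KernelMatrix(ids, Y @ Y.T)
    # residual-based approach: regress the covariates out of every feature
    # column, then compute the plain KRV of the residual linear kernels
    Zr = X.residualize_matrix(Z @ Z.T)  # = (P Z)(P Z)'
    Yr = X.residualize_matrix(Y @ Y.T)
    Zres = Z - X._Q @ (X._Q.T @ Z)
    Yres = Y - X._Q @ (X._Q.T @ Y)
    assert np.allclose(Zr, Zres @ Zres.T, atol=1e-10)
    resid_stat = krv_statistic(KernelMatrix(ids, Zres @ Zres.T, centered=True),
                               KernelMatrix(ids, Yres @ Yres.T, centered=True))
    assert adjusted_krv(K, L, X) == pytest.approx(resid_stat, rel=1e-10)


def test_pearson3_matches_permutation_small(rng):
    n = 25
    ids = np.arange(n)
    K = KernelMatrix(ids, _centered_psd(rng, n, 3), centered=True)
    L = KernelMatrix(ids, _centered_psd(rng, n, 4), centered=True)
    analytic = krv_pvalue(K, L)
    mc = permutation_pvalue(K, L, n_perm=20_000, seed=0)
    se = np.sqrt(analytic.p_value * (1 - analytic.p_value) / 20_000)
    assert abs(analytic.p_value - mc.p_value) < 3 * se + 1e-4


def test_adjusted_null_uses_raw_sample_permutations(rng):
    """The analytic adjusted p-value must match a Monte-Carlo permutation of
    the raw phenotype samples (permute, re-center, re-project)."""
    n = 30
    ids = np.arange(n)
    X = CovariateDesign(ids, np.column_stack([np.ones(n), rng.standard_normal(n)]))
    K = KernelMatrix(ids, _centered_psd(rng, n, 4))
    Lraw = rng.standard_normal((n, 6))
    L = KernelMatrix(ids, Lraw @ Lraw.T)
    analytic = krv_pvalue(K, L, X)
    # brute-force null: permute phenotype samples, redo the whole procedure
    W1 = X.residualize_matrix(K.K)
    obs = np.sum(W1 * X.residualize_matrix(L.K))
    prng = np.random.default_rng(1)
    B = 4000
    exceed = 0
    for _ in range(B):
        p = prng.permutation(n)
        Lp = L.K[np.ix_(p, p)]
        exceed += np.sum(W1 * X.residualize_matrix(Lp)) >= obs - 1e-12
    mc = (1 + exceed) / (B + 1)
    se = np.sqrt(mc * (1 - mc) / B)
    assert abs(analytic.p_value - mc) < 3 * se + 1e-3


def test_degenerate_kernel_raises():
    n = 8
    ids = np.arange(n)
    zero = KernelMatrix(ids, np.zeros((n, n)), centered=True)
    other = KernelMatrix(ids, np.eye(n))
    with pytest.raises(DegenerateKernelError):
        krv_statistic(zero, other)
    # constant kernel centers to zero as well
    const = KernelMatrix(ids, np.ones((n, n)))
    with pytest.raises(DegenerateKernelError):
        krv_statistic(const, other)


def test_adjust_kernel_removes_covariate_directions(rng):
    n = 10
    ids = np.arange(n)
    X = CovariateDesign(ids, np.column_stack([np.ones(n), rng.standard_normal(n)]))
    K = KernelMatrix(ids, _centered_psd(rng, n, 3))
    A = adjust_kernel(K, X)
    assert np.allclose(A.K @ X.X, 0.0, atol=1e-10)
    assert A.centered


def test_kernel_pca_reconstructs_kernel(rng):
    n = 9
    W = _centered_psd(rng, n, 4)
    K = KernelMatrix(np.arange(n), W, centered=True)
    scores, vals, frac = kernel_pca(K)
    assert np.allclose(scores @ scores.T, W, atol=1e-8)
    assert frac.sum() == pytest.approx(1.0)
    s2, _, f2 = kernel_pca(K, n_components=2)
    assert s2.shape == (n, 2)
    assert f2.sum() < 1.0  # rank 4 kernel: two PCs explain only part
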