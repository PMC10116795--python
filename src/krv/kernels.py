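"""Construction of positive semi-definite sample-similarity (kernel) matrices.

Microbiome kernels are built from dissimilarity matrices via the Gower
transform L = -1/2 H D^2 H followed by an eigenvalue clip to restore positive
semi-definiteness; genotype kernels are linear or identity-by-state.
"""

from __future__ import annotations

import warnings

import numpy as np
import skbio

from krv.datatypes import GenotypeMatrix, KernelMatrix, ValidationError

#: relative tolerance for symmetry / PSD checks
TOL = 1e-8


def linear_kernel(Z, sample_ids=None, weights=None, label: str = "linear") -> KernelMatrix:
    """K = Z Z' (optionally with per-feature weights), PSD by construction."""
    if hasattr(Z, "counts"):  # CountTable
        sample_ids = Z.sample_ids if sample_ids is None else sample_ids
        Z = Z.counts
    elif isinstance(Z, GenotypeMatrix):
        sample_ids = Z.sample_ids if sample_ids is None else sample_ids
        Z = Z.dosages
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValidationError("non-finite entries in feature matrix")
    if sample_ids is None:
        sample_ids = np.arange(Z.shape[0])
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (Z.shape[1],) or np.any(w < 0):
            raise ValidationError("weights must be non-negative, one per feature")
        Z = Z * np.sqrt(w)
    return KernelMatrix(sample_ids, Z @ Z.T, label=label)


def ibs_kernel(G: GenotypeMatrix, weights=None) -> KernelMatrix:
    """Identity-by-state kernel: average genotype matching over variants,
    k(g_i, g_j) = (1/2m) sum_l (2 - |g_il - g_jl|)."""
    dos = G.dosages
    if dos.shape[1] == 0:
        raise ValidationError("IBS kernel requires at least one variant")
    if not np.all(np.isin(dos, (0.0, 1.0, 2.0))):
        warnings.warn("IBS kernel received non-integer dosages; rounding to hard calls")
        dos = np.round(dos)
    m = dos.shape[1]
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    # sum_l w_l |g_il - g_jl| via one pass per variant value difference
    diff = np.zeros((dos.shape[0], dos.shape[0]))
    for l in range(m):
        col = dos[:, l]
        diff += w[l] * np.abs(col[:, None] - col[None, :])
    K = (2.0 * wsum - diff) / (2.0 * wsum)
    return KernelMatrix(G.sample_ids, K, label="ibs")


def distance_to_kernel(D, label: str | None = None) -> KernelMatrix:
    """Gower transform of a dissimilarity matrix: L = -1/2 H D^2 H with
    H = I - 11'/n; the result is centered by construction."""
    if isinstance(D, skbio.DistanceMatrix):
        ids = np.asarray(D.ids, dtype=object)
        Dm = D.data
    else:
        Dm = np.asarray(D, dtype=float)
        ids = np.arange(Dm.shape[0])
    if Dm.shape[0] != Dm.shape[1] or not np.allclose(Dm, Dm.T, atol=TOL * max(1.0, np.abs(Dm).max())):
        raise ValidationError("distance matrix must be square and symmetric")
    D2 = Dm ** 2
    n = D2.shape[0]
    D2c = D2 - D2.mean(axis=0, keepdims=True)
    D2c -= D2c.mean(axis=1, keepdims=True)
    L = -0.5 * D2c
    return KernelMatrix(ids, L, label=label or "gower", centered=True)


def psd_correct(K: KernelMatrix) -> KernelMatrix:
    """Clip negative eigenvalues to zero and reconstruct; idempotent."""
    vals, vecs = np.linalg.eigh(K.K)
    top = max(vals[-1], 0.0)
    clipped = np.where(vals < TOL * max(top, 1.0), np.maximum(vals, 0.0), vals)
    clipped[clipped < 0] = 0.0
    if np.all(clipped == vals):
        out = K.K
    else:
        out = (vecs * clipped) @ vecs.T
    return KernelMatrix(K.sample_ids, out, label=K.label,
                        centered=K.centered, psd_corrected=True)


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """K-tilde = H K H; row and column sums of the result are zero."""
    if K.centered:
        return K
    M = K.K - K.K.mean(axis=0, keepdims=True)
    M -= M.mean(axis=1, keepdims=True)
    M = (M + M.T) / 2.0
    return KernelMatrix(K.sample_ids, M, label=K.label,
                        centered=True, psd_corrected=K.psd_corrected)


def microbiome_kernel(D, label: str | None = None) -> KernelMatrix:
    """Distance -> Gower transform -> PSD correction, the standard pipeline
    for beta-diversity kernels."""
    return psd_correct(distance_to_kernel(D, label=label))


def write_kernel(K: KernelMatrix, path: str) -> None:
    import pandas as pd

    with open(path, "w") as fh:
        fh.write(f"# kernel={K.label} centered={K.centered} psd_corrected={K.psd_corrected}\n")
        pd.DataFrame(K.K, index=K.sample_ids, columns=K.sample_ids).to_csv(
            fh, sep="\t", index_label="sample_id"
        )


def read_kernel(path: str) -> KernelMatrix:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t", index_col=0)
    meta = dict(item.split("=") for item in header.lstrip("# ").split())
    return KernelMatrix(
        df.index.to_numpy(object), df.to_numpy(float), label=meta.get("kernel", "kernel"),
        centered=meta.get("centered") == "True",
        psd_corrected=meta.get("psd_corrected") == "True",
    )
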