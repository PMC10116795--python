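"""Two-stage gene-level then variant-level genome scan for microbiome
beta-diversity, with variant filtering, Bonferroni control, genomic-inflation
diagnostics and taxa attribution.

Stage 1 tests every gene-level variant set against the community-level
microbiome kernel with the covariate-adjusted KRV; stage 2 marginally tests
the individual variants inside stage-1 hits, correcting only for the number
of variants in those genes (nested testing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from krv.datatypes import (
    CountTable,
    CovariateDesign,
    GeneRegion,
    GenotypeMatrix,
    KernelMatrix,
    ValidationError,
)
from krv.inference import (
    DegenerateKernelError,
    _centered_matrix,
    kernel_pca,
    matrix_invariants,
    pvalue_from_W,
)

logger = logging.getLogger(__name__)

SCAN_COLUMNS = ["stage", "unit", "n_variants", "kernel", "statistic",
                "p_value", "significant", "threshold"]


@dataclass
class InflationResult:
    """Genomic inflation factor evaluated at an upper quantile of the
    chi-square-converted p-value distribution."""

    quantile: float
    lambda_gc: float
    n_pvalues: int


# --------------------------------------------------------------------------
# variant filtering and gene sets
# --------------------------------------------------------------------------

def effective_minor_allele_count(G: GenotypeMatrix) -> np.ndarray:
    """N_eff = 2 p-hat (1 - p-hat) N v per variant."""
    p = G.maf()
    return 2.0 * p * (1.0 - p) * G.n_samples * G.v


def filter_variants(G: GenotypeMatrix, maf_min: float = 0.05,
                    neff_min: float = 30.0) -> GenotypeMatrix:
    """Retain common variants (folded MAF >= maf_min) with sufficient
    effective minor allele count (N_eff >= neff_min)."""
    keep = (G.maf() >= maf_min) & (effective_minor_allele_count(G) >= neff_min)
    logger.info("variant filter: %d of %d retained", int(keep.sum()), G.n_variants)
    if not np.any(keep):
        warnings.warn("no variants pass the MAF / N_eff filters")
    return G.select_variants(np.where(keep)[0])


def build_gene_sets(G: GenotypeMatrix, annotations: list[GeneRegion],
                    flank: int = 10_000) -> list[GeneRegion]:
    """Map variants into flanked gene windows; a variant may belong to several
    overlapping genes.  Genes with no member variants are dropped."""
    chrom = G.variants["chrom"].astype(str).to_numpy()
    pos = G.variants["pos"].to_numpy(int)
    out = []
    for gene in annotations:
        lo, hi = gene.start - flank, gene.end + flank
        members = np.where((chrom == str(gene.chrom)) & (pos >= lo) & (pos <= hi))[0]
        if members.size:
            out.append(GeneRegion(gene.gene_id, gene.chrom, gene.start, gene.end,
                                  flank=flank, member_idx=members))
    if not out:
        raise ValidationError("no testable genes: every gene window is empty")
    return out


# --------------------------------------------------------------------------
# scans
# --------------------------------------------------------------------------

def _adjusted(M: np.ndarray, X: CovariateDesign) -> np.ndarray:
    W = X.residualize_matrix(M)
    return (W + W.T) / 2.0


def _phenotype_null(L: KernelMatrix, X: CovariateDesign):
    """Pieces of the microbiome side shared by every test in a scan: the
    centered kernel and its invariants (the permutation null side) plus the
    squared norm of the projected kernel (for the adjusted coefficient)."""
    WLc = _centered_matrix(L)
    invL = matrix_invariants(WLc)
    WLa = _adjusted(L.K, X)
    norm_adj = float(np.einsum("ij,ij->", WLa, WLa))
    return WLc, invL, norm_adj


def _gene_test(WK: np.ndarray, WLc: np.ndarray, invL, norm_adj: float):
    """Adjusted-KRV p-value and coefficient for one projected genotype kernel."""
    res = pvalue_from_W(WK, WLc, inv2=invL)
    norm_c = invL[1]  # tr(WLc^2)
    stat_adj = res.statistic * np.sqrt(norm_c / norm_adj) if norm_adj > 0 else np.nan
    return stat_adj, res.p_value


def stage1_scan(genes: list[GeneRegion], G: GenotypeMatrix, L: KernelMatrix,
                X: CovariateDesign, alpha: float = 0.05) -> pd.DataFrame:
    """Gene-level covariate-adjusted KRV scan with Bonferroni control.

    Genes whose kernels are degenerate after adjustment (e.g. all member
    variants monomorphic) are reported with a missing p-value and excluded
    from the Bonferroni denominator.
    """
    WLc, invL, norm_adj = _phenotype_null(L, X)
    rows = []
    for gene in genes:
        Z = G.dosages[:, gene.member_idx]
        WK = _adjusted(Z @ Z.T, X)
        try:
            stat, p = _gene_test(WK, WLc, invL, norm_adj)
            rows.append((gene.gene_id, len(gene.member_idx), stat, p))
        except DegenerateKernelError:
            rows.append((gene.gene_id, len(gene.member_idx), np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["unit", "n_variants", "statistic", "p_value"])
    n_tested = int(df["p_value"].notna().sum())
    n_untestable = len(df) - n_tested
    if n_untestable:
        logger.info("stage 1: %d untestable genes excluded from Bonferroni", n_untestable)
    threshold = alpha / n_tested if n_tested else np.nan
    df.insert(0, "stage", 1)
    df["kernel"] = L.label
    df["threshold"] = threshold
    df["significant"] = df["p_value"] < threshold
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)[SCAN_COLUMNS]


def merge_significant_regions(genes: list[GeneRegion],
                              significant_ids: list[str]) -> list[GeneRegion]:
    """Union overlapping flanked windows of stage-1 hits into single regions,
    deduplicating shared variants."""
    hits = [g for g in genes if g.gene_id in set(significant_ids)]
    merged: list[GeneRegion] = []
    for gene in sorted(hits, key=lambda g: (str(g.chrom), g.window[0])):
        if merged and str(merged[-1].chrom) == str(gene.chrom) \
                and gene.window[0] <= merged[-1].window[1]:
            prev = merged[-1]
            members = np.union1d(prev.member_idx, gene.member_idx)
            merged[-1] = GeneRegion(f"{prev.gene_id}-{gene.gene_id}", prev.chrom,
                                    min(prev.start, gene.start),
                                    max(prev.end, gene.end),
                                    flank=prev.flank, member_idx=members)
        else:
            merged.append(gene)
    return merged


def stage2_scan(genes: list[GeneRegion], significant_ids: list[str],
                G: GenotypeMatrix, L: KernelMatrix, X: CovariateDesign,
                alpha: float = 0.05) -> pd.DataFrame:
    """Variant-level scan inside stage-1 hits.  The Bonferroni family is the
    total number of variants tested in this stage."""
    regions = merge_significant_regions(genes, significant_ids)
    if not regions:
        return pd.DataFrame(columns=SCAN_COLUMNS)
    WLc, invL, norm_adj = _phenotype_null(L, X)
    rows = []
    for region in regions:
        for col in region.member_idx:
            z = G.dosages[:, [col]]
            WK = _adjusted(z @ z.T, X)
            vid = G.variants["id"].iloc[col]
            try:
                stat, p = _gene_test(WK, WLc, invL, norm_adj)
                rows.append((f"{region.gene_id}:{vid}", stat, p))
            except DegenerateKernelError:
                rows.append((f"{region.gene_id}:{vid}", np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["unit", "statistic", "p_value"])
    n_tested = int(df["p_value"].notna().sum())
    threshold = alpha / n_tested if n_tested else np.nan
    df.insert(0, "stage", 2)
    df["n_variants"] = 1
    df["kernel"] = L.label
    df["threshold"] = threshold
    df["significant"] = df["p_value"] < threshold
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)[SCAN_COLUMNS]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def genomic_inflation(pvalues, quantile: float = 0.1) -> InflationResult:
    """Genomic inflation factor at an upper quantile.

    P-values are converted to 1-df chi-square statistics through the
    upper-tail inverse; lambda is the ratio of the observed to the theoretical
    upper-``quantile`` quantile.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if len(p) < 100:
        warnings.warn("fewer than 100 p-values; inflation estimate is unstable")
    chisq = stats.chi2.isf(p, df=1)
    observed = np.quantile(chisq, 1.0 - quantile)
    expected = stats.chi2.isf(quantile, df=1)
    return InflationResult(quantile, float(observed / expected), len(p))


# --------------------------------------------------------------------------
# taxa attribution
# --------------------------------------------------------------------------

def taxa_attribution(L: KernelMatrix, counts: CountTable, top_variant: np.ndarray,
                     X: CovariateDesign, n_pcs: int = 10, fdr: float = 0.05,
                     corr_min: float = 0.5) -> pd.DataFrame:
    """Identify taxa driving a gene-microbiome association.

    Step 1: regress each leading microbiome kernel PC on the top variant's
    dosage with covariates, collect the dosage p-values, apply
    Benjamini-Hochberg at ``fdr``.  Step 2: for each significant PC, report
    taxa whose abundance correlates with the PC scores at |r| >= corr_min.
    """
    from statsmodels.stats.multitest import multipletests

    scores, _, _ = kernel_pca(L, n_components=n_pcs)
    n_pcs = scores.shape[1]
    g = np.asarray(top_variant, dtype=float).reshape(-1)
    design = np.column_stack([X.X, g])
    pvals, betas = [], []
    for k in range(n_pcs):
        beta, *_ = np.linalg.lstsq(design, scores[:, k], rcond=None)
        resid = scores[:, k] - design @ beta
        dof = len(g) - design.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        t = beta[-1] / np.sqrt(cov[-1, -1])
        pvals.append(2 * stats.t.sf(abs(t), dof))
        betas.append(beta[-1])
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    rows = []
    for k in np.where(reject)[0]:
        pc = scores[:, k]
        for t_idx, taxon in enumerate(counts.taxon_ids):
            col = counts.counts[:, t_idx]
            if np.std(col) == 0 or np.std(pc) == 0:
                continue
            r = float(np.corrcoef(col, pc)[0, 1])
            if abs(r) >= corr_min:
                rows.append((k + 1, pvals[k], taxon, r))
    df = pd.DataFrame(rows, columns=["pc", "pc_p_value", "taxon", "correlation"])
    if df.empty:
        df.attrs["note"] = "no kernel PC passed the FDR screen"
    return df
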