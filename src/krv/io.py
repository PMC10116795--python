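"""Readers and writers for the formats the tool touches, plus sample alignment.

Dialects
--------
* Count tables: UTF-8 TSV, samples in rows, first column sample id, header row
  of taxon ids.
* Covariates: TSV, first column sample id, remaining columns numeric.
* Genotypes: VCF 4.x (GT hard calls or DS dosages) via cyvcf2, or a TSV dosage
  matrix (samples x variants) with a sidecar variant-metadata TSV
  (columns chrom, pos, id[, ref, alt, v]).
* Trees: rooted Newick with branch lengths (scikit-bio TreeNode).
* Gene annotations: TSV with columns chrom, start, end, gene_id, declared
  1-based inclusive.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd
import skbio

from krv.datatypes import (
    CountTable,
    CovariateDesign,
    GeneRegion,
    GenotypeMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# count tables
# --------------------------------------------------------------------------

def read_count_table(path: str) -> CountTable:
    """Read a samples-x-taxa TSV count table.

    Raises a parse error naming the offending row/column for negative or
    non-numeric cells, and a validation error for duplicate identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample or taxon identifiers")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-numeric value in column {col!r}") from exc
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return CountTable(df.index.to_numpy(object), df.columns.to_numpy(object), values)


def write_count_table(table: CountTable, path: str) -> None:
    df = table.to_dataframe()
    if not table.is_transformed:
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="sample_id")


# --------------------------------------------------------------------------
# covariates
# --------------------------------------------------------------------------

def read_covariates(path: str, add_intercept: bool = True) -> CovariateDesign:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample identifiers")
    return CovariateDesign.from_dataframe(df, add_intercept=add_intercept)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def _orient_minor(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns so dosages count the minor allele in the loaded sample."""
    p = np.nanmean(dosages, axis=0) / 2.0
    flip = p > 0.5
    dosages = dosages.copy()
    dosages[:, flip] = 2.0 - dosages[:, flip]
    return dosages, flip


def _impute_and_v(dosages: np.ndarray, hard_calls: bool) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages (2 p-hat) and compute the imputation
    variance ratio v (1 for hard calls)."""
    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        logger.info("mean-imputing %d missing genotypes", n_missing)
        col_mean = np.nanmean(dosages, axis=0)
        idx = np.where(np.isnan(dosages))
        dosages[idx] = np.take(col_mean, idx[1])
    if hard_calls:
        v = np.ones(dosages.shape[1])
    else:
        p = dosages.mean(axis=0) / 2.0
        expected = 2.0 * p * (1.0 - p)
        observed = dosages.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(expected > 0, observed / expected, 0.0)
    return dosages, v


def read_genotypes(path: str, sidecar: str | None = None) -> GenotypeMatrix:
    """Read genotype dosages from a VCF (GT or DS) or a TSV dosage matrix.

    Output is oriented so dosages count the minor allele; hard-call input gets
    v = 1, dosage input gets v = observed variance / expected binomial
    variance per variant.
    """
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path)
    return _read_dosage_tsv(path, sidecar)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.asarray(vcf.samples, dtype=object)
    records, columns = [], []
    has_dosage = False
    for var in vcf:
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = ds[:, 0].astype(float)
            col[col < 0] = np.nan
            has_dosage = True
        else:
            gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=missing? no
            # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            col = np.where(gt == 3, 2.0, gt)
            col[gt == 2] = np.nan
        if np.nanmax(col, initial=0.0) > 2.0 + 1e-9 or np.nanmin(col, initial=0.0) < -1e-9:
            raise ValidationError(f"{path}: dosage outside [0, 2] at {var.ID or var.POS}")
        columns.append(col)
        alt = var.ALT[0] if var.ALT else "."
        records.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                        var.REF, alt))
    if not columns:
        raise ValidationError(f"{path}: no variant records")
    dosages = np.column_stack(columns)
    dosages, _ = _orient_minor(dosages)
    dosages, v = _impute_and_v(dosages, hard_calls=not has_dosage)
    meta = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(samples, dosages, meta, v)


def _read_dosage_tsv(path: str, sidecar: str | None) -> GenotypeMatrix:
    if sidecar is None:
        base, _ = os.path.splitext(path)
        sidecar = base + ".variants.tsv"
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(sidecar, sep="\t", comment="#")
    dosages = df.to_numpy(float)
    if np.nanmin(dosages, initial=0.0) < -1e-9 or np.nanmax(dosages, initial=0.0) > 2 + 1e-9:
        raise ValidationError(f"{path}: dosage outside [0, 2]")
    dosages, _ = _orient_minor(dosages)
    hard = bool(np.all(np.isin(dosages[~np.isnan(dosages)], (0.0, 1.0, 2.0))))
    dosages, v = _impute_and_v(dosages, hard_calls=hard)
    if "v" in meta.columns:
        v = meta["v"].to_numpy(float)
    return GenotypeMatrix(df.index.to_numpy(object), dosages, meta, v)


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

def read_tree(path_or_buffer) -> skbio.TreeNode:
    """Read and validate a rooted Newick tree with branch lengths."""
    tree = skbio.TreeNode.read(path_or_buffer, format="newick")
    return validate_tree(tree)


def validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    names = []
    for leaf in tree.tips():
        if leaf.name is None:
            raise ValidationError("tree has an unlabeled leaf")
        names.append(leaf.name)
    if len(set(names)) != len(names):
        raise ValidationError("tree has duplicate leaf labels")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValidationError(f"negative branch length at {node.name or 'internal node'}")
    if tree.length is None:
        tree.length = 0.0
    return tree


# --------------------------------------------------------------------------
# gene annotations
# --------------------------------------------------------------------------

def read_gene_table(path: str, flank: int = 0) -> list[GeneRegion]:
    """Read a BED-like TSV (chrom, start, end, gene_id), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", "gene_id"], dtype={"chrom": str})
    regions = []
    for row in df.itertuples(index=False):
        regions.append(GeneRegion(str(row.gene_id), str(row.chrom),
                                  int(row.start), int(row.end), flank=flank))
    return regions


# --------------------------------------------------------------------------
# sample alignment
# --------------------------------------------------------------------------

def align_samples(*objects):
    """Restrict and reorder all inputs to their common sample set.

    The common ordering follows the first input's sample order.  Raises on an
    empty intersection.
    """
    if not objects:
        raise ValueError("align_samples requires at least one input")
    common = set(objects[0].sample_ids)
    for obj in objects[1:]:
        common &= set(obj.sample_ids)
    if not common:
        raise ValidationError("no samples shared across inputs")
    order = [sid for sid in objects[0].sample_ids if sid in common]
    logger.info("aligning %d shared samples across %d inputs", len(order), len(objects))
    aligned = []
    for obj in objects:
        pos = {sid: i for i, sid in enumerate(obj.sample_ids)}
        idx = np.array([pos[sid] for sid in order], dtype=int)
        aligned.append(obj.subset(idx))
    return tuple(aligned) if len(aligned) > 1 else aligned[0]
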