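# krv

Covariate-adjusted kernel RV (KRV) association tests between gene-level
genotype sets and community-level microbiome composition.

The KRV coefficient measures the alignment of two sample-similarity
structures — a genotype kernel built from the variants of a gene and a
microbiome kernel built from a beta-diversity measure over a count table —
and tests it analytically against an exact-moment permutation null
(Pearson Type III tail). Covariates such as ancestry principal components
are regressed out of both kernels, which removes the spurious associations
that population stratification otherwise induces between allele
frequencies and community composition. See `docs/methods.md` for the full
statistical description.

Included:

- six community kernels: Bray-Curtis, unweighted / weighted / generalized
  UniFrac, CLR-linear, PhILR-linear (all as distance → Gower transform →
  PSD correction, or linear kernels on log-ratio coordinates);
- linear and IBS genotype kernels with variant QC (folded MAF, effective
  minor-allele count);
- adjusted and unadjusted KRV tests with analytic and Monte-Carlo
  permutation p-values;
- a two-stage gene → variant genome scan with Bonferroni control,
  genomic-inflation diagnostics and taxa attribution;
- a simulation engine for confounded-null and causal-effect studies.

## Worked example

The package CLI operates on plain TSV/VCF/Newick files. Suppose we have:

- `counts.tsv` — samples × taxa count table (first column sample id);
- `genotypes.tsv` + `genotypes.variants.tsv` — dosage matrix and variant
  metadata (VCF input is equally supported);
- `covariates.tsv` — e.g. the top ancestry principal component;
- `genes.tsv` — gene annotations (chrom, start, end, gene_id);
- `tree.nwk` — rooted phylogeny (needed for UniFrac / PhILR kernels only).

Build a community kernel once and reuse it:

```console
$ krv kernel --counts counts.tsv --kernel bray_curtis --rarefy-depth 1500 --out bc_kernel.tsv
wrote bray_curtis kernel for 100 samples to bc_kernel.tsv
```

Test one gene set (here `gene_a.tsv` holds the dosages of the two variants
in one gene window) against the community kernel, adjusting for the
covariates:

```console
$ krv test --microbiome-kernel bc_kernel.tsv --genotypes gene_a.tsv --covariates covariates.tsv
kernel      : bray_curtis
samples     : 100
variants    : 2
KRV         : 0.153564
p-value     : 4.8656e-06  (pearson3)
```

Run the two-stage genome scan — stage 1 tests every gene at a Bonferroni
threshold, stage 2 tests the variants inside significant genes:

```console
$ krv gwas --microbiome-kernel bc_kernel.tsv --genotypes genotypes.tsv \
      --genes genes.tsv --covariates covariates.tsv --flank 5000 --out-prefix scan
stage 1: 1 significant gene(s) of 2 tested (threshold 0.025)
stage 2: 1 significant variant(s) of 2 tested (threshold 0.025)
lambda_GC (upper 0.1 quantile): 7.086
```

(The toy scan has two genes and one planted causal variant, so the
inflation factor is dominated by the true signal; with genome-wide gene
counts it hovers near 1 under the null.) The scan writes `scan.stage1.tsv`,
`scan.stage2.tsv` and `scan.summary.json`:

```json
{
  "n_samples": 100,
  "n_variants": 57,
  "n_genes_tested": 2,
  "stage1_threshold": 0.025,
  "stage1_hits": ["GENE_A"],
  "n_stage2_variants": 2,
  "stage2_threshold": 0.025,
  "stage2_hits": ["GENE_A:v0074"],
  "lambda_gc": 7.086392691767983,
  "lambda_quantile": 0.1
}
```

`GENE_A:v0074` is exactly the variant whose effect was planted when the toy
data were generated. `krv attribute` then reports which taxa drive an
association for a given top variant.

The same analysis from Python:

```python
from krv import krv_pvalue, linear_kernel, microbiome_kernel
from krv.distances import bray_curtis, rarefy
from krv.io import align_samples, read_count_table, read_covariates, read_genotypes

counts, genotypes, covariates = align_samples(
    read_count_table("counts.tsv"),
    read_genotypes("gene_a.tsv"),
    read_covariates("covariates.tsv"),
)
L = microbiome_kernel(bray_curtis(rarefy(counts, 1500, seed=0)), label="bray_curtis")
K = linear_kernel(genotypes)
result = krv_pvalue(K, L, covariates)
print(f"KRV = {result.statistic:.4f}, p = {result.p_value:.3g}")
```

```
KRV = 0.1536, p = 4.87e-06
```

## Simulation studies

`krv simulate` reproduces the package's calibration and power studies:
two-population genotypes with Balding-Nichols allele-frequency divergence,
Dirichlet-multinomial microbiome counts (856 taxa, depth 1000), confounded
null scenarios (T1/T2) and causal-effect power scenarios (P1/P2/P3). A
quick 100-replicate smoke run of the T1 confounded null:

```console
$ krv simulate --scenario T1 --replicates 100 --seed 3
    method              kernel   n  alpha_0.05  alpha_0.01
  adjusted         bray_curtis 100        0.07        0.01
unadjusted         bray_curtis 100        0.08        0.02
  adjusted  unweighted_unifrac 100        0.03        0.01
unadjusted  unweighted_unifrac 100        0.03        0.01
  adjusted    weighted_unifrac 100        0.03        0.00
unadjusted    weighted_unifrac 100        0.06        0.00
  adjusted generalized_unifrac 100        0.02        0.00
unadjusted generalized_unifrac 100        0.05        0.00
  adjusted          clr_linear 100        0.08        0.03
unadjusted          clr_linear 100        0.09        0.02
```

(At 2000 replicates the adjusted rates settle inside the 99% binomial band
around 0.05 for every kernel while the unadjusted Bray-Curtis rate inflates
well above it — see `tests/test_acceptance.py`.)

## Layout

- `src/krv/datatypes.py` — validated core types (count tables, genotypes,
  kernels, covariate designs, gene regions)
- `src/krv/io.py` — TSV/VCF/Newick readers and sample alignment
- `src/krv/distances.py` — rarefaction, Bray-Curtis, UniFrac family,
  CLR/PhILR transforms
- `src/krv/kernels.py` — Gower transform, PSD correction, linear/IBS kernels
- `src/krv/inference.py` — KRV statistic, covariate adjustment, exact
  permutation moments, Pearson III and Monte-Carlo p-values
- `src/krv/gwas.py` — variant QC, two-stage scan, inflation, taxa attribution
- `src/krv/simulate.py` — simulation engine and experiment drivers
- `src/krv/cli.py` — the `krv` command-line interface
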