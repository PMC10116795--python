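"""Simulation engine: population-structured genotypes, Dirichlet-multinomial
microbiome counts, confounded null scenarios, genetic-effect power scenarios
and replicate drivers for type-I-error and power experiments.

Study design
------------
Samples come from two ancestral populations (A and B) whose allele
frequencies diverge by a fixed F_ST.  Population membership confounds the
genotype-microbiome relationship: in the null scenarios the microbiome is
shifted between populations while no variant has a direct effect, so an
unadjusted test that is sensitive to abundance shifts rejects spuriously,
and adjusting for the leading genotype principal component (a proxy for
ancestry) restores validity.  In the power scenarios a single common causal
variant inside a small test subregion alters taxa abundances on top of the
population-level confounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import skbio

from krv.datatypes import (
    CountTable,
    CovariateDesign,
    GenotypeMatrix,
    ValidationError,
)
from krv.distances import (
    TreeIndex,
    bray_curtis,
    clr_transform,
    rarefy,
)
from krv.inference import (
    DegenerateKernelError,
    matrix_invariants,
    pvalue_from_W,
)
from krv.kernels import distance_to_kernel
from scipy import stats as _sstats

logger = logging.getLogger(__name__)

#: the community kernels built in every experiment replicate
DEFAULT_KERNELS = (
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "generalized_unifrac",
    "clr_linear",
)
ALL_KERNELS = DEFAULT_KERNELS + ("philr_linear",)

#: (c1, c2, c3) multiplicative / additive effect sizes per named set
EFFECT_SIZES = {"small": (0.3, 0.3, 0.5), "large": (0.8, 0.7, 1.0)}


@dataclass
class DMParams:
    """Dirichlet-multinomial parameters: mean composition and overdispersion."""

    pi: np.ndarray
    theta: float

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi <= 0) or not np.isclose(self.pi.sum(), 1.0):
            raise ValidationError("pi must be a strictly positive probability vector")
        if not 0.0 < self.theta < 1.0:
            raise ValidationError("theta must lie in (0, 1)")

    @property
    def concentration(self) -> np.ndarray:
        return self.pi * (1.0 - self.theta) / self.theta


@dataclass
class SimulationConfig:
    """Study conditions for one experiment; defaults are the study design."""

    n_per_pop: int = 100
    n_variants: int = 300
    region_length: int = 1_000_000
    subregion_start: int = 496_000
    subregion_length: int = 8_000
    n_subregion_variants: int = 5
    fst: float = 0.1
    n_taxa: int = 856
    depth: int = 1000
    theta: float = 0.01
    scenario: str = "T1"
    effect_set: str = "small"
    n_replicates: int = 2000
    seed: int = 0
    maf_min: float = 0.05

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_pop

    @property
    def subregion_window(self) -> tuple[int, int]:
        return self.subregion_start, self.subregion_start + self.subregion_length - 1

    @property
    def effect_sizes(self) -> tuple[float, float, float]:
        return EFFECT_SIZES[self.effect_set]


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig, rng) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two-population genotypes with Balding-Nichols allele-frequency
    divergence at the configured F_ST.

    Ancestral frequencies are uniform on (0.1, 0.9); population-specific
    frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws; haplotypes are
    independent Bernoulli draws paired into diploid dosages.  A fixed number
    of variants is placed inside the test subregion, the rest uniformly over
    the region.  Returns the genotype matrix and a population-label array.
    """
    rng = np.random.default_rng(rng)
    m = config.n_variants
    p_anc = rng.uniform(0.1, 0.9, m)
    if config.fst > 0:
        a = p_anc * (1.0 - config.fst) / config.fst
        b = (1.0 - p_anc) * (1.0 - config.fst) / config.fst
        p_pop = np.stack([rng.beta(a, b), rng.beta(a, b)])
    else:
        p_pop = np.stack([p_anc, p_anc])
    n = config.n_per_pop
    dosages = np.empty((2 * n, m))
    for k in range(2):
        hap = rng.random((2 * n, m)) < p_pop[k]
        dosages[k * n:(k + 1) * n] = hap[::2].astype(float) + hap[1::2]

    m_sub = config.n_subregion_variants
    lo, hi = config.subregion_window
    pos_sub = rng.integers(lo, hi + 1, size=m_sub)
    pos_rest = rng.integers(1, config.region_length + 1, size=m - m_sub)
    pos = np.sort(np.concatenate([pos_sub, pos_rest]))
    variants = pd.DataFrame({
        "chrom": "1",
        "pos": pos,
        "id": [f"v{i + 1:04d}" for i in range(m)],
    })
    sample_ids = np.array([f"A{i + 1:03d}" for i in range(n)]
                          + [f"B{i + 1:03d}" for i in range(n)], dtype=object)
    labels = np.array(["A"] * n + ["B"] * n, dtype=object)
    return GenotypeMatrix(sample_ids, dosages, variants), labels


def ancestry_covariate(G: GenotypeMatrix) -> CovariateDesign:
    """Intercept plus the leading principal component of the full (all-region)
    genotype matrix, centered and scaled to unit variance."""
    Z = G.dosages - G.dosages.mean(axis=0)
    sd = Z.std(axis=0)
    Z = Z[:, sd > 0] / sd[sd > 0]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc = Z @ vt[0]
    pc = (pc - pc.mean()) / pc.std()
    return CovariateDesign(G.sample_ids, np.column_stack([np.ones(len(pc)), pc]))


def select_causal_variant(G: GenotypeMatrix, config: SimulationConfig) -> int:
    """Column index of the common subregion variant whose folded MAF is
    closest to 0.3."""
    lo, hi = config.subregion_window
    pos = G.variants["pos"].to_numpy(int)
    maf = G.maf()
    cand = np.where((pos >= lo) & (pos <= hi) & (maf >= config.maf_min))[0]
    if cand.size == 0:
        raise ValidationError("no common variant inside the test subregion")
    return int(cand[np.argmin(np.abs(maf[cand] - 0.3))])


# --------------------------------------------------------------------------
# microbiome counts
# --------------------------------------------------------------------------

def synthesize_dm_params(n_taxa: int = 856, theta: float = 0.01,
                         sigma: float = 2.0, seed: int = 20230856) -> DMParams:
    """A fixed long-tailed mean composition: ranked log-normal weights,
    normalized.  Deterministic given the seed; used as the stand-in for a
    composition estimated from a reference 16S data set."""
    rng = np.random.default_rng(seed)
    w = np.sort(rng.lognormal(0.0, sigma, n_taxa))[::-1]
    return DMParams(w / w.sum(), theta)


def estimate_dm_params(table: CountTable) -> DMParams:
    """Method-of-moments Dirichlet-multinomial fit (pooled mean composition
    and a moment estimator of the overdispersion)."""
    x = table.counts
    N = x.sum(axis=1)
    n = x.shape[0]
    if n < 2:
        raise ValidationError("need at least two samples to estimate overdispersion")
    pi = x.sum(axis=0) / N.sum()
    q = x / N[:, None]
    msp = (N[:, None] * (q - pi) ** 2).sum(axis=0) / (n - 1)
    msg = (N[:, None] * q * (1.0 - q)).sum(axis=0) / (N.sum() - n)
    nc = (N.sum() - (N ** 2).sum() / N.sum()) / (n - 1)
    theta = msp.sum() / (msp.sum() + (nc - 1.0) * msg.sum())
    theta = float(np.clip(theta, 1e-6, 1 - 1e-6))
    pi = np.clip(pi, 1e-12, None)
    return DMParams(pi / pi.sum(), theta)


def simulate_otu_counts(params: DMParams, n_samples: int, depth: int,
                        rng, sample_ids=None) -> CountTable:
    """Dirichlet-multinomial counts at fixed sequencing depth."""
    rng = np.random.default_rng(rng)
    p = rng.dirichlet(params.concentration, size=n_samples)
    p /= p.sum(axis=1, keepdims=True)
    counts = rng.multinomial(depth, p)
    if sample_ids is None:
        sample_ids = np.array([f"s{i + 1:03d}" for i in range(n_samples)], dtype=object)
    taxon_ids = np.array([f"t{j + 1:04d}" for j in range(len(params.pi))], dtype=object)
    return CountTable(sample_ids, taxon_ids, counts)


def random_bifurcating_tree(taxon_ids, seed: int) -> skbio.TreeNode:
    """Random coalescent-shaped binary tree over the given taxa: random
    pairwise joins with exponentially distributed waiting times."""
    rng = np.random.default_rng(seed)
    nodes = []
    for t in taxon_ids:
        leaf = skbio.TreeNode(name=str(t), length=None)
        nodes.append((leaf, 0.0))
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = height - ha
        b.length = height - hb
        parent = skbio.TreeNode(length=None)
        parent.append(a)
        parent.append(b)
        for idx in sorted((int(i), int(j)), reverse=True):
            nodes.pop(idx)
        nodes.append((parent, height))
    root = nodes[0][0]
    root.length = None
    return root


def _stochastic_round(x: np.ndarray, rng) -> np.ndarray:
    """Round each entry up with probability equal to its fractional part."""
    floor = np.floor(x)
    frac = x - floor
    return (floor + (rng.random(x.shape) < frac)).astype(np.int64)


# --------------------------------------------------------------------------
# confounding and genetic-effect scenarios
# --------------------------------------------------------------------------

def apply_confounding(table: CountTable, labels: np.ndarray, scenario: str,
                      pi: np.ndarray, rng, depth: int | None = None,
                      seed_rarefy: int | None = None) -> CountTable:
    """Population-level abundance shifts with no genetic cause.

    ``T1``: the 10 most common taxa (by mean composition) are increased by
    10% in population A, with stochastic rounding.  ``T2``: 10 taxa drawn at
    random from the 40 rarest gain one count in population A.  If ``depth``
    is given the result is rarefied back to that depth (requires
    ``seed_rarefy``); otherwise the shifted raw counts are returned.
    """
    rng = np.random.default_rng(rng)
    counts = table.counts.astype(np.int64).copy()
    in_a = np.asarray(labels) == "A"
    order = np.argsort(pi)[::-1]
    if scenario == "T1":
        top10 = order[:10]
        shifted = counts[np.ix_(in_a, top10)] * 1.10
        counts[np.ix_(in_a, top10)] = _stochastic_round(shifted, rng)
    elif scenario == "T2":
        rare40 = order[-40:]
        chosen = rng.choice(rare40, size=10, replace=False)
        counts[np.ix_(in_a, chosen)] += 1
    else:
        raise ValueError(f"unknown confounding scenario {scenario!r}")
    out = CountTable(table.sample_ids, table.taxon_ids, counts)
    if depth is not None:
        if seed_rarefy is None:
            raise ValidationError("rarefaction requires seed_rarefy")
        out = rarefy(out, depth, seed=seed_rarefy)
    return out


def select_effect_clade(index: TreeIndex, pi: np.ndarray,
                        target: float = 0.103,
                        bounds: tuple[float, float] = (0.05, 0.20)) -> np.ndarray:
    """Taxa of the clade whose total mean composition is nearest ``target``;
    errors out if no proper clade lands inside ``bounds``."""
    best, best_gap = None, np.inf
    q = len(pi)
    for b in range(index.n_branches):
        taxa = index.clade_taxa(b)
        if len(taxa) < 2 or len(taxa) >= q:
            continue
        total = pi[taxa].sum()
        gap = abs(total - target)
        if bounds[0] <= total <= bounds[1] and gap < best_gap:
            best, best_gap = taxa, gap
    if best is None:
        raise ValidationError(
            f"no clade with total composition in [{bounds[0]}, {bounds[1]}]"
        )
    return np.asarray(best, dtype=int)


def apply_genetic_effect(table: CountTable, g: np.ndarray, scenario: str,
                         effect: float, pi: np.ndarray, rng,
                         clade: np.ndarray | None = None,
                         depth: int | None = None,
                         seed_rarefy: int | None = None) -> CountTable:
    """Causal-variant effects on taxa abundances.

    ``P1``: taxa ranked 11-20 by mean composition are multiplied by
    1 + c * g_i.  ``P2``: the same multiplicative effect on the members of a
    phylogenetic ``clade``.  ``P3``: 5 taxa drawn from the 40 rarest gain
    c * g_i counts additively.  Carriers only are modified; ``depth`` triggers
    re-rarefaction as in :func:`apply_confounding`.
    """
    rng = np.random.default_rng(rng)
    g = np.asarray(g, dtype=float)
    counts = table.counts.astype(float).copy()
    order = np.argsort(pi)[::-1]
    if scenario == "P1":
        targets = order[10:20]
        counts[:, targets] *= (1.0 + effect * g)[:, None]
    elif scenario == "P2":
        if clade is None:
            raise ValidationError("scenario P2 requires a clade")
        counts[:, clade] *= (1.0 + effect * g)[:, None]
    elif scenario == "P3":
        rare40 = order[-40:]
        chosen = rng.choice(rare40, size=5, replace=False)
        counts[:, chosen] += (effect * g)[:, None]
    else:
        raise ValueError(f"unknown power scenario {scenario!r}")
    out = CountTable(table.sample_ids, table.taxon_ids,
                     _stochastic_round(counts, rng))
    if depth is not None:
        if seed_rarefy is None:
            raise ValidationError("rarefaction requires seed_rarefy")
        out = rarefy(out, depth, seed=seed_rarefy)
    return out


# --------------------------------------------------------------------------
# per-replicate kernel construction
# --------------------------------------------------------------------------

def _psd_clip(W: np.ndarray, return_top_pc: bool = False):
    """Eigen-clip a centered Gower matrix to PSD; optionally also return the
    leading kernel principal component scores."""
    vals, vecs = np.linalg.eigh(W)
    clipped = np.maximum(vals, 0.0)
    out = (vecs * clipped) @ vecs.T
    if return_top_pc:
        top = vecs[:, -1] * np.sqrt(clipped[-1])
        return out, top
    return out


def build_community_kernels(raw: CountTable, rarefied: CountTable,
                            kernel_names, tree_index: TreeIndex,
                            philr_V: np.ndarray | None = None,
                            return_top_pc: bool = False):
    """Centered PSD kernel matrices (plain numpy) for the requested community
    kernels.  Distance kernels use the rarefied table; log-ratio linear
    kernels use pseudo-counted raw counts.  Returns ``{name: W}`` or, with
    ``return_top_pc``, ``{name: (W, top_pc_scores)}``."""
    from krv._fast import weighted_and_generalized_pairs

    unifrac_names = {"unweighted_unifrac", "weighted_unifrac", "generalized_unifrac"}
    distances = {}
    if unifrac_names & set(kernel_names):
        P = tree_index.branch_proportions(rarefied.counts)
        lengths = tree_index.lengths
        active = np.any(P > 0, axis=0)
        P, lengths = np.ascontiguousarray(P[:, active]), lengths[active]
        if "unweighted_unifrac" in kernel_names:
            pres = (P > 0).astype(np.float64)
            both = pres @ (pres * lengths).T
            total = pres @ lengths
            union = total[:, None] + total[None, :] - both
            with np.errstate(divide="ignore", invalid="ignore"):
                D = np.where(union > 0, 1.0 - both / union, 0.0)
            np.fill_diagonal(D, 0.0)
            distances["unweighted_unifrac"] = (D + D.T) / 2.0
        if {"weighted_unifrac", "generalized_unifrac"} & set(kernel_names):
            Dw, Dg = weighted_and_generalized_pairs(P, lengths, 0.5)
            distances["weighted_unifrac"] = Dw
            distances["generalized_unifrac"] = Dg
    out = {}
    for name in kernel_names:
        if name == "bray_curtis":
            D = bray_curtis(rarefied).data
            W = distance_to_kernel(D).K
        elif name in unifrac_names:
            W = distance_to_kernel(distances[name]).K
        elif name == "clr_linear":
            Z = clr_transform(raw).counts
            Zc = Z - Z.mean(axis=0)
            W = Zc @ Zc.T
        elif name == "philr_linear":
            if philr_V is None:
                raise ValidationError(
                    "philr_linear requires a precomputed contrast matrix (philr_V)"
                )
            Z = np.log(raw.counts + 1.0) @ philr_V
            Zc = Z - Z.mean(axis=0)
            W = Zc @ Zc.T
        else:
            raise ValueError(f"unknown kernel {name!r}")
        out[name] = _psd_clip((W + W.T) / 2.0, return_top_pc=return_top_pc)
    return out


# --------------------------------------------------------------------------
# experiment drivers
# --------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-replicate p-values for every (method, kernel) combination."""

    config: SimulationConfig
    pvalues: pd.DataFrame  # columns: replicate, method, kernel, p_value
    n_completed: int
    n_failed: int
    failures: list = field(default_factory=list)

    def rejection_table(self, alphas=(0.05, 0.01, 0.001)) -> pd.DataFrame:
        """Rejection rate per method x kernel at each level."""
        rows = []
        for (method, kernel), grp in self.pvalues.groupby(["method", "kernel"],
                                                          sort=False):
            p = grp["p_value"].to_numpy()
            rows.append([method, kernel, len(p)] + [float((p < a).mean()) for a in alphas])
        return pd.DataFrame(rows, columns=["method", "kernel", "n"]
                            + [f"alpha_{a}" for a in alphas])

    def pvalue_array(self, method: str, kernel: str) -> np.ndarray:
        m = (self.pvalues["method"] == method) & (self.pvalues["kernel"] == kernel)
        return self.pvalues.loc[m, "p_value"].to_numpy()


def _replicate_seeds(master_seed: int, rep: int, n_streams: int):
    ss = np.random.SeedSequence(entropy=(master_seed, rep))
    children = ss.spawn(n_streams)
    return children


def _int_seed(seed_seq) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _experiment_fixtures(config: SimulationConfig):
    """Experiment-level fixtures shared by all replicates: the mean
    composition, the taxon tree and its branch index, the PhILR basis."""
    params = synthesize_dm_params(config.n_taxa, config.theta)
    taxon_ids = np.array([f"t{j + 1:04d}" for j in range(config.n_taxa)], dtype=object)
    tree = random_bifurcating_tree(taxon_ids, seed=20230857)
    index = TreeIndex(tree, taxon_ids)
    return params, taxon_ids, tree, index


def _pc_regression_pvalue(y: np.ndarray, x: np.ndarray, X: CovariateDesign) -> float:
    """Two-sided t-test p-value for x in the linear model y ~ X + x."""
    design = np.column_stack([X.X, x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = len(y) - design.shape[1]
    sigma2 = resid @ resid / dof
    if sigma2 <= 0:
        return 1.0
    cov = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * cov[-1, -1])
    if se == 0:
        return 1.0
    t = beta[-1] / se
    return float(2.0 * _sstats.t.sf(abs(t), dof))


def run_type1_experiment(config: SimulationConfig,
                         kernels=DEFAULT_KERNELS,
                         methods=("adjusted", "unadjusted"),
                         unadjusted_kernels=None,
                         progress: bool = False) -> ExperimentResult:
    """Type-I-error study: confounded microbiome (scenario T1 or T2), no
    causal variant, adjusted and unadjusted KRV tests of the subregion
    genotype kernel against each community kernel.

    ``unadjusted_kernels`` optionally restricts the unadjusted method to a
    subset of the community kernels (the adjusted method always covers all).
    """
    if config.scenario not in ("T1", "T2"):
        raise ValueError("type-I experiments use scenarios T1 or T2")
    params, taxon_ids, tree, index = _experiment_fixtures(config)
    philr_V = None
    if "philr_linear" in kernels:
        from krv.distances import philr_basis
        philr_V, _ = philr_basis(tree, taxon_ids)
    rows, failures = [], []
    for rep in range(config.n_replicates):
        seeds = _replicate_seeds(config.seed, rep, 5)
        try:
            rows.extend(_type1_replicate(config, params, index, philr_V,
                                         kernels, methods, unadjusted_kernels,
                                         rep, seeds))
        except (ValidationError, DegenerateKernelError) as exc:
            failures.append((rep, str(exc)))
            logger.warning("replicate %d failed: %s", rep, exc)
        if progress and (rep + 1) % 100 == 0:
            logger.info("type-I replicate %d / %d", rep + 1, config.n_replicates)
    pvalues = pd.DataFrame(rows, columns=["replicate", "method", "kernel", "p_value"])
    return ExperimentResult(config, pvalues,
                            n_completed=config.n_replicates - len(failures),
                            n_failed=len(failures), failures=failures)


def _type1_replicate(config, params, index, philr_V, kernels, methods,
                     unadjusted_kernels, rep, seeds):
    G, labels = simulate_genotypes(config, np.random.default_rng(seeds[0]))
    raw0 = simulate_otu_counts(params, config.n_samples, config.depth,
                               np.random.default_rng(seeds[1]),
                               sample_ids=G.sample_ids)
    raw = apply_confounding(raw0, labels, config.scenario, params.pi,
                            np.random.default_rng(seeds[2]))
    rarefied = rarefy(raw, config.depth, seed=_int_seed(seeds[3]))
    X = ancestry_covariate(G)

    lo, hi = config.subregion_window
    pos = G.variants["pos"].to_numpy(int)
    sub = np.where((pos >= lo) & (pos <= hi) & (G.maf() >= config.maf_min))[0]
    if sub.size == 0:
        raise ValidationError("no common variant inside the test subregion")
    Z = G.dosages[:, sub]
    K = Z @ Z.T

    geno_W = {}
    if "adjusted" in methods:
        WK = X.residualize_matrix(K)
        geno_W["adjusted"] = ((WK + WK.T) / 2.0, None)
    if "unadjusted" in methods:
        Kc = K - K.mean(axis=0, keepdims=True)
        Kc -= Kc.mean(axis=1, keepdims=True)
        geno_W["unadjusted"] = ((Kc + Kc.T) / 2.0, None)
    for method in geno_W:
        W, _ = geno_W[method]
        geno_W[method] = (W, matrix_invariants(W))

    community = build_community_kernels(raw, rarefied, kernels, index, philr_V)
    rows = []
    for name, WL in community.items():
        # the permutation null always permutes the centered community kernel,
        # so its invariants are shared between the adjusted and unadjusted tests
        invL = matrix_invariants(WL)
        for method, (WK_m, invK) in geno_W.items():
            if (method == "unadjusted" and unadjusted_kernels is not None
                    and name not in unadjusted_kernels):
                continue
            res = pvalue_from_W(WK_m, WL, inv1=invK, inv2=invL)
            rows.append((rep, method, name, res.p_value))
    return rows


def run_power_experiment(config: SimulationConfig,
                         kernels=DEFAULT_KERNELS,
                         methods=("adjusted", "pc_regression"),
                         progress: bool = False) -> ExperimentResult:
    """Power study: confounding (scenario T1) plus a causal-variant effect
    (P1, P2 or P3) on taxa abundances; the adjusted KRV test and a
    kernel-principal-component linear regression competitor."""
    if config.scenario not in ("P1", "P2", "P3"):
        raise ValueError("power experiments use scenarios P1, P2 or P3")
    params, taxon_ids, tree, index = _experiment_fixtures(config)
    philr_V = None
    if "philr_linear" in kernels:
        from krv.distances import philr_basis
        philr_V, _ = philr_basis(tree, taxon_ids)
    c1, c2, c3 = config.effect_sizes
    effect = {"P1": c1, "P2": c2, "P3": c3}[config.scenario]
    clade = select_effect_clade(index, params.pi) if config.scenario == "P2" else None
    rows, failures = [], []
    for rep in range(config.n_replicates):
        seeds = _replicate_seeds(config.seed, rep, 7)
        try:
            rows.extend(_power_replicate(config, params, index, philr_V, kernels,
                                         methods, rep, seeds, effect, clade))
        except (ValidationError, DegenerateKernelError) as exc:
            failures.append((rep, str(exc)))
            logger.warning("replicate %d failed: %s", rep, exc)
        if progress and (rep + 1) % 100 == 0:
            logger.info("power replicate %d / %d", rep + 1, config.n_replicates)
    pvalues = pd.DataFrame(rows, columns=["replicate", "method", "kernel", "p_value"])
    return ExperimentResult(config, pvalues,
                            n_completed=config.n_replicates - len(failures),
                            n_failed=len(failures), failures=failures)


def _power_replicate(config, params, index, philr_V, kernels, methods, rep,
                     seeds, effect, clade):
    G, labels = simulate_genotypes(config, np.random.default_rng(seeds[0]))
    raw0 = simulate_otu_counts(params, config.n_samples, config.depth,
                               np.random.default_rng(seeds[1]),
                               sample_ids=G.sample_ids)
    # population-level confounding first, then the genetic effect
    confounded = apply_confounding(raw0, labels, "T1", params.pi,
                                   np.random.default_rng(seeds[2]),
                                   depth=config.depth,
                                   seed_rarefy=_int_seed(seeds[3]))
    causal = select_causal_variant(G, config)
    g = G.dosages[:, causal]
    raw = apply_genetic_effect(confounded, g, config.scenario, effect,
                               params.pi, np.random.default_rng(seeds[4]),
                               clade=clade)
    rarefied = rarefy(raw, config.depth, seed=_int_seed(seeds[5]))
    X = ancestry_covariate(G)

    lo, hi = config.subregion_window
    pos = G.variants["pos"].to_numpy(int)
    sub = np.where((pos >= lo) & (pos <= hi) & (G.maf() >= config.maf_min))[0]
    Z = G.dosages[:, sub]
    K = Z @ Z.T
    WK = X.residualize_matrix(K)
    WK = (WK + WK.T) / 2.0
    invK = matrix_invariants(WK)

    need_pc = "pc_regression" in methods
    if need_pc:
        Kc = K - K.mean(axis=0, keepdims=True)
        Kc -= Kc.mean(axis=1, keepdims=True)
        _, geno_pc = _psd_clip((Kc + Kc.T) / 2.0, return_top_pc=True)
    community = build_community_kernels(raw, rarefied, kernels, index, philr_V,
                                        return_top_pc=need_pc)
    rows = []
    for name, built in community.items():
        WL, top_pc = built if need_pc else (built, None)
        if "adjusted" in methods:
            res = pvalue_from_W(WK, WL, inv1=invK)
            rows.append((rep, "adjusted", name, res.p_value))
        if need_pc:
            p = _pc_regression_pvalue(top_pc, geno_pc, X)
            rows.append((rep, "pc_regression", name, p))
    return rows


def power_config(config: SimulationConfig, scenario: str,
                 effect_set: str = "large", n_replicates: int = 500,
                 seed_offset: int = 1) -> SimulationConfig:
    """Derive a power-study configuration from a type-I configuration."""
    return replace(config, scenario=scenario, effect_set=effect_set,
                   n_replicates=n_replicates, seed=config.seed + seed_offset)
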