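"""Polygenic genotype/phenotype cohort simulator.

Generates cohorts with the statistical structure the downstream
estimators assume: HWE genotypes with a configurable MAF spectrum, SNPs
spread over chromosomes proportionally to their length, additive
polygenic trait architectures with effects on standardized genotypes,
cohort/sex/age nuisance structure, and an optional minority of closely
related individual pairs.

All randomness flows from a single master seed through named
:class:`numpy.random.SeedSequence` child streams, so every artefact is
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotypes import MISSING, GenotypeMatrix
from .phenotype_prep import PhenotypeTable

logger = logging.getLogger(__name__)

# stream tags: stable names -> child-seed index
_STREAM_GENO = 0
_STREAM_TRAIT = 1
_STREAM_COVAR = 2


def default_chromosome_lengths(n_chromosomes: int, genome_bp: int = 3_000_000_000):
    """Decreasing chromosome lengths summing to ``genome_bp``.

    Length of chromosome k is proportional to (K + 1 - k), a crude but
    adequate stand-in for the human karyotype's length gradient.
    """
    weights = np.arange(n_chromosomes, 0, -1, dtype=float)
    lengths = np.floor(genome_bp * weights / weights.sum()).astype(np.int64)
    return tuple(int(x) for x in lengths)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort."""

    n_individuals: int
    n_snps: int
    n_chromosomes: int = 22
    chromosome_lengths: tuple = None
    maf_range: tuple = (0.01, 0.5)
    causal_fraction: float = 1.0
    h2_target: float = 0.2
    per_component_fractions: dict = None
    related_pair_fraction: float = 0.0
    related_redraw_fraction: float = 0.5
    missing_rate: float = 0.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    cohort_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ConfigurationError("n_individuals must be >= 2")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.chromosome_lengths is None:
            object.__setattr__(
                self,
                "chromosome_lengths",
                default_chromosome_lengths(self.n_chromosomes),
            )
        else:
            object.__setattr__(
                self, "chromosome_lengths", tuple(self.chromosome_lengths)
            )
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ConfigurationError(
                "chromosome_lengths length must equal n_chromosomes"
            )
        if any(L <= 0 for L in self.chromosome_lengths):
            raise ConfigurationError("chromosome lengths must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low < high <= 0.5, got {self.maf_range}"
            )
        if not 0.0 <= self.h2_target <= 1.0:
            raise ConfigurationError("h2_target must lie in [0, 1]")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise ConfigurationError("causal_fraction must lie in (0, 1]")
        if self.per_component_fractions is not None:
            total = sum(self.per_component_fractions.values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"per_component_fractions must sum to 1, got {total}"
                )
        for name in ("related_pair_fraction", "related_redraw_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    def rng(self, stream: int, *extra) -> np.random.Generator:
        """Named child generator of the master seed (logged)."""
        seq = np.random.SeedSequence((self.seed, stream) + tuple(extra))
        logger.debug("derived rng stream %s extra=%s from seed %s", stream, extra, self.seed)
        return np.random.default_rng(seq)


@dataclass
class SimTruth:
    """Ground truth of one simulated trait, for parameter-recovery tests."""

    causal_ids: np.ndarray
    effects: np.ndarray
    true_h2: float
    true_component_fractions: dict
    genetic_values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        fracs = np.array(list(self.true_component_fractions.values()), dtype=float)
        if fracs.size:
            if ((fracs < -1e-12) | (fracs > 1 + 1e-12)).any():
                raise ValueError("component fractions must lie in [0, 1]")
            if abs(fracs.sum() - 1.0) > 1e-9:
                raise ValueError("component fractions must sum to 1")


@dataclass
class CohortBundle:
    """One genotype panel plus a multi-trait phenotype table and its truths."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truths: dict


# ----------------------------------------------------------------------
def _allocate_counts(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items by ``weights``."""
    weights = np.asarray(weights, dtype=float)
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw an HWE genotype panel under ``config``.

    Each SNP's allele frequency is uniform on ``maf_range``; dosages are
    Binomial(2, p). SNP counts per chromosome follow chromosome length,
    with positions uniform along the chromosome. Related pairs are made
    by copying one member's genotypes and redrawing a fraction of SNPs;
    missing calls are then masked in at ``missing_rate``.
    """
    n, m = config.n_individuals, config.n_snps
    rng = config.rng(_STREAM_GENO)

    lengths = np.asarray(config.chromosome_lengths, dtype=np.int64)
    counts = _allocate_counts(m, lengths)
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), counts)
    bp = np.empty(m, dtype=np.int64)
    start = 0
    for k, (cnt, L) in enumerate(zip(counts, lengths)):
        pos = np.sort(rng.integers(1, L + 1, size=cnt))
        # resolve ties so positions are strictly increasing where possible
        bp[start : start + cnt] = pos
        start += cnt

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    # two independent Bernoulli(p) draws summed (uniform-threshold form is
    # much faster than array-p binomial sampling at this scale)
    p32 = p.astype(np.float32)
    dosages = (rng.random((n, m), dtype=np.float32) < p32).astype(np.int8)
    dosages += rng.random((n, m), dtype=np.float32) < p32

    n_pairs = int(round(config.related_pair_fraction * n / 2))
    for j in range(n_pairs):
        a, b = 2 * j, 2 * j + 1
        dosages[b] = dosages[a]
        redraw = rng.random(m) < config.related_redraw_fraction
        k = int(redraw.sum())
        if k:
            pr = p[redraw]
            dosages[b, redraw] = (
                rng.binomial(1, pr, size=k) + rng.binomial(1, pr, size=k)
            ).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = MISSING

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "bp": bp,
            "id": [f"snp{i + 1}" for i in range(m)],
            "a1": "A",
            "a2": "G",
        }
    )
    samples = np.array([f"id{i + 1}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def _draw_covariates(config: SimConfig) -> pd.DataFrame:
    rng = config.rng(_STREAM_COVAR)
    n = config.n_individuals
    return pd.DataFrame(
        {
            "age": rng.integers(40, 70, size=n),
            "sex": rng.integers(1, 3, size=n),
            "cohort": rng.choice(["ansung", "ansan"], size=n),
        },
        index=[f"id{i + 1}" for i in range(n)],
    )


def _draw_causal_sets(G: GenotypeMatrix, config: SimConfig, rng) -> dict:
    """Causal column indices per component.

    Default: one uniform draw over all SNPs (SNP density already tracks
    chromosome length), keyed per chromosome. With explicit
    ``per_component_fractions`` the keys must be chromosome labels and
    draws happen within each chromosome.
    """
    m = G.n_variants
    n_causal = max(1, int(round(config.causal_fraction * m)))
    chrom = G.variants["chrom"].to_numpy()
    if config.per_component_fractions is None:
        causal = np.sort(rng.choice(m, size=n_causal, replace=False))
        return {f"chr{c}": causal[chrom[causal] == c] for c in np.unique(chrom[causal])}
    # explicit variance shares: causal density is uniform within each
    # component's pool; the shares themselves are enforced by rescaling
    sets = {}
    for name, frac in config.per_component_fractions.items():
        label = int(str(name).removeprefix("chr"))
        pool = np.flatnonzero(chrom == label)
        if len(pool) == 0:
            raise ConfigurationError(f"component {name!r} has no SNPs")
        cnt = max(1, int(round(config.causal_fraction * len(pool)))) if frac > 0 else 0
        if cnt:
            sets[str(name)] = np.sort(rng.choice(pool, size=cnt, replace=False))
    return sets


def simulate_phenotype(
    G: GenotypeMatrix,
    config: SimConfig,
    trait_index: int = 0,
    covariates: pd.DataFrame = None,
    trait_name: str = "trait1",
):
    """Simulate one additive polygenic trait on ``G``.

    Effects are drawn i.i.d. normal on standardized genotypes; the total
    genetic value is rescaled so its sample variance equals ``h2_target``
    exactly, and independent normal noise with variance 1 - h2_target is
    added (zero noise when h2_target == 1). When
    ``per_component_fractions`` is set, each component's genetic value is
    rescaled to its requested share of the genetic variance. Nuisance
    age/sex/cohort shifts are added afterwards (they are removed again by
    phenotype preparation downstream).

    Returns ``(PhenotypeTable, SimTruth)``.
    """
    rng = config.rng(_STREAM_TRAIT, trait_index)
    n = G.n_samples
    causal_sets = _draw_causal_sets(G, config, rng)
    # SNPs monomorphic in this finite sample cannot carry an effect
    p_obs = G.allele_frequencies()
    poly = (p_obs > 0) & (p_obs < 1)
    causal_sets = {
        k: v[poly[v]] for k, v in causal_sets.items() if poly[v].any()
    }
    all_idx = np.concatenate(list(causal_sets.values())) if causal_sets else np.array([], int)
    if all_idx.size == 0 and config.h2_target > 0:
        raise ConfigurationError("h2_target > 0 requires at least one causal SNP")

    # float32 is ample for effect aggregation and halves the matmul cost
    W = G.subset_variants(np.sort(all_idx)).standardized(dtype=np.float32)
    pos_of = {j: k for k, j in enumerate(np.sort(all_idx))}
    effects = rng.standard_normal(all_idx.size).astype(np.float32)

    # per-component genetic values, optionally rescaled to requested shares
    g_parts = {}
    eff_by_idx = np.empty(all_idx.size)
    for name, idx in causal_sets.items():
        cols = np.array([pos_of[j] for j in idx])
        beta = effects[np.searchsorted(np.sort(all_idx), idx)]
        g = W[:, cols] @ beta
        g_parts[name] = (g, cols, beta)

    if config.per_component_fractions is not None:
        for name, (g, cols, beta) in list(g_parts.items()):
            want = config.per_component_fractions[name]
            v = g.var()
            if v > 0 and want > 0:
                s = np.sqrt(want / v)
                g_parts[name] = (g * s, cols, beta * s)
            elif want == 0:
                g_parts[name] = (g * 0, cols, beta * 0)

    g_total = np.sum([g for g, _, _ in g_parts.values()], axis=0)
    v_g = g_total.var()
    if v_g > 0:
        scale = np.sqrt(config.h2_target / v_g) if config.h2_target > 0 else 0.0
        # keep an unscaled unit-variance copy for h2 = 0 bookkeeping
        g_unit = g_total / np.sqrt(v_g)
    else:
        scale = 0.0
        g_unit = g_total
    g_scaled = g_total * scale
    for name, (g, cols, beta) in list(g_parts.items()):
        g_parts[name] = (g * scale, cols, beta * scale)

    if config.h2_target >= 1.0:
        e = np.zeros(n)
    else:
        e = rng.standard_normal(n) * np.sqrt(1.0 - config.h2_target)
    y = g_scaled + e

    # component fractions from the (pre-h2-scaling) per-component variances
    part_vars = {name: float(g.var()) for name, (g, _, _) in g_parts.items()}
    total_part = sum(part_vars.values())
    if total_part > 0:
        fractions = {k: v / total_part for k, v in part_vars.items()}
    else:
        raw = {name: float((W[:, cols] @ beta).var()) for name, (g, cols, beta) in g_parts.items()}
        s = sum(raw.values())
        fractions = {k: v / s for k, v in raw.items()} if s > 0 else {}

    var_y = y.var()
    true_h2 = float(g_scaled.var() / var_y) if var_y > 0 else 0.0

    if covariates is None:
        covariates = _draw_covariates(config)
    age = covariates["age"].to_numpy(dtype=float)
    age_z = (age - age.mean()) / age.std() if age.std() > 0 else age * 0
    y = (
        y
        + config.age_effect * age_z
        + config.sex_effect * (covariates["sex"].to_numpy() == 2)
        + config.cohort_effect * (covariates["cohort"].to_numpy() == "ansan")
    )

    data = covariates.copy()
    data[trait_name] = y
    table = PhenotypeTable(data=data, trait_names=[trait_name])

    order = np.sort(all_idx)
    effects_out = np.zeros(order.size)
    for _, cols, beta in g_parts.values():
        effects_out[cols] = beta
    truth = SimTruth(
        causal_ids=G.variant_ids[order],
        effects=effects_out,
        true_h2=true_h2,
        true_component_fractions=fractions,
        genetic_values=g_scaled if config.h2_target > 0 else g_unit,
    )
    return table, truth


def simulate_multi_trait_cohort(
    config: SimConfig, n_traits: int, h2_list
) -> CohortBundle:
    """One genotype panel with ``n_traits`` independently drawn traits.

    Each trait gets its own causal draw and its own target h2 from
    ``h2_list``; covariates are shared across traits.
    """
    h2_list = list(h2_list)
    if len(h2_list) != n_traits:
        raise ConfigurationError("h2_list must have length n_traits")
    from dataclasses import replace

    G = simulate_genotypes(config)
    covariates = _draw_covariates(config)
    data = covariates.copy()
    truths = {}
    names = []
    for t, h2 in enumerate(h2_list):
        cfg_t = replace(config, h2_target=float(h2))
        name = f"trait{t + 1}"
        table, truth = simulate_phenotype(
            G, cfg_t, trait_index=t, covariates=covariates, trait_name=name
        )
        data[name] = table.data[name]
        truths[name] = truth
        names.append(name)
    return CohortBundle(
        genotypes=G,
        phenotypes=PhenotypeTable(data=data, trait_names=names),
        truths=truths,
    )
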