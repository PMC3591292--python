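"""Partitioning heritability by chromosome and genomic region.

Per-chromosome and genic/intergenic decompositions fit all components
jointly in one multi-component REML; across-trait aggregation and the
regression of variance shares on DNA length summarize the polygenic
length relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .qc_grm import compute_grm
from .reml import RemlFit, RemlModel, fit_reml


@dataclass
class RegionSet:
    """Named genomic intervals (1-based, inclusive) with symmetric padding."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end
    pad_kb: float = 0.0

    def __post_init__(self):
        if not isinstance(self.intervals, pd.DataFrame):
            self.intervals = pd.DataFrame(
                self.intervals, columns=["chrom", "start", "end"]
            )
        need = {"chrom", "start", "end"} - set(self.intervals.columns)
        if need:
            raise ValueError(f"interval table lacks columns {sorted(need)}")
        iv = self.intervals
        if len(iv) and (iv["start"].to_numpy() > iv["end"].to_numpy()).any():
            raise ValueError("interval start must be <= end")

    def padded(self) -> pd.DataFrame:
        """Intervals extended by pad_kb on both sides, clipped at position 1."""
        iv = self.intervals.copy()
        pad = int(round(self.pad_kb * 1000))
        iv["start"] = np.maximum(iv["start"].to_numpy() - pad, 1)
        iv["end"] = iv["end"].to_numpy() + pad
        return iv

    def total_length(self) -> int:
        """Union length (bp) of the padded intervals."""
        total = 0
        iv = self.padded()
        for _, sub in iv.groupby("chrom"):
            sub = sub.sort_values("start")
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_e is None or s > cur_e + 1:
                    if cur_e is not None:
                        total += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s + 1
        return int(total)

    @classmethod
    def from_bed(cls, path, name=None, pad_kb: float = 0.0) -> "RegionSet":
        """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
        )
        bed["start"] = bed["start"].astype(np.int64) + 1
        bed["end"] = bed["end"].astype(np.int64)
        return cls(name=name or str(path), intervals=bed, pad_kb=pad_kb)

    @classmethod
    def from_gene_table(cls, genes: pd.DataFrame, name="genic", pad_kb: float = 0.0):
        """Build from a gene table with chrom/start/end (transcript bounds)."""
        return cls(name=name, intervals=genes[["chrom", "start", "end"]].copy(), pad_kb=pad_kb)


@dataclass
class PartitionResult:
    """Per-component variance fractions for one trait."""

    trait: str
    component_names: tuple
    v_c: np.ndarray  # fraction of phenotypic variance per component
    se: np.ndarray
    v_total: float
    lengths: np.ndarray
    fit: RemlFit = field(default=None, repr=False)

    def __post_init__(self):
        self.v_c = np.asarray(self.v_c, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if (self.v_c < -1e-12).any():
            raise ValueError("variance fractions must be non-negative")
        if abs(self.v_total - self.v_c.sum()) > 1e-9:
            raise ValueError("v_total must equal the sum of v_c")

    def genetic_fractions(self) -> np.ndarray:
        """v_c / v_total (NaN-free only when v_total > 0)."""
        return self.v_c / self.v_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait,
                "component": list(self.component_names),
                "v_c": self.v_c,
                "se": self.se,
                "length_bp": self.lengths,
            }
        )


# ----------------------------------------------------------------------
def partition_by_chromosome(
    G: GenotypeMatrix,
    y: np.ndarray,
    X: np.ndarray = None,
    chrom_lengths: dict = None,
    trait: str = "trait",
    min_snps: int = 2,
    max_iter: int = 300,
    grm_dtype=np.float64,
) -> PartitionResult:
    """Joint multi-component REML with one GRM per chromosome.

    Chromosomes with fewer than ``min_snps`` SNPs are excluded with a
    warning. ``chrom_lengths`` maps chromosome label to bp length; when
    omitted the largest observed bp per chromosome is used as a proxy.
    """
    chrom = G.variants["chrom"].to_numpy()
    labels = pd.unique(chrom)
    if len(labels) < 2:
        raise ValueError("need at least 2 chromosomes to partition")
    comps = {}
    lengths = []
    for c in labels:
        mask = chrom == c
        if mask.sum() < min_snps:
            warnings.warn(f"chromosome {c} has < {min_snps} SNPs; excluded", stacklevel=2)
            continue
        sub = G.subset_variants(mask)
        comps[f"chr{c}"] = compute_grm(sub, dtype=grm_dtype, with_counts=False).values
        if chrom_lengths is not None:
            lengths.append(float(chrom_lengths[c]))
        else:
            lengths.append(float(G.variants.loc[mask, "bp"].max()))
    fit = fit_reml(RemlModel(y=y, components=comps, X=X), max_iter=max_iter)
    return PartitionResult(
        trait=trait,
        component_names=fit.component_names,
        v_c=fit.h2,
        se=fit.h2_se,
        v_total=float(fit.h2.sum()),
        lengths=np.asarray(lengths),
        fit=fit,
    )


def assign_snps_to_regions(variants: pd.DataFrame, regions: RegionSet):
    """Split variant ids into (in-region, out-of-region) sets.

    A SNP is in-region iff its bp falls inside any padded interval
    (inclusive bounds). Raises if the region set names chromosomes absent
    from the variant table.
    """
    iv = regions.padded()
    var_chroms = set(variants["chrom"].unique())
    offenders = sorted(set(iv["chrom"].unique()) - var_chroms)
    if offenders:
        raise ValueError(
            f"region chromosomes absent from variant table: {offenders}"
        )
    in_mask = np.zeros(len(variants), dtype=bool)
    bp = variants["bp"].to_numpy()
    chrom = variants["chrom"].to_numpy()
    for c, sub in iv.groupby("chrom"):
        rows = chrom == c
        if not rows.any():
            continue
        pos = bp[rows]
        hit = np.zeros(pos.size, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            hit |= (pos >= s) & (pos <= e)
        in_mask[np.flatnonzero(rows)] = hit
    ids = variants["id"].to_numpy()
    return ids[in_mask], ids[~in_mask]


def fit_region_partition(
    G: GenotypeMatrix,
    y: np.ndarray,
    regions: RegionSet,
    X: np.ndarray = None,
    genome_length: float = None,
    trait: str = "trait",
    min_snps_warn: int = 100,
    max_iter: int = 300,
    grm_dtype=np.float64,
) -> PartitionResult:
    """Two-component REML: SNPs inside vs outside ``regions``.

    When one side is empty the result collapses to a single-component
    fit on the non-empty side (degenerate partition).
    """
    in_ids, out_ids = assign_snps_to_regions(G.variants, regions)
    comps = {}
    lengths = []
    total_len = float(genome_length) if genome_length else float(
        G.variants.groupby("chrom")["bp"].max().sum()
    )
    region_len = float(min(regions.total_length(), total_len))
    for label, ids, length in (
        (regions.name, in_ids, region_len),
        (f"non-{regions.name}", out_ids, total_len - region_len),
    ):
        if len(ids) == 0:
            continue
        if len(ids) < min_snps_warn:
            warnings.warn(
                f"component {label!r} has only {len(ids)} SNPs", stacklevel=2
            )
        sub = G.subset_variants(ids)
        comps[label] = compute_grm(sub, dtype=grm_dtype, with_counts=False).values
        lengths.append(length)
    if not comps:
        raise ValueError("both region sides are empty")
    fit = fit_reml(RemlModel(y=y, components=comps, X=X), max_iter=max_iter)
    return PartitionResult(
        trait=trait,
        component_names=fit.component_names,
        v_c=fit.h2,
        se=fit.h2_se,
        v_total=float(fit.h2.sum()),
        lengths=np.asarray(lengths),
        fit=fit,
    )


def fit_region_partition_by_chromosome(
    G: GenotypeMatrix,
    y: np.ndarray,
    regions: RegionSet,
    X: np.ndarray = None,
    trait: str = "trait",
    max_iter: int = 300,
    grm_dtype=np.float64,
) -> list:
    """Per-chromosome genic/intergenic partitioning.

    For each chromosome fits three components jointly: that chromosome's
    in-region SNPs, its out-of-region SNPs, and the rest of the genome.
    Returns one PartitionResult per chromosome with the rest-of-genome
    component last.
    """
    in_ids, out_ids = assign_snps_to_regions(G.variants, regions)
    in_set, out_set = set(in_ids), set(out_ids)
    results = []
    chrom = G.variants["chrom"].to_numpy()
    ids = G.variants["id"].to_numpy()
    for c in pd.unique(chrom):
        on_c = ids[chrom == c]
        cin = [v for v in on_c if v in in_set]
        cout = [v for v in on_c if v in out_set]
        rest = ids[chrom != c]
        comps = {}
        lengths = []
        for label, vset in (
            (f"chr{c}-{regions.name}", cin),
            (f"chr{c}-non-{regions.name}", cout),
            ("rest", list(rest)),
        ):
            if len(vset) < 2:
                continue
            sub = G.subset_variants(np.asarray(vset, dtype=object))
            comps[label] = compute_grm(sub, dtype=grm_dtype, with_counts=False).values
            lengths.append(float(len(vset)))
        fit = fit_reml(RemlModel(y=y, components=comps, X=X), max_iter=max_iter)
        results.append(
            PartitionResult(
                trait=trait,
                component_names=fit.component_names,
                v_c=fit.h2,
                se=fit.h2_se,
                v_total=float(fit.h2.sum()),
                lengths=np.asarray(lengths),
                fit=fit,
            )
        )
    return results


# ----------------------------------------------------------------------
@dataclass
class AggregateResult:
    """Across-trait aggregate of per-component variance shares."""

    component_names: tuple
    values: np.ndarray
    se: np.ndarray  # empirical SD / sqrt(n_traits); optimistic under trait correlation
    n_traits: int
    mode: str


def aggregate_across_traits(results, mode: str = "mean") -> AggregateResult:
    """Average partition results over traits.

    ``mean`` averages the phenotypic-variance fractions v_c;
    ``genetic-fraction-mean`` first normalizes each trait by its total
    genetic variance and then averages. Traits whose total is zero are
    excluded (they carry no partition information).
    """
    if mode not in ("mean", "genetic-fraction-mean"):
        raise ValueError(f"unknown mode {mode!r}")
    results = [r for r in results if r.v_total > 0]
    if not results:
        raise ValueError("no traits with non-zero total genetic variance")
    names = results[0].component_names
    for r in results:
        if r.component_names != names:
            raise ValueError("partition results have inconsistent components")
    rows = np.vstack(
        [r.genetic_fractions() if mode == "genetic-fraction-mean" else r.v_c for r in results]
    )
    k = len(results)
    se = rows.std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else np.full(len(names), np.nan)
    return AggregateResult(
        component_names=names,
        values=rows.mean(axis=0),
        se=se,
        n_traits=k,
        mode=mode,
    )


class LengthRegression(NamedTuple):
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r: float
    r2: float
    p_slope_eq_1: float
    p_intercept_eq_0: float


def length_variance_regression(v, lengths) -> LengthRegression:
    """OLS of per-component variance on per-component DNA length.

    Returns classical slope/intercept SEs, Pearson r and r^2, and
    two-sided t-tests of slope = 1 and intercept = 0.
    """
    v = np.asarray(v, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if v.size != lengths.size or v.size < 3:
        raise ValueError("need >= 3 matched (value, length) pairs")
    if lengths.std() == 0:
        raise ValueError("zero variance in lengths")
    res = stats.linregress(lengths, v)
    df = v.size - 2
    scale = max(np.abs(v).max(), 1e-30)
    if res.stderr > 0:
        p_slope = 2.0 * stats.t.sf(abs((res.slope - 1.0) / res.stderr), df)
    else:  # exact fit: the hypothesis holds iff the slope is (numerically) 1
        p_slope = 1.0 if abs(res.slope - 1.0) < 1e-10 else 0.0
    if res.intercept_stderr > 0:
        p_int = 2.0 * stats.t.sf(abs(res.intercept / res.intercept_stderr), df)
    else:
        p_int = 1.0 if abs(res.intercept) < 1e-10 * scale else 0.0
    return LengthRegression(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        p_slope_eq_1=float(p_slope),
        p_intercept_eq_0=float(p_int),
    )


def equal_snp_subsample(G: GenotypeMatrix, k_per_chr: int = 3500, seed=None) -> GenotypeMatrix:
    """Sample ``k_per_chr`` SNPs uniformly without replacement per chromosome.

    Chromosomes with fewer SNPs are kept whole with a warning.
    """
    rng = np.random.default_rng(seed)
    chrom = G.variants["chrom"].to_numpy()
    keep = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size <= k_per_chr:
            if idx.size < k_per_chr:
                warnings.warn(
                    f"chromosome {c} has {idx.size} < {k_per_chr} SNPs; keeping all",
                    stacklevel=2,
                )
            keep.append(idx)
        else:
            keep.append(np.sort(rng.choice(idx, size=k_per_chr, replace=False)))
    return G.subset_variants(np.sort(np.concatenate(keep)))
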