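"""Per-SNP association scan and GWA p-value enrichment (theta_P).

The scan is simple linear regression of the adjusted phenotype on each
SNP dosage (missing dosages mean-imputed), with two-sided Wald p-values
from the t distribution. theta_P is the fraction of SNPs passing a
p-value threshold; correlating theta_P with per-trait h2_SNP estimates
over a threshold grid locates the enrichment maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix


def default_threshold_grid() -> np.ndarray:
    """Thresholds 0.001 to 0.201 in steps of 0.005 (41 points)."""
    return np.round(0.001 + 0.005 * np.arange(41), 6)


@dataclass
class GwaScan:
    """Per-SNP association results aligned to a variant table."""

    variants: pd.DataFrame
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    maf: np.ndarray
    n_used: int
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self):
        m = len(self.variants)
        for name in ("beta", "se", "p", "maf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have one entry per variant")
            setattr(self, name, arr)
        if self.degenerate is None:
            self.degenerate = np.zeros(m, dtype=bool)
        ok = self.degenerate
        if ((self.p <= 0) | (self.p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (self.se[~ok] <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def to_frame(self) -> pd.DataFrame:
        out = self.variants[["chrom", "bp", "id"]].copy()
        out["beta"] = self.beta
        out["se"] = self.se
        out["p"] = self.p
        out["maf"] = self.maf
        return out


@dataclass
class ThetaScan:
    """theta_P curves across traits and their correlation with h2_SNP."""

    thresholds: np.ndarray
    theta: np.ndarray  # (n_traits_kept, n_thresholds)
    correlations: np.ndarray  # Pearson r per threshold, NaN where undefined
    argmax_threshold: float
    r_max: float
    trait_names: tuple = ()


def gwa_scan(G: GenotypeMatrix, y: np.ndarray) -> GwaScan:
    """Single-SNP linear-regression scan of ``y`` on each dosage.

    Rows with missing phenotype are dropped; missing dosages are imputed
    to the per-SNP mean. SNPs with zero dosage variance are flagged
    degenerate with beta = 0 and p = 1.
    """
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 non-missing phenotypes")
    x = G.dosage_float()[keep]
    mean = np.nanmean(x, axis=0)
    nan_cols = ~np.isfinite(mean)
    mean[nan_cols] = 0.0
    inds = np.where(np.isnan(x))
    x[inds] = mean[inds[1]]

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    degenerate = sxx <= 0
    sxx_safe = np.where(degenerate, 1.0, sxx)
    beta = sxy / sxx_safe
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / ((n - 2) * sxx_safe))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    beta[degenerate] = 0.0
    se[degenerate] = np.nan
    p[degenerate] = 1.0

    af = G.allele_frequencies()
    maf = np.minimum(af, 1 - af)
    return GwaScan(
        variants=G.variants.copy(),
        beta=beta,
        se=se,
        p=p,
        maf=maf,
        n_used=n,
        degenerate=degenerate,
    )


def variance_explained_top_snps(
    scan: GwaScan,
    G: GenotypeMatrix,
    y: np.ndarray,
    alpha: float = 5e-8,
    window_kb: float = 1000.0,
) -> float:
    """Adjusted R^2 of a joint OLS on window-pruned significant SNPs.

    SNPs with p < ``alpha`` are pruned by keeping the most significant
    SNP per ``window_kb`` window per chromosome (distance-based
    independence), then jointly regressed on the phenotype.
    """
    if scan.n_snps != G.n_variants:
        raise ValueError("scan and genotype matrix are not aligned")
    hits = np.flatnonzero((scan.p < alpha) & ~scan.degenerate)
    if hits.size == 0:
        return 0.0
    order = hits[np.argsort(scan.p[hits], kind="stable")]
    chrom = scan.variants["chrom"].to_numpy()
    bp = scan.variants["bp"].to_numpy()
    window_bp = window_kb * 1000.0
    kept = []
    for j in order:
        if all(chrom[k] != chrom[j] or abs(int(bp[k]) - int(bp[j])) > window_bp for k in kept):
            kept.append(j)
    kept = np.array(sorted(kept))

    y = np.asarray(y, dtype=float)
    rows = ~np.isnan(y)
    yv = y[rows]
    x = G.dosage_float()[np.ix_(rows, kept)]
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    X = np.column_stack([np.ones(yv.size), x])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    n, k = yv.size, kept.size
    tss = float(((yv - yv.mean()) ** 2).sum())
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return float(max(adj, 0.0))


def theta_p(scan: GwaScan, threshold: float) -> float:
    """Fraction of SNPs with association p below ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return float((scan.p < threshold).sum() / scan.n_snps)


def theta_curve(scan: GwaScan, thresholds=None) -> np.ndarray:
    """theta_P evaluated on a threshold grid (default grid if omitted)."""
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    return np.array([theta_p(scan, t) for t in thresholds])


def theta_h2_correlation_scan(
    thetas,
    h2,
    thresholds=None,
    trait_names=None,
    exclude_zero_h2: bool = True,
) -> ThetaScan:
    """Pearson correlation of theta_P with h2_SNP across traits, per threshold.

    ``thetas`` is (n_traits x n_thresholds). Traits with h2 <= 0 are
    excluded by default (they sit at the zero boundary). Thresholds where
    either vector is constant get a NaN correlation; the argmax is taken
    over defined values.
    """
    thetas = np.asarray(thetas, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if thetas.ndim != 2 or thetas.shape != (h2.size, thresholds.size):
        raise ValueError("thetas must be (n_traits x n_thresholds)")
    names = tuple(trait_names) if trait_names is not None else tuple(
        f"trait{i + 1}" for i in range(h2.size)
    )
    if exclude_zero_h2:
        keep = h2 > 0
    else:
        keep = np.ones(h2.size, dtype=bool)
    if keep.sum() < 3:
        raise ValueError("need at least 3 traits with non-zero h2")
    th = thetas[keep]
    hv = h2[keep]
    corr = np.full(thresholds.size, np.nan)
    hs = hv.std()
    for j in range(thresholds.size):
        ts = th[:, j].std()
        if ts > 0 and hs > 0:
            corr[j] = float(np.corrcoef(th[:, j], hv)[0, 1])
    if np.isnan(corr).all():
        raise ValueError("correlation undefined at every threshold")
    jmax = int(np.nanargmax(corr))
    return ThetaScan(
        thresholds=thresholds,
        theta=th,
        correlations=corr,
        argmax_threshold=float(thresholds[jmax]),
        r_max=float(corr[jmax]),
        trait_names=tuple(np.array(names)[keep]),
    )
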