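"""SNP quality control, GRM construction and relatedness pruning.

QC removes SNPs with missingness > 5%, MAF < 0.01 or an exact
Hardy-Weinberg test p-value < 1e-6 (in that order, each on the surviving
set). The GRM is the standard cross-product of standardized dosages
averaged over SNPs; unrelated-subset selection greedily removes the
individual involved in the most pairs above the relationship cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import QcError
from .genotypes import MISSING, GenotypeMatrix


@dataclass
class QcReport:
    """Per-filter SNP removal counts, in filter order."""

    n_input: int
    n_removed_missingness: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        total = (
            self.n_removed_missingness
            + self.n_removed_maf
            + self.n_removed_hwe
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("QC counts do not add up to n_input")


@dataclass
class GRM:
    """Symmetric n x n genetic relationship estimates.

    ``pair_snp_counts`` records the number of SNPs with non-missing calls
    in both members of each pair (diagnostic only; missing calls are
    mean-imputed in the estimator itself).
    """

    values: np.ndarray
    pair_snp_counts: np.ndarray
    samples: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM must be symmetric to 1e-12")
        self.pair_snp_counts = np.asarray(self.pair_snp_counts)
        if self.pair_snp_counts.shape != (n, n):
            raise ValueError("pair_snp_counts must match the GRM shape")
        if (self.pair_snp_counts < 1).any():
            raise ValueError("pair_snp_counts must be >= 1 wherever defined")
        self.samples = np.asarray(self.samples, dtype=object)
        if len(self.samples) != n:
            raise ValueError("sample ids must match the GRM dimension")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, selector) -> "GRM":
        sel = np.asarray(selector)
        if sel.dtype == bool:
            idx = np.flatnonzero(sel)
        elif np.issubdtype(sel.dtype, np.integer):
            idx = sel
        else:
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in sel])
        return GRM(
            values=self.values[np.ix_(idx, idx)].copy(),
            pair_snp_counts=self.pair_snp_counts[np.ix_(idx, idx)].copy(),
            samples=self.samples[idx].copy(),
        )


# ----------------------------------------------------------------------
# Hardy-Weinberg tests
# ----------------------------------------------------------------------
def _hwe_log_probs(n_het_obs_parity: int, n_rare: int, n_total: int):
    """Log-probabilities of every admissible heterozygote count.

    Given ``n_rare`` copies of the rarer allele among ``n_total``
    diploid individuals, heterozygote counts share the parity of
    ``n_rare`` and range up to min(n_rare, 2*n_total - n_rare). Uses the
    standard hypergeometric recurrence in log space.
    """
    n_common = 2 * n_total - n_rare
    h_max = min(n_rare, n_common)
    h_min = n_het_obs_parity  # 0 or 1, parity anchor
    hs = np.arange(h_min, h_max + 1, 2)
    if hs.size == 0:
        hs = np.array([h_min])
    # ratio P(h+2)/P(h) = 4 * nAA(h) * naa(h) / ((h+2)(h+1))
    # with nAA(h) = (n_rare - h)/2, naa(h) = (n_common - h)/2
    log_ratios = np.zeros(hs.size)
    if hs.size > 1:
        h = hs[:-1].astype(float)
        num = (n_rare - h) * (n_common - h)  # 4 * nAA * naa
        den = (h + 2.0) * (h + 1.0)
        log_ratios[1:] = np.log(num) - np.log(den)
    logp = np.cumsum(log_ratios)
    logp -= logsumexp(logp)
    return hs, logp


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (conditional on the
    allele counts) whose probability does not exceed that of the observed
    count, under the hypergeometric null.
    """
    counts = (int(n_hom1), int(n_het), int(n_hom2))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n_total = sum(counts)
    if n_total < 1:
        raise ValueError("at least one genotyped individual is required")
    n_a1 = 2 * counts[0] + counts[1]
    n_rare = min(n_a1, 2 * n_total - n_a1)
    hs, logp = _hwe_log_probs(n_rare % 2, n_rare, n_total)
    obs = counts[1]
    k = np.flatnonzero(hs == obs)
    if k.size == 0:
        raise ValueError(
            f"heterozygote count {obs} inconsistent with allele counts"
        )
    lp_obs = logp[k[0]]
    keep = logp <= lp_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def hwe_chisq_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """1-df chi-square Hardy-Weinberg p-value (PLINK's non-default mode)."""
    counts = np.array([n_hom1, n_het, n_hom2], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotyped individual is required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    if (expected == 0).any():
        return 1.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(G: GenotypeMatrix):
    d = G.dosages
    return (
        (d == 2).sum(axis=0),
        (d == 1).sum(axis=0),
        (d == 0).sum(axis=0),
    )


# ----------------------------------------------------------------------
def apply_snp_qc(
    G: GenotypeMatrix,
    miss_max: float = 0.05,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    hwe_method: str = "exact",
):
    """Remove SNPs failing missingness, MAF, then HWE filters.

    Thresholds are strict in the direction the defaults read: removed if
    missingness > ``miss_max``, MAF < ``maf_min``, or HWE p < ``hwe_alpha``.
    Returns the filtered matrix and a :class:`QcReport`.
    """
    if G.n_variants == 0:
        raise QcError("empty genotype matrix")
    n = G.n_samples
    miss_rate = (G.dosages == MISSING).sum(axis=0) / n
    keep = miss_rate <= miss_max
    n_miss = int((~keep).sum())

    p = G.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    with np.errstate(invalid="ignore"):
        fail_maf = keep & ((maf < maf_min) | ~np.isfinite(maf))
    n_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    test = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test
    n2, n1, n0 = _genotype_counts(G)
    fail_hwe = np.zeros(G.n_variants, dtype=bool)
    for j in np.flatnonzero(keep):
        if test(int(n2[j]), int(n1[j]), int(n0[j])) < hwe_alpha:
            fail_hwe[j] = True
    n_hwe = int(fail_hwe.sum())
    keep &= ~fail_hwe

    if not keep.any():
        raise QcError("all SNPs removed by QC")
    report = QcReport(
        n_input=G.n_variants,
        n_removed_missingness=n_miss,
        n_removed_maf=n_maf,
        n_removed_hwe=n_hwe,
        n_retained=int(keep.sum()),
        thresholds={
            "miss_max": miss_max,
            "maf_min": maf_min,
            "hwe_alpha": hwe_alpha,
            "hwe_method": hwe_method,
        },
    )
    return G.subset_variants(keep), report


# ----------------------------------------------------------------------
def compute_grm(
    G: GenotypeMatrix,
    dtype=np.float64,
    gcta_diagonal: bool = False,
    with_counts: bool = True,
) -> GRM:
    """Genetic relationship matrix from standardized dosages.

    A_jk = (1/m) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
    with sample allele frequencies and mean-imputed missing calls. With
    ``gcta_diagonal`` the diagonal uses the within-individual correction
    1 + (x^2 - (1 + 2p) x + 2 p^2) / (2 p (1 - p)) instead.
    """
    p = G.allele_frequencies()
    if np.any((p <= 0) | (p >= 1) | ~np.isfinite(p)):
        raise ValueError("GRM requires every SNP to have 0 < p < 1 (run QC first)")
    m = G.n_variants
    W = G.standardized(dtype=dtype)
    A = (W @ W.T) / m
    A = np.asarray((A + A.T) / 2.0, dtype=np.float64)

    if gcta_diagonal:
        x = G.dosage_float()
        num = x * x - (1 + 2 * p) * x + 2 * p * p
        den = 2 * p * (1 - p)
        terms = num / den
        diag = 1.0 + np.nanmean(terms, axis=1)
        np.fill_diagonal(A, diag)

    if with_counts and (G.dosages == MISSING).any():
        obs = (G.dosages != MISSING).astype(np.float32)
        counts = np.rint(obs @ obs.T).astype(np.int64)
    else:
        counts = np.full((G.n_samples, G.n_samples), m, dtype=np.int64)
    return GRM(values=A, pair_snp_counts=counts, samples=G.samples.copy())


def select_unrelated(A: GRM, cutoff: float = 0.025) -> np.ndarray:
    """Greedy unrelated-subset selection.

    Repeatedly removes the individual participating in the most pairs
    with relationship > ``cutoff`` (ties broken by removing the
    lexicographically smallest sample id) until no pair exceeds the
    cutoff. Returns retained sample ids in their original order.
    """
    n = A.n_samples
    adj = A.values > cutoff
    np.fill_diagonal(adj, False)
    active = np.ones(n, dtype=bool)
    degrees = adj.sum(axis=1)
    ids = A.samples.astype(str)
    while True:
        degrees_active = np.where(active, degrees, -1)
        dmax = degrees_active.max()
        if dmax <= 0:
            break
        cand = np.flatnonzero(degrees_active == dmax)
        victim = cand[np.argmin(ids[cand])]
        active[victim] = False
        degrees -= adj[:, victim].astype(int)
        adj[victim, :] = False
        adj[:, victim] = False
        degrees[victim] = 0
    return A.samples[active]
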