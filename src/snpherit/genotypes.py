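"""Core genotype container shared by every analysis stage.

Dosages are stored as an ``int8`` matrix (individuals x SNPs) holding the
count of A1 alleles, with :data:`MISSING` (-1) marking missing calls.
Variant metadata travels alongside as a :class:`pandas.DataFrame` with
columns ``chrom``, ``bp``, ``id``, ``a1``, ``a2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ("chrom", "bp", "id", "a1", "a2")


@dataclass
class GenotypeMatrix:
    """n x m allele-dosage matrix plus variant and sample metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x SNPs) array")
        n, m = self.dosages.shape
        if self.samples is None:
            self.samples = np.array([f"id{i + 1}" for i in range(n)])
        self.samples = np.asarray(self.samples, dtype=object)
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if not isinstance(self.variants, pd.DataFrame):
            self.variants = pd.DataFrame(self.variants)
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table lacks columns {sorted(missing_cols)}")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} columns")
        self.variants = self.variants.reset_index(drop=True)
        bad = (self.dosages < MISSING) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosage values must lie in {0, 1, 2} or be MISSING (-1)")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"]
            raise ValueError(f"duplicate variant ids: {list(dups[:5])}")
        if (self.variants["bp"].to_numpy() <= 0).any():
            raise ValueError("variant bp positions must be positive (1-based)")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        """Boolean n x m mask of missing calls."""
        return self.dosages == MISSING

    def dosage_float(self, dtype=np.float64) -> np.ndarray:
        """Dosages as floats with NaN in place of missing calls."""
        x = self.dosages.astype(dtype)
        x[self.dosages == MISSING] = np.nan
        return x

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP A1 allele frequency from non-missing calls."""
        obs = self.dosages != MISSING
        counts = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sums = np.where(self.dosages == MISSING, 0, self.dosages).sum(axis=0)
            p = sums / (2.0 * counts)
        return p

    def standardized(self, dtype=np.float64) -> np.ndarray:
        """Centered and scaled dosages, (x - 2p)/sqrt(2p(1-p)).

        Missing calls are mean-imputed, i.e. set to zero after centering.
        SNPs must be polymorphic (0 < p < 1).
        """
        p = self.allele_frequencies()
        if np.any((p <= 0) | (p >= 1) | ~np.isfinite(p)):
            raise ValueError("standardization requires 0 < p < 1 for every SNP")
        x = self.dosages.astype(dtype)
        x[self.dosages == MISSING] = 0.0
        center = (2.0 * p).astype(dtype)
        scale = np.sqrt(2.0 * p * (1.0 - p)).astype(dtype)
        w = (x - center) / scale
        w[self.dosages == MISSING] = 0.0
        return w

    # ------------------------------------------------------------------
    def subset_variants(self, selector) -> "GenotypeMatrix":
        """New matrix restricted to variants picked by a boolean mask,
        integer positions, or an iterable of variant ids."""
        idx = self._variant_indices(selector)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx].copy(),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def subset_samples(self, selector) -> "GenotypeMatrix":
        """New matrix restricted to the given samples (mask, positions or ids)."""
        sel = np.asarray(selector)
        if sel.dtype == bool:
            idx = np.flatnonzero(sel)
        elif np.issubdtype(sel.dtype, np.integer):
            idx = sel
        else:
            lookup = {s: i for i, s in enumerate(self.samples)}
            try:
                idx = np.array([lookup[s] for s in sel])
            except KeyError as e:
                raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return GenotypeMatrix(
            dosages=self.dosages[idx, :].copy(),
            variants=self.variants.copy(),
            samples=self.samples[idx].copy(),
        )

    def _variant_indices(self, selector) -> np.ndarray:
        sel = np.asarray(selector)
        if sel.dtype == bool:
            if sel.size != self.n_variants:
                raise ValueError("boolean variant mask has wrong length")
            return np.flatnonzero(sel)
        if np.issubdtype(sel.dtype, np.integer):
            return sel
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            return np.array([lookup[v] for v in sel])
        except KeyError as e:
            raise KeyError(f"unknown variant id {e.args[0]!r}") from None
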