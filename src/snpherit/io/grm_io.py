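"""GRM interchange in the GCTA text and binary conventions.

Text: ``<prefix>.grm.gz`` holds gzip-compressed tab-separated lower
triangle rows (index1 index2 n_snps value, 1-based, index1 >= index2)
with sample ids in ``<prefix>.grm.id``. Binary: ``<prefix>.grm.bin``
holds the lower triangle as little-endian float32 and
``<prefix>.grm.N.bin`` the per-pair SNP counts as float32.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from ..qc_grm import GRM


def _tri_indices(n):
    rows, cols = np.tril_indices(n)
    return rows, cols


def _write_ids(prefix, samples):
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{s}\n")


def _read_ids(prefix):
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None, names=["fid", "iid"], dtype=str)
    return ids["iid"].to_numpy(dtype=object)


def write_grm_text(grm: GRM, prefix) -> None:
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    rows, cols = _tri_indices(grm.n_samples)
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i, j in zip(rows, cols):
            fh.write(
                f"{i + 1}\t{j + 1}\t{grm.pair_snp_counts[i, j]}\t"
                f"{grm.values[i, j]:.10g}\n"
            )
    _write_ids(prefix, grm.samples)


def read_grm_text(prefix) -> GRM:
    samples = _read_ids(prefix)
    n = len(samples)
    tab = pd.read_csv(
        f"{prefix}.grm.gz", sep="\t", header=None,
        names=["i", "j", "n_snps", "value"], compression="gzip",
    )
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    i = tab["i"].to_numpy() - 1
    j = tab["j"].to_numpy() - 1
    values[i, j] = tab["value"]
    values[j, i] = tab["value"]
    counts[i, j] = tab["n_snps"]
    counts[j, i] = tab["n_snps"]
    return GRM(values=values, pair_snp_counts=counts, samples=samples)


def write_grm_bin(grm: GRM, prefix) -> None:
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    rows, cols = _tri_indices(grm.n_samples)
    grm.values[rows, cols].astype("<f4").tofile(f"{prefix}.grm.bin")
    grm.pair_snp_counts[rows, cols].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    _write_ids(prefix, grm.samples)


def read_grm_bin(prefix) -> GRM:
    samples = _read_ids(prefix)
    n = len(samples)
    k = n * (n + 1) // 2
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    cnt = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    if tri.size != k or cnt.size != k:
        raise ValueError(f"{prefix}: binary GRM size does not match {n} ids")
    rows, cols = _tri_indices(n)
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    values[rows, cols] = tri
    values[cols, rows] = tri
    counts[rows, cols] = cnt
    counts[cols, rows] = cnt
    return GRM(
        values=values,
        pair_snp_counts=np.rint(counts).astype(np.int64),
        samples=samples,
    )
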