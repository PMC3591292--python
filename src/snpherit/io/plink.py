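"""PLINK bed/bim/fam reading and writing (SNP-major v1 layout).

The bed codec follows the documented 2-bit encoding: per SNP,
individuals are packed four to a byte, low bits first, with
00 = homozygous A1 (dosage 2), 01 = missing, 10 = heterozygous and
11 = homozygous A2 (dosage 0). Trailing pad bits in each SNP's final
byte are ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..genotypes import MISSING, GenotypeMatrix

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage of A1
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _paths(prefix):
    prefix = Path(prefix)
    return (
        prefix.with_suffix(".bed"),
        prefix.with_suffix(".bim"),
        prefix.with_suffix(".fam"),
    )


def read_plink(prefix=None, bed=None, bim=None, fam=None) -> GenotypeMatrix:
    """Load a PLINK fileset, by shared prefix or explicit paths."""
    if prefix is not None:
        bed, bim, fam = _paths(prefix)
    if bed is None or bim is None or fam is None:
        raise ValueError("provide either a prefix or all of bed/bim/fam")

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n = len(fam_df)
    m = len(bim_df)

    raw = Path(bed).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise ValueError(
            f"{bed}: bad magic bytes {raw[:3].hex()} (want {BED_MAGIC.hex()}; "
            "only SNP-major v1 bed files are supported)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f"{bed}: {len(raw)} bytes, expected {expected} for {n} samples x {m} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, low bits = first individual
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)

    variants = bim_df[["chrom", "bp", "id", "a1", "a2"]].copy()
    samples = fam_df["iid"].to_numpy(dtype=object)
    return GenotypeMatrix(dosages=np.ascontiguousarray(dosages), variants=variants, samples=samples)


def write_plink(G: GenotypeMatrix, prefix, fid=None) -> None:
    """Write a GenotypeMatrix as SNP-major bed plus bim/fam text files."""
    bed, bim, fam = _paths(prefix)
    bed.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_samples, G.n_variants
    bytes_per_snp = (n + 3) // 4

    code_lut = np.empty(4, dtype=np.uint8)  # index by dosage + 1 (missing -> 0)
    code_lut[MISSING + 1] = _DOSAGE_TO_CODE[MISSING]
    for d in (0, 1, 2):
        code_lut[d + 1] = _DOSAGE_TO_CODE[d]
    codes = code_lut[G.dosages.T.astype(np.int16) + 1]  # (m, n)
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    # pad positions encode dosage 0 (code 11)? PLINK pads with zero bits.
    out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        out |= padded[:, shift::4] << (2 * shift)
    with open(bed, "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(out.tobytes())

    v = G.variants
    bim_df = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "bp": v["bp"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim_df.to_csv(bim, sep="\t", header=False, index=False)
    fids = fid if fid is not None else G.samples
    fam_df = pd.DataFrame(
        {
            "fid": fids,
            "iid": G.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam_df.to_csv(fam, sep="\t", header=False, index=False)
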