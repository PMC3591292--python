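"""TSV readers/writers for phenotypes, truth tables and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..phenotype_prep import COVARIATE_COLS, PhenotypeTable
from ..synthetic_data import SimTruth


def write_phenotypes(table: PhenotypeTable, path) -> None:
    """Write FID, IID, age, sex, cohort and trait columns as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = table.data.copy()
    out.insert(0, "IID", table.data.index)
    out.insert(0, "FID", table.data.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"FID": str, "IID": str})
    df = df.set_index("IID").drop(columns=["FID"])
    df.index.name = None
    trait_names = [c for c in df.columns if c not in COVARIATE_COLS]
    return PhenotypeTable(data=df, trait_names=trait_names)


def write_truth(truth: SimTruth, path) -> None:
    """Per-causal-SNP effects plus summary lines in TSV comments."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# true_h2\t{truth.true_h2:.10g}\n")
        for k, v in truth.true_component_fractions.items():
            fh.write(f"# fraction\t{k}\t{v:.10g}\n")
        fh.write("id\teffect\n")
        for vid, eff in zip(truth.causal_ids, truth.effects):
            fh.write(f"{vid}\t{eff:.10g}\n")


def write_reml_table(rows, path, comment="Per-trait single-GRM REML estimates") -> None:
    """Per-trait fit table: trait, n, estimate, SE, p (plus flags)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def reml_table_row(trait: str, fit) -> dict:
    return {
        "trait": trait,
        "n": fit.n_used,
        "estimate": fit.h2_total,
        "se": fit.h2_total_se,
        "p": fit.lrt_p,
        "constrained": bool(np.asarray(fit.constrained).any()),
    }


def write_tsv(df: pd.DataFrame, path, comment=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
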