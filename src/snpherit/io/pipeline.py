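"""Configuration and the end-to-end analysis pipeline.

Chains QC -> GRM -> relatedness pruning -> phenotype adjustment ->
per-trait REML -> GWA + theta_P scan -> chromosome (and optional region)
partitioning, writing every stage's table under the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..errors import ConfigurationError
from ..gwa_theta import (
    default_threshold_grid,
    gwa_scan,
    theta_curve,
    theta_h2_correlation_scan,
    variance_explained_top_snps,
)
from ..partitioning import (
    RegionSet,
    aggregate_across_traits,
    fit_region_partition,
    length_variance_regression,
    partition_by_chromosome,
)
from ..phenotype_prep import adjust_and_standardize
from ..qc_grm import apply_snp_qc, compute_grm, select_unrelated
from ..reml import RemlModel, fit_reml
from .grm_io import write_grm_text
from .plink import read_plink
from .tables import read_phenotypes, reml_table_row, write_reml_table, write_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-compatible)."""

    genotypes: str
    phenotypes: str
    out_dir: str
    regions: str = None  # BED path
    region_pad_kb: float = 0.0
    traits: list = None  # default: every trait column
    miss_max: float = 0.05
    maf_min: float = 0.01
    hwe_alpha: float = 1e-6
    relatedness_cutoff: float = 0.025
    gwa_alpha: float = 5e-8
    threshold_grid: list = None  # default 0.001..0.201 by 0.005
    do_chromosome_partition: bool = True
    write_grm: bool = False
    seed: int = 0
    log_level: str = "INFO"
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.miss_max <= 1:
            raise ConfigurationError("miss_max must lie in [0, 1]")
        if not 0 <= self.maf_min <= 0.5:
            raise ConfigurationError("maf_min must lie in [0, 0.5]")
        if not 0 < self.hwe_alpha < 1:
            raise ConfigurationError("hwe_alpha must lie in (0, 1)")
        if self.relatedness_cutoff < 0:
            raise ConfigurationError("relatedness_cutoff must be non-negative")
        for p, what in ((self.genotypes, "genotypes"), (self.phenotypes, "phenotypes")):
            probe = Path(p)
            if what == "genotypes":
                probe = Path(f"{p}.bed")
            if not probe.exists():
                raise ConfigurationError(f"{what} path not found: {probe}")
        if self.regions is not None and not Path(self.regions).exists():
            raise ConfigurationError(f"regions path not found: {self.regions}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all tables under ``config.out_dir``.

    Returns a bundle of in-memory results keyed by stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)

    bundle = {}
    logger.info("stage qc: reading %s", config.genotypes)
    G = read_plink(config.genotypes)
    G_qc, report = apply_snp_qc(
        G, miss_max=config.miss_max, maf_min=config.maf_min, hwe_alpha=config.hwe_alpha
    )
    bundle["qc_report"] = report
    write_tsv(
        pd.DataFrame([{
            "n_input": report.n_input,
            "n_removed_missingness": report.n_removed_missingness,
            "n_removed_maf": report.n_removed_maf,
            "n_removed_hwe": report.n_removed_hwe,
            "n_retained": report.n_retained,
        }]),
        out / "qc_report.tsv",
        comment="SNP QC summary (filters applied missingness -> MAF -> HWE)",
    )

    logger.info("stage grm: %d samples x %d SNPs", G_qc.n_samples, G_qc.n_variants)
    grm = compute_grm(G_qc)
    if config.write_grm:
        write_grm_text(grm, out / "grm")
    unrelated = select_unrelated(grm, cutoff=config.relatedness_cutoff)
    bundle["unrelated_ids"] = unrelated
    pd.DataFrame({"iid": unrelated}).to_csv(out / "unrelated_ids.tsv", sep="\t", index=False)

    pheno = read_phenotypes(config.phenotypes)
    common = [s for s in unrelated if s in set(pheno.samples)]
    G_u = G_qc.subset_samples(np.asarray(common, dtype=object))
    pheno.data = pheno.data.loc[common]
    grm_u = grm.subset(np.asarray(common, dtype=object))
    traits = config.traits or pheno.trait_names

    logger.info("stage adjust: %d traits on %d samples", len(traits), len(common))
    adjusted = {t: adjust_and_standardize(pheno, t).to_numpy() for t in traits}
    adj_df = pd.DataFrame(adjusted, index=common)
    adj_df.insert(0, "IID", common)
    write_tsv(adj_df, out / "adjusted_phenotypes.tsv",
              comment="age-adjusted cohort x sex z-scores")

    logger.info("stage reml")
    fits = {}
    rows = []
    for t in traits:
        fit = fit_reml(RemlModel(y=adjusted[t], components={"genome": grm_u.values}))
        fits[t] = fit
        rows.append(reml_table_row(t, fit))
    bundle["reml"] = fits
    write_reml_table(rows, out / "reml_estimates.tsv",
                     comment="per-trait variance explained by all SNPs")

    logger.info("stage gwa + theta")
    grid = (
        np.asarray(config.threshold_grid, dtype=float)
        if config.threshold_grid
        else default_threshold_grid()
    )
    thetas = []
    top_r2 = {}
    for t in traits:
        scan = gwa_scan(G_u, adjusted[t])
        thetas.append(theta_curve(scan, grid))
        top_r2[t] = variance_explained_top_snps(scan, G_u, adjusted[t], alpha=config.gwa_alpha)
    thetas = np.vstack(thetas)
    theta_df = pd.DataFrame(thetas.T, columns=traits)
    theta_df.insert(0, "threshold", grid)
    write_tsv(theta_df, out / "theta_curves.tsv", comment="theta_P per trait per threshold")
    write_tsv(
        pd.DataFrame({"trait": traits, "top_snp_r2": [top_r2[t] for t in traits]}),
        out / "top_snp_r2.tsv",
        comment="adjusted R^2 of window-pruned genome-wide-significant SNPs",
    )
    bundle["top_snp_r2"] = top_r2

    h2 = np.array([fits[t].h2_total for t in traits])
    if (h2 > 0).sum() >= 3:
        scan47 = theta_h2_correlation_scan(thetas, h2, grid, trait_names=traits)
        bundle["theta_scan"] = scan47
        write_tsv(
            pd.DataFrame({"threshold": grid, "r": scan47.correlations}),
            out / "theta_h2_correlation.tsv",
            comment=f"argmax threshold {scan47.argmax_threshold} (r={scan47.r_max:.3f})",
        )

    if config.do_chromosome_partition and G_u.variants["chrom"].nunique() >= 2:
        logger.info("stage chromosome partition")
        parts = []
        for t in traits:
            if fits[t].h2_total <= 0:
                continue  # zero-estimate traits carry no partition signal
            parts.append(partition_by_chromosome(G_u, adjusted[t], trait=t))
        if parts:
            write_tsv(
                pd.concat([p.to_frame() for p in parts]),
                out / "chromosome_partition.tsv",
                comment="per-trait per-chromosome variance fractions",
            )
            agg = aggregate_across_traits(parts, mode="genetic-fraction-mean")
            lengths = parts[0].lengths
            reg = length_variance_regression(agg.values, lengths / lengths.sum())
            bundle["chromosome_partition"] = parts
            bundle["length_regression"] = reg
            write_tsv(
                pd.DataFrame([reg._asdict()]),
                out / "length_regression.tsv",
                comment="genetic-fraction mean vs relative chromosome length",
            )

    if config.regions is not None:
        logger.info("stage region partition")
        regions = RegionSet.from_bed(config.regions, name="genic", pad_kb=config.region_pad_kb)
        parts = []
        for t in traits:
            if fits[t].h2_total <= 0:
                continue
            parts.append(fit_region_partition(G_u, adjusted[t], regions, trait=t))
        if parts:
            write_tsv(
                pd.concat([p.to_frame() for p in parts]),
                out / "region_partition.tsv",
                comment="per-trait genic/intergenic variance fractions",
            )
            bundle["region_partition"] = parts

    logger.info("pipeline complete: outputs in %s", out)
    return bundle
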