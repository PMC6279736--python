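"""Partition complex-trait heritability into mQTL and rest-of-genome parts.

GWAS χ² statistics are regressed on the stratified LD scores,

    χ²_j = α + β_mQTL · L_j,mQTL + β_G · L_j,G ,

by ordinary least squares, and each slope converts to a heritability
component h²_c = β_c · M_c / N_GWAS, with M_c the number of SNPs in the
component and N_GWAS the GWAS sample size (cases + controls for case-
control studies). The quantity of interest is the proportion of explained
heritability attributable to mQTL, h²_mQTL / (h²_mQTL + h²_G). Inference
comes from matched-null resampling (``mqtlkit.nulls``), not from the OLS
standard errors, which are reported for orientation only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mqtlkit.containers import LDScoreTable, SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class PartitionFit:
    alpha: float
    beta_mqtl: float
    beta_g: float
    se_alpha: float
    se_beta_mqtl: float
    se_beta_g: float
    m_mqtl: int
    m_g: int
    n_gwas: float
    h2_mqtl: float
    h2_g: float
    proportion: float
    n_snps_fit: int


def exclude_region(
    sumstats: SummaryStats, ldscores: LDScoreTable, chrom: str, start: int, end: int
) -> tuple[SummaryStats, LDScoreTable]:
    """Mask a genomic region (e.g. the HLA block) out of the fit inputs."""
    tab = ldscores.table
    drop = (tab["chrom"].astype(str) == str(chrom)) & tab["pos"].between(start, end)
    keep_ids = set(tab.loc[~drop, "snp_id"])
    ss = SummaryStats(
        table=sumstats.table[sumstats.table["snp_id"].isin(keep_ids)].reset_index(drop=True)
    )
    ld = LDScoreTable(table=tab.loc[~drop].reset_index(drop=True), n_ref=ldscores.n_ref)
    return ss, ld


def fit_partition(
    sumstats: SummaryStats,
    ldscores: LDScoreTable,
    n_gwas: float | None = None,
    membership_threshold: float = 0.5,
) -> PartitionFit:
    """OLS of χ² on (1, L_mQTL, L_G) and conversion to h² components.

    SNPs are joined on id; M_mQTL / M_G are the component SNP counts, read
    off the self-indicator part of the stratified scores. Negative h²
    estimates are reported as-is with a warning. Collinear score columns
    abort the fit.
    """
    merged = sumstats.table.merge(ldscores.table, on="snp_id", how="inner")
    if len(merged) < 100:
        raise ValueError(f"only {len(merged)} SNPs after join; need >= 100")
    if n_gwas is None:
        n_gwas = float(merged["n"].median())
    if "is_mqtl" not in merged.columns:
        raise ValueError("LD-score table must carry the is_mqtl membership column")
    is_mqtl = merged["is_mqtl"].to_numpy(bool)
    y = merged["chisq"].to_numpy()
    if not is_mqtl.any():
        # empty mQTL component: the model collapses to single-column
        # LD-score regression with β_mQTL pinned at 0
        design = sm.add_constant(merged[["L_G"]].to_numpy())
        res = sm.OLS(y, design).fit()
        alpha, beta_g = res.params
        beta_mqtl = 0.0
        se = [res.bse[0], 0.0, res.bse[1]]
    else:
        x = merged[["L_mqtl", "L_G"]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) < 3:
            raise ValueError("collinear LD-score columns; fit aborted")
        design = sm.add_constant(x)
        res = sm.OLS(y, design).fit()
        alpha, beta_mqtl, beta_g = res.params
        se = list(res.bse)
    m_mqtl = int(is_mqtl.sum())
    m_g = int(len(merged) - m_mqtl)
    h2_mqtl = beta_mqtl * m_mqtl / n_gwas
    h2_g = beta_g * m_g / n_gwas
    if h2_mqtl < 0 or h2_g < 0:
        warnings.warn("negative heritability component estimate; reported untruncated",
                      stacklevel=2)
    denom = h2_mqtl + h2_g
    proportion = h2_mqtl / denom if denom != 0 else float("nan")
    return PartitionFit(
        alpha=float(alpha), beta_mqtl=float(beta_mqtl), beta_g=float(beta_g),
        se_alpha=float(se[0]), se_beta_mqtl=float(se[1]), se_beta_g=float(se[2]),
        m_mqtl=m_mqtl, m_g=m_g, n_gwas=float(n_gwas),
        h2_mqtl=float(h2_mqtl), h2_g=float(h2_g), proportion=float(proportion),
        n_snps_fit=len(merged),
    )


def proportion_of_heritability(fit: PartitionFit) -> float:
    """h²_mQTL / (h²_mQTL + h²_G); undefined when both components ≤ 0."""
    if fit.h2_mqtl <= 0 and fit.h2_g <= 0:
        raise ValueError("both heritability components non-positive; proportion undefined")
    return fit.h2_mqtl / (fit.h2_mqtl + fit.h2_g)


__all__ = [
    "PartitionFit",
    "exclude_region",
    "fit_partition",
    "proportion_of_heritability",
]
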