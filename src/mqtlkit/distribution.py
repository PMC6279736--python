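"""Subtelomeric and per-chromosome distribution of trans mQTL positions.

Trans-acting mQTL SNPs cluster in the 1 Mbp subtelomeric ends of
chromosomes and on gene-dense chromosomes. The subtelomeric test compares
the observed fraction of positions falling within a margin of either
chromosome end against the genome fraction those margins cover, with an
exact one-sided binomial test. The per-chromosome table compares observed
SNP counts against expectations proportional to gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# GRCh37/hg19 autosome lengths (bp); the analysis genome excludes sex
# chromosomes throughout.
GRCH37_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}


@dataclass
class SubtelomericConfig:
    margin_bp: int = 1_000_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(GRCH37_AUTOSOME_LENGTHS)
    )

    def __post_init__(self) -> None:
        shortest = min(self.chrom_lengths.values())
        if self.margin_bp < 0 or 2 * self.margin_bp > shortest:
            raise ValueError(
                f"margin {self.margin_bp} too large for shortest chromosome {shortest}"
            )


def subtelomeric_fraction(config: SubtelomericConfig | None = None) -> float:
    """Fraction of the genome inside the margin at either chromosome end."""
    config = config or SubtelomericConfig()
    total = sum(config.chrom_lengths.values())
    return 2.0 * config.margin_bp * len(config.chrom_lengths) / total


def is_subtelomeric(
    positions: pd.DataFrame, config: SubtelomericConfig | None = None
) -> np.ndarray:
    """Boolean mask: position within margin_bp of either end of its chromosome."""
    config = config or SubtelomericConfig()
    chroms = positions["chrom"].astype(str)
    unknown = sorted(set(chroms) - set(config.chrom_lengths))
    if unknown:
        raise ValueError(f"positions on unknown chromosomes: {unknown[:5]}")
    lengths = chroms.map(config.chrom_lengths).to_numpy(float)
    pos = positions["pos"].to_numpy(float)
    return (pos <= config.margin_bp) | (pos > lengths - config.margin_bp)


def subtelomeric_enrichment(
    positions: pd.DataFrame, config: SubtelomericConfig | None = None
) -> tuple[float, float]:
    """Observed subtelomeric fraction and one-sided exact binomial p.

    Tests whether more positions fall in the subtelomeric margins than the
    genome fraction they cover would predict under uniform placement.
    """
    config = config or SubtelomericConfig()
    if positions.empty:
        raise ValueError("empty position list")
    hits = int(is_subtelomeric(positions, config).sum())
    n = len(positions)
    expected = subtelomeric_fraction(config)
    p = stats.binomtest(hits, n, expected, alternative="greater").pvalue
    return hits / n, float(p)


def per_chromosome_distribution(
    snp_positions: pd.DataFrame,
    gene_counts: dict[str, int] | pd.Series,
    outlier_chroms: list[str] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Observed vs gene-count-proportional expected counts per chromosome.

    Returns ``(table, chi2_gof_p, correlation)``: the per-chromosome table
    with observed counts, expected counts (proportional to gene counts,
    summing to the observed total), and Pearson residuals
    (obs − exp)/√exp; the χ² goodness-of-fit p over all chromosomes; and
    the gene-count/SNP-count Pearson correlation excluding any
    ``outlier_chroms``.
    """
    gene_counts = pd.Series(gene_counts, dtype=float)
    obs = (
        snp_positions["chrom"].astype(str).value_counts()
        .reindex(gene_counts.index.astype(str), fill_value=0)
        .astype(float)
    )
    total = obs.sum()
    expected = gene_counts / gene_counts.sum() * total
    resid = (obs - expected) / np.sqrt(expected)
    table = pd.DataFrame(
        {"observed": obs, "gene_count": gene_counts.to_numpy(),
         "expected": expected.to_numpy(), "pearson_resid": resid.to_numpy()}
    )
    table.index.name = "chrom"
    chi2_p = float(stats.chisquare(obs.to_numpy(), expected.to_numpy()).pvalue)
    keep = ~table.index.isin(outlier_chroms or [])
    sub = table.loc[keep]
    if len(sub) >= 3 and sub["observed"].std() > 0 and sub["gene_count"].std() > 0:
        corr = float(np.corrcoef(sub["observed"], sub["gene_count"])[0, 1])
    else:
        corr = float("nan")
    return table, chi2_p, corr


__all__ = [
    "GRCH37_AUTOSOME_LENGTHS",
    "SubtelomericConfig",
    "is_subtelomeric",
    "per_chromosome_distribution",
    "subtelomeric_enrichment",
    "subtelomeric_fraction",
]
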