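"""Positional genomic annotation with category precedence.

Each position gets exactly one category. Within a transcript: coding-exon
bases are Exonic; exon bases 5'/3' of the CDS are UTR5/UTR3; intra-
transcript non-exon bases are Intronic; non-coding transcripts give
ncRNA-exonic / ncRNA-intronic. Outside transcripts, bases within the
upstream/downstream distance (default 2 Mbp, matching the cis-window
definition) of a transcript are Upstream (5' side, strand-aware) or
Downstream; everything else is Intergenic. When several transcripts
disagree, the highest-precedence category wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mqtlkit.containers import GeneModel

logger = logging.getLogger(__name__)

PRECEDENCE = [
    "Exonic",
    "UTR5",
    "UTR3",
    "ncRNA-exonic",
    "Intronic",
    "ncRNA-intronic",
    "Upstream",
    "Downstream",
    "Intergenic",
]
_RANK = {c: i for i, c in enumerate(PRECEDENCE)}


@dataclass
class AnnotationConfig:
    upstream_downstream_bp: int = 2_000_000
    precedence: list[str] = field(default_factory=lambda: list(PRECEDENCE))

    def __post_init__(self) -> None:
        if set(self.precedence) != set(PRECEDENCE):
            raise ValueError("precedence must be a total order over the category set")
        if self.upstream_downstream_bp < 0:
            raise ValueError("upstream/downstream distance must be non-negative")


def _tx_category(pos: int, tx: pd.Series, up_bp: int) -> str | None:
    """Category of ``pos`` relative to a single transcript, or None."""
    if tx["tx_start"] <= pos <= tx["tx_end"]:
        in_exon = any(s <= pos <= e for s, e in zip(tx["exon_starts"], tx["exon_ends"]))
        if not tx["coding"]:
            return "ncRNA-exonic" if in_exon else "ncRNA-intronic"
        if not in_exon:
            return "Intronic"
        if tx["cds_start"] <= pos <= tx["cds_end"]:
            return "Exonic"
        five_prime = pos < tx["cds_start"] if tx["strand"] == "+" else pos > tx["cds_end"]
        return "UTR5" if five_prime else "UTR3"
    if tx["tx_start"] - up_bp <= pos < tx["tx_start"]:
        return "Upstream" if tx["strand"] == "+" else "Downstream"
    if tx["tx_end"] < pos <= tx["tx_end"] + up_bp:
        return "Downstream" if tx["strand"] == "+" else "Upstream"
    return None


def annotate_position(
    chrom: str, pos: int, gene_model: GeneModel, config: AnnotationConfig | None = None
) -> str:
    """Annotate one position; highest-precedence category across transcripts."""
    config = config or AnnotationConfig()
    if gene_model.chrom_lengths and chrom not in gene_model.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    rank = {c: i for i, c in enumerate(config.precedence)}
    best = "Intergenic"
    txs = gene_model.transcripts
    for _, tx in txs[txs["chrom"] == chrom].iterrows():
        cat = _tx_category(pos, tx, config.upstream_downstream_bp)
        if cat is not None and rank[cat] < rank[best]:
            best = cat
    return best


def annotate_positions(
    positions: pd.DataFrame, gene_model: GeneModel, config: AnnotationConfig | None = None
) -> pd.Series:
    """Vector version: ``positions`` has columns chrom, pos."""
    config = config or AnnotationConfig()
    return pd.Series(
        [
            annotate_position(row["chrom"], row["pos"], gene_model, config)
            for _, row in positions.iterrows()
        ],
        index=positions.index,
        name="category",
    )


def category_table(
    positions: pd.DataFrame, gene_model: GeneModel, config: AnnotationConfig | None = None
) -> pd.DataFrame:
    """Per-category counts and proportions (summing to 1) for a position set."""
    if positions.empty:
        raise ValueError("empty position list")
    cats = annotate_positions(positions, gene_model, config)
    counts = cats.value_counts().reindex(PRECEDENCE, fill_value=0)
    out = pd.DataFrame({"count": counts, "proportion": counts / counts.sum()})
    out.index.name = "category"
    return out


def category_enrichment(
    subset_positions: pd.DataFrame,
    background_positions: pd.DataFrame,
    gene_model: GeneModel,
    config: AnnotationConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category 2×2 enrichment of a subset against a background.

    Columns: counts, odds ratio, χ² p (or exact p when any expected cell
    count is < 5), Bonferroni-adjusted p and a significance flag.
    """
    sub = category_table(subset_positions, gene_model, config)["count"]
    bg = category_table(background_positions, gene_model, config)["count"]
    n_sub, n_bg = sub.sum(), bg.sum()
    rows = []
    for cat in PRECEDENCE:
        a, b = int(sub[cat]), int(n_sub - sub[cat])
        c, d = int(bg[cat]), int(n_bg - bg[cat])
        table = np.array([[a, b], [c, d]], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        if table.sum() == 0 or a + c == 0:
            p = np.nan
        else:
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if expected.min() < 5:
                _, p = stats.fisher_exact([[a, b], [c, d]])
                logger.info("category_enrichment: exact test for %s (low expected count)", cat)
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"category": cat, "subset": a, "background": c,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows).set_index("category")
    m = out["p"].notna().sum()
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


__all__ = [
    "PRECEDENCE",
    "AnnotationConfig",
    "annotate_position",
    "annotate_positions",
    "category_enrichment",
    "category_table",
]
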