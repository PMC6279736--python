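"""Matched-null resampling for the mQTL heritability-proportion test.

The mQTL SNP set is first LD-pruned (greedy, most significant first, no
retained pair with r² > 0.8) so its LD structure resembles a random
MAF-matched draw. Null SNP sets are then sampled from the non-mQTL pool
with the target's exact per-stratum composition — MAF bins of width 0.05
(null #1), optionally crossed with the genomic-annotation category
(null #2). The observed mQTL heritability proportion is compared to the
null distribution via a one-sided upper-tail normal approximation
z = (obs − mean)/sd plus an empirical p-value (r+1)/(B+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mqtlkit.containers import GenotypeMatrix

logger = logging.getLogger(__name__)

MIN_B_FOR_NORMAL = 20


@dataclass
class NullTestResult:
    observed: float
    b: int
    null_mean: float
    null_sd: float
    z: float
    p_normal: float | None  # one-sided upper tail; None when B < 20
    p_empirical: float
    null_values: np.ndarray


def ld_prune(
    snp_ids: Sequence[str],
    geno_ref: GenotypeMatrix,
    r2_max: float = 0.8,
    order_p: dict[str, float] | None = None,
    window_bp: float = 1_000_000,
) -> list[str]:
    """Greedy LD pruning: keep SNPs in order of ascending p, drop any SNP
    with r² > ``r2_max`` to an already-retained SNP within ``window_bp``.

    Distal pairs (beyond the window) are assumed unlinked. With no p-values
    the input order is used. Idempotent on an already-pruned set.
    """
    idx = geno_ref.snp_index()
    ids = [s for s in snp_ids if s in idx.index]
    if order_p:
        ids = sorted(ids, key=lambda s: (order_p.get(s, 1.0), s))
    pos = geno_ref.snps.set_index("snp_id")
    dose = geno_ref.dosages
    kept: list[str] = []
    kept_cols: list[int] = []
    for s in ids:
        j = int(idx[s])
        chrom_j, pos_j = pos.loc[s, "chrom"], pos.loc[s, "pos"]
        ok = True
        for t, k in zip(kept, kept_cols):
            if pos.loc[t, "chrom"] != chrom_j:
                continue
            if abs(pos.loc[t, "pos"] - pos_j) > window_bp:
                continue
            a, b = dose[:, j], dose[:, k]
            mask = np.isfinite(a) & np.isfinite(b)
            if a[mask].std() == 0 or b[mask].std() == 0:
                continue
            r = np.corrcoef(a[mask], b[mask])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(s)
            kept_cols.append(j)
    logger.info("LD pruning: %d/%d SNPs retained at r² <= %g", len(kept), len(ids), r2_max)
    return kept


def maf_bin(maf: np.ndarray, width: float = 0.05) -> np.ndarray:
    """Bin index of each MAF; bins [0,0.05), ..., [0.45,0.5] (0.5 in last)."""
    b = np.floor(np.asarray(maf) / width).astype(int)
    n_bins = int(np.ceil(0.5 / width))
    return np.minimum(b, n_bins - 1)


def sample_matched_sets(
    target_set: Sequence[str],
    pool: pd.DataFrame,
    maf_bin_width: float = 0.05,
    match_annotation: bool = False,
    b: int = 199,
    seed: int = 0,
) -> list[list[str]]:
    """Draw ``b`` null SNP sets matching the target's stratum composition.

    ``pool`` has columns snp_id, maf and, when ``match_annotation``,
    category; the target SNPs must appear in it too (they are excluded from
    the sampling pool). Strata are MAF bins, jointly crossed with the
    annotation category when requested. Each null set reproduces the
    target's per-stratum counts exactly, sampled without replacement within
    a set and independently across sets. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    pool = pool.copy()
    pool["stratum"] = maf_bin(pool["maf"].to_numpy(), maf_bin_width).astype(str)
    if match_annotation:
        if "category" not in pool.columns:
            raise ValueError("match_annotation requires a 'category' column in the pool")
        pool["stratum"] = pool["stratum"] + "|" + pool["category"].astype(str)
    target_set = list(target_set)
    target_rows = pool[pool["snp_id"].isin(set(target_set))]
    if len(target_rows) < len(set(target_set)):
        missing = set(target_set) - set(target_rows["snp_id"])
        raise ValueError(f"target SNPs absent from pool metadata: {sorted(missing)[:5]}")
    counts = target_rows["stratum"].value_counts()
    candidates = pool[~pool["snp_id"].isin(set(target_set))]
    by_stratum = {s: g["snp_id"].to_numpy() for s, g in candidates.groupby("stratum")}
    short = [
        s for s, c in counts.items() if len(by_stratum.get(s, ())) < c
    ]
    if short:
        raise ValueError(
            f"pool cannot cover strata {short}: need "
            f"{[int(counts[s]) for s in short]} candidates"
        )
    sets = []
    for _ in range(b):
        chosen: list[str] = []
        for s, c in counts.items():
            chosen.extend(rng.choice(by_stratum[s], size=int(c), replace=False))
        sets.append(chosen)
    return sets


def enrichment_test(
    observed_fit_fn: Callable[[Sequence[str]], float],
    target_set: Sequence[str],
    null_sets: list[list[str]],
) -> NullTestResult:
    """Compare the observed statistic against its matched-null distribution.

    ``observed_fit_fn`` maps a SNP set to the statistic (here: the mQTL
    heritability proportion, rebuilding stratified LD scores per set). The
    normal-approximation p is one-sided upper tail; with fewer than 20 null
    sets only the empirical p (r+1)/(B+1) is reported.
    """
    observed = float(observed_fit_fn(target_set))
    null_vals = np.array([observed_fit_fn(s) for s in null_sets], dtype=float)
    b = len(null_vals)
    mean, sd = float(null_vals.mean()), float(null_vals.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("inf") * np.sign(observed - mean)
    p_normal = float(stats.norm.sf(z)) if b >= MIN_B_FOR_NORMAL else None
    r = int(np.sum(null_vals >= observed))
    p_empirical = (r + 1) / (b + 1)
    return NullTestResult(
        observed=observed, b=b, null_mean=mean, null_sd=sd, z=float(z),
        p_normal=p_normal, p_empirical=float(p_empirical), null_values=null_vals,
    )


__all__ = [
    "NullTestResult",
    "enrichment_test",
    "ld_prune",
    "maf_bin",
    "sample_matched_sets",
]
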