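"""MAF-scaled correlation between mQTL and GWAS effect sizes.

If mQTL drive trait variation, SNPs with large effects on methylation
should also have large trait effects. Raw effect sizes scale inversely
with heterozygosity, so absolute effects are first multiplied by
√(2f(1−f)) — the per-allele standard deviation at minor allele frequency
f — putting every SNP on the variance-contribution scale; the correlation
is then Pearson's r on the two scaled absolute-effect vectors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def scale_effect(effect: float | np.ndarray, f: float | np.ndarray) -> float | np.ndarray:
    """|effect| · √(2f(1−f)) for minor allele frequency f ∈ (0, 0.5]."""
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f > 0.5)):
        raise ValueError("minor allele frequency must lie in (0, 0.5]")
    out = np.abs(effect) * np.sqrt(2.0 * f * (1.0 - f))
    return float(out) if np.ndim(out) == 0 else out


def effect_correlation(
    mqtl_effects: pd.DataFrame,
    gwas_effects: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> tuple[float, float, int]:
    """Pearson correlation of MAF-scaled absolute effects, joined on snp_id.

    Both inputs need columns snp_id, effect, f and (for allele alignment)
    a1, a2. Absolute values are taken before scaling, so allele orientation
    cannot flip the result; strand-ambiguous (A/T, C/G) SNPs are dropped
    and counted, and SNPs whose allele pairs do not match are dropped.
    Returns ``(r, two-sided p, n_pairs)``; needs ≥ 10 joined SNPs.
    """
    joined = mqtl_effects.merge(gwas_effects, on="snp_id", suffixes=("_m", "_g"))
    n_ambig = 0
    if drop_ambiguous and {"a1_m", "a2_m"}.issubset(joined.columns):
        ambig = [
            (a1, a2) in _AMBIGUOUS
            for a1, a2 in zip(joined["a1_m"].str.upper(), joined["a2_m"].str.upper())
        ]
        n_ambig = int(np.sum(ambig))
        joined = joined.loc[~np.asarray(ambig)]
    if {"a1_m", "a2_m", "a1_g", "a2_g"}.issubset(joined.columns):
        same = (joined["a1_m"] == joined["a1_g"]) & (joined["a2_m"] == joined["a2_g"])
        swapped = (joined["a1_m"] == joined["a2_g"]) & (joined["a2_m"] == joined["a1_g"])
        joined = joined.loc[same | swapped]
    if n_ambig:
        logger.info("effect_correlation: dropped %d strand-ambiguous SNPs", n_ambig)
    if len(joined) < 10:
        raise ValueError(f"only {len(joined)} joined SNPs; need >= 10")
    x = scale_effect(joined["effect_m"].to_numpy(), joined["f_m"].to_numpy())
    y = scale_effect(joined["effect_g"].to_numpy(), joined["f_g"].to_numpy())
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a scaled effect vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(joined))


__all__ = ["effect_correlation", "scale_effect"]
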