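"""Probe–SNP overlap: flags and the attributable-fraction accounting.

A variant inside a probe's binding region can cause genotype-specific
measurement error, producing a spurious mQTL; a variant inside the CpG
dinucleotide itself disrupts methylation at the site. The summary compares
the proportion of mQTL probes carrying such a variant against the
background proportion among probes with no mQTL: the excess of the cis
proportion over background is the fraction of cis mQTL potentially
attributable to within-probe variation. Flagged mQTL are reported but not
removed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OverlapSummary:
    n_probes: int
    n_probes_with_snp: int
    background_pct: float          # over probes with no mQTL
    n_cis: int
    n_cis_with_probe_snp: int
    cis_pct: float
    n_trans: int
    n_trans_with_probe_snp: int
    trans_pct: float
    n_cis_with_cpg_snp: int
    cis_cpg_pct: float
    attributable_fraction_pct: float  # max(0, cis% - background%)


def flag_probe_snps(
    probe_intervals: pd.DataFrame, variants: pd.DataFrame
) -> pd.DataFrame:
    """Flag probes whose binding interval or CpG dinucleotide contains a variant.

    ``probe_intervals`` needs columns probe_id, chrom, cpg_pos,
    interval_start, interval_end (1-based inclusive); ``variants`` needs
    chrom, pos. Pure interval geometry — independent of any mQTL result.
    Probes with missing interval metadata get null flags and are excluded
    from denominators downstream.
    """
    out = probe_intervals[["probe_id"]].copy()
    out["snp_in_probe"] = pd.array([pd.NA] * len(out), dtype="boolean")
    out["snp_in_cpg"] = pd.array([pd.NA] * len(out), dtype="boolean")
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in variants.groupby("chrom")}
    for i, probe in probe_intervals.iterrows():
        s, e = probe["interval_start"], probe["interval_end"]
        if pd.isna(s) or pd.isna(e):
            continue
        pos = by_chrom.get(probe["chrom"])
        if pos is None:
            out.loc[i, ["snp_in_probe", "snp_in_cpg"]] = False, False
            continue
        out.loc[i, "snp_in_probe"] = bool(
            np.searchsorted(pos, e, side="right") > np.searchsorted(pos, s, side="left")
        )
        out.loc[i, "snp_in_cpg"] = bool(
            np.searchsorted(pos, probe["cpg_pos"] + 1, side="right")
            > np.searchsorted(pos, probe["cpg_pos"], side="left")
        )
    return out


def _pct(numer: int, denom: int, label: str) -> float:
    if denom == 0:
        logger.warning("overlap summary: zero denominator for %s", label)
        return float("nan")
    return 100.0 * numer / denom


def overlap_summary(
    flags: pd.DataFrame, mqtl_records: pd.DataFrame, all_probe_ids: list[str]
) -> OverlapSummary:
    """Overlap proportions for background, cis and trans mQTL probes.

    Background is computed over probes with no mQTL; the attributable
    fraction is max(0, cis% − background%). Invariant under probe
    reordering.
    """
    flags = flags.dropna(subset=["snp_in_probe"]).set_index("probe_id")
    known = flags.index.intersection(pd.Index(all_probe_ids))
    cis_probes = set(mqtl_records.loc[mqtl_records["class"] == "cis", "probe_id"])
    trans_probes = set(mqtl_records.loc[mqtl_records["class"] == "trans", "probe_id"])
    mqtl_probes = cis_probes | trans_probes
    bg = [p for p in known if p not in mqtl_probes]
    cis = [p for p in known if p in cis_probes]
    trans = [p for p in known if p in trans_probes]
    in_probe = flags["snp_in_probe"].astype(bool)
    in_cpg = flags["snp_in_cpg"].astype(bool)
    n_bg_snp = int(in_probe.loc[bg].sum())
    n_cis_snp = int(in_probe.loc[cis].sum())
    n_trans_snp = int(in_probe.loc[trans].sum())
    n_cis_cpg = int(in_cpg.loc[cis].sum())
    background_pct = _pct(n_bg_snp, len(bg), "background")
    cis_pct = _pct(n_cis_snp, len(cis), "cis")
    attributable = (
        max(0.0, cis_pct - background_pct)
        if np.isfinite(cis_pct) and np.isfinite(background_pct)
        else float("nan")
    )
    return OverlapSummary(
        n_probes=len(known),
        n_probes_with_snp=int(in_probe.loc[known].sum()),
        background_pct=background_pct,
        n_cis=len(cis),
        n_cis_with_probe_snp=n_cis_snp,
        cis_pct=cis_pct,
        n_trans=len(trans),
        n_trans_with_probe_snp=n_trans_snp,
        trans_pct=_pct(n_trans_snp, len(trans), "trans"),
        n_cis_with_cpg_snp=n_cis_cpg,
        cis_cpg_pct=_pct(n_cis_cpg, len(cis), "cis CpG"),
        attributable_fraction_pct=attributable,
    )


__all__ = ["OverlapSummary", "flag_probe_snps", "overlap_summary"]
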