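"""Two-stage cis/trans mQTL scan, cross-cohort replication and summaries.

cis: for every probe, all SNPs within ±2 Mbp of the target CpG are tested
and the single most significant SNP is retained at p < 1e-11. trans: all
SNPs outside the 4 Mbp cis window are scanned in two stages — genotyped
SNPs first per probe × chromosome, with pairs reaching p < 1e-7 re-analysed
on all (including imputed) SNPs of that chromosome at the experiment-wide
threshold p < 1e-13. Discoveries replicate in the other cohort at class-
specific Bonferroni thresholds (1e-6 cis, 1e-5 trans) with the same
direction of effect. Association is simple linear regression of the
normalised (logit-residual) phenotype on the alt-allele dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mqtlkit.containers import GenotypeMatrix, MethylationMatrix

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "probe_id", "probe_chrom", "cpg_pos", "snp_id", "snp_chrom", "snp_pos",
    "a1", "a2", "maf", "beta", "se", "p", "r2", "class",
    "rep_beta", "rep_p", "same_dir", "rep_se", "rep_r2", "cohort",
]


@dataclass
class ScanConfig:
    cis_window_bp: int = 2_000_000
    cis_discovery_p: float = 1e-11
    cis_replication_p: float = 1e-6
    trans_stage1_p: float = 1e-7
    trans_discovery_p: float = 1e-13
    trans_replication_p: float = 1e-5
    require_same_direction: bool = True
    restrict_maf_threshold: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.cis_discovery_p, self.cis_replication_p, self.trans_stage1_p,
                  self.trans_discovery_p, self.trans_replication_p):
            if not 0 < p < 1:
                raise ValueError("significance thresholds must lie in (0, 1)")
        if self.cis_window_bp <= 0:
            raise ValueError("cis window must be positive")


def assoc_test(dosage: np.ndarray, phenotype: np.ndarray) -> tuple[float, float, float, float]:
    """Simple linear regression of phenotype on dosage.

    Returns ``(effect, SE, p, r²)``: the per-dosage slope, its standard
    error, the two-sided t-test p-value, and the squared sample correlation
    (fraction of phenotype variance explained). Requires ≥ 10 paired
    non-missing observations and non-zero dosage variance.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    mask = np.isfinite(d) & np.isfinite(y)
    if mask.sum() < 10:
        raise ValueError("need at least 10 paired non-missing observations")
    eff, se, p, r2 = _assoc_block(d[mask, None], y[mask])
    if not np.isfinite(eff[0]):
        raise ValueError("dosage has zero variance")
    return float(eff[0]), float(se[0]), float(p[0]), float(r2[0])


def _assoc_block(d_block: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised simple regression of ``y`` on each column of ``d_block``.

    NaNs in either input are handled pairwise per column. Columns with zero
    dosage variance or fewer than 10 complete pairs give NaN throughout.
    """
    yfin = np.isfinite(y)
    mask = np.isfinite(d_block) & yfin[:, None]
    n = mask.sum(axis=0).astype(float)
    dm = np.where(mask, d_block, 0.0)
    ym = np.where(mask, y[:, None], 0.0)
    sx = dm.sum(axis=0)
    sy = ym.sum(axis=0)
    sxx = (dm * dm).sum(axis=0)
    syy = (ym * ym).sum(axis=0)
    sxy = (dm * ym).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssxx = sxx - sx * sx / n
        ssyy = syy - sy * sy / n
        ssxy = sxy - sx * sy / n
        slope = ssxy / ssxx
        resid_ss = np.maximum(ssyy - slope * ssxy, 0.0)
        se = np.sqrt(resid_ss / (n - 2) / ssxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = slope / se
        r2 = np.where(ssyy > 0, ssxy * ssxy / (ssxx * ssyy), np.nan)
    bad = (ssxx <= 0) | (n < 10)
    slope = np.where(bad, np.nan, slope)
    se = np.where(bad, np.nan, se)
    r2 = np.where(bad, np.nan, r2)
    p = np.full(slope.shape, np.nan)
    ok = ~bad & np.isfinite(tstat)
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), n[ok] - 2)
    # exact fit: zero residual variance -> p underflows to 0
    exact = ~bad & ~np.isfinite(tstat) & (resid_ss == 0)
    p[exact] = 0.0
    se[exact] = 0.0
    return slope, se, p, r2


def _best_index(p: np.ndarray, chroms: np.ndarray, positions: np.ndarray) -> int | None:
    """Index of the smallest p; ties broken by (chrom, position)."""
    ok = np.isfinite(p)
    if not ok.any():
        return None
    pmin = p[ok].min()
    tied = np.flatnonzero(ok & (p == pmin))
    if len(tied) == 1:
        return int(tied[0])
    order = np.lexsort((positions[tied], chroms[tied]))
    return int(tied[order[0]])


def _make_record(probe, geno: GenotypeMatrix, j: int, eff, se, p, r2, cls, cohort) -> dict:
    snp = geno.snps.iloc[j]
    return {
        "probe_id": probe["probe_id"], "probe_chrom": probe["chrom"],
        "cpg_pos": probe["cpg_pos"], "snp_id": snp["snp_id"],
        "snp_chrom": snp["chrom"], "snp_pos": snp["pos"],
        "a1": snp["alt"], "a2": snp["ref"], "maf": snp["maf"],
        "beta": eff, "se": se, "p": p, "r2": r2, "class": cls,
        "rep_beta": np.nan, "rep_p": np.nan, "same_dir": pd.NA,
        "rep_se": np.nan, "rep_r2": np.nan, "cohort": cohort,
    }


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=RECORD_COLUMNS)


def cis_scan(
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    config: ScanConfig | None = None,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Scan ±cis_window_bp around each CpG; keep the best SNP per probe.

    Probes flagged ``restrict_maf`` are tested only against SNPs with
    MAF > ``restrict_maf_threshold``. Probes with no SNP in the window are
    counted and skipped.
    """
    config = config or ScanConfig()
    records = []
    n_no_snp = 0
    snp_chrom = geno.snps["chrom"].to_numpy()
    snp_pos = geno.snps["pos"].to_numpy()
    maf = geno.snps["maf"].to_numpy()
    chrom_codes = pd.factorize(snp_chrom)[0]
    restrict = meth.probes.get("restrict_maf")
    for i in range(meth.n_probes):
        probe = meth.probes.iloc[i]
        in_win = (snp_chrom == probe["chrom"]) & (
            np.abs(snp_pos - probe["cpg_pos"]) <= config.cis_window_bp
        )
        if restrict is not None and bool(restrict.iloc[i]):
            in_win &= maf > config.restrict_maf_threshold
        idx = np.flatnonzero(in_win)
        if idx.size == 0:
            n_no_snp += 1
            continue
        eff, se, p, r2 = _assoc_block(geno.dosages[:, idx], meth.beta[i])
        best = _best_index(p, chrom_codes[idx], snp_pos[idx])
        if best is None:
            continue
        if p[best] < config.cis_discovery_p:
            j = int(idx[best])
            records.append(
                _make_record(probe, geno, j, eff[best], se[best], p[best], r2[best],
                             "cis", cohort)
            )
    logger.info("cis scan: %d discoveries, %d probes without a window SNP",
                len(records), n_no_snp)
    out = pd.DataFrame(records, columns=RECORD_COLUMNS) if records else _empty_records()
    return out


def _trans_mask(geno: GenotypeMatrix, probe, window_bp: int) -> np.ndarray:
    """SNPs outside the cis window: other chromosomes, or > window_bp away."""
    snp_chrom = geno.snps["chrom"].to_numpy()
    snp_pos = geno.snps["pos"].to_numpy()
    same = snp_chrom == probe["chrom"]
    return ~same | (np.abs(snp_pos - probe["cpg_pos"]) > window_bp)


def trans_scan(
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    config: ScanConfig | None = None,
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Two-stage trans scan; best SNP per probe per chromosome at p < 1e-13.

    Stage 1 tests genotyped SNPs only; any probe × chromosome pair reaching
    ``trans_stage1_p`` is re-analysed on all SNPs (including imputed) of
    that chromosome before applying the discovery threshold.
    """
    config = config or ScanConfig()
    records = []
    snp_chrom = geno.snps["chrom"].to_numpy()
    snp_pos = geno.snps["pos"].to_numpy()
    genotyped = geno.snps["genotyped"].to_numpy(dtype=bool)
    maf = geno.snps["maf"].to_numpy()
    chrom_codes = pd.factorize(snp_chrom)[0]
    restrict = meth.probes.get("restrict_maf")
    for i in range(meth.n_probes):
        probe = meth.probes.iloc[i]
        outside = _trans_mask(geno, probe, config.cis_window_bp)
        if restrict is not None and bool(restrict.iloc[i]):
            outside &= maf > config.restrict_maf_threshold
        for chrom in np.unique(snp_chrom):
            on_chrom = outside & (snp_chrom == chrom)
            stage1 = np.flatnonzero(on_chrom & genotyped)
            if stage1.size == 0:
                continue
            _, _, p1, _ = _assoc_block(geno.dosages[:, stage1], meth.beta[i])
            if not np.isfinite(p1).any() or np.nanmin(p1) >= config.trans_stage1_p:
                continue
            idx = np.flatnonzero(on_chrom)
            eff, se, p, r2 = _assoc_block(geno.dosages[:, idx], meth.beta[i])
            best = _best_index(p, chrom_codes[idx], snp_pos[idx])
            if best is not None and p[best] < config.trans_discovery_p:
                j = int(idx[best])
                records.append(
                    _make_record(probe, geno, j, eff[best], se[best], p[best],
                                 r2[best], "trans", cohort)
                )
    logger.info("trans scan: %d discoveries", len(records))
    return pd.DataFrame(records, columns=RECORD_COLUMNS) if records else _empty_records()


def replicate(
    discovery: pd.DataFrame,
    other_geno: GenotypeMatrix,
    other_meth: MethylationMatrix,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Test each discovery in the other cohort; keep replicated records.

    Replication requires the class-specific threshold (cis 1e-6, trans 1e-5)
    and the same direction of effect after aligning alleles (an allele-
    swapped encoding in the replication cohort flips the sign before
    comparison). SNPs or probes absent from the replication cohort are
    dropped and counted separately from failed replication.
    """
    config = config or ScanConfig()
    if discovery.empty:
        return _empty_records()
    snp_idx = other_geno.snp_index()
    probe_idx = pd.Series(
        np.arange(other_meth.n_probes), index=other_meth.probes["probe_id"]
    )
    kept, n_absent, n_failed = [], 0, 0
    for _, rec in discovery.iterrows():
        if rec["snp_id"] not in snp_idx.index or rec["probe_id"] not in probe_idx.index:
            n_absent += 1
            continue
        j = int(snp_idx[rec["snp_id"]])
        i = int(probe_idx[rec["probe_id"]])
        snp = other_geno.snps.iloc[j]
        if snp["alt"] == rec["a1"] and snp["ref"] == rec["a2"]:
            flip = 1.0
        elif snp["alt"] == rec["a2"] and snp["ref"] == rec["a1"]:
            flip = -1.0
        else:
            n_absent += 1
            continue
        try:
            eff, se, p, r2 = assoc_test(other_geno.dosages[:, j], other_meth.beta[i])
        except ValueError:
            n_absent += 1
            continue
        eff *= flip
        threshold = (
            config.cis_replication_p if rec["class"] == "cis" else config.trans_replication_p
        )
        same_dir = bool(np.sign(eff) == np.sign(rec["beta"]))
        if p < threshold and (same_dir or not config.require_same_direction):
            row = rec.to_dict()
            row.update(rep_beta=eff, rep_se=se, rep_p=p, rep_r2=r2, same_dir=same_dir)
            kept.append(row)
        else:
            n_failed += 1
    logger.info(
        "replication: %d/%d replicated (%d failed, %d absent in other cohort)",
        len(kept), len(discovery), n_failed, n_absent,
    )
    return pd.DataFrame(kept, columns=RECORD_COLUMNS) if kept else _empty_records()


def fisher_combined(p1: float, p2: float) -> tuple[float, float]:
    """Fisher's combination of two p-values: statistic and 4-df p."""
    stat = -2.0 * (np.log(p1) + np.log(p2))
    return float(stat), float(stats.chi2.sf(stat, df=4))


def select_best_combined(record_a: pd.Series, record_b: pd.Series | None) -> pd.Series:
    """Pick the SNP with the best combined discovery+replication evidence.

    When one probe has replicated associations from both scan directions at
    different SNPs, the SNP with the larger Fisher statistic
    −2(ln p_disc + ln p_rep) (smaller 4-df combined p) is retained; ties go
    to the smaller (chromosome, position).
    """
    if record_b is None:
        return record_a
    stat_a, _ = fisher_combined(max(record_a["p"], 1e-300), max(record_a["rep_p"], 1e-300))
    stat_b, _ = fisher_combined(max(record_b["p"], 1e-300), max(record_b["rep_p"], 1e-300))
    if stat_a != stat_b:
        return record_a if stat_a > stat_b else record_b
    key_a = (str(record_a["snp_chrom"]), int(record_a["snp_pos"]))
    key_b = (str(record_b["snp_chrom"]), int(record_b["snp_pos"]))
    return record_a if key_a <= key_b else record_b


def merge_replicated(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """Merge the two scan directions' replicated records per probe and class.

    Identical (probe, SNP) pairs collapse to one record; a probe replicated
    at different SNPs in the two directions keeps the best-combined SNP.
    """
    frames = [df for df in (records_a, records_b) if not df.empty]
    if not frames:
        return _empty_records()
    merged: dict[tuple, pd.Series] = {}
    for _, rec in pd.concat(frames, ignore_index=True).iterrows():
        key = (rec["probe_id"], rec["class"], rec["snp_chrom"]) if rec["class"] == "trans" \
            else (rec["probe_id"], rec["class"])
        if key not in merged:
            merged[key] = rec
        elif merged[key]["snp_id"] == rec["snp_id"]:
            pass  # same pair found from both directions
        else:
            merged[key] = select_best_combined(merged[key], rec)
    return pd.DataFrame(list(merged.values()), columns=RECORD_COLUMNS).reset_index(drop=True)


def variance_explained_summary(
    records: pd.DataFrame, all_probe_ids: list[str]
) -> tuple[pd.Series, float, float]:
    """Per-probe variance explained, its mean over ALL probes, and the
    cross-cohort effect-size correlation.

    The mean includes zeros for probes with no mQTL. Variance explained uses
    the replication-cohort r² when available. The correlation pairs each
    record's discovery and replication effects. With no records the mean is
    0 and the correlation is NaN (undefined, signalled by warning).
    """
    per_probe = pd.Series(0.0, index=pd.Index(all_probe_ids, name="probe_id"))
    if records.empty:
        logger.warning("variance summary: no records; correlation undefined")
        return per_probe, 0.0, float("nan")
    r2 = records["rep_r2"].where(records["rep_r2"].notna(), records["r2"])
    sums = r2.groupby(records["probe_id"]).sum().clip(upper=1.0)
    per_probe.loc[sums.index.intersection(per_probe.index)] = sums
    mean_r2 = float(per_probe.mean())
    pairs = records[["beta", "rep_beta"]].dropna()
    if len(pairs) >= 2 and pairs["beta"].std() > 0 and pairs["rep_beta"].std() > 0:
        corr = float(np.corrcoef(pairs["beta"], pairs["rep_beta"])[0, 1])
    else:
        corr = float("nan")
    return per_probe, mean_r2, corr


__all__ = [
    "RECORD_COLUMNS",
    "ScanConfig",
    "assoc_test",
    "cis_scan",
    "fisher_combined",
    "merge_replicated",
    "replicate",
    "select_best_combined",
    "trans_scan",
    "variance_explained_summary",
]
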