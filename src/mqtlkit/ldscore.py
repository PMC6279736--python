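"""Pairwise r² and bias-corrected, stratified LD scores.

The LD score of SNP j is L_j = 1 + Σ r²_jk − n/N over the n SNPs k ≠ j in
the 1 Mbp window centred on j, with r² the squared Pearson correlation of
dosages in a reference panel of N samples. The −n/N term removes the
upward finite-sample bias of squared correlations (E[r̂²] ≈ 1/N under
independence), so an isolated SNP scores exactly 1 and a LD-free genome
has mean score → 1 as N grows. Stratified scores split the window sum into
an mQTL component and a rest-of-genome component, each with its own bias
correction n_c/N; the two components add up to the total exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

from mqtlkit.containers import GenotypeMatrix, LDScoreTable


def pairwise_r2(geno: GenotypeMatrix, snp_j: str, snp_k: str) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    idx = geno.snp_index()
    a = geno.dosages[:, int(idx[snp_j])]
    b = geno.dosages[:, int(idx[snp_k])]
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic SNP: r² undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


class StratifiedLDScorer:
    """Precomputes the windowed r² structure once; restratifies cheaply.

    The windowed r² values form a sparse band matrix R (zero diagonal,
    zero outside the ±half-window); W is the same band with unit entries.
    Component scores for any mQTL membership vector m are then two sparse
    mat-vecs:

        L_mqtl = m + R·m − (W·m)/N,   L_G = (1−m) + R·(1−m) − (W·(1−m))/N,

    which is what makes resampling-null re-stratification affordable.
    SNPs exactly at the half-window boundary are inside the window.
    """

    BLOCK = 512

    def __init__(self, geno: GenotypeMatrix, window_bp: float = 1_000_000):
        chrom = geno.snps["chrom"].to_numpy()
        pos = geno.snps["pos"].to_numpy(float)
        codes = pd.factorize(chrom)[0]
        order = np.lexsort((pos, codes))
        self.snps = (
            geno.snps[["snp_id", "chrom", "pos", "maf"]].iloc[order].reset_index(drop=True)
        )
        self.n_ref = geno.n_samples
        m = geno.n_snps
        half = window_bp / 2.0

        dose = geno.dosages[:, order]
        col_mean = np.nanmean(dose, axis=0)
        z = np.where(np.isfinite(dose), dose, col_mean[None, :]) - col_mean[None, :]
        sd = z.std(axis=0)
        if np.any(sd == 0):
            bad = self.snps.loc[sd == 0, "snp_id"].tolist()
            raise ValueError(f"monomorphic SNPs in reference panel: {bad[:5]}")
        z = z / sd

        pos_s = self.snps["pos"].to_numpy(float)
        chrom_s = self.snps["chrom"].to_numpy()
        data, indices, indptr = [], [], [0]
        starts = np.r_[0, 1 + np.flatnonzero(chrom_s[1:] != chrom_s[:-1]), m]
        for c0, c1 in zip(starts[:-1], starts[1:]):
            p = pos_s[c0:c1]
            lo = np.searchsorted(p, p - half, side="left") + c0
            hi = np.searchsorted(p, p + half, side="right") + c0
            for b0 in range(c0, c1, self.BLOCK):
                b1 = min(b0 + self.BLOCK, c1)
                span0, span1 = lo[b0 - c0], hi[b1 - 1 - c0]
                corr = (z[:, b0:b1].T @ z[:, span0:span1]) / self.n_ref
                r2 = corr * corr
                for j in range(b0, b1):
                    s, e = lo[j - c0] - span0, hi[j - c0] - span0
                    row_idx = np.arange(s + span0, e + span0)
                    row_val = r2[j - b0, s:e]
                    keep = row_idx != j
                    data.append(row_val[keep])
                    indices.append(row_idx[keep])
                    indptr.append(indptr[-1] + keep.sum())
        data = np.concatenate(data) if data else np.empty(0)
        indices = np.concatenate(indices) if indices else np.empty(0, dtype=int)
        self.r2 = sparse.csr_matrix((data, indices, indptr), shape=(m, m))
        self.window = sparse.csr_matrix(
            (np.ones_like(data), indices.copy(), list(indptr)), shape=(m, m)
        )

    def scores(self, mqtl_ids: set[str] | list[str]) -> LDScoreTable:
        """Stratified LD-score table for a given mQTL SNP-id set."""
        member = self.snps["snp_id"].isin(set(mqtl_ids)).to_numpy(float)
        other = 1.0 - member
        n_m = self.window @ member
        n_g = self.window @ other
        l_mqtl = member + self.r2 @ member - n_m / self.n_ref
        l_g = other + self.r2 @ other - n_g / self.n_ref
        table = self.snps.copy()
        table["is_mqtl"] = member.astype(bool)
        table["L_total"] = l_mqtl + l_g
        table["L_mqtl"] = l_mqtl
        table["L_G"] = l_g
        table["n_window"] = (n_m + n_g).astype(int)
        return LDScoreTable(table=table, n_ref=self.n_ref)


def ld_scores(
    geno: GenotypeMatrix,
    window_bp: float = 1_000_000,
    mqtl_ids: set[str] | list[str] = (),
) -> LDScoreTable:
    """Stratified LD scores over the 1 Mbp window centred on each SNP.

    ``mqtl_ids`` is the mQTL component of the SNP partition; everything
    else is the rest-of-genome component. One-shot convenience wrapper
    around :class:`StratifiedLDScorer`.
    """
    return StratifiedLDScorer(geno, window_bp=window_bp).scores(mqtl_ids)


def write_ldscores(ld: LDScoreTable, path) -> None:
    ld.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ldscores(path, n_ref: int) -> LDScoreTable:
    return LDScoreTable(table=pd.read_csv(path, sep="\t"), n_ref=n_ref)


__all__ = [
    "StratifiedLDScorer",
    "ld_scores",
    "pairwise_r2",
    "read_ldscores",
    "write_ldscores",
]
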