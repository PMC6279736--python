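"""In-memory containers shared across the pipeline stages.

All genomic coordinates are 1-based inclusive (VCF/GFF3 convention); BED
inputs are shifted on read. Dosages are additive alt-allele counts in
``[0, 2]`` (hard calls or fractional imputed dosages); missing genotypes and
β-values are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "maf", "genotyped"]
PROBE_COLUMNS = [
    "probe_id",
    "chrom",
    "cpg_pos",
    "interval_start",
    "interval_end",
]


@dataclass
class GenotypeMatrix:
    """Per-sample additive dosages plus SNP metadata.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per dosage row.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt, maf,
        genotyped``. Positions are sorted within chromosome; ``maf`` is the
        minor allele frequency min(p, 1-p) of the alt allele.
    dosages : numpy.ndarray
        ``(n_samples, n_snps)`` float array of alt-allele dosages in
        ``[0, 2]``; ``NaN`` marks missing calls.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            dupes = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dupes))[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to SNPs where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_snps, dtype=bool)
            idx[mask] = True
            mask = idx
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def snp_index(self) -> pd.Series:
        """snp_id -> column index lookup."""
        return pd.Series(np.arange(self.n_snps), index=self.snps["snp_id"])


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP column from dosages, ignoring NaN."""
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p_alt, 1.0 - p_alt)


@dataclass
class MethylationMatrix:
    """β-value matrix (probes × samples) with probe metadata.

    ``probes`` carries ``probe_id, chrom, cpg_pos, interval_start,
    interval_end`` and optional QC columns (``is_cpg``, ``restrict_maf``).
    β-values live in [0, 1]; NaN marks missing measurements.
    """

    probes: pd.DataFrame
    samples: list[str]
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        if self.beta.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        finite = self.beta[np.isfinite(self.beta)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("β-values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_probes(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask, dtype=bool)
        return MethylationMatrix(
            probes=self.probes.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            beta=self.beta[mask],
        )


SUMSTATS_COLUMNS = ["snp_id", "a1", "a2", "freq", "effect", "se", "p", "chisq", "n"]


@dataclass
class SummaryStats:
    """GWAS summary statistics, one row per SNP.

    ``table`` columns: ``snp_id, a1, a2, freq, effect, se, p, chisq, n``.
    ``effect`` is a regression beta or log odds-ratio; ``chisq`` is the
    1-df association statistic, consistent with ``(effect/se)**2`` when both
    are present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        both = self.table["effect"].notna() & self.table["se"].notna()
        if both.any():
            expect = (self.table.loc[both, "effect"] / self.table.loc[both, "se"]) ** 2
            got = self.table.loc[both, "chisq"]
            rel = np.abs(got - expect) / np.maximum(expect, 1e-300)
            bad = (rel > 1e-6) & expect.gt(0)
            if bad.any():
                raise ValueError("chisq inconsistent with (effect/se)^2")
        if (self.table["n"] <= 0).any():
            raise ValueError("sample size N must be positive")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneModel:
    """Transcript models for positional annotation.

    ``transcripts`` rows: ``tx_id, gene_id, chrom, strand, tx_start, tx_end,
    cds_start, cds_end, coding`` with ``exon_starts`` / ``exon_ends`` as
    tuples of 1-based inclusive bounds. Non-coding transcripts carry
    ``cds_start = cds_end = -1`` and ``coding = False``.
    """

    transcripts: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transcripts = self.transcripts.reset_index(drop=True)
        for _, tx in self.transcripts.iterrows():
            starts, ends = tx["exon_starts"], tx["exon_ends"]
            if len(starts) != len(ends) or len(starts) == 0:
                raise ValueError(f"{tx['tx_id']}: malformed exon list")
            prev_end = -1
            for s, e in zip(starts, ends):
                if s > e or s <= prev_end:
                    raise ValueError(f"{tx['tx_id']}: exons overlap or unsorted")
                prev_end = e
            if starts[0] < tx["tx_start"] or ends[-1] > tx["tx_end"]:
                raise ValueError(f"{tx['tx_id']}: exons outside transcript bounds")
            if tx["coding"] and not (
                tx["tx_start"] <= tx["cds_start"] <= tx["cds_end"] <= tx["tx_end"]
            ):
                raise ValueError(f"{tx['tx_id']}: CDS outside transcript bounds")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)


@dataclass
class LDScoreTable:
    """Stratified LD scores per SNP.

    ``table`` columns: ``snp_id, chrom, pos, maf, L_total, L_mqtl, L_G,
    n_window`` where ``L_total = 1 + Σ r² − n/N`` over the 1 Mbp window
    centred on the SNP and the two components partition the window SNPs into
    the mQTL set and the rest of the genome. ``n_ref`` is the reference-panel
    sample size used for the r² estimates.
    """

    table: pd.DataFrame
    n_ref: int

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        resid = (self.table["L_mqtl"] + self.table["L_G"] - self.table["L_total"]).to_numpy()
        if resid.size and np.abs(resid).max() > 1e-9:
            raise ValueError("stratified LD scores do not sum to the total")

    def __len__(self) -> int:
        return len(self.table)


__all__ = [
    "GeneModel",
    "GenotypeMatrix",
    "LDScoreTable",
    "MethylationMatrix",
    "SummaryStats",
    "SNP_COLUMNS",
    "PROBE_COLUMNS",
    "SUMSTATS_COLUMNS",
    "compute_maf",
    "replace",
]
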