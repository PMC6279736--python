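"""Readers/writers for the on-disk formats and genotype quality control.

Formats: VCF for genotypes (GT, optional DS), TSV for methylation matrices
and GWAS summary statistics, GFF3 for gene models. Every reader/writer pair
round-trips losslessly at the declared precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mqtlkit.containers import (
    PROBE_COLUMNS,
    SUMSTATS_COLUMNS,
    GeneModel,
    GenotypeMatrix,
    MethylationMatrix,
    SummaryStats,
    compute_maf,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage is the alt-allele count from GT, or the DS field when present.
    Missing genotypes become NaN; MAF is recomputed from the data. An INFO
    flag ``IMPUTED`` marks SNPs as imputed (``genotyped=False``).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValueError(
                f"{path}: record {i + 1} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = ds[:, 0].astype(float)
        else:
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
            gt = var.gt_types.astype(float)
            gt[gt == 3] = np.nan
            dose = gt
        dosage_cols.append(dose)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "genotyped": var.INFO.get("IMPUTED") is None,
            }
        )
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no variant records")
    dosages = np.column_stack(dosage_cols)
    snps = pd.DataFrame(rows)
    snps["maf"] = compute_maf(dosages)
    snps = snps[["snp_id", "chrom", "pos", "ref", "alt", "maf", "genotyped"]]
    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
    snps = snps.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages[:, order])


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as VCF (GT), fractional dosages via DS."""
    hard = np.all(np.isin(geno.dosages[np.isfinite(geno.dosages)], [0.0, 1.0, 2.0]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Imputed SNP">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if not hard:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, snp in geno.snps.iterrows():
            info = "." if snp["genotyped"] else "IMPUTED"
            col = geno.dosages[:, j]
            if hard:
                cells = [
                    gt_map[d] if np.isfinite(d) else "./." for d in col
                ]
                fmt = "GT"
            else:
                cells = []
                for d in col:
                    if not np.isfinite(d):
                        cells.append("./.:.")
                        continue
                    gt = gt_map.get(round(d) if abs(d - round(d)) < 1e-9 else -1.0, "./.")
                    cells.append(f"{gt}:{d:.6g}")
                fmt = "GT:DS"
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t{snp['snp_id']}\t{snp['ref']}\t"
                f"{snp['alt']}\t.\t.\t{info}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Methylation TSV
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path) -> MethylationMatrix:
    """Read a probes × samples β-value TSV written by :func:`write_methylation`."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in df.columns if c in PROBE_COLUMNS or c in ("is_cpg", "restrict_maf")]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    probes = df[meta_cols].copy()
    beta = df[sample_cols].to_numpy(dtype=float)
    return MethylationMatrix(probes=probes, samples=sample_cols, beta=beta)


def write_methylation(meth: MethylationMatrix, path: str | Path) -> None:
    meta = meth.probes.copy()
    vals = pd.DataFrame(meth.beta, columns=meth.samples)
    pd.concat([meta, vals], axis=1).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

_DIALERS = {
    "beta": {},
    "or": {"or": "effect"},
}

_REQUIRED = ["snp_id", "a1", "a2"]


def read_sumstats(path: str | Path, effect_column_dialect: str = "beta") -> SummaryStats:
    """Read a GWAS summary-statistics TSV.

    Parameters
    ----------
    effect_column_dialect : {"beta", "or"}
        "or" means the effect column is an odds ratio named ``or``; it is
        converted to the log scale. χ² is filled from ``(effect/se)²`` when
        absent, or from the p-value via the χ²₁ quantile function when only
        ``p`` is available.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if effect_column_dialect == "or":
        if "or" not in df.columns:
            raise ValueError(f"{path}: dialect 'or' but no 'or' column")
        df["effect"] = np.log(df.pop("or"))
    elif effect_column_dialect != "beta":
        raise ValueError(f"unknown effect column dialect {effect_column_dialect!r}")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if "n" not in df.columns:
        raise ValueError(f"{path}: missing required column 'n'")
    for col in ("freq", "effect", "se", "p", "chisq"):
        if col not in df.columns:
            df[col] = np.nan
    have_es = df["effect"].notna() & df["se"].notna()
    df.loc[have_es & df["chisq"].isna(), "chisq"] = (
        df.loc[have_es, "effect"] / df.loc[have_es, "se"]
    ) ** 2
    only_p = df["chisq"].isna() & df["p"].notna()
    df.loc[only_p, "chisq"] = stats.chi2.isf(df.loc[only_p, "p"], df=1)
    df.loc[df["p"].isna() & df["chisq"].notna(), "p"] = stats.chi2.sf(
        df.loc[df["p"].isna() & df["chisq"].notna(), "chisq"], df=1
    )
    return SummaryStats(table=df[SUMSTATS_COLUMNS])


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    ss.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gff3(model: GeneModel, path: str | Path) -> None:
    """Write transcripts as GFF3 (mRNA/ncRNA + exon + CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in model.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for _, tx in model.transcripts.iterrows():
            kind = "mRNA" if tx["coding"] else "ncRNA"
            attrs = f"ID={tx['tx_id']};gene_id={tx['gene_id']}"
            fh.write(
                f"{tx['chrom']}\tmqtlkit\t{kind}\t{tx['tx_start']}\t{tx['tx_end']}\t.\t"
                f"{tx['strand']}\t.\t{attrs}\n"
            )
            for k, (s, e) in enumerate(zip(tx["exon_starts"], tx["exon_ends"])):
                fh.write(
                    f"{tx['chrom']}\tmqtlkit\texon\t{s}\t{e}\t.\t{tx['strand']}\t.\t"
                    f"ID={tx['tx_id']}.exon{k};Parent={tx['tx_id']}\n"
                )
            if tx["coding"]:
                fh.write(
                    f"{tx['chrom']}\tmqtlkit\tCDS\t{tx['cds_start']}\t{tx['cds_end']}\t.\t"
                    f"{tx['strand']}\t0\tID={tx['tx_id']}.cds;Parent={tx['tx_id']}\n"
                )


def read_gff3(path: str | Path) -> GeneModel:
    """Read a GFF3 written by :func:`write_gff3` back into a GeneModel."""
    chrom_lengths: dict[str, int] = {}
    tx_rows: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                chrom_lengths[chrom] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype in ("mRNA", "ncRNA"):
                tx_rows[attr["ID"]] = {
                    "tx_id": attr["ID"],
                    "gene_id": attr.get("gene_id", attr["ID"]),
                    "chrom": chrom,
                    "strand": strand,
                    "tx_start": int(start),
                    "tx_end": int(end),
                    "cds_start": -1,
                    "cds_end": -1,
                    "coding": ftype == "mRNA",
                    "exon_starts": [],
                    "exon_ends": [],
                }
            elif ftype == "exon":
                parent = tx_rows[attr["Parent"]]
                parent["exon_starts"].append(int(start))
                parent["exon_ends"].append(int(end))
            elif ftype == "CDS":
                parent = tx_rows[attr["Parent"]]
                parent["cds_start"] = int(start)
                parent["cds_end"] = int(end)
    for row in tx_rows.values():
        order = np.argsort(row["exon_starts"])
        row["exon_starts"] = tuple(np.asarray(row["exon_starts"])[order])
        row["exon_ends"] = tuple(np.asarray(row["exon_ends"])[order])
    return GeneModel(
        transcripts=pd.DataFrame(list(tx_rows.values())),
        chrom_lengths=chrom_lengths,
    )


# ---------------------------------------------------------------------------
# Genotype QC
# ---------------------------------------------------------------------------

def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson 1-df χ² test of Hardy–Weinberg proportions.

    Returns ``(chisq, p)``; monomorphic sites return (0, 1).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chisq = float(np.sum((observed - expected) ** 2 / expected))
    return chisq, float(stats.chi2.sf(chisq, df=1))


def apply_genotype_qc(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Remove SNPs with MAF below ``maf_min`` or HWE p below ``hwe_p_min``.

    HWE is tested by Pearson 1-df χ² on genotype counts (fractional dosages
    are rounded to the nearest hard call for counting). Idempotent.
    """
    maf = compute_maf(geno.dosages)
    keep = maf >= maf_min
    hwe_p = np.ones(geno.n_snps)
    for j in np.flatnonzero(keep):
        col = geno.dosages[:, j]
        col = col[np.isfinite(col)]
        counts = np.bincount(np.clip(np.rint(col), 0, 2).astype(int), minlength=3)
        _, hwe_p[j] = hwe_chisq(counts[0], counts[1], counts[2])
    keep &= hwe_p >= hwe_p_min
    logger.info(
        "genotype QC: %d/%d SNPs retained (%d MAF<%g, %d HWE p<%g)",
        keep.sum(),
        geno.n_snps,
        (maf < maf_min).sum(),
        maf_min,
        ((maf >= maf_min) & (hwe_p < hwe_p_min)).sum(),
        hwe_p_min,
    )
    out = geno.subset_snps(keep)
    out.snps["maf"] = compute_maf(out.dosages)
    return out


__all__ = [
    "apply_genotype_qc",
    "hwe_chisq",
    "read_gff3",
    "read_methylation",
    "read_sumstats",
    "read_vcf",
    "write_gff3",
    "write_methylation",
    "write_sumstats",
    "write_vcf",
]
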