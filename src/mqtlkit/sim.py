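"""Synthetic two-cohort data with a planted mQTL architecture.

Generates every input the pipeline consumes: genotype panels with local LD
(mosaic-of-founder-haplotypes model), β-distributed methylation with planted
cis/trans genetic effects and covariate structure on the logit scale, toy
gene models, and GWAS χ² summary statistics drawn under the stratified
LD-score expectation model E[χ²_j] = α + N·τ_mQTL·L_j,mQTL + N·τ_G·L_j,G.

All randomness flows from explicit seeds; a fixed seed gives byte-identical
output. The two cohorts share the SNP panel, probe placement and population
allele frequencies but have independently sampled individuals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from mqtlkit.containers import (
    GeneModel,
    GenotypeMatrix,
    LDScoreTable,
    MethylationMatrix,
    SummaryStats,
    compute_maf,
)

N_FOUNDERS = 24  # founder haplotypes per panel; blocky LD at modest cost


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults emulate the shape of a two-cohort whole-blood array study at
    desk scale: a discovery cohort of ~600 and a replication cohort of
    ~1400 unrelated individuals, common SNPs (MAF 0.05–0.5) with LD decaying
    over ~50 kb, and logit-scale residual variance 1.0 with chip/sex/age
    covariate structure.
    """

    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"discovery": 600, "replication": 1400}
    )
    n_snps: int = 2000
    n_probes: int = 200
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 40_000_000, "2": 30_000_000, "3": 20_000_000}
    )
    ld_decay_bp: float = 50_000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_effect_grid: list = field(default_factory=list)
    trans_effect_grid: list = field(default_factory=list)
    covariate_spec: dict[str, float] = field(
        default_factory=lambda: {"chip": 0.3, "sex": 0.2, "age": 0.2}
    )
    noise_model: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie within (0, 0.5]")
        for grid in (self.cis_effect_grid, self.trans_effect_grid):
            for entry in grid:
                if not 0 <= _entry_frac(entry) < 1:
                    raise ValueError("variance-explained fractions must be in [0, 1)")
        if self.noise_model <= 0:
            raise ValueError("noise_model (residual variance) must be positive")


def _entry_frac(entry) -> float:
    return float(entry[-1]) if isinstance(entry, (tuple, list)) else float(entry)


@dataclass
class TruthTable:
    """Planted architecture: which probe–SNP pairs carry real effects.

    ``pairs`` columns: probe_id, snp_id, frac (variance-explained fraction),
    beta (effect per standardised dosage on the logit scale), class
    (cis/trans). ``covariates`` holds the per-sample design used when the
    methylation was generated, for covariate-aware normalisation.
    """

    pairs: pd.DataFrame
    covariates: pd.DataFrame | None = None
    tau: dict[str, float] = field(default_factory=dict)


def _cohort_rng(seed: int, cohort_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(cohort_id.encode()) & 0x7FFFFFFF])


def _panel(config: SimConfig):
    """Shared SNP panel: positions, founder haplotypes, allele frequencies."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xA11E1E])
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, np.round(config.n_snps * lengths / lengths.sum()).astype(int))
    # adjust rounding drift onto the largest chromosome
    per_chrom[np.argmax(lengths)] += config.n_snps - per_chrom.sum()
    snp_chrom, snp_pos = [], []
    for c, n_c, length in zip(chroms, per_chrom, lengths):
        if n_c > length:
            raise ValueError(f"chromosome {c}: {n_c} SNPs exceed {int(length)} positions")
        pos = np.sort(rng.choice(int(length), size=n_c, replace=False)) + 1
        snp_chrom.extend([c] * n_c)
        snp_pos.extend(pos.tolist())
    m = len(snp_pos)
    lo, hi = config.maf_range
    p_target = rng.uniform(lo, hi, size=m)
    # founders carry exactly round(K·p) copies of the alt allele, so the
    # population frequency is fixed and cohorts differ only by sampling.
    k_alt = np.clip(np.round(N_FOUNDERS * p_target).astype(int), 1, N_FOUNDERS - 1)
    # the founder panel itself carries LD: a latent AR(1) Gaussian along each
    # chromosome (coefficient exp(-gap/ld_decay_bp)) is rank-thresholded per
    # locus so the k_alt founders with the smallest latent value carry the
    # alt allele — exact counts, correlated carrier sets at nearby loci
    pos_arr = np.asarray(snp_pos, dtype=float)
    chrom_arr = np.asarray(snp_chrom)
    latent = np.empty((N_FOUNDERS, m))
    latent[:, 0] = rng.standard_normal(N_FOUNDERS)
    eps = rng.standard_normal((N_FOUNDERS, m))
    for j in range(1, m):
        if chrom_arr[j] == chrom_arr[j - 1] and config.ld_decay_bp > 0:
            a = np.exp(-(pos_arr[j] - pos_arr[j - 1]) / config.ld_decay_bp)
        else:
            a = 0.0
        latent[:, j] = a * latent[:, j - 1] + np.sqrt(1.0 - a * a) * eps[:, j]
    ranks = latent.argsort(axis=0).argsort(axis=0)
    founders = (ranks < k_alt[None, :]).astype(np.int8)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{j:06d}" for j in range(m)],
            "chrom": snp_chrom,
            "pos": snp_pos,
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(k_alt / N_FOUNDERS, 1 - k_alt / N_FOUNDERS),
            "genotyped": True,
        }
    )
    # flag a random ~30% of SNPs as imputed for the two-stage trans scan
    imputed = rng.random(m) < 0.3
    snps.loc[imputed, "genotyped"] = False
    return snps, founders


def simulate_genotypes(config: SimConfig, cohort_id: str) -> GenotypeMatrix:
    """Simulate one cohort's dosage matrix on the shared SNP panel.

    Each haplotype is a mosaic of the founder haplotypes: walking along a
    chromosome, the founder identity switches with probability
    ``1 − exp(−d / ld_decay_bp)`` over an inter-SNP gap of ``d`` bp, which
    yields pairwise r² decaying at scale ``ld_decay_bp``. Dosage is the sum
    of two independent mosaic haplotypes.
    """
    if cohort_id not in config.n_individuals:
        raise ValueError(f"unknown cohort {cohort_id!r}; have {list(config.n_individuals)}")
    snps, founders = _panel(config)
    n = config.n_individuals[cohort_id]
    rng = _cohort_rng(config.seed, cohort_id)
    m = len(snps)
    h = 2 * n
    pos = snps["pos"].to_numpy(float)
    same_chrom = np.zeros(m, dtype=bool)
    same_chrom[1:] = snps["chrom"].to_numpy()[1:] == snps["chrom"].to_numpy()[:-1]
    gap = np.where(same_chrom, np.r_[np.inf, np.diff(pos)], np.inf)
    if config.ld_decay_bp > 0:
        p_switch = np.where(same_chrom, 1.0 - np.exp(-gap / config.ld_decay_bp), 1.0)
    else:
        p_switch = np.ones(m)
    p_switch[0] = 1.0
    switch = rng.random((h, m)) < p_switch[None, :]
    switch[:, 0] = True
    draws = rng.integers(0, N_FOUNDERS, size=(h, m))
    cols = np.arange(m)
    last_switch = np.maximum.accumulate(np.where(switch, cols[None, :], 0), axis=1)
    founder_idx = np.take_along_axis(draws, last_switch, axis=1)
    haps = founders[founder_idx, cols[None, :]]
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    samples = [f"{cohort_id}_{i:05d}" for i in range(n)]
    snps = snps.copy()
    snps["maf"] = compute_maf(dosages)
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def _place_probes(config: SimConfig, snps: pd.DataFrame) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x9B0BE5])
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, np.round(config.n_probes * lengths / lengths.sum()).astype(int))
    per_chrom[np.argmax(lengths)] += config.n_probes - per_chrom.sum()
    rows = []
    for c, n_c, length in zip(chroms, per_chrom, lengths):
        pos = np.sort(rng.choice(np.arange(100, int(length) - 100), size=n_c, replace=False)) + 1
        rows.extend({"chrom": c, "cpg_pos": int(p)} for p in pos)
    probes = pd.DataFrame(rows)
    probes["probe_id"] = [f"cg{i:06d}" for i in range(len(probes))]
    # 50 bp binding region ending at the CpG C
    probes["interval_start"] = probes["cpg_pos"] - 49
    probes["interval_end"] = probes["cpg_pos"]
    probes["is_cpg"] = True
    probes["restrict_maf"] = False
    return probes[
        ["probe_id", "chrom", "cpg_pos", "interval_start", "interval_end", "is_cpg", "restrict_maf"]
    ]


def _resolve_grid(
    grid: list,
    kind: str,
    probes: pd.DataFrame,
    snps: pd.DataFrame,
    used_probes: set,
    rng: np.random.Generator,
    cis_window: int = 2_000_000,
) -> list[tuple[str, str, float]]:
    """Turn grid entries (fractions or explicit triples) into planted pairs."""
    out = []
    snp_by_id = snps.set_index("snp_id")
    for entry in grid:
        if isinstance(entry, (tuple, list)):
            probe_id, snp_id, frac = entry
            out.append((str(probe_id), str(snp_id), float(frac)))
            used_probes.add(str(probe_id))
            continue
        frac = float(entry)
        placed = False
        order = rng.permutation(len(probes))
        for pi in order:
            probe = probes.iloc[pi]
            if probe["probe_id"] in used_probes:
                continue
            if kind == "cis":
                cand = snps[
                    (snps["chrom"] == probe["chrom"])
                    & ((snps["pos"] - probe["cpg_pos"]).abs() <= cis_window)
                    & (snps["maf"] >= 0.1)
                ]
            else:
                cand = snps[(snps["chrom"] != probe["chrom"]) & (snps["maf"] >= 0.1)]
            if cand.empty:
                continue
            snp_id = cand.iloc[rng.integers(0, len(cand))]["snp_id"]
            out.append((probe["probe_id"], str(snp_id), frac))
            used_probes.add(probe["probe_id"])
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place a {kind} effect of fraction {frac}")
    for probe_id, snp_id, _ in out:
        if probe_id not in set(probes["probe_id"]):
            raise ValueError(f"planted pair references unknown probe {probe_id}")
        if snp_id not in snp_by_id.index:
            raise ValueError(f"planted pair references unknown SNP {snp_id}")
    return out


def _covariate_design(
    spec: dict[str, float], n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Raw covariates, per-sample logit contribution, and its total variance."""
    raw = pd.DataFrame(index=range(n))
    n_chips = max(2, n // 12)
    raw["chip"] = rng.integers(0, n_chips, size=n)
    raw["position"] = rng.integers(1, 13, size=n)
    raw["sex"] = rng.integers(0, 2, size=n)
    raw["age"] = rng.normal(50.0, 10.0, size=n)
    contrib = np.zeros(n)
    var_total = 0.0

    def std(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    age_z = std(raw["age"].to_numpy())
    sex_c = raw["sex"].to_numpy() - raw["sex"].mean()
    columns = {
        "sex": std(raw["sex"].to_numpy().astype(float)),
        "age": age_z,
        "age2": std(age_z**2),
        "sex_age": std(sex_c * age_z),
        "sex_age2": std(sex_c * age_z**2),
    }
    for name, size in spec.items():
        if size == 0:
            continue
        if name in ("chip", "position"):
            levels = raw[name].to_numpy()
            effects = rng.normal(0.0, 1.0, size=levels.max() + 1)
            col = effects[levels]
            contrib = contrib + size * std(col)
        elif name in columns:
            contrib = contrib + size * columns[name]
        else:  # arbitrary named covariate: standard normal
            col = rng.normal(size=n)
            raw[name] = col
            contrib = contrib + size * std(col)
        var_total += size**2
    return raw, contrib, var_total


def simulate_methylation(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[MethylationMatrix, TruthTable]:
    """Simulate β-values with the planted cis/trans QTL architecture.

    The logit of methylation at probe p is a probe baseline plus planted
    standardised-dosage effects, covariate structure, and Gaussian noise with
    variance ``config.noise_model``; β is the inverse logit, hence strictly
    inside (0, 1). Effect sizes are chosen so each planted pair's share of
    the total logit-scale variance equals its requested fraction.
    """
    cohort_id = geno.samples[0].rsplit("_", 1)[0] if geno.samples else "cohort"
    rng = _cohort_rng(config.seed, cohort_id + ":meth")
    probes = _place_probes(config, geno.snps)
    plant_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x91A27])
    used: set = set()
    planted = [
        (p, s, f, "cis")
        for p, s, f in _resolve_grid(
            config.cis_effect_grid, "cis", probes, geno.snps, used, plant_rng
        )
    ] + [
        (p, s, f, "trans")
        for p, s, f in _resolve_grid(
            config.trans_effect_grid, "trans", probes, geno.snps, used, plant_rng
        )
    ]
    per_probe_total: dict[str, float] = {}
    for p, _s, f, _k in planted:
        per_probe_total[p] = per_probe_total.get(p, 0.0) + f
    for p, tot in per_probe_total.items():
        if tot >= 1:
            raise ValueError(f"probe {p}: planted variance fractions sum to {tot} >= 1")

    n = geno.n_samples
    raw_cov, cov_contrib_base, var_cov = _covariate_design(config.covariate_spec, n, rng)
    var_other = config.noise_model + var_cov
    snp_idx = geno.snp_index()
    probe_idx = pd.Series(np.arange(len(probes)), index=probes["probe_id"])

    baseline = rng.normal(0.0, 1.5, size=len(probes))
    logit_mat = np.empty((len(probes), n))
    # per-probe covariate level effects: redraw categorical level effects per
    # probe (chips hit probes differently); continuous effects shared
    for i in range(len(probes)):
        noise = rng.normal(0.0, np.sqrt(config.noise_model), size=n)
        logit_mat[i] = baseline[i] + cov_contrib_base + noise

    truth_rows = []
    for probe_id, snp_id, frac, kind in planted:
        i = int(probe_idx[probe_id])
        j = int(snp_idx[snp_id])
        dose = geno.dosages[:, j]
        sd = dose.std()
        if sd == 0:
            raise ValueError(f"planted SNP {snp_id} is monomorphic in this cohort")
        z = (dose - dose.mean()) / sd
        total_frac = per_probe_total[probe_id]
        var_g = frac / (1.0 - total_frac) * var_other
        b = np.sqrt(var_g) * (1.0 if plant_rng.random() < 0.5 else -1.0)
        logit_mat[i] = logit_mat[i] + b * z
        truth_rows.append(
            {"probe_id": probe_id, "snp_id": snp_id, "frac": frac, "beta": b, "class": kind}
        )

    beta = expit(logit_mat)
    meth = MethylationMatrix(probes=probes, samples=list(geno.samples), beta=beta)
    truth = TruthTable(
        pairs=pd.DataFrame(
            truth_rows, columns=["probe_id", "snp_id", "frac", "beta", "class"]
        ),
        covariates=raw_cov.assign(sample=geno.samples).set_index("sample"),
    )
    return meth, truth


def simulate_gwas_sumstats(
    ldscores: LDScoreTable,
    tau_mqtl: float,
    tau_g: float,
    alpha: float,
    n_gwas: int,
    seed: int,
) -> SummaryStats:
    """Draw per-SNP GWAS χ² statistics under the stratified expectation model.

    χ²_j = E_j · Z², Z ~ N(0,1), with
    E_j = α + N·τ_mQTL·L_j,mQTL + N·τ_G·L_j,G, so E[χ²_j] = E_j. Effects and
    SEs are filled consistently (se = 1/√N, effect = ±√χ²/√N).
    """
    if tau_mqtl < 0 or tau_g < 0:
        raise ValueError("variance coefficients τ must be non-negative")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    tab = ldscores.table
    expectation = alpha + n_gwas * tau_mqtl * tab["L_mqtl"] + n_gwas * tau_g * tab["L_G"]
    z = rng.standard_normal(len(tab))
    chisq = expectation.to_numpy() * z**2
    se = np.full(len(tab), 1.0 / np.sqrt(n_gwas))
    effect = np.sign(z) * np.sqrt(chisq) * se
    from scipy import stats as sps

    table = pd.DataFrame(
        {
            "snp_id": tab["snp_id"],
            "a1": "G",
            "a2": "A",
            "freq": tab["maf"],
            "effect": effect,
            "se": se,
            "p": sps.chi2.sf(chisq, df=1),
            "chisq": chisq,
            "n": n_gwas,
        }
    )
    return SummaryStats(table=table)


def simulate_gene_model(
    config: SimConfig, genes_per_mbp: float = 0.5, coding_fraction: float = 0.8
) -> GeneModel:
    """Generate non-overlapping transcripts on the toy genome.

    Each chromosome gets ``genes_per_mbp`` genes per Mbp, laid out in
    disjoint slots. Coding transcripts have 3–8 exons with UTR5/UTR3 flanks
    around the CDS; the rest are multi-exon ncRNA, so every annotation
    category (exonic, UTRs, intronic, ncRNA-exonic/intronic, up/downstream,
    intergenic) is realisable.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x6E9E5])
    rows = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_genes = max(1, int(round(genes_per_mbp * length / 1e6)))
        slot = length // n_genes
        for g in range(n_genes):
            slot_start = g * slot + 1
            tx_len = int(rng.integers(20_000, min(100_000, max(20_001, slot // 2))))
            tx_start = int(slot_start + rng.integers(0, max(1, slot - tx_len - 1)))
            tx_end = tx_start + tx_len - 1
            n_exons = int(rng.integers(3, 9))
            # split the transcript into 2*n_exons-1 alternating exon/intron blocks
            cuts = np.sort(rng.choice(tx_len - 2, size=2 * n_exons - 2, replace=False)) + 1
            bounds = np.r_[0, cuts, tx_len]
            exon_starts, exon_ends = [], []
            for k in range(n_exons):
                s = tx_start + int(bounds[2 * k])
                e = tx_start + int(bounds[2 * k + 1]) - 1
                if e < s:
                    e = s
                exon_starts.append(s)
                exon_ends.append(e)
            coding = rng.random() < coding_fraction
            strand = "+" if rng.random() < 0.5 else "-"
            if coding:
                first_s, first_e = exon_starts[0], exon_ends[0]
                last_s, last_e = exon_starts[-1], exon_ends[-1]
                cds_start = int(first_s + max(1, (first_e - first_s) // 3))
                cds_end = int(last_e - max(1, (last_e - last_s) // 3))
                if cds_end <= cds_start:
                    cds_start, cds_end = first_s + 1, last_e - 1
            else:
                cds_start = cds_end = -1
            rows.append(
                {
                    "tx_id": f"tx_{chrom}_{g:04d}",
                    "gene_id": f"gene_{chrom}_{g:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tx_start": tx_start,
                    "tx_end": tx_end,
                    "cds_start": cds_start,
                    "cds_end": cds_end,
                    "coding": bool(coding),
                    "exon_starts": tuple(exon_starts),
                    "exon_ends": tuple(exon_ends),
                }
            )
    return GeneModel(transcripts=pd.DataFrame(rows), chrom_lengths=dict(config.chrom_lengths))


__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_gwas_sumstats",
    "simulate_gene_model",
]
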