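"""MAF-matched resampling null for the mQTL heritability proportion.

Takes an LD-pruned mQTL SNP set whose component genuinely carries an
enriched share of trait heritability, rebuilds the stratified LD scores
for 99 random MAF-matched SNP sets, and compares the observed proportion
against the null distribution with a one-sided z test and an empirical p.
"""

import numpy as np

from mqtlkit import sim
from mqtlkit.ldscore import StratifiedLDScorer
from mqtlkit.nulls import enrichment_test, ld_prune, sample_matched_sets
from mqtlkit.partition import fit_partition

cfg = sim.SimConfig(
    n_individuals={"ref": 500},
    n_snps=3000,
    n_probes=10,
    chrom_lengths={str(c): 50_000_000 for c in range(1, 4)},
    seed=3,
)
geno = sim.simulate_genotypes(cfg, "ref")
scorer = StratifiedLDScorer(geno)

rng = np.random.default_rng(3)
mqtl = ld_prune(list(rng.choice(geno.snps["snp_id"], 400, replace=False)), geno)
scores = scorer.scores(mqtl)
m_m = int(scores.table["is_mqtl"].sum())
m_g = len(scores.table) - m_m
n_gwas = 50_000
ss = sim.simulate_gwas_sumstats(
    scores, tau_mqtl=0.33 * 0.5 / m_m, tau_g=0.67 * 0.5 / m_g,
    alpha=1.0, n_gwas=n_gwas, seed=3,
)


def proportion_for(snp_set):
    return fit_partition(ss, scorer.scores(snp_set), n_gwas=n_gwas).proportion


pool = geno.snps[["snp_id", "maf"]]
null_sets = sample_matched_sets(mqtl, pool, b=99, seed=3)
res = enrichment_test(proportion_for, mqtl, null_sets)

print(f"observed mQTL proportion : {res.observed:.3f}")
print(f"null mean (SD), B={res.b}   : {res.null_mean:.3f} ({res.null_sd:.3f})")
print(f"z                        : {res.z:.2f}")
print(f"one-sided normal p       : {res.p_normal:.2e}")
print(f"empirical p              : {res.p_empirical:.3f}")
print(
    "\nEach null set matches the mQTL set's MAF-bin composition exactly;"
    "\nthe empirical p has resolution 1/(B+1) = 0.01 at B = 99."
)
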