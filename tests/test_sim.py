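"""Synthetic-data generator: determinism, planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from mqtlkit import sim
from mqtlkit.annotation import annotate_position
from mqtlkit.ldscore import ld_scores


def test_genotypes_deterministic(small_config):
    a = sim.simulate_genotypes(small_config, "discovery")
    b = sim.simulate_genotypes(small_config, "discovery")
    assert np.array_equal(a.dosages, b.dosages)
    assert a.snps.equals(b.snps)


def test_cohorts_share_panel_but_not_samples(cohorts):
    g_a, g_b = cohorts["geno"]
    assert (g_a.snps["snp_id"] == g_b.snps["snp_id"]).all()
    assert (g_a.snps["pos"] == g_b.snps["pos"]).all()
    assert not np.array_equal(g_a.dosages, g_b.dosages)


def test_dosages_are_hard_calls(cohorts):
    g_a, _ = cohorts["geno"]
    assert np.isin(g_a.dosages, [0.0, 1.0, 2.0]).all()


def test_ld_decays_with_distance(ref_panel):
    """Adjacent SNPs are correlated; distant SNPs on the same chromosome are not."""
    snps = ref_panel.snps
    chrom1 = snps[snps["chrom"] == "1"]
    pos = chrom1["pos"].to_numpy()
    dose = ref_panel.dosages[:, chrom1.index]
    close_r2, mid_r2, far_r2 = [], [], []
    for j in range(len(pos) - 1):
        for k in range(j + 1, min(j + 6, len(pos))):
            gap = pos[k] - pos[j]
            if gap < 10_000:
                close_r2.append(np.corrcoef(dose[:, j], dose[:, k])[0, 1] ** 2)
            elif 25_000 <= gap < 50_000:
                mid_r2.append(np.corrcoef(dose[:, j], dose[:, k])[0, 1] ** 2)
        far = np.searchsorted(pos, pos[j] + 5_000_000)
        if far < len(pos) and j % 7 == 0:
            far_r2.append(np.corrcoef(dose[:, j], dose[:, far])[0, 1] ** 2)
    assert np.mean(close_r2) > 0.15
    assert np.mean(close_r2) > np.mean(mid_r2) > np.mean(far_r2)
    assert np.mean(far_r2) < 0.02


def test_zero_ld_decay_gives_independent_snps():
    """ld_decay_bp -> 0: mean off-diagonal r² at the independence noise floor."""
    cfg = sim.SimConfig(
        n_individuals={"a": 500}, n_snps=120, n_probes=5,
        chrom_lengths={"1": 10_000_000}, ld_decay_bp=0.0, seed=5,
    )
    g = sim.simulate_genotypes(cfg, "a")
    corr = np.corrcoef(g.dosages.T)
    off = corr[np.triu_indices_from(corr, k=1)] ** 2
    assert off.mean() < 0.02


def test_maf_range_respected_at_boundary():
    """maf_range=[0.5,0.5]: realized MAF within binomial sampling error."""
    cfg = sim.SimConfig(
        n_individuals={"a": 500}, n_snps=100, n_probes=5,
        chrom_lengths={"1": 10_000_000}, maf_range=(0.5, 0.5), seed=9,
    )
    g = sim.simulate_genotypes(cfg, "a")
    assert (g.snps["maf"] >= 0.4).all() and (g.snps["maf"] <= 0.5).all()


def test_too_many_snps_rejected():
    cfg = sim.SimConfig(
        n_individuals={"a": 10}, n_snps=200, n_probes=5, chrom_lengths={"1": 100},
    )
    with pytest.raises(ValueError, match="exceed"):
        sim.simulate_genotypes(cfg, "a")


def test_unknown_cohort_rejected(small_config):
    with pytest.raises(ValueError, match="unknown cohort"):
        sim.simulate_genotypes(small_config, "nonexistent")


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="maf_range"):
        sim.SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError, match="fractions"):
        sim.SimConfig(cis_effect_grid=[1.2])


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def test_beta_values_strictly_inside_unit_interval(cohorts):
    m_a, _ = cohorts["meth"]
    assert (m_a.beta > 0).all() and (m_a.beta < 1).all()


def test_methylation_deterministic(small_config, cohorts):
    m_a, _ = cohorts["meth"]
    g_a = sim.simulate_genotypes(small_config, "discovery")
    m_a2, _ = sim.simulate_methylation(g_a, small_config)
    assert np.array_equal(m_a.beta, m_a2.beta)


def test_truth_references_existing_probes_and_snps(cohorts):
    g_a, _ = cohorts["geno"]
    m_a, _ = cohorts["meth"]
    t_a, _ = cohorts["truth"]
    assert t_a.pairs["probe_id"].isin(m_a.probes["probe_id"]).all()
    assert t_a.pairs["snp_id"].isin(g_a.snps["snp_id"]).all()


def test_planted_variance_fraction_recovered():
    """Planted fraction 0.5 at n=1000: dosage vs logit(β) r² in [0.42, 0.58]."""
    cfg = sim.SimConfig(
        n_individuals={"a": 1000}, n_snps=300, n_probes=20,
        chrom_lengths={"1": 30_000_000}, cis_effect_grid=[0.5], seed=123,
    )
    g = sim.simulate_genotypes(cfg, "a")
    m, truth = sim.simulate_methylation(g, cfg)
    row = truth.pairs.iloc[0]
    i = m.probes.index[m.probes["probe_id"] == row["probe_id"]][0]
    j = int(g.snp_index()[row["snp_id"]])
    r2 = np.corrcoef(g.dosages[:, j], logit(m.beta[i]))[0, 1] ** 2
    assert 0.42 <= r2 <= 0.58


def test_excess_planted_variance_rejected():
    cfg = sim.SimConfig(
        n_individuals={"a": 50}, n_snps=100, n_probes=5,
        chrom_lengths={"1": 10_000_000}, seed=2,
    )
    g = sim.simulate_genotypes(cfg, "a")
    probe = "cg000000"
    snps = g.snps["snp_id"].iloc[:2]
    cfg.cis_effect_grid = [(probe, snps.iloc[0], 0.6), (probe, snps.iloc[1], 0.5)]
    with pytest.raises(ValueError, match="sum"):
        sim.simulate_methylation(g, cfg)


def test_null_methylation_has_no_strong_association():
    """No planted effects: min association p stays far from 1e-11."""
    cfg = sim.SimConfig(
        n_individuals={"a": 300}, n_snps=200, n_probes=30,
        chrom_lengths={"1": 20_000_000}, seed=31,
    )
    g = sim.simulate_genotypes(cfg, "a")
    m, truth = sim.simulate_methylation(g, cfg)
    assert truth.pairs.empty
    y = logit(m.beta)
    pmin = 1.0
    for i in range(m.n_probes):
        for j in range(0, g.n_snps, 10):
            r, p = stats.pearsonr(g.dosages[:, j], y[i])
            pmin = min(pmin, p)
    assert pmin > 1e-11


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def null_ldscores(ref_panel):
    return ld_scores(ref_panel, mqtl_ids=ref_panel.snps["snp_id"].iloc[:300].tolist())


def test_sumstats_null_mean_chisq(null_ldscores):
    ss = sim.simulate_gwas_sumstats(null_ldscores, 0.0, 0.0, 1.0, 10_000, seed=3)
    m = len(ss.table)
    assert abs(ss.table["chisq"].mean() - 1.0) < 3 * np.sqrt(2.0 / m)


def test_sumstats_regression_recovers_planted_coefficients(null_ldscores):
    import statsmodels.api as sm

    tau_m, tau_g, alpha, n = 2e-5, 1e-5, 1.2, 20_000
    ss = sim.simulate_gwas_sumstats(null_ldscores, tau_m, tau_g, alpha, n, seed=4)
    tab = null_ldscores.table
    x = sm.add_constant(tab[["L_mqtl", "L_G"]].to_numpy())
    res = sm.OLS(ss.table["chisq"].to_numpy(), x).fit()
    truth = np.array([alpha, n * tau_m, n * tau_g])
    assert np.all(np.abs(res.params - truth) < 3 * res.bse)


def test_sumstats_deterministic(null_ldscores):
    a = sim.simulate_gwas_sumstats(null_ldscores, 1e-5, 1e-5, 1.0, 1000, seed=8)
    b = sim.simulate_gwas_sumstats(null_ldscores, 1e-5, 1e-5, 1.0, 1000, seed=8)
    assert a.table.equals(b.table)


def test_sumstats_negative_tau_rejected(null_ldscores):
    with pytest.raises(ValueError, match="non-negative"):
        sim.simulate_gwas_sumstats(null_ldscores, -1e-5, 0.0, 1.0, 1000, seed=0)


# ---------------------------------------------------------------------------
# gene model
# ---------------------------------------------------------------------------

def test_gene_model_nonoverlapping_and_bounded():
    cfg = sim.SimConfig(
        n_individuals={"a": 10}, n_snps=50, n_probes=5,
        chrom_lengths={"1": 10_000_000}, seed=6,
    )
    model = sim.simulate_gene_model(cfg, genes_per_mbp=1.0)
    txs = model.transcripts
    assert len(txs) == 10
    ends = txs.sort_values("tx_start")
    assert (ends["tx_start"].to_numpy()[1:] > ends["tx_end"].to_numpy()[:-1]).all()
    for _, tx in txs.iterrows():
        for s, e in zip(tx["exon_starts"], tx["exon_ends"]):
            assert tx["tx_start"] <= s <= e <= tx["tx_end"]


def test_gene_model_utr5_round_trip():
    """A base inside a coding transcript's 5' UTR annotates as UTR5."""
    cfg = sim.SimConfig(
        n_individuals={"a": 10}, n_snps=50, n_probes=5,
        chrom_lengths={"1": 10_000_000}, seed=6,
    )
    model = sim.simulate_gene_model(cfg, genes_per_mbp=1.0, coding_fraction=1.0)
    tx = model.transcripts.iloc[0]
    if tx["strand"] == "+":
        utr5_pos = tx["exon_starts"][0]  # first exon base, before cds_start
        assert utr5_pos < tx["cds_start"]
    else:
        utr5_pos = tx["exon_ends"][-1]
        assert utr5_pos > tx["cds_end"]
    assert annotate_position(tx["chrom"], int(utr5_pos), model) == "UTR5"
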