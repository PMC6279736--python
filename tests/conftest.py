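"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mqtlkit import sim
from mqtlkit.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    return sim.SimConfig(
        n_individuals={"discovery": 500, "replication": 500},
        n_snps=600,
        n_probes=40,
        chrom_lengths={"1": 40_000_000, "2": 30_000_000, "3": 20_000_000},
        cis_effect_grid=[0.4, 0.35],
        trans_effect_grid=[0.4],
        seed=20240901,
    )


@pytest.fixture(scope="session")
def cohorts(small_config):
    """Two cohorts with planted cis/trans effects, plus the truth table."""
    g_a = sim.simulate_genotypes(small_config, "discovery")
    g_b = sim.simulate_genotypes(small_config, "replication")
    m_a, t_a = sim.simulate_methylation(g_a, small_config)
    m_b, t_b = sim.simulate_methylation(g_b, small_config)
    return {"geno": (g_a, g_b), "meth": (m_a, m_b), "truth": (t_a, t_b)}


@pytest.fixture(scope="session")
def ref_panel() -> GenotypeMatrix:
    """LD-bearing reference panel for LD-score and pruning tests."""
    cfg = sim.SimConfig(
        n_individuals={"ref": 500},
        n_snps=2000,
        n_probes=10,
        chrom_lengths={"1": 60_000_000, "2": 40_000_000},
        seed=77,
    )
    return sim.simulate_genotypes(cfg, "ref")


def make_geno(
    dosages: np.ndarray,
    chroms: list[str] | None = None,
    positions: list[int] | None = None,
    genotyped: list[bool] | None = None,
) -> GenotypeMatrix:
    """Hand-built GenotypeMatrix from a dosage array (samples × SNPs)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chroms or ["1"] * m,
            "pos": positions or list(range(1000, 1000 + m)),
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(dosages.mean(0) / 2, 1 - dosages.mean(0) / 2),
            "genotyped": genotyped or [True] * m,
        }
    )
    return GenotypeMatrix(
        samples=[f"i{i}" for i in range(n)], snps=snps, dosages=dosages
    )
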