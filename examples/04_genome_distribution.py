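"""Subtelomeric enrichment and annotation of simulated positions.

Computes the genome fraction covered by 1 Mbp subtelomeric margins on the
GRCh37 autosomes, tests a position set concentrated near chromosome ends
against that expectation, and annotates a toy gene model's neighbourhood.
"""

import numpy as np
import pandas as pd

from mqtlkit import sim
from mqtlkit.annotation import AnnotationConfig, category_table
from mqtlkit.distribution import (
    GRCH37_AUTOSOME_LENGTHS,
    SubtelomericConfig,
    subtelomeric_enrichment,
    subtelomeric_fraction,
)

cfg = SubtelomericConfig()  # 1 Mbp margins, GRCh37 autosomes
frac = subtelomeric_fraction(cfg)
print(f"subtelomeric genome fraction: {100 * frac:.2f}%")

rng = np.random.default_rng(4)
chroms = list(GRCH37_AUTOSOME_LENGTHS)
rows = []
for i in range(2000):
    c = chroms[i % len(chroms)]
    if i < 360:  # concentrate 18% of positions in the margins
        rows.append({"chrom": c, "pos": int(rng.integers(1, 1_000_000))})
    else:
        rows.append({"chrom": c, "pos": int(
            rng.integers(1_000_001, GRCH37_AUTOSOME_LENGTHS[c] - 1_000_000))})
observed, p = subtelomeric_enrichment(pd.DataFrame(rows), cfg)
print(f"observed subtelomeric share : {100 * observed:.1f}%")
print(f"one-sided binomial p        : {p:.2e}")

sim_cfg = sim.SimConfig(
    n_individuals={"a": 10}, n_snps=50, n_probes=5,
    chrom_lengths={"1": 30_000_000}, seed=4,
)
model = sim.simulate_gene_model(sim_cfg, genes_per_mbp=1.0)
positions = pd.DataFrame({"chrom": "1", "pos": rng.integers(1, 30_000_000, 400)})
table = category_table(positions, model, AnnotationConfig(upstream_downstream_bp=100_000))
print("\nannotation of 400 uniform positions (100 kb up/downstream):")
print(table[table["count"] > 0].to_string())
print(
    "\nA position's category is decided by precedence when transcripts"
    "\ndisagree (Exonic > UTR5 > UTR3 > ncRNA-exonic > Intronic > ...)."
)
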