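#!/usr/bin/env python
"""Per-gene nucleotide diversity across a simulated species panel.

Evolves the default synthetic genome along a 5-taxon tree with
per-gene rate multipliers (cytochrome genes and nad1 slow, atp8/nad2
fast), then recomputes Pi and Pi(JC) per gene and compares the
recovered ranking to the configured rates.  Writes
results/diversity.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

import mitocomp as mc
from mitocomp.simulate import (SimulationConfig, alignments_from_panel,
                               evolve_on_tree, simulate_genome)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = SimulationConfig(seed=args.seed)
panel = evolve_on_tree(simulate_genome(cfg), cfg)
records = mc.per_gene_diversity(alignments_from_panel(panel))

rows = [{"gene": r.gene, "n_taxa": r.n_taxa, "sites": round(r.sites_used, 1),
         "pi": round(r.pi, 5), "pi_jc": round(r.pi_jc, 5),
         "true_rate": cfg.per_gene_rate[r.gene]} for r in records]
pd.DataFrame(rows).to_csv(OUT / "diversity.tsv", sep="\t", index=False)

rho = spearmanr([r["true_rate"] for r in rows],
                [r["pi"] for r in rows]).statistic
print("genes ranked by Pi (ascending):",
      " < ".join(r["gene"] for r in rows))
print(f"Spearman rho between configured rates and recovered Pi: {rho:.3f}")
print(f"wrote {OUT / 'diversity.tsv'}")
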