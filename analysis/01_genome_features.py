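#!/usr/bin/env python
"""Annotation geometry and gene order of the two hoverfly mitogenomes.

Recomputes, from the bundled coordinate tables, the junction-level
accounting (intergenic spacers, overlaps, adjacencies), per-category
length totals, and the comparison of each gene arrangement to the
ancestral insect arrangement.  Writes results/geometry_junctions.tsv
and results/geometry_summary.tsv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

import mitocomp as mc
from mitocomp.fixtures import episyrphus_genome, eupeodes_genome
from mitocomp.geometry import category_totals, geometry_summary, junction_gaps

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

junctions, summaries = [], []
for genome in (episyrphus_genome(), eupeodes_genome()):
    for j in junction_gaps(genome):
        junctions.append({"genome": genome.id, **dataclasses.asdict(j)})
    s = dataclasses.asdict(geometry_summary(genome))
    s["genome"] = genome.id
    s["genome_length"] = genome.length
    for cat, (total, _) in category_totals(genome).items():
        s[f"{cat}_total_bp"] = total
    arr = mc.arrangement_of(genome)
    s["breakpoints_vs_ancestral"] = mc.breakpoint_distance(
        arr, mc.ANCESTRAL_INSECT)
    s["strand_counts"] = "%d/%d" % mc.strand_counts(arr)
    summaries.append(s)

    print(f"{genome.id}: {s['n_spacer_locations']} spacer locations "
          f"({s['spacer_min']}-{s['spacer_max']} bp, longest at "
          f"{s['longest_spacer_junction']}), {s['n_overlap_pairs']} "
          f"overlaps ({s['overlap_min']}-{s['overlap_max']} bp), "
          f"{s['n_adjacent_pairs']} adjacent pairs; "
          f"breakpoints vs ancestral arrangement: "
          f"{s['breakpoints_vs_ancestral']}")

pd.DataFrame(junctions).to_csv(OUT / "geometry_junctions.tsv",
                               sep="\t", index=False)
pd.DataFrame(summaries).to_csv(OUT / "geometry_summary.tsv",
                               sep="\t", index=False)
print(f"wrote {OUT / 'geometry_junctions.tsv'} and geometry_summary.tsv")
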