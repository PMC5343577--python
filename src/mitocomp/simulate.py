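"""Synthetic annotated mitogenomes with known ground truth.

The generator lays out the 37 genes plus control region in the
ancestral insect arrangement, with the gene lengths, intergenic gaps,
strands, anticodons and start codons of the complete hoverfly
mitogenome annotation as defaults — so the default synthetic genome
has exactly the geometry of the real one (16,175 bp; 22 spacers, 7
overlaps, 8 adjacencies).  PCGs are an ATN start + body codons drawn
from an A+T-biased codon weight table + a (possibly incomplete) stop;
tRNAs are instantiated from the clover-leaf templates; rRNAs, control
region and spacers are drawn i.i.d. from per-category base
probabilities.

Species panels are produced by Jukes–Cantor substitution along a
Newick tree, with per-gene rate multipliers and PCG start/stop codons
masked (immutable), and no indels — so per-gene "alignments" across
the panel are exact by construction.

One seeded numpy generator drives everything; a config plus seed
fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import brentq

from .codon_usage import INVERTEBRATE_MITO
from .diversity import Alignment
from .gene_order import ANCESTRAL_INSECT, Arrangement
from .model import (AnnotatedGenome, GeneFeature, category_of,
                    gene_sequence, reverse_complement)
from .trna import TRNA_ANTICODONS, cloverleaf_template

__all__ = ["SimulationConfig", "simulate_genome", "evolve_on_tree",
           "expected_p", "alignments_from_panel",
           "EPISYRPHUS_GENE_LENGTHS", "EPISYRPHUS_GAPS",
           "DEFAULT_PER_GENE_RATE", "default_codon_weights"]

#: Gene lengths (bp) of the complete hoverfly mitogenome annotation.
EPISYRPHUS_GENE_LENGTHS = {
    "trnI": 66, "trnQ": 69, "trnM": 69, "nad2": 1032, "trnW": 68,
    "trnC": 67, "trnY": 66, "cox1": 1560, "trnL2": 66, "cox2": 684,
    "trnK": 71, "trnD": 67, "atp8": 162, "atp6": 678, "cox3": 789,
    "trnG": 66, "nad3": 354, "trnA": 69, "trnR": 64, "trnN": 67,
    "trnS1": 67, "trnE": 65, "trnF": 67, "nad5": 1722, "trnH": 67,
    "nad4": 1341, "nad4l": 297, "trnT": 65, "trnP": 66, "nad6": 525,
    "cob": 1137, "trnS2": 68, "nad1": 939, "trnL1": 65, "rrnL": 1338,
    "trnV": 72, "rrnS": 804,
}

#: Intergenic gap after each gene (negative = overlap with the next),
#: from the same annotation; the last entry leads into the control region.
EPISYRPHUS_GAPS = {
    "trnI": 2, "trnQ": 14, "trnM": 0, "nad2": 3, "trnW": 8, "trnC": 14,
    "trnY": 5, "cox1": -5, "trnL2": 2, "cox2": 5, "trnK": 60, "trnD": 0,
    "atp8": -7, "atp6": 35, "cox3": 3, "trnG": 0, "nad3": 4, "trnA": -1,
    "trnR": 2, "trnN": -1, "trnS1": 1, "trnE": 23, "trnF": -1,
    "nad5": 15, "trnH": -1, "nad4": -7, "nad4l": 2, "trnT": 0,
    "trnP": 2, "nad6": 3, "cob": 1, "trnS2": 16, "nad1": 10,
    "trnL1": 0, "rrnL": 0, "trnV": 0, "rrnS": 0,
}

EPISYRPHUS_START_CODONS = {
    "nad2": "ATT", "cox1": "ATT", "cox2": "ATG", "atp8": "ATT",
    "atp6": "ATG", "cox3": "ATG", "nad3": "ATT", "nad5": "ATT",
    "nad4": "ATG", "nad4l": "ATG", "nad6": "ATT", "cob": "ATG",
    "nad1": "ATA",
}

#: Relative substitution-rate multipliers emulating the observed
#: per-gene diversity ranking: cox1/cox2/cox3/cob/nad1 slow,
#: atp8/nad2/nad3 fast, the rest in between.
DEFAULT_PER_GENE_RATE = {
    "cox1": 0.40, "cox2": 0.45, "cox3": 0.50, "cob": 0.55, "nad1": 0.60,
    "nad4l": 0.90, "nad4": 1.00, "atp6": 1.05, "nad6": 1.10,
    "nad5": 1.15, "nad3": 1.30, "nad2": 1.45, "atp8": 1.60,
}

#: Base probabilities for regions drawn i.i.d. (A, C, G, T order).
DEFAULT_CATEGORY_COMPOSITION = {
    "rRNA": {"A": 0.44, "C": 0.088, "G": 0.066, "T": 0.406},      # A+T 84.6%
    "control": {"A": 0.45, "C": 0.080, "G": 0.070, "T": 0.400},   # A+T 85%
    "intergenic": {"A": 0.42, "C": 0.100, "G": 0.080, "T": 0.400},
}

_FOUR_FREQUENT = ("TTA", "ATT", "TTT", "ATA")


def default_codon_weights(target_at: float = 0.7885,
                          frequent_boost: float = 4.0) -> dict[str, float]:
    """Codon weights for PCG bodies, calibrated to a target A+T content.

    Weights are exp(beta · #AT-bases) over the sense codons of the
    invertebrate mitochondrial code, with an extra multiplicative
    boost for TTA/ATT/TTT/ATA (the four codons that dominate fly
    mitogenomes); beta is solved so the expected A+T fraction of a
    drawn codon equals ``target_at``.  Deterministic.
    """
    codons = sorted(INVERTEBRATE_MITO.forward)

    def at_count(c: str) -> int:
        return sum(b in "AT" for b in c)

    def expected_at(beta: float) -> float:
        w = np.array([math.exp(beta * at_count(c)) *
                      (frequent_boost if c in _FOUR_FREQUENT else 1.0)
                      for c in codons])
        at = np.array([at_count(c) / 3 for c in codons])
        return float(np.average(at, weights=w))

    beta = brentq(lambda b: expected_at(b) - target_at, -5.0, 5.0,
                  xtol=1e-12)
    return {c: math.exp(beta * at_count(c)) *
            (frequent_boost if c in _FOUR_FREQUENT else 1.0)
            for c in codons}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines output."""

    seed: int = 0
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(EPISYRPHUS_GENE_LENGTHS))
    arrangement: Arrangement = ANCESTRAL_INSECT
    gaps: dict[str, int] = field(
        default_factory=lambda: dict(EPISYRPHUS_GAPS))
    start_codons: dict[str, str] = field(
        default_factory=lambda: dict(EPISYRPHUS_START_CODONS))
    stop_codons: dict[str, str] = field(default_factory=dict)  # default TAA
    composition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_CATEGORY_COMPOSITION.items()})
    codon_weights: dict[str, float] = field(
        default_factory=default_codon_weights)
    control_region_length: int = 1129
    tree: str = ("((A:0.025,B:0.025):0.0125,(C:0.025,D:0.025):0.0125,"
                 "E:0.0375);")
    per_gene_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PER_GENE_RATE))


def _default_stop(length: int) -> str:
    """Complete TAA for 3k genes, incomplete TA / T otherwise."""
    return {0: "TAA", 2: "TA", 1: "T"}[length % 3]


def _draw(rng: np.random.Generator, probs: dict[str, float],
          n: int) -> str:
    bases = sorted(probs)
    p = np.array([probs[b] for b in bases], dtype=float)
    p = p / p.sum()
    return "".join(np.array(bases)[rng.choice(len(bases), size=n, p=p)])


def _pcg_sequence(name: str, length: int, cfg: SimulationConfig,
                  rng: np.random.Generator) -> str:
    start = cfg.start_codons.get(name, "ATG")
    stop = cfg.stop_codons.get(name, _default_stop(length))
    body_nt = length - 3 - len(stop)
    if body_nt < 0 or body_nt % 3:
        raise ValueError(f"{name}: length {length} incompatible with "
                         f"start+stop structure")
    codons = sorted(cfg.codon_weights)
    w = np.array([cfg.codon_weights[c] for c in codons], dtype=float)
    w = w / w.sum()
    picks = rng.choice(len(codons), size=body_nt // 3, p=w)
    body = "".join(codons[i] for i in picks)
    return start + body + stop


def simulate_genome(cfg: SimulationConfig | None = None) -> AnnotatedGenome:
    """Generate one annotated genome according to the configuration."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    # lay out coordinates in arrangement order
    feats: list[GeneFeature] = []
    pos = 1
    for name, strand in cfg.arrangement:
        length = cfg.gene_lengths[name]
        start, end = pos, pos + length - 1
        cat = category_of(name)
        feats.append(GeneFeature(
            name=name, start=start, end=end, strand=strand, category=cat,
            anticodon=TRNA_ANTICODONS.get(name) if cat == "tRNA" else None,
            start_codon=cfg.start_codons.get(name) if cat == "PCG" else None,
            stop_codon=(cfg.stop_codons.get(name, _default_stop(length))
                        if cat == "PCG" else None),
        ))
        pos = end + 1 + cfg.gaps.get(name, 0)
    ctrl_start = pos
    ctrl_end = pos + cfg.control_region_length - 1
    feats.append(GeneFeature(name="CONTROL", start=ctrl_start, end=ctrl_end,
                             strand="N", category="control"))
    genome_length = ctrl_end

    # background fill, then write features in genomic order
    seq = list(_draw(rng, cfg.composition["intergenic"], genome_length))
    for f in sorted(feats, key=lambda f: f.start):
        if f.category == "PCG":
            coding = _pcg_sequence(f.name, f.length, cfg, rng)
        elif f.category == "tRNA":
            coding = cloverleaf_template(f.name, f.length)[0].replace("U", "T")
        elif f.category == "rRNA":
            coding = _draw(rng, cfg.composition["rRNA"], f.length)
        else:
            coding = _draw(rng, cfg.composition["control"], f.length)
        genomic = reverse_complement(coding) if f.strand == "N" else coding
        seq[f.start - 1:f.end] = genomic

    # overlapping neighbours may have clobbered PCG termini: re-force them
    for f in feats:
        if f.category != "PCG":
            continue
        coding_start = f.start_codon or "ATG"
        coding_stop = f.stop_codon or "TAA"
        if f.strand == "J":
            seq[f.start - 1:f.start - 1 + 3] = coding_start
            seq[f.end - len(coding_stop):f.end] = coding_stop
        else:
            seq[f.end - 3:f.end] = reverse_complement(coding_start)
            seq[f.start - 1:f.start - 1 + len(coding_stop)] = \
                reverse_complement(coding_stop)

    return AnnotatedGenome(id=f"SYN{cfg.seed:06d}", length=genome_length,
                           circular=True, sequence="".join(seq),
                           features=feats)


def expected_p(d: float) -> float:
    """Expected mismatch proportion after Jukes–Cantor evolution over
    branch length ``d`` (substitutions/site): (3/4)(1 − e^(−4d/3))."""
    if d < 0:
        raise ValueError("negative branch length")
    return 0.75 * -math.expm1(-4.0 * d / 3.0)


def _site_rates(genome: AnnotatedGenome,
                per_gene_rate: dict[str, float]) -> np.ndarray:
    rates = np.ones(genome.length)
    for f in genome.features:
        rate = per_gene_rate.get(f.name, 1.0)
        rates[f.start - 1:f.end] = rate
    # PCG start/stop codons are masked (immutable under evolution)
    for f in genome.features:
        if f.category != "PCG":
            continue
        stop_len = len(f.stop_codon or "TAA")
        if f.strand == "J":
            rates[f.start - 1:f.start + 2] = 0.0
            rates[f.end - stop_len:f.end] = 0.0
        else:
            rates[f.end - 3:f.end] = 0.0
            rates[f.start - 1:f.start - 1 + stop_len] = 0.0
    return rates


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _mutate(seq_idx: np.ndarray, d: float, rates: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor substitution over branch length d at per-site rates."""
    p = 0.75 * -np.expm1(-4.0 * d * rates / 3.0)
    hit = rng.random(seq_idx.size) < p
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out = seq_idx.copy()
    out[hit] = (out[hit] + shift) % 4
    return out


def evolve_on_tree(genome: AnnotatedGenome,
                   cfg: SimulationConfig | None = None,
                   ) -> dict[str, AnnotatedGenome]:
    """Evolve a genome along ``cfg.tree``; one genome per leaf taxon.

    Substitutions follow the Jukes–Cantor model site-wise, scaled by
    per-gene rate multipliers; annotations carry over unchanged (no
    indels).  The RNG is seeded from ``cfg.seed`` independently of
    :func:`simulate_genome`.
    """
    cfg = cfg or SimulationConfig()
    if genome.sequence is None:
        raise ValueError("sequence required")
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length: {edge.length}")

    rng = np.random.default_rng((cfg.seed, 0x9E3779B9))
    rates = _site_rates(genome, cfg.per_gene_rate)
    base_to_idx = {b: i for i, b in enumerate("ACGT")}
    root_idx = np.array([base_to_idx[b] for b in genome.sequence])

    panel: dict[str, AnnotatedGenome] = {}
    seqs = {id(tree.seed_node): root_idx}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = seqs[id(node.parent_node)]
        d = node.edge.length or 0.0
        child = _mutate(parent, d, rates, rng)
        seqs[id(node)] = child
        if node.is_leaf():
            taxon = node.taxon.label if node.taxon else f"leaf{len(panel)}"
            panel[taxon] = AnnotatedGenome(
                id=taxon, length=genome.length, circular=genome.circular,
                sequence="".join("ACGT"[i] for i in child),
                features=list(genome.features))
    return panel


def alignments_from_panel(panel: dict[str, AnnotatedGenome],
                          genes: list[str] | None = None) -> list[Alignment]:
    """Per-gene alignments (exact, since evolution is indel-free)."""
    taxa = sorted(panel)
    if genes is None:
        some = panel[taxa[0]]
        genes = [f.name for f in some.features if f.category == "PCG"]
    return [Alignment(gene=g, taxa=tuple(taxa),
                      rows=tuple(gene_sequence(panel[t], g) for t in taxa))
            for g in genes]
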