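"""Junction-level accounting of an annotated mitogenome.

Every pair of consecutive features defines a junction with a signed
gap: positive bp are an intergenic spacer, negative bp an overlap,
zero an exact adjacency.  The circular junction from the control
region back to the first gene is deliberately not emitted — published
annotation tables do not carry an intergenic entry for it, and spacer
location counts are only reproducible under that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnnotatedGenome, gene_sequence

__all__ = ["JunctionRecord", "GeometrySummary", "CodonRecord",
           "junction_gaps", "geometry_summary", "codon_inventory",
           "category_totals"]


@dataclass(frozen=True)
class JunctionRecord:
    upstream: str
    downstream: str
    gap: int  # start(downstream) - end(upstream) - 1


@dataclass(frozen=True)
class GeometrySummary:
    n_spacer_locations: int
    spacer_total: int
    spacer_min: int | None
    spacer_max: int | None
    longest_spacer_junction: tuple[str, str] | None
    n_overlap_pairs: int
    overlap_min: int | None
    overlap_max: int | None
    n_adjacent_pairs: int


@dataclass(frozen=True)
class CodonRecord:
    gene: str
    start_codon: str
    stop_codon: str  # "TAA" | "TAG" | "TA" | "T"
    complete_stop: bool


def junction_gaps(genome: AnnotatedGenome) -> list[JunctionRecord]:
    """Signed gaps between consecutive features, in start order."""
    feats = genome.features
    if len(feats) < 2:
        raise ValueError("need at least two features")
    return [JunctionRecord(a.name, b.name, b.start - a.end - 1)
            for a, b in zip(feats, feats[1:])]


def geometry_summary(genome: AnnotatedGenome) -> GeometrySummary:
    """Spacer/overlap/adjacency statistics over all junctions."""
    gaps = junction_gaps(genome)
    spacers = [j for j in gaps if j.gap > 0]
    overlaps = [abs(j.gap) for j in gaps if j.gap < 0]
    longest = max(spacers, key=lambda j: j.gap) if spacers else None
    return GeometrySummary(
        n_spacer_locations=len(spacers),
        spacer_total=sum(j.gap for j in spacers),
        spacer_min=min((j.gap for j in spacers), default=None),
        spacer_max=longest.gap if longest else None,
        longest_spacer_junction=(longest.upstream, longest.downstream)
        if longest else None,
        n_overlap_pairs=len(overlaps),
        overlap_min=min(overlaps, default=None),
        overlap_max=max(overlaps, default=None),
        n_adjacent_pairs=sum(1 for j in gaps if j.gap == 0),
    )


def codon_inventory(genome: AnnotatedGenome) -> list[CodonRecord]:
    """Start and stop codons of every PCG, read in coding sense.

    Stops may be incomplete: a gene of length 3k+2 must end in TA and
    one of length 3k+1 in T (completed to TAA by polyadenylation of
    the transcript).  Complete genes (length 3k) must end TAA or TAG.
    """
    records = []
    for f in genome.features:
        if f.category != "PCG":
            continue
        seq = gene_sequence(genome, f.name).upper()
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            stop, complete = seq[-3:], True
            if stop not in ("TAA", "TAG"):
                raise ValueError(f"unrecognized stop in {f.name}: {stop}")
        elif rem == 2:
            stop, complete = seq[-2:], False
            if stop != "TA":
                raise ValueError(f"unrecognized stop in {f.name}: {stop}")
        else:
            stop, complete = seq[-1:], False
            if stop != "T":
                raise ValueError(f"unrecognized stop in {f.name}: {stop}")
        records.append(CodonRecord(f.name, start, stop, complete))
    return records


def category_totals(genome: AnnotatedGenome) -> dict[str, tuple[int, float | None]]:
    """Per-category (total length bp, A+T% or None) sums.

    Lengths are summed per gene with no overlap deduplication, matching
    how published tables total their per-gene length columns.  A+T% is
    computed over the concatenated coding-sense sequences when the
    genome carries a sequence.
    """
    from .composition import composition  # local import avoids a cycle
    totals: dict[str, tuple[int, float | None]] = {}
    by_cat: dict[str, list] = {}
    for f in genome.features:
        by_cat.setdefault(f.category, []).append(f)
    for cat, feats in by_cat.items():
        total = sum(f.length for f in feats)
        at = None
        if genome.sequence is not None:
            concat = "".join(gene_sequence(genome, f.name) for f in feats)
            at = composition(concat).at_content
        totals[cat] = (total, at)
    return totals
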