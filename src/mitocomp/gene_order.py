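"""Circular gene arrangements and breakpoint comparison.

An arrangement is the circular, strand-aware order of the 37
mitochondrial genes (control region excluded), canonically rotated to
begin at trnI.  Rearrangement between two arrangements is quantified
as the breakpoint distance: the number of signed gene adjacencies
present in one arrangement but absent from the other, where adjacency
(x→y) on given strands also matches its mirror read on the opposite
strand (−y→−x).
"""

from __future__ import annotations

from .model import AnnotatedGenome

__all__ = ["Arrangement", "ANCESTRAL_INSECT", "arrangement_of",
           "strand_counts", "breakpoint_distance"]

#: (gene, strand) pairs; strand J = majority, N = minority.
Arrangement = tuple[tuple[str, str], ...]

#: The putative ancestral insect mitochondrial gene arrangement,
#: identical to the order and strand assignment of hoverfly (and most
#: other dipteran) mitogenomes: 23 genes on J, 14 on N.
ANCESTRAL_INSECT: Arrangement = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"), ("cox1", "J"),
    ("trnL2", "J"), ("cox2", "J"), ("trnK", "J"), ("trnD", "J"),
    ("atp8", "J"), ("atp6", "J"), ("cox3", "J"), ("trnG", "J"),
    ("nad3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"),
    ("trnH", "N"), ("nad4", "N"), ("nad4l", "N"), ("trnT", "J"),
    ("trnP", "N"), ("nad6", "J"), ("cob", "J"), ("trnS2", "J"),
    ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"), ("trnV", "N"),
    ("rrnS", "N"),
)


def _rotate(entries: list[tuple[str, str]]) -> Arrangement:
    names = [g for g, _ in entries]
    if "trnI" in names:
        k = names.index("trnI")
    else:
        k = names.index(min(names))
    return tuple(entries[k:] + entries[:k])


def arrangement_of(genome: AnnotatedGenome) -> Arrangement:
    """Strand-aware gene order of a genome, rotated to start at trnI.

    The control region is excluded; if trnI is absent the rotation
    anchors at the lexicographically smallest gene token instead.
    """
    entries = [(f.name, f.strand) for f in genome.features
               if f.category != "control"]
    if len(set(g for g, _ in entries)) != len(entries):
        raise ValueError("duplicate genes in arrangement")
    if not entries:
        return ()
    return _rotate(entries)


def strand_counts(a: Arrangement) -> tuple[int, int]:
    """(J count, N count) over the arrangement entries."""
    j = sum(1 for _, s in a if s == "J")
    return j, len(a) - j


def _signed_adjacencies(a: Arrangement) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Canonical signed adjacency set of a circular arrangement."""
    signed = [(g, 1 if s == "J" else -1) for g, s in a]
    adj = set()
    n = len(signed)
    for i in range(n):
        x, y = signed[i], signed[(i + 1) % n]
        mirror = ((y[0], -y[1]), (x[0], -x[1]))
        adj.add(min((x, y), mirror))  # orientation-free canonical form
    return adj


def breakpoint_distance(a: Arrangement, b: Arrangement) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (symmetric).

    Zero iff the circular arrangements are identical up to rotation.
    Requires the same gene set in both arrangements.
    """
    genes_a, genes_b = {g for g, _ in a}, {g for g, _ in b}
    if genes_a != genes_b:
        raise ValueError(
            f"gene sets differ: only in first {sorted(genes_a - genes_b)}, "
            f"only in second {sorted(genes_b - genes_a)}")
    return len(_signed_adjacencies(a) - _signed_adjacencies(b))
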