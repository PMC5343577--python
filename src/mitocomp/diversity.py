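"""Nucleotide diversity (Pi) with Jukes–Cantor correction.

Pi is the unweighted mean of pairwise p-distances over all unordered
sequence pairs of an alignment, computed with pairwise deletion of
gapped/ambiguous columns — the interspecific diversity reported for
one-sequence-per-species panels.  Pi(JC) applies the Jukes–Cantor
correction d = −(3/4)·ln(1 − (4/3)p) to each pairwise p before
averaging (correct-then-average, not JC of the mean).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

__all__ = ["Alignment", "DiversityRecord", "p_distance", "jc_correct",
           "nucleotide_diversity", "per_gene_diversity"]

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class Alignment:
    """Equal-length homologous sequences for one gene ('-' gaps allowed)."""

    gene: str
    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")
        object.__setattr__(self, "rows",
                           tuple(r.upper().replace("U", "T")
                                 for r in self.rows))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class DiversityRecord:
    gene: str
    n_taxa: int
    sites_used: float    # mean comparable sites per pair
    pi: float
    pi_jc: float


def p_distance(a: str, b: str) -> tuple[float, int]:
    """(mismatch proportion, comparable sites) under pairwise deletion."""
    if len(a) != len(b):
        raise ValueError("unequal lengths")
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    sites = mismatches = 0
    for x, y in zip(a, b):
        if x in _VALID and y in _VALID:
            sites += 1
            if x != y:
                mismatches += 1
    if sites == 0:
        raise ValueError("no overlap")
    return mismatches / sites, sites


def jc_correct(p: float) -> float:
    """Jukes–Cantor distance d = −(3/4)·ln(1 − (4/3)·p)."""
    if not 0 <= p < 0.75:
        raise ValueError(f"JC saturation: p={p}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def nucleotide_diversity(aln: Alignment) -> DiversityRecord:
    """Pi and Pi(JC) over all unordered pairs of an alignment.

    Pairs with no comparable sites are skipped with a warning; if every
    pair is skipped the alignment is unusable and an error is raised.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least two sequences")
    ps, sites = [], []
    for i, j in combinations(range(aln.n_taxa), 2):
        try:
            p, s = p_distance(aln.rows[i], aln.rows[j])
        except ValueError:
            warnings.warn(f"{aln.gene}: pair ({aln.taxa[i]}, {aln.taxa[j]}) "
                          "has no comparable sites; skipped", stacklevel=2)
            continue
        ps.append(p)
        sites.append(s)
    if not ps:
        raise ValueError("all pairs lack comparable sites")
    pi = sum(ps) / len(ps)
    pi_jc = sum(jc_correct(p) for p in ps) / len(ps)
    return DiversityRecord(gene=aln.gene, n_taxa=aln.n_taxa,
                           sites_used=sum(sites) / len(sites),
                           pi=pi, pi_jc=pi_jc)


def per_gene_diversity(alignments: list[Alignment]) -> list[DiversityRecord]:
    """Diversity per gene, sorted ascending by Pi (ties by gene token)."""
    records = [nucleotide_diversity(a) for a in alignments]
    return sorted(records, key=lambda r: (r.pi, r.gene))
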