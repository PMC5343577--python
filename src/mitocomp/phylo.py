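"""Concatenated supermatrix construction, JC distances and NJ trees.

The 37 mitochondrial genes are concatenated in the ancestral gene
order into one supermatrix with 1-based per-gene partition
coordinates, exportable as relaxed PHYLIP/NEXUS matrices and
RAxML/NEXUS partition (charset) files for external Bayesian/ML
inference.  A neighbor-joining tree on Jukes–Cantor distances is
provided as an in-package sanity check, not as a replacement for
those inference engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .diversity import Alignment, jc_correct, p_distance
from .gene_order import ANCESTRAL_INSECT

__all__ = ["Supermatrix", "DistanceMatrix", "concatenate",
           "split_supermatrix", "write_partitions", "write_phylip",
           "write_nexus", "jc_matrix", "nj_tree", "CANONICAL_GENE_ORDER"]

#: Concatenation order: the ancestral arrangement's gene order.
CANONICAL_GENE_ORDER = tuple(g for g, _ in ANCESTRAL_INSECT)


@dataclass(frozen=True)
class Supermatrix:
    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    partitions: tuple[tuple[str, int, int], ...]  # (gene, start, end) 1-based

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows have unequal lengths")
        expected = 1
        for gene, start, end in self.partitions:
            if start != expected or end < start:
                raise ValueError(f"partitions do not tile at {gene}")
            expected = end + 1
        if self.rows and expected - 1 != len(self.rows[0]):
            raise ValueError("partitions do not cover the matrix")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric "
                             "with zero diagonal")
        object.__setattr__(self, "d", d)


def concatenate(gene_alignments: list[Alignment],
                taxa: list[str] | None = None) -> Supermatrix:
    """Concatenate per-gene alignments in canonical gene order.

    A taxon missing from some gene receives an all-gap block for it,
    so partially sequenced taxa are retained rather than dropped.
    """
    if taxa is None:
        taxa = []
        for aln in gene_alignments:
            for t in aln.taxa:
                if t not in taxa:
                    taxa.append(t)
    by_gene = {a.gene: a for a in gene_alignments}
    if len(by_gene) != len(gene_alignments):
        raise ValueError("duplicate gene alignment")
    order = [g for g in CANONICAL_GENE_ORDER if g in by_gene]
    order += [g for g in sorted(by_gene) if g not in order]

    blocks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    col = 1
    for gene in order:
        aln = by_gene[gene]
        if len(set(aln.taxa)) != len(aln.taxa):
            raise ValueError(f"duplicate taxon within {gene}")
        index = dict(zip(aln.taxa, aln.rows))
        if not any(t in index for t in taxa):
            raise ValueError(f"no requested taxon present in {gene}")
        for t in taxa:
            blocks[t].append(index.get(t, "-" * aln.length))
        partitions.append((gene, col, col + aln.length - 1))
        col += aln.length
    return Supermatrix(taxa=tuple(taxa),
                       rows=tuple("".join(blocks[t]) for t in taxa),
                       partitions=tuple(partitions))


def split_supermatrix(sm: Supermatrix) -> list[Alignment]:
    """Inverse of :func:`concatenate` (gap-only rows dropped per gene)."""
    out = []
    for gene, start, end in sm.partitions:
        taxa, rows = [], []
        for t, row in zip(sm.taxa, sm.rows):
            block = row[start - 1:end]
            if set(block) != {"-"}:
                taxa.append(t)
                rows.append(block)
        out.append(Alignment(gene=gene, taxa=tuple(taxa), rows=tuple(rows)))
    return out


def write_partitions(sm: Supermatrix, dialect: str = "raxml") -> str:
    """Partition definitions as RAxML lines or a NEXUS sets block."""
    if dialect == "raxml":
        return "".join(f"DNA, {g} = {s}-{e}\n" for g, s, e in sm.partitions)
    if dialect == "nexus":
        body = "".join(f"  charset {g} = {s}-{e};\n"
                       for g, s, e in sm.partitions)
        return f"begin sets;\n{body}end;\n"
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_phylip(sm: Supermatrix) -> str:
    """Relaxed PHYLIP serialization of the supermatrix."""
    lines = [f" {len(sm.taxa)} {sm.length}"]
    lines += [f"{t}  {row}" for t, row in zip(sm.taxa, sm.rows)]
    return "\n".join(lines) + "\n"


def write_nexus(sm: Supermatrix) -> str:
    """NEXUS data block (plus the charset sets block)."""
    body = "".join(f"    {t}  {row}\n" for t, row in zip(sm.taxa, sm.rows))
    return ("#NEXUS\nbegin data;\n"
            f"  dimensions ntax={len(sm.taxa)} nchar={sm.length};\n"
            "  format datatype=dna missing=? gap=-;\n"
            "  matrix\n" + body + "  ;\nend;\n" + write_partitions(sm, "nexus"))


def jc_matrix(sm: Supermatrix) -> DistanceMatrix:
    """Pairwise Jukes–Cantor distance matrix (pairwise deletion)."""
    n = len(sm.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, _ = p_distance(sm.rows[i], sm.rows[j])
            try:
                d[i, j] = d[j, i] = jc_correct(p)
            except ValueError:
                raise ValueError(
                    f"saturated pair ({sm.taxa[i]}, {sm.taxa[j]}): "
                    f"p={p:.4f}") from None
    return DistanceMatrix(taxa=sm.taxa, d=d)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor joining (Saitou–Nei Q criterion) → Newick string.

    Ties in Q are broken by the lowest (i, j) index pair, negative
    branch-length estimates are clamped to zero with a warning, and
    branch lengths are printed to 6 decimals, so output is fully
    deterministic for a given matrix.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least three taxa")
    d = dm.d.copy()
    nodes = [f"{t}" for t in dm.taxa]
    active = list(range(n))

    def blen(x: float) -> float:
        if x < -1e-12:
            warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0",
                          stacklevel=3)
        return max(x, 0.0)

    while len(active) > 3:
        m = len(active)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] \
                    - sum(d[i, k] for k in active) \
                    - sum(d[j, k] for k in active)
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        m = len(active)
        ri = sum(d[i, k] for k in active)
        rj = sum(d[j, k] for k in active)
        li = 0.5 * d[i, j] + (ri - rj) / (2 * (m - 2))
        lj = d[i, j] - li
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(f"({nodes[i]}:{blen(li):.6f},{nodes[j]}:{blen(lj):.6f})")
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    return (f"({nodes[i]}:{blen(li):.6f},{nodes[j]}:{blen(lj):.6f},"
            f"{nodes[k]}:{blen(lk):.6f});")
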