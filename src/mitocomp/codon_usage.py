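"""Codon counting and relative synonymous codon usage (RSCU).

All counting is done under the invertebrate mitochondrial genetic
code (NCBI translation table 5; AGA/AGG → Ser, TGA → Trp, ATA → Met),
taken from Biopython's codon-table data.  RSCU of a codon is its
observed count divided by the mean count of its synonymous family, so
values sum to the family size and average exactly 1 within any family
that is used at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = ["GeneticCode", "INVERTEBRATE_MITO", "CodonCountTable",
           "count_codons", "rscu", "amino_acid_usage"]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon → amino acid map plus synonymous families."""

    table_id: int
    forward: dict[str, str]          # 61-ish sense codons → 1-letter AA
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi_table(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id=table_id,
                   forward=dict(t.forward_table),
                   stop_codons=frozenset(t.stop_codons))

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        fam: dict[str, list[str]] = {}
        for codon, aa in sorted(self.forward.items()):
            fam.setdefault(aa, []).append(codon)
        return {aa: tuple(cs) for aa, cs in fam.items()}


INVERTEBRATE_MITO = GeneticCode.from_ncbi_table(5)


@dataclass
class CodonCountTable:
    counts: Counter = field(default_factory=Counter)       # sense codons
    stop_counts: Counter = field(default_factory=Counter)
    ambiguous: int = 0        # codons containing non-ACGT symbols
    discarded: int = 0        # sequences ending in 1-2 trailing nt
    n_sequences: int = 0

    def per_amino_acid(self, code: GeneticCode) -> Counter:
        totals: Counter = Counter()
        for codon, n in self.counts.items():
            totals[code.forward[codon]] += n
        return totals


def count_codons(cds_set: list[str],
                 code: GeneticCode = INVERTEBRATE_MITO) -> CodonCountTable:
    """Count non-overlapping triplets over a set of coding sequences.

    Trailing 1–2 nt (incomplete stop codons) are tallied in
    ``discarded`` rather than padded; codons containing ambiguity
    symbols are tallied in ``ambiguous`` and not counted.
    """
    table = CodonCountTable()
    for seq in cds_set:
        s = seq.upper().replace("U", "T")
        if len(s) < 6:
            raise ValueError(f"coding sequence too short: {len(s)} nt")
        table.n_sequences += 1
        for i in range(0, len(s) - 2, 3):
            codon = s[i:i + 3]
            if any(b not in "ACGT" for b in codon):
                table.ambiguous += 1
            elif codon in code.stop_codons:
                table.stop_counts[codon] += 1
            else:
                table.counts[codon] += 1
        if len(s) % 3:
            table.discarded += 1
    return table


def rscu(table: CodonCountTable,
         code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """RSCU per sense codon: count / mean count of its family.

    Families with zero total usage get RSCU 0.0 for every member.
    """
    values: dict[str, float] = {}
    for aa, codons in code.families.items():
        total = sum(table.counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                values[c] = 0.0
            continue
        mean = total / len(codons)
        for c in codons:
            values[c] = table.counts.get(c, 0) / mean
    return values


def amino_acid_usage(table: CodonCountTable,
                     code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """Amino-acid frequencies over all counted sense codons."""
    totals = table.per_amino_acid(code)
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {aa: n / grand for aa, n in sorted(totals.items())}
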