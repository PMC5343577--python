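"""Domain model for annotated circular mitochondrial genomes.

An insect mitogenome carries 37 genes — 13 protein-coding genes (PCGs),
22 tRNAs and 2 rRNAs — plus one non-coding A+T-rich control region.
Coordinates are 1-based inclusive throughout, matching the convention of
published annotation tables.  The two coding strands are called J
(majority) and N (minority); features on N are stored with their genomic
coordinates and read in coding sense by reverse complementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GENE_VOCABULARY",
    "CONTROL_REGION",
    "PCG_GENES",
    "TRNA_GENES",
    "RRNA_GENES",
    "GeneFeature",
    "AnnotatedGenome",
    "reverse_complement",
    "gene_sequence",
    "category_of",
]

#: The 13 protein-coding genes of the animal mitogenome.
PCG_GENES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)

#: The 22 tRNA genes, named by amino acid with the standard L1/L2 and
#: S1/S2 split for the duplicated leucine and serine isoacceptors.
TRNA_GENES = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
)

RRNA_GENES = ("rrnL", "rrnS")

CONTROL_REGION = "CONTROL"

GENE_VOCABULARY = frozenset(PCG_GENES) | frozenset(TRNA_GENES) | \
    frozenset(RRNA_GENES) | {CONTROL_REGION}

_CATEGORY = {g: "PCG" for g in PCG_GENES}
_CATEGORY.update({g: "tRNA" for g in TRNA_GENES})
_CATEGORY.update({g: "rRNA" for g in RRNA_GENES})
_CATEGORY[CONTROL_REGION] = "control"

CATEGORIES = ("PCG", "tRNA", "rRNA", "control")


def category_of(name: str) -> str:
    """Return the canonical category (PCG/tRNA/rRNA/control) of a gene token."""
    try:
        return _CATEGORY[name]
    except KeyError:
        raise ValueError(f"unknown gene token: {name!r}") from None


_STRAND_ALIASES = {"+": "J", "J": "J", "-": "N", "−": "N", "N": "N"}


def normalize_strand(symbol: str) -> str:
    """Map '+'/'J' to J and '-'/'−'/'N' to N."""
    try:
        return _STRAND_ALIASES[symbol]
    except KeyError:
        raise ValueError(f"unknown strand symbol: {symbol!r}") from None


_COMPLEMENT = str.maketrans(
    "ACGTUWSMKRYBDHVNacgtuwsmkrybdhvn",
    "TGCAAWSKMYRVHDBNtgcaawskmyrvhdbn",
)
_IUPAC = set("ACGTUWSMKRYBDHVNacgtuwsmkrybdhvn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes honoured).

    Applying it twice is the identity.  Raises ``ValueError`` on any
    character outside the IUPAC nucleotide alphabet.
    """
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: 1-based inclusive coordinates on a named strand."""

    name: str
    start: int
    end: int
    strand: str
    category: str
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self):
        if self.name not in GENE_VOCABULARY:
            raise ValueError(f"unknown gene token: {self.name!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad coordinates for {self.name}: {self.start}..{self.end}")
        object.__setattr__(self, "strand", normalize_strand(self.strand))
        expected = category_of(self.name)
        if self.category != expected:
            raise ValueError(
                f"{self.name} declared {self.category!r}, expected {expected!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """A circular mitogenome: declared length, optional sequence, features.

    Features are kept sorted by start coordinate and never wrap the
    origin; gene names are unique within a genome.
    """

    id: str
    length: int
    circular: bool = True
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: f.start)
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValueError(f"duplicate gene: {f.name}")
            seen.add(f.name)
            if f.end > self.length:
                raise ValueError(
                    f"{f.name} extends past genome length "
                    f"({f.end} > {self.length})")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared {self.length}")

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"unknown gene: {name}")

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def with_sequence(self, sequence: str) -> "AnnotatedGenome":
        return AnnotatedGenome(self.id, self.length, self.circular,
                               sequence, list(self.features))


def gene_sequence(genome: AnnotatedGenome, name: str) -> str:
    """Coding-sense nucleotide sequence of one gene.

    J-strand genes are a direct slice of the genome sequence; N-strand
    genes are returned reverse-complemented so PCGs always read 5'→3'
    in mRNA sense.
    """
    if genome.sequence is None:
        raise ValueError("sequence required")
    f = genome.feature(name)
    sub = genome.sequence[f.start - 1:f.end]
    return reverse_complement(sub) if f.strand == "N" else sub
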