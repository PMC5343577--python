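"""tRNA clover-leaf secondary structures.

A clover-leaf is four nested helices — the acceptor (AA) stem
enclosing, left to right, the DHU, anticodon (AC) and TΨC arms —
with a variable loop between the AC and TΨC arms.  Structures are
inputs, given as dot-bracket strings alongside the sequence; the
package ships one synthetic template per tRNA whose arm lengths sit
inside the ranges observed in fly mitogenomes (AA stem 7 bp, AC loop
7 nt, DHU stem 2–4 bp, AC stem 4–5 bp, TΨC stem 3–5 bp, variable
loop 4–8 nt).

A stem pair is a mismatch iff it is not Watson–Crick or G·U wobble.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diversity import Alignment

__all__ = ["CloverLeaf", "parse_cloverleaf", "render_structure",
           "count_mismatches", "stem_variability", "validate_armlengths",
           "TRNA_ANTICODONS", "TRNA_LENGTHS", "cloverleaf_template",
           "all_templates"]

STEM_NAMES = ("AA", "DHU", "AC", "TPsiC")

VALID_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

#: Anticodons (DNA spelling) of the 22 hoverfly mitochondrial tRNAs.
TRNA_ANTICODONS = {
    "trnI": "GAT", "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA",
    "trnC": "GCA", "trnY": "GTA", "trnL2": "TAA", "trnK": "CTT",
    "trnD": "GTC", "trnG": "TCC", "trnA": "TGC", "trnR": "TCG",
    "trnN": "GTT", "trnS1": "GCT", "trnE": "TTC", "trnF": "GAA",
    "trnH": "GTG", "trnT": "TGT", "trnP": "TGG", "trnS2": "TGA",
    "trnL1": "TAG", "trnV": "TAC",
}

#: Template lengths (bp), matching the per-tRNA gene lengths of the
#: complete hoverfly mitogenome annotation (64–72 bp).
TRNA_LENGTHS = {
    "trnI": 66, "trnQ": 69, "trnM": 69, "trnW": 68, "trnC": 67,
    "trnY": 66, "trnL2": 66, "trnK": 71, "trnD": 67, "trnG": 66,
    "trnA": 69, "trnR": 64, "trnN": 67, "trnS1": 67, "trnE": 65,
    "trnF": 67, "trnH": 67, "trnT": 65, "trnP": 66, "trnS2": 68,
    "trnL1": 65, "trnV": 72,
}


def _normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class CloverLeaf:
    seq: str                                   # RNA alphabet, upper case
    stems: dict[str, tuple[tuple[int, int], ...]]  # name -> (pos5, pos3)
    loops: dict[str, range]                    # DHU, AC, variable, TPsiC
    anticodon: str

    @property
    def paired_positions(self) -> tuple[int, ...]:
        pos = []
        for pairs in self.stems.values():
            for i, j in pairs:
                pos.extend((i, j))
        return tuple(sorted(pos))


def _pair_list(structure: str) -> list[tuple[int, int]]:
    if any(c in "[]{}<>" for c in structure):
        raise ValueError("pseudoknot")
    if set(structure) - set(".()"):
        raise ValueError(f"bad structure characters: "
                         f"{sorted(set(structure) - set('.()'))}")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced brackets")
            pairs.append((stack.pop(), pos))
    if stack:
        raise ValueError("unbalanced brackets")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into maximal stacked runs ((i,j),(i+1,j-1),...)."""
    helices: list[list[tuple[int, int]]] = []
    for pair in pairs:
        if helices and pair == (helices[-1][-1][0] + 1,
                                helices[-1][-1][1] - 1):
            helices[-1].append(pair)
        else:
            helices.append([pair])
    return helices


def parse_cloverleaf(seq: str, structure: str) -> CloverLeaf:
    """Build a :class:`CloverLeaf` from sequence + dot-bracket string.

    The outermost helix is the AA stem; the three helices inside it,
    left to right, are the DHU, AC and TΨC arms.  Anything else (3 or
    5 helices, helices outside the acceptor stem) is not a clover-leaf.
    """
    if len(seq) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    helices = _helices(_pair_list(structure))
    if len(helices) != 4:
        raise ValueError(f"not clover-leaf: {len(helices)} helices")
    aa, dhu, ac, tpsic = helices
    inner_i, inner_j = aa[-1]
    for helix in (dhu, ac, tpsic):
        if not (inner_i < helix[0][0] and helix[0][1] < inner_j):
            raise ValueError("not clover-leaf: helix outside acceptor stem")

    def loop_of(helix):
        i, j = helix[-1]
        return range(i + 1, j)

    ac_loop = loop_of(ac)
    if len(ac_loop) < 5:
        raise ValueError("anticodon loop shorter than 5 nt")
    variable = range(ac[0][1] + 1, tpsic[0][0])
    rna = _normalize_rna(seq)
    anticodon = "".join(rna[p - 1] for p in list(ac_loop)[2:5])
    return CloverLeaf(
        seq=rna,
        stems={"AA": tuple(aa), "DHU": tuple(dhu), "AC": tuple(ac),
               "TPsiC": tuple(tpsic)},
        loops={"DHU": loop_of(dhu), "AC": ac_loop,
               "variable": variable, "TPsiC": loop_of(tpsic)},
        anticodon=anticodon,
    )


def render_structure(cl: CloverLeaf) -> str:
    """Dot-bracket string of a clover-leaf (inverse of parsing)."""
    chars = ["."] * len(cl.seq)
    for pairs in cl.stems.values():
        for i, j in pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
    return "".join(chars)


def count_mismatches(cl: CloverLeaf) -> list[tuple[str, int, int, str]]:
    """All non-canonical stem pairs (G·U wobble counts as canonical)."""
    out = []
    for stem in STEM_NAMES:
        for i, j in cl.stems[stem]:
            duo = cl.seq[i - 1] + cl.seq[j - 1]
            if duo not in VALID_PAIRS:
                out.append((stem, i, j, f"{duo[0]}-{duo[1]}"))
    return out


def validate_armlengths(cl: CloverLeaf) -> None:
    """Enforce the observed fly-mitogenome clover-leaf geometry."""
    checks = [
        ("AA stem", len(cl.stems["AA"]), 7, 7),
        ("AC loop", len(cl.loops["AC"]), 7, 7),
        ("DHU stem", len(cl.stems["DHU"]), 2, 4),
        ("AC stem", len(cl.stems["AC"]), 4, 5),
        ("TPsiC stem", len(cl.stems["TPsiC"]), 3, 5),
        ("variable loop", len(cl.loops["variable"]), 4, 8),
    ]
    for what, got, lo, hi in checks:
        if not lo <= got <= hi:
            raise ValueError(f"{what} length {got} outside [{lo}, {hi}]")


def stem_variability(homologs: Alignment, reference: CloverLeaf) -> int:
    """Number of variable stem columns across a tRNA homolog panel.

    The reference structure is on the first (ungapped) row; an
    alignment column mapped from a reference stem position is variable
    when more than one distinct non-gap nucleotide occurs in it.
    """
    first = _normalize_rna(homologs.rows[0])
    if "-" in first:
        raise ValueError("reference must be ungapped")
    if first != reference.seq:
        raise ValueError("first alignment row differs from reference")
    variable = 0
    for col in reference.paired_positions:
        seen = {_normalize_rna(row)[col - 1] for row in homologs.rows}
        seen.discard("-")
        if len(seen) > 1:
            variable += 1
    return variable


# ------------------------------------------------------------ templates

_LOOP_FILL = "UAAUUAAUAUAAUU"  # AT-rich filler for loop regions
_STEM_FILL = "GCUGGAUAGCUGGAUAG"  # 5' stem bases; 3' side complements


def _complement_rna(seq: str) -> str:
    return seq.translate(str.maketrans("AUGC", "UACG"))[::-1]


def _arm_plan(length: int) -> dict[str, int]:
    """Arm lengths for a template of the given total length.

    Fixed core (AA 7, links 2+1, AC stem 5, AC loop 7, TΨC stem 4 +
    loop 7, DHU stem 3, discriminator 1) leaves the DHU and variable
    loops to absorb the length difference, within their legal ranges.
    """
    plan = {"d": 3, "a": 5, "t": 4, "v": 4, "tl": 7}
    dl = length - 60
    while dl > 9:
        dl -= 1
        plan["v"] += 1
        if plan["v"] > 8:
            raise ValueError(f"length {length} outside template range")
    if dl < 3:
        raise ValueError(f"length {length} outside template range")
    plan["dl"] = dl
    return plan


def cloverleaf_template(name: str, length: int | None = None) -> tuple[str, str]:
    """(sequence, dot-bracket) template for one tRNA gene.

    Stems are fully Watson–Crick paired; the anticodon sits at
    positions 3–5 of the 7-nt AC loop.  Deterministic: the same name
    and length always yield the same template.
    """
    anticodon = _normalize_rna(TRNA_ANTICODONS[name])
    p = _arm_plan(TRNA_LENGTHS[name] if length is None else length)
    d, dl, a, v, t, tl = p["d"], p["dl"], p["a"], p["v"], p["t"], p["tl"]

    aa5 = _STEM_FILL[:7]
    d5 = _STEM_FILL[7:7 + d]
    ac5 = _STEM_FILL[:a]
    t5 = _STEM_FILL[5:5 + t]
    ac_loop = "CU" + anticodon + "AA"

    seq = (aa5 + "UA" + d5 + _LOOP_FILL[:dl] + _complement_rna(d5) + "A"
           + ac5 + ac_loop + _complement_rna(ac5) + _LOOP_FILL[:v]
           + t5 + _LOOP_FILL[:tl] + _complement_rna(t5)
           + _complement_rna(aa5) + "A")
    structure = ("(" * 7 + ".." + "(" * d + "." * dl + ")" * d + "."
                 + "(" * a + "." * 7 + ")" * a + "." * v
                 + "(" * t + "." * tl + ")" * t + ")" * 7 + ".")
    assert len(seq) == len(structure)
    return seq, structure


def all_templates() -> dict[str, CloverLeaf]:
    """Parsed clover-leaf templates for all 22 tRNAs."""
    return {name: parse_cloverleaf(*cloverleaf_template(name))
            for name in TRNA_ANTICODONS}
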