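"""Base composition, A+T content and strand-asymmetry skews.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed on
counts or on already-tabulated percentages.  Both lie in [−1, 1] and
flip sign under reverse complementation.  Ambiguous IUPAC bases are
excluded from every denominator and tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import AnnotatedGenome, gene_sequence

__all__ = ["CompositionProfile", "composition", "skew_from_percentages",
           "region_composition"]


@dataclass(frozen=True)
class CompositionProfile:
    counts: dict[str, int]          # A,C,G,T plus "other"
    fractions: dict[str, float]     # over unambiguous bases only
    at_content: float               # percent
    length_used: int                # unambiguous bases
    _at_skew: float | None
    _gc_skew: float | None

    @property
    def at_skew(self) -> float:
        if self._at_skew is None:
            raise ValueError("empty AT pool")
        return self._at_skew

    @property
    def gc_skew(self) -> float:
        if self._gc_skew is None:
            raise ValueError("empty GC pool")
        return self._gc_skew


def composition(seq: str) -> CompositionProfile:
    """Base counts, fractions, A+T% and skews of one sequence.

    A skew whose base pool is empty (e.g. GC-skew of an all-A/T
    sequence) raises when accessed, not when the profile is built.
    """
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in "ACGT"}
    length = sum(counts.values())
    counts["other"] = len(s) - length
    if length == 0:
        raise ValueError("no unambiguous bases")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    return CompositionProfile(
        counts=counts,
        fractions={b: counts[b] / length for b in "ACGT"},
        at_content=100.0 * (a + t) / length,
        length_used=length,
        _at_skew=(a - t) / (a + t) if a + t else None,
        _gc_skew=(g - c) / (g + c) if g + c else None,
    )


def skew_from_percentages(a_pct: float, t_pct: float,
                          g_pct: float, c_pct: float) -> tuple[float, float]:
    """(AT-skew, GC-skew) from tabulated percentages, rounded to 4 dp."""
    if min(a_pct, t_pct, g_pct, c_pct) < 0:
        raise ValueError("negative percentage")
    if a_pct + t_pct == 0:
        raise ValueError("empty AT pool")
    if g_pct + c_pct == 0:
        raise ValueError("empty GC pool")
    at = (a_pct - t_pct) / (a_pct + t_pct)
    gc = (g_pct - c_pct) / (g_pct + c_pct)
    return round(at, 4), round(gc, 4)


def region_composition(genome: AnnotatedGenome,
                       selector) -> CompositionProfile:
    """Composition of a category ("PCG", "tRNA", "rRNA", "control",
    "all") or an explicit list of gene tokens.

    Selected genes are concatenated in genomic order, each in coding
    sense (N-strand genes reverse-complemented), so PCG composition is
    mRNA-sense — the convention under which fly PCG sets show their
    characteristic negative GC-skew.
    """
    if genome.sequence is None:
        raise ValueError("sequence required")
    if isinstance(selector, str):
        if selector == "all":
            names = [f.name for f in genome.features]
        else:
            names = [f.name for f in genome.features
                     if f.category == selector]
    else:
        names = list(selector)
    if not names:
        raise ValueError(f"empty selection: {selector!r}")
    concat = "".join(gene_sequence(genome, n) for n in names)
    return composition(concat)
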