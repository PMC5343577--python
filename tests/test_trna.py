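"""Clover-leaf parsing, mismatch detection and stem variability."""

import pytest

from mitocomp.diversity import Alignment
from mitocomp.trna import (TRNA_ANTICODONS, TRNA_LENGTHS, all_templates,
                           cloverleaf_template, count_mismatches,
                           parse_cloverleaf, render_structure,
                           stem_variability, validate_armlengths)


@pytest.fixture(scope="module")
def templates():
    return all_templates()


def test_all_templates_parse_and_validate(templates):
    assert len(templates) == 22
    for name, cl in templates.items():
        validate_armlengths(cl)
        assert len(cl.stems["AA"]) == 7
        assert len(cl.loops["AC"]) == 7
        assert 2 <= len(cl.stems["DHU"]) <= 4
        assert 4 <= len(cl.stems["AC"]) <= 5
        assert 3 <= len(cl.stems["TPsiC"]) <= 5
        assert 4 <= len(cl.loops["variable"]) <= 8
        assert cl.anticodon == TRNA_ANTICODONS[name].replace("T", "U")
        assert len(cl.seq) == TRNA_LENGTHS[name]
        assert count_mismatches(cl) == []


def test_render_round_trip(templates):
    for name, cl in templates.items():
        seq, structure = cloverleaf_template(name)
        assert render_structure(cl) == structure
        assert parse_cloverleaf(seq, structure) == cl


def test_non_cloverleaf_rejected():
    seq, structure = cloverleaf_template("trnM")
    # blank out the TPsiC helix -> only 3 helices remain
    cl = parse_cloverleaf(seq, structure)
    chars = list(structure)
    for i, j in cl.stems["TPsiC"]:
        chars[i - 1] = chars[j - 1] = "."
    with pytest.raises(ValueError, match="not clover-leaf"):
        parse_cloverleaf(seq, "".join(chars))
    with pytest.raises(ValueError, match="pseudoknot"):
        parse_cloverleaf(seq, structure.replace("(", "[", 1))
    with pytest.raises(ValueError):
        parse_cloverleaf(seq, structure[:-1] + "(")


def test_armlength_validation_rejects_six_pair_acceptor():
    seq, structure = cloverleaf_template("trnM")
    # break the outermost acceptor pair: 6-pair AA stem
    broken = "." + structure[1:-2] + ".."
    assert broken.count("(") == structure.count("(") - 1
    cl = parse_cloverleaf(seq, broken)
    with pytest.raises(ValueError, match="AA stem"):
        validate_armlengths(cl)


def test_mismatch_detection_and_wobble(templates):
    cl = templates["trnI"]
    i, j = cl.stems["AA"][0]
    seq = list(cl.seq)
    seq[i - 1] = seq[j - 1] = "U"  # force a U-U pair
    mm = count_mismatches(parse_cloverleaf(
        "".join(seq), render_structure(cl)))
    assert mm == [("AA", i, j, "U-U")]
    seq[i - 1] = seq[j - 1] = "A"  # A-A pair
    mm = count_mismatches(parse_cloverleaf(
        "".join(seq), render_structure(cl)))
    assert mm == [("AA", i, j, "A-A")]
    # G·U wobble is not a mismatch
    seq[i - 1], seq[j - 1] = "G", "U"
    assert count_mismatches(parse_cloverleaf(
        "".join(seq), render_structure(cl))) == []


def test_mismatch_count_alphabet_invariant(templates):
    cl = templates["trnW"]
    i, j = cl.stems["TPsiC"][1]
    rna = list(cl.seq)
    rna[i - 1] = rna[j - 1] = "U"
    dna = "".join(rna).replace("U", "T")
    structure = render_structure(cl)
    assert len(count_mismatches(parse_cloverleaf(dna, structure))) == \
        len(count_mismatches(parse_cloverleaf("".join(rna), structure))) == 1


def test_stem_variability_counts_mutated_columns(templates):
    cl = templates["trnC"]
    ref = cl.seq
    stem_cols = list(cl.paired_positions)
    loop_cols = [p for p in range(1, len(ref) + 1) if p not in stem_cols]

    def mutate(row, col):
        other = {"A": "G", "G": "A", "C": "U", "U": "C"}
        return row[:col - 1] + other[row[col - 1]] + row[col:]

    for k in (0, 1, 3, 5):
        rows = [ref]
        for t in range(14):
            row = ref
            for col in stem_cols[:k]:
                row = mutate(row, col)
            rows.append(row)
        aln = Alignment(gene="trnC", taxa=tuple(f"t{i}" for i in range(15)),
                        rows=tuple(rows))
        assert stem_variability(aln, cl) == k

    # mutations confined to loops never count
    rows = [ref] + [mutate(mutate(ref, loop_cols[0]), loop_cols[3])] * 5
    aln = Alignment(gene="trnC", taxa=tuple(f"t{i}" for i in range(6)),
                    rows=tuple(rows))
    assert stem_variability(aln, cl) == 0


def test_stem_variability_monotone(templates):
    cl = templates["trnH"]
    ref = cl.seq
    cols = list(cl.paired_positions)
    counts = []
    for k in range(0, 8, 2):
        rows = [ref]
        row = ref
        for col in cols[:k]:
            row = row[:col - 1] + ("A" if row[col - 1] != "A" else "G") + \
                row[col:]
        rows.append(row)
        aln = Alignment(gene="trnH", taxa=("r", "m"), rows=tuple(rows))
        counts.append(stem_variability(aln, cl))
    assert counts == sorted(counts)


def test_gapped_reference_rejected(templates):
    cl = templates["trnM"]
    aln = Alignment(gene="trnM", taxa=("a", "b"),
                    rows=("-" + cl.seq[1:], cl.seq))
    with pytest.raises(ValueError, match="ungapped"):
        stem_variability(aln, cl)
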