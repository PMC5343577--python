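#!/usr/bin/env python
"""Optional integration check against real GenBank records.

Given locally downloaded GenBank flat files for the two hoverfly
accessions (KU351241, KU379658) — e.g. fetched with NCBI's efetch or
Entrez — this recomputes per-region base composition and skews from
the actual sequences and compares them with the bundled printed
composition table to 2 decimals.  It is not run in CI: it needs files
this repository deliberately does not ship.

Usage:  python scripts/real_data_check.py KU351241.gb [KU379658.gb ...]
"""

from __future__ import annotations

import argparse
import sys

import mitocomp as mc
from mitocomp.fixtures import muscomorpha_composition


def check(path: str) -> bool:
    genome = mc.read_genbank(path)
    if genome.sequence is None:
        print(f"{path}: no ORIGIN sequence block; cannot check composition")
        return False
    table = muscomorpha_composition().set_index("accession")
    acc = genome.id.split(".")[0]
    if acc not in table.index:
        print(f"{path}: accession {acc} not in the bundled table")
        return False
    row = table.loc[acc]
    ok = True

    prof = mc.region_composition(genome, "PCG")
    f = prof.fractions
    for label, got, want in [
        ("PCG T%", 100 * f["T"], row.pcg_t),
        ("PCG C%", 100 * f["C"], row.pcg_c),
        ("PCG A%", 100 * f["A"], row.pcg_a),
        ("PCG G%", 100 * f["G"], row.pcg_g),
        ("PCG A+T%", prof.at_content, row.pcg_at),
        ("rrnL A+T%", mc.region_composition(genome, ["rrnL"]).at_content,
         row.rrnl_at),
        ("rrnS A+T%", mc.region_composition(genome, ["rrnS"]).at_content,
         row.rrns_at),
    ]:
        agree = abs(got - want) < 0.005 + 1e-12
        ok &= agree
        print(f"{acc} {label}: computed {got:.2f}, printed {want:.2f} "
              f"{'OK' if agree else 'MISMATCH'}")
    at, gc = mc.skew_from_percentages(100 * f["A"], 100 * f["T"],
                                      100 * f["G"], 100 * f["C"])
    print(f"{acc} AT-skew {at:+.4f}  GC-skew {gc:+.4f} "
          f"(printed {row.pcg_at_skew:+.4f} / {row.pcg_gc_skew:+.4f})")
    return ok


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("genbank_files", nargs="+")
    args = ap.parse_args()
    sys.exit(0 if all(check(p) for p in args.genbank_files) else 1)


if __name__ == "__main__":
    main()
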