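"""Readers and writers for annotated-genome interchange formats.

Three formats are supported:

* a plain feature-table TSV mirroring published annotation tables
  (pragma header lines ``#id=``, ``#length=``, ``#circular=``, then
  columns ``gene  start  end  strand  category`` with optional
  ``anticodon``, ``start_codon``, ``stop_codon`` and any extra columns
  ignored);
* GenBank flat files (read and write, through Biopython), with GenBank
  gene/product spellings mapped onto the canonical 37-token vocabulary
  via a bundled, editable synonym table;
* FASTA (70-column wrap, read and write).

All writers are byte-deterministic given the same genome.
"""

from __future__ import annotations

import csv
import logging
import warnings
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import (AnnotatedGenome, GENE_VOCABULARY, GeneFeature,
                    category_of, normalize_strand)

logger = logging.getLogger(__name__)

__all__ = [
    "read_feature_table", "write_feature_table",
    "read_genbank", "write_genbank",
    "read_fasta", "write_fasta",
    "load_synonym_table", "canonical_gene_name",
]


# ---------------------------------------------------------------- TSV

def read_feature_table(path) -> AnnotatedGenome:
    """Parse a feature-table TSV into an :class:`AnnotatedGenome`."""
    meta: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            rows.append(dict(zip(header, cells)))
    if header is None:
        raise ValueError(f"{path}: no header line")
    required = {"gene", "start", "end", "strand", "category"}
    if not required <= set(header):
        raise ValueError(f"{path}: missing columns {required - set(header)}")
    for key in ("id", "length"):
        if key not in meta:
            raise ValueError(f"{path}: missing #{key}= pragma")

    features = []
    for row in rows:
        name = row["gene"].strip()
        if name not in GENE_VOCABULARY:
            raise ValueError(f"unknown gene token: {name!r}")
        start, end = int(row["start"]), int(row["end"])
        if start > end:
            raise ValueError(f"bad coordinates for {name}: {start}..{end}")
        features.append(GeneFeature(
            name=name, start=start, end=end,
            strand=normalize_strand(row["strand"].strip()),
            category=row["category"].strip(),
            anticodon=row.get("anticodon", "").strip() or None,
            start_codon=row.get("start_codon", "").strip() or None,
            stop_codon=row.get("stop_codon", "").strip() or None,
        ))
    seen = [f.name for f in features]
    if len(seen) != len(set(seen)):
        raise ValueError("duplicate gene")
    return AnnotatedGenome(
        id=meta["id"], length=int(meta["length"]),
        circular=meta.get("circular", "true").lower() in ("true", "1", "yes"),
        features=features,
    )


def write_feature_table(genome: AnnotatedGenome, path) -> None:
    cols = ["gene", "start", "end", "strand", "category",
            "anticodon", "start_codon", "stop_codon"]
    with open(path, "w", newline="") as fh:
        fh.write(f"#id={genome.id}\n#length={genome.length}\n"
                 f"#circular={'true' if genome.circular else 'false'}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for f in genome.features:
            writer.writerow([f.name, f.start, f.end, f.strand, f.category,
                             f.anticodon or "", f.start_codon or "",
                             f.stop_codon or ""])


def read_feature_table_frame(path):
    """Raw feature-table rows as a pandas DataFrame (all columns kept).

    Used for cross-checking auxiliary columns (length, intergenic) that
    the :class:`AnnotatedGenome` model recomputes from coordinates.
    """
    import pandas as pd
    return pd.read_csv(path, sep="\t", comment="#")


# ------------------------------------------------------------- GenBank

def load_synonym_table() -> dict[str, str]:
    """Bundled GenBank-label → canonical-token mapping (lower-cased keys)."""
    table: dict[str, str] = {}
    text = resources.files("mitocomp.data").joinpath(
        "gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[alias.strip().lower()] = canonical.strip()
    for token in GENE_VOCABULARY:  # identity spellings always work
        table.setdefault(token.lower(), token)
    return table


_SYNONYMS: dict[str, str] | None = None


def canonical_gene_name(label: str) -> str | None:
    """Map a GenBank gene/product label to a canonical token, or None."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = load_synonym_table()
    return _SYNONYMS.get(label.strip().lower())


def read_genbank(path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Features whose labels cannot be mapped onto the canonical
    vocabulary are skipped with a warning.  A missing ORIGIN block
    yields a genome without sequence.
    """
    record = SeqIO.read(path, "genbank")
    try:
        sequence = str(record.seq).upper() or None
    except Bio_UndefinedSequenceError:
        sequence = None

    features: dict[str, GeneFeature] = {}
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "gene",
                             "misc_feature", "D-loop"):
            continue
        labels = (feat.qualifiers.get("gene", []) +
                  feat.qualifiers.get("product", []) +
                  feat.qualifiers.get("note", []))
        if feat.type in ("misc_feature", "D-loop"):
            labels = labels or [feat.type]
        name = next((n for n in map(canonical_gene_name, labels) if n), None)
        if name is None:
            warnings.warn(f"unmappable feature skipped: {feat.type} "
                          f"{labels}", stacklevel=2)
            logger.warning("skipped feature %s %s", feat.type, labels)
            continue
        start = int(feat.location.start) + 1  # Biopython is 0-based
        end = int(feat.location.end)
        strand = "N" if feat.location.strand == -1 else "J"
        gf = GeneFeature(name=name, start=start, end=end, strand=strand,
                         category=category_of(name))
        # gene + CDS/tRNA pairs describe the same feature once
        features.setdefault(name, gf)

    length = len(record.seq) if record.seq is not None else \
        int(record.annotations.get("length", 0))
    return AnnotatedGenome(
        id=record.id or record.name, length=length,
        circular=record.annotations.get("topology", "circular") == "circular",
        sequence=sequence, features=list(features.values()),
    )


try:  # Biopython raises this when ORIGIN is absent
    from Bio.Seq import UndefinedSequenceError as Bio_UndefinedSequenceError
except ImportError:  # pragma: no cover
    Bio_UndefinedSequenceError = Exception


_GB_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
            "control": "misc_feature"}
_GB_LABEL = {"nad1": "ND1", "nad2": "ND2", "nad3": "ND3", "nad4": "ND4",
             "nad4l": "ND4L", "nad5": "ND5", "nad6": "ND6",
             "cox1": "COI", "cox2": "COII", "cox3": "COIII",
             "atp6": "ATPase6", "atp8": "ATPase8", "cob": "CytB",
             "rrnL": "l-rRNA", "rrnS": "s-rRNA",
             "trnI": "tRNA-Ile", "trnQ": "tRNA-Gln", "trnM": "tRNA-Met",
             "trnW": "tRNA-Trp", "trnC": "tRNA-Cys", "trnY": "tRNA-Tyr",
             "trnL2": "tRNA-Leu(UUR)", "trnL1": "tRNA-Leu(CUN)",
             "trnK": "tRNA-Lys", "trnD": "tRNA-Asp", "trnG": "tRNA-Gly",
             "trnA": "tRNA-Ala", "trnR": "tRNA-Arg", "trnN": "tRNA-Asn",
             "trnS1": "tRNA-Ser(AGN)", "trnS2": "tRNA-Ser(UCN)",
             "trnE": "tRNA-Glu", "trnF": "tRNA-Phe", "trnH": "tRNA-His",
             "trnT": "tRNA-Thr", "trnP": "tRNA-Pro", "trnV": "tRNA-Val",
             "CONTROL": "A+T-rich region"}


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Emit a GenBank flat file; requires a sequence."""
    if genome.sequence is None:
        raise ValueError("sequence required")
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id,
                       description="synthetic mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = \
        "circular" if genome.circular else "linear"
    for f in genome.features:
        loc = FeatureLocation(f.start - 1, f.end,
                              strand=-1 if f.strand == "N" else 1)
        qualifiers = {"gene": [_GB_LABEL[f.name]]}
        record.features.append(
            SeqFeature(loc, type=_GB_TYPE[f.category], qualifiers=qualifiers))
    SeqIO.write(record, path, "genbank")


# --------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
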