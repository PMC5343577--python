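"""Bundled fixture data: the two hoverfly annotation tables and the
Muscomorpha composition table, transcribed from the published
annotations (accessions KU351241 and KU379658).

Only coordinates, strands and codons are bundled — not sequences,
which would have to be fetched from GenBank.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_feature_table
from .model import AnnotatedGenome

__all__ = ["episyrphus_genome", "eupeodes_genome",
           "episyrphus_table", "eupeodes_table",
           "muscomorpha_composition"]

_FILES = {
    "episyrphus": "episyrphus_KU351241.tsv",
    "eupeodes": "eupeodes_KU379658.tsv",
}


def _fixture_path(key: str):
    return resources.files("mitocomp.data").joinpath(_FILES[key])


def episyrphus_genome() -> AnnotatedGenome:
    """The complete 16,175 bp *Episyrphus balteatus* annotation."""
    with resources.as_file(_fixture_path("episyrphus")) as p:
        return read_feature_table(p)


def eupeodes_genome() -> AnnotatedGenome:
    """The partial 15,326 bp *Eupeodes corollae* annotation."""
    with resources.as_file(_fixture_path("eupeodes")) as p:
        return read_feature_table(p)


def _table(key: str) -> pd.DataFrame:
    with resources.as_file(_fixture_path(key)) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def episyrphus_table() -> pd.DataFrame:
    """Raw fixture rows incl. the published length/intergenic columns."""
    return _table("episyrphus")


def eupeodes_table() -> pd.DataFrame:
    return _table("eupeodes")


def muscomorpha_composition() -> pd.DataFrame:
    """Printed PCG/rRNA composition statistics for 15 Muscomorpha species."""
    with resources.as_file(resources.files("mitocomp.data").joinpath(
            "muscomorpha_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t")
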