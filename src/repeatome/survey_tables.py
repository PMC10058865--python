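"""Published repeat-survey reference values for five Asteraceae genomes.

Three small tables from a published genome-skimming survey of *Helianthus
annuus*, *Lactuca sativa*, *Cynara cardunculus*, *Artemisia annua* and
*Chrysanthemum seticuspe* are bundled as TSV: per-species read-clustering
counts, LTR retrotransposon genome proportions by lineage, and full-length
element counts by lineage.  They serve as worked inputs for the comparative
arithmetic in :mod:`repeatome.summary` and :mod:`repeatome.annotate`
(ratios, maximum differences, superfamily totals) — the derived columns are
always recomputed from the primary cells, never read off.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SPECIES = (
    "Helianthus annuus",
    "Lactuca sativa",
    "Cynara cardunculus",
    "Artemisia annua",
    "Chrysanthemum seticuspe",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("repeatome.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_read_clustering() -> pd.DataFrame:
    """Per-species total and clustered read counts (with published %)."""
    return _read("read_clustering.tsv").set_index("species")


def load_ltr_proportions() -> pd.DataFrame:
    """Genome proportion (%) of LTR-RE lineages per species.

    Rows include the published per-superfamily "Total" rows and the published
    "max_difference" column so that recomputation can be checked against them.
    """
    return _read("ltr_proportions.tsv")


def load_element_counts() -> pd.DataFrame:
    """Full-length element counts per lineage and species (lineage rows only).

    Superfamily totals and the grand total are not stored; they are recomputed
    by :func:`repeatome.annotate.summarize_counts`.  Cells published as "-"
    are stored as 0.
    """
    return _read("element_counts.tsv")
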