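"""The curated in-study fixture: the 16-gene odor network, the published
chemotaxis table, and the pathway-position categories.

See ``odornet/data/README.md`` for the provenance of the curated edge list.
"""
from __future__ import annotations

from importlib.resources import files

import networkx as nx
import pandas as pd

from .contribution import ChemotaxisRecord

ODOR_GENES = (
    "gpa-3", "odr-3", "gpa-5", "gpa-13", "arr-1", "rgs-3",
    "egl-4", "tax-6", "odr-1", "daf-11", "tax-2", "tax-4",
    "goa-1", "egl-30", "dgk-1", "eat-4",
)

GENE_ALIASES = {"pkg-1": "egl-4"}

_DATA = files("odornet") / "data"


def _data_path(name: str):
    return _DATA / name


def load_odor_network() -> nx.Graph:
    from .io import read_edge_list
    return read_edge_list(str(_data_path("odor_network.sif")))


def load_chemotaxis_table() -> pd.DataFrame:
    from .io import read_chemotaxis_table
    return read_chemotaxis_table(str(_data_path("chemotaxis.tsv")))


def load_pathway_categories() -> dict[str, str]:
    df = pd.read_csv(str(_data_path("pathway_categories.tsv")), sep="\t")
    return dict(zip(df["gene"], df["category"]))


def chemotaxis_records(df: pd.DataFrame | None = None) -> list[ChemotaxisRecord]:
    """The chemotaxis table as typed records (wildtype reference rows
    included, gene id 'wildtype')."""
    if df is None:
        df = load_chemotaxis_table()
    records = []
    for row in df.itertuples(index=False):
        records.append(ChemotaxisRecord(
            gene=row.gene, neuron=row.neuron, assay=row.assay,
            ci_wt=None if pd.isna(row.ci_wt) else float(row.ci_wt),
            ci_mut=None if pd.isna(row.ci_mut) else float(row.ci_mut),
            ci_diff=None if pd.isna(row.ci_diff) else float(row.ci_diff),
            n_odors=None if pd.isna(row.n_odors) else int(row.n_odors)))
    return records


def wildtype_references(records: list[ChemotaxisRecord] | None = None,
                        assay: str = "odortaxis") -> dict[str, float]:
    """Per-neuron wildtype chemotaxis indices (gene id 'wildtype')."""
    if records is None:
        records = chemotaxis_records()
    return {r.neuron: r.ci_wt for r in records
            if r.gene == "wildtype" and r.assay == assay and r.ci_wt is not None}


def make_odor_fixture() -> tuple[nx.Graph, list[ChemotaxisRecord], dict[str, str]]:
    """The full curated fixture: (16-gene network, chemotaxis records,
    pathway-position category map)."""
    return load_odor_network(), chemotaxis_records(), load_pathway_categories()
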