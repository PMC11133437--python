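"""Bundled study inputs and a random molecular-like graph generator.

The package ships the hydrogen-suppressed skeletons of the eleven
sulfonamide-study drugs as edge-list files, together with the published
descriptor (drug x 7 indices) and property (drug x 6 physico-chemical
values) tables. Each drug fixture carries a ``verified`` flag: True iff
recomputing the indices from the bundled skeleton reproduces the published
descriptor row (exactly for the integer-valued indices, to the printed
decimals otherwise). Four rows could not be reproduced from the canonical
skeletons; those fixtures ship as-is with ``verified=False`` and the
discrepancy documented in the edge-list file — never silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .indices import INDEX_NAMES, IndexVector, compute_all
from .molgraph import MolecularGraph, from_edge_list

__all__ = [
    "DRUG_NAMES",
    "VERIFIED_DRUGS",
    "DrugFixture",
    "drug_graph",
    "paper_tables",
    "random_molecular_graph",
]

#: The eleven drugs, in published descriptor-table order.
DRUG_NAMES: tuple[str, ...] = (
    "Sulfadiazine",
    "Dorzolamide",
    "Meloxicam",
    "Sulphadoxine",
    "Meticrane",
    "Famotidine",
    "Dabrafenib",
    "Diuril",
    "Daranide",
    "Metahydrin",
    "Sulfapyridine",
)

#: Drugs whose bundled skeleton reproduces its full published index row.
VERIFIED_DRUGS: frozenset[str] = frozenset(
    {
        "Sulfadiazine",
        "Sulfapyridine",
        "Dorzolamide",
        "Meticrane",
        "Famotidine",
        "Dabrafenib",
        "Daranide",
    }
)


@dataclass(frozen=True)
class DrugFixture:
    """One drug: its skeleton, its published index row, and whether the
    former reproduces the latter."""

    name: str
    graph: MolecularGraph
    printed_indices: IndexVector
    verified: bool


def _data_text(filename: str) -> str:
    return (resources.files("topoqspr") / "data" / filename).read_text(encoding="utf-8")


def drug_graph(name: str) -> DrugFixture:
    """Load one of the eleven bundled drug fixtures by published name."""
    if name not in DRUG_NAMES:
        raise KeyError(
            f"unknown drug {name!r}; expected one of {', '.join(DRUG_NAMES)}"
        )
    g = from_edge_list(_data_text(name.lower() + ".edgelist"), name=name)
    desc, _ = paper_tables()
    printed = IndexVector(*(float(v) for v in desc.loc[name, list(INDEX_NAMES)]))
    return DrugFixture(
        name=name, graph=g, printed_indices=printed, verified=name in VERIFIED_DRUGS
    )


def paper_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The published descriptor and property tables, verbatim.

    Returns
    -------
    (descriptors, properties)
        DataFrames indexed by drug name: 11 x 7 index values and
        11 x 6 physico-chemical properties (polarizability cm^3,
        complexity, boiling point degC at 760 mmHg, molecular weight g/mol,
        molar volume cm^3, flash point degC).
    """
    import io

    desc = pd.read_csv(io.StringIO(_data_text("table2.csv")), index_col="drug")
    props = pd.read_csv(io.StringIO(_data_text("table3.csv")), index_col="drug")
    return desc, props


def random_molecular_graph(
    seed: int, n_vertices: int, max_degree: int = 4
) -> MolecularGraph:
    """Random connected simple graph with bounded degree, reproducible.

    Emulates the shape of hydrogen-suppressed organic skeletons: a random
    spanning tree grown vertex-by-vertex (guaranteeing connectivity, as a
    molecule is), then extra edges rejection-sampled under the degree cap,
    producing occasional rings. Chemistry it does *not* emulate: valence
    rules per element, realistic ring-size statistics.

    Parameters
    ----------
    seed : RNG seed (numpy default_rng); same seed, same graph.
    n_vertices : at least 2.
    max_degree : degree cap, between 2 and 4 (4 = tetravalent carbon).
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if not 2 <= max_degree <= 4:
        raise ValueError("max_degree must be in [2, 4]")
    rng = np.random.default_rng(seed)
    labels = [f"v{i}" for i in range(n_vertices)]
    deg = dict.fromkeys(labels, 0)
    edges: list[tuple[str, str]] = []
    # random spanning tree: attach each new vertex to a uniformly chosen
    # existing vertex that still has spare valence
    for i in range(1, n_vertices):
        open_slots = [v for v in labels[:i] if deg[v] < max_degree]
        if not open_slots:  # cannot happen for max_degree >= 2, kept defensive
            raise ValueError("degree cap too tight for a spanning tree")
        parent = open_slots[rng.integers(len(open_slots))]
        edges.append((parent, labels[i]))
        deg[parent] += 1
        deg[labels[i]] += 1
    # sprinkle ring-closing edges, rejection-sampling against the cap
    existing = {frozenset(e) for e in edges}
    n_extra = int(rng.integers(0, max(1, n_vertices // 4) + 1))
    for _ in range(n_extra * 8):  # bounded number of attempts
        if n_extra == 0:
            break
        u, v = (labels[k] for k in rng.choice(n_vertices, size=2, replace=False))
        e = frozenset((u, v))
        if e in existing or deg[u] >= max_degree or deg[v] >= max_degree:
            continue
        edges.append((u, v))
        existing.add(e)
        deg[u] += 1
        deg[v] += 1
        n_extra -= 1
    return MolecularGraph.from_edges(edges, name=f"random-{seed}")
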