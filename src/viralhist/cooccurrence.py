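"""Histone-type co-occurrence networks and complement Venn counts.

The presence matrix records, per genome, which histone types it encodes.
From it, a directed network is built whose nodes carry type frequencies
(number of genomes containing the type) and whose edge A→B carries the
conditional proportion P(B present | A present); a symmetric Jaccard
variant is available.  Venn counts partition genomes by their core-family
complement subset.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd

from .domains import Architecture, GenomeComplement
from .io import CORE_FAMILIES


def build_presence_matrix(architectures: Iterable[Architecture]) -> pd.DataFrame:
    """Boolean genome × type presence matrix.

    A cell is true iff the genome encodes at least one protein of that
    type; duplicates within a genome collapse to a single cell.
    """
    pairs = {(a.genome_id, a.type_label) for a in architectures}
    genomes = sorted({g for g, _ in pairs})
    types = sorted({t for _, t in pairs})
    mat = pd.DataFrame(False, index=genomes, columns=types, dtype=bool)
    for g, t in pairs:
        mat.loc[g, t] = True
    mat.index.name = "genome_id"
    mat.columns.name = "type_label"
    return mat


def build_network(matrix: pd.DataFrame,
                  metric: Literal["conditional", "jaccard"] = "conditional",
                  drop_zero: bool = True) -> nx.DiGraph:
    """Directed co-occurrence network from a presence matrix.

    Node attribute ``frequency`` is the number of genomes containing the
    type.  Edge A→B carries ``proportion`` = |A∧B| / |A| (conditional,
    default) or the symmetric Jaccard |A∧B| / |A∨B|, plus the raw counts
    ``n_joint`` and ``n_source``.  Zero-frequency types keep their node
    but emit no edges; zero-proportion edges are omitted unless
    ``drop_zero`` is false.
    """
    if matrix.empty:
        raise ValueError("empty presence matrix")
    g = nx.DiGraph()
    counts = matrix.sum(axis=0).astype(int)
    for t in matrix.columns:
        g.add_node(t, frequency=int(counts[t]))
    for a in matrix.columns:
        n_a = int(counts[a])
        if n_a == 0:
            continue
        for b in matrix.columns:
            if a == b:
                continue
            joint = int((matrix[a] & matrix[b]).sum())
            if metric == "conditional":
                prop = joint / n_a
            elif metric == "jaccard":
                union = int((matrix[a] | matrix[b]).sum())
                prop = joint / union if union else 0.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            if joint == 0 and drop_zero:
                continue
            g.add_edge(a, b, proportion=prop, n_joint=joint, n_source=n_a)
    return g


def venn_counts(complements: Iterable[GenomeComplement]
                ) -> dict[frozenset[str], int]:
    """Partition genomes by their exact core-family subset.

    Every genome lands in exactly one of the 16 subsets of
    {H2A, H2B, H3, H4} (histone-free genomes under the empty set); all 16
    keys are present so the counts always sum to the number of genomes.
    """
    subsets: list[frozenset[str]] = [frozenset()]
    for fam in sorted(CORE_FAMILIES):
        subsets += [s | {fam} for s in subsets]
    counts = {s: 0 for s in subsets}
    for c in complements:
        counts[frozenset(c.families_present)] += 1
    return counts


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _subset_key(s: frozenset[str]) -> str:
    return "+".join(sorted(s)) if s else "none"


def write_venn_json(counts: dict[frozenset[str], int], path: str | Path) -> None:
    ordered = dict(sorted(((_subset_key(k), v) for k, v in counts.items()),
                          key=lambda kv: (kv[0].count("+"), kv[0])))
    Path(path).write_text(json.dumps(ordered, indent=2) + "\n")


def network_edge_table(g: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"source": a, "target": b, "proportion": d["proportion"],
         "n_joint": d["n_joint"], "n_source": d["n_source"]}
        for a, b, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "proportion",
                                       "n_joint", "n_source"])


def write_network(g: nx.DiGraph, edges_tsv: str | Path,
                  graphml: str | Path | None = None) -> None:
    network_edge_table(g).to_csv(edges_tsv, sep="\t", index=False)
    if graphml is not None:
        nx.write_graphml(g, str(graphml))
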