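"""Assemble the regulatory network from curated edges and DE results.

Curated interactions are projected onto the differential-expression calls
(active-node mapping): mti edges survive only when the miRNA is a
high-confidence DEmiR and the gene is DE in the *opposite* direction
(miRNAs repress their targets); tf_mirna edges survive when the miRNA is a
DEmiR, with the TF retained regardless of its own DE status.  Nodes not
touching a surviving edge are removed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .de_calling import DECall, HighConfidenceDEmiR, DOWN, NONE, UP
from .exceptions import MiremapError
from .interaction_db import InteractionRecord

_OPPOSITE = {UP: DOWN, DOWN: UP}


def build_tf_mirna_network(
    records: Iterable[InteractionRecord],
    demirs: Sequence[HighConfidenceDEmiR],
    tf_expression: Mapping[str, str] | None = None,
    mir122_targets: Iterable[str] | None = None,
) -> nx.DiGraph:
    """TF->miRNA subnetwork restricted to DEmiRs.

    TF nodes are annotated with an expression direction when supplied
    (``none`` otherwise -- non-DE TFs stay in the network) and with an
    ``is_mir122_target`` flag.
    """
    tf_expression = tf_expression or {}
    mir122 = set(mir122_targets or ())
    de_by_name = {d.mirna: d for d in demirs}
    g = nx.DiGraph()
    for rec in records:
        if rec.kind != "tf_mirna" or rec.target not in de_by_name:
            continue
        d = de_by_name[rec.target]
        g.add_node(rec.source, type="TF",
                   direction=tf_expression.get(rec.source, NONE),
                   is_mir122_target=rec.source in mir122)
        g.add_node(rec.target, type="miRNA", direction=d.direction,
                   is_mir122_target=False,
                   chrom=d.locus.chrom if d.locus else "")
        g.add_edge(rec.source, rec.target, kind="tf_mirna", sign="activating_or_unknown",
                   evidence=",".join(sorted(rec.evidence)))
    return g


def build_mti_network(
    records: Iterable[InteractionRecord],
    demirs: Sequence[HighConfidenceDEmiR],
    gene_calls: Iterable[DECall],
) -> nx.DiGraph:
    """miRNA->gene subnetwork after the inverse-expression filter.

    An edge is kept iff the miRNA is a DEmiR, the gene is DE, and their
    directions are opposite.  Direction-``none`` genes never enter.
    """
    de_by_name = {d.mirna: d for d in demirs}
    gene_dir = {c.molecule: c.direction for c in gene_calls}
    g = nx.DiGraph()
    for rec in records:
        if rec.kind != "mti" or rec.source not in de_by_name:
            continue
        mdir = de_by_name[rec.source].direction
        gdir = gene_dir.get(rec.target, NONE)
        if gdir != _OPPOSITE[mdir]:
            continue
        d = de_by_name[rec.source]
        g.add_node(rec.source, type="miRNA", direction=mdir,
                   is_mir122_target=False,
                   chrom=d.locus.chrom if d.locus else "")
        g.add_node(rec.target, type="gene", direction=gdir, is_mir122_target=False)
        g.add_edge(rec.source, rec.target, kind="mti", sign="repressive",
                   evidence=",".join(sorted(rec.evidence)))
    return g


def per_mirna_target_counts(
    records: Iterable[InteractionRecord],
    network: nx.DiGraph,
    demirs: Sequence[HighConfidenceDEmiR],
) -> pd.DataFrame:
    """Per-DEmiR curated-target and DE-target counts.

    ``n_curated`` = unique curated targets of the miRNA in the merged MTI
    table; ``n_de_targets`` = its out-degree in the inverse-filtered network.
    The ``n_de_targets`` column sums to the network edge count.
    """
    curated: dict[str, set[str]] = {}
    for rec in records:
        if rec.kind == "mti":
            curated.setdefault(rec.source, set()).add(rec.target)
    rows = []
    for d in demirs:
        rows.append({
            "mirna": d.mirna,
            "direction": d.direction,
            "n_curated": len(curated.get(d.mirna, ())),
            "n_de_targets": network.out_degree(d.mirna) if d.mirna in network else 0,
        })
    return pd.DataFrame(rows, columns=["mirna", "direction", "n_curated", "n_de_targets"])


def compose(*networks: nx.DiGraph) -> nx.DiGraph:
    return nx.compose_all(list(networks)) if networks else nx.DiGraph()


def export_network(network: nx.DiGraph, graphml_path: str | Path,
                   edge_tsv_path: str | Path | None = None) -> None:
    """Write GraphML (typed node attributes) and optionally a flat edge TSV."""
    try:
        nx.write_graphml(network, str(graphml_path))
    except OSError as exc:  # pragma: no cover
        raise MiremapError(f"cannot write network to {graphml_path}: {exc}") from exc
    if edge_tsv_path is not None:
        rows = [
            {"src": u, "dst": v, "kind": d.get("kind", ""), "evidence": d.get("evidence", "")}
            for u, v, d in network.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["src", "dst", "kind", "evidence"]).to_csv(
            edge_tsv_path, sep="\t", index=False
        )


def read_network(graphml_path: str | Path) -> nx.DiGraph:
    g = nx.read_graphml(str(graphml_path))
    return nx.DiGraph(g)


def validate_network(network: nx.DiGraph) -> None:
    """Assert the structural invariants of a built mti network."""
    for node in network.nodes:
        if network.degree(node) == 0:
            raise MiremapError(f"orphan node {node!r} in network")
    for u, v, data in network.edges(data=True):
        if data.get("kind") != "mti":
            continue
        du = network.nodes[u].get("direction")
        dv = network.nodes[v].get("direction")
        if NONE in (du, dv) or du == dv:
            raise MiremapError(
                f"mti edge {u}->{v} violates the inverse-expression filter "
                f"({du} -> {dv})"
            )
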