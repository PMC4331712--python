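"""Results-level analyses on a built network: hubs, combinatorial
regulation, co-targeting of a reference miRNA's target set, chromosomal
clustering, and DEG coverage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .de_calling import DOWN, UP, HighConfidenceDEmiR
from .exceptions import ConfigError
from .interaction_db import InteractionRecord, MirnaLocus


@dataclass
class HubReport:
    """Maximum degree within one side of a subnetwork, with the full tie set.

    Ties are reported as a set rather than an arbitrary single winner.
    """

    side: str                     # "regulator" | "target"
    subnetwork: str               # "up" | "down" | "tf" | ...
    max_degree: int = 0
    hubs: set[str] = field(default_factory=set)
    degrees: dict[str, int] = field(default_factory=dict)
    empty: bool = False


@dataclass(frozen=True)
class RegionSpec:
    """A genomic region; omit start/end for a whole chromosome."""

    label: str
    chrom: str
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise ConfigError("region start/end must be given together")
        if self.start is not None and self.start > self.end:
            raise ConfigError(f"region {self.label}: start > end")

    def contains(self, locus: MirnaLocus) -> bool:
        # membership by locus start, so boundary loci are never double counted
        if locus.chrom != self.chrom:
            return False
        if self.start is None:
            return True
        return self.start <= locus.start <= self.end


def hub_report_from_degrees(degrees: Mapping[str, int], side: str = "regulator",
                            subnetwork: str = "") -> HubReport:
    degrees = dict(degrees)
    if not degrees:
        return HubReport(side=side, subnetwork=subnetwork, empty=True)
    max_degree = max(degrees.values())
    return HubReport(
        side=side, subnetwork=subnetwork, max_degree=max_degree,
        hubs={n for n, d in degrees.items() if d == max_degree},
        degrees=degrees,
    )


def find_hubs(network: nx.DiGraph, side: str = "regulator",
              subnetwork: str = "", node_type: str | None = None) -> HubReport:
    """Hub(s) of a (sub)network.

    ``side="regulator"`` uses out-degree over source nodes, ``"target"``
    in-degree over sink nodes; ``subnetwork`` of ``up``/``down`` restricts
    to edges whose miRNA node has that direction; ``node_type`` restricts
    the scored nodes (e.g. "miRNA", "TF", "gene").
    """
    if side not in ("regulator", "target"):
        raise ConfigError(f"unknown hub side {side!r}")
    edges = []
    for u, v, data in network.edges(data=True):
        if subnetwork in (UP, DOWN):
            u_attrs = network.nodes[u]
            mir_node = u if u_attrs.get("type") == "miRNA" else v
            if network.nodes[mir_node].get("direction") != subnetwork:
                continue
        edges.append((u, v))
    degrees: dict[str, int] = {}
    for u, v in edges:
        node = u if side == "regulator" else v
        if node_type and network.nodes[node].get("type") != node_type:
            continue
        degrees[node] = degrees.get(node, 0) + 1
    return hub_report_from_degrees(degrees, side=side, subnetwork=subnetwork)


def combinatorial_regulation(tf_network: nx.DiGraph) -> pd.DataFrame:
    """For every unordered TF pair, the set of miRNAs regulated by both.

    Long-format frame (tf_a, tf_b, shared_mirnas, n_shared), tf_a < tf_b;
    pairs with empty intersection are omitted.
    """
    targets: dict[str, set[str]] = {}
    for u, v, data in tf_network.edges(data=True):
        if data.get("kind") == "tf_mirna":
            targets.setdefault(u, set()).add(v)
    tfs = sorted(targets)
    rows = []
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            shared = targets[a] & targets[b]
            if shared:
                rows.append({"tf_a": a, "tf_b": b,
                             "shared_mirnas": ",".join(sorted(shared)),
                             "n_shared": len(shared)})
    return pd.DataFrame(rows, columns=["tf_a", "tf_b", "shared_mirnas", "n_shared"])


def co_targeting(
    mti_records: Iterable[InteractionRecord],
    reference_targets: Iterable[str],
    demirs: Sequence[HighConfidenceDEmiR],
    de_genes_only: bool = False,
    de_gene_directions: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-DEmiR overlap of curated targets with a reference target set.

    Returns (table, union of shared genes); miRNAs sharing nothing are
    omitted.  With ``de_genes_only`` the curated targets are first
    restricted to genes present in ``de_gene_directions``.
    """
    reference = set(reference_targets)
    if not reference:
        raise ConfigError("reference target set is empty")
    curated: dict[str, set[str]] = {}
    for rec in mti_records:
        if rec.kind == "mti":
            curated.setdefault(rec.source, set()).add(rec.target)
    rows = []
    union: set[str] = set()
    for d in demirs:
        targets = curated.get(d.mirna, set())
        if de_genes_only:
            keep = de_gene_directions or {}
            targets = {g for g in targets if keep.get(g, "none") != "none"}
        shared = targets & reference
        if not shared:
            continue
        union |= shared
        rows.append({"mirna": d.mirna, "direction": d.direction,
                     "shared_genes": ",".join(sorted(shared)),
                     "n_shared": len(shared)})
    table = pd.DataFrame(rows, columns=["mirna", "direction", "shared_genes", "n_shared"])
    return table, union


def chromosomal_clustering(
    demirs: Sequence[HighConfidenceDEmiR],
    regions: Sequence[RegionSpec],
    enrichment: bool = False,
) -> pd.DataFrame:
    """Up/down DEmiR counts per region (membership by locus start).

    With ``enrichment=True`` a hypergeometric upper-tail p-value for
    over-representation of region members among UPmiRs (vs all DEmiRs) is
    added per region.
    """
    with_loci = [d for d in demirs if d.locus is not None]
    rows = []
    n_total = len(with_loci)
    n_up_total = sum(1 for d in with_loci if d.direction == UP)
    for region in regions:
        members = [d for d in with_loci if region.contains(d.locus)]
        n_up = sum(1 for d in members if d.direction == UP)
        n_down = sum(1 for d in members if d.direction == DOWN)
        row = {"region": region.label, "chrom": region.chrom,
               "n_up": n_up, "n_down": n_down, "n_total": len(members)}
        if enrichment:
            # P(X >= n_up) drawing |members| from n_total with n_up_total successes
            row["p_enrichment"] = float(
                hypergeom.sf(n_up - 1, n_total, n_up_total, len(members))
            ) if members else 1.0
        rows.append(row)
    cols = ["region", "chrom", "n_up", "n_down", "n_total"]
    if enrichment:
        cols.append("p_enrichment")
    return pd.DataFrame(rows, columns=cols)


def deg_coverage(network: nx.DiGraph, reference_degs: Iterable[str]) -> dict:
    """Fraction of a reference DEG list covered by targeted genes."""
    reference = {g.upper() for g in reference_degs}
    if not reference:
        raise ConfigError("reference DEG list is empty")
    targeted = {
        v.upper() for _, v, d in network.edges(data=True) if d.get("kind") == "mti"
    }
    n_covered = len(targeted & reference)
    return {
        "n_covered": n_covered,
        "n_reference": len(reference),
        "fraction": n_covered / len(reference),
    }
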