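"""Over-representation analysis of gene lists against GMT collections.

The statistic is the one-sided Fisher exact test, i.e. the hypergeometric
upper tail ``P(X >= overlap)`` for drawing ``|query|`` genes from the
universe with ``|set in universe|`` marked successes.  The significance
flag follows the raw p < alpha convention; Benjamini-Hochberg adjusted
p-values are reported alongside for modern practice but do not drive the
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ConfigError, ParseError


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ParseError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    significant: bool


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name <tab> description <tab> member genes...)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
        members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {fields[0]!r} has no members")
        sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def fisher_ora(query: Iterable[str], gene_set: Iterable[str],
               universe: Iterable[str]) -> float:
    """One-sided over-representation p-value.

    ``P(X >= k)`` where k is the observed overlap, under hypergeometric
    sampling of ``|query|`` genes from ``|universe|`` containing
    ``|gene_set & universe|`` set members.  The query must lie within the
    universe; the gene set is intersected with it.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ConfigError("universe is empty")
    query = {g.upper() for g in query}
    if not query <= universe:
        raise ConfigError("query contains genes outside the universe")
    marked = {g.upper() for g in gene_set} & universe
    k = len(query & marked)
    return float(hypergeom.sf(k - 1, len(universe), len(marked), len(query)))


def _benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def run_collection(query: Iterable[str], collection: Sequence[GeneSet],
                   universe: Iterable[str], alpha: float = 0.05) -> list[EnrichmentResult]:
    """ORA of a query list against every set in a collection, sorted by p."""
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in query}
    raw = []
    for gs in collection:
        marked = gs.members & universe
        raw.append((gs, len(query & marked), len(marked),
                    fisher_ora(query, gs.members, universe)))
    adjusted = _benjamini_hochberg([r[3] for r in raw])
    results = [
        EnrichmentResult(
            set_name=gs.name, overlap=k, query_size=len(query),
            set_size=n_marked, universe_size=len(universe),
            p_value=p, p_adjusted=p_adj, significant=p < alpha,
        )
        for (gs, k, n_marked, p), p_adj in zip(raw, adjusted)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in results],
        columns=["set_name", "overlap", "query_size", "set_size",
                 "universe_size", "p_value", "p_adjusted", "significant"],
    )
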