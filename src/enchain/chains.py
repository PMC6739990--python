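"""Regulatory-element networks and enhancer chains.

Promoters and enhancers are vertices; significant intra-chromosomal Hi-C
contacts between their 5-kb bins are edges.  Within each connected
component an enhancer's rank is its minimum edge-count to the closest
promoter (E1 = directly contacting, E2 = one intermediate, ...).  An
enhancer chain (EC) is a maximal rank-increasing path P-E1-...-En with at
least two enhancers; a promoter touching a single otherwise-unconnected
enhancer is a "single enhancer" case, not a chain.  Equidistant
alternatives are all enumerated, but statistics count each enhancer once
per (promoter, rank) via :func:`assign_single_rank`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .elements import DEFAULT_BIN_SIZE, RegulatoryElement

logger = logging.getLogger(__name__)

DEFAULT_MAX_ALTERNATIVES = 64


@dataclass
class RegulatoryNetwork:
    """A connected component of elements joined by significant contacts."""

    network_id: str
    graph: nx.Graph
    chrom: str
    span: int

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def promoters(self) -> list[str]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "promoter"]

    @property
    def enhancers(self) -> list[str]:
        return [n for n, k in self.graph.nodes(data="kind") if k == "enhancer"]


@dataclass(frozen=True)
class RankedEnhancer:
    element_id: str
    rank: int
    nearest_promoter_ids: frozenset


@dataclass(frozen=True)
class EnhancerChain:
    chain_id: str
    promoter_id: str
    enhancers: tuple[str, ...]
    tissue: str = ""

    @property
    def length(self) -> int:
        return len(self.enhancers)


@dataclass(frozen=True)
class ScenarioLabel:
    chain_id: str
    e1_farther_than_e2: bool
    side_pattern: str  # same_side | opposite_side | other
    scenario: str  # "1" | "2" | "other"


def map_elements_to_chrom_bins(
    elements: Sequence[RegulatoryElement],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, set[tuple[str, int]]]:
    """Element id -> set of (chrom, bin_start) for every overlapped bin."""
    mapping: dict[str, set[tuple[str, int]]] = {}
    for el in elements:
        first = (el.interval.start // bin_size) * bin_size
        last = ((el.interval.end - 1) // bin_size) * bin_size
        mapping[el.element_id] = {
            (el.interval.chrom, b) for b in range(first, last + bin_size, bin_size)
        }
    return mapping


def _bin_index(bin_map: Mapping[str, set]) -> dict[tuple[str, int], list[str]]:
    index: dict[tuple[str, int], list[str]] = {}
    for eid, bins in bin_map.items():
        for key in bins:
            index.setdefault(key, []).append(eid)
    return index


def build_networks(
    elements: Sequence[RegulatoryElement],
    significant_contacts: pd.DataFrame,
    bin_map: Mapping[str, set] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[RegulatoryNetwork]:
    """Connect elements whose bins are joined by a significant contact.

    Elements merely sharing a bin are *not* connected; only a significant
    bin pair creates an edge, and never a self edge.  Components with at
    least one edge become networks; the span is the genomic distance
    between the two most distant elements (by reference point).
    """
    by_id = {el.element_id: el for el in elements}
    if bin_map is None:
        bin_map = map_elements_to_chrom_bins(elements, bin_size)
    index = _bin_index(bin_map)

    g = nx.Graph()
    for row in significant_contacts.itertuples(index=False):
        left = index.get((row.chrom, int(row.bin_i)), ())
        right = index.get((row.chrom, int(row.bin_j)), ())
        for a in left:
            for b in right:
                if a != b:
                    g.add_edge(a, b)
    for n in g.nodes:
        g.nodes[n]["kind"] = by_id[n].kind

    networks = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for i, comp in enumerate(components):
        sub = g.subgraph(comp).copy()
        refs = [by_id[n].reference_point for n in comp]
        chrom = by_id[next(iter(comp))].interval.chrom
        networks.append(
            RegulatoryNetwork(
                network_id=f"net{i}",
                graph=sub,
                chrom=chrom,
                span=max(refs) - min(refs),
            )
        )
    return networks


def rank_enhancers(network: RegulatoryNetwork) -> list[RankedEnhancer]:
    """Rank enhancers by BFS depth from the nearest promoter.

    Multi-source BFS from all promoters in the component; an enhancer's
    rank is its shortest edge-count to any promoter, and its nearest
    promoters are those attaining that distance.  Enhancers unreachable
    from every promoter receive no rank; promoter-less networks yield an
    empty list (logged).
    """
    promoters = network.promoters
    if not promoters:
        logger.info("network %s has no promoter; skipped", network.network_id)
        return []
    per_promoter = {
        p: nx.single_source_shortest_path_length(network.graph, p) for p in promoters
    }
    ranked = []
    for e in network.enhancers:
        dists = {p: d[e] for p, d in per_promoter.items() if e in d}
        if not dists:
            continue
        best = min(dists.values())
        ranked.append(
            RankedEnhancer(
                element_id=e,
                rank=best,
                nearest_promoter_ids=frozenset(p for p, d in dists.items() if d == best),
            )
        )
    return sorted(ranked, key=lambda r: (r.rank, r.element_id))


def enumerate_chains(
    network: RegulatoryNetwork,
    ranks: Sequence[RankedEnhancer],
    tissue: str = "",
    max_alternatives: int = DEFAULT_MAX_ALTERNATIVES,
) -> list[EnhancerChain]:
    """Enumerate all maximal rank-increasing paths P-E1-...-En, n >= 2.

    A path starts at a promoter, its i-th enhancer has rank i, and it
    cannot be extended by any adjacent enhancer of rank i+1 (maximality).
    Single-enhancer cases (n = 1 with no extension) are excluded.  All
    equidistant alternatives are emitted; the number of partial paths per
    (promoter, rank) is capped at ``max_alternatives`` (overflow logged).
    """
    rank_of = {r.element_id: r.rank for r in ranks}
    chains: list[EnhancerChain] = []
    for p in sorted(network.promoters):
        frontier: list[tuple[str, ...]] = [
            (e,) for e in sorted(network.graph.neighbors(p)) if rank_of.get(e) == 1
        ]
        depth = 1
        while frontier:
            if len(frontier) > max_alternatives:
                logger.warning(
                    "promoter %s: %d alternative paths at rank %d, capped at %d",
                    p, len(frontier), depth, max_alternatives,
                )
                frontier = frontier[:max_alternatives]
            next_frontier: list[tuple[str, ...]] = []
            for path in frontier:
                extensions = sorted(
                    e
                    for e in network.graph.neighbors(path[-1])
                    if rank_of.get(e) == depth + 1
                )
                if extensions:
                    next_frontier.extend(path + (e,) for e in extensions)
                elif len(path) >= 2:
                    chains.append(
                        EnhancerChain(
                            chain_id=f"{p}~" + "~".join(path),
                            promoter_id=p,
                            enhancers=path,
                            tissue=tissue,
                        )
                    )
            frontier = next_frontier
            depth += 1
    return sorted(chains, key=lambda c: c.chain_id)


def assign_single_rank(
    chains: Sequence[EnhancerChain],
    elements: Mapping[str, RegulatoryElement],
) -> dict[str, tuple[EnhancerChain, int]]:
    """Assign each enhancer to the single chain where its rank is minimal.

    Ties break by smaller genomic distance between the enhancer and the
    chain's promoter, then by lexicographic chain id, so every enhancer
    is counted exactly once in per-rank statistics.
    """
    best: dict[str, tuple[int, int, str, EnhancerChain]] = {}
    for chain in chains:
        p_ref = elements[chain.promoter_id].reference_point
        for pos, eid in enumerate(chain.enhancers, start=1):
            dist = abs(elements[eid].reference_point - p_ref)
            key = (pos, dist, chain.chain_id, chain)
            if eid not in best or key[:3] < best[eid][:3]:
                best[eid] = key
    return {eid: (key[3], key[0]) for eid, key in best.items()}


def classify_scenario(
    chain: EnhancerChain,
    elements: Mapping[str, RegulatoryElement],
) -> ScenarioLabel:
    """Label chain geometry by the relative positions of P, E1 and E2.

    Scenario 1: E1 and E2 on the same side of the promoter with E1 farther;
    scenario 2: opposite sides with E1 farther; anything else is "other".
    """
    if chain.length < 2:
        raise ValueError(f"chain {chain.chain_id} has fewer than 2 enhancers")
    p = elements[chain.promoter_id].reference_point
    e1 = elements[chain.enhancers[0]].reference_point
    e2 = elements[chain.enhancers[1]].reference_point
    d1, d2 = abs(e1 - p), abs(e2 - p)
    s1, s2 = e1 - p, e2 - p
    if s1 == 0 or s2 == 0:
        side = "other"
    elif (s1 > 0) == (s2 > 0):
        side = "same_side"
    else:
        side = "opposite_side"
    farther = d1 > d2
    if farther and side == "same_side":
        scenario = "1"
    elif farther and side == "opposite_side":
        scenario = "2"
    else:
        scenario = "other"
    return ScenarioLabel(
        chain_id=chain.chain_id,
        e1_farther_than_e2=farther,
        side_pattern=side,
        scenario=scenario,
    )


def detect_indirect_chains(
    promoters: Sequence[RegulatoryElement],
    significant_contacts: pd.DataFrame,
    elements: Sequence[RegulatoryElement],
    bin_map: Mapping[str, set] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> list[tuple[str, tuple[str, int], str]]:
    """Find promoters reaching a chain only through a neutral DNA segment.

    A promoter qualifies when it has no significant contact with any
    enhancer bin, but does contact a bin overlapping no element (the
    neutral segment), and that bin in turn contacts an enhancer heading a
    chain of at least two enhancers (i.e. with an enhancer neighbour in
    the element graph).  Returns (promoter_id, neutral (chrom, bin),
    head enhancer id) triples.
    """
    if bin_map is None:
        bin_map = map_elements_to_chrom_bins(elements, bin_size)
    index = _bin_index(bin_map)
    by_id = {el.element_id: el for el in elements}

    # bin-level adjacency from significant contacts
    adj: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for row in significant_contacts.itertuples(index=False):
        a = (row.chrom, int(row.bin_i))
        b = (row.chrom, int(row.bin_j))
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    # element-level adjacency, for the "heads a chain" condition
    element_adj: dict[str, set[str]] = {}
    for a, partners in adj.items():
        for b in partners:
            for ea in index.get(a, ()):
                for eb in index.get(b, ()):
                    if ea != eb:
                        element_adj.setdefault(ea, set()).add(eb)

    def heads_chain(eid: str) -> bool:
        return any(
            by_id[n].kind == "enhancer" for n in element_adj.get(eid, ())
        )

    flagged = []
    for prom in promoters:
        pbins = bin_map.get(prom.element_id, set())
        contacted = set().union(*(adj.get(b, set()) for b in pbins)) if pbins else set()
        contacted -= pbins
        has_direct = any(
            by_id[e].kind == "enhancer" for b in contacted for e in index.get(b, ())
        )
        if has_direct:
            continue
        for neutral in sorted(contacted):
            if index.get(neutral):
                continue  # overlaps an element: not a neutral segment
            for nb in sorted(adj.get(neutral, ())):
                for eid in sorted(index.get(nb, ())):
                    if by_id[eid].kind == "enhancer" and heads_chain(eid):
                        flagged.append((prom.element_id, neutral, eid))
    return flagged
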