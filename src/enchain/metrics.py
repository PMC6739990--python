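"""Per-rank metrics over enhancer chains and their networks.

Covers genomic distances per rank, restricted betweenness centrality
(shortest enhancer-to-promoter paths), connectivity z-scores, convergent
CTCF motif fractions, loop-anchor / sub-TAD / TAD overlap fractions,
tissue-specificity Jaccard, cross-tissue rank persistence, and inter-chain
contact fractions with a label-shuffled control.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .chains import EnhancerChain, RegulatoryNetwork
from .elements import GenomicInterval, RegulatoryElement, build_interval_trees, overlaps_any

logger = logging.getLogger(__name__)


@dataclass
class CentralityRecord:
    element_id: str
    bc_score: float = 0.0
    n_connected_promoters: int = 0
    n_connected_enhancers: int = 0
    n_connected_chains: int = 0
    z_score: float = 0.0


@dataclass(frozen=True)
class TissueActivityVector:
    element_id: str
    panel: tuple[str, ...]
    active: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.panel) != len(self.active):
            raise ValueError("panel and activity lengths differ")


def rank_class(rank: int) -> str:
    return f"E{rank}" if rank <= 2 else "E3+"


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def chain_distances(
    chains: Sequence[EnhancerChain],
    elements: Mapping[str, RegulatoryElement],
) -> tuple[pd.DataFrame, dict]:
    """Per-(chain, rank) promoter distances plus per-rank-class summary.

    Distance is |enhancer centre - promoter TSS|; the signed value keeps
    the side (positive = downstream of the TSS in coordinate terms).
    The summary holds per-class medians and Wilcoxon rank-sum p-values
    between adjacent rank classes.
    """
    rows = []
    for chain in chains:
        p = elements[chain.promoter_id].reference_point
        for rank, eid in enumerate(chain.enhancers, start=1):
            signed = elements[eid].reference_point - p
            rows.append(
                (chain.chain_id, chain.tissue, eid, rank, rank_class(rank),
                 abs(signed), signed)
            )
    table = pd.DataFrame(
        rows,
        columns=["chain_id", "tissue", "element_id", "rank", "rank_class",
                 "distance", "signed_distance"],
    )
    summary: dict = {"median_by_class": {}, "tests": {}}
    if len(table):
        dedup = table.drop_duplicates(["element_id", "rank_class"])
        summary["median_by_class"] = (
            dedup.groupby("rank_class")["distance"].median().to_dict()
        )
        classes = [c for c in ("E1", "E2", "E3+") if c in set(dedup["rank_class"])]
        for a, b in zip(classes[:-1], classes[1:]):
            da = dedup.loc[dedup["rank_class"] == a, "distance"]
            db = dedup.loc[dedup["rank_class"] == b, "distance"]
            if len(da) >= 2 and len(db) >= 2:
                stat, p = stats.ranksums(da, db)
                summary["tests"][f"{a}_vs_{b}"] = {"statistic": float(stat),
                                                   "p_value": float(p)}
    return table, summary


# ---------------------------------------------------------------------------
# centrality and connectivity
# ---------------------------------------------------------------------------

def _bfs_counts(graph: nx.Graph, source) -> tuple[dict, dict]:
    """Distances and shortest-path counts from one source (BFS)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = nxt
    return dist, sigma


def betweenness_scores(network: RegulatoryNetwork) -> dict[str, float]:
    """Restricted betweenness: sources are enhancers, targets promoters.

    bc(v) = sum over enhancer-promoter pairs (s, t), s != v != t, of the
    fraction of shortest s-t paths passing through v (unnormalised,
    endpoints excluded).  A promoter's lone enhancer scores 0, as there
    are no other source-target pairs routed through it.
    """
    g = network.graph
    enh, prom = network.enhancers, network.promoters
    counts = {n: _bfs_counts(g, n) for n in g.nodes}
    bc = {e: 0.0 for e in enh}
    for s in enh:
        d_s, sig_s = counts[s]
        for t in prom:
            if t not in d_s:
                continue
            d_t, sig_t = counts[t]
            d_st, sig_st = d_s[t], sig_s[t]
            for v in enh:
                if v == s or v == t or v not in d_s or v not in d_t:
                    continue
                if d_s[v] + d_t[v] == d_st:
                    bc[v] += sig_s[v] * sig_t[v] / sig_st
    return bc


def connectivity_counts(
    networks: Sequence[RegulatoryNetwork],
    chains: Sequence[EnhancerChain],
    top_fraction: float = 0.05,
) -> tuple[list[CentralityRecord], list[str]]:
    """Per-enhancer connection counts, BC, z-scores, and the top-z set.

    z-scores standardise the total connection count over all enhancers
    (zero variance maps to all-zero z).  The top set holds the top 5%
    enhancers by z-score; with fewer than 20 enhancers it degenerates to
    the argmax (logged).
    """
    chain_membership: dict[str, set[str]] = defaultdict(set)
    for chain in chains:
        for eid in chain.enhancers:
            chain_membership[eid].add(chain.chain_id)

    records: list[CentralityRecord] = []
    for net in networks:
        bc = betweenness_scores(net)
        kinds = dict(net.graph.nodes(data="kind"))
        for e in net.enhancers:
            neigh = list(net.graph.neighbors(e))
            records.append(
                CentralityRecord(
                    element_id=e,
                    bc_score=bc.get(e, 0.0),
                    n_connected_promoters=sum(kinds[n] == "promoter" for n in neigh),
                    n_connected_enhancers=sum(kinds[n] == "enhancer" for n in neigh),
                    n_connected_chains=len(chain_membership.get(e, ())),
                )
            )
    if not records:
        return records, []
    totals = np.array(
        [r.n_connected_promoters + r.n_connected_enhancers for r in records], dtype=float
    )
    sd = totals.std()
    z = (totals - totals.mean()) / sd if sd > 0 else np.zeros_like(totals)
    for r, zv in zip(records, z):
        r.z_score = float(zv)
    order = sorted(records, key=lambda r: (-r.z_score, r.element_id))
    if len(records) < 20:
        logger.info("fewer than 20 enhancers; top-connected set reduced to argmax")
        top = [order[0].element_id]
    else:
        top = [r.element_id for r in order[: max(1, int(len(records) * top_fraction))]]
    return records, top


# ---------------------------------------------------------------------------
# CTCF convergence
# ---------------------------------------------------------------------------

def _best_motif(element: RegulatoryElement, motif_trees: Mapping[str, IntervalTree]):
    tree = motif_trees.get(element.interval.chrom)
    if tree is None:
        return None
    hits = tree.overlap(element.interval.start, element.interval.end)
    if not hits:
        return None
    return max(hits, key=lambda h: h.data[0]).data  # (score, strand)


def convergent_ctcf_fraction(
    element_pairs: Sequence[tuple[RegulatoryElement, RegulatoryElement, str]],
    motifs: pd.DataFrame,
) -> dict:
    """Fraction of element pairs with convergently oriented CTCF motifs.

    Each element contributes its highest-scoring overlapping motif; the
    pair is ordered by genomic coordinate and is convergent iff the left
    motif is '+' and the right one '-'.  Pairs lacking a motif on either
    side are excluded from the denominator.  Returns overall and
    per-class fractions plus pairwise binomial tests between classes.
    """
    motif_trees: dict[str, IntervalTree] = {}
    for row in motifs.itertuples(index=False):
        motif_trees.setdefault(row.chrom, IntervalTree()).addi(
            int(row.start), int(row.end), (float(row.score), str(row.strand))
        )
    per_class: dict[str, list[bool]] = defaultdict(list)
    for a, b, label in element_pairs:
        ma, mb = _best_motif(a, motif_trees), _best_motif(b, motif_trees)
        if ma is None or mb is None:
            continue
        if a.reference_point <= b.reference_point:
            left, right = ma, mb
        else:
            left, right = mb, ma
        per_class[label].append(left[1] == "+" and right[1] == "-")

    table = {
        label: {
            "n_pairs": len(v),
            "n_convergent": int(sum(v)),
            "fraction": (sum(v) / len(v)) if v else float("nan"),
        }
        for label, v in per_class.items()
    }
    all_flags = [f for v in per_class.values() for f in v]
    tests = {}
    labels = sorted(per_class)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            va, vb = per_class[la], per_class[lb]
            if va and vb and 0 < sum(vb) / len(vb) < 1:
                res = stats.binomtest(int(sum(va)), len(va), sum(vb) / len(vb))
                tests[f"{la}_vs_{lb}"] = float(res.pvalue)
    return {
        "fraction": (sum(all_flags) / len(all_flags)) if all_flags else float("nan"),
        "by_class": table,
        "tests": tests,
    }


# ---------------------------------------------------------------------------
# structural overlaps
# ---------------------------------------------------------------------------

def structural_overlap_fractions(
    elements: Mapping[str, RegulatoryElement],
    chains: Sequence[EnhancerChain],
    edges: Sequence[tuple[str, str]],
    ranks: Mapping[str, int],
    loop_anchors: pd.DataFrame | None = None,
    subtads: Sequence[GenomicInterval] = (),
    tads: Sequence[GenomicInterval] = (),
) -> dict:
    """Loop-anchor overlap per rank class, sub-TAD edge crossings per edge
    class, and the fraction of chains contained within a single TAD."""
    out: dict = {}

    if loop_anchors is not None and len(loop_anchors):
        anchor_ivs = [
            GenomicInterval(r.chrom1, int(r.start1), int(r.end1))
            for r in loop_anchors.itertuples(index=False)
        ] + [
            GenomicInterval(r.chrom2, int(r.start2), int(r.end2))
            for r in loop_anchors.itertuples(index=False)
        ]
        trees = build_interval_trees(anchor_ivs)
        per_class: dict[str, list[bool]] = defaultdict(list)
        for eid, rank in ranks.items():
            per_class[rank_class(rank)].append(
                overlaps_any(elements[eid].interval, trees)
            )
        out["loop_anchor_overlap"] = {
            c: sum(v) / len(v) for c, v in per_class.items() if v
        }

    if subtads:
        sub_sorted = sorted(subtads, key=lambda v: (v.chrom, v.start))

        def subtad_of(eid: str) -> int | None:
            el = elements[eid]
            c = el.reference_point
            for i, iv in enumerate(sub_sorted):
                if iv.chrom == el.interval.chrom and iv.start <= c < iv.end:
                    return i
            return None

        crossing: dict[str, list[bool]] = defaultdict(list)
        for a, b in edges:
            sa, sb = subtad_of(a), subtad_of(b)
            if sa is None or sb is None:
                continue
            ka = "P" if elements[a].is_promoter else rank_class(ranks.get(a, 99))
            kb = "P" if elements[b].is_promoter else rank_class(ranks.get(b, 99))
            label = "-".join(sorted((ka, kb)))
            crossing[label].append(sa != sb)
        out["subtad_crossing"] = {c: sum(v) / len(v) for c, v in crossing.items() if v}

    if tads:
        contained = []
        for chain in chains:
            members = [elements[chain.promoter_id]] + [
                elements[e] for e in chain.enhancers
            ]
            inside_one = any(
                all(
                    m.interval.chrom == tad.chrom
                    and tad.start <= m.interval.start
                    and m.interval.end <= tad.end
                    for m in members
                )
                for tad in tads
            )
            contained.append(inside_one)
        out["tad_containment"] = (
            sum(contained) / len(contained) if contained else float("nan")
        )
    return out


# ---------------------------------------------------------------------------
# tissue specificity
# ---------------------------------------------------------------------------

def tissue_jaccard(
    promoter_vec: TissueActivityVector,
    enhancer_vec: TissueActivityVector,
) -> float:
    """Jaccard index of the two activity vectors; 0 when both are empty."""
    if promoter_vec.panel != enhancer_vec.panel:
        raise ValueError("tissue panels differ between the two vectors")
    a = np.asarray(promoter_vec.active, dtype=bool)
    b = np.asarray(enhancer_vec.active, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return int((a & b).sum()) / union


# ---------------------------------------------------------------------------
# rank persistence across tissues
# ---------------------------------------------------------------------------

def rank_persistence(ranks_per_tissue: Mapping[str, Mapping[str, int]]) -> dict:
    """Cross-tissue transition tallies of chained-enhancer positions.

    For every ordered tissue pair and every enhancer chained in the first
    tissue, its state in the second tissue is one of E1 / E2 / E3+ /
    absent (not chained or not active).  Returns raw counts, fractions
    including and excluding the absent category, and one-sided binomial
    tests of staying in place vs switching to each other rank class.
    """
    tissues = list(ranks_per_tissue)
    if len(tissues) < 2:
        raise ValueError("rank persistence needs at least two tissues")
    origin_classes = ("E1", "E2", "E3+")
    dest_classes = ("E1", "E2", "E3+", "absent")
    counts = {o: {d: 0 for d in dest_classes} for o in origin_classes}
    for t1 in tissues:
        for t2 in tissues:
            if t1 == t2:
                continue
            other = ranks_per_tissue[t2]
            for eid, rank in ranks_per_tissue[t1].items():
                o = rank_class(rank)
                d = rank_class(other[eid]) if eid in other else "absent"
                counts[o][d] += 1

    def fractions(include_absent: bool) -> dict:
        out = {}
        for o in origin_classes:
            dests = dest_classes if include_absent else origin_classes
            total = sum(counts[o][d] for d in dests)
            out[o] = {
                d: (counts[o][d] / total if total else float("nan")) for d in dests
            }
        return out

    tests = {}
    for o in origin_classes:
        for d in origin_classes:
            if d == o:
                continue
            stay, switch = counts[o][o], counts[o][d]
            if stay + switch:
                res = stats.binomtest(stay, stay + switch, 0.5, alternative="greater")
                tests[f"{o}_stays_vs_{d}"] = float(res.pvalue)
    return {
        "counts": counts,
        "fractions": fractions(include_absent=True),
        "fractions_excluding_absent": fractions(include_absent=False),
        "tests": tests,
    }


# ---------------------------------------------------------------------------
# inter-chain contacts with shuffled control
# ---------------------------------------------------------------------------

def inter_ec_contacts(
    network: RegulatoryNetwork,
    chains: Sequence[EnhancerChain],
    n_shuffles: int = 10,
    seed: int = 0,
) -> dict | None:
    """Contacts between non-overlapping same-promoter chains vs a shuffled
    control.

    Observed: among same-promoter chain pairs with disjoint enhancer sets,
    the fraction linked by at least one enhancer-enhancer edge, and the
    fraction of same-rank cross-chain enhancer pairs with an edge.
    Control: the same statistics after permuting enhancer identities
    within the network (topology fixed), averaged over ``n_shuffles``;
    the permutation preserves the degree sequence by construction.
    Returns None when no qualifying chain pair exists (logged).
    """
    local = [c for c in chains if c.promoter_id in network.vertices]
    by_promoter: dict[str, list[EnhancerChain]] = defaultdict(list)
    for c in local:
        by_promoter[c.promoter_id].append(c)
    pairs = [
        (a, b)
        for cs in by_promoter.values()
        for i, a in enumerate(cs)
        for b in cs[i + 1:]
        if not (set(a.enhancers) & set(b.enhancers))
    ]
    if not pairs:
        logger.info("network %s: no non-overlapping same-promoter chain pairs",
                    network.network_id)
        return None

    edge_set = network.edges
    enhancers = sorted(network.enhancers)
    rng = np.random.default_rng(seed)

    def statistics(mapping: Mapping[str, str]) -> tuple[list[int], list[int]]:
        chain_pair_linked, same_rank_linked = [], []
        for a, b in pairs:
            ea = [mapping.get(e, e) for e in a.enhancers]
            eb = [mapping.get(e, e) for e in b.enhancers]
            linked = any(
                frozenset((x, y)) in edge_set for x in ea for y in eb
            )
            chain_pair_linked.append(int(linked))
            for r in range(min(len(ea), len(eb))):
                same_rank_linked.append(int(frozenset((ea[r], eb[r])) in edge_set))
        return chain_pair_linked, same_rank_linked

    obs_pairs, obs_rank = statistics({})
    ctl_pairs, ctl_rank = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(enhancers))
        mapping = {enhancers[i]: enhancers[perm[i]] for i in range(len(enhancers))}
        cp, cr = statistics(mapping)
        ctl_pairs.extend(cp)
        ctl_rank.extend(cr)

    def mean(v):
        return float(np.mean(v)) if v else float("nan")

    result = {
        "n_chain_pairs": len(pairs),
        "observed_chain_pair_fraction": mean(obs_pairs),
        "control_chain_pair_fraction": mean(ctl_pairs),
        "observed_same_rank_fraction": mean(obs_rank),
        "control_same_rank_fraction": mean(ctl_rank),
    }
    if len(obs_pairs) >= 2 and len(ctl_pairs) >= 2:
        result["chain_pair_p_value"] = float(stats.ranksums(obs_pairs, ctl_pairs).pvalue)
    if len(obs_rank) >= 2 and len(ctl_rank) >= 2:
        result["same_rank_p_value"] = float(stats.ranksums(obs_rank, ctl_rank).pvalue)
    return result
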