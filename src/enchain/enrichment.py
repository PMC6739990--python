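"""Feature enrichment and expression statistics over enhancer classes.

TFBS enrichment contrasts chained enhancers against a DNase open-chromatin
background (or E1 vs E2 directly), with fold = overlap-density ratio and
a two-sided Fisher's exact test on element-level 2x2 tables.  eQTL density
is variants per enhancer by class; promoters are partitioned into the
multi-chain / one-chain / one-enhancer / indirect (non-enh) / none
categories, and expression is compared across them with Wilcoxon rank-sum
tests.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chains import EnhancerChain, RegulatoryNetwork
from .elements import (
    ENHANCER_LENGTH,
    GeneRecord,
    GenomicInterval,
    RegulatoryElement,
    build_interval_trees,
    count_overlap_events,
    overlaps_any,
)

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    feature: str
    positive_density: float
    control_density: float
    fold: float          # inf-flagged when control density is 0
    odds_ratio: float
    p_value: float
    table: tuple[int, int, int, int]  # (pos_hit, pos_miss, ctl_hit, ctl_miss)


@dataclass(frozen=True)
class PromoterCategory:
    promoter_id: str
    category: str  # multi_EC | one_EC | one_enh | non_enh | none
    n_chains: int


def build_dnase_background(
    dnase: Sequence[GenomicInterval],
    promoters: Sequence[RegulatoryElement],
    enhancers: Sequence[RegulatoryElement],
    blacklist: Sequence[GenomicInterval] = (),
) -> list[RegulatoryElement]:
    """Control set: 400-bp segments at DNase peak centres, excluding any
    segment overlapping promoters, enhancers or blacklisted regions.
    Adjacent controls may overlap each other."""
    exclusion = build_interval_trees(
        [p.interval for p in promoters]
        + [e.interval for e in enhancers]
        + list(blacklist)
    )
    controls = []
    seen: set[tuple[str, int]] = set()
    for peak in sorted(dnase, key=lambda p: (p.chrom, p.start, p.end)):
        start = max(0, peak.center - ENHANCER_LENGTH // 2)
        seg = GenomicInterval(peak.chrom, start, start + ENHANCER_LENGTH)
        if overlaps_any(seg, exclusion):
            continue
        key = (seg.chrom, seg.start)
        if key in seen:
            continue
        seen.add(key)
        controls.append(
            RegulatoryElement(
                element_id=f"bg:{seg.chrom}:{seg.start}",
                interval=seg,
                kind="enhancer",
            )
        )
    if not controls:
        raise ValueError("empty DNase background after exclusions")
    return controls


def feature_density(
    elements: Sequence[RegulatoryElement],
    feature_peaks: Sequence[GenomicInterval],
) -> float:
    """Overlap events per bp: total element-peak overlaps over total element
    length (a peak spanning two elements counts twice)."""
    total_bp = sum(el.interval.length for el in elements)
    if total_bp == 0:
        raise ValueError("zero total element length")
    trees = build_interval_trees(feature_peaks)
    events = sum(count_overlap_events(el.interval, trees) for el in elements)
    return events / total_bp


def tfbs_enrichment(
    positives: Sequence[RegulatoryElement],
    controls: Sequence[RegulatoryElement],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, EnrichmentResult]:
    """Per-TF density fold enrichment and Fisher's exact test.

    Fold is the ratio of overlap densities (positive / control); the test
    is two-sided Fisher on the element-level 2x2 table of overlapping vs
    non-overlapping elements.  A zero control density is reported as an
    infinite fold with the p-value still computed.  Passing E2 elements
    as ``controls`` gives the E1-vs-E2 mode; non-chain enhancers give the
    chain-vs-non-chain mode.
    """
    if not positives or not controls:
        raise ValueError("both element sets must be non-empty")
    results = {}
    for tf, peaks in peak_sets.items():
        trees = build_interval_trees(peaks)
        pos_hit = sum(overlaps_any(el.interval, trees) for el in positives)
        ctl_hit = sum(overlaps_any(el.interval, trees) for el in controls)
        pos_density = feature_density(positives, peaks)
        ctl_density = feature_density(controls, peaks)
        table = (pos_hit, len(positives) - pos_hit, ctl_hit, len(controls) - ctl_hit)
        odds, p = stats.fisher_exact(
            [[table[0], table[1]], [table[2], table[3]]], alternative="two-sided"
        )
        fold = pos_density / ctl_density if ctl_density > 0 else math.inf
        results[tf] = EnrichmentResult(
            feature=tf,
            positive_density=pos_density,
            control_density=ctl_density,
            fold=fold,
            odds_ratio=float(odds),
            p_value=float(p),
            table=table,
        )
    return results


def eqtl_density(
    elements_by_class: Mapping[str, Sequence[RegulatoryElement]],
    variants: pd.DataFrame,
) -> dict[str, float]:
    """Variants per enhancer, by class.

    A variant (0-based ``pos0``) counts once for every containing element
    of the class (interval end exclusive); density divides by the class
    member count.  Empty classes are omitted with a warning.
    """
    by_chrom: dict[str, np.ndarray] = {
        c: np.sort(sub["pos0"].to_numpy())
        for c, sub in variants.groupby("chrom")
    }
    out = {}
    for cls, members in elements_by_class.items():
        if not members:
            logger.warning("eqtl_density: class %s is empty, omitted", cls)
            continue
        count = 0
        for el in members:
            pos = by_chrom.get(el.interval.chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, el.interval.start, side="left")
            hi = np.searchsorted(pos, el.interval.end, side="left")
            count += int(hi - lo)
        out[cls] = count / len(members)
    return out


def classify_promoters(
    networks: Sequence[RegulatoryNetwork],
    chains: Sequence[EnhancerChain],
    indirect_flags: Iterable[tuple[str, tuple, str]] = (),
    all_promoter_ids: Iterable[str] = (),
) -> tuple[dict[str, PromoterCategory], dict[str, str]]:
    """Partition promoters into regulatory categories and label E1s.

    multi_EC: >= 2 chains; one_EC: exactly one; one_enh: a single
    connected enhancer and no chain; non_enh: reaches a chain only via a
    neutral segment (from ``indirect_flags``); none: everything else.
    Each E1 is also labelled 1P-E1 or MP-E1 by the number of promoters it
    directly contacts in its network.
    """
    n_chains: dict[str, int] = defaultdict(int)
    for c in chains:
        n_chains[c.promoter_id] += 1
    indirect = {pid for pid, *_ in indirect_flags}

    enhancer_degree: dict[str, int] = {}
    e1_prom_contacts: dict[str, int] = {}
    for net in networks:
        kinds = dict(net.graph.nodes(data="kind"))
        for p in net.promoters:
            enhancer_degree[p] = sum(
                kinds[n] == "enhancer" for n in net.graph.neighbors(p)
            )
        for e in net.enhancers:
            e1_prom_contacts[e] = sum(
                kinds[n] == "promoter" for n in net.graph.neighbors(e)
            )

    categories: dict[str, PromoterCategory] = {}
    all_ids = set(all_promoter_ids) | set(enhancer_degree) | indirect
    for pid in sorted(all_ids):
        k = n_chains.get(pid, 0)
        if k >= 2:
            cat = "multi_EC"
        elif k == 1:
            cat = "one_EC"
        elif enhancer_degree.get(pid, 0) == 1:
            cat = "one_enh"
        elif pid in indirect:
            cat = "non_enh"
        else:
            cat = "none"
        categories[pid] = PromoterCategory(pid, cat, k)

    e1_labels = {}
    for c in chains:
        e1 = c.enhancers[0]
        n = e1_prom_contacts.get(e1, 1)
        e1_labels[e1] = "MP-E1" if n > 1 else "1P-E1"
    return categories, e1_labels


def _wilcoxon(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum; exact for small samples."""
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    try:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method=method).pvalue)
    except ValueError:
        return float("nan")


def expression_comparisons(
    categories: Mapping[str, PromoterCategory],
    genes: Mapping[str, GeneRecord],
    chains: Sequence[EnhancerChain],
    promoter_gene: Mapping[str, str],
    seed: int = 0,
    n_random_groups: int = 50,
    distance_tolerance: float = 0.2,
) -> dict:
    """Expression statistics across promoter categories and shared chains.

    (a) RPKM by category with pairwise Wilcoxon tests (categories with
    fewer than 3 genes are excluded from the tests, logged); (b) median
    expression by number of chains; (c) co-expression of gene groups
    sharing a chain: within-group standard deviation of log2(RPKM + 1)
    against random same-chromosome groups matched on mean pairwise TSS
    distance (within +/- ``distance_tolerance``), rank-sum test.
    """
    rng = np.random.default_rng(seed)

    # (a) expression by category
    expr_by_cat: dict[str, list[float]] = defaultdict(list)
    for pid, rec in categories.items():
        gid = promoter_gene.get(pid)
        if gid in genes:
            expr_by_cat[rec.category].append(genes[gid].rpkm)
    medians = {c: float(np.median(v)) for c, v in expr_by_cat.items() if v}
    tests = {}
    usable = {c: v for c, v in expr_by_cat.items() if len(v) >= 3}
    for c in set(expr_by_cat) - set(usable):
        logger.info("category %s has <3 genes; excluded from tests", c)
    cats = sorted(usable)
    for i, ca in enumerate(cats):
        for cb in cats[i + 1:]:
            tests[f"{ca}_vs_{cb}"] = _wilcoxon(usable[ca], usable[cb])

    # (b) expression vs number of chains
    by_n: dict[str, list[float]] = defaultdict(list)
    for pid, rec in categories.items():
        gid = promoter_gene.get(pid)
        if gid not in genes:
            continue
        label = str(rec.n_chains) if rec.n_chains < 3 else "3+"
        by_n[label].append(genes[gid].rpkm)
    by_n_chains = {k: float(np.median(v)) for k, v in by_n.items()}

    # (c) co-expression of genes sharing a chain
    genes_per_chainset: dict[tuple[str, ...], set[str]] = defaultdict(set)
    for c in chains:
        gid = promoter_gene.get(c.promoter_id)
        if gid in genes:
            genes_per_chainset[c.enhancers].add(gid)
    shared_groups = [sorted(g) for g in genes_per_chainset.values() if len(g) >= 2]

    def dispersion(gids: Sequence[str]) -> float:
        vals = np.log2(np.array([genes[g].rpkm for g in gids]) + 1.0)
        return float(vals.std())

    def mean_pairwise_distance(gids: Sequence[str]) -> float:
        tss = [genes[g].tss for g in gids]
        return float(
            np.mean([abs(a - b) for i, a in enumerate(tss) for b in tss[i + 1:]])
        )

    by_chrom: dict[str, list[str]] = defaultdict(list)
    for g in genes.values():
        by_chrom[g.chrom].append(g.gene_id)

    obs_disp, rand_disp = [], []
    for group in shared_groups:
        chrom = genes[group[0]].chrom
        target_d = mean_pairwise_distance(group)
        obs_disp.append(dispersion(group))
        pool = by_chrom[chrom]
        found = 0
        for _ in range(500):
            if found >= max(1, n_random_groups // max(1, len(shared_groups))):
                break
            pick = [pool[i] for i in rng.choice(len(pool), size=len(group),
                                                replace=False)]
            d = mean_pairwise_distance(pick)
            if abs(d - target_d) <= distance_tolerance * target_d:
                rand_disp.append(dispersion(pick))
                found += 1

    coexpr = {
        "n_shared_groups": len(shared_groups),
        "observed_dispersion_median": float(np.median(obs_disp)) if obs_disp else float("nan"),
        "random_dispersion_median": float(np.median(rand_disp)) if rand_disp else float("nan"),
    }
    if len(obs_disp) >= 2 and len(rand_disp) >= 2:
        coexpr["p_value"] = _wilcoxon(obs_disp, rand_disp)

    return {
        "median_by_category": medians,
        "category_tests": tests,
        "median_by_n_chains": by_n_chains,
        "coexpression": coexpr,
    }
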