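"""Self-contained synthetic datasets with planted enhancer chains.

The generator emulates the statistical structure the pipeline assumes in
real data: 5-kb binned intra-chromosomal contact counts with power-law
distance decay and multiplicative per-bin coverage biases, tissue-specific
H3K27ac/H3K4me1/H3K27me3/DNase/TF peaks, stranded CTCF motifs, loop
anchors, TAD/sub-TAD intervals, expression tiers with an RPKM < 1
calibration set, and eQTL variants.  Planted chains (promoter, E1, E2,
...) receive a (1 + beta) boost on their consecutive bin pairs so the
full significance -> network -> chain machinery is exercised end to end;
the ground truth is recorded for recovery tests.

Counts follow ``count(i, j) ~ Poisson(c0 * d^-alpha * (1 + beta *
planted(i, j)) * b_i * b_j)`` for 5 kb <= d <= 2 Mb, with biases b drawn
log-normal so ICE has something to remove.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .elements import GeneRecord, GenomicInterval

logger = logging.getLogger(__name__)

PROMOTER_HALF_EXCLUSION = 3000  # enhancers keep this far from promoter windows


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults are sized so balancing, decay fitting, significance calling
    and chain recovery all run in seconds while remaining statistically
    non-trivial: two 6-Mb chromosomes at 5-kb bins, 50 planted chains,
    a 6x contact boost on planted pairs (beta = 5) over an alpha = 1
    power-law background, and log-normal bin biases (sigma = 0.2).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 6_000_000
    n_genes: int = 60              # per chromosome
    n_enhancers: int = 40          # background (non-chain) enhancers per chromosome
    bin_size: int = 5000
    decay_exponent: float = 1.0    # alpha
    base_rate: float = 1e6         # c0: contact depth, ~1.5M contacts/chromosome
    planted_boost: float = 5.0     # beta
    n_planted_chains: int = 50     # total across the genome
    scenario1_fraction: float = 0.8  # same-side geometry (E1 farther), vs opposite-side
    chain_length_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # lengths 2, 3, 4
    tissue_panel: tuple[str, ...] = ("T1", "T2", "T3", "T4")
    chain_tissue_activity_prob: float = 0.7
    jaccard_panel_size: int = 20
    n_low_expressed: int = 40      # total calibration genes (RPKM < 1, H3K27me3)
    n_single_enhancer_genes: int = 6
    n_indirect_genes: int = 4
    shared_promoter_fraction: float = 0.2  # chains whose E1 also contacts a 2nd promoter
    e1_median_distance: int = 96_000
    e2_median_distance: int = 45_000
    distance_log_sigma: float = 0.35
    bias_log_sigma: float = 0.2
    ctcf_convergent_prob: float = 0.8
    max_contact_distance: int = 2_000_000
    overdispersion: float | None = None  # negative-binomial dispersion; None = Poisson

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.n_genes, self.n_planted_chains, self.bin_size) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.scenario1_fraction <= 1:
            raise ValueError("scenario1_fraction must be in [0, 1]")
        if abs(sum(self.chain_length_probs) - 1.0) > 1e-9:
            raise ValueError("chain_length_probs must sum to 1")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PlantedChain:
    chain_id: str
    chrom: str
    gene_id: str
    promoter_tss: int
    enhancer_centers: tuple[int, ...]  # ordered E1..En
    scenario: str                      # "1" | "2"
    active_tissues: tuple[str, ...]
    shared_gene_ids: tuple[str, ...] = ()  # extra promoters contacting this E1


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: planted chains, the bin pairs that
    were boosted (per tissue), activity vectors, motif orientations and
    the low-expression calibration gene list."""

    chains: list[PlantedChain]
    planted_pairs: dict[str, list[tuple[str, int, int]]]  # tissue -> (chrom, bi, bj)
    single_enhancer_genes: list[str]
    indirect_genes: list[str]
    low_expressed_genes: list[str]
    bin_biases: dict[str, list[float]]  # chrom -> per-bin bias
    motif_orientation: dict[str, str]   # chain_id -> "convergent" | "random"

    def e1_bin_pairs(self, bin_size: int) -> dict[str, set[tuple[str, int, int]]]:
        """Per tissue, the promoter-E1 bin pairs of active planted chains."""
        out: dict[str, set] = {}
        for ch in self.chains:
            bp = (ch.promoter_tss // bin_size) * bin_size
            be = (ch.enhancer_centers[0] // bin_size) * bin_size
            pair = (ch.chrom, min(bp, be), max(bp, be))
            for t in ch.active_tissues:
                out.setdefault(t, set()).add(pair)
        return out


@dataclass
class SyntheticAnnotations:
    genes: list[GeneRecord]                      # strand/TSS; rpkm = tissue-1 values
    expression: pd.DataFrame                     # gene x tissue RPKM
    peaks: dict[str, dict[str, list[GenomicInterval]]]  # mark -> tissue -> peaks
    motifs: pd.DataFrame                         # CTCF sites (chrom,start,end,name,score,strand)
    eqtls: pd.DataFrame                          # chrom,pos(1-based),gene_id,tissue
    loops: pd.DataFrame                          # BEDPE anchors
    tads: list[GenomicInterval]
    subtads: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    activity: pd.DataFrame                       # element-position x 20-tissue panel (bool)
    chrom_sizes: dict[str, int]
    truth: SyntheticTruth


def _lognormal_distance(rng: np.random.Generator, median: float, sigma: float,
                        lo: float, hi: float) -> float:
    for _ in range(100):
        d = float(np.exp(np.log(median) + sigma * rng.standard_normal()))
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))


def generate_annotations(config: SyntheticConfig) -> SyntheticAnnotations:
    """Generate the full annotation set and ground truth, deterministically.

    Genes sit on a jittered grid with minimum spacing; planted chains obey
    their scenario geometry (|E1-P| > |E2-P|, same or opposite side);
    low-expressed genes get H3K27me3-covered promoters and no planted
    contacts, providing the flexible-FDR calibration set.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_sizes = {c: config.chrom_length for c in chroms}
    margin = 300_000
    if config.n_genes * 30_000 > config.chrom_length - 2 * margin:
        raise ValueError("infeasible placement: too many genes for chromosome length")

    # --- genes on a jittered grid -------------------------------------
    genes: list[GeneRecord] = []
    tss_by_chrom: dict[str, list[int]] = {}
    for c in chroms:
        grid = np.linspace(margin, config.chrom_length - margin, config.n_genes)
        jitter = rng.uniform(-15_000, 15_000, size=config.n_genes)
        tss = np.sort((grid + jitter).astype(int))
        tss_by_chrom[c] = list(tss)
        for i, t in enumerate(tss):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"g_{c}_{i:03d}", c, int(t), strand, rpkm=1.0))
    by_gene = {g.gene_id: g for g in genes}

    # --- gene roles ----------------------------------------------------
    all_ids = [g.gene_id for g in genes]
    order = list(rng.permutation(len(all_ids)))
    n_chain = min(config.n_planted_chains, len(all_ids))
    chain_gene_ids = [all_ids[i] for i in order[:n_chain]]
    rest = [all_ids[i] for i in order[n_chain:]]
    n_low = min(config.n_low_expressed, len(rest))
    low_ids = rest[:n_low]
    rest = rest[n_low:]
    single_ids = rest[: config.n_single_enhancer_genes]
    rest = rest[config.n_single_enhancer_genes:]
    indirect_ids = rest[: config.n_indirect_genes]

    # --- planted chains -----------------------------------------------
    occupied: dict[str, list[int]] = {c: list(tss_by_chrom[c]) for c in chroms}

    def place_enhancer(chrom: str, pos: int) -> bool:
        pos = int(pos)
        if not margin // 2 < pos < config.chrom_length - margin // 2:
            return False
        if any(abs(pos - q) < PROMOTER_HALF_EXCLUSION for q in tss_by_chrom[chrom]):
            return False
        if any(abs(pos - q) < 2 * config.bin_size for q in occupied[chrom]):
            return False
        occupied[chrom].append(pos)
        return True

    chains: list[PlantedChain] = []
    lengths = rng.choice([2, 3, 4], size=len(chain_gene_ids), p=config.chain_length_probs)
    for ci, gid in enumerate(chain_gene_ids):
        g = by_gene[gid]
        placed = None
        for _ in range(50):
            d1 = _lognormal_distance(rng, config.e1_median_distance,
                                     config.distance_log_sigma, 20_000, 280_000)
            d2 = _lognormal_distance(rng, config.e2_median_distance,
                                     config.distance_log_sigma, 12_000, 280_000)
            if d1 <= d2:
                d1, d2 = max(d1, d2) * 1.3, min(d1, d2)
            same_side = rng.random() < config.scenario1_fraction
            s1 = 1 if rng.random() < 0.5 else -1
            s2 = s1 if same_side else -s1
            e1, e2 = g.tss + s1 * int(d1), g.tss + s2 * int(d2)
            centers = [e1, e2]
            n = int(lengths[ci])
            ok = True
            for extra in range(n - 2):
                # E3+ most often falls between E1 and E2 along the genome
                lo, hi = sorted((e1, e2))
                if rng.random() < 0.7 and hi - lo > 30_000:
                    pos = int(rng.uniform(lo + 10_000, hi - 10_000))
                else:
                    pos = g.tss + s1 * int(d1 + rng.uniform(15_000, 60_000))
                centers.append(pos)
            snapshot = list(occupied[g.chrom])
            for pos in centers:
                if not place_enhancer(g.chrom, pos):
                    occupied[g.chrom] = snapshot
                    ok = False
                    break
            if ok:
                placed = centers
                break
        if placed is None:
            raise ValueError("infeasible placement: could not site chain enhancers")
        active = tuple(
            t for t in config.tissue_panel
            if rng.random() < config.chain_tissue_activity_prob
        ) or (config.tissue_panel[int(rng.integers(len(config.tissue_panel)))],)
        chains.append(
            PlantedChain(
                chain_id=f"pc{ci:03d}",
                chrom=g.chrom,
                gene_id=gid,
                promoter_tss=g.tss,
                enhancer_centers=tuple(int(x) for x in placed),
                scenario="1" if same_side else "2",
                active_tissues=active,
            )
        )

    # --- shared-promoter chains (MP-E1s, co-expressed gene groups) -------
    for ch in chains:
        if rng.random() >= config.shared_promoter_fraction:
            continue
        e1 = ch.enhancer_centers[0]
        candidates = [
            gid for gid in all_ids
            if by_gene[gid].chrom == ch.chrom
            and gid != ch.gene_id
            and gid not in low_ids
            and gid not in single_ids
            and gid not in indirect_ids
            and 30_000 <= abs(by_gene[gid].tss - e1) <= 1_500_000
        ]
        if candidates:
            ch.shared_gene_ids = (candidates[int(rng.integers(len(candidates)))],)

    # --- single-enhancer and indirect (non-enh) plants ------------------
    single_pairs: list[tuple[str, int, int]] = []  # (chrom, tss, enh_center)
    for gid in single_ids:
        g = by_gene[gid]
        for _ in range(50):
            d = _lognormal_distance(rng, 40_000, 0.3, 15_000, 150_000)
            pos = g.tss + (1 if rng.random() < 0.5 else -1) * int(d)
            if place_enhancer(g.chrom, pos):
                single_pairs.append((g.chrom, g.tss, pos))
                break

    indirect_links: list[tuple[str, int, int, int]] = []  # (chrom, tss, neutral_pos, e1)
    for gid in indirect_ids:
        g = by_gene[gid]
        # a chain on the same chromosome whose E1 is in looping range
        cands = [
            c for c in chains
            if c.chrom == g.chrom
            and 60_000 <= abs(c.enhancer_centers[0] - g.tss) <= 1_500_000
        ]
        if not cands:
            continue
        ch = cands[int(rng.integers(len(cands)))]
        e1 = ch.enhancer_centers[0]
        for _ in range(50):
            # neutral segment between the promoter and the chain head,
            # clear of every element so its bin stays annotation-free
            frac = rng.uniform(0.3, 0.7)
            pos = int(g.tss + frac * (e1 - g.tss))
            if abs(pos - g.tss) < 2 * config.bin_size or abs(pos - e1) < 2 * config.bin_size:
                continue
            if all(abs(pos - q) >= 2 * config.bin_size for q in occupied[g.chrom]):
                occupied[g.chrom].append(pos)
                indirect_links.append((g.chrom, g.tss, pos, e1))
                break

    # --- background enhancers -------------------------------------------
    background: list[tuple[str, int, tuple[str, ...]]] = []
    for c in chroms:
        made = 0
        while made < config.n_enhancers:
            pos = int(rng.uniform(margin // 2, config.chrom_length - margin // 2))
            if place_enhancer(c, pos):
                active = tuple(t for t in config.tissue_panel if rng.random() < 0.5)
                background.append((c, pos, active or (config.tissue_panel[0],)))
                made += 1

    # --- peaks per mark and tissue ---------------------------------------
    peaks: dict[str, dict[str, list[GenomicInterval]]] = {
        m: {t: [] for t in config.tissue_panel}
        for m in ("h3k27ac", "h3k4me1", "h3k27me3", "dnase")
    }
    tf_names = ("CTCF", "RAD21", "SMC3", "EP300")
    tf_peaks: dict[str, dict[str, list[GenomicInterval]]] = {
        tf: {t: [] for t in config.tissue_panel} for tf in tf_names
    }
    tf_prob_by_rank = {1: 0.8, 2: 0.5, 3: 0.4, 4: 0.4}

    def add_enhancer_peaks(chrom: str, center: int, tissues: Sequence[str],
                           rank: int | None) -> None:
        ac = GenomicInterval(chrom, center - 400, center + 400)
        me1 = GenomicInterval(chrom, center - 500, center + 500)
        dn = GenomicInterval(chrom, center - 300, center + 300)
        for t in tissues:
            peaks["h3k27ac"][t].append(ac)
            peaks["h3k4me1"][t].append(me1)
            peaks["dnase"][t].append(dn)
            p = tf_prob_by_rank.get(rank or 0, 0.35)
            for tf in tf_names:
                if rng.random() < p:
                    tf_peaks[tf][t].append(GenomicInterval(chrom, center - 150, center + 150))

    for ch in chains:
        for pos_rank, center in enumerate(ch.enhancer_centers, start=1):
            add_enhancer_peaks(ch.chrom, center, ch.active_tissues, pos_rank)
    for chrom, tss, pos in single_pairs:
        add_enhancer_peaks(chrom, pos, config.tissue_panel, None)
    for chrom, pos, active in background:
        add_enhancer_peaks(chrom, pos, active, None)

    # open-chromatin background for the DNase control set
    for c in chroms:
        for _ in range(80):
            pos = int(rng.uniform(margin // 2, config.chrom_length - margin // 2))
            for t in config.tissue_panel:
                if rng.random() < 0.8:
                    peaks["dnase"][t].append(GenomicInterval(c, pos - 300, pos + 300))

    # H3K27me3 over low-expressed promoters (calibration set)
    for gid in low_ids:
        g = by_gene[gid]
        width = int(rng.uniform(1500, 4000))
        iv = GenomicInterval(g.chrom, max(0, g.tss - width), g.tss + width)
        for t in config.tissue_panel:
            peaks["h3k27me3"][t].append(iv)

    peaks.update(tf_peaks)

    # --- CTCF motifs -------------------------------------------------------
    motif_rows = []
    motif_orientation: dict[str, str] = {}
    for ch in chains:
        e1 = ch.enhancer_centers[0]
        left, right = sorted((ch.promoter_tss, e1))
        convergent = rng.random() < config.ctcf_convergent_prob
        motif_orientation[ch.chain_id] = "convergent" if convergent else "random"
        if convergent:
            strands = ("+", "-")
        else:
            strands = (rng.choice(["+", "-"]), rng.choice(["+", "-"]))
        for pos, strand in zip((left, right), strands):
            motif_rows.append(
                (ch.chrom, pos - 9, pos + 10, "CTCF", float(rng.uniform(5, 10)), strand)
            )
        # occasional weak motifs at E2 with random orientation
        if ch.scenario == "1" and rng.random() < 0.3:
            e2 = ch.enhancer_centers[1]
            motif_rows.append(
                (ch.chrom, e2 - 9, e2 + 10, "CTCF",
                 float(rng.uniform(1, 5)), rng.choice(["+", "-"]))
            )
    for c in chroms:  # genome-wide background motifs
        for _ in range(30):
            pos = int(rng.uniform(0, config.chrom_length - 20))
            motif_rows.append(
                (c, pos, pos + 19, "CTCF", float(rng.uniform(1, 6)), rng.choice(["+", "-"]))
            )
    motifs = pd.DataFrame(
        motif_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # --- loops, TADs, sub-TADs --------------------------------------------
    loop_rows = []
    tads: list[GenomicInterval] = []
    subtads: list[GenomicInterval] = []
    bs = config.bin_size
    for ch in chains:
        p_bin = (ch.promoter_tss // bs) * bs
        e1_bin = (ch.enhancer_centers[0] // bs) * bs
        if rng.random() < 0.8:
            loop_rows.append((ch.chrom, p_bin, p_bin + bs, ch.chrom, e1_bin, e1_bin + bs))
        if len(ch.enhancer_centers) >= 2 and rng.random() < 0.4:
            e2_bin = (ch.enhancer_centers[1] // bs) * bs
            loop_rows.append((ch.chrom, e1_bin, e1_bin + bs, ch.chrom, e2_bin, e2_bin + bs))
        lo = min((ch.promoter_tss, *ch.enhancer_centers)) - 50_000
        hi = max((ch.promoter_tss, *ch.enhancer_centers)) + 50_000
        lo, hi = max(0, lo), min(config.chrom_length, hi)
        tads.append(GenomicInterval(ch.chrom, lo, hi))
        # sub-TAD border between P and E1 so P-E1 edges cross sub-TADs
        mid = (ch.promoter_tss + ch.enhancer_centers[0]) // 2
        if lo < mid < hi:
            subtads.append(GenomicInterval(ch.chrom, lo, mid))
            subtads.append(GenomicInterval(ch.chrom, mid, hi))
        else:
            subtads.append(GenomicInterval(ch.chrom, lo, hi))
    # merge overlapping TADs so each chain sits inside exactly one interval
    merged: list[GenomicInterval] = []
    for iv in sorted(tads, key=lambda v: (v.chrom, v.start)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            merged[-1] = GenomicInterval(iv.chrom, merged[-1].start,
                                         max(merged[-1].end, iv.end))
        else:
            merged.append(iv)
    tads = merged
    loops = pd.DataFrame(
        loop_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )

    # --- expression ---------------------------------------------------------
    chain_count = {}
    for ch in chains:
        chain_count[ch.gene_id] = chain_count.get(ch.gene_id, 0) + 1
    expr = {}
    low_set, single_set, indirect_set = set(low_ids), set(single_ids), set(indirect_ids)
    for t in config.tissue_panel:
        col = {}
        for g in genes:
            noise = float(np.exp(0.3 * rng.standard_normal()))
            if g.gene_id in low_set:
                col[g.gene_id] = float(rng.uniform(0.05, 0.8))
            elif g.gene_id in chain_count:
                active = any(
                    t in c.active_tissues for c in chains if c.gene_id == g.gene_id
                )
                base = 8.0 * (1.0 + 0.5 * (chain_count[g.gene_id] - 1))
                col[g.gene_id] = (base if active else 3.0) * noise
            elif g.gene_id in single_set:
                col[g.gene_id] = 4.5 * noise
            elif g.gene_id in indirect_set:
                col[g.gene_id] = 2.0 * noise
            else:
                col[g.gene_id] = 3.0 * noise
        # genes sharing a chain co-express with the primary target
        for ch in chains:
            for gid in ch.shared_gene_ids:
                col[gid] = col[ch.gene_id] * float(
                    np.exp(0.15 * rng.standard_normal())
                )
        expr[t] = col
    expression = pd.DataFrame(expr)
    expression.index.name = "gene_id"
    genes = [
        GeneRecord(g.gene_id, g.chrom, g.tss, g.strand,
                   float(expression.loc[g.gene_id, config.tissue_panel[0]]))
        for g in genes
    ]

    # --- eQTLs ---------------------------------------------------------------
    eqtl_rate = {1: 2.0, 2: 1.2, 3: 0.8, 4: 0.8}
    eqtl_rows = []
    for ch in chains:
        for pos_rank, center in enumerate(ch.enhancer_centers, start=1):
            for t in ch.active_tissues:
                for _ in range(rng.poisson(eqtl_rate.get(pos_rank, 0.8))):
                    p = int(rng.integers(center - 200, center + 200))
                    eqtl_rows.append((ch.chrom, p + 1, ch.gene_id, t))
    for chrom, tss, pos in single_pairs:
        for t in config.tissue_panel:
            for _ in range(rng.poisson(0.6)):
                eqtl_rows.append((chrom, int(rng.integers(pos - 200, pos + 200)) + 1,
                                  "", t))
    for chrom, pos, active in background:
        for t in active:
            for _ in range(rng.poisson(0.4)):
                eqtl_rows.append((chrom, int(rng.integers(pos - 200, pos + 200)) + 1,
                                  "", t))
    eqtls = pd.DataFrame(eqtl_rows, columns=["chrom", "pos", "gene_id", "tissue"])

    # --- 20-tissue activity panel for Jaccard ------------------------------
    panel = [f"A{i + 1:02d}" for i in range(config.jaccard_panel_size)]
    act_rows = {}
    for ch in chains:
        p_active = rng.random(len(panel)) < 0.7  # promoters nearly ubiquitous
        act_rows[f"P:{ch.gene_id}:{ch.promoter_tss}"] = p_active
        for pos_rank, center in enumerate(ch.enhancer_centers, start=1):
            if pos_rank == 1:
                # E1 mirrors the promoter on a small subset of tissues
                e_active = p_active & (rng.random(len(panel)) < 0.35)
            else:
                e_active = rng.random(len(panel)) < 0.18
            if not e_active.any():
                e_active[int(rng.integers(len(panel)))] = True
            act_rows[f"E:{ch.chrom}:{center - 200}"] = e_active
    activity = pd.DataFrame.from_dict(act_rows, orient="index", columns=panel)
    activity.index.name = "element_id"

    # --- planted bin pairs per tissue ---------------------------------------
    planted: dict[str, list[tuple[str, int, int]]] = {t: [] for t in config.tissue_panel}

    def add_pair(tissues: Sequence[str], chrom: str, a: int, b: int) -> None:
        ba, bb = (a // bs) * bs, (b // bs) * bs
        if ba == bb:
            return
        lo, hi = min(ba, bb), max(ba, bb)
        if hi - lo > config.max_contact_distance:
            return
        for t in tissues:
            planted[t].append((chrom, lo, hi))

    for ch in chains:
        anchors = (ch.promoter_tss, *ch.enhancer_centers)
        for a, b in zip(anchors[:-1], anchors[1:]):
            add_pair(ch.active_tissues, ch.chrom, a, b)
        for gid in ch.shared_gene_ids:
            add_pair(ch.active_tissues, ch.chrom, by_gene[gid].tss,
                     ch.enhancer_centers[0])
    for chrom, tss, pos in single_pairs:
        add_pair(config.tissue_panel, chrom, tss, pos)
    for chrom, tss, pos, e1 in indirect_links:
        add_pair(config.tissue_panel, chrom, tss, pos)
        add_pair(config.tissue_panel, chrom, pos, e1)

    # --- per-bin biases -----------------------------------------------------
    n_bins = config.chrom_length // bs
    biases = {
        c: list(np.exp(config.bias_log_sigma * rng.standard_normal(n_bins)))
        for c in chroms
    }

    truth = SyntheticTruth(
        chains=chains,
        planted_pairs={t: sorted(set(v)) for t, v in planted.items()},
        single_enhancer_genes=list(single_ids),
        indirect_genes=list(indirect_ids),
        low_expressed_genes=list(low_ids),
        bin_biases=biases,
        motif_orientation=motif_orientation,
    )
    blacklist = [GenomicInterval(c, 0, 10_000) for c in chroms]
    return SyntheticAnnotations(
        genes=genes,
        expression=expression,
        peaks=peaks,
        motifs=motifs,
        eqtls=eqtls,
        loops=loops,
        tads=tads,
        subtads=subtads,
        blacklist=blacklist,
        activity=activity,
        chrom_sizes=chrom_sizes,
        truth=truth,
    )


def generate_contact_map(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    tissue: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw a raw 5-kb contact list for one tissue.

    Poisson (or negative-binomial, if ``overdispersion`` is set) counts
    with power-law decay, per-bin biases and the planted boost; only
    nonzero pairs with 1 bin <= separation <= 2 Mb are emitted.
    """
    if rng is None:
        # independent, reproducible stream per tissue
        salt = int(hashlib.sha256(tissue.encode()).hexdigest()[:8], 16)
        rng = np.random.default_rng((config.seed, salt))
    bs = config.bin_size
    n_bins = config.chrom_length // bs
    max_k = min(config.max_contact_distance // bs, n_bins - 1)
    planted = {
        (c, bi, bj): True for (c, bi, bj) in truth.planted_pairs.get(tissue, ())
    }
    frames = []
    for chrom, bias in truth.bin_biases.items():
        b = np.asarray(bias)
        rows_i, rows_j, rows_c = [], [], []
        for k in range(1, max_k + 1):
            d = k * bs
            rate = config.base_rate * d ** (-config.decay_exponent)
            i = np.arange(n_bins - k)
            lam = rate * b[i] * b[i + k]
            # boost planted pairs at this offset
            for (c, bi, bj), _ in planted.items():
                if c == chrom and bj - bi == d:
                    idx = bi // bs
                    if idx < len(lam):
                        lam[idx] *= 1.0 + config.planted_boost
            if config.overdispersion:
                r = 1.0 / config.overdispersion
                counts = rng.negative_binomial(r, r / (r + lam))
            else:
                counts = rng.poisson(lam)
            nz = counts > 0
            rows_i.append(i[nz] * bs)
            rows_j.append((i[nz] + k) * bs)
            rows_c.append(counts[nz])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_i": np.concatenate(rows_i),
                    "bin_j": np.concatenate(rows_j),
                    "count": np.concatenate(rows_c),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# fixture bundle on disk
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    config: SyntheticConfig,
    directory: str | Path,
    annotations: SyntheticAnnotations | None = None,
) -> dict:
    """Write the complete bundle in the formats the pipeline readers accept.

    Returns the manifest (also written as ``manifest.json``), keyed by the
    config hash; empty optional tracks are omitted and noted.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ann = annotations or generate_annotations(config)

    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "tissues": list(config.tissue_panel),
        "chrom_sizes": ann.chrom_sizes,
        "files": {},
        "omitted": [],
    }

    def record(key: str, name: str) -> Path:
        manifest["files"][key] = name
        return directory / name

    eio.write_gene_table(ann.genes, record("genes", "genes.tsv"))
    ann.expression.to_csv(record("expression", "expression.tsv"), sep="\t")
    for mark, per_tissue in ann.peaks.items():
        for t, ivs in per_tissue.items():
            key = f"peaks/{mark}/{t}"
            if not ivs:
                manifest["omitted"].append(key)
                continue
            eio.write_bed(sorted(ivs, key=lambda v: (v.chrom, v.start)),
                          record(key, f"{mark}_{t}.bed"))
    if len(ann.motifs):
        ann.motifs.to_csv(record("motifs", "ctcf_motifs.bed"), sep="\t",
                          header=False, index=False)
    else:
        manifest["omitted"].append("motifs")
    if len(ann.eqtls):
        ann.eqtls.to_csv(record("eqtls", "eqtls.tsv"), sep="\t", index=False)
    else:
        manifest["omitted"].append("eqtls")
    if len(ann.loops):
        eio.write_bedpe(ann.loops, record("loops", "loops.bedpe"))
    else:
        manifest["omitted"].append("loops")
    eio.write_bed(ann.tads, record("tads", "tads.bed"))
    eio.write_bed(ann.subtads, record("subtads", "subtads.bed"))
    eio.write_bed(ann.blacklist, record("blacklist", "blacklist.bed"))
    ann.activity.to_csv(record("activity", "activity_panel.tsv"), sep="\t")

    for t in config.tissue_panel:
        contacts = generate_contact_map(config, ann.truth, t)
        eio.write_contacts(contacts, record(f"contacts/{t}", f"contacts_{t}.tsv"))

    truth_payload = {
        "chains": [asdict(c) for c in ann.truth.chains],
        "planted_pairs": ann.truth.planted_pairs,
        "single_enhancer_genes": ann.truth.single_enhancer_genes,
        "indirect_genes": ann.truth.indirect_genes,
        "low_expressed_genes": ann.truth.low_expressed_genes,
        "motif_orientation": ann.truth.motif_orientation,
        "bin_biases": {c: list(map(float, b)) for c, b in ann.truth.bin_biases.items()},
    }
    with open(record("truth", "truth.json"), "w") as fh:
        json.dump(truth_payload, fh)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_truth(directory: str | Path) -> SyntheticTruth:
    with open(Path(directory) / "truth.json") as fh:
        payload = json.load(fh)
    return SyntheticTruth(
        chains=[
            PlantedChain(
                chain_id=c["chain_id"], chrom=c["chrom"], gene_id=c["gene_id"],
                promoter_tss=c["promoter_tss"],
                enhancer_centers=tuple(c["enhancer_centers"]),
                scenario=c["scenario"], active_tissues=tuple(c["active_tissues"]),
                shared_gene_ids=tuple(c.get("shared_gene_ids", ())),
            )
            for c in payload["chains"]
        ],
        planted_pairs={
            t: [tuple(p) for p in pairs] for t, pairs in payload["planted_pairs"].items()
        },
        single_enhancer_genes=payload["single_enhancer_genes"],
        indirect_genes=payload["indirect_genes"],
        low_expressed_genes=payload["low_expressed_genes"],
        bin_biases=payload["bin_biases"],
        motif_orientation=payload["motif_orientation"],
    )
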