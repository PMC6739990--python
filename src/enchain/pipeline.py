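"""End-to-end orchestration: elements -> significance -> networks ->
chains -> metrics -> enrichment, driven by a fixture-bundle manifest.

The pipeline consumes the on-disk bundle layout written by
:func:`enchain.simulate.write_fixture_bundle` (or any directory with a
compatible ``manifest.json``), processes each tissue independently, and
finishes with the cross-tissue metrics.  Significance calling — the slow
stage — is cached per tissue under ``<out>/cache``, keyed by the bundle's
config hash, so re-runs resume from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chains as chainmod
from . import enrichment as enrich
from . import hic
from . import io as eio
from . import metrics
from .elements import (
    GeneRecord,
    GenomicInterval,
    RegulatoryElement,
    define_enhancers,
    define_promoters,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"
ALL_STAGES = ("elements", "hic-call", "chains", "metrics", "enrich")


@dataclass
class PipelineConfig:
    bundle_dir: str
    out_dir: str
    seed: int = 0
    tissues: tuple[str, ...] | None = None  # None = all in manifest
    bin_size: int = 5000
    distance_lower: int = hic.DEFAULT_L
    distance_upper: int = hic.DEFAULT_U
    n_distance_bins: int = hic.DEFAULT_N_DISTANCE_BINS
    fdr_grid: tuple[float, ...] = hic.DEFAULT_FDR_GRID
    max_alternatives: int = chainmod.DEFAULT_MAX_ALTERNATIVES
    stages: tuple[str, ...] = ALL_STAGES
    use_cache: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tissues", "fdr_grid", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not (Path(self.bundle_dir) / "manifest.json").exists():
            raise FileNotFoundError(f"no manifest.json under {self.bundle_dir}")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        # downstream stages need their producers enabled
        order = {s: i for i, s in enumerate(ALL_STAGES)}
        enabled = sorted(order[s] for s in self.stages)
        if enabled and enabled != list(range(enabled[0], enabled[-1] + 1)) or (
            enabled and enabled[0] != 0
        ):
            raise ValueError(
                "stages must form a prefix of "
                f"{ALL_STAGES}: downstream stages need their inputs"
            )


@dataclass
class RunReport:
    schema_version: str
    config: dict
    sections: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame


# ---------------------------------------------------------------------------
# bundle loading
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    directory: Path
    manifest: dict
    genes: pd.DataFrame
    expression: pd.DataFrame
    peaks: dict[str, dict[str, list[GenomicInterval]]]
    motifs: pd.DataFrame
    eqtls: pd.DataFrame
    loops: pd.DataFrame
    tads: list[GenomicInterval]
    subtads: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    activity: pd.DataFrame
    chrom_sizes: dict[str, int]

    def tissue_genes(self, tissue: str) -> list[GeneRecord]:
        rpkm = self.expression[tissue]
        return [
            GeneRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand),
                       float(rpkm.get(r.gene_id, 0.0)))
            for r in self.genes.itertuples(index=False)
        ]


def load_bundle(directory: str | Path) -> Bundle:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    files = manifest["files"]

    def maybe_bed(key: str) -> list[GenomicInterval]:
        return eio.read_bed(directory / files[key]) if key in files else []

    peaks: dict[str, dict[str, list[GenomicInterval]]] = {}
    for key, name in files.items():
        if key.startswith("peaks/"):
            _, mark, tissue = key.split("/")
            peaks.setdefault(mark, {})[tissue] = eio.read_bed(directory / name)

    return Bundle(
        directory=directory,
        manifest=manifest,
        genes=pd.read_csv(directory / files["genes"], sep="\t"),
        expression=eio.read_expression(directory / files["expression"]),
        peaks=peaks,
        motifs=(eio.read_motifs_bed(directory / files["motifs"])
                if "motifs" in files else pd.DataFrame(
                    columns=["chrom", "start", "end", "name", "score", "strand"])),
        eqtls=(eio.read_eqtls(directory / files["eqtls"])
               if "eqtls" in files else pd.DataFrame(
                   columns=["chrom", "pos", "gene_id", "tissue", "pos0"])),
        loops=(eio.read_bedpe(directory / files["loops"])
               if "loops" in files else pd.DataFrame()),
        tads=maybe_bed("tads"),
        subtads=maybe_bed("subtads"),
        blacklist=maybe_bed("blacklist"),
        activity=(pd.read_csv(directory / files["activity"], sep="\t", index_col=0)
                  if "activity" in files else pd.DataFrame()),
        chrom_sizes={k: int(v) for k, v in manifest["chrom_sizes"].items()},
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@dataclass
class TissueElements:
    tissue: str
    genes: list[GeneRecord]
    promoters: list[RegulatoryElement]
    enhancers: list[RegulatoryElement]
    bin_map: dict[str, set]

    @property
    def elements(self) -> dict[str, RegulatoryElement]:
        return {e.element_id: e for e in self.promoters + self.enhancers}


def stage_elements(bundle: Bundle, tissue: str, bin_size: int) -> TissueElements:
    genes = bundle.tissue_genes(tissue)
    promoters = define_promoters(genes, bundle.chrom_sizes, tissue=tissue)
    enhancers = define_enhancers(
        bundle.peaks.get("h3k27ac", {}).get(tissue, []),
        bundle.peaks.get("h3k4me1", {}).get(tissue, []),
        promoters,
        bundle.peaks.get("h3k27me3", {}).get(tissue, []),
        bundle.blacklist,
        tissue=tissue,
    )
    all_elements = promoters + enhancers
    logger.info("tissue %s: %d promoters, %d enhancers", tissue,
                len(promoters), len(enhancers))
    return TissueElements(
        tissue=tissue,
        genes=genes,
        promoters=promoters,
        enhancers=enhancers,
        bin_map=chainmod.map_elements_to_chrom_bins(all_elements, bin_size),
    )


def stage_hic(
    bundle: Bundle,
    tissue: str,
    elems: TissueElements,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, hic.FdrCalibration]:
    """ICE -> decay -> significance -> flexible-FDR threshold; cached."""
    cache_dir = Path(config.out_dir) / "cache"
    cache_key = bundle.manifest.get("config_hash", "nohash")
    cache_file = cache_dir / f"significant_{tissue}_{cache_key}.tsv"
    cal_file = cache_dir / f"calibration_{tissue}_{cache_key}.json"
    if config.use_cache and cache_file.exists() and cal_file.exists():
        logger.info("tissue %s: reusing cached significance results", tissue)
        sig = pd.read_csv(cache_file, sep="\t")
        with open(cal_file) as fh:
            payload = json.load(fh)
        calibration = hic.FdrCalibration(
            grid=np.asarray(payload["grid"]),
            fraction_flagged=np.asarray(payload["fraction_flagged"]),
            chosen_threshold=payload["chosen_threshold"],
        )
        return sig, calibration

    contacts = eio.read_contacts(
        bundle.directory / bundle.manifest["files"][f"contacts/{tissue}"]
    )
    balanced, _ = hic.ice_balance(contacts)
    model = hic.fit_distance_decay(
        balanced, L=config.distance_lower, U=config.distance_upper,
        n_bins=config.n_distance_bins,
    )
    tested = hic.contact_significance(balanced, model)
    low = hic.select_low_expressed_promoters(
        elems.genes, elems.promoters,
        bundle.peaks.get("h3k27me3", {}).get(tissue, []),
    )
    calibration = hic.calibrate_flexible_fdr(
        tested, low, elems.bin_map, grid=config.fdr_grid
    )
    sig = tested[tested["q_value"] <= calibration.chosen_threshold].reset_index(drop=True)

    cache_dir.mkdir(parents=True, exist_ok=True)
    sig.to_csv(cache_file, sep="\t", index=False)
    with open(cal_file, "w") as fh:
        json.dump(
            {
                "grid": list(map(float, calibration.grid)),
                "fraction_flagged": list(map(float, calibration.fraction_flagged)),
                "chosen_threshold": calibration.chosen_threshold,
            },
            fh,
        )
    return sig, calibration


@dataclass
class TissueChains:
    networks: list
    ranks: dict[str, int]
    chains: list
    assignment: dict
    scenarios: list
    indirect: list


def stage_chains(
    elems: TissueElements,
    significant: pd.DataFrame,
    config: PipelineConfig,
) -> TissueChains:
    all_elements = elems.promoters + elems.enhancers
    networks = chainmod.build_networks(all_elements, significant, elems.bin_map)
    ranks: dict[str, int] = {}
    all_chains = []
    for net in networks:
        ranked = chainmod.rank_enhancers(net)
        ranks.update({r.element_id: r.rank for r in ranked})
        all_chains.extend(
            chainmod.enumerate_chains(net, ranked, tissue=elems.tissue,
                                      max_alternatives=config.max_alternatives)
        )
    element_map = elems.elements
    assignment = chainmod.assign_single_rank(all_chains, element_map)
    scenarios = [chainmod.classify_scenario(c, element_map) for c in all_chains]
    indirect = chainmod.detect_indirect_chains(
        elems.promoters, significant, all_elements, elems.bin_map
    )
    return TissueChains(
        networks=networks, ranks=ranks, chains=all_chains,
        assignment=assignment, scenarios=scenarios, indirect=indirect,
    )


def _assigned_ranks(result: TissueChains) -> dict[str, int]:
    return {eid: rank for eid, (_, rank) in result.assignment.items()}


def _enhancer_classes(
    elems: TissueElements, result: TissueChains
) -> dict[str, list[RegulatoryElement]]:
    """E1/E2/E3+/single/non-chain partition of the tissue's enhancers."""
    element_map = elems.elements
    assigned = _assigned_ranks(result)
    chained = set(assigned)
    classes: dict[str, list[RegulatoryElement]] = {
        "E1": [], "E2": [], "E3+": [], "single": [], "non_chain": []
    }
    for e in elems.enhancers:
        eid = e.element_id
        if eid in chained:
            classes[metrics.rank_class(assigned[eid])].append(e)
        elif result.ranks.get(eid) == 1:
            classes["single"].append(e)
        else:
            classes["non_chain"].append(e)
    return classes


def _ctcf_pairs(result: TissueChains, element_map) -> list[tuple]:
    pairs = {}
    for c in result.chains:
        chain_members = [("P", c.promoter_id)] + [
            (metrics.rank_class(i + 1).replace("E3+", f"E{i + 1}"), eid)
            for i, eid in enumerate(c.enhancers)
        ]
        for (la, a), (lb, b) in zip(chain_members[:-1], chain_members[1:]):
            pairs[(a, b)] = f"{la}-{lb}"
        if c.length >= 2:  # promoter also paired with E2 for the P-E2 class
            pairs[(c.promoter_id, c.enhancers[1])] = "P-E2"
    return [
        (element_map[a], element_map[b], label) for (a, b), label in pairs.items()
    ]


def stage_metrics(
    bundle: Bundle,
    elems: TissueElements,
    result: TissueChains,
    config: PipelineConfig,
) -> dict:
    element_map = elems.elements
    section: dict = {}

    dist_table, dist_summary = metrics.chain_distances(result.chains, element_map)
    section["distances"] = dist_summary

    records, top = metrics.connectivity_counts(result.networks, result.chains)
    by_class: dict[str, list[float]] = {}
    assigned = _assigned_ranks(result)
    for r in records:
        cls = metrics.rank_class(assigned[r.element_id]) if r.element_id in assigned else "other"
        by_class.setdefault(cls, []).append(r.bc_score)
    section["betweenness_mean_by_class"] = {
        c: float(np.mean(v)) for c, v in by_class.items() if v
    }
    section["top_connected"] = top

    if len(bundle.motifs):
        section["ctcf_convergence"] = metrics.convergent_ctcf_fraction(
            _ctcf_pairs(result, element_map), bundle.motifs
        )

    edges = sorted(
        (tuple(sorted(e)) for net in result.networks for e in net.graph.edges),
    )
    section["structural"] = metrics.structural_overlap_fractions(
        element_map, result.chains, edges, assigned,
        loop_anchors=bundle.loops if len(bundle.loops) else None,
        subtads=bundle.subtads, tads=bundle.tads,
    )

    if len(bundle.activity):
        panel = tuple(bundle.activity.columns)
        jc: dict[str, list[float]] = {}
        for c in result.chains:
            if c.promoter_id not in bundle.activity.index:
                continue
            pvec = metrics.TissueActivityVector(
                c.promoter_id, panel,
                tuple(bundle.activity.loc[c.promoter_id].astype(bool)),
            )
            for i, eid in enumerate(c.enhancers, start=1):
                if eid not in bundle.activity.index:
                    continue
                evec = metrics.TissueActivityVector(
                    eid, panel, tuple(bundle.activity.loc[eid].astype(bool))
                )
                jc.setdefault(f"P-{metrics.rank_class(i)}", []).append(
                    metrics.tissue_jaccard(pvec, evec)
                )
        section["jaccard_median"] = {
            k: float(np.median(v)) for k, v in jc.items() if v
        }

    inter = []
    for net in result.networks:
        r = metrics.inter_ec_contacts(net, result.chains, seed=config.seed)
        if r is not None:
            inter.append(r)
    if inter:
        section["inter_ec"] = {
            "n_networks": len(inter),
            "observed_chain_pair_fraction": float(
                np.mean([r["observed_chain_pair_fraction"] for r in inter])
            ),
            "control_chain_pair_fraction": float(
                np.mean([r["control_chain_pair_fraction"] for r in inter])
            ),
            "observed_same_rank_fraction": float(
                np.mean([r["observed_same_rank_fraction"] for r in inter])
            ),
            "control_same_rank_fraction": float(
                np.mean([r["control_same_rank_fraction"] for r in inter])
            ),
        }
    return section, dist_table


def stage_enrich(
    bundle: Bundle,
    elems: TissueElements,
    result: TissueChains,
    config: PipelineConfig,
) -> dict:
    section: dict = {}
    element_map = elems.elements
    classes = _enhancer_classes(elems, result)

    categories, e1_labels = enrich.classify_promoters(
        result.networks, result.chains, result.indirect,
        all_promoter_ids=[p.element_id for p in elems.promoters],
    )
    section["promoter_categories"] = {
        cat: sum(1 for c in categories.values() if c.category == cat)
        for cat in ("multi_EC", "one_EC", "one_enh", "non_enh", "none")
    }
    section["e1_promoter_sharing"] = {
        lab: sum(1 for v in e1_labels.values() if v == lab)
        for lab in ("1P-E1", "MP-E1")
    }

    dnase = bundle.peaks.get("dnase", {}).get(elems.tissue, [])
    tf_sets = {
        mark: per_t.get(elems.tissue, [])
        for mark, per_t in bundle.peaks.items()
        if mark not in ("h3k27ac", "h3k4me1", "h3k27me3", "dnase")
    }
    if dnase and tf_sets:
        try:
            background = enrich.build_dnase_background(
                dnase, elems.promoters, elems.enhancers, bundle.blacklist
            )
            chained = classes["E1"] + classes["E2"] + classes["E3+"]
            if chained:
                section["tfbs_chain_vs_background"] = {
                    tf: {"fold": r.fold, "p_value": r.p_value}
                    for tf, r in enrich.tfbs_enrichment(
                        chained, background, tf_sets
                    ).items()
                }
            if classes["E1"] and classes["E2"]:
                section["tfbs_e1_vs_e2"] = {
                    tf: {"fold": r.fold, "p_value": r.p_value}
                    for tf, r in enrich.tfbs_enrichment(
                        classes["E1"], classes["E2"], tf_sets
                    ).items()
                }
        except ValueError as exc:
            logger.warning("TFBS enrichment skipped: %s", exc)

    if len(bundle.eqtls):
        variants = bundle.eqtls[bundle.eqtls["tissue"] == elems.tissue]
        split = dict(classes)
        split["1P-E1"] = [e for e in classes["E1"] if e1_labels.get(e.element_id) == "1P-E1"]
        split["MP-E1"] = [e for e in classes["E1"] if e1_labels.get(e.element_id) == "MP-E1"]
        if len(variants):
            section["eqtl_density"] = enrich.eqtl_density(split, variants)

    promoter_gene = {p.element_id: p.gene_id for p in elems.promoters}
    gene_map = {g.gene_id: g for g in elems.genes}
    section["expression"] = enrich.expression_comparisons(
        categories, gene_map, result.chains, promoter_gene, seed=config.seed
    )
    return section


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages over every tissue and assemble the report."""
    config.validate()
    bundle = load_bundle(config.bundle_dir)
    tissues = list(config.tissues or bundle.manifest["tissues"])
    report = RunReport(
        schema_version=SCHEMA_VERSION,
        config={**asdict(config), "bundle_hash": bundle.manifest.get("config_hash")},
    )
    stages = set(config.stages)
    ranks_per_tissue: dict[str, dict[str, int]] = {}
    chains_tables = []

    for tissue in tissues:
        section: dict = {}
        if "elements" not in stages:
            break
        elems = stage_elements(bundle, tissue, config.bin_size)
        section["n_promoters"] = len(elems.promoters)
        section["n_enhancers"] = len(elems.enhancers)

        if "hic-call" in stages:
            significant, calibration = stage_hic(bundle, tissue, elems, config)
            section["chosen_fdr"] = calibration.chosen_threshold
            section["n_significant_contacts"] = int(len(significant))

        if "chains" in stages:
            result = stage_chains(elems, significant, config)
            element_map = elems.elements
            unique_sets = {
                (c.promoter_id, frozenset(c.enhancers)) for c in result.chains
            }
            assigned = _assigned_ranks(result)
            section.update(
                n_networks=len(result.networks),
                n_networks_with_promoter=sum(
                    1 for n in result.networks if n.promoters
                ),
                median_network_span=float(
                    np.median([n.span for n in result.networks])
                ) if result.networks else 0.0,
                n_chains_paths=len(result.chains),
                n_chains_unique_sets=len(unique_sets),
                n_promoters_with_chain=len({c.promoter_id for c in result.chains}),
                mean_enhancers_per_chain=float(
                    np.mean([c.length for c in result.chains])
                ) if result.chains else 0.0,
                per_rank_tallies={
                    cls: sum(1 for r in assigned.values()
                             if metrics.rank_class(r) == cls)
                    for cls in ("E1", "E2", "E3+")
                },
                scenario_fractions=_scenario_fractions(result.scenarios),
                n_indirect_promoters=len({pid for pid, *_ in result.indirect}),
            )
            ranks_per_tissue[tissue] = assigned
            chains_tables.append(_chains_table(result, element_map, tissue))

        if "metrics" in stages:
            msec, dist_table = stage_metrics(bundle, elems, result, config)
            section["metrics"] = msec
            report.tables[f"distances_{tissue}"] = dist_table

        if "enrich" in stages:
            section["enrichment"] = stage_enrich(bundle, elems, result, config)

        report.sections[tissue] = section

    if "metrics" in stages and len(ranks_per_tissue) >= 2:
        report.sections["cross_tissue"] = {
            "rank_persistence": metrics.rank_persistence(ranks_per_tissue)
        }
    if chains_tables:
        report.tables["chains"] = pd.concat(chains_tables, ignore_index=True)
    return report


def _scenario_fractions(scenarios) -> dict:
    if not scenarios:
        return {}
    n = len(scenarios)
    return {
        "e1_farther_fraction": sum(s.e1_farther_than_e2 for s in scenarios) / n,
        "scenario1_fraction": sum(s.scenario == "1" for s in scenarios) / n,
        "scenario2_fraction": sum(s.scenario == "2" for s in scenarios) / n,
    }


def _chains_table(result: TissueChains, element_map, tissue: str) -> pd.DataFrame:
    rows = []
    for c in result.chains:
        gene_id = element_map[c.promoter_id].gene_id
        for rank, eid in enumerate(c.enhancers, start=1):
            iv = element_map[eid].interval
            rows.append(
                (c.chain_id, tissue, c.promoter_id, gene_id, rank, eid,
                 iv.chrom, iv.start, iv.end)
            )
    return pd.DataFrame(
        rows,
        columns=["chain_id", "tissue", "promoter_id", "gene_id", "rank",
                 "element_id", "chrom", "start", "end"],
    )


def _validate_chains_table(table: pd.DataFrame) -> None:
    """Re-assert chain invariants at write time: ranks are 1..n per chain."""
    for (tissue, chain_id), sub in table.groupby(["tissue", "chain_id"]):
        ranks = sorted(sub["rank"])
        if ranks != list(range(1, len(ranks) + 1)):
            raise AssertionError(
                f"chain {chain_id} ({tissue}) has inconsistent ranks {ranks}"
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_report(report: RunReport, directory: str | Path) -> list[Path]:
    """Write the JSON summary and one TSV per table; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    summary = {
        "schema_version": report.schema_version,
        "config": _jsonable(report.config),
        "sections": _jsonable(report.sections),
    }
    path = directory / "report.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1)
    written.append(path)
    for name, table in report.tables.items():
        if name == "chains" and len(table):
            _validate_chains_table(table)
        tsv = directory / f"{name}.tsv"
        table.to_csv(tsv, sep="\t", index=False)
        written.append(tsv)
    return written
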