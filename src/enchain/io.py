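"""Readers and writers for the plain-text genomic formats the pipeline uses.

All tabular IO goes through pandas.  BED files are 0-based half-open;
eQTL positions are read as 1-based and converted to 0-based on input.
Contact lists may be gzipped (pandas handles compression by extension).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .elements import GeneRecord, GenomicInterval, RegulatoryElement

CONTACT_COLUMNS = ["chrom", "bin_i", "bin_j", "count"]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; strand (column 6) is kept when present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    intervals = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) >= 6 and row[5] in ("+", "-") else None
        intervals.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        name = names[i] if names is not None else f"iv{i}"
        rows.append((iv.chrom, iv.start, iv.end, name, 0, iv.strand or "."))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_elements_bed(elements: Sequence[RegulatoryElement], path: str | Path) -> None:
    """Write elements as BED6 (name = element_id, strand only for promoters)."""
    rows = [
        (
            el.interval.chrom,
            el.interval.start,
            el.interval.end,
            el.element_id,
            0,
            (el.interval.strand or ".") if el.is_promoter else ".",
        )
        for el in elements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_motifs_bed(path: str | Path, factor: str = "CTCF") -> pd.DataFrame:
    """Read stranded, scored motif sites from BED6 into a tidy frame."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    df["factor"] = factor
    return df


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Tab-delimited gene table: gene_id, chrom, tss, strand, rpkm."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand), float(r.rpkm))
        for r in df.itertuples(index=False)
    ]


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand, g.rpkm) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand", "rpkm"],
    ).to_csv(path, sep="\t", index=False)


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Raw 5-kb contact list: chrom, bin_i, bin_j, count (GSE63525-style dump)."""
    df = pd.read_csv(path, sep="\t", header=None, names=CONTACT_COLUMNS, comment="#")
    df["bin_i"] = df["bin_i"].astype(int)
    df["bin_j"] = df["bin_j"].astype(int)
    # normalise orientation so bin_i < bin_j, drop the diagonal
    swap = df["bin_i"] > df["bin_j"]
    df.loc[swap, ["bin_i", "bin_j"]] = df.loc[swap, ["bin_j", "bin_i"]].to_numpy()
    df = df[df["bin_i"] != df["bin_j"]].reset_index(drop=True)
    return df


def write_contacts(contacts: pd.DataFrame, path: str | Path) -> None:
    contacts[CONTACT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """BEDPE anchor pairs (loops): chrom1,start1,end1,chrom2,start2,end2[,name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    return df


def write_bedpe(loops: pd.DataFrame, path: str | Path) -> None:
    loops.to_csv(path, sep="\t", header=False, index=False)


def read_eqtls(path: str | Path) -> pd.DataFrame:
    """eQTL extract: chrom, pos (1-based), gene_id, tissue -> 0-based ``pos0``."""
    df = pd.read_csv(path, sep="\t")
    df["pos0"] = df["pos"].astype(int) - 1
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x tissue RPKM matrix, genes as rows indexed by gene_id."""
    return pd.read_csv(path, sep="\t", index_col=0)
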