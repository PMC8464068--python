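"""Readers and writers for the plain-text formats the pipeline consumes.

BED and narrowPeak follow UCSC/ENCODE conventions (0-based half-open;
narrowPeak column 9 is the -log10 q-value).  The gene table is a TSV with
columns symbol, chrom, strand, tss and a comma-separated ``start-end`` exon
list.  TAD ensembles are BED3 files referenced from a manifest TSV with
columns dataset_id, window, path.  Activity matrices are TSV tables with a
``region_id`` index column and one column per cell type.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .regions import GeneAnnotation, Interval, Peak

__all__ = [
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "read_gene_table",
    "write_gene_table",
    "read_tad_manifest",
    "read_activity_matrix",
    "write_activity_matrix",
    "read_bedgraph",
    "read_washu_interactions",
]


def read_bed(path: str) -> list[Interval]:
    """Read BED3/BED6; strand taken from column 6 when present."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            out.append(Interval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(path: str, intervals: Sequence[Interval], names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else str(i + 1)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand in '+-' else '.'}\n")


def read_narrowpeak(path: str) -> list[Peak]:
    """Read ENCODE narrowPeak; q-value column (9, 1-based) as -log10."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: narrowPeak needs >=9 columns, got {len(f)}")
            strand = f[5] if f[5] in "+-" else "."
            q = float(f[8])
            # MACS writes -1 for 'not computed'; treat as 0 evidence
            peaks.append(Peak(Interval(f[0], int(f[1]), int(f[2]), strand), max(q, 0.0)))
    return peaks


def _parse_exons(spec: str, chrom: str) -> tuple[Interval, ...]:
    if not spec or spec == ".":
        return ()
    out = []
    for token in spec.split(","):
        s, e = token.split("-")
        out.append(Interval(chrom, int(s), int(e)))
    return tuple(out)


def read_gene_table(path: str) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "strand": str})
    required = {"symbol", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        exons = _parse_exons(getattr(row, "exons", "."), row.chrom)
        genes.append(GeneAnnotation(row.symbol, row.chrom, int(row.tss), row.strand, exons))
    return genes


def write_gene_table(path: str, genes: Sequence[GeneAnnotation]) -> None:
    rows = []
    for g in genes:
        exons = ",".join(f"{e.start}-{e.end}" for e in g.exons) or "."
        rows.append((g.symbol, g.chrom, g.strand, g.tss, exons))
    pd.DataFrame(rows, columns=["symbol", "chrom", "strand", "tss", "exons"]).to_csv(
        path, sep="\t", index=False
    )


def read_tad_manifest(path: str) -> list[tuple[str, int, list[Interval]]]:
    """Read a manifest TSV (dataset_id, window, path) plus the BEDs it lists.

    Relative paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "path": str})
    missing = {"dataset_id", "window", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(path))
    out = []
    for row in df.itertuples(index=False):
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        out.append((row.dataset_id, int(row.window), read_bed(p)))
    return out


def read_activity_matrix(path: str) -> pd.DataFrame:
    """Region x cell-type TSV with a region_id index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no cell-type columns")
    return df


def write_activity_matrix(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="region_id")


def read_bedgraph(path: str) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into the chrom -> (start, end, value) block map used
    by the activity module."""
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            track.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    return track


def _parse_washu_anchor(token: str) -> Interval:
    chrom, rest = token.split(":")
    s, e = rest.replace(",", "").split("-")
    return Interval(chrom, int(s), int(e))


def read_washu_interactions(path: str) -> list[tuple[Interval, Interval, float]]:
    """washU-style pairs: ``chr:start-end  chr:start-end  score`` per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            score = float(f[2]) if len(f) > 2 else float("nan")
            out.append((_parse_washu_anchor(f[0]), _parse_washu_anchor(f[1]), score))
    return out
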