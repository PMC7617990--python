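"""Cell × feature counting, feature classification, and table export.

Counts are numbers of collapsed molecules (one consensus record per UMI
group), never raw reads.  Features are classified by interval overlap
against a repeat annotation (BED) and a gene/isoform annotation (GTF):

* overlaps a known isoform only            → gene
* overlaps a repeat only                   → TE
* overlaps both repeat and exonic gene     → TE_isoform
* overlaps nothing                         → unassigned

Coordinates are normalised internally to 0-based half-open (BED native;
GTF 1-based closed converted on read).  Overlap is strand-aware by default.
Exports: a long-format table and a MatrixMarket sparse triple
(matrix.mtx + features.tsv + cells.tsv) for single-cell toolchains.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from intervaltree import IntervalTree

FEATURE_CLASSES = ("gene", "TE", "TE_isoform", "unassigned")


class AnnotationParseError(ValueError):
    pass


def read_bed(path) -> pd.DataFrame:
    """Read BED (0-based half-open) into chrom/start/end/name/strand."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationParseError(f"{path}:{ln}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{ln}: non-integer coordinate") from exc
            rows.append({
                "chrom": parts[0], "start": start, "end": end,
                "name": parts[3] if len(parts) > 3 else f"bed{ln}",
                "strand": parts[5] if len(parts) > 5 else ".",
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path, feature_types: tuple[str, ...] = ("exon",)) -> pd.DataFrame:
    """Read GTF (1-based closed → converted to 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise AnnotationParseError(f"{path}:{ln}: expected 9 GTF fields")
            if parts[2] not in feature_types:
                continue
            try:
                start, end = int(parts[3]) - 1, int(parts[4])
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{ln}: non-integer coordinate") from exc
            attrs = dict(_ATTR_RE.findall(parts[8]))
            rows.append({
                "chrom": parts[0], "start": start, "end": end,
                "strand": parts[6], "feature_type": parts[2],
                "gene_id": attrs.get("gene_id", ""),
                "transcript_id": attrs.get("transcript_id", ""),
            })
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "feature_type",
                 "gene_id", "transcript_id"],
    )


def _build_trees(df: pd.DataFrame, stranded: bool) -> dict:
    trees: dict = {}
    for _, row in df.iterrows():
        key = (row["chrom"], row["strand"]) if stranded else row["chrom"]
        trees.setdefault(key, IntervalTree()).addi(row["start"], row["end"], row)
    return trees


def _overlap_amount(tree_map: dict, chrom, start, end, strand, stranded) -> int:
    keys = [(chrom, strand)] if stranded else [chrom]
    best = 0
    for key in keys:
        tree = tree_map.get(key)
        if tree is None:
            continue
        for iv in tree.overlap(start, end):
            best = max(best, min(end, iv.end) - max(start, iv.begin))
    return best


def classify_features(
    feature_loci: pd.DataFrame,
    repeats: pd.DataFrame,
    genes: pd.DataFrame,
    min_overlap: int | float = 1,
    stranded: bool = True,
) -> pd.Series:
    """Assign gene / TE / TE_isoform / unassigned labels to feature loci.

    ``feature_loci`` needs feature_id/chrom/start/end/strand (0-based
    half-open); ``repeats`` from read_bed; ``genes`` from read_gtf (exons).
    ``min_overlap`` is a bp count, or a fraction of the feature length when
    < 1.  Classification is independent of annotation row order.
    """
    rtrees = _build_trees(repeats, stranded)
    gtrees = _build_trees(genes, stranded)
    labels = {}
    for _, row in feature_loci.iterrows():
        length = row["end"] - row["start"]
        need = min_overlap if min_overlap >= 1 else max(1, int(np.ceil(min_overlap * length)))
        r_ov = _overlap_amount(rtrees, row["chrom"], row["start"], row["end"],
                               row["strand"], stranded) >= need
        g_ov = _overlap_amount(gtrees, row["chrom"], row["start"], row["end"],
                               row["strand"], stranded) >= need
        if r_ov and g_ov:
            label = "TE_isoform"
        elif r_ov:
            label = "TE"
        elif g_ov:
            label = "gene"
        else:
            label = "unassigned"
        labels[row["feature_id"]] = label
    return pd.Series(labels, name="feature_class")


def count_molecules(
    consensus_table: pd.DataFrame, cells: list[str] | None = None
) -> pd.DataFrame:
    """Cell × feature matrix of collapsed molecules.

    ``consensus_table`` has one row per consensus record with columns
    (cell, feature_id).  Cells passed explicitly keep all-zero columns.
    The matrix total equals the number of records with assigned features.
    """
    tab = consensus_table.dropna(subset=["feature_id"])
    tab = tab[tab["feature_id"] != ""]
    counts = (
        tab.groupby(["feature_id", "cell"]).size().unstack(fill_value=0)
    )
    if cells is not None:
        counts = counts.reindex(columns=cells, fill_value=0)
    return counts.sort_index()


def merge_counts_annotations(
    counts: pd.DataFrame,
    labels: pd.Series,
    loci: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-format (feature, cell, count, class, locus) table.

    Features missing from ``loci`` are flagged with class retained and
    locus fields empty -- never dropped silently.
    """
    loci_idx = loci.set_index("feature_id") if loci is not None else None
    rows = []
    for feature in counts.index:
        label = labels.get(feature, "unassigned")
        if loci_idx is not None and feature in loci_idx.index:
            loc = loci_idx.loc[feature]
            chrom, start, end, strand = loc["chrom"], loc["start"], loc["end"], loc["strand"]
            flagged = False
        else:
            chrom, start, end, strand = "", -1, -1, ".",
            flagged = loci is not None
        for cell in counts.columns:
            rows.append({
                "feature_id": feature, "cell": cell,
                "count": int(counts.loc[feature, cell]),
                "feature_class": label,
                "chrom": chrom, "start": start, "end": end, "strand": strand,
                "missing_locus": flagged,
            })
    return pd.DataFrame(rows)


def export_sparse(counts: pd.DataFrame, out_dir) -> None:
    """Write MatrixMarket matrix.mtx + features.tsv + cells.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(counts.to_numpy())
    scipy.io.mmwrite(str(out_dir / "matrix.mtx"), mat)
    pd.Series(counts.index).to_csv(out_dir / "features.tsv", sep="\t",
                                   index=False, header=False)
    pd.Series(counts.columns).to_csv(out_dir / "cells.tsv", sep="\t",
                                     index=False, header=False)


def import_sparse(out_dir) -> pd.DataFrame:
    out_dir = Path(out_dir)
    mat = scipy.io.mmread(str(out_dir / "matrix.mtx")).toarray().astype(int)
    features = pd.read_csv(out_dir / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(out_dir / "cells.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=features.to_list(), columns=cells.to_list())
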