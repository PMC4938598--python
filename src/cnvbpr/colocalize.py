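"""Gene colocalization of altered regions and breakpoint regions.

Overlap is computed on 1-based inclusive spans; a single shared base pair
counts.  Every interval falls in exactly one location category:
``intragenic`` (entirely inside at least one gene span), ``intergenic``
(overlapping no gene), or ``overlapping`` (straddling a gene boundary).
Overlapping transcripts are assumed to be flattened to gene spans by the
annotation; isoform structure is ignored.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .bpr import BprCatalog, round_half_up
from .cna import AlteredRegion
from .io import GeneAnnotation

CATEGORIES = ("intragenic", "overlapping", "intergenic")


def _gene_trees(genes: GeneAnnotation) -> dict[int, IntervalTree]:
    """Per-chromosome interval trees over gene spans (inclusive -> half-open)."""
    trees: dict[int, IntervalTree] = {}
    for row in genes.df.itertuples():
        trees.setdefault(int(row.chrom), IntervalTree()).addi(
            row.start, row.end + 1, row.Index)
    return trees


def affected_genes(regions: Sequence[AlteredRegion],
                   genes: GeneAnnotation) -> pd.DataFrame:
    """Per-gene hit table: which groups' altered regions touch each gene.

    A gene is affected by a group iff at least one of that group's regions
    overlaps its span by >= 1 bp.  Output columns: gene id/name/coords, one
    0/1 flag per group, the total number of affected groups, and the
    tumor-associated flag.
    """
    trees = _gene_trees(genes)
    groups = sorted({r.group for r in regions})
    flags = {g: [0] * len(genes.df) for g in groups}
    for r in regions:
        tree = trees.get(int(r.chrom))
        if tree is None:
            continue
        for hit in tree.overlap(r.start_pos, r.end_pos + 1):
            flags[r.group][hit.data] = 1
    out = genes.df[["gene_id", "gene_name", "chrom", "start", "end"]].copy()
    for g in groups:
        out[g] = flags[g]
    out["n_affected_groups"] = out[groups].sum(axis=1) if groups else 0
    out["tumor_associated"] = genes.df["tumor_associated"].to_numpy()
    return out


def categorize_interval(chrom: int, start: int, end: int,
                        genes: GeneAnnotation | Mapping[int, IntervalTree]) -> str:
    """Location category of one 1-based inclusive interval."""
    trees = genes if isinstance(genes, dict) else _gene_trees(genes)
    tree = trees.get(int(chrom))
    hits = tree.overlap(start, end + 1) if tree is not None else set()
    if not hits:
        return "intergenic"
    if any(h.begin <= start and h.end - 1 >= end for h in hits):
        return "intragenic"
    return "overlapping"


def location_summary(intervals: Iterable[tuple[str, int, int, int]],
                     genes: GeneAnnotation) -> pd.DataFrame:
    """Per-group percentages of the three location categories.

    ``intervals`` yields (group, chrom, start, end) tuples; one interval
    may be attributed to several groups by listing it once per group.
    Percentages per group sum to 100 (up to display rounding).
    """
    trees = _gene_trees(genes)
    tallies: dict[str, dict[str, int]] = {}
    for group, chrom, start, end in intervals:
        cat = categorize_interval(chrom, start, end, trees)
        tallies.setdefault(group, {c: 0 for c in CATEGORIES})[cat] += 1
    rows = []
    for group in sorted(tallies):
        t = tallies[group]
        total = sum(t.values())
        rows.append({"group": group, "n_intervals": total,
                     **{f"pct_{c}": round_half_up(100.0 * t[c] / total, 2)
                        for c in CATEGORIES}})
    return pd.DataFrame(rows, columns=["group", "n_intervals",
                                       *(f"pct_{c}" for c in CATEGORIES)])


def catalog_intervals(catalog: BprCatalog) -> Iterable[tuple[str, int, int, int]]:
    """Attribute each catalog BPR to every group with at least one carrier."""
    for _, row in catalog.df.iterrows():
        for g in catalog.groups:
            if row.get(f"count_{g}", 0) > 0:
                yield g, int(row["chrom"]), int(row["start"]), int(row["end"])


def region_intervals(regions: Sequence[AlteredRegion]) -> Iterable[tuple[str, int, int, int]]:
    for r in regions:
        yield r.group, r.chrom, r.start_pos, r.end_pos
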