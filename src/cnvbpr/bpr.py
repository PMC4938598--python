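"""Breakpoint-region (BPR) detection, aggregation, classification, hotspots.

A BPR is the genomic stretch between the last probe of one segment and the
first probe of the next whenever the two segment means differ by more than
``jump_threshold`` log2 units (default 0.6, about one copy).  The true
breakpoint lies somewhere inside that stretch.  BPRs are matched across
samples by their exact probe-pair boundary (all samples share one array
layout), tallied per group, and classified by recurrence:

1. entity-specific  — >= 1% of samples in exactly one tumor entity
                       (regardless of the normal frequency);
2. cancer-specific  — >= 1% in at least a quarter of the entities and
                       < 0.5% of normal samples;
3. common           — >= 1% in at least a quarter of the entities and
                       >= 0.5% of normal samples;
4. none             — < 1% in every tumor entity.

A BPR with a noticeable occurrence frequency (NOF) reaches >= 10% in at
least one tumor entity or the normal group.  Classification operates on
unrounded frequencies; rounding (half away from zero, 2 decimals) is
display-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import SegmentationProfile

logger = logging.getLogger("cnvbpr.bpr")


@dataclass
class BprParams:
    """Thresholds of BPR detection and classification.

    jump_threshold is a strict cut on the adjacent segment-mean difference;
    the frequency cuts are inclusive and in percent.  hotspot_gap (bp) and
    hotspot_min_members control adjacency clustering of catalog intervals.
    """

    jump_threshold: float = 0.6
    class_entity_freq: float = 1.0
    class_entity_fraction: float = 0.25
    class_normal_freq: float = 0.5
    nof_freq: float = 10.0
    hotspot_gap: int = 100_000
    hotspot_min_members: int = 2

    def __post_init__(self) -> None:
        if self.jump_threshold <= 0:
            raise ValueError("jump_threshold must be > 0")
        for name in ("class_entity_freq", "class_normal_freq", "nof_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100]")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (how frequency tables are printed)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Per-sample detection
# ---------------------------------------------------------------------------

def detect_bprs(profile: SegmentationProfile,
                params: BprParams) -> list[tuple[int, int, int]]:
    """BPR intervals of one sample: (chrom, start_pos, end_pos) tuples.

    start_pos is the last probe of the left segment, end_pos the first
    probe of the right segment; the mean difference must exceed the
    threshold strictly.  Duplicate intervals within a sample count once.
    """
    found: set[tuple[int, int, int]] = set()
    for chrom, segs in profile.segments.items():
        for left, right in zip(segs[:-1], segs[1:]):
            if abs(left.mean - right.mean) > params.jump_threshold:
                found.add((chrom, left.end_pos, right.start_pos))
    return sorted(found)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

@dataclass
class BprCatalog:
    """Distinct BPR intervals with per-group counts and metadata.

    ``df`` columns: chrom, start, end, ``count_<group>`` per group,
    cancer_total; frequency/class/NOF columns are added by
    :func:`frequency_table` and :func:`classify_catalog`.
    """

    df: pd.DataFrame
    entities: list[str]
    normal_group: str
    group_sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> list[str]:
        return self.entities + [self.normal_group]


def aggregate_catalog(sample_bprs: Mapping[str, Sequence[tuple[int, int, int]]],
                      groups: Mapping[str, str],
                      group_sizes: Mapping[str, int],
                      normal_group: str = "normal") -> BprCatalog:
    """Tally per-group carriers of each distinct (chrom, start, end) interval.

    Every sample must have a group; the cancer total of an interval is the
    sum of its tumor-entity counts.
    """
    unknown = [s for s in sample_bprs if s not in groups]
    if unknown:
        raise ValueError(f"sample(s) without group assignment: {unknown[:5]}")
    entities = [g for g in group_sizes if g != normal_group]
    counts: dict[tuple[int, int, int], dict[str, int]] = {}
    for sample, intervals in sample_bprs.items():
        g = groups[sample]
        if g not in group_sizes:
            raise ValueError(f"sample {sample!r} has unknown group {g!r}")
        for iv in set(intervals):          # a sample carries an interval once
            counts.setdefault(iv, {k: 0 for k in group_sizes})[g] += 1
    rows = []
    for (chrom, start, end) in sorted(counts):
        c = counts[(chrom, start, end)]
        row = {"chrom": chrom, "start": start, "end": end}
        row.update({f"count_{g}": c[g] for g in entities})
        row[f"count_{normal_group}"] = c[normal_group] if normal_group in c else 0
        row["cancer_total"] = sum(c[g] for g in entities)
        rows.append(row)
    cols = (["chrom", "start", "end"] + [f"count_{g}" for g in entities]
            + [f"count_{normal_group}", "cancer_total"])
    df = pd.DataFrame(rows, columns=cols)
    return BprCatalog(df, entities=entities, normal_group=normal_group,
                      group_sizes=dict(group_sizes))


def frequency_table(catalog: BprCatalog) -> BprCatalog:
    """Add unrounded percent frequencies (100 * count / group size).

    Rounded display values are produced by :func:`catalog_display`.
    """
    df = catalog.df.copy()
    for g in catalog.groups:
        size = catalog.group_sizes.get(g)
        if not size:
            raise ValueError(f"group {g!r} has zero or missing size")
        df[f"freq_{g}"] = 100.0 * df[f"count_{g}"] / size
    return BprCatalog(df, catalog.entities, catalog.normal_group,
                      dict(catalog.group_sizes))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_bpr(entity_freqs: Sequence[float], normal_freq: float,
                 params: BprParams) -> int:
    """Four-class recurrence rule on unrounded percent frequencies.

    k = number of entities at or above the entity cut.  k = 0 -> class 4;
    k = 1 -> class 1 (the normal frequency is irrelevant); k/n_entities at
    or above the entity fraction -> class 2 if the normal frequency is
    below the normal cut, else class 3.  The remaining cell (k >= 2 but
    below the entity fraction, impossible with eight entities) falls back
    to class 4 with a warning.
    """
    freqs = np.asarray(entity_freqs, dtype=float)
    n_entities = freqs.size
    k = int((freqs >= params.class_entity_freq).sum())
    if k == 0:
        return 4
    if k == 1:
        return 1
    if k / n_entities >= params.class_entity_fraction:
        return 2 if normal_freq < params.class_normal_freq else 3
    logger.warning("BPR with %d/%d qualifying entities falls outside the "
                   "four-class scheme; assigned class 4", k, n_entities)
    return 4


def flag_nof(group_freqs: Sequence[float], params: BprParams) -> bool:
    """True iff any tumor entity or the normal group reaches the NOF cut."""
    return bool((np.asarray(group_freqs, dtype=float) >= params.nof_freq).any())


def classify_catalog(catalog: BprCatalog, params: BprParams) -> BprCatalog:
    """Add ``bpr_class`` and ``nof`` columns to a frequency-annotated catalog."""
    df = catalog.df.copy()
    ef = df[[f"freq_{g}" for g in catalog.entities]].to_numpy(float)
    nf = df[f"freq_{catalog.normal_group}"].to_numpy(float)
    df["bpr_class"] = [classify_bpr(ef[i], nf[i], params) for i in range(len(df))]
    df["nof"] = [flag_nof(np.append(ef[i], nf[i]), params) for i in range(len(df))]
    return BprCatalog(df, catalog.entities, catalog.normal_group,
                      dict(catalog.group_sizes))


def catalog_display(catalog: BprCatalog) -> pd.DataFrame:
    """Display table with frequencies rounded half away from zero, 2 dp."""
    df = catalog.df.copy()
    for g in catalog.groups:
        col = f"freq_{g}"
        if col in df.columns:
            df[col] = df[col].map(lambda v: round_half_up(v, 2))
    return df


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

def find_hotspots(catalog: BprCatalog, params: BprParams) -> pd.DataFrame:
    """Cluster catalog intervals whose gaps are at most ``hotspot_gap`` bp.

    Clusters with at least ``hotspot_min_members`` distinct BPRs are
    reported with their span, member count and total carrier count
    (cancer + normal).
    """
    df = catalog.df.sort_values(["chrom", "start", "end"])
    carrier_cols = [f"count_{g}" for g in catalog.groups
                    if f"count_{g}" in df.columns]
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cluster: list[pd.Series] = []
        span_end = None
        for _, rec in sub.iterrows():
            if cluster and rec["start"] - span_end > params.hotspot_gap:
                rows.append((chrom, cluster, span_end))
                cluster = []
                span_end = None
            cluster.append(rec)
            span_end = max(span_end, rec["end"]) if span_end is not None else rec["end"]
        if cluster:
            rows.append((chrom, cluster, span_end))
    out = []
    for chrom, cluster, span_end in rows:
        if len(cluster) < params.hotspot_min_members:
            continue
        out.append({
            "chrom": int(chrom),
            "start": int(min(r["start"] for r in cluster)),
            "end": int(span_end),
            "n_bprs": len(cluster),
            "total_carriers": int(sum(sum(r[c] for c in carrier_cols)
                                      for r in cluster)),
        })
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_bprs",
                                      "total_carriers"])
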