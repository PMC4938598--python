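"""End-to-end orchestration: ratios -> segmentation -> BPR catalog + CNA
regions -> gene colocalization, deterministic from a single seed.

Each sample is segmented with its own random stream derived from the
global seed and the sample's index, so results do not depend on
processing order and a rerun with the same config and seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .bpr import (BprCatalog, BprParams, aggregate_catalog, catalog_display,
                  classify_catalog, detect_bprs, find_hotspots, frequency_table)
from .cna import (AlteredRegion, CnaParams, call_altered_regions,
                  entity_mean_profile, regions_to_frame)
from .colocalize import (affected_genes, catalog_intervals, location_summary,
                         region_intervals)
from .reference import build_reference, ratio_matrix
from .segmentation import (SegmentationParams, SegmentationProfile,
                           profile_to_frame, segment_sample)

logger = logging.getLogger("cnvbpr.pipeline")


@dataclass
class PipelineConfig:
    """Validated run configuration (paths, group table, stage parameters)."""

    probe_map: str
    signals: str
    group_table: str                       # TSV: sample_id <tab> group
    reference: str | None = None           # intensity TSV of reference samples
    ratio_scale: bool = False              # signals are already log2 ratios
    genes: str | None = None
    tumor_gene_list: str | None = None
    out_dir: str = "results"
    normal_group: str = "normal"
    allele_suffixes: tuple[str, str] | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cna: CnaParams = field(default_factory=CnaParams)
    bpr: BprParams = field(default_factory=BprParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (("segmentation", SegmentationParams),
                           ("cna", CnaParams), ("bpr", BprParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if raw.get("allele_suffixes") is not None:
            raw["allele_suffixes"] = tuple(raw["allele_suffixes"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("probe_map", "signals", "group_table", "reference",
                     "genes", "tumor_gene_list"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if not self.ratio_scale and self.reference is None:
            raise ValueError("intensity-scale signals require a reference")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    profiles: list[SegmentationProfile]
    segments: pd.DataFrame
    catalog: BprCatalog
    regions: list[AlteredRegion]
    hotspots: pd.DataFrame
    gene_table: pd.DataFrame | None = None
    locations: pd.DataFrame | None = None


def read_group_table(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("group table needs columns sample_id and group")
    return dict(zip(df["sample_id"], df["group"]))


def analyze_cohort(ratios: cio.SignalMatrix, groups: Mapping[str, str],
                   seg_params: SegmentationParams, cna_params: CnaParams,
                   bpr_params: BprParams, seed: int = 0,
                   normal_group: str = "normal") -> ResultBundle:
    """Run segmentation, BPR cataloguing and CNA calling on a ratio matrix.

    ``groups`` must assign every sample to exactly one group; group sizes
    are taken from the assignment itself.
    """
    if ratios.scale != "ratio":
        raise ValueError("analyze_cohort expects a ratio-scale matrix")
    missing = [s for s in ratios.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"sample(s) without group assignment: {missing[:5]}")

    group_sizes: dict[str, int] = {}
    for s in ratios.sample_ids:
        group_sizes[groups[s]] = group_sizes.get(groups[s], 0) + 1
    if normal_group not in group_sizes:
        raise ValueError(f"no samples in normal group {normal_group!r}")

    t0 = time.time()
    profiles: list[SegmentationProfile] = []
    for idx, sid in enumerate(ratios.sample_ids):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))
        profiles.append(segment_sample(sid, ratios.values[idx], ratios.probe_map,
                                       seg_params, rng=rng))
    logger.info("segmented %d samples in %.1fs", len(profiles), time.time() - t0)

    segments = pd.concat([profile_to_frame(p) for p in profiles],
                         ignore_index=True)

    sample_bprs = {p.sample_id: detect_bprs(p, bpr_params) for p in profiles}
    catalog = aggregate_catalog(sample_bprs, dict(groups), group_sizes,
                                normal_group=normal_group)
    catalog = classify_catalog(frequency_table(catalog), bpr_params)
    hotspots = find_hotspots(catalog, bpr_params)

    regions: list[AlteredRegion] = []
    by_group: dict[str, list[SegmentationProfile]] = {}
    for p in profiles:
        by_group.setdefault(groups[p.sample_id], []).append(p)
    for g in sorted(by_group):
        prof = entity_mean_profile(by_group[g], ratios.probe_map)
        regions.extend(call_altered_regions(prof, ratios.probe_map,
                                            cna_params, group=g))
    return ResultBundle(profiles=profiles, segments=segments, catalog=catalog,
                        regions=regions, hotspots=hotspots)


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute all stages of a configured run and write the result tables."""
    config.validate()
    pm = cio.read_probe_map(config.probe_map)
    groups = read_group_table(config.group_table)
    matrix = cio.read_signal_matrix(
        config.signals, pm, allele_suffixes=config.allele_suffixes,
        scale="ratio" if config.ratio_scale else "intensity")
    missing = [s for s in matrix.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"sample(s) without group assignment: {missing[:5]}")

    if config.ratio_scale:
        ratios = matrix
        ratio_source = "input"
    else:
        ref_matrix = cio.read_signal_matrix(config.reference, pm,
                                            allele_suffixes=config.allele_suffixes)
        ratios = ratio_matrix(matrix, build_reference(ref_matrix))
        ratio_source = "reference"

    bundle = analyze_cohort(ratios, groups, config.segmentation, config.cna,
                            config.bpr, seed=config.seed,
                            normal_group=config.normal_group)

    if config.genes is not None:
        annotation = cio.read_gene_annotation(
            config.genes, tumor_gene_list=config.tumor_gene_list)
        bundle.gene_table = affected_genes(bundle.regions, annotation)
        intervals = list(catalog_intervals(bundle.catalog))
        bundle.locations = location_summary(intervals, annotation)

    out = cio.ensure_out_dir(config.out_dir)
    cio.write_segments_tsv(bundle.segments, out / "segments.tsv")
    cio.write_intervals_bed(bundle.segments, out / "segments.bed",
                            name_col="sample_id")
    reg_df = regions_to_frame(bundle.regions)
    cio.write_table(reg_df, out / "altered_regions.tsv")
    if len(reg_df):
        cio.write_intervals_bed(reg_df, out / "altered_regions.bed",
                                name_col="type")
    cio.write_table(catalog_display(bundle.catalog), out / "bpr_catalog.tsv")
    cio.write_intervals_bed(bundle.catalog.df, out / "bpr_catalog.bed",
                            score_col="cancer_total")
    cio.write_table(bundle.hotspots, out / "hotspots.tsv")
    if bundle.gene_table is not None:
        cio.write_table(bundle.gene_table, out / "affected_genes.tsv")
        cio.write_table(bundle.locations, out / "bpr_locations.tsv")

    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "ratio_source": ratio_source,
                "n_samples": matrix.n_samples, "n_probes": len(pm)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return bundle
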