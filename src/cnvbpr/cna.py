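"""Entity-level copy-number-altered region calling.

Per sample, every probe takes its segment's mean log2 ratio; those
per-probe values are then averaged across all samples of an entity.  On
the averaged profile each probe's deviation from its chromosome's mean is
computed, and maximal runs of consecutive probes deviating by at least
+threshold (gain) or at most -threshold (loss) are reported as altered
regions.  The default threshold of 0.1 log2 units is deliberately
permissive: it marks consistent shifts of the cohort average, not
single-sample events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ProbeMap
from .segmentation import SegmentationProfile


@dataclass
class CnaParams:
    """threshold: absolute deviation cut (inclusive); min_markers_per_region:
    shortest run reported."""

    threshold: float = 0.1
    min_markers_per_region: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.min_markers_per_region < 1:
            raise ValueError("min_markers_per_region must be >= 1")


@dataclass
class AlteredRegion:
    group: str
    chrom: int
    start_pos: int
    end_pos: int
    n_markers: int
    mean_deviation: float
    direction: str  # "gain" | "loss"


def expand_profile(profile: SegmentationProfile, probe_map: ProbeMap) -> np.ndarray:
    """Per-probe vector of the sample's segment means, aligned to the map."""
    out = np.empty(len(probe_map))
    out.fill(np.nan)
    for chrom, segs in profile.segments.items():
        sl = probe_map.chrom_slice(chrom)
        base = sl.start
        for seg in segs:
            out[base + seg.start_index: base + seg.end_index + 1] = seg.mean
    if np.isnan(out).any():
        raise ValueError(f"profile {profile.sample_id} does not tile the probe map")
    return out


def entity_mean_profile(profiles: Sequence[SegmentationProfile],
                        probe_map: ProbeMap) -> np.ndarray:
    """Average the per-probe segment means across one group's samples."""
    if not profiles:
        raise ValueError("empty group: no profiles to average")
    acc = np.zeros(len(probe_map))
    for p in profiles:
        acc += expand_profile(p, probe_map)
    return acc / len(profiles)


def _runs(mask: np.ndarray):
    """Maximal runs of True in a boolean vector, as (start, end) inclusive."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    yield from zip(starts, ends)


def call_altered_regions(entity_profile: np.ndarray, probe_map: ProbeMap,
                         params: CnaParams,
                         group: str = "") -> list[AlteredRegion]:
    """Call gain/loss runs against each chromosome's mean.

    deviation_i = value_i - chromosomal mean; runs with deviation >=
    +threshold are gains, <= -threshold losses (both cuts inclusive).
    """
    entity_profile = np.asarray(entity_profile, dtype=float)
    if entity_profile.shape != (len(probe_map),):
        raise ValueError("entity profile not aligned to probe map")
    regions: list[AlteredRegion] = []
    for chrom in probe_map.chromosomes:
        sl = probe_map.chrom_slice(chrom)
        v = entity_profile[sl]
        pos = probe_map.positions(chrom)
        dev = v - v.mean()
        for direction, mask in (("gain", dev >= params.threshold),
                                ("loss", dev <= -params.threshold)):
            for lo, hi in _runs(mask):
                n = hi - lo + 1
                if n < params.min_markers_per_region:
                    continue
                regions.append(AlteredRegion(
                    group=group, chrom=chrom,
                    start_pos=int(pos[lo]), end_pos=int(pos[hi]),
                    n_markers=int(n),
                    mean_deviation=float(dev[lo: hi + 1].mean()),
                    direction=direction))
    regions.sort(key=lambda r: (r.chrom, r.start_pos, r.direction))
    return regions


def regions_to_frame(regions: Sequence[AlteredRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.group, r.chrom, r.direction, r.start_pos, r.end_pos,
          r.n_markers, r.mean_deviation) for r in regions],
        columns=["group", "chrom", "type", "start_pos", "end_pos",
                 "n_markers", "mean_deviation"])
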