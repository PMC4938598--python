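"""Synthetic multi-entity cohorts with planted segments and recurrent BPRs.

The generator emulates the statistical structure the downstream analysis
assumes: per-sample log2-ratio tracks that are piecewise constant around a
zero baseline, with copy-number jumps planted at fixed probe boundaries and
i.i.d. Gaussian probe noise on top.  All samples share one probe layout, so
a planted breakpoint falls on the identical probe pair in every carrier —
exactly the situation in which breakpoint regions recur at matching
coordinates across samples of a cohort.

Each planted event is a shifted segment: the profile jumps up by ``jump``
log2 units after probe ``left_index`` and drops back after
``left_index + length``, producing two breakpoint-region boundaries per
carrier.  Per-group presence probabilities make entity-private, shared and
normal-tissue events expressible, so all four recurrence classes can be
constructed.  What the generator does not attempt: raw allele intensities,
genotyping error, GC waviness, whole-genome baseline shifts, or the
empirical size distribution of real breakpoint regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bpr import round_half_up
from .io import ProbeMap, SignalMatrix

#: Cohort sizes of the study design this generator mirrors by default.
STUDY_GROUP_SIZES = {
    "breast": 377, "colorectal": 189, "gastric": 340, "lung": 291,
    "medulloblastoma": 1104, "ovarian": 207, "prostate": 120, "renal": 109,
}
STUDY_NORMAL_SIZE = 432


@dataclass
class PlantedBpr:
    """One planted copy-number segment and its two breakpoint boundaries.

    The shifted probes are ``left_index + 1 .. left_index + length`` (0-based
    within the chromosome), so the up-jump boundary lies between probes
    ``left_index`` and ``left_index + 1`` and the down-jump boundary between
    ``left_index + length`` and ``left_index + length + 1``.
    """

    chrom: int
    left_index: int
    presence: Mapping[str, float]   # group -> per-sample carrier probability
    jump: float = 1.0               # log2 shift of the planted segment
    length: int = 30                # probes in the shifted segment


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    entities: (name, n_samples) per tumor entity; normal_group likewise.
    The probe layout is shared by all samples: ``probes_per_chrom`` probes
    ``spacing`` bp apart on each of ``n_chromosomes`` autosomes.
    """

    entities: list[tuple[str, int]]
    normal_group: tuple[str, int] = ("normal", 432)
    probes_per_chrom: int = 2000
    n_chromosomes: int = 4
    spacing: int = 1000
    planted_bprs: list[PlantedBpr] = field(default_factory=list)
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in list(self.entities) + [self.normal_group]:
            if n < 1:
                raise ValueError(f"group {name!r} must have n_samples >= 1")
        spans: dict[int, list[tuple[int, int]]] = {}
        for b in self.planted_bprs:
            if b.jump <= 0:
                raise ValueError("jump magnitudes must be > 0")
            if b.length < 1:
                raise ValueError("planted segment length must be >= 1")
            for p in b.presence.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("presence probabilities must be in [0, 1]")
            if not 1 <= b.chrom <= self.n_chromosomes:
                raise ValueError(f"planted BPR on unknown chromosome {b.chrom}")
            if b.left_index < 0 or b.left_index + b.length + 1 >= self.probes_per_chrom:
                raise ValueError("planted segment does not fit inside its chromosome")
            spans.setdefault(b.chrom, []).append(
                (b.left_index, b.left_index + b.length + 1))
        for chrom, ss in spans.items():
            ss.sort()
            for (s1, e1), (s2, e2) in zip(ss[:-1], ss[1:]):
                if s2 <= e1:   # overlapping or touching spans blur the truth
                    raise ValueError(
                        f"planted spans overlap on chromosome {chrom}: "
                        f"({s1},{e1}) vs ({s2},{e2})")

    @property
    def groups(self) -> list[tuple[str, int]]:
        return list(self.entities) + [self.normal_group]

    def probe_map(self) -> ProbeMap:
        return ProbeMap.regular(self.n_chromosomes, self.probes_per_chrom,
                                self.spacing)


def study_cohort_spec(scale: float = 1.0, **kwargs) -> CohortSpec:
    """A spec mirroring the study's eight entities and normal group.

    ``scale`` shrinks every group proportionally (minimum 1 sample) for
    fast tests; the full-size design is ``scale=1``.
    """
    entities = [(g, max(1, round(n * scale))) for g, n in STUDY_GROUP_SIZES.items()]
    normal = ("normal", max(1, round(STUDY_NORMAL_SIZE * scale)))
    return CohortSpec(entities=entities, normal_group=normal, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth of one simulated cohort.

    events: one row per (sample, planted event) with the carried segment.
    boundaries: two rows per planted event (up and down jump) giving the
    exact probe-pair interval a perfect detector would report.
    realized_counts: per (event, group) carrier tallies.
    """

    events: pd.DataFrame
    boundaries: pd.DataFrame
    realized_counts: pd.DataFrame
    groups: dict[str, int]
    normal_group: str


def simulate_cohort(spec: CohortSpec) -> tuple[SignalMatrix, GroundTruth]:
    """Draw a cohort of ratio-scale tracks plus its planted truth.

    For each sample every planted event is independently present with its
    group's probability; carriers shift by the jump magnitude over the
    planted span.  Gaussian noise is added everywhere.  Fully reproducible
    from ``spec.seed``: group order, then per-event presence draws, then
    noise, in a fixed sequence.
    """
    rng = np.random.default_rng(spec.seed)
    pm = spec.probe_map()
    n_probes = len(pm)
    sample_ids: list[str] = []
    values = []
    event_rows = []
    counts: dict[tuple[int, str], int] = {}

    for group, n in spec.groups:
        presence = {bi: rng.random(n) < b.presence.get(group, 0.0)
                    for bi, b in enumerate(spec.planted_bprs)}
        noise = (rng.normal(0.0, spec.noise_sd, size=(n, n_probes))
                 if spec.noise_sd > 0 else np.zeros((n, n_probes)))
        for i in range(n):
            sid = f"{group}_{i:04d}"
            sample_ids.append(sid)
            track = noise[i]
            for bi, b in enumerate(spec.planted_bprs):
                counts.setdefault((bi, group), 0)
                if not presence[bi][i]:
                    continue
                counts[(bi, group)] += 1
                base = pm.chrom_slice(b.chrom).start
                lo = base + b.left_index + 1
                track[lo: lo + b.length] += b.jump
                event_rows.append((sid, group, bi, b.chrom, b.left_index,
                                   b.length, b.jump))
            values.append(track)

    matrix = SignalMatrix(sample_ids, np.asarray(values), pm, scale="ratio")

    events = pd.DataFrame(event_rows, columns=[
        "sample_id", "group", "event", "chrom", "left_index", "length", "jump"])
    brows = []
    for bi, b in enumerate(spec.planted_bprs):
        pos = pm.positions(b.chrom)
        for side, left in (("up", b.left_index), ("down", b.left_index + b.length)):
            brows.append((bi, side, b.chrom, int(pos[left]), int(pos[left + 1])))
    boundaries = pd.DataFrame(brows, columns=["event", "side", "chrom",
                                              "start", "end"])
    crows = [(bi, g, counts.get((bi, g), 0))
             for bi in range(len(spec.planted_bprs))
             for g, _ in spec.groups]
    realized = pd.DataFrame(crows, columns=["event", "group", "count"])
    truth = GroundTruth(events=events, boundaries=boundaries,
                        realized_counts=realized,
                        groups={g: n for g, n in spec.groups},
                        normal_group=spec.normal_group[0])
    return matrix, truth


def truth_to_expected_catalog(truth: GroundTruth, spec: CohortSpec) -> pd.DataFrame:
    """Expected BPR frequency table implied by the realized truth.

    One row per planted boundary interval with per-group carrier counts and
    percent frequencies (rounded half away from zero to 2 decimals for
    direct comparison with the pipeline's display catalog).
    """
    counts = truth.realized_counts.pivot(index="event", columns="group",
                                         values="count")
    rows = []
    for _, b in truth.boundaries.iterrows():
        row = {"chrom": int(b["chrom"]), "start": int(b["start"]),
               "end": int(b["end"])}
        for g, n in spec.groups:
            c = int(counts.loc[b["event"], g])
            row[f"count_{g}"] = c
            row[f"freq_{g}"] = round_half_up(100.0 * c / n, 2)
        rows.append(row)
    return (pd.DataFrame(rows)
            .sort_values(["chrom", "start", "end"])
            .reset_index(drop=True))
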