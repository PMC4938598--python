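"""Circular binary segmentation (CBS) of per-sample log2-ratio tracks.

The change-point statistic is the classical circular two-sample t form: for
a stretch of n markers, every circular arc of length k (with both the arc
and its complement holding at least ``min_width`` markers) is scored

    Z(arc) = (mean_arc - mean_complement) / (s * sqrt(1/k + 1/(n-k)))

with s the pooled within-split standard deviation.  The maximal |Z| is
referred to a permutation distribution: the stretch is split where the
permutation p-value of T = max|Z| falls at or below ``alpha``, and the
procedure recurses on the resulting pieces.  Post hoc, change-points whose
adjacent segment means differ by less than ``undo_sd`` noise standard
deviations are removed ("sd-undo" pruning), and isolated outlier markers
are shrunk toward their neighbours before segmentation.

Implementation notes
--------------------
Maximising |Z| is equivalent to maximising the between-split sum of squares
B = k(n-k)/n * (mean_arc - mean_complement)^2, because
Z^2 = (n-2) B / (SS_total - B) with SS_total the (permutation-invariant)
centred total sum of squares.  Internally the scan therefore maximises
|S[j] - S[i]| / sqrt(k(n-k)) over cumulative sums S of the centred data,
which vectorises over all arcs of a given length.  Permutation tests use
exhaustive enumeration when n! does not exceed the permutation budget, and
seeded uniform sampling with an add-one p-value estimate otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("cnvbpr.segmentation")

# MAD-to-sd consistency constant for a normal distribution
_MAD_NORM = 0.6745
_SD_FLOOR = 1e-8


@dataclass
class SegmentationParams:
    """Tuning knobs of the segmentation stage.

    alpha is the split significance level, n_perm the permutation budget per
    split test, min_width the minimal markers per arc candidate and segment,
    undo_sd the sd-undo pruning threshold in noise-sd units.  smooth_region,
    outlier_sd and shrink_sd control outlier smoothing: a marker further
    than outlier_sd noise-sds from every neighbour within +-smooth_region
    markers is pulled to shrink_sd noise-sds of its nearest neighbour value.
    """

    alpha: float = 0.001
    n_perm: int = 10_000
    min_width: int = 4
    undo_sd: float = 0.5
    smooth_region: int = 10
    outlier_sd: float = 4.0
    shrink_sd: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.undo_sd < 0:
            raise ValueError("undo_sd must be >= 0")
        if 1.0 / (1.0 + self.n_perm) > self.alpha:
            logger.warning(
                "n_perm=%d cannot reach alpha=%g under the add-one p-value "
                "convention (minimum attainable p is %.3g); no split will "
                "ever be accepted", self.n_perm, self.alpha,
                1.0 / (1.0 + self.n_perm))


@dataclass
class Segment:
    """A constant-mean run of consecutive markers on one chromosome.

    Marker indices are 0-based within the chromosome and inclusive;
    positions are the base-pair coordinates of the first and last marker.
    """

    chrom: int
    start_index: int
    end_index: int
    start_pos: int
    end_pos: int
    n_markers: int
    mean: float


@dataclass
class SegmentationProfile:
    """All segments of one sample, ordered per chromosome, tiling its markers."""

    sample_id: str
    segments: dict[int, list[Segment]] = field(default_factory=dict)
    noise_sd: dict[int, float] = field(default_factory=dict)

    def all_segments(self):
        for chrom in sorted(self.segments):
            yield from self.segments[chrom]


# ---------------------------------------------------------------------------
# Noise estimation and outlier smoothing
# ---------------------------------------------------------------------------

def estimate_noise_sd(ratios: np.ndarray) -> float:
    """Robust noise sd from lag-1 differences.

    median(|x[i+1]-x[i]|) / (0.6745 * sqrt(2)); robust against true
    change-points, which enter only a handful of the differences.  Floored
    at 1e-8 so noise-free fixtures keep well-defined sd-unit thresholds.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 markers to estimate noise sd")
    sd = float(np.median(np.abs(np.diff(x)))) / (_MAD_NORM * math.sqrt(2.0))
    return max(sd, _SD_FLOOR)


def smooth_outliers(ratios: np.ndarray, params: SegmentationParams,
                    noise_sd: float | None = None) -> np.ndarray:
    """Shrink isolated spikes toward their nearest neighbour value.

    A marker whose smallest distance to any value within +-smooth_region
    markers exceeds ``outlier_sd * sd`` is replaced by that nearest
    neighbour value offset by ``shrink_sd * sd`` toward the original value.
    Genuine short levels survive because their members are mutual
    neighbours.
    """
    x = np.asarray(ratios, dtype=float).copy()
    n = x.size
    if n < 2:
        return x
    sd = estimate_noise_sd(x) if noise_sd is None else noise_sd
    r = params.smooth_region
    out = x.copy()
    for i in range(n):
        lo, hi = max(0, i - r), min(n, i + r + 1)
        neigh = np.concatenate([x[lo:i], x[i + 1:hi]])
        if neigh.size == 0:
            continue
        dist = np.abs(neigh - x[i])
        j = int(np.argmin(dist))
        if dist[j] > params.outlier_sd * sd:
            out[i] = neigh[j] + math.copysign(params.shrink_sd * sd, x[i] - neigh[j])
    return out


# ---------------------------------------------------------------------------
# Maximal circular-arc statistic
# ---------------------------------------------------------------------------

def _rms_scan(prefix: np.ndarray, n: int, min_width: int):
    """Max of |S[j]-S[i]|/sqrt(k(n-k)) over arc lengths k in the allowed range.

    ``prefix`` is the length-(n+1) cumulative sum of the centred data.
    Returns (value, arc_start, arc_end_inclusive) with ties broken by
    smallest start index, then smallest end index (scanning k ascending and
    taking the first argmax within each k realises that order).
    """
    best_v, best_i, best_j = -1.0, -1, -1
    for k in range(min_width, n - min_width + 1):
        d = np.abs(prefix[k:] - prefix[: n - k + 1]) / math.sqrt(k * (n - k))
        i = int(np.argmax(d))
        v = float(d[i])
        j = i + k - 1
        if v > best_v or (v == best_v and (i < best_i or (i == best_i and j < best_j))):
            best_v, best_i, best_j = v, i, j
    return best_v, best_i, best_j


def max_arc_statistic(values: np.ndarray, min_width: int = 4):
    """Maximal |Z| over circular arcs, with the maximising arc.

    Returns ``(T, (arc_start, arc_end))`` with inclusive marker indices, or
    ``None`` ("no test") when fewer than ``2 * min_width`` markers are
    available.  A perfect split (zero within-split variance but distinct
    means) yields ``T = inf``; a constant stretch yields ``T = 0``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return None
    xc = x - x.mean()
    ss_tot = float(xc @ xc)
    prefix = np.concatenate([[0.0], np.cumsum(xc)])
    v, i, j = _rms_scan(prefix, n, min_width)
    if ss_tot <= _degenerate_ss(x) or v <= 0.0:
        return 0.0, (i, j)
    b = n * v * v                     # between-split sum of squares
    w = ss_tot - b
    if w <= 0.0:
        return math.inf, (i, j)
    return math.sqrt((n - 2) * b / w), (i, j)


def _degenerate_ss(x: np.ndarray) -> float:
    """Centred sum-of-squares below this is float residue of a constant."""
    return 1e-20 * max(1.0, float(x @ x))


def _t_to_rms(t_obs: float, ss_tot: float, n: int) -> float:
    """Invert Z back to the internal rms scale sqrt(B/n) for comparisons."""
    if ss_tot <= 0.0:
        return 0.0
    if math.isinf(t_obs):
        b = ss_tot
    else:
        z2 = t_obs * t_obs
        b = ss_tot * z2 / (n - 2 + z2)
    return math.sqrt(b / n)


def _batch_max_rms(rows: np.ndarray, min_width: int) -> np.ndarray:
    """Per-row maximal rms arc statistic for a batch of permuted tracks."""
    m, n = rows.shape
    xc = rows - rows.mean(axis=1, keepdims=True)
    prefix = np.concatenate([np.zeros((m, 1)), np.cumsum(xc, axis=1)], axis=1)
    best = np.zeros(m)
    for k in range(min_width, n - min_width + 1):
        d = np.abs(prefix[:, k:] - prefix[:, : n - k + 1]).max(axis=1)
        np.maximum(best, d / math.sqrt(k * (n - k)), out=best)
    return best


def permutation_pvalue(values: np.ndarray, t_obs: float,
                       params: SegmentationParams,
                       rng: np.random.Generator | None = None) -> float:
    """Permutation p-value of the observed maximal arc statistic.

    When n! fits inside the permutation budget, the reference distribution
    is enumerated exhaustively and p = #{T_perm >= T_obs} / n! (exact and
    deterministic).  Otherwise n_perm uniform permutations are drawn and
    p = (1 + #{T_perm >= T_obs}) / (1 + n_perm); sampling stops early once
    the p-value can no longer fall at or below alpha.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * params.min_width:
        return 1.0
    xc = x - x.mean()
    ss_tot = float(xc @ xc)
    if ss_tot <= _degenerate_ss(x):
        return 1.0
    v_obs = _t_to_rms(t_obs, ss_tot, n)
    # tolerate float round-trip noise in the >= comparison
    thresh = v_obs * (1.0 - 1e-12) - 1e-15

    if math.factorial(n) <= params.n_perm:
        perms = np.array(list(itertools.permutations(x)), dtype=float)
        exceed = int((_batch_max_rms(perms, params.min_width) >= thresh).sum())
        return exceed / len(perms)

    if rng is None:
        rng = np.random.default_rng(params.seed)
    count = 0
    done = 0
    chunk = 128
    while done < params.n_perm:
        m = min(chunk, params.n_perm - done)
        perms = rng.permuted(np.tile(x, (m, 1)), axis=1)
        count += int((_batch_max_rms(perms, params.min_width) >= thresh).sum())
        done += m
        if (1 + count) / (1 + params.n_perm) > params.alpha:
            # cannot reach significance any more
            return (1 + count) / (1 + done)
    return (1 + count) / (1 + params.n_perm)


# ---------------------------------------------------------------------------
# sd-undo pruning
# ---------------------------------------------------------------------------

def _mean_of(values: np.ndarray, lo: int, hi: int) -> float:
    return float(values[lo: hi + 1].mean())


def sd_undo(segments: list[Segment], values: np.ndarray, undo_sd: float,
            noise_sd: float) -> list[Segment]:
    """Remove change-points whose mean jump is below ``undo_sd * noise_sd``.

    The weakest boundary (smallest adjacent |mean difference|) is merged
    first and the merged mean recomputed from the data; this repeats until
    every remaining adjacent pair differs by at least the threshold.
    """
    segs = list(segments)
    if not segs:
        return segs
    threshold = undo_sd * noise_sd
    while len(segs) > 1:
        gaps = [abs(segs[i + 1].mean - segs[i].mean) for i in range(len(segs) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] >= threshold:
            break
        a, b = segs[i], segs[i + 1]
        merged = Segment(
            chrom=a.chrom,
            start_index=a.start_index, end_index=b.end_index,
            start_pos=a.start_pos, end_pos=b.end_pos,
            n_markers=a.n_markers + b.n_markers,
            mean=_mean_of(values, a.start_index, b.end_index),
        )
        segs[i: i + 2] = [merged]
    return segs


# ---------------------------------------------------------------------------
# Recursive segmentation of one chromosome
# ---------------------------------------------------------------------------

def _find_boundaries(x: np.ndarray, lo: int, hi: int,
                     params: SegmentationParams,
                     rng: np.random.Generator) -> list[int]:
    """Significant internal change-points of x[lo:hi], as global indices."""
    n = hi - lo
    if n < 2 * params.min_width:
        return []
    res = max_arc_statistic(x[lo:hi], params.min_width)
    if res is None:
        return []
    t_obs, (i, j) = res
    p = permutation_pvalue(x[lo:hi], t_obs, params, rng)
    if p > params.alpha:
        return []
    # arc [i, j] inclusive -> candidate cut points before i and after j
    cuts = []
    if i > 0:
        cuts.append(i)
    if j + 1 < n:
        cuts.append(j + 1)
    # drop a cut that would strand an edge piece shorter than min_width
    cuts = [c for c in cuts if c >= params.min_width and n - c >= params.min_width]
    if not cuts:
        return []
    bounds: list[int] = []
    prev = lo
    for c in cuts:
        bounds.extend(_find_boundaries(x, prev, lo + c, params, rng))
        bounds.append(lo + c)
        prev = lo + c
    bounds.extend(_find_boundaries(x, prev, hi, params, rng))
    return bounds


def segment_chromosome(ratios: np.ndarray, positions: np.ndarray,
                       params: SegmentationParams,
                       chrom: int = 0,
                       rng: np.random.Generator | None = None,
                       noise_sd: float | None = None) -> list[Segment]:
    """Segment one chromosome's ordered log2 ratios into constant-mean runs.

    Recursively splits at significant maximal arcs, then applies sd-undo
    pruning with the chromosome-level noise sd.  Positions must be strictly
    increasing base-pair coordinates, one per marker.  Stretches shorter
    than ``min_width`` are returned whole (flagged in the log).
    """
    x = np.asarray(ratios, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if x.size != positions.size:
        raise ValueError("ratios and positions differ in length")
    if x.size == 0:
        return []
    if positions.size > 1 and not (np.diff(positions) > 0).all():
        raise ValueError("positions must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = x.size
    if n < params.min_width:
        logger.warning("chromosome %s has %d markers (< min_width=%d); "
                       "kept as a single segment", chrom, n, params.min_width)
    if n < 2:
        sd = _SD_FLOOR
    else:
        sd = estimate_noise_sd(x) if noise_sd is None else noise_sd

    bounds = sorted(_find_boundaries(x, 0, n, params, rng))
    edges = [0] + bounds + [n]
    segments = [
        Segment(chrom=chrom, start_index=lo, end_index=hi - 1,
                start_pos=int(positions[lo]), end_pos=int(positions[hi - 1]),
                n_markers=hi - lo, mean=_mean_of(x, lo, hi - 1))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return sd_undo(segments, x, params.undo_sd, sd)


# ---------------------------------------------------------------------------
# Whole-sample segmentation
# ---------------------------------------------------------------------------

def segment_sample(sample_id: str, ratios: np.ndarray, probe_map,
                   params: SegmentationParams,
                   rng: np.random.Generator | None = None,
                   smooth: bool = True) -> SegmentationProfile:
    """Smooth and segment every chromosome of one sample's ratio track."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    profile = SegmentationProfile(sample_id=sample_id)
    for chrom in probe_map.chromosomes:
        sl = probe_map.chrom_slice(chrom)
        x = np.asarray(ratios[sl], dtype=float)
        sd = estimate_noise_sd(x) if x.size >= 2 else _SD_FLOOR
        if smooth and x.size >= 2:
            x = smooth_outliers(x, params, noise_sd=sd)
        profile.noise_sd[chrom] = sd
        profile.segments[chrom] = segment_chromosome(
            x, probe_map.positions(chrom), params, chrom=chrom, rng=rng,
            noise_sd=sd)
    return profile


def profile_to_frame(profile: SegmentationProfile) -> "pd.DataFrame":
    """Flatten a profile to the standard segment-table layout."""
    import pandas as pd

    rows = [(profile.sample_id, s.chrom, s.start_pos, s.end_pos,
             s.n_markers, s.mean) for s in profile.all_segments()]
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_pos",
                                       "end_pos", "n_markers", "seg_mean"])


def profiles_from_frame(df: "pd.DataFrame", probe_map) -> list[SegmentationProfile]:
    """Rebuild profiles from a written segment table (stage resume)."""
    profiles = []
    for sid, sub in df.groupby("sample_id", sort=True):
        profile = SegmentationProfile(sample_id=str(sid))
        for chrom, csub in sub.groupby("chrom", sort=True):
            pos = probe_map.positions(int(chrom))
            segs = []
            for rec in csub.sort_values("start_pos").itertuples():
                lo = int(np.searchsorted(pos, rec.start_pos))
                hi = int(np.searchsorted(pos, rec.end_pos))
                if lo >= len(pos) or pos[lo] != rec.start_pos or pos[hi] != rec.end_pos:
                    raise ValueError(
                        f"segment {rec.start_pos}-{rec.end_pos} of sample {sid} "
                        f"does not start/end on probes of chromosome {chrom}")
                segs.append(Segment(chrom=int(chrom), start_index=lo,
                                    end_index=hi, start_pos=int(rec.start_pos),
                                    end_pos=int(rec.end_pos),
                                    n_markers=hi - lo + 1,
                                    mean=float(rec.seg_mean)))
            profile.segments[int(chrom)] = segs
        profiles.append(profile)
    return profiles
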