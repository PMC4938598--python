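"""Pooled reference profile and per-probe log2 ratios.

The reference is the arithmetic mean intensity across a pool of reference
samples (e.g. population-panel arrays), probe by probe.  A sample's copy
number track is then ``log2(sample / reference)`` per probe: 0 is neutral,
+1 roughly one copy gained, -1 one copy lost on this scale.  Averaging is
done on the intensity scale, before the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ProbeMap, SignalMatrix


@dataclass
class ReferenceProfile:
    """Probe-aligned mean reference intensities (strictly positive)."""

    values: np.ndarray
    n_reference_samples: int
    probe_map: ProbeMap

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.probe_map):
            raise ValueError("reference profile not aligned to probe map")
        if (self.values <= 0).any():
            bad = self.probe_map.probe_id[int(np.argmax(self.values <= 0))]
            raise ValueError(f"non-positive reference intensity at probe {bad!r}")


def build_reference(matrix: SignalMatrix) -> ReferenceProfile:
    """Average the reference samples' intensities probe-wise."""
    if matrix.scale != "intensity":
        raise ValueError("reference must be built from intensity-scale data")
    if matrix.n_samples < 1:
        raise ValueError("at least one reference sample required")
    mean = matrix.values.mean(axis=0)
    if (mean <= 0).any():
        bad = matrix.probe_map.probe_id[int(np.argmax(mean <= 0))]
        raise ValueError(f"reference mean <= 0 at probe {bad!r}")
    return ReferenceProfile(mean, matrix.n_samples, matrix.probe_map)


def compute_log2_ratio(sample: np.ndarray, reference: ReferenceProfile) -> np.ndarray:
    """log2 of a sample's intensities over the pooled reference, probe-wise."""
    sample = np.asarray(sample, dtype=float)
    if sample.shape != reference.values.shape:
        raise ValueError("sample not aligned to reference profile")
    if (sample <= 0).any():
        bad = reference.probe_map.probe_id[int(np.argmax(sample <= 0))]
        raise ValueError(f"non-positive sample intensity at probe {bad!r}")
    return np.log2(sample / reference.values)


def ratio_matrix(matrix: SignalMatrix, reference: ReferenceProfile) -> SignalMatrix:
    """Convert a whole intensity matrix to log2 ratios against a reference."""
    if matrix.scale == "ratio":
        raise ValueError("matrix is already on ratio scale")
    ratios = np.stack([compute_log2_ratio(row, reference) for row in matrix.values])
    return SignalMatrix(list(matrix.sample_ids), ratios, matrix.probe_map, scale="ratio")
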