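"""Readers and writers for the tabular formats the pipeline touches.

Internal genomic coordinates are 1-based inclusive throughout the package,
matching how SNP-array probe positions and segment boundaries are usually
printed.  BED import/export converts to/from 0-based half-open.  Only the
22 human autosomes are retained; records on other chromosomes are dropped
with a logged count.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cnvbpr.io")

AUTOSOMES = tuple(range(1, 23))


def normalize_chrom(label: object) -> int | None:
    """Map a chromosome label to an autosome number, or None if not autosomal.

    A leading ``chr`` prefix is stripped; ``"chr8"``, ``"8"`` and ``8`` all
    map to 8.  Sex chromosomes, mitochondria, scaffolds etc. return None.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        c = int(s)
    except ValueError:
        return None
    return c if 1 <= c <= 22 else None


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open BED interval."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive span."""
    return start + 1, end


# ---------------------------------------------------------------------------
# Probe map
# ---------------------------------------------------------------------------

@dataclass
class ProbeMap:
    """Ordered autosomal probe positions: the coordinate backbone of a run.

    Probes are sorted by (chromosome, position); within each chromosome the
    positions are strictly increasing.
    """

    probe_id: np.ndarray   # object dtype
    chrom: np.ndarray      # int
    pos: np.ndarray        # int64, 1-based
    _offsets: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if not (len(self.probe_id) == len(self.chrom) == len(self.pos)):
            raise ValueError("probe_id, chrom and pos must have equal length")
        order = np.lexsort((self.pos, self.chrom))
        self.probe_id = self.probe_id[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        # duplicate (chrom, pos) pairs are ambiguous coordinates -> hard error
        if len(self.pos) > 1:
            same = (np.diff(self.chrom) == 0) & (np.diff(self.pos) == 0)
            if same.any():
                i = int(np.nonzero(same)[0][0])
                raise ValueError(
                    f"duplicate probe coordinate chr{self.chrom[i]}:{self.pos[i]} "
                    f"({self.probe_id[i]} / {self.probe_id[i + 1]})"
                )
        self._offsets = {}
        for c in np.unique(self.chrom):
            lo = int(np.searchsorted(self.chrom, c, side="left"))
            hi = int(np.searchsorted(self.chrom, c, side="right"))
            self._offsets[int(c)] = slice(lo, hi)

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self._offsets)

    def chrom_slice(self, chrom: int) -> slice:
        """Slice of the global probe order covering one chromosome."""
        return self._offsets[int(chrom)]

    def positions(self, chrom: int) -> np.ndarray:
        return self.pos[self.chrom_slice(chrom)]

    @classmethod
    def regular(cls, n_chromosomes: int, probes_per_chrom: int,
                spacing: int = 1000, start: int = 1) -> "ProbeMap":
        """Evenly spaced synthetic layout: ``probes_per_chrom`` probes on each
        of ``n_chromosomes`` autosomes, ``spacing`` bp apart."""
        if not 1 <= n_chromosomes <= 22:
            raise ValueError("n_chromosomes must be in 1..22")
        chroms = np.repeat(np.arange(1, n_chromosomes + 1), probes_per_chrom)
        pos = np.tile(start + spacing * np.arange(probes_per_chrom, dtype=np.int64),
                      n_chromosomes)
        ids = np.array([f"P{c}_{i:06d}" for c, i in
                        zip(chroms, np.tile(np.arange(probes_per_chrom), n_chromosomes))],
                       dtype=object)
        return cls(ids, chroms, pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"probe_id": self.probe_id,
                             "chrom": self.chrom, "pos": self.pos})


def read_probe_map(path: str | os.PathLike) -> ProbeMap:
    """Read a probe map TSV with columns ``probe_id``, ``chrom``, ``pos``.

    ``chromosome``/``position`` are accepted as column aliases.  Probes on
    non-autosomal chromosomes are dropped (count logged); duplicate
    (chromosome, position) pairs and non-numeric positions are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={"chromosome": "chrom", "position": "pos"})
    missing = {"probe_id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise ValueError(f"probe map {path} lacks columns: {sorted(missing)}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        bad = df.loc[pos.isna(), "probe_id"].iloc[0]
        raise ValueError(f"non-numeric position for probe {bad!r} in {path}")
    chrom = df["chrom"].map(normalize_chrom)
    n_dropped = int(chrom.isna().sum())
    if n_dropped:
        logger.info("read_probe_map: dropped %d non-autosomal probe(s)", n_dropped)
    keep = chrom.notna()
    return ProbeMap(df.loc[keep, "probe_id"].to_numpy(dtype=object),
                    chrom[keep].to_numpy(dtype=np.int64),
                    pos[keep].to_numpy(dtype=np.int64))


def write_probe_map(pm: ProbeMap, path: str | os.PathLike) -> None:
    pm.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signal matrix
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    """Samples x probes matrix of raw intensities or log2 ratios.

    ``values[i, j]`` is the value of sample ``sample_ids[i]`` at the j-th
    probe of ``probe_map`` (probe order always equals the map order).  The
    ``scale`` flag ("intensity" or "ratio") is explicit; mixing scales
    downstream is an error.
    """

    sample_ids: list[str]
    values: np.ndarray
    probe_map: ProbeMap
    scale: str = "intensity"

    def __post_init__(self) -> None:
        if self.scale not in ("intensity", "ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_map)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_map)} probes")
        if self.scale == "intensity" and (self.values < 0).any():
            raise ValueError("negative value on intensity scale")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


def read_signal_matrix(path: str | os.PathLike, probe_map: ProbeMap,
                       allele_suffixes: tuple[str, str] | None = None,
                       scale: str = "intensity") -> SignalMatrix:
    """Read a per-probe signal TSV (first column ``probe_id``) aligned to a map.

    With ``allele_suffixes`` (e.g. ``("_A", "_B")``) each sample is expected
    as a pair of columns ``<sample><suffix>``; the per-probe value is the sum
    of the two allele intensities.  Rows are reordered to the probe-map order;
    probes unknown to the map (or missing from the file) are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [p for p in df.index if p not in set(probe_map.probe_id)]
    if unknown:
        raise ValueError(f"probes absent from probe map: {unknown[:10]}")
    try:
        df = df.loc[probe_map.probe_id]
    except KeyError as exc:
        raise ValueError(f"signal file is missing probes of the map: {exc}") from exc

    if allele_suffixes is not None:
        sa, sb = allele_suffixes
        a_cols = [c for c in df.columns if c.endswith(sa)]
        samples = [c[: -len(sa)] for c in a_cols]
        missing_b = [s for s in samples if s + sb not in df.columns]
        if missing_b:
            raise ValueError(f"missing {sb} allele column for sample(s) {missing_b}")
        values = np.stack([df[s + sa].to_numpy(float) + df[s + sb].to_numpy(float)
                           for s in samples])
    else:
        samples = list(df.columns)
        values = df.to_numpy(float).T
    return SignalMatrix(samples, values, probe_map, scale=scale)


def write_signal_matrix(matrix: SignalMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(matrix.values.T, index=matrix.probe_map.probe_id,
                      columns=matrix.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Flattened gene spans (1-based inclusive) on the autosomes.

    ``df`` columns: gene_id, gene_name, chrom (int), start, end,
    tumor_associated (bool).  ``provenance`` records where the annotation
    came from (file path or a user-supplied version string).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        required = {"gene_id", "gene_name", "chrom", "start", "end", "tumor_associated"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"gene annotation lacks columns {sorted(missing)}")
        if (self.df["start"] > self.df["end"]).any():
            bad = self.df[self.df["start"] > self.df["end"]].iloc[0]
            raise ValueError(f"gene {bad['gene_id']} has start > end")

    def __len__(self) -> int:
        return len(self.df)


def _read_tumor_list(path: str | os.PathLike | None) -> set[str]:
    if path is None:
        return set()
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _read_bed_genes(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                bed_start, bed_end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}") from exc
            start, end = from_bed_interval(bed_start, bed_end)
            name = parts[3] if len(parts) > 3 else f"bed_{lineno}"
            rows.append((name, name, parts[0], start, end))
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end"])


def _read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    # cheap structural validation first so malformed lines are reported with
    # their line number rather than through gffutils internals
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}")
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [gid])[0]
        rows.append((gid, name, feat.seqid, feat.start, feat.end))
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end"])


def read_gene_annotation(path: str | os.PathLike, fmt: str | None = None,
                         tumor_gene_list: str | os.PathLike | None = None,
                         provenance: str | None = None) -> GeneAnnotation:
    """Load gene spans from GFF3 (gene-typed features) or BED4+.

    BED intervals (0-based half-open) are converted to 1-based inclusive.
    Genes on non-autosomal chromosomes are dropped with a logged count.
    Genes whose id or name appears in ``tumor_gene_list`` (one id per line)
    are flagged tumor_associated.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gff3"
    fmt = fmt.lower()
    if fmt == "bed":
        df = _read_bed_genes(path)
    elif fmt in ("gff3", "gff"):
        df = _read_gff3_genes(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    chrom = df["chrom"].map(normalize_chrom)
    n_dropped = int(chrom.isna().sum())
    if n_dropped:
        logger.info("read_gene_annotation: dropped %d non-autosomal gene(s)", n_dropped)
    df = df[chrom.notna()].copy()
    df["chrom"] = chrom[chrom.notna()].astype(np.int64)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    tumor = _read_tumor_list(tumor_gene_list)
    df["tumor_associated"] = (df["gene_id"].isin(tumor)
                              | df["gene_name"].isin(tumor))
    return GeneAnnotation(df.reset_index(drop=True),
                          provenance=provenance or str(path))


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["sample_id", "chrom", "start_pos", "end_pos", "n_markers", "seg_mean"]


def write_segments_tsv(segments: pd.DataFrame, path: str | os.PathLike) -> None:
    """Per-sample segment table (1-based inclusive coordinates)."""
    segments.to_csv(path, sep="\t", index=False,
                    columns=[c for c in SEGMENT_COLUMNS if c in segments.columns])


def read_segments_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_intervals_bed(df: pd.DataFrame, path: str | os.PathLike,
                        name_col: str | None = None,
                        score_col: str | None = None) -> None:
    """Export any table with chrom/start_pos/end_pos (or start/end) as BED."""
    start = df["start_pos"] if "start_pos" in df.columns else df["start"]
    end = df["end_pos"] if "end_pos" in df.columns else df["end"]
    bed = pd.DataFrame({
        "chrom": "chr" + df["chrom"].astype(str),
        "start": start.astype(np.int64) - 1,
        "end": end.astype(np.int64),
        "name": df[name_col] if name_col else ".",
        "score": df[score_col] if score_col else 0,
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def ensure_out_dir(out_dir: str | os.PathLike) -> Path:
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    return out
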