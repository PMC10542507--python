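"""Core domain types and tabular/genomic I/O.

The pipeline works on three kinds of data: barcode / RNA-seq count matrices
(genes x samples, integer), sample sheets binding each sample to its strain,
condition, generation or timepoint, and replicate, and per-base sequencing
depth tracks with gene-interval annotations.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere; 1-based coordinates
  appear only at file boundaries (samtools-depth-style TSV).
* TSV is the canonical tabular format; gzip is handled transparently.
* A missing barcode is a zero count: the count matrix is dense, and the
  dropout-imputation rule downstream operates on zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleSheet",
    "CountMatrix",
    "NormCountMatrix",
    "GeneInterval",
    "DepthTrack",
    "ValidationError",
    "read_sample_sheet",
    "read_count_matrix",
    "write_count_matrix",
    "read_depth_track",
    "write_bedgraph",
    "read_bed",
    "write_bed",
]


class ValidationError(ValueError):
    """Raised when an input file or object violates its contract."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_REQUIRED = ("sample_id", "strain", "condition", "replicate")


@dataclass
class SampleSheet:
    """Sample metadata: one row per sequencing sample.

    Exactly one of the ``generation`` (competitive-growth doublings) or
    ``timepoint`` (minutes after stress shift) columns is present, depending
    on whether the sheet describes fitness-competition or expression samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _SHEET_REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        has_gen = "generation" in df.columns
        has_time = "timepoint" in df.columns
        if has_gen == has_time:
            raise ValidationError(
                "sample sheet must have exactly one of 'generation' or 'timepoint'"
            )
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_ids: {dups}")
        axis = "generation" if has_gen else "timepoint"
        if (df[axis] < 0).any():
            raise ValidationError(f"negative {axis} values")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive integers")
        self.data = df.reset_index(drop=True)

    @property
    def axis(self) -> str:
        """Name of the time-like column: 'generation' or 'timepoint'."""
        return "generation" if "generation" in self.data.columns else "timepoint"

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique().tolist())

    def select(self, **where) -> "SampleSheet":
        """Subset rows by equality on any column, e.g. select(strain='BY4743')."""
        df = self.data
        for col, val in where.items():
            df = df[df[col] == val]
        return SampleSheet(df.reset_index(drop=True))

    def sample_ids_where(self, **where) -> list[str]:
        return self.select(**where).sample_ids


def read_sample_sheet(path: str | Path) -> SampleSheet:
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Dense gene x sample matrix of non-negative integer read counts."""

    data: pd.DataFrame  # index = gene_ids, columns = sample_ids

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene_ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric entries")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        self.data = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class NormCountMatrix:
    """Normalized (real-valued) counts plus the per-sample size factors.

    Dividing each raw column by its size factor reproduces ``values``;
    ``provenance`` records which normalization produced the matrix.
    """

    data: pd.DataFrame
    size_factors: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            bad = self.size_factors[self.size_factors <= 0].index.tolist()
            raise ValidationError(f"non-positive size factors for samples: {bad}")
        if list(self.size_factors.index) != list(self.data.columns):
            raise ValidationError("size_factors index must match sample columns")
        if (self.data.to_numpy() < 0).any():
            raise ValidationError("normalized counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()


def read_count_matrix(
    path: str | Path, sheet: SampleSheet | None = None
) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene_id, header samples).

    If ``sheet`` is given, the file's samples are reconciled against it: the
    columns are reordered to the sheet order and any mismatch is an error
    listing the offending samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
            raise ValidationError(
                f"non-numeric count at gene {bad.tolist()}, sample {col!r}"
            )
    cm = CountMatrix(df)
    if sheet is not None:
        file_samples = set(cm.samples)
        sheet_samples = set(sheet.sample_ids)
        if file_samples != sheet_samples:
            only_file = sorted(file_samples - sheet_samples)
            only_sheet = sorted(sheet_samples - file_samples)
            raise ValidationError(
                "sample mismatch between counts and sheet: "
                f"only in file {only_file}; only in sheet {only_sheet}"
            )
        cm = CountMatrix(cm.data[sheet.sample_ids])
    return cm


def write_count_matrix(
    counts: CountMatrix | NormCountMatrix, path: str | Path
) -> None:
    counts.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Genomic intervals and depth tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneInterval:
    """A gene interval in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    gene_id: str
    role: str = "target"  # "target" or "single_copy_reference"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.gene_id}: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DepthTrack:
    """Per-base sequencing depth over one contig (dense, 0-based)."""

    contig: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValidationError("depth must be a 1-D array")
        if (self.depth < 0).any():
            raise ValidationError(f"negative depth on contig {self.contig}")

    def __len__(self) -> int:
        return len(self.depth)

    def slice(self, interval: GeneInterval) -> np.ndarray:
        if interval.contig != self.contig:
            raise ValidationError(
                f"interval contig {interval.contig!r} != track contig {self.contig!r}"
            )
        if interval.end > len(self.depth):
            raise ValidationError(
                f"interval {interval.gene_id} extends past contig end "
                f"({interval.end} > {len(self.depth)})"
            )
        return self.depth[interval.start : interval.end]


def read_depth_track(
    path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> dict[str, DepthTrack]:
    """Read per-base depth from a 3-column samtools-depth TSV or a bedGraph.

    Depth TSV rows are ``contig<TAB>1-based position<TAB>depth``; bedGraph rows
    are ``contig<TAB>0-based start<TAB>end<TAB>depth``. Positions absent from
    the file get depth 0. Returns one dense track per contig; track length is
    the contig length if supplied, otherwise the maximum covered coordinate.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] == 3:
        return _depth_from_tsv(df, contig_lengths)
    if df.shape[1] == 4:
        return _depth_from_bedgraph(df, contig_lengths)
    raise ValidationError(
        f"expected 3 (depth TSV) or 4 (bedGraph) columns, got {df.shape[1]}"
    )


def _contig_len(contig: str, needed: int, lengths: Mapping[str, int] | None) -> int:
    if lengths is not None and contig in lengths:
        if needed > lengths[contig]:
            raise ValidationError(
                f"position {needed} beyond declared length of {contig}"
            )
        return lengths[contig]
    return needed


def _depth_from_tsv(df: pd.DataFrame, lengths) -> dict[str, DepthTrack]:
    tracks: dict[str, DepthTrack] = {}
    for contig, sub in df.groupby(0, sort=True):
        pos = sub[1].to_numpy(dtype=np.int64) - 1  # 1-based file -> 0-based
        if (pos < 0).any():
            raise ValidationError(f"depth TSV position < 1 on contig {contig}")
        n = _contig_len(str(contig), int(pos.max()) + 1, lengths)
        depth = np.zeros(n)
        depth[pos] = sub[2].to_numpy(dtype=float)
        tracks[str(contig)] = DepthTrack(str(contig), depth)
    return tracks


def _depth_from_bedgraph(df: pd.DataFrame, lengths) -> dict[str, DepthTrack]:
    tracks: dict[str, DepthTrack] = {}
    for contig, sub in df.groupby(0, sort=True):
        starts = sub[1].to_numpy(dtype=np.int64)
        ends = sub[2].to_numpy(dtype=np.int64)
        vals = sub[3].to_numpy(dtype=float)
        order = np.argsort(starts, kind="stable")
        starts, ends, vals = starts[order], ends[order], vals[order]
        if (starts[1:] < ends[:-1]).any():
            raise ValidationError(f"overlapping bedGraph intervals on {contig}")
        n = _contig_len(str(contig), int(ends.max()), lengths)
        depth = np.zeros(n)
        for s, e, v in zip(starts, ends, vals):
            depth[s:e] = v
        tracks[str(contig)] = DepthTrack(str(contig), depth)
    return tracks


def write_bedgraph(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    """Write dense tracks as run-length-encoded bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for tr in tracks:
            d = tr.depth
            if len(d) == 0:
                continue
            change = np.flatnonzero(d[1:] != d[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(d)]])
            for s, e in zip(starts, ends):
                v = d[s]
                if v == 0:
                    continue  # absent positions are depth 0 by convention
                fh.write(f"{tr.contig}\t{s}\t{e}\t{v:g}\n")


def read_bed(path: str | Path, role: str = "target") -> list[GeneInterval]:
    """Read gene intervals from BED (contig, start, end, name[, score, strand]).

    A 5th column equal to ``target`` or ``single_copy_reference`` overrides
    the default role.
    """
    out: list[GeneInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"BED line has <4 columns: {line!r}")
            r = role
            if len(parts) >= 5 and parts[4] in ("target", "single_copy_reference"):
                r = parts[4]
            out.append(
                GeneInterval(parts[0], int(parts[1]), int(parts[2]), parts[3], r)
            )
    return out


def write_bed(intervals: Sequence[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t{iv.role}\n")
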