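"""Copy-number estimation from per-base sequencing depth.

The estimator normalizes a depth track to the genome-wide median, picks (or
is given) single-copy reference genes whose median depth sits at the genome
median on distinct contigs, divides every base by the pooled reference
median to obtain copies per haploid genome, and calls each target's copy
number as the median ratio over its bases. A 500-bp centered running average
is produced for display; calls are made on the raw ratio track.

Median convention: the *lower* median for even counts, applied consistently
(genome median, reference median, and copy calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DepthTrack, GeneInterval, ValidationError

__all__ = [
    "CopyNumberResult",
    "lower_median",
    "genome_median_normalize",
    "select_single_copy_references",
    "coverage_ratio",
    "running_average",
    "copy_number_call",
    "call_targets",
]


def lower_median(x: np.ndarray) -> float:
    """Median using the lower of the two central order statistics for even n."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("median of empty array")
    return float(np.partition(x, (x.size - 1) // 2)[(x.size - 1) // 2])


@dataclass
class CopyNumberResult:
    """Copy-number call for one target interval."""

    gene_id: str
    median_ratio: float  # copies per haploid genome
    iqr: float
    heterogeneous: bool  # IQR > iqr_flag: possible partial duplication
    smoothed: np.ndarray = field(repr=False, default=None)


def genome_median_normalize(
    tracks: dict[str, DepthTrack] | DepthTrack,
) -> dict[str, DepthTrack] | DepthTrack:
    """Divide every base by the genome-wide (lower) median depth."""
    single = isinstance(tracks, DepthTrack)
    tr = {tracks.contig: tracks} if single else tracks
    alld = np.concatenate([t.depth for t in tr.values()])
    med = lower_median(alld)
    if med <= 0:
        raise ValidationError("genome median depth is zero")
    out = {c: DepthTrack(c, t.depth / med) for c, t in tr.items()}
    return out[tracks.contig] if single else out


def select_single_copy_references(
    tracks: dict[str, DepthTrack],
    intervals: list[GeneInterval],
    k: int = 3,
    tolerance: float = 0.05,
    seed: int = 0,
) -> list[GeneInterval]:
    """Pick k genes at the genome-median depth on k distinct contigs.

    A gene qualifies when its (lower) median depth is within ``tolerance``
    of the genome median. Selection is uniform at random (seeded) among
    qualifying genes, greedily constrained to distinct contigs.
    """
    alld = np.concatenate([t.depth for t in tracks.values()])
    med = lower_median(alld)
    if med <= 0:
        raise ValidationError("genome median depth is zero")
    qualifying = []
    for iv in intervals:
        if iv.contig not in tracks:
            continue
        gmed = lower_median(tracks[iv.contig].slice(iv))
        if abs(gmed - med) <= tolerance * med:
            qualifying.append(iv)
    contigs = {iv.contig for iv in qualifying}
    if len(contigs) < k:
        raise ValidationError(
            f"only {len(contigs)} contigs have genes at the median depth; need {k}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(qualifying))
    chosen: list[GeneInterval] = []
    used: set[str] = set()
    for i in order:
        iv = qualifying[i]
        if iv.contig in used:
            continue
        chosen.append(
            GeneInterval(iv.contig, iv.start, iv.end, iv.gene_id,
                         "single_copy_reference")
        )
        used.add(iv.contig)
        if len(chosen) == k:
            break
    return chosen


def coverage_ratio(
    tracks: dict[str, DepthTrack] | DepthTrack,
    references: list[GeneInterval],
) -> dict[str, DepthTrack] | DepthTrack:
    """Divide every base by the pooled reference-gene (lower) median depth.

    The result is interpreted as copies per haploid genome, assuming the
    references are single copy.
    """
    if not references:
        raise ValidationError("reference interval list is empty")
    single = isinstance(tracks, DepthTrack)
    tr = {tracks.contig: tracks} if single else tracks
    pooled = np.concatenate([tr[iv.contig].slice(iv) for iv in references])
    med = lower_median(pooled)
    if med <= 0:
        raise ValidationError("pooled reference median depth is zero")
    out = {c: DepthTrack(c, t.depth / med) for c, t in tr.items()}
    return out[tracks.contig] if single else out


def running_average(track: DepthTrack | np.ndarray, window: int = 500):
    """Centered running mean, truncated at the edges.

    For window w the value at position p averages positions
    p - ceil(w/2) + 1 .. p + floor(w/2) clipped to the track, so interior
    windows contain exactly w bases (even w: one more base to the right).
    Window 1 is the identity; a window longer than the track broadcasts the
    global mean.
    """
    arr = track.depth if isinstance(track, DepthTrack) else np.asarray(track, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(arr)
    if n == 0 or window == 1:
        smoothed = arr.copy()
    elif window >= n:
        smoothed = np.full(n, arr.mean())
    else:
        left = (window - 1) // 2 if window % 2 else window // 2 - 1
        right = window - 1 - left
        csum = np.concatenate([[0.0], np.cumsum(arr)])
        pos = np.arange(n)
        lo = np.maximum(pos - left, 0)
        hi = np.minimum(pos + right + 1, n)
        smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    if isinstance(track, DepthTrack):
        return DepthTrack(track.contig, smoothed)
    return smoothed


def copy_number_call(
    ratio_track: DepthTrack,
    target: GeneInterval,
    window: int = 500,
    iqr_flag: float = 0.5,
) -> CopyNumberResult:
    """Median of the raw ratio over the target's bases (smoothing is display).

    Flags the call as heterogeneous when the interquartile range of the
    per-base ratio exceeds ``iqr_flag`` — e.g. a partial duplication where
    half the gene sits at one copy level and half at another.
    """
    vals = ratio_track.slice(target)
    if vals.size == 0 or not np.any(vals > 0):
        return CopyNumberResult(target.gene_id, float("nan"), float("nan"),
                                False, np.array([]))
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    return CopyNumberResult(
        gene_id=target.gene_id,
        median_ratio=lower_median(vals),
        iqr=float(q3 - q1),
        heterogeneous=bool(q3 - q1 > iqr_flag),
        smoothed=running_average(vals, window),
    )


def call_targets(
    tracks: dict[str, DepthTrack],
    targets: list[GeneInterval],
    references: list[GeneInterval] | None = None,
    intervals_for_ref: list[GeneInterval] | None = None,
    window: int = 500,
    ref_tolerance: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[CopyNumberResult], list[GeneInterval]]:
    """Full call pipeline: normalize, pick references if needed, call targets."""
    normed = genome_median_normalize(tracks)
    if references is None:
        pool = intervals_for_ref if intervals_for_ref is not None else []
        references = select_single_copy_references(
            normed, pool, tolerance=ref_tolerance, seed=seed
        )
    ratio = coverage_ratio(normed, references)
    results = [copy_number_call(ratio[t.contig], t, window=window) for t in targets]
    table = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "median_ratio": r.median_ratio,
                "copy_call_1dp": round(r.median_ratio, 1),
                "iqr": r.iqr,
                "heterogeneous": r.heterogeneous,
            }
            for r in results
        ]
    )
    return table, results, references
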