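"""Consensus TAD construction from weighted multi-tissue TAD maps.

Scores are computed in sliding windows of length L = 40 kb stepped by
1 kb (97.5% overlap between adjacent windows):

* conservation ``c_i``: weighted fraction of the window's nucleotides that
  lie inside a TAD, averaged over maps with tissue weights ``w_k``;
* boundary ``b_i``: weighted indicator that the window contains at least
  one TAD boundary of map k.

Windows are merged into consensus TADs while the nucleotide-wise mean
conservation stays >= c* (0.5) and no merged window has boundary score
>= b* (0.5). Merged runs >= 40 kb become consensus TADs; the gaps between
consecutive TADs are topological boundary regions (TBRs) if <= 400 kb and
disorganized chromatin otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import TADMap

__all__ = [
    "ScoreTrack",
    "ConsensusSegmentation",
    "map_similarity",
    "window_scores",
    "build_consensus",
]


@dataclass
class ScoreTrack:
    """Windowed conservation/boundary scores per chromosome.

    ``tracks[chrom] = (starts, ends, c, b)`` with windows on a fixed step
    grid from position 0; the last windows are truncated at the chromosome
    end and scored over their actual covered length.
    """

    tracks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    window: int
    step: int
    chrom_sizes: dict[str, int]


@dataclass
class ConsensusSegmentation:
    """Partition into consensus TADs, TBRs, and disorganized regions."""

    regions: pd.DataFrame  # columns: chrom, start, end, label
    params: dict = field(default_factory=dict)

    def tads(self) -> pd.DataFrame:
        return self.regions[self.regions["label"] == "TAD"].reset_index(drop=True)

    def by_label(self, label: str) -> pd.DataFrame:
        return self.regions[self.regions["label"] == label].reset_index(drop=True)

    def to_tad_map(self, sample_id: str = "consensus", condition: str = "normal") -> TADMap:
        return TADMap(sample_id, condition, self.tads()[["chrom", "start", "end"]])

    def to_bed(self, path) -> None:
        self.regions.to_csv(path, sep="\t", header=False, index=False)


def _coverage_fn(starts: np.ndarray, ends: np.ndarray):
    """Return cum(x) = bases of [0, x) covered by sorted disjoint intervals."""
    prefix = np.concatenate([[0], np.cumsum(ends - starts)])

    def cum(x: np.ndarray) -> np.ndarray:
        # index of the first interval with end > x
        i = np.searchsorted(ends, x, side="right")
        full = prefix[np.minimum(i, len(starts))]
        # partial coverage of the interval containing x
        inside = (i < len(starts)) & (starts[np.minimum(i, len(starts) - 1)] < x)
        partial = np.where(inside, x - starts[np.minimum(i, len(starts) - 1)], 0)
        return full + partial

    return cum


def map_similarity(a: TADMap, b: TADMap) -> float:
    """Directed similarity of map ``a`` to map ``b`` in [0, 1].

    For each TAD in ``a``, the largest fraction of it covered by a single
    TAD of ``b`` (0 if none overlaps); the similarity is the median of
    those fractions. Deliberately asymmetric.
    """
    if len(a) == 0:
        raise ValueError("similarity undefined for an empty map A")
    fractions = []
    for chrom in a.chroms():
        a_starts, a_ends = a.chrom_arrays(chrom)
        b_starts, b_ends = b.chrom_arrays(chrom)
        for s, e in zip(a_starts, a_ends):
            if len(b_starts) == 0:
                fractions.append(0.0)
                continue
            lo = np.searchsorted(b_ends, s, side="right")
            hi = np.searchsorted(b_starts, e, side="left")
            if hi <= lo:
                fractions.append(0.0)
                continue
            ov = np.minimum(b_ends[lo:hi], e) - np.maximum(b_starts[lo:hi], s)
            fractions.append(float(ov.max()) / (e - s))
    return float(np.median(fractions))


def window_scores(
    maps: Sequence[TADMap],
    weights: Sequence[float],
    chrom_sizes: Mapping[str, int],
    window: int = 40_000,
    step: int = 1_000,
) -> ScoreTrack:
    """Weighted conservation and boundary scores on the sliding-window grid."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(maps):
        raise ValueError("one weight per map required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("map weights must sum to 1")
    if step > window:
        raise ValueError("step must not exceed the window length")

    tracks = {}
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, step, dtype=np.int64)
        ends = np.minimum(starts + window, size)
        lengths = (ends - starts).astype(float)
        c = np.zeros(len(starts))
        b = np.zeros(len(starts))
        for m, w in zip(maps, weights):
            t_starts, t_ends = m.chrom_arrays(chrom)
            if len(t_starts):
                cum = _coverage_fn(t_starts, t_ends)
                covered = cum(ends) - cum(starts)
                c += w * covered / lengths
                bounds = np.unique(np.concatenate([t_starts, t_ends]))
                # boundary p is inside window [s, e) iff s <= p < e
                n_in = np.searchsorted(bounds, ends, side="left") - np.searchsorted(
                    bounds, starts, side="left"
                )
                b += w * (n_in > 0)
        tracks[chrom] = (starts, ends, c, b)
    return ScoreTrack(tracks=tracks, window=window, step=step,
                      chrom_sizes=dict(chrom_sizes))


def _nucleotide_mean(starts, ends, c, size, step):
    """Per-step-segment mean of c over all windows covering the segment.

    Windows sit on the step grid, so the set of covering windows is
    constant within each step-sized segment; segment t = [t*step,
    (t+1)*step) is covered by window i iff starts[i] <= t*step and
    ends[i] >= (t+1)*step (clipped at the chromosome tail).
    """
    n_seg = int(np.ceil(size / step))
    seg_start = np.arange(n_seg, dtype=np.int64) * step
    seg_end = np.minimum(seg_start + step, size)
    # windows are ordered by start; window i covers segment t iff
    # i <= t (start condition) and ends[i] >= seg_end[t]
    sums = np.zeros(n_seg)
    counts = np.zeros(n_seg)
    # suffix structure over window ends: for segment t, eligible windows are
    # i in [lo_t, t] with ends[i] >= seg_end[t]; ends is non-decreasing, so
    # the eligible i form a contiguous tail [first_t, t].
    csum = np.concatenate([[0.0], np.cumsum(c)])
    first = np.searchsorted(ends, seg_end, side="left")
    idx_hi = np.minimum(np.arange(n_seg), len(c) - 1)
    lo = np.minimum(first, idx_hi)
    counts = idx_hi - lo + 1
    sums = csum[idx_hi + 1] - csum[lo]
    return seg_start, seg_end, sums / counts


def build_consensus(
    track: ScoreTrack,
    c_star: float = 0.5,
    b_star: float = 0.5,
    min_tad: int = 40_000,
    tbr_max: int = 400_000,
    mode: str = "greedy",
) -> ConsensusSegmentation:
    """Merge score windows into consensus TADs and label inter-TAD gaps.

    ``mode="greedy"`` (default): windows with b >= b* are excluded from
    any run; a run keeps extending while the nucleotide-wise mean
    conservation over the merged region stays >= c*, where the
    per-nucleotide conservation is the mean of c over all windows covering
    that nucleotide. ``mode="window"`` instead requires each window's own
    c >= c*. Runs >= ``min_tad`` become consensus TADs; gaps between
    consecutive TADs of length <= ``tbr_max`` are TBRs, longer gaps are
    disorganized chromatin.
    """
    if mode not in ("greedy", "window"):
        raise ValueError("mode must be 'greedy' or 'window'")
    rows = []
    for chrom, (starts, ends, c, b) in track.tracks.items():
        size = track.chrom_sizes[chrom]
        step = track.step
        seg_start, seg_end, m = _nucleotide_mean(starts, ends, c, size, step)
        seg_len = (seg_end - seg_start).astype(float)
        m_int = np.concatenate([[0.0], np.cumsum(m * seg_len)])  # integral of m

        def region_mean(x0: int, x1: int) -> float:
            # mean of the per-nucleotide score over [x0, x1); x0, x1 on grid
            i0, i1 = x0 // step, int(np.ceil(x1 / step))
            return (m_int[i1] - m_int[i0]) / (x1 - x0)

        tads = []
        run_start = None
        run_end = None

        def close_run():
            nonlocal run_start, run_end
            if run_start is not None:
                start = run_start
                if tads and start < tads[-1][1]:
                    start = tads[-1][1]  # clip at the previous region's end
                if run_end - start >= min_tad:
                    tads.append((start, run_end))
            run_start = run_end = None

        for i in range(len(starts)):
            if b[i] >= b_star:
                close_run()
                continue
            if run_start is None:
                ok = (c[i] >= c_star) if mode == "window" else (
                    region_mean(starts[i], ends[i]) >= c_star
                )
                if ok:
                    run_start, run_end = int(starts[i]), int(ends[i])
            else:
                ok = (c[i] >= c_star) if mode == "window" else (
                    region_mean(run_start, ends[i]) >= c_star
                )
                if ok:
                    run_end = int(ends[i])
                else:
                    close_run()
                    ok0 = (c[i] >= c_star) if mode == "window" else (
                        region_mean(starts[i], ends[i]) >= c_star
                    )
                    if ok0:
                        run_start, run_end = int(starts[i]), int(ends[i])
        close_run()

        for j, (s, e) in enumerate(tads):
            rows.append((chrom, s, e, "TAD"))
            if j + 1 < len(tads):
                gap_s, gap_e = e, tads[j + 1][0]
                label = "TBR" if gap_e - gap_s <= tbr_max else "disorganized"
                rows.append((chrom, gap_s, gap_e, label))

    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    return ConsensusSegmentation(
        regions=regions,
        params=dict(c_star=c_star, b_star=b_star, min_tad=min_tad,
                    tbr_max=tbr_max, mode=mode, window=track.window, step=track.step),
    )
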