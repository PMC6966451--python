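"""Normal-vs-cancer TAD classification and genomic meta-profiles.

Each normal consensus TAD is compared with the cancer consensus map via
best-overlap fractions: f_N is the largest fraction of the normal TAD
covered by a single cancer TAD, and f_C the largest fraction of that
cancer TAD covered by a single normal TAD. A pair is *reciprocal* when
the cancer TAD's best normal partner is the original TAD. Normal TADs
with reciprocal fractions >= 0.95 are "constitutive", TADs with either
fraction <= 0.7 are "perturbed", everything else is "ambiguous" (a
deliberate safety buffer, never merged into either class).

Split TADs are perturbed normal TADs containing two or more cancer TADs
each lying >= 95% inside them; fused groups are two or more perturbed
normal TADs each lying >= 95% inside one covering cancer TAD (connected
components of the covering relation).

Meta-profiles mirror the deepTools conventions: ``scaled_profile`` is the
scale-regions mode (body rescaled to 2 Mb, 1 Mb unscaled flanks, 10 kb
bins, median across regions), ``reference_point_profile`` the
reference-point mode (+-200 kb around centers, 5 kb bins, missing data as
zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MetaProfile",
    "classify_tads",
    "detect_split_fused",
    "scaled_profile",
    "reference_point_profile",
    "patient_coverage_intervals",
]


@dataclass
class MetaProfile:
    """Aggregated per-bin signal over flank/body/flank (or center +- flank)."""

    bins: pd.DataFrame  # columns: bin, position_class, value
    bin_size: int
    aggregate: str
    n_regions: int


def _frame(tads) -> pd.DataFrame:
    if hasattr(tads, "tads"):
        return tads.tads()[["chrom", "start", "end"]].reset_index(drop=True)
    if hasattr(tads, "intervals"):
        return tads.intervals[["chrom", "start", "end"]].reset_index(drop=True)
    return pd.DataFrame(tads)[["chrom", "start", "end"]].reset_index(drop=True)


def _best_overlap(df_a: pd.DataFrame, df_b: pd.DataFrame):
    """For each interval in a: (best fraction of a covered, index in b)."""
    frac = np.zeros(len(df_a))
    best = np.full(len(df_a), -1, dtype=np.int64)
    by_chrom = {c: sub for c, sub in df_b.groupby("chrom")}
    for i, row in enumerate(df_a.itertuples(index=False)):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            continue
        starts, ends, idx = sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy()
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        if hi <= lo:
            continue
        ov = np.minimum(ends[lo:hi], row.end) - np.maximum(starts[lo:hi], row.start)
        k = int(np.argmax(ov))
        frac[i] = ov[k] / (row.end - row.start)
        best[i] = idx[lo + k]
    return frac, best


def classify_tads(
    normal,
    cancer,
    c_thresh: float = 0.95,
    p_thresh: float = 0.7,
) -> pd.DataFrame:
    """Label each normal TAD constitutive / perturbed / ambiguous.

    Returns one row per normal TAD with columns tad, chrom, start, end,
    f_N, f_C, reciprocal, label.
    """
    nd = _frame(normal)
    cd = _frame(cancer)
    f_n, best_c = _best_overlap(nd, cd)
    f_c_all, best_n = (_best_overlap(cd, nd) if len(cd) else (np.array([]), np.array([])))
    rows = []
    for i, row in enumerate(nd.itertuples(index=False)):
        ci = best_c[i]
        if ci >= 0:
            f_c = float(f_c_all[ci])
            reciprocal = int(best_n[ci]) == i
        else:
            f_c = 0.0
            reciprocal = False
        if reciprocal and f_n[i] >= c_thresh and f_c >= c_thresh:
            label = "constitutive"
        elif f_n[i] <= p_thresh or f_c <= p_thresh:
            label = "perturbed"
        else:
            label = "ambiguous"
        rows.append((f"{row.chrom}:{row.start}-{row.end}", row.chrom, row.start,
                     row.end, float(f_n[i]), f_c, reciprocal, label))
    return pd.DataFrame(rows, columns=["tad", "chrom", "start", "end", "f_N",
                                       "f_C", "reciprocal", "label"])


def detect_split_fused(
    classification: pd.DataFrame,
    normal,
    cancer,
    cover: float = 0.95,
) -> tuple[set[str], set[str], list[set[str]]]:
    """Identify split and fused subsets of the perturbed normal TADs.

    Split: a perturbed normal TAD containing >= 2 cancer TADs, each with
    >= ``cover`` of its own length inside the normal TAD. Fused: groups
    of >= 2 perturbed normal TADs each with >= ``cover`` of their length
    inside one and the same cancer TAD; groups are connected components
    of the covering relation and all members must be perturbed. Returns
    (split ids, fused ids, fused groups).
    """
    nd = _frame(normal)
    cd = _frame(cancer)
    n_ids = [f"{r.chrom}:{r.start}-{r.end}" for r in nd.itertuples(index=False)]
    perturbed = set(classification.loc[classification["label"] == "perturbed", "tad"])

    split: set[str] = set()
    # cancer TADs >= cover inside a normal TAD -> count per normal TAD
    inside_counts = np.zeros(len(nd), dtype=int)
    # normal TADs >= cover inside a cancer TAD -> grouping per cancer TAD
    groups_by_cancer: dict[int, list[int]] = {}

    by_chrom_c = {c: sub for c, sub in cd.groupby("chrom")}
    for i, row in enumerate(nd.itertuples(index=False)):
        sub = by_chrom_c.get(row.chrom)
        if sub is None:
            continue
        starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        for k in range(lo, hi):
            ov = min(ends[k], row.end) - max(starts[k], row.start)
            if ov / (ends[k] - starts[k]) >= cover:  # cancer TAD inside normal
                inside_counts[i] += 1
            if ov / (row.end - row.start) >= cover:  # normal TAD inside cancer
                groups_by_cancer.setdefault(int(sub.index[k]), []).append(i)

    for i, tid in enumerate(n_ids):
        if tid in perturbed and inside_counts[i] >= 2:
            split.add(tid)

    fused_groups: list[set[str]] = []
    for _, members in sorted(groups_by_cancer.items()):
        ids = {n_ids[i] for i in members}
        if len(ids) >= 2 and ids <= perturbed:
            fused_groups.append(ids)
    fused: set[str] = set().union(*fused_groups) if fused_groups else set()
    return split, fused, fused_groups


def _coverage_integral(starts: np.ndarray, ends: np.ndarray):
    """F(x) = integral of the coverage-stack depth over [0, x).

    Intervals may overlap; F(x) = sum_i (min(x, e_i) - s_i)+ computed from
    sorted starts/ends with prefix sums.
    """
    s = np.sort(starts.astype(np.int64))
    e = np.sort(ends.astype(np.int64))
    s_pre = np.concatenate([[0], np.cumsum(s)])
    e_pre = np.concatenate([[0], np.cumsum(e)])

    def F(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(s, x, side="left")
        j = np.searchsorted(e, x, side="left")
        a = x * i - s_pre[i]  # sum over starts < x of (x - s)
        b = x * j - e_pre[j]  # sum over ends < x of (x - e)
        return (a - b).astype(float)

    return F


def _bin_means(F, edges: np.ndarray) -> np.ndarray:
    """Mean coverage depth in each [edges[i], edges[i+1]) span."""
    vals = F(np.clip(edges, 0, None))
    widths = np.diff(edges).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(widths > 0, np.diff(vals) / widths, 0.0)


def patient_coverage_intervals(cnvs) -> pd.DataFrame:
    """Per-patient union of CNV intervals, one row per merged interval.

    Counting coverage over these merged intervals yields, at each base,
    the number of patients with a CNV there (not the number of segments).
    """
    rows = []
    by_patient: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for seg in cnvs:
        by_patient.setdefault((seg.patient_id, seg.interval.chrom), []).append(
            (seg.interval.start, seg.interval.end)
        )
    for (pid, chrom), ivs in by_patient.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e, pid))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e, pid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "patient_id"])


def scaled_profile(
    regions,
    signal: pd.DataFrame,
    body: int = 2_000_000,
    flank: int = 1_000_000,
    bin_size: int = 10_000,
    aggregate: str = "median",
) -> MetaProfile:
    """Scale-regions meta-profile of interval coverage depth.

    Each region's body is linearly rescaled to ``body`` and divided into
    ``body / bin_size`` bins; flanks are unscaled. The per-bin value is
    the mean coverage depth of ``signal`` intervals (chrom/start/end
    rows) over the bin span, aggregated across regions by ``aggregate``
    (median by default). Regions shorter than two bins are skipped with a
    warning.
    """
    rd = _frame(regions)
    if not len(rd):
        raise ValueError("no regions")
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be median or mean")
    n_body = body // bin_size
    n_flank = flank // bin_size
    Fs = {
        chrom: _coverage_integral(sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in signal.groupby("chrom")
    }
    zero = lambda x: np.zeros(len(np.atleast_1d(x)), dtype=float)  # noqa: E731
    mat = []
    for row in rd.itertuples(index=False):
        length = row.end - row.start
        if length < 2 * bin_size:
            logger.warning("region %s:%d-%d shorter than two bins; skipped",
                           row.chrom, row.start, row.end)
            continue
        F = Fs.get(row.chrom, zero)
        up = row.start - flank + bin_size * np.arange(n_flank + 1)
        body_edges = row.start + np.round(length * np.arange(n_body + 1) / n_body).astype(np.int64)
        down = row.end + bin_size * np.arange(n_flank + 1)
        vals = np.concatenate([
            _bin_means(F, up),
            _bin_means(F, body_edges),
            _bin_means(F, down),
        ])
        mat.append(vals)
    if not mat:
        raise ValueError("all regions skipped")
    mat = np.vstack(mat)
    agg = np.median(mat, axis=0) if aggregate == "median" else mat.mean(axis=0)
    classes = ["flank5"] * n_flank + ["body"] * n_body + ["flank3"] * n_flank
    bins = pd.DataFrame({"bin": np.arange(len(agg)), "position_class": classes, "value": agg})
    return MetaProfile(bins=bins, bin_size=bin_size, aggregate=aggregate, n_regions=len(mat))


def reference_point_profile(
    centers,
    features: pd.DataFrame,
    flank: int = 200_000,
    bin_size: int = 5_000,
    aggregate: str = "mean",
) -> MetaProfile:
    """Reference-point meta-profile of feature coverage around centers.

    ``centers`` is a frame of intervals whose midpoints anchor the
    profile (e.g. TBRs); per-bin values are mean feature coverage depth
    over each bin from -flank to +flank, with spans beyond the chromosome
    start counting as zero (missing data as zero), averaged across
    centers.
    """
    cd = _frame(centers)
    if not len(cd):
        raise ValueError("no centers")
    n_bins = 2 * flank // bin_size
    Fs = {
        chrom: _coverage_integral(sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in features.groupby("chrom")
    }
    zero = lambda x: np.zeros(len(np.atleast_1d(x)), dtype=float)  # noqa: E731
    mat = np.zeros((len(cd), n_bins))
    for i, row in enumerate(cd.itertuples(index=False)):
        mid = (row.start + row.end) // 2
        edges = mid - flank + bin_size * np.arange(n_bins + 1)
        F = Fs.get(row.chrom, zero)
        mat[i] = _bin_means(F, edges)
    agg = mat.mean(axis=0) if aggregate == "mean" else np.median(mat, axis=0)
    offsets = -flank + bin_size * np.arange(n_bins) + bin_size // 2
    bins = pd.DataFrame({"bin": offsets, "position_class": "center_flank", "value": agg})
    return MetaProfile(bins=bins, bin_size=bin_size, aggregate=aggregate, n_regions=len(cd))
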