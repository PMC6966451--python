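"""CNV filtering, patient x TAD overlap matrices, and the random-region
permutation test for CNV enrichment/depletion.

A patient "exhibits a CNV in a TAD" if any of their filtered somatic
segments overlaps the TAD by at least 1 bp. Each TAD's observed patient
count is compared against counts for ``n_perm`` random regions of the same
size placed uniformly in the genome; a TAD is enriched (depleted) if at
most ``alpha`` of its random counterparts reach a count >= (<=) the
observed one.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import CNVSegment

logger = logging.getLogger(__name__)

__all__ = [
    "filter_cnvs",
    "sample_cohort",
    "overlap_matrix",
    "enrichment_test",
    "annotate_genes",
]

MIN_LEN = 1_000
MAX_LEN = 10_000_000
MIN_ABS_MEAN = 0.1
MIN_PROBES = 10


def filter_cnvs(
    segments: Sequence[CNVSegment],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    min_abs_mean: float = MIN_ABS_MEAN,
    min_probes: int = MIN_PROBES,
) -> list[CNVSegment]:
    """Keep segments longer than 1 kb, up to 10 Mb, with |segment mean|
    strictly above 0.1 and at least 10 probes."""
    kept = [
        s
        for s in segments
        if min_len < len(s) <= max_len
        and abs(s.segment_mean) > min_abs_mean
        and s.num_probes >= min_probes
    ]
    return kept


def sample_cohort(
    patients: pd.DataFrame,
    n: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample ``n`` patients per cancer type, without replacement.

    ``patients`` needs columns patient_id, cancer_type. Types with fewer
    than ``n`` patients are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    out = []
    for ctype, sub in patients.groupby("cancer_type", sort=True):
        ids = np.sort(sub["patient_id"].unique())
        if len(ids) < n:
            logger.warning("cancer type %s has %d < %d patients; excluded", ctype, len(ids), n)
            continue
        chosen = rng.choice(ids, size=n, replace=False)
        out.append(pd.DataFrame({"patient_id": chosen, "cancer_type": ctype}))
    if not out:
        return pd.DataFrame(columns=["patient_id", "cancer_type"])
    return pd.concat(out, ignore_index=True)


def _tad_frame(tads) -> pd.DataFrame:
    """Accept a ConsensusSegmentation, TADMap or DataFrame of intervals."""
    if hasattr(tads, "tads"):
        return tads.tads()[["chrom", "start", "end"]].reset_index(drop=True)
    if hasattr(tads, "intervals"):
        return tads.intervals[["chrom", "start", "end"]].reset_index(drop=True)
    return pd.DataFrame(tads)[["chrom", "start", "end"]].reset_index(drop=True)


def _tad_ids(tad_df: pd.DataFrame) -> list[str]:
    return [f"{r.chrom}:{r.start}-{r.end}" for r in tad_df.itertuples(index=False)]


def overlap_matrix(
    cnvs: Sequence[CNVSegment],
    tads,
    patients: Sequence[str] | None = None,
    sign: str | None = None,
) -> pd.DataFrame:
    """Binary patients x TADs matrix: 1 iff >= 1 bp CNV/TAD overlap.

    ``sign`` restricts to "gain" or "loss" segments. Patients with no
    (restricted) CNVs are excluded and logged; ``patients`` optionally
    limits and orders the rows.
    """
    tad_df = _tad_frame(tads)
    ids = _tad_ids(tad_df)
    chrom_arrays = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in tad_df.groupby("chrom")
    }
    if sign is not None:
        cnvs = [s for s in cnvs if s.sign == sign]
    patient_set = set(patients) if patients is not None else None
    hits: dict[str, set[int]] = {}
    for seg in cnvs:
        if patient_set is not None and seg.patient_id not in patient_set:
            continue
        arr = chrom_arrays.get(seg.interval.chrom)
        bucket = hits.setdefault(seg.patient_id, set())
        if arr is None:
            continue
        starts, ends, idx = arr
        lo = np.searchsorted(ends, seg.interval.start, side="right")
        hi = np.searchsorted(starts, seg.interval.end, side="left")
        bucket.update(idx[lo:hi].tolist())

    if patients is None:
        patients = sorted(hits)
    else:
        present = [p for p in patients if p in hits]
        absent = len(list(patients)) - len(present)
        if absent:
            logger.info("excluded %d patients with no filtered CNVs", absent)
        patients = present
    mat = np.zeros((len(patients), len(tad_df)), dtype=np.int8)
    for i, p in enumerate(patients):
        mat[i, sorted(hits.get(p, ()))] = 1
    return pd.DataFrame(mat, index=pd.Index(patients, name="patient_id"), columns=ids)


def _patient_arrays(cnvs: Sequence[CNVSegment], patient_index: Mapping[str, int]):
    """Per-chromosome (starts, ends, patient ids) sorted by start."""
    buckets: dict[str, list[tuple[int, int, int]]] = {}
    for seg in cnvs:
        pid = patient_index.get(seg.patient_id)
        if pid is None:
            continue
        buckets.setdefault(seg.interval.chrom, []).append(
            (seg.interval.start, seg.interval.end, pid)
        )
    arrays = {}
    for chrom, rows in buckets.items():
        rows.sort()
        a = np.asarray(rows, dtype=np.int64)
        arrays[chrom] = (a[:, 0], a[:, 1], a[:, 2])
    return arrays


def _count_patients(arrays, chrom: str, start: int, end: int) -> int:
    """Distinct patients with a CNV overlapping [start, end) by >= 1 bp."""
    arr = arrays.get(chrom)
    if arr is None:
        return 0
    starts, ends, pids = arr
    hi = np.searchsorted(starts, end, side="left")
    if hi == 0:
        return 0
    hit = pids[:hi][ends[:hi] > start]
    return int(np.unique(hit).size)


def enrichment_test(
    tads,
    cnvs: Sequence[CNVSegment],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    patients: Sequence[str] | None = None,
    plus_one: bool = False,
    exclusion_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Random-region permutation test for per-TAD CNV enrichment/depletion.

    For each TAD, ``n_perm`` random regions of identical size are drawn
    (chromosome chosen with probability proportional to the number of
    valid placements, start uniform, never crossing a chromosome end) and
    the number of patients with >= 1 bp CNV overlap is recorded.
    Empirical p-values are plain null fractions including ties
    (``plus_one`` adds the observed region to the null). Returns one row
    per TAD: observed, expectation, log2 fold-difference, p_enriched,
    p_depleted and the call at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    tad_df = _tad_frame(tads)
    ids = _tad_ids(tad_df)
    if patients is None:
        patients = sorted({s.patient_id for s in cnvs})
    patient_index = {p: i for i, p in enumerate(patients)}
    arrays = _patient_arrays(cnvs, patient_index)

    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)

    if exclusion_mask is not None:
        masked = {
            chrom: IntervalTree.from_tuples(
                (int(r.start), int(r.end)) for r in sub.itertuples(index=False)
            )
            for chrom, sub in exclusion_mask.groupby("chrom")
        }
    else:
        masked = {}

    rows = []
    denom = n_perm + 1 if plus_one else n_perm
    extra = 1 if plus_one else 0
    for tid, tad in zip(ids, tad_df.itertuples(index=False)):
        length = int(tad.end - tad.start)
        placements = np.maximum(sizes - length + 1, 0)
        if placements.sum() == 0:
            raise ValueError(f"TAD {tid} is longer than every chromosome")
        observed = _count_patients(arrays, tad.chrom, int(tad.start), int(tad.end))
        probs = placements / placements.sum()
        null = np.empty(n_perm, dtype=np.int64)
        chosen = rng.choice(len(chroms), size=n_perm, p=probs)
        starts = rng.integers(0, placements[chosen])
        for k in range(n_perm):
            c = chroms[chosen[k]]
            s = int(starts[k])
            if masked:
                tree = masked.get(c)
                tries = 0
                while tree is not None and tree.overlaps(s, s + length) and tries < 100:
                    ci = rng.choice(len(chroms), p=probs)
                    c = chroms[ci]
                    s = int(rng.integers(0, placements[ci]))
                    tree = masked.get(c)
                    tries += 1
            null[k] = _count_patients(arrays, c, s, s + length)
        expectation = float(null.mean())
        p_enr = (int((null >= observed).sum()) + extra) / denom
        p_dep = (int((null <= observed).sum()) + extra) / denom
        if observed > 0 and expectation > 0:
            log2fold = float(np.log2(observed / expectation))
        elif observed == 0 and expectation > 0:
            log2fold = -np.inf
        else:
            log2fold = np.nan
        call = "none"
        if p_enr <= alpha:
            call = "enriched"
        elif p_dep <= alpha:
            call = "depleted"
        rows.append((tid, tad.chrom, int(tad.start), int(tad.end), observed,
                     expectation, log2fold, p_enr, p_dep, call))
    return pd.DataFrame(
        rows,
        columns=["tad", "chrom", "start", "end", "observed", "expectation",
                 "log2_fold", "p_enriched", "p_depleted", "call"],
    )


def annotate_genes(tads, genes: pd.DataFrame) -> dict[str, list[str]]:
    """Map each TAD to the genes overlapping it by >= 1 bp.

    ``genes`` is a BED-like frame (chrom, start, end, name); a gene
    straddling two TADs is assigned to both, a gene in a TBR to none.
    """
    tad_df = _tad_frame(tads)
    ids = _tad_ids(tad_df)
    out: dict[str, list[str]] = {tid: [] for tid in ids}
    by_chrom = {chrom: sub for chrom, sub in genes.groupby("chrom")}
    for tid, tad in zip(ids, tad_df.itertuples(index=False)):
        sub = by_chrom.get(tad.chrom)
        if sub is None:
            continue
        hit = (sub["start"] < tad.end) & (sub["end"] > tad.start)
        out[tid] = sub.loc[hit, "name"].tolist()
    return out
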