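"""Readers/writers for tabular genomic formats and TAD map summaries.

All coordinates are held internally as 0-based half-open intervals.
Published TAD coordinates of the form ``chr9:21240000-24400999`` use
inclusive ends on a 1 kb grid; the ``"inclusive"`` dialect converts them by
``end + 1`` on input and ``end - 1`` on output, so round-trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("bed", "inclusive")

__all__ = [
    "GenomicInterval",
    "TADMap",
    "CNVSegment",
    "SurvivalRecord",
    "read_chrom_sizes",
    "read_tad_map",
    "write_tad_map",
    "read_bed",
    "read_seg_file",
    "read_clinical_table",
    "tad_map_summary",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TADMap:
    """An ordered, non-overlapping set of TADs for one tissue/cell line."""

    sample_id: str
    condition: str  # "normal" | "cancer"
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self):
        if self.condition not in ("normal", "cancer"):
            raise ValueError(f"condition must be normal|cancer, got {self.condition!r}")
        df = self.intervals.reset_index(drop=True)
        df = df[["chrom", "start", "end"]].astype({"start": np.int64, "end": np.int64})
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(f"empty/inverted interval {bad.chrom}:{bad.start}-{bad.end}")
        if (df["start"] < 0).any():
            raise ValueError("negative coordinates in TAD map")
        same = df["chrom"].values[1:] == df["chrom"].values[:-1]
        if np.any(same & (df["start"].values[1:] < df["end"].values[:-1])):
            i = int(np.nonzero(same & (df["start"].values[1:] < df["end"].values[:-1]))[0][0])
            raise ValueError(
                f"overlapping intervals in map {self.sample_id!r} near "
                f"{df['chrom'].values[i]}:{df['end'].values[i]}"
            )
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["chrom"]))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) arrays for one chromosome."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def iter_intervals(self) -> Iterable[GenomicInterval]:
        for row in self.intervals.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))


@dataclass(frozen=True)
class CNVSegment:
    """A somatic copy-number segment (log-ratio segment mean, probe count)."""

    patient_id: str
    cancer_type: str | None
    interval: GenomicInterval
    num_probes: int
    segment_mean: float

    def __post_init__(self):
        if self.num_probes < 1:
            raise ValueError("num_probes must be >= 1")
        if not np.isfinite(self.segment_mean):
            raise ValueError("segment_mean must be finite")

    @property
    def sign(self) -> str:
        return "gain" if self.segment_mean > 0 else "loss"

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class SurvivalRecord:
    """Overall survival: time to death or last follow-up, with covariates."""

    patient_id: str
    cancer_type: str
    time: float
    event: int  # 1 = death, 0 = censored
    age: float
    sex: str  # "female" | "male"

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chrom.sizes file -> {chrom: length}."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"], dtype={"chrom": str})
    if df["chrom"].duplicated().any():
        raise ValueError("duplicated chromosome in sizes file")
    sizes = dict(zip(df["chrom"], df["size"].astype(int)))
    if any(v <= 0 for v in sizes.values()):
        raise ValueError("chromosome lengths must be positive")
    return sizes


def _normalize(df: pd.DataFrame, dialect: str) -> pd.DataFrame:
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    if dialect == "inclusive":
        df = df.assign(end=df["end"] + 1)
    return df


def read_tad_map(
    path,
    sample_id: str,
    condition: str,
    dialect: str = "bed",
    chrom_sizes: Mapping[str, int] | None = None,
) -> TADMap:
    """Parse a BED-like TAD map (>=3 whitespace-separated columns).

    ``dialect="bed"`` reads 0-based half-open rows; ``dialect="inclusive"``
    reads 1 kb-grid inclusive ends (published style) and adds 1 to each end.
    Chromosomes absent from ``chrom_sizes`` are dropped with a warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates ({exc})") from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = _normalize(df, dialect)
    if chrom_sizes is not None and len(df):
        known = df["chrom"].isin(chrom_sizes)
        if not known.all():
            dropped = sorted(set(df.loc[~known, "chrom"]))
            logger.warning("%s: dropped %d intervals on unknown chromosomes %s",
                           path, int((~known).sum()), dropped)
            df = df[known]
        for chrom, sub in df.groupby("chrom"):
            if (sub["end"] > chrom_sizes[chrom]).any():
                raise ValueError(f"{path}: interval exceeds length of {chrom}")
    return TADMap(sample_id=sample_id, condition=condition, intervals=df)


def write_tad_map(tad_map: TADMap, path, dialect: str = "bed", extra: pd.Series | None = None) -> None:
    """Write a TAD map as BED3 (optional 4th column from ``extra``)."""
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    df = tad_map.intervals.copy()
    if dialect == "inclusive":
        df["end"] = df["end"] - 1
    if extra is not None:
        df["name"] = np.asarray(extra)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, chrom_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Generic BED reader (chrom, start, end[, name]) for gene sets / peaks."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3], dtype={0: str}, engine="python",
                     on_bad_lines="error")
    if df["name"].isna().all():
        df["name"] = [f"feature_{i}" for i in range(len(df))]
    df[["start", "end"]] = df[["start", "end"]].astype(np.int64)
    if chrom_sizes is not None:
        known = df["chrom"].isin(chrom_sizes)
        if not known.all():
            logger.warning("%s: dropped %d rows on unknown chromosomes", path, int((~known).sum()))
            df = df[known]
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


_SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "segment_mean"]


def read_seg_file(
    path,
    barcode_chars: int | None = 12,
    barcode_delimiter: str | None = None,
    barcode_fields: int | None = None,
    cancer_type: str | None = None,
) -> list[CNVSegment]:
    """Parse a SEG-style TSV (sample, chrom, start, end, num_probes, segment_mean).

    A header row is tolerated. ``patient_id`` is derived from the sample
    column: by default the first 12 characters (TCGA-style barcodes), or the
    first ``barcode_fields`` fields split on ``barcode_delimiter``. An
    optional 7th column supplies the cancer type, else ``cancer_type``.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: SEG file needs >=6 columns, found {df.shape[1]}")
    names = _SEG_COLUMNS + (["cancer_type"] if df.shape[1] >= 7 else [])
    df = df.iloc[:, : len(names)]
    df.columns = names
    # tolerate a header row
    first = df.iloc[0]
    try:
        int(first["start"])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)

    segments: list[CNVSegment] = []
    for lineno, row in enumerate(df.itertuples(index=False), 1):
        try:
            start, end = int(row.start), int(row.end)
            probes = int(row.num_probes)
            mean = float(row.segment_mean)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {lineno}: malformed numeric field ({exc})") from None
        sample = row.sample
        if barcode_delimiter is not None:
            pid = barcode_delimiter.join(sample.split(barcode_delimiter)[: (barcode_fields or 1)])
        elif barcode_chars is not None:
            pid = sample[:barcode_chars]
        else:
            pid = sample
        ctype = getattr(row, "cancer_type", None) or cancer_type
        segments.append(
            CNVSegment(
                patient_id=pid,
                cancer_type=ctype,
                interval=GenomicInterval(str(row.chrom), start, end),
                num_probes=probes,
                segment_mean=mean,
            )
        )
    return segments


_DEAD_WORDS = {"dead", "deceased", "1"}
_ALIVE_WORDS = {"alive", "living", "0"}


def read_clinical_table(path) -> list[SurvivalRecord]:
    """Parse a clinical TSV (patient_id, cancer_type, days, vital_status, age, sex).

    ``event = 1`` iff vital status indicates death. Rows with missing time or
    status are dropped (count logged); duplicated patient ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "cancer_type", "days", "vital_status", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"{path}: duplicated patient_id {dup!r}")

    n_in = len(df)
    days = pd.to_numeric(df["days"], errors="coerce")
    status = df["vital_status"].str.strip().str.lower()
    ok = days.notna() & status.isin(_DEAD_WORDS | _ALIVE_WORDS)
    if (~ok).any():
        logger.warning("%s: dropped %d/%d records with missing time or vital status",
                       path, int((~ok).sum()), n_in)
    records = []
    for i in df.index[ok]:
        records.append(
            SurvivalRecord(
                patient_id=df.at[i, "patient_id"],
                cancer_type=df.at[i, "cancer_type"],
                time=float(days[i]),
                event=1 if status[i] in _DEAD_WORDS else 0,
                age=float(df.at[i, "age"]),
                sex=df.at[i, "sex"].strip().lower(),
            )
        )
    return records


def tad_map_summary(maps: list[TADMap]) -> tuple[pd.DataFrame, pd.Series]:
    """Per-map TAD count/median size plus the median-of-medians per condition."""
    if not maps:
        raise ValueError("need at least one TAD map")
    rows = []
    for m in maps:
        sizes = (m.intervals["end"] - m.intervals["start"]).to_numpy()
        rows.append(
            {
                "sample_id": m.sample_id,
                "condition": m.condition,
                "n_tads": len(sizes),
                "median_size": float(np.median(sizes)) if len(sizes) else np.nan,
            }
        )
    per_map = pd.DataFrame(rows)
    med_of_med = per_map.groupby("condition")["median_size"].median()
    return per_map, med_of_med
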