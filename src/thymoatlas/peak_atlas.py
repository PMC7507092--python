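"""Interval bookkeeping for open chromatin regions (OCRs).

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  The module covers peak merging, TSS/distal
classification against a TSS catalog, accessible-peak counting at a
read-count floor, cohort set partitions, and a shuffled-peak overlap
null used to score peak/annotation enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start


class PeakSet:
    """A set of genomic intervals sorted by (chrom, start).

    Backed by a DataFrame with columns chrom/start/end/name/score.  If
    ``merged`` is set, no two intervals overlap.
    """

    def __init__(self, intervals: pd.DataFrame, merged: bool = False):
        df = intervals.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"PeakSet requires a '{col}' column")
        if "name" not in df.columns:
            df["name"] = [f"peak_{i}" for i in range(len(df))]
        if "score" not in df.columns:
            df["score"] = 0.0
        bad = ~(df["start"] < df["end"]) | (df["start"] < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"malformed interval at row {i}: need 0 <= start < end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.df = df[["chrom", "start", "end", "name", "score"]]
        self.merged = merged
        if merged:
            grp = self.df.groupby("chrom", sort=False)
            for _, sub in grp:
                if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                    raise ValueError("merged PeakSet contains overlapping intervals")

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], merged: bool = False
    ) -> "PeakSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name or f"peak_{i}", iv.score or 0.0)
            for i, iv in enumerate(intervals)
        ]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def names(self) -> pd.Series:
        return self.df["name"]

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


def read_bed(path) -> PeakSet:
    """Read a BED3/BED6 file; malformed lines raise with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ValueError(f"{path}:{lineno}: need 0 <= start < end")
            name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            rows.append((parts[0], start, end, name, score))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]))


def write_bed(peaks: PeakSet, path) -> None:
    df = peaks.df.copy()
    df["strand"] = "."
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


@dataclass
class AtlasConfig:
    """Thresholds for TSS classification and accessibility counting."""

    tss_window_bp: int = 1_000
    accessibility_read_floor: int = 10

    def __post_init__(self) -> None:
        if self.tss_window_bp <= 0 or self.accessibility_read_floor <= 0:
            raise ValueError("tss_window_bp and accessibility_read_floor must be > 0")


def merge_peaks(peak_sets: Sequence[PeakSet]) -> PeakSet:
    """Union-merge peak sets; overlapping or book-ended intervals coalesce.

    The merged interval is named after the first (leftmost) member.
    Idempotent and commutative.
    """
    if not peak_sets:
        raise ValueError("merge_peaks needs at least one PeakSet")
    df = pd.concat([ps.df for ps in peak_sets], ignore_index=True)
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        names = sub["name"].to_numpy()
        cur_s, cur_e, cur_n = starts[0], ends[0], names[0]
        for s, e, n in zip(starts[1:], ends[1:], names[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, cur_n, 0.0))
                cur_s, cur_e, cur_n = s, e, n
        out.append((chrom, cur_s, cur_e, cur_n, 0.0))
    merged = pd.DataFrame(out, columns=["chrom", "start", "end", "name", "score"])
    return PeakSet(merged, merged=True)


def classify_tss(peaks: PeakSet, genome, cfg: AtlasConfig | None = None) -> pd.Series:
    """Label each peak ``TSS`` or ``distal``.

    A peak is TSS-proximal iff it overlaps the closed genomic span
    ``[tss - w, tss + w]`` of any TSS by at least one base.
    """
    cfg = cfg or AtlasConfig()
    w = cfg.tss_window_bp
    known = {name for name, _ in genome.chromosomes}
    tss_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in genome.tss_catalog.groupby("chrom")
    }
    labels = np.empty(len(peaks), dtype=object)
    for i, (chrom, start, end) in enumerate(
        zip(peaks.df["chrom"], peaks.df["start"], peaks.df["end"])
    ):
        if chrom not in known:
            raise ValueError(f"peak on chromosome {chrom!r} absent from genome model")
        positions = tss_by_chrom.get(chrom)
        if positions is None:
            labels[i] = "distal"
            continue
        # peak covers bases start..end-1; window covers tss-w..tss+w
        lo = np.searchsorted(positions, start - w, side="left")
        labels[i] = (
            "TSS" if lo < len(positions) and positions[lo] <= (end - 1) + w else "distal"
        )
    return pd.Series(labels, index=peaks.names.to_numpy(), name="tss_class")


def count_accessible(counts, sample: str, cfg: AtlasConfig | None = None) -> int:
    """Number of features with read count >= the accessibility floor."""
    cfg = cfg or AtlasConfig()
    mat = counts.counts if hasattr(counts, "counts") else counts
    if sample not in mat.columns:
        raise KeyError(f"unknown sample id {sample!r}")
    return int((mat[sample] >= cfg.accessibility_read_floor).sum())


def cohort_presence(counts, sample_ids: Sequence[str], cfg: AtlasConfig | None = None) -> set:
    """Features accessible (count >= floor) in at least one sample of a cohort."""
    cfg = cfg or AtlasConfig()
    mat = counts.counts if hasattr(counts, "counts") else counts
    missing = [s for s in sample_ids if s not in mat.columns]
    if missing:
        raise KeyError(f"unknown sample ids {missing!r}")
    mask = (mat[list(sample_ids)] >= cfg.accessibility_read_floor).any(axis=1)
    return set(mat.index[mask])


def overlap_partition(
    union_peaks: PeakSet | Iterable[str], presence_a: set, presence_b: set
) -> tuple[int, int, int]:
    """Partition peaks present in either cohort into (shared, only_A, only_B)."""
    if isinstance(union_peaks, PeakSet):
        universe = set(union_peaks.names)
    else:
        universe = set(union_peaks)
    stray = (set(presence_a) | set(presence_b)) - universe
    if stray:
        raise ValueError(f"presence ids outside the union peak set: {sorted(stray)[:5]}")
    a, b = set(presence_a), set(presence_b)
    return len(a & b), len(a - b), len(b - a)


def _overlap_flags(starts, ends, ann_starts, ann_ends) -> np.ndarray:
    """Vectorized >=1 bp overlap of query intervals against merged sorted intervals."""
    if len(ann_starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    # first annotation whose end > query start; overlap iff its start < query end
    j = np.searchsorted(ann_ends, starts, side="right")
    inside = j < len(ann_starts)
    flags = np.zeros(len(starts), dtype=bool)
    flags[inside] = ann_starts[j[inside]] < ends[inside]
    return flags


def overlap_count(peaks: PeakSet, annotation: PeakSet) -> int:
    """Number of peaks overlapping the annotation by >= 1 bp."""
    ann = annotation if annotation.merged else merge_peaks([annotation])
    total = 0
    ann_by_chrom = dict(tuple(ann.df.groupby("chrom", sort=False)))
    for chrom, sub in peaks.df.groupby("chrom", sort=False):
        asub = ann_by_chrom.get(chrom)
        if asub is None:
            continue
        flags = _overlap_flags(
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            asub["start"].to_numpy(),
            asub["end"].to_numpy(),
        )
        total += int(flags.sum())
    return total


def shuffled_overlap_enrichment(
    peaks: PeakSet,
    annotation: PeakSet,
    genome,
    n_perm: int,
    seed: int,
) -> tuple[int, float, float]:
    """Observed vs expected peak/annotation overlap under a shuffle null.

    Each permutation re-places every peak uniformly at random within its
    own chromosome, preserving its length; shuffled peaks may overlap
    each other.  Returns ``(observed, expected, fold)``; ``fold`` is NaN
    when the expected overlap is zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_len = dict(genome.chromosomes)
    for chrom in peaks.df["chrom"].unique():
        if chrom not in chrom_len:
            raise ValueError(f"peak on chromosome {chrom!r} absent from genome model")
    observed = overlap_count(peaks, annotation)
    ann = annotation if annotation.merged else merge_peaks([annotation])
    ann_by_chrom = dict(tuple(ann.df.groupby("chrom", sort=False)))
    total = np.zeros(n_perm)
    for chrom, sub in peaks.df.groupby("chrom", sort=False):
        lengths = (sub["end"] - sub["start"]).to_numpy()
        max_start = chrom_len[chrom] - lengths
        if (max_start < 0).any():
            raise ValueError(f"peak longer than chromosome {chrom!r}")
        asub = ann_by_chrom.get(chrom)
        if asub is None:
            continue
        ann_starts = asub["start"].to_numpy()
        ann_ends = np.sort(asub["end"].to_numpy())
        for p in range(n_perm):
            starts = rng.integers(0, max_start + 1)
            flags = _overlap_flags(starts, starts + lengths, ann_starts, ann_ends)
            total[p] += flags.sum()
    expected = float(total.mean())
    fold = observed / expected if expected > 0 else math.nan
    return observed, expected, fold
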