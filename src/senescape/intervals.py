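"""Genomic interval containers and BED I/O.

All coordinates are 0-based half-open, matching BED. Chromosome names are
taken verbatim; mixing naming schemes across files is treated as a hard
error downstream, never silently reconciled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_SKIP_PREFIXES = ("track", "browser", "#")

#: Category of each of the 25 segmentation states.  States 1-5 promoter,
#: 6-12 enhancer, 13-18 transcription, 19-25 miscellaneous; state 25 is the
#: mark-free "undefined" (quiescent) state.
DEFAULT_STATE_CATEGORIES: dict[str, str] = (
    {str(i): "promoter" for i in range(1, 6)}
    | {str(i): "enhancer" for i in range(6, 13)}
    | {str(i): "transcription" for i in range(13, 19)}
    | {str(i): "miscellaneous" for i in range(19, 26)}
)
UNDEFINED_STATE = "25"


class BedParseError(ValueError):
    """Raised for malformed BED records; message names the offending line."""


@dataclass
class IntervalSet:
    """A set of labeled genomic intervals backed by a DataFrame.

    Columns: chrom (str), start (int), end (int), name (str), score (float,
    NaN when absent), strand ('+', '-' or '.').  start < end for every
    record; names need not be unique.
    """

    df: pd.DataFrame

    REQUIRED = ("chrom", "start", "end")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("name", ""), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[["chrom", "start", "end", "name", "score", "strand"]]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["name"] = df["name"].astype(str)
        if len(df):
            bad = df["start"] >= df["end"]
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"interval record {i}: start >= end "
                    f"({df['start'].iat[i]} >= {df['end'].iat[i]})"
                )
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def sort(self) -> "IntervalSet":
        """Stable total order by (chrom, start, end, name)."""
        out = self.df.sort_values(
            ["chrom", "start", "end", "name"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(out)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {c: g for c, g in self.df.groupby("chrom", sort=True)}

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, name[, score[, strand]]])."""
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        rows = []
        for r in records:
            r = list(r) + ["", np.nan, "."][len(r) - 3 :] if len(r) < 6 else list(r)
            rows.append(r[:6])
        df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
        return cls(df)


@dataclass
class ChromatinStateMap:
    """A genome segmentation: intervals named by state id ('1'..'25').

    State instances within one chromosome must be non-overlapping (the
    segmentation tiles the genome).  ``state_categories`` maps every state id
    to one of {promoter, enhancer, transcription, miscellaneous};
    ``undefined_state`` designates the mark-free state inside miscellaneous.
    """

    intervals: IntervalSet
    state_categories: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STATE_CATEGORIES)
    )
    undefined_state: str = UNDEFINED_STATE

    def __post_init__(self) -> None:
        unknown = set(self.intervals.df["name"]) - set(self.state_categories)
        if unknown:
            raise ValueError(f"states without a category: {sorted(unknown)[:5]}")
        for chrom, g in self.intervals.by_chrom().items():
            g = g.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping state instances on {chrom}")

    def category_of(self, state: str) -> str:
        return self.state_categories[state]

    def instance_ids(self) -> pd.Series:
        d = self.intervals.df
        return d["chrom"] + ":" + d["start"].astype(str) + "-" + d["end"].astype(str)


def read_bed(path) -> IntervalSet:
    """Read a BED file (>= 3 tab-separated columns) into an IntervalSet.

    track/browser/comment lines are skipped.  Malformed coordinates raise
    :class:`BedParseError` naming the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from e
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative start")
            name = parts[3] if len(parts) > 3 else ""
            score = np.nan
            if len(parts) > 4 and parts[4] not in ("", "."):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    logger.info("read_bed: %s -> %d records", path, len(df))
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write an IntervalSet as BED; optional trailing columns are omitted
    right-to-left (a record with strand but no score gets a 0 score
    placeholder, per BED column order)."""
    with open(path, "w") as fh:
        for rec in intervals.df.itertuples(index=False):
            fields = [rec.chrom, str(rec.start), str(rec.end)]
            has_strand = rec.strand in ("+", "-")
            has_score = not (isinstance(rec.score, float) and np.isnan(rec.score))
            has_name = rec.name != ""
            if has_name or has_score or has_strand:
                fields.append(rec.name if has_name else ".")
            if has_score or has_strand:
                fields.append(_fmt_score(rec.score) if has_score else "0")
            if has_strand:
                fields.append(rec.strand)
            fh.write("\t".join(fields) + "\n")
    logger.info("write_bed: %d records -> %s", len(intervals), path)


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# interval arithmetic on sorted arrays


def merge_intervals(iv: IntervalSet) -> IntervalSet:
    """Union of intervals: merged, sorted, non-overlapping per chromosome."""
    out = []
    for chrom, g in iv.by_chrom().items():
        g = g.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(g["start"], g["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return IntervalSet.from_records(out)


def overlap_flags(query: IntervalSet, domains: IntervalSet) -> np.ndarray:
    """For each query interval, whether >= 1 bp intersects any domain.

    Domains are merged first; query chromosomes absent from the domain set
    simply get False (a domain set need not cover every chromosome).
    """
    merged = merge_intervals(domains).by_chrom()
    flags = np.zeros(len(query), dtype=bool)
    d = query.df
    for chrom, g in d.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        dom = merged[chrom]
        starts = dom["start"].to_numpy()
        ends = dom["end"].to_numpy()
        qs = g["start"].to_numpy()
        qe = g["end"].to_numpy()
        # domain i overlaps [qs, qe) iff start_i < qe and end_i > qs
        i0 = np.searchsorted(ends, qs, side="right")
        i1 = np.searchsorted(starts, qe, side="left")
        flags[g.index.to_numpy()] = i1 > i0
    return flags


def overlapped_bp(query: IntervalSet, domains: IntervalSet) -> np.ndarray:
    """Number of query bp covered by the union of the domains."""
    merged = merge_intervals(domains).by_chrom()
    out = np.zeros(len(query), dtype=np.int64)
    for chrom, g in query.df.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        dom = merged[chrom]
        starts = dom["start"].to_numpy()
        ends = dom["end"].to_numpy()
        for idx, qs, qe in zip(g.index, g["start"], g["end"]):
            i0 = np.searchsorted(ends, qs, side="right")
            i1 = np.searchsorted(starts, qe, side="left")
            bp = 0
            for j in range(i0, i1):
                bp += min(qe, ends[j]) - max(qs, starts[j])
            out[idx] = bp
    return out
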