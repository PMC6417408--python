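"""Sliding-window mutational-event statistic and divergence hotspots.

For a window of L alignment columns the statistic is

    percent = 100 * (NS + ID) / L

where NS counts columns holding at least two distinct bases from
{A,C,G,T} among the rows (gaps and N are ignored for distinctness), and
ID counts indel events: maximal gap runs with identical column bounds are
one event regardless of how many rows share them (``indel_mode
='per-row'`` counts each row's run separately instead).  An event is
assigned to the window containing its first column.

Windows advance by ``step`` columns over the alignment (not the
ungapped reference); the terminal window is truncated at the last column
and its percent uses its actual length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Alignment, GENIC_KINDS, PlastomeRecord

logger = logging.getLogger(__name__)

#: hotspot thresholds (percent) used for published Ipomoea data sets
PRESET_THRESHOLDS = {"genus": 13.0, "batatas": 3.2, "quamoclit": 7.5}


@dataclass(frozen=True)
class IndelEvent:
    """A maximal gap run; rows sharing exactly these bounds are one event."""

    col_start: int
    col_end: int
    member_rows: frozenset[int]


@dataclass(frozen=True)
class WindowStat:
    col_start: int
    col_end: int
    ns: int
    id_count: int

    @property
    def length(self) -> int:
        return self.col_end - self.col_start

    @property
    def percent(self) -> float:
        return 100.0 * (self.ns + self.id_count) / self.length


@dataclass(frozen=True)
class Hotspot:
    col_start: int
    col_end: int
    max_percent: float
    name: str | None = None
    ref_start: int | None = None
    ref_end: int | None = None


def _matrix(alignment: Alignment) -> np.ndarray:
    return np.frombuffer(
        "".join(alignment.rows).encode(), dtype=np.uint8
    ).reshape(alignment.n_rows, alignment.n_cols)


def substitution_columns(alignment: Alignment) -> np.ndarray:
    """Boolean mask over columns: >=2 distinct bases from {A,C,G,T}."""
    arr = _matrix(alignment)
    distinct = np.zeros(alignment.n_cols, dtype=np.int8)
    for b in b"ACGT":
        distinct += (arr == b).any(axis=0).astype(np.int8)
    return distinct >= 2


def indel_events(alignment: Alignment) -> list[IndelEvent]:
    """All distinct maximal gap runs, grouped by identical bounds."""
    runs: dict[tuple[int, int], set[int]] = {}
    gap = ord("-")
    arr = _matrix(alignment)
    for r in range(alignment.n_rows):
        row = arr[r] == gap
        if not row.any():
            continue
        padded = np.concatenate(([False], row, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            runs.setdefault((int(s), int(e)), set()).add(r)
    return [
        IndelEvent(col_start=s, col_end=e, member_rows=frozenset(rows))
        for (s, e), rows in sorted(runs.items())
    ]


def count_events(
    alignment: Alignment,
    col_start: int = 0,
    col_end: int | None = None,
    indel_mode: str = "per-event",
    _sub_cols: np.ndarray | None = None,
    _events: list[IndelEvent] | None = None,
) -> tuple[int, int]:
    """(NS, ID) for the column range [col_start, col_end)."""
    if col_end is None:
        col_end = alignment.n_cols
    if not (0 <= col_start <= col_end <= alignment.n_cols):
        raise ValueError("bad column range")
    if indel_mode not in ("per-event", "per-row"):
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    sub = substitution_columns(alignment) if _sub_cols is None else _sub_cols
    events = indel_events(alignment) if _events is None else _events
    ns = int(sub[col_start:col_end].sum())
    in_range = [ev for ev in events if col_start <= ev.col_start < col_end]
    if indel_mode == "per-event":
        id_count = len(in_range)
    else:
        id_count = sum(len(ev.member_rows) for ev in in_range)
    return ns, id_count


def sliding_window_stats(
    alignment: Alignment,
    window: int = 800,
    step: int = 400,
    indel_mode: str = "per-event",
) -> list[WindowStat]:
    """Window statistics at starts 0, step, 2*step, ...; the final window
    is truncated at the last column."""
    if window < step:
        warnings.warn("window < step leaves uncovered columns", stacklevel=2)
    n = alignment.n_cols
    sub = substitution_columns(alignment)
    events = indel_events(alignment)
    stats = []
    for start in range(0, n, step):
        end = min(start + window, n)
        ns, idc = count_events(
            alignment, start, end, indel_mode, _sub_cols=sub, _events=events
        )
        if idc > end - start:
            logger.warning(
                "window [%d,%d): indel count %d exceeds window length", start,
                end, idc,
            )
        stats.append(WindowStat(col_start=start, col_end=end, ns=ns, id_count=idc))
    return stats


def identical_sites_percent(alignment: Alignment) -> float:
    """Percent of columns where every row carries the same character
    (gaps count as characters)."""
    arr = _matrix(alignment)
    same = (arr == arr[0]).all(axis=0)
    return 100.0 * float(same.mean())


def mean_variation(stats: list[WindowStat]) -> float:
    """Unweighted mean of window percents."""
    if not stats:
        raise ValueError("no windows")
    return float(np.mean([w.percent for w in stats]))


def call_hotspots(stats: list[WindowStat], threshold: float) -> list[Hotspot]:
    """Merge consecutive windows with percent > threshold into hotspots."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hotspots = []
    run: list[WindowStat] = []
    for w in stats:
        if w.percent > threshold:
            run.append(w)
        elif run:
            hotspots.append(_merge(run))
            run = []
    if run:
        hotspots.append(_merge(run))
    return hotspots


def _merge(run: list[WindowStat]) -> Hotspot:
    return Hotspot(
        col_start=run[0].col_start,
        col_end=run[-1].col_end,
        max_percent=max(w.percent for w in run),
    )


# ---------------------------------------------------------------------------
# projection onto a reference genome


def column_to_ref(row: str, col: int) -> int:
    """Reference coordinate of an alignment column: the number of non-gap
    characters strictly before it."""
    return col - row[:col].count("-")


def _name_interval(record: PlastomeRecord, start: int, end: int) -> str:
    """Feature/IGS label for a reference interval, intron-aware."""
    feats = [f for f in record.features if f.kind in GENIC_KINDS]
    names = []
    for f in sorted(feats, key=lambda f: f.start):
        if f.start < end and f.end > start:
            exonic = any(s < end and e > start for s, e in f.intervals)
            label = f.name if exonic else f"{f.name} intron"
            if label not in names:
                names.append(label)
    if names:
        return "/".join(names)
    left = max((f for f in feats if f.end <= start), key=lambda f: f.end,
               default=None)
    right = min((f for f in feats if f.start >= end), key=lambda f: f.start,
                default=None)
    return f"{left.name if left else 'start'}-{right.name if right else 'end'}"


def map_hotspots(
    hotspots: list[Hotspot],
    alignment: Alignment,
    reference_row: str,
    reference_record: PlastomeRecord,
) -> list[Hotspot]:
    """Project hotspots through the reference row's gap structure onto
    reference-genome coordinates and name them by overlapping features or
    the intergenic spacer."""
    row = alignment.row(reference_row)
    gaps = np.cumsum(np.frombuffer(row.encode(), dtype=np.uint8) == ord("-"))
    out = []
    for h in hotspots:
        rs = h.col_start - int(gaps[h.col_start - 1]) if h.col_start else 0
        re_ = h.col_end - int(gaps[h.col_end - 1]) if h.col_end else 0
        name = _name_interval(reference_record, rs, re_)
        out.append(
            Hotspot(col_start=h.col_start, col_end=h.col_end,
                    max_percent=h.max_percent, name=name,
                    ref_start=rs, ref_end=re_)
        )
    return out


# ---------------------------------------------------------------------------
# tabular views


def stats_to_frame(stats: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "col_start_1based": w.col_start + 1,
                "col_end": w.col_end,
                "NS": w.ns,
                "ID": w.id_count,
                "L": w.length,
                "percent": round(w.percent, 4),
            }
            for w in stats
        ]
    )


def hotspots_to_frame(hotspots: list[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "col_start_1based": h.col_start + 1,
                "col_end": h.col_end,
                "ref_start_1based": (h.ref_start + 1) if h.ref_start is not None else "",
                "ref_end": h.ref_end if h.ref_end is not None else "",
                "max_percent": round(h.max_percent, 4),
                "name": h.name or "",
            }
            for h in hotspots
        ]
    )


def hotspots_to_bed(hotspots: list[Hotspot], ref_name: str) -> str:
    """BED lines (0-based half-open) on reference coordinates."""
    lines = []
    for h in hotspots:
        if h.ref_start is None:
            continue
        lines.append(
            f"{ref_name}\t{h.ref_start}\t{h.ref_end}\t{h.name or '.'}\t"
            f"{h.max_percent:.2f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
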