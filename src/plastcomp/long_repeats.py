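"""Dispersed repeat pairs: forward (F), palindromic (P), reverse (R) and
complement (C) matches of at least 30 bp and >90% identity.

The search compares the genome against each of its four transforms
(itself, reverse complement, reverse, complement) with exact k-mer seeds,
then computes, on every seeded diagonal, all maximal windows whose ends
are matches and whose identity exceeds the threshold.  Windows contained
in a longer reported window of the same type are suppressed, and the
symmetric duplicate of each pair (found from either copy) is emitted
once.

Identity is judged on the window as a whole: a reported pair cannot be
extended by one base in either direction without dropping to or below
the identity threshold or running off the sequence.  The two IR copies
of a plastome appear as one giant P pair; ``mask_second_ir`` removes it
while keeping dispersed repeats.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import GENIC_KINDS, PlastomeRecord, complement, revcomp
from .structure import QuadripartitePartition

REPEAT_TYPES = ("F", "P", "R", "C")

DEFAULT_BINS = ((30, 59), (60, 79), (80, 139), (140, None))


@dataclass(frozen=True)
class RepeatPair:
    """One dispersed repeat: two copies related by the type transform."""

    rtype: str
    pos1: int
    pos2: int
    length: int
    mismatches: int
    loc1: str | None = None
    loc2: str | None = None
    region1: str | None = None
    region2: str | None = None

    @property
    def identity(self) -> float:
        return (self.length - self.mismatches) / self.length


def _transform(seq: str, rtype: str) -> str:
    if rtype == "F":
        return seq
    if rtype == "P":
        return revcomp(seq)
    if rtype == "R":
        return seq[::-1]
    if rtype == "C":
        return complement(seq)
    raise ValueError(f"unknown repeat type {rtype!r}")


def _pair_positions(i: int, j: int, length: int, n: int, rtype: str):
    """Map a match at S position i / transform position j back to two
    genome start positions."""
    if rtype in ("F", "C"):
        return i, j
    return i, n - j - length  # P and R reverse the coordinate axis


def _max_windows(p: np.ndarray, min_identity: float, min_len: int):
    """Maximal qualifying windows over match positions ``p`` on one
    diagonal.

    A window is a pair of match indices (a, b): it spans p[a]..p[b],
    contains b-a+1 matches, and qualifies when its identity exceeds
    ``min_identity`` and its length reaches ``min_len``.  For each start
    ``a`` the farthest qualifying end B(a) is found via a suffix-maximum
    of g[x] = x - min_identity * p[x] (the qualifying condition is
    g[b] > g[a] - (1 - min_identity)); containment between starts is then
    filtered in one ascending pass.
    """
    m = len(p)
    if m == 0:
        return []
    idx = np.arange(m, dtype=np.float64)
    g = idx - min_identity * p
    suffix_max = np.maximum.accumulate(g[::-1])[::-1]
    cutoffs = g - (1.0 - min_identity)
    # largest b with suffix_max[b] > cutoff  (suffix_max is non-increasing)
    b_idx = np.searchsorted(-suffix_max, -cutoffs, side="left") - 1
    out = []
    best_b = -1
    for a in range(m):
        b = int(b_idx[a])
        if b <= best_b:
            continue
        length = int(p[b] - p[a] + 1)
        if length >= min_len:
            out.append((int(p[a]), int(p[b]), length, length - (b - a + 1)))
        best_b = b
    return out


def find_repeats(
    record: PlastomeRecord | str,
    min_len: int = 30,
    min_identity: float = 0.90,
    k: int = 15,
    types: tuple[str, ...] = REPEAT_TYPES,
    mask_second_ir: bool = False,
    partition: QuadripartitePartition | None = None,
) -> list[RepeatPair]:
    """Find dispersed repeat pairs of the requested types.

    ``mask_second_ir`` replaces the IRb region (from ``partition``, which
    must be in the record's coordinate system) with N before searching,
    removing the giant IR-vs-IR palindromic pair.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record.upper()
    n = len(seq)
    if n < min_len:
        return []
    if mask_second_ir:
        if partition is None:
            raise ValueError("mask_second_ir requires a partition")
        s, e = partition.irb
        seq = seq[:s] + "N" * (e - s) + seq[e:]
    s_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_code = ord("N")
    pairs: list[RepeatPair] = []
    for rtype in types:
        t = _transform(seq, rtype)
        t_arr = np.frombuffer(t.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = defaultdict(list)
        for j in range(n - k + 1):
            kmer = t[j : j + k]
            if "N" not in kmer:
                index[kmer].append(j)
        diagonals: set[int] = set()
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            for j in index.get(kmer, ()):
                diagonals.add(i - j)
        if rtype == "F":
            diagonals.discard(0)  # a segment trivially matches itself
        seen: set[tuple[int, int, int]] = set()
        for d in sorted(diagonals):
            i0, i1 = max(0, d), min(n, n + d)
            s_slice = s_arr[i0:i1]
            t_slice = t_arr[i0 - d : i1 - d]
            m = (s_slice == t_slice) & (s_slice != n_code)
            p = np.flatnonzero(m) + i0
            for ps, pe, length, mism in _max_windows(p, min_identity, min_len):
                j_start = ps - d
                pos1, pos2 = _pair_positions(ps, j_start, length, n, rtype)
                lo, hi = min(pos1, pos2), max(pos1, pos2)
                if rtype == "F" and lo == hi:
                    continue
                key = (lo, hi, length)
                if key not in seen:
                    seen.add(key)
                    pairs.append(
                        RepeatPair(rtype=rtype, pos1=lo, pos2=hi,
                                   length=length, mismatches=mism)
                    )
    return _suppress_contained(pairs)


def _suppress_contained(pairs: list[RepeatPair]) -> list[RepeatPair]:
    """Drop pairs whose both copies lie inside the corresponding copies of
    a longer pair of the same type."""
    out = []
    by_type: dict[str, list[RepeatPair]] = defaultdict(list)
    for p in pairs:
        by_type[p.rtype].append(p)
    for rtype, group in by_type.items():
        group.sort(key=lambda r: -r.length)
        kept: list[RepeatPair] = []
        for r in group:
            contained = any(
                b.pos1 <= r.pos1 and r.pos1 + r.length <= b.pos1 + b.length
                and b.pos2 <= r.pos2 and r.pos2 + r.length <= b.pos2 + b.length
                and b.length > r.length
                for b in kept
            )
            if not contained:
                kept.append(r)
        out.extend(kept)
    out.sort(key=lambda r: (r.pos1, r.pos2, r.rtype))
    return out


# ---------------------------------------------------------------------------
# location labelling


def locate(record: PlastomeRecord, start: int, end: int) -> str:
    """Feature or IGS label for an interval, by majority overlap.

    Returns the gene name when the interval mostly overlaps a genic
    feature, otherwise "IGS(left-right)"; exact ties join both labels
    with "/".
    """
    feats = [f for f in record.features if f.kind in GENIC_KINDS]
    overlaps: dict[str, int] = {}
    for f in feats:
        ov = sum(max(0, min(e, end) - max(s, start)) for s, e in f.intervals)
        if ov > 0:
            overlaps[f.name] = max(overlaps.get(f.name, 0), ov)
    genic_total = 0
    arr = np.zeros(end - start, dtype=bool)
    for f in feats:
        for s, e in f.intervals:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                arr[lo - start : hi - start] = True
    genic_total = int(arr.sum())
    igs_overlap = (end - start) - genic_total
    candidates = list(overlaps.items())
    if igs_overlap > 0:
        left = max((f for f in feats if f.end <= start),
                   key=lambda f: f.end, default=None)
        right = min((f for f in feats if f.start >= end),
                    key=lambda f: f.start, default=None)
        # flanks for a partially covered interval: the overlapped genes
        if left is None and overlaps:
            left = max((f for f in feats if f.start < start), key=lambda f: f.end,
                       default=None)
        if right is None and overlaps:
            right = min((f for f in feats if f.end > end), key=lambda f: f.start,
                        default=None)
        lname = left.name if left else "start"
        rname = right.name if right else "end"
        candidates.append((f"IGS({lname}-{rname})", igs_overlap))
    if not candidates:
        return "IGS(?)"
    best = max(ov for _, ov in candidates)
    labels = [name for name, ov in candidates if ov == best]
    return "/".join(labels)


def _majority_region(
    partition: QuadripartitePartition, start: int, end: int
) -> str:
    best_name, best_ov = "?", -1
    for name, (s, e) in partition.regions().items():
        ov = max(0, min(e, end) - max(s, start))
        if ov > best_ov:
            best_name, best_ov = name, ov
    return best_name


def classify_repeat_locations(
    pairs: list[RepeatPair],
    record: PlastomeRecord,
    partition: QuadripartitePartition | None = None,
) -> tuple[list[RepeatPair], pd.DataFrame]:
    """Label both copies of each pair with gene/IGS context and region;
    also return a per-location count summary.

    Coordinates must be in the partition's (canonical) system; pass the
    rotated record.
    """
    annotated = []
    counts: dict[str, int] = {}
    for r in pairs:
        loc1 = locate(record, r.pos1, r.pos1 + r.length)
        loc2 = locate(record, r.pos2, r.pos2 + r.length)
        reg1 = _majority_region(partition, r.pos1, r.pos1 + r.length) if partition else None
        reg2 = _majority_region(partition, r.pos2, r.pos2 + r.length) if partition else None
        annotated.append(
            replace(r, loc1=loc1, loc2=loc2, region1=reg1, region2=reg2)
        )
        for loc in (loc1, loc2):
            counts[loc] = counts.get(loc, 0) + 1
    summary = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: -kv[1]),
        columns=["location", "repeat_copies"],
    )
    return annotated, summary


def summarize_repeats(
    pairs_by_genome: dict[str, list[RepeatPair]],
    bins=DEFAULT_BINS,
) -> pd.DataFrame:
    """Length-bin x type counts per genome, with pooled percentages."""

    def bin_label(lo, hi):
        return f"{lo}-{hi}" if hi is not None else f">={lo}"

    labels = [bin_label(*b) for b in bins]
    rows = []
    for genome, pairs in pairs_by_genome.items():
        row = {"genome": genome}
        for (lo, hi), lab in zip(bins, labels):
            for rtype in REPEAT_TYPES:
                row[f"{rtype}_{lab}"] = sum(
                    1 for r in pairs
                    if r.rtype == rtype and lo <= r.length
                    and (hi is None or r.length <= hi)
                )
        row["total"] = len(pairs)
        rows.append(row)
    df = pd.DataFrame(rows)
    pooled = {"genome": "pooled_pct"}
    grand = df["total"].sum()
    for col in df.columns:
        if col in ("genome", "total"):
            continue
        pooled[col] = round(100.0 * df[col].sum() / grand, 2) if grand else 0.0
    pooled["total"] = grand
    return pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)


def pairs_to_frame(genome: str, pairs: list[RepeatPair]) -> pd.DataFrame:
    rows = [
        {
            "genome": genome,
            "rtype": r.rtype,
            "pos1_1based": r.pos1 + 1,
            "pos2_1based": r.pos2 + 1,
            "length": r.length,
            "mismatches": r.mismatches,
            "identity": round(r.identity, 4),
            "loc1": r.loc1 or "",
            "loc2": r.loc2 or "",
            "region1": r.region1 or "",
            "region2": r.region2 or "",
        }
        for r in pairs
    ]
    return pd.DataFrame(rows)
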