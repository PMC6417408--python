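"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives an expected result by exhaustive enumeration at
small n, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# circular slicing


def extract_region_doubled(seq: str, start: int, end: int) -> str:
    """Rotation oracle: slice the doubled string."""
    return (seq + seq)[start:end]


# ---------------------------------------------------------------------------
# inverted repeat


def longest_inverted_pair(seq: str):
    """O(n^2) longest pair of disjoint intervals (a, b, length) with
    seq[b:b+length] == revcomp(seq[a:a+length]), by dynamic programming
    over common suffixes of seq and its reverse complement."""
    n = len(seq)
    t = revcomp(seq)
    s_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    t_arr = np.frombuffer(t.encode(), dtype=np.uint8)
    prev = np.zeros(n, dtype=np.int32)
    best = (0, 0, 0)
    for i in range(n):
        cur = np.zeros(n, dtype=np.int32)
        match = t_arr == s_arr[i]
        cur[0] = 1 if match[0] else 0
        cur[1:] = np.where(match[1:], prev[:-1] + 1, 0)
        for j in np.flatnonzero(cur >= best[2]):
            length = int(cur[j])
            a = i - length + 1
            b = n - 1 - j  # T suffix ending at j maps to seq start n-1-j
            lo1, hi1 = a, a + length
            lo2, hi2 = b, b + length
            if hi1 <= lo2 or hi2 <= lo1:
                if length > best[2]:
                    best = (min(lo1, lo2), max(lo1, lo2), length)
        prev = cur
    return best


# ---------------------------------------------------------------------------
# SSRs


def _primitive(motif: str) -> bool:
    k = len(motif)
    return not any(
        k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
    )


def exhaustive_ssrs(seq: str, thresholds: dict[int, int]):
    """Every (position, unit_len) tested for a maximal, leftmost-phase
    perfect tract meeting the threshold.  Returns {(motif, start, copies)}."""
    n = len(seq)
    hits = set()
    for k, thr in thresholds.items():
        for i in range(n - k + 1):
            unit = seq[i : i + k]
            if "N" in unit or not _primitive(unit):
                continue
            # leftmost phase: the period must not continue to the left
            if i > 0 and seq[i - 1] == seq[i - 1 + k] and seq[i - 1] != "N":
                continue
            c = 1
            while seq[i + c * k : i + (c + 1) * k] == unit:
                c += 1
            if c >= thr:
                hits.add((unit, i, c))
    return hits


# ---------------------------------------------------------------------------
# dispersed repeats


def _transform(seq: str, rtype: str) -> str:
    if rtype == "F":
        return seq
    if rtype == "P":
        return revcomp(seq)
    if rtype == "R":
        return seq[::-1]
    return seq.translate(_COMP)


def allpairs_repeats(seq: str, min_len: int = 30, min_identity: float = 0.90):
    """Seed-free enumeration of maximal qualifying windows on every
    diagonal against each transform.  Returns
    {(rtype, pos1, pos2, length, mismatches)} with pos1 <= pos2."""
    n = len(seq)
    s_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    ncode = ord("N")
    found = set()
    min_matches = int(np.ceil(min_identity * min_len))
    for rtype in "FPRC":
        t_arr = np.frombuffer(_transform(seq, rtype).encode(), dtype=np.uint8)
        for d in range(-(n - 1), n):
            if rtype == "F" and d == 0:
                continue
            i0, i1 = max(0, d), min(n, n + d)
            if i1 - i0 < min_len:
                continue
            s_sl = s_arr[i0:i1]
            t_sl = t_arr[i0 - d : i1 - d]
            m = (s_sl == t_sl) & (s_sl != ncode) & (t_sl != ncode)
            p = np.flatnonzero(m) + i0
            mm = len(p)
            if mm < min_matches:
                continue
            # enumerate every window between two match positions
            L = p[None, :] - p[:, None] + 1
            idx = np.arange(mm)
            M = idx[None, :] - idx[:, None] + 1
            Q = (M >= 1) & (L >= min_len) & (M > min_identity * L)
            qualifying = np.argwhere(Q)
            if not len(qualifying):
                continue
            # keep windows maximal under containment (a'<=a and b'>=b)
            maxb = {}
            for a, b in qualifying:
                maxb[int(a)] = max(maxb.get(int(a), -1), int(b))
            best_b = -1
            for a in sorted(maxb):
                b = maxb[a]
                if b <= best_b:
                    continue
                best_b = b
                ps, pe = int(p[a]), int(p[b])
                length = pe - ps + 1
                mism = length - (b - a + 1)
                j = ps - d
                if rtype in ("F", "C"):
                    pos1, pos2 = ps, j
                else:
                    pos1, pos2 = ps, n - j - length
                lo, hi = min(pos1, pos2), max(pos1, pos2)
                found.add((rtype, lo, hi, length, mism))
    # cross-diagonal containment, mirroring the reported-pair contract
    out = set()
    for cand in found:
        rt, lo, hi, length, mism = cand
        contained = any(
            o != cand and o[0] == rt and o[3] > length
            and o[1] <= lo and lo + length <= o[1] + o[3]
            and o[2] <= hi and hi + length <= o[2] + o[3]
            for o in found
        )
        if not contained:
            out.add(cand)
    return out


# ---------------------------------------------------------------------------
# alignment statistics


def naive_alignment_counts(rows: list[str], col_start: int, col_end: int):
    """(NS, ID) by direct column scanning and per-row gap-run collection."""
    ns = 0
    for c in range(col_start, col_end):
        bases = {r[c] for r in rows if r[c] in "ACGT"}
        if len(bases) >= 2:
            ns += 1
    events = set()
    for r in rows:
        c = 0
        while c < len(r):
            if r[c] == "-":
                s = c
                while c < len(r) and r[c] == "-":
                    c += 1
                events.add((s, c))
            else:
                c += 1
    idc = sum(1 for s, _ in events if col_start <= s < col_end)
    return ns, idc


def naive_identical_percent(rows: list[str]) -> float:
    n = len(rows[0])
    same = sum(1 for c in range(n) if len({r[c] for r in rows}) == 1)
    return 100.0 * same / n


def naive_col_to_ref(row: str, col: int) -> int:
    """Reference coordinate by direct counting."""
    return sum(1 for ch in row[:col] if ch != "-")
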