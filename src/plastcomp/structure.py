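"""Quadripartite structure: inverted-repeat detection, region statistics
and junction reports.

A plastome is canonically laid out LSC + IRb + SSC + IRa along the forward
strand, where IRa is the exact reverse complement of IRb.  Detection finds
the maximal pair of disjoint intervals whose sequences are exact reverse
complements, labels the two intervening arcs LSC (longer) and SSC
(shorter), and rotates coordinates so the LSC starts at position 0.

Exactness (rather than 90% identity) is required for the IR pair itself:
in assembled plastomes the two IR copies are identical by construction.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .io_formats import (
    GENIC_KINDS,
    GeneFeature,
    PlastomeRecord,
    extract_region,
    revcomp,
    rotate_record,
    to_1based,
)

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: canonical junction names, in forward-strand order
JUNCTIONS = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")


class NoQuadripartiteStructure(ValueError):
    """No inverted repeat of at least ``min_ir`` bp was found."""


class AmbiguousStructure(ValueError):
    """Several co-maximal, non-identical IR candidates exist."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            "multiple co-maximal inverted-repeat candidates: "
            + ", ".join(
                f"[{a}..{a + l}) / [{b}..{b + l})" for a, b, l in candidates
            )
        )


@dataclass(frozen=True)
class QuadripartitePartition:
    """The four region intervals, in canonical (rotated) coordinates.

    ``rotation_offset`` is the input-coordinate position that became
    position 0: canonical = (input - rotation_offset) mod length.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    rotation_offset: int
    length: int

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    def regions(self) -> dict[str, Interval]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def region_of(self, pos: int) -> str:
        """Region label for a canonical-coordinate position."""
        for name, (s, e) in self.regions().items():
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside [0, {self.length})")

    def to_input_coords(self, start: int, end: int) -> Interval:
        """Map a canonical half-open interval back to input coordinates.
        May wrap: returned ``end`` can be <= ``start`` (mod length)."""
        n = self.length
        return ((start + self.rotation_offset) % n,
                ((end - 1 + self.rotation_offset) % n) + 1)

    def validate(self, record: PlastomeRecord) -> None:
        n = record.length
        assert n == self.length
        ivs = [self.lsc, self.irb, self.ssc, self.ira]
        assert ivs[0][0] == 0 and ivs[-1][1] == n
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            assert e1 == s2, "regions must tile the genome"
        rot = rotate_record(record, self.rotation_offset)
        ira = rot.sequence[slice(*self.ira)]
        irb = rot.sequence[slice(*self.irb)]
        assert ira == revcomp(irb), "IRa must be the reverse complement of IRb"
        assert self.lsc[1] - self.lsc[0] > self.ssc[1] - self.ssc[0]


# ---------------------------------------------------------------------------
# IR detection


def _inverted_match_candidates(seq: str, min_len: int, k: int):
    """Maximal exact matches between ``seq`` and its reverse complement,
    reported as (startA, startB, length) with disjoint A/B intervals,
    canonicalized so startA <= startB.  k-mer anchors joined along
    diagonals and extended to maximal exact runs."""
    n = len(seq)
    t = revcomp(seq)
    if n < k:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(n - k + 1):
        kmer = t[j : j + k]
        if "N" not in kmer:
            index[kmer].append(j)
    # group anchor hits by diagonal, then merge into runs
    by_diag: dict[int, list[int]] = defaultdict(list)
    step = max(1, k // 2)
    for i in range(0, n - k + 1, step):
        kmer = seq[i : i + k]
        for j in index.get(kmer, ()):
            by_diag[i - j].append(i)
    out: set[tuple[int, int, int]] = set()
    for d, i_list in by_diag.items():
        i_list = sorted(set(i_list))
        covered_hi = -1  # anchors inside an already-extended run are skipped
        for i in i_list:
            if i + k <= covered_hi:
                continue
            j = i - d
            # extend exact match around [i, i+k)
            lo = i
            while lo > 0 and (j - (i - lo)) > 0 and seq[lo - 1] == t[j - (i - lo) - 1] and seq[lo - 1] != "N":
                lo -= 1
            hi = i + k
            while hi < n and (j + (hi - i)) < n and seq[hi] == t[j + (hi - i)] and seq[hi] != "N":
                hi += 1
            covered_hi = hi
            a, jb, length = lo, j - (i - lo), hi - lo
            if length < min_len:
                continue
            b = n - jb - length  # T interval mapped back onto seq
            lo1, hi1 = a, a + length
            lo2, hi2 = b, b + length
            if hi1 <= lo2 or hi2 <= lo1:  # disjoint copies only
                pair = (min(lo1, lo2), max(lo1, lo2), length)
                out.add(pair)
    return sorted(out)


def detect_inverted_repeat(
    record: PlastomeRecord,
    min_ir: int = 1000,
    k: int = 21,
    rotate: bool = True,
) -> QuadripartitePartition:
    """Find the IR pair and derive the quadripartite partition.

    Returns the partition in canonical coordinates (LSC at 0, order LSC,
    IRb, SSC, IRa); ``rotation_offset`` records the rotation applied.
    With ``rotate=False`` the offset is forced to 0 and region intervals
    are reported in input coordinates (the IRa interval may wrap).

    Raises :class:`NoQuadripartiteStructure` if no exact inverted repeat
    of at least ``min_ir`` bp exists, and :class:`AmbiguousStructure` if
    several distinct co-maximal candidates are found.
    """
    n = record.length
    if n < 4:
        raise NoQuadripartiteStructure(f"{record.id}: sequence too short")
    offsets = [0]
    if record.circular:
        offsets.append(n // 2)
    candidates: set[tuple[int, int, int]] = set()
    for off in offsets:
        seq = record.sequence[off:] + record.sequence[:off]
        for a, b, length in _inverted_match_candidates(seq, min_ir, k):
            a0, b0 = (a + off) % n, (b + off) % n
            lo, hi = min(a0, b0), max(a0, b0)
            candidates.add((lo, hi, length))
    if not candidates:
        raise NoQuadripartiteStructure(
            f"{record.id}: no inverted repeat of >= {min_ir} bp"
        )
    best_len = max(c[2] for c in candidates)
    best = sorted(c for c in candidates if c[2] == best_len)
    if len(best) > 1:
        raise AmbiguousStructure(best)
    a, b, ir_len = best[0]
    # arcs between the two IR copies (circular)
    arc1 = ((a + ir_len) % n, b)               # from end of copy A to start of copy B
    arc2 = ((b + ir_len) % n, a)               # from end of copy B to start of copy A
    len1 = (arc1[1] - arc1[0]) % n
    len2 = (arc2[1] - arc2[0]) % n
    if len1 >= len2:
        lsc_start, lsc_len, ssc_len = arc1[0], len1, len2
        irb_start = b       # IR following the LSC
    else:
        lsc_start, lsc_len, ssc_len = arc2[0], len2, len1
        irb_start = a
    if lsc_len == ssc_len:
        logger.warning("%s: single-copy arcs have equal length", record.id)
    offset = lsc_start if rotate and record.circular else 0
    if offset == 0 and lsc_start != 0:
        # report in input coordinates; regions may wrap
        lsc = (lsc_start, (lsc_start + lsc_len - 1) % n + 1)
        irb = (irb_start, (irb_start + ir_len - 1) % n + 1)
        ssc_start = (irb_start + ir_len) % n
        ssc = (ssc_start, (ssc_start + ssc_len - 1) % n + 1)
        ira_start = (ssc_start + ssc_len) % n
        ira = (ira_start, (ira_start + ir_len - 1) % n + 1)
        return QuadripartitePartition(
            lsc=lsc, irb=irb, ssc=ssc, ira=ira, rotation_offset=0, length=n
        )
    return QuadripartitePartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len, n),
        rotation_offset=offset,
        length=n,
    )


# ---------------------------------------------------------------------------
# region statistics


def gc_percent(seq: str) -> float:
    """GC% with N excluded from numerator and denominator."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def region_stats(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> pd.DataFrame:
    """Per-region length, proportion of the genome, and GC%.

    The IR row reports the length and GC of one copy; its proportion is
    that of both copies together (2 x ir_length / total), matching the
    convention of published plastome feature tables.
    """
    rot = rotate_record(record, partition.rotation_offset)
    n = record.length
    ir_len = partition.ir_length
    rows = []
    for name, (s, e) in (("LSC", partition.lsc), ("IR", partition.irb),
                         ("SSC", partition.ssc)):
        seq = rot.sequence[s:e]
        length = e - s
        prop = 100.0 * (2 * length if name == "IR" else length) / n
        rows.append(
            {
                "region": name,
                "length_bp": length,
                "proportion_pct": round(prop, 2),
                "gc_pct": round(gc_percent(seq), 2),
            }
        )
    rows.append(
        {
            "region": "total",
            "length_bp": n,
            "proportion_pct": 100.0,
            "gc_pct": round(gc_percent(rot.sequence), 2),
        }
    )
    assert rows[0]["length_bp"] + rows[2]["length_bp"] + 2 * ir_len == n
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# junction report


def _genic(features) -> list[GeneFeature]:
    # Fig-2-style junction maps display genes, not introns/spacers; prefer
    # the 'gene' record when the same name also has a CDS entry.
    best: dict[tuple[str, int], GeneFeature] = {}
    for f in features:
        if f.kind not in GENIC_KINDS:
            continue
        key = (f.name, f.start)
        if key not in best or (f.kind == "gene" and best[key].kind != "gene"):
            best[key] = f
    return list(best.values())


def _feature_overlap(feat: GeneFeature, region: Interval) -> int:
    s, e = region
    return sum(max(0, min(ie, e) - max(is_, s)) for is_, ie in feat.intervals)


def _unrolled_span(feat: GeneFeature, n: int) -> tuple[int, int]:
    """Outer span (start, end) of a feature in canonical coordinates,
    with end > n when the feature was wrap-split at the origin."""
    ivs = sorted(feat.intervals)
    touches_end = any(e == n for _, e in ivs)
    touches_start = any(s == 0 for s, _ in ivs)
    if touches_end and touches_start and len(ivs) > 1:
        s = min(s for s, _ in ivs if s > n // 2)
        e = max(e for _, e in ivs if e < n // 2) + n
        return s, e
    return feat.start, feat.end


def junction_report(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> pd.DataFrame:
    """For each of the four junctions, the overlapping or nearest genic
    feature on each side, signed distances, and the length of any
    truncated fragment falling inside the adjacent IR.

    Distances are from the feature edge to the junction: positive means a
    gap, 0 means the feature abuts the junction, negative means it
    straddles it.  A feature straddling an SC/IR junction leaves a
    duplicated (pseudogene) fragment of ``truncated_fragment_len`` bp
    inside the IR; the copy in the opposite IR has the same length.
    """
    rot = rotate_record(record, partition.rotation_offset)
    feats = _genic(rot.features)
    if not feats:
        logger.warning("%s: no genic features; junction report is empty",
                       record.id)
    n = record.length
    regions = partition.regions()
    junction_pos = {
        "LSC/IRb": partition.irb[0],
        "IRb/SSC": partition.ssc[0],
        "SSC/IRa": partition.ira[0],
        "IRa/LSC": n,  # the origin junction, evaluated at position n
    }
    ir_side = {"LSC/IRb": "IRb", "IRb/SSC": "IRb",
               "SSC/IRa": "IRa", "IRa/LSC": "IRa"}
    spans = [(f, *_unrolled_span(f, n)) for f in feats]
    rows = []
    for jname in JUNCTIONS:
        p = junction_pos[jname]
        left = right = straddler = None
        left_dist = right_dist = None
        for f, s, e in spans:
            straddles = any(s < q < e for q in (p, p + n))
            if straddles:
                q = p if s < p < e else p + n
                straddler = f
                left = right = f
                left_dist = q - e      # negative: extends past the junction
                right_dist = s - q
                break
            dl = (p - e) % n
            dr = (s - p) % n
            if left is None or dl < left_dist:
                left, left_dist = f, dl
            if right is None or dr < right_dist:
                right, right_dist = f, dr
        frag = 0
        if straddler is not None:
            frag = _feature_overlap(straddler, regions[ir_side[jname]])
        rows.append(
            {
                "junction": jname,
                "position_1based": p,
                "left_gene": left.name if left else "",
                "left_dist": left_dist if left is not None else "",
                "right_gene": right.name if right else "",
                "right_dist": right_dist if right is not None else "",
                "truncated_fragment_len": frag,
            }
        )
    return pd.DataFrame(rows)
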