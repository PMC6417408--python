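"""Microsatellite (SSR) detection and summaries.

Detection reports maximal perfect tandem tracts of 1-6 bp motifs at the
conventional plastome thresholds: at least 10 copies for mononucleotides,
6 for dinucleotides, 4 for trinucleotides and 3 for tetra-, penta- and
hexanucleotides.  Two qualifying tracts separated by at most
``max_interruption`` bp additionally form one compound ("c") SSR, while
the member tracts are kept and flagged.

Motifs are reported in the phase and strand encountered; a normalized
motif (lexicographic minimum over cyclic rotations, no complementing) is
provided for grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io_formats import PlastomeRecord
from .structure import QuadripartitePartition

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}

#: Fig-3-style category labels by unit length; "c" marks compound SSRs
CATEGORY = {1: "p1", 2: "p2", 3: "p3", 4: "p4", 5: "p5", 6: "p6", 0: "c"}


@dataclass(frozen=True)
class SSRHit:
    """One microsatellite tract (or one merged compound SSR).

    Compound SSRs carry ``motif='c'``, ``unit_len=0`` and span from the
    first member tract to the last; member tracts are retained in the hit
    list with ``compound=True``.
    """

    motif: str
    unit_len: int
    copies: int
    start: int
    end: int
    region: str | None = None
    context: str | None = None
    compound: bool = False

    @property
    def normalized_motif(self) -> str:
        if not self.motif or self.motif == "c":
            return self.motif
        m = self.motif
        return min(m[i:] + m[:i] for i in range(len(m)))

    @property
    def category(self) -> str:
        return CATEGORY[self.unit_len]


def _primitive(motif: str) -> bool:
    """True unless the motif is itself a repetition of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def find_ssrs(
    source: PlastomeRecord | str,
    thresholds: dict[int, int] | None = None,
    max_interruption: int = 100,
) -> list[SSRHit]:
    """All maximal perfect SSR tracts meeting the copy-number thresholds,
    plus merged compound hits.

    N breaks every tract.  A tract whose unit is non-primitive (e.g. ATAT
    as a tetranucleotide) is reported only at its shortest unit.
    """
    seq = source.sequence if isinstance(source, PlastomeRecord) else source.upper()
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    n = len(seq)
    simple: list[SSRHit] = []
    for k, min_copies in sorted(thresholds.items()):
        i = 0
        while i + k * min_copies <= n:
            unit = seq[i : i + k]
            if "N" in unit or not _primitive(unit):
                i += 1
                continue
            c = 1
            while seq[i + c * k : i + (c + 1) * k] == unit:
                c += 1
            if c >= min_copies:
                simple.append(
                    SSRHit(motif=unit, unit_len=k, copies=c, start=i,
                           end=i + c * k)
                )
                i += c * k
            else:
                i += 1
    simple.sort(key=lambda h: (h.start, h.end))
    # chain tracts separated by short spacers into compound SSRs
    hits: list[SSRHit] = []
    group: list[SSRHit] = []

    def flush():
        if len(group) >= 2:
            hits.extend(replace(h, compound=True) for h in group)
            hits.append(
                SSRHit(motif="c", unit_len=0, copies=0,
                       start=group[0].start, end=group[-1].end,
                       compound=True)
            )
        else:
            hits.extend(group)
        group.clear()

    for h in simple:
        if group and h.start - group[-1].end <= max_interruption:
            group.append(h)
        else:
            flush()
            group.append(h)
    flush()
    hits.sort(key=lambda h: (h.start, h.end, h.unit_len))
    return hits


# ---------------------------------------------------------------------------
# annotation and summaries


def annotate_ssrs(
    hits: list[SSRHit],
    record: PlastomeRecord,
    partition: QuadripartitePartition | None = None,
) -> list[SSRHit]:
    """Attach region (LSC/IRb/SSC/IRa) and feature/IGS context to hits.

    Hit coordinates must be in the same (canonical) coordinate system as
    the partition; pass the rotated record.
    """
    from .long_repeats import locate  # shared location labelling

    out = []
    for h in hits:
        region = partition.region_of(h.start) if partition else None
        context = locate(record, h.start, h.end)
        out.append(replace(h, region=region, context=context))
    return out


def summarize_ssrs(hits_by_genome: dict[str, list[SSRHit]]) -> pd.DataFrame:
    """Counts by category (p1..p6, c) per genome, with a pooled share row.

    Member tracts of a compound SSR are represented by the single "c"
    entry, so categories are mutually exclusive and the total is the
    number of SSR loci.
    """
    cats = ["p1", "p2", "p3", "p4", "p5", "p6", "c"]
    rows = []
    for genome, hits in hits_by_genome.items():
        counted = [h for h in hits if h.motif == "c" or not h.compound]
        row = {"genome": genome, **{c: 0 for c in cats}}
        for h in counted:
            row[h.category] += 1
        row["total"] = len(counted)
        rows.append(row)
    df = pd.DataFrame(rows)
    pooled = {"genome": "pooled_pct"}
    grand = df["total"].sum()
    for c in cats:
        pooled[c] = round(100.0 * df[c].sum() / grand, 2) if grand else 0.0
    pooled["total"] = grand
    return pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)


def motif_composition(hits_by_genome: dict[str, list[SSRHit]]) -> pd.DataFrame:
    """Pooled share of each normalized motif within its unit-length class
    (e.g. the fraction of mononucleotide SSRs that are A/T)."""
    counts: dict[tuple[int, str], int] = {}
    for hits in hits_by_genome.values():
        for h in hits:
            if h.motif == "c" or h.compound:
                continue
            key = (h.unit_len, h.normalized_motif)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    totals: dict[int, int] = {}
    for (k, _), c in counts.items():
        totals[k] = totals.get(k, 0) + c
    for (k, motif), c in sorted(counts.items()):
        rows.append(
            {
                "unit_len": k,
                "normalized_motif": motif,
                "count": c,
                "share_pct": round(100.0 * c / totals[k], 2),
            }
        )
    return pd.DataFrame(rows)


def hits_to_frame(genome: str, hits: list[SSRHit]) -> pd.DataFrame:
    """Tabular (1-based inclusive) view of a hit list."""
    rows = [
        {
            "genome": genome,
            "motif": h.motif,
            "normalized_motif": h.normalized_motif,
            "unit_len": h.unit_len,
            "copies": h.copies,
            "start_1based": h.start + 1,
            "end_1based": h.end,
            "region": h.region or "",
            "context": h.context or "",
            "compound": h.compound,
        }
        for h in hits
    ]
    return pd.DataFrame(rows)
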