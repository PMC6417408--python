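"""Synthetic plastomes and alignment families with complete ground truth.

``simulate_plastome`` builds a circular quadripartite genome (LSC + IRb +
SSC + IRa, with IRa the exact reverse complement of IRb) around an
i.i.d. background of chosen GC content, and plants microsatellite
tracts, dispersed repeat pairs of all four types, and named gene
features, each recorded in a :class:`SyntheticTruth` ledger.  Planted
elements never overlap one another, their flanks are locally broken so
that each element is exactly maximal, and background tracts that would
qualify as SSRs by chance are scrubbed, so detector output can be
compared to the ledger exactly.

``simulate_family`` evolves a family of sequences from a common ancestor
by per-column substitutions and shared/private indel (gap-run) events,
emitting the true alignment (no realignment) plus the ledger of
substitution columns and indel events.

Default dimensions follow published Ipomoea plastomes: regions of
roughly 87.6 kb (LSC), 30.9 kb (IR) and 12 kb (SSC), 37.5% GC, a few
dozen SSRs and repeat pairs per genome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .io_formats import GeneFeature, PlastomeRecord, revcomp
from .ssr import DEFAULT_THRESHOLDS, find_ssrs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class PackingError(ValueError):
    """Requested planted elements do not fit in the region."""


@dataclass
class SyntheticTruth:
    """Ground-truth ledger emitted next to every simulated fixture."""

    params: dict = field(default_factory=dict)
    partition: dict = field(default_factory=dict)
    planted_ssrs: list = field(default_factory=list)
    planted_compound: list = field(default_factory=list)
    planted_repeats: list = field(default_factory=list)
    planted_features: list = field(default_factory=list)
    background_intervals: list = field(default_factory=list)
    substitution_columns: list = field(default_factory=list)
    indel_events: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# helpers


def _random_background(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _other_base(rng, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


class _Packer:
    """Non-overlapping placement of padded intervals within [0, length)."""

    def __init__(self, rng, length: int):
        self.rng = rng
        self.length = length
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, start: int, size: int, margin: int) -> None:
        self.occupied.append((start - margin, start + size + margin))

    def place(self, size: int, margin: int, tries: int = 2000) -> int:
        lo, hi = margin, self.length - size - margin
        if hi <= lo:
            raise PackingError(
                f"element of {size} bp cannot fit in {self.length} bp region"
            )
        for _ in range(tries):
            start = int(self.rng.integers(lo, hi))
            s, e = start - margin, start + size + margin
            if all(e <= os or oe <= s for os, oe in self.occupied):
                self.occupied.append((s, e))
                return start
        raise PackingError(
            f"could not place a {size} bp element after {tries} tries; "
            f"{len(self.occupied)} elements occupy "
            f"{sum(e - s for s, e in self.occupied)} of {self.length} bp"
        )


def _scrub_chance_ssrs(rng, arr: np.ndarray, thresholds=None) -> None:
    """Mutate one base inside any background tract that would qualify as
    an SSR, so that planted tracts are the only qualifying ones."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    for _ in range(10):
        hits = [h for h in find_ssrs(arr.tobytes().decode(), thresholds)
                if h.motif != "c"]
        if not hits:
            return
        for h in hits:
            mid = (h.start + h.end) // 2
            arr[mid] = ord(_other_base(rng, chr(arr[mid])))
    raise RuntimeError("SSR scrubbing did not converge")


# mismatch/complement relations for repeat-flank breaking, per repeat type:
# pairing of positions just outside the planted window along its diagonal
def _flank_pairs(rtype: str, p1: int, p2: int, length: int, f: int):
    """Yield (read_pos, write_pos, relation) for ``f`` diagonal positions
    past each end of a planted pair; relation 'eq' means the match would
    require equality, 'comp' complement equality."""
    rel = "comp" if rtype in ("P", "C") else "eq"
    for t in range(f):
        if rtype in ("F", "C"):
            yield p1 - 1 - t, p2 - 1 - t, rel
            yield p1 + length + t, p2 + length + t, rel
        else:  # P and R reverse the axis: left of copy1 pairs right of copy2
            yield p1 - 1 - t, p2 + length + t, rel
            yield p1 + length + t, p2 - 1 - t, rel


# ---------------------------------------------------------------------------
# plastome simulator


def simulate_plastome(
    lsc_len: int = 87_600,
    ir_len: int = 30_900,
    ssc_len: int = 12_040,
    gc: float = 0.375,
    n_ssrs: int = 30,
    n_compound: int = 2,
    n_repeats: int = 20,
    n_genes: int = 40,
    junction_overlap: int | None = None,
    seed: int = 0,
) -> tuple[PlastomeRecord, SyntheticTruth]:
    """Simulate one quadripartite plastome with planted truth.

    ``junction_overlap`` plants a 900-bp CDS straddling the SSC/IRa
    junction with that many bp inside the IR (the truncated-fragment
    case).  Deterministic for a fixed seed.
    """
    if not (lsc_len > ssc_len > 0 and ir_len > 0):
        raise ValueError("need lsc_len > ssc_len > 0 and ir_len > 0")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = lsc_len + 2 * ir_len + ssc_len
    truth = SyntheticTruth(
        params=dict(lsc_len=lsc_len, ir_len=ir_len, ssc_len=ssc_len, gc=gc,
                    n_ssrs=n_ssrs, n_compound=n_compound, n_repeats=n_repeats,
                    n_genes=n_genes, junction_overlap=junction_overlap,
                    seed=seed),
        partition=dict(
            lsc=[0, lsc_len],
            irb=[lsc_len, lsc_len + ir_len],
            ssc=[lsc_len + ir_len, lsc_len + ir_len + ssc_len],
            ira=[lsc_len + ir_len + ssc_len, n],
            ir_length=ir_len,
        ),
    )
    lsc = _random_background(rng, lsc_len, gc)
    irb = _random_background(rng, ir_len, gc)
    ssc = _random_background(rng, ssc_len, gc)
    _scrub_chance_ssrs(rng, lsc)
    _scrub_chance_ssrs(rng, irb)
    _scrub_chance_ssrs(rng, ssc)
    packer = _Packer(rng, lsc_len)
    features: list[GeneFeature] = []

    # --- SSRs (in the LSC, as in real plastomes) ---------------------------
    unit_weights = {1: 0.70, 2: 0.02, 3: 0.01, 4: 0.17, 5: 0.06, 6: 0.04}
    units = list(unit_weights)
    probs = np.array([unit_weights[u] for u in units])
    probs /= probs.sum()
    for _ in range(n_ssrs):
        k = int(rng.choice(units, p=probs))
        motif = _random_primitive_motif(rng, k)
        copies = DEFAULT_THRESHOLDS[k] + int(rng.integers(0, 3))
        size = k * copies
        # margin > compound interruption distance so that independent
        # tracts never chain into unplanned compound SSRs
        start = packer.place(size, margin=110)
        _write_ssr(rng, lsc, start, motif, copies)
        truth.planted_ssrs.append(
            dict(motif=motif, unit_len=k, copies=copies, start=start,
                 end=start + size)
        )
    for _ in range(n_compound):
        k1, k2 = 1, 4
        m1 = _random_primitive_motif(rng, k1)
        m2 = _random_primitive_motif(rng, k2)
        while m2[0] == m1 or m2[-1] == m1:  # keep the two tracts separable
            m2 = _random_primitive_motif(rng, k2)
        c1 = DEFAULT_THRESHOLDS[k1] + 1
        c2 = DEFAULT_THRESHOLDS[k2] + 1
        gap = int(rng.integers(5, 60))
        size = k1 * c1 + gap + k2 * c2
        start = packer.place(size, margin=110)
        _write_ssr(rng, lsc, start, m1, c1)
        s2 = start + k1 * c1 + gap
        _write_ssr(rng, lsc, s2, m2, c2)
        truth.planted_ssrs.append(dict(motif=m1, unit_len=k1, copies=c1,
                                       start=start, end=start + k1 * c1))
        truth.planted_ssrs.append(dict(motif=m2, unit_len=k2, copies=c2,
                                       start=s2, end=s2 + k2 * c2))
        truth.planted_compound.append(dict(start=start, end=s2 + k2 * c2))

    # --- dispersed repeat pairs (both copies in the LSC) -------------------
    bin_choices = [(30, 59), (60, 79), (80, 139), (140, 180)]
    bin_probs = np.array([0.58, 0.25, 0.14, 0.03])
    for idx in range(n_repeats):
        rtype = "FPRC"[idx % 4]
        lo, hi = bin_choices[int(rng.choice(4, p=bin_probs / bin_probs.sum()))]
        length = int(rng.integers(lo, hi + 1))
        max_mm = min(3, (length + 9) // 10 - 1) if length >= 32 else 0
        mism = int(rng.integers(0, max_mm + 1)) if max_mm > 0 else 0
        flank = length // 9 + 5
        p1 = packer.place(length, margin=flank + 4)
        p2 = packer.place(length, margin=flank + 4)
        p1, p2 = min(p1, p2), max(p1, p2)
        copy1 = lsc[p1 : p1 + length].tobytes().decode()
        copy2 = _transform_segment(copy1, rtype)
        copy2 = _mutate_block(rng, copy2, mism)
        lsc[p2 : p2 + length] = np.frombuffer(copy2.encode(), dtype=np.uint8)
        for u, v, rel in _flank_pairs(rtype, p1, p2, length, flank):
            if not (0 <= u < lsc_len and 0 <= v < lsc_len):
                continue
            ref = chr(lsc[u])
            bad = _COMP[ref] if rel == "comp" else ref
            lsc[v] = ord(_other_base(rng, bad))
        truth.planted_repeats.append(
            dict(rtype=rtype, pos1=p1, pos2=p2, length=length,
                 mismatches=mism)
        )

    # --- gene features -----------------------------------------------------
    ssc_packer = _Packer(rng, ssc_len)
    junction_feature = None
    if junction_overlap is not None:
        size = 900
        if not 0 < junction_overlap < size:
            raise ValueError("junction_overlap must be in (0, 900)")
        junction = lsc_len + ir_len + ssc_len  # SSC/IRa
        g = junction - (size - junction_overlap)
        ssc_packer.reserve(g - (lsc_len + ir_len), size, margin=20)
        junction_feature = (g, size)
    n_ssc_genes = max(1, n_genes // 8)
    gene_id = 0
    for region, arr, packer_, offset, count in (
        ("LSC", lsc, packer, 0, n_genes - n_ssc_genes),
        ("SSC", ssc, ssc_packer, lsc_len + ir_len, n_ssc_genes),
    ):
        # scale gene sizes so the requested number always packs
        hi_codons = max(50, min(400, packer_.length // (3 * max(count, 1) * 3)))
        lo_codons = max(30, hi_codons // 4)
        for _ in range(count):
            gene_id += 1
            name = f"gene{gene_id:03d}"
            kind = "CDS" if rng.random() < 0.8 else "tRNA"
            if kind == "CDS":
                n_codons = int(rng.integers(lo_codons, hi_codons + 1))
                size = 3 * n_codons
            else:
                size = int(rng.integers(70, 90))
            strand = "+" if rng.random() < 0.5 else "-"
            try:
                start = packer_.place(size, margin=20)
            except PackingError:
                # region full (e.g. a junction gene in a tiny SSC): the
                # gene split across regions is best-effort
                gene_id -= 1
                break
            if kind == "CDS":
                _write_cds(rng, arr, start, size, strand, gc)
            g = start + offset
            features.append(
                GeneFeature(name=name, kind=kind, strand=strand,
                            intervals=((g, g + size),))
            )
            truth.planted_features.append(
                dict(name=name, kind=kind, strand=strand, region=region,
                     start=g, end=g + size)
            )
    # one spliced CDS and one IR-duplicated CDS for realism (best-effort
    # on crowded small fixtures)
    try:
        ex1, ex2, intron = 150, 300, 120
        start = packer.place(ex1 + intron + ex2, margin=20)
        gene_id += 1
        name = f"gene{gene_id:03d}"
        features.append(
            GeneFeature(name=name, kind="CDS", strand="+",
                        intervals=((start, start + ex1),
                                   (start + ex1 + intron,
                                    start + ex1 + intron + ex2)))
        )
        truth.planted_features.append(
            dict(name=name, kind="CDS", strand="+", region="LSC",
                 start=start, end=start + ex1 + intron + ex2, spliced=True)
        )
    except PackingError:
        pass
    gene_id += 1
    ir_packer = _Packer(rng, ir_len)
    size = 3 * int(rng.integers(100, 200))
    s_local = ir_packer.place(size, margin=20)
    _write_cds(rng, irb, s_local, size, "+", gc)
    name = f"gene{gene_id:03d}"
    g1 = lsc_len + s_local
    features.append(GeneFeature(name=name, kind="CDS", strand="+",
                                intervals=((g1, g1 + size),)))
    # mirrored copy inside IRa (reverse complement -> minus strand)
    ira_off = lsc_len + ir_len + ssc_len
    g2 = ira_off + (ir_len - s_local - size)
    features.append(GeneFeature(name=name, kind="CDS", strand="-",
                                intervals=((g2, g2 + size),)))
    truth.planted_features.append(
        dict(name=name, kind="CDS", strand="+", region="IRb", start=g1,
             end=g1 + size, ir_duplicate=True)
    )
    truth.planted_features.append(
        dict(name=name, kind="CDS", strand="-", region="IRa", start=g2,
             end=g2 + size, ir_duplicate=True)
    )
    if junction_feature is not None:
        gene_id += 1
        g, size = junction_feature
        name = f"gene{gene_id:03d}"
        features.append(GeneFeature(name=name, kind="CDS", strand="+",
                                    intervals=((g, g + size),)))
        truth.planted_features.append(
            dict(name=name, kind="CDS", strand="+", region="SSC/IRa",
                 start=g, end=g + size, junction_overlap=junction_overlap)
        )

    # break inverted-repeat extension at the region boundaries so the
    # detected IR equals the planted one exactly: extending the IRb/IRa
    # match one base pairs the last LSC base with the first LSC base
    # (wrapping the origin) and the first SSC base with the last SSC base
    lsc[-1] = ord(_other_base(rng, _COMP[chr(lsc[0])]))
    ssc[0] = ord(_other_base(rng, _COMP[chr(ssc[-1])]))
    genome = np.concatenate([lsc, irb, ssc])
    seq = genome.tobytes().decode()
    full = seq + revcomp(seq[lsc_len : lsc_len + ir_len])
    record = PlastomeRecord(
        id=f"SYNPL{seed:04d}", sequence=full, circular=True,
        features=sorted(features, key=lambda f: f.start),
    )
    # background = everything not written by a planted element (for GC checks)
    planted = sorted(
        [(d["start"], d["end"]) for d in truth.planted_ssrs]
        + [(d["pos1"], d["pos1"] + d["length"]) for d in truth.planted_repeats]
        + [(d["pos2"], d["pos2"] + d["length"]) for d in truth.planted_repeats]
        + [(d["start"], d["end"]) for d in truth.planted_features]
    )
    cursor = 0
    bg = []
    limit = lsc_len + 2 * ir_len + ssc_len - ir_len  # exclude derived IRa
    for s, e in planted + [(limit, limit)]:
        s = min(s, limit)
        if s > cursor:
            bg.append([cursor, s])
        cursor = max(cursor, min(e, limit))
    truth.background_intervals = bg
    return record, truth


def _random_primitive_motif(rng, k: int) -> str:
    while True:
        motif = "".join(chr(b) for b in rng.choice(_BASES, size=k))
        from .ssr import _primitive

        if _primitive(motif):
            return motif


def _write_ssr(rng, arr: np.ndarray, start: int, motif: str, copies: int):
    k = len(motif)
    tract = (motif * copies).encode()
    arr[start : start + k * copies] = np.frombuffer(tract, dtype=np.uint8)
    # break unit-level extension on both flanks
    arr[start - 1] = ord(_other_base(rng, motif[-1]))
    arr[start + k * copies] = ord(_other_base(rng, motif[0]))


def _transform_segment(seg: str, rtype: str) -> str:
    from .long_repeats import _transform

    return _transform(seg, rtype)


def _mutate_block(rng, seg: str, mism: int) -> str:
    """Apply ``mism`` mismatches confined to a short block near the end,
    spaced two apart, so a long exact stretch remains for seeding."""
    if mism == 0:
        return seg
    chars = list(seg)
    L = len(seg)
    positions = [L - 4 - 2 * t for t in range(mism)]
    for p in positions:
        chars[p] = _other_base(rng, chars[p])
    return "".join(chars)


def _write_cds(rng, arr: np.ndarray, start: int, size: int, strand: str,
               gc: float):
    """Write ATG + sense codons (no internal stops) + TAA at ``start``."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    body = _random_background(rng, size, gc).tobytes().decode()
    for i in range(1, size // 3 - 1):
        codon = body[3 * i : 3 * i + 3]
        if codon in stops:
            codon = "C" + codon[1:]
        codons.append(codon)
    codons.append("TAA")
    cds = "".join(codons)
    # scrub chance SSR tracts inside the coding body (keep start/stop)
    for _ in range(10):
        hits = [h for h in find_ssrs(cds) if h.motif != "c"]
        if not hits:
            break
        chars = list(cds)
        for h in hits:
            mid = min(max((h.start + h.end) // 2, 3), size - 4)
            chars[mid] = _other_base(rng, chars[mid])
        cds = "".join(chars)
    if strand == "-":
        cds = revcomp(cds)
    arr[start : start + size] = np.frombuffer(cds.encode(), dtype=np.uint8)


# ---------------------------------------------------------------------------
# alignment-family simulator


def simulate_family(
    ancestor_len: int = 10_000,
    n_taxa: int = 8,
    subst_rate: float = 0.03,
    indel_rate: float = 0.003,
    mean_indel_len: float = 6.0,
    hotspot_spec: list[tuple[int, int, float]] | None = None,
    gc: float = 0.375,
    seed: int = 0,
):
    """Evolve ``n_taxa`` sequences from a common ancestor.

    ``subst_rate`` is the per-column probability of a substitution column
    (a random nonempty proper subset of rows receives one alternative
    base); ``indel_rate`` the per-column probability that an indel event
    starts there, with geometric length of the given mean, shared by a
    random nonempty proper subset of rows.  Events are kept disjoint from
    each other and from substitution columns so the ledger counts are
    exact.  ``hotspot_spec`` entries (col_start, col_end, multiplier)
    scale both rates inside the interval.

    Returns (Alignment, SyntheticTruth).
    """
    from .io_formats import Alignment

    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if not (0 <= subst_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    if mean_indel_len < 1:
        raise ValueError("mean_indel_len must be >= 1")
    rng = np.random.default_rng(seed)
    mult = np.ones(ancestor_len)
    for a, b, m in hotspot_spec or []:
        mult[a:b] = m
    ancestor = _random_background(rng, ancestor_len, gc)
    matrix = np.tile(ancestor, (n_taxa, 1))
    sub_cols = np.flatnonzero(
        rng.random(ancestor_len) < np.minimum(subst_rate * mult, 0.95)
    )
    sub_set = set(int(c) for c in sub_cols)
    truth = SyntheticTruth(
        params=dict(ancestor_len=ancestor_len, n_taxa=n_taxa,
                    subst_rate=subst_rate, indel_rate=indel_rate,
                    mean_indel_len=mean_indel_len,
                    hotspot_spec=[list(h) for h in hotspot_spec or []],
                    gc=gc, seed=seed),
    )
    for c in sub_cols:
        rows = _proper_subset(rng, n_taxa)
        alt = ord(_other_base(rng, chr(ancestor[c])))
        matrix[rows, c] = alt
        truth.substitution_columns.append(int(c))
    # indel events: left-to-right greedy, disjoint, separated by >=1 column
    starts = np.flatnonzero(
        rng.random(ancestor_len) < np.minimum(indel_rate * mult, 0.5)
    )
    cursor = -2
    gap = ord("-")
    for s in starts:
        s = int(s)
        if s <= cursor + 1:
            continue
        length = int(rng.geometric(1.0 / mean_indel_len))
        e = s + length
        if e > ancestor_len:
            continue
        if any(c in sub_set for c in range(s, e)):
            continue
        rows = _proper_subset(rng, n_taxa)
        matrix[rows, s:e] = gap
        truth.indel_events.append(
            dict(col_start=s, col_end=e, member_rows=[int(r) for r in rows])
        )
        cursor = e
    names = [f"taxon{i + 1:02d}" for i in range(n_taxa)]
    rows_str = ["".join(map(chr, matrix[i])) for i in range(n_taxa)]
    return Alignment(names=names, rows=rows_str), truth


def _proper_subset(rng, n: int) -> np.ndarray:
    size = int(rng.integers(1, n))  # 1 .. n-1
    return rng.choice(n, size=size, replace=False)
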