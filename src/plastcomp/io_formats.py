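"""Readers and writers for plastome data, plus circular-coordinate access.

Internal convention: all coordinates are 0-based half-open. User-facing
reports use 1-based inclusive coordinates (the GenBank convention); the
converters at the bottom of this module are the only place the two meet.

Plastomes are circular molecules; ``PlastomeRecord.circular`` defaults to
True and enables wrap-around slicing through :func:`extract_region`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: feature kinds that denote an annotated genic element
GENIC_KINDS = frozenset({"gene", "CDS", "tRNA", "rRNA"})

_VALID_KINDS = frozenset({"gene", "CDS", "tRNA", "rRNA", "intron", "IGS"})


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature: a gene, CDS, tRNA or rRNA.

    ``intervals`` are 0-based half-open pairs in genome order; spliced
    features carry one interval per exon.  ``partial`` flags CDS whose
    total length is not a multiple of 3 (truncated annotations).
    """

    name: str
    kind: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    partial: bool = False

    def __post_init__(self):
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.intervals:
            raise ValueError("feature needs at least one interval")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValueError(f"bad interval ({s}, {e}) in {self.name}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def span(self) -> int:
        """Total feature length in bp (sum over intervals)."""
        return sum(e - s for s, e in self.intervals)


@dataclass
class PlastomeRecord:
    """One (possibly circular) genome with its annotated features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"{self.id}: sequence contains non-ACGTN characters {sorted(bad)}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"{self.id}: feature {f.name} extends past sequence end"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genes_once(self) -> list[GeneFeature]:
        """One feature per gene name (IR duplicates collapsed), 'gene' kind
        preferred, keeping the first occurrence otherwise."""
        seen: dict[str, GeneFeature] = {}
        for f in self.features:
            if f.name not in seen or (
                f.kind == "gene" and seen[f.name].kind != "gene"
            ):
                seen.setdefault(f.name, f)
                if f.kind == "gene":
                    seen[f.name] = f
        return list(seen.values())


@dataclass
class Alignment:
    """A multiple sequence alignment over {A,C,G,T,N,-}."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise FormatError("alignment needs at least two rows")
        ncol = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != ncol:
                raise FormatError(
                    f"ragged alignment: row {name!r} has length {len(row)}, "
                    f"expected {ncol}"
                )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no alignment row named {name!r}") from None


# ---------------------------------------------------------------------------
# readers


def _clean_alignment_row(name: str, seq: str) -> str:
    seq = seq.upper()
    extra = set(seq) - set("ACGTN-")
    if extra:
        warnings.warn(
            f"{name}: ambiguity characters {sorted(extra)} mapped to N",
            stacklevel=3,
        )
        seq = "".join(c if c in "ACGTN-" else "N" for c in seq)
    return seq


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def read_genbank(path, circular: bool | None = None) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    Gene/CDS/tRNA/rRNA entries become features; ``join()`` locations become
    multi-interval features; 1-based inclusive GenBank coordinates are
    converted to 0-based half-open.  Unparseable features are skipped with
    a warning.  ``circular`` overrides the record topology annotation
    (plastomes default to circular when the annotation is absent).
    """
    rec = SeqIO.read(str(path), "genbank")
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise FormatError(f"{path}: GenBank record has no sequence block")
    if circular is None:
        topo = rec.annotations.get("topology", "circular")
        circular = topo == "circular"
    features: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type not in GENIC_KINDS:
            continue
        try:
            parts = feat.location.parts
            intervals = tuple((int(p.start), int(p.end)) for p in parts)
            strand = "-" if feat.location.strand == -1 else "+"
            partial = feat.type == "CDS" and sum(
                e - s for s, e in intervals
            ) % 3 != 0
            features.append(
                GeneFeature(
                    name=_feature_name(feat),
                    kind=feat.type,
                    strand=strand,
                    intervals=intervals,
                    partial=partial,
                )
            )
        except (ValueError, AttributeError, TypeError) as exc:
            logger.warning("%s: skipping feature with bad location: %s", path, exc)
    return PlastomeRecord(
        id=rec.id or rec.name, sequence=seq, circular=circular, features=features
    )


def read_fasta(path, circular: bool = True) -> list[PlastomeRecord]:
    """Read (multi-)FASTA into uppercase, feature-less records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        records.append(PlastomeRecord(id=rec.id, sequence=seq, circular=circular))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write records (PlastomeRecord or (name, seq) pairs), wrapped at
    ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, PlastomeRecord):
                name, seq = rec.id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_aligned_fasta(path) -> Alignment:
    """Read an aligned FASTA (gap character '-') into an :class:`Alignment`."""
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(_clean_alignment_row(rec.id, str(rec.seq)))
    if not names:
        raise FormatError(f"{path}: no FASTA records found")
    return Alignment(names=names, rows=rows)


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a minimal GenBank flat file (sequence + genic features)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.split(".")[0][:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        seqrec.features.append(
            SeqFeature(loc, type=f.kind, qualifiers={"gene": [f.name]})
        )
    SeqIO.write([seqrec], str(path), "genbank")


# ---------------------------------------------------------------------------
# circular-coordinate access


def extract_region(record: PlastomeRecord, start: int, end: int) -> str:
    """Sequence of ``[start, end)``, wrapping across the origin when the
    record is circular and ``end`` exceeds the length."""
    n = record.length
    if not (0 <= start < n):
        raise ValueError(f"start {start} outside [0, {n})")
    if end < start:
        raise ValueError("end < start")
    if end - start > n:
        raise ValueError("requested region longer than the genome")
    if end <= n:
        return record.sequence[start:end]
    if not record.circular:
        raise ValueError(
            f"{record.id}: wrap-around slice on a non-circular record"
        )
    return record.sequence[start:] + record.sequence[: end - n]


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate a circular record so that input position ``offset`` becomes
    position 0.  Features are shifted accordingly; a feature that comes to
    straddle the new origin is split into two intervals."""
    n = record.length
    offset %= n
    if offset == 0:
        return record
    if not record.circular:
        raise ValueError(f"{record.id}: cannot rotate a non-circular record")
    seq = record.sequence[offset:] + record.sequence[:offset]
    feats = []
    for f in record.features:
        ivs = []
        for s, e in f.intervals:
            s2, e2 = (s - offset) % n, (e - offset) % n or n
            if s2 < e2:
                ivs.append((s2, e2))
            else:  # wraps the new origin
                ivs.append((s2, n))
                ivs.append((0, e2))
        # re-merge intervals made contiguous (undoes an earlier wrap-split)
        merged = [ivs[0]]
        for s2, e2 in ivs[1:]:
            if merged[-1][1] == s2:
                merged[-1] = (merged[-1][0], e2)
            else:
                merged.append((s2, e2))
        feats.append(replace(f, intervals=tuple(merged)))
    return PlastomeRecord(
        id=record.id, sequence=seq, circular=True, features=feats
    )


def to_1based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_1based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end
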