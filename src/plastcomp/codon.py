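"""Codon counting and relative synonymous codon usage (RSCU) from
annotated CDS features.

RSCU(c) = count(c) * family_size / family_total within each synonymous
family of the genetic code (the bacterial/plastid code, NCBI table 11,
by default).  Stop codons form their own family and are included in the
totals.  A uniform usage within every family gives RSCU 1 everywhere.
"""

from __future__ import annotations

import logging
from collections import Counter

import pandas as pd
from Bio.Data import CodonTable

from .io_formats import PlastomeRecord, revcomp

logger = logging.getLogger(__name__)

BASES = "TCAG"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def synonymous_families(table_id: int = 11) -> dict[str, list[str]]:
    """Map each codon to the list of codons encoding the same amino acid
    (stop codons form the '*' family)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = "*" if codon in table.stop_codons else table.forward_table[codon]
        by_aa.setdefault(aa, []).append(codon)
    return {codon: by_aa[aa] for aa, codons in by_aa.items() for codon in codons}


def codon_to_aa(table_id: int = 11) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return {
        c: ("*" if c in table.stop_codons else table.forward_table[c])
        for c in ALL_CODONS
    }


def cds_sequence(record: PlastomeRecord, feature) -> str:
    """Nucleotide CDS: exon intervals concatenated in genome order, then
    reverse-complemented for minus-strand features."""
    parts = [record.sequence[s:e] for s, e in feature.intervals]
    seq = "".join(parts)
    return revcomp(seq) if feature.strand == "-" else seq


def extract_cds_codons(
    record: PlastomeRecord, dedupe_ir: bool = True
) -> Counter:
    """Count all in-frame codons (including stops) over the record's CDS.

    CDS whose length is not a multiple of 3 are skipped with a warning.
    With ``dedupe_ir`` a CDS that recurs with the same gene name and an
    identical sequence (an IR duplicate) is counted once.
    """
    cds = [f for f in record.features if f.kind == "CDS"]
    if not cds:
        raise ValueError(f"{record.id}: no CDS features")
    counts: Counter = Counter()
    seen: set[tuple[str, str]] = set()
    for f in cds:
        seq = cds_sequence(record, f)
        if len(seq) % 3 != 0:
            logger.warning(
                "%s: CDS %s length %d not a multiple of 3; skipped",
                record.id, f.name, len(seq),
            )
            continue
        if dedupe_ir:
            key = (f.name, seq)
            if key in seen:
                continue
            seen.add(key)
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
    return counts


def rscu(counts: Counter, table_id: int = 11) -> pd.DataFrame:
    """RSCU table: codon, amino acid, count, rscu (empty for families with
    zero total)."""
    families = synonymous_families(table_id)
    aa = codon_to_aa(table_id)
    rows = []
    for codon in ALL_CODONS:
        family = families[codon]
        family_total = sum(counts.get(c, 0) for c in family)
        value = (
            counts.get(codon, 0) * len(family) / family_total
            if family_total > 0
            else float("nan")
        )
        rows.append(
            {
                "codon": codon,
                "amino_acid": aa[codon],
                "count": counts.get(codon, 0),
                "rscu": round(value, 4) if family_total > 0 else None,
            }
        )
    return pd.DataFrame(rows)


def usage_summary(record: PlastomeRecord, dedupe_ir: bool = True) -> dict:
    """Total codon count and the most frequent codon (RNA spelling)."""
    counts = extract_cds_codons(record, dedupe_ir=dedupe_ir)
    top, top_n = max(counts.items(), key=lambda kv: kv[1])
    return {
        "total_codons": sum(counts.values()),
        "most_frequent_codon": top.replace("T", "U"),
        "most_frequent_count": top_n,
    }
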