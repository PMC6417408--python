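import numpy as np
import pytest

from plastcomp.io_formats import GeneFeature, PlastomeRecord, revcomp
from plastcomp.long_repeats import (
    RepeatPair,
    classify_repeat_locations,
    find_repeats,
    locate,
    summarize_repeats,
)
from plastcomp.structure import detect_inverted_repeat
from plastcomp.io_formats import rotate_record
from oracles import allpairs_repeats


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant(seq: list, src: tuple, dst_start: int, rtype: str, rng):
    """Copy seq[src] to dst (transformed) and break both flanks so the
    planted window is exactly maximal."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    s0, s1 = src
    length = s1 - s0
    segment = "".join(seq[s0:s1])
    if rtype == "F":
        copy = segment
    elif rtype == "P":
        copy = revcomp(segment)
    elif rtype == "R":
        copy = segment[::-1]
    else:
        copy = "".join(comp[c] for c in segment)
    seq[dst_start : dst_start + length] = list(copy)
    rel = (lambda a, b: a == comp[b]) if rtype in ("P", "C") else \
        (lambda a, b: a == b)
    for t in range(8):
        for u, v in (
            ((s0 - 1 - t, dst_start - 1 - t) if rtype in ("F", "C")
             else (s0 - 1 - t, dst_start + length + t)),
            ((s1 + t, dst_start + length + t) if rtype in ("F", "C")
             else (s1 + t, dst_start - 1 - t)),
        ):
            if 0 <= u < len(seq) and 0 <= v < len(seq):
                while rel(seq[u], seq[v]):
                    seq[v] = "ACGT"[int(rng.integers(4))]


def test_exact_forward_copy_found_once():
    """A 40-bp segment copied elsewhere yields exactly one F pair of
    length 40 and identity 1."""
    rng = np.random.default_rng(2)
    seq = list(_random_seq(rng, 1000))
    _plant(seq, (100, 140), 600, "F", rng)
    pairs = find_repeats("".join(seq))
    f_pairs = [p for p in pairs if p.rtype == "F"]
    assert len(f_pairs) == 1
    (p,) = f_pairs
    assert (p.pos1, p.pos2, p.length, p.identity) == (100, 600, 40, 1.0)


def test_exact_palindromic_copy_found_once():
    rng = np.random.default_rng(4)
    seq = list(_random_seq(rng, 1000))
    _plant(seq, (100, 140), 600, "P", rng)
    pairs = [p for p in find_repeats("".join(seq)) if p.rtype == "P"]
    assert len(pairs) == 1
    assert (pairs[0].pos1, pairs[0].pos2, pairs[0].length) == (100, 600, 40)


def test_matches_allpairs_oracle_with_mismatches():
    """Planted F/P/R/C repeats with up to 3 mismatches on a 1 kb genome:
    detector output equals the seed-free all-pairs oracle."""
    rng = np.random.default_rng(3)
    seq = list(_random_seq(rng, 1000))
    _plant(seq, (30, 70), 200, "F", rng)
    _plant(seq, (300, 336), 450, "P", rng)
    _plant(seq, (520, 565), 700, "R", rng)
    _plant(seq, (820, 854), 900, "C", rng)
    # scattered mismatches that keep a long exact stretch for seeding
    for pos in (216, 468, 712):
        old = seq[pos]
        while seq[pos] == old:
            seq[pos] = "ACGT"[int(rng.integers(4))]
    genome = "".join(seq)
    got = {(p.rtype, p.pos1, p.pos2, p.length, p.mismatches)
           for p in find_repeats(genome)}
    expected = allpairs_repeats(genome)
    assert got == expected
    assert {g[0] for g in got} == {"F", "P", "R", "C"}


def test_reverse_complement_symmetry():
    """Running on the reverse complement preserves F and P counts."""
    rng = np.random.default_rng(6)
    seq = list(_random_seq(rng, 800))
    _plant(seq, (50, 90), 300, "F", rng)
    _plant(seq, (450, 500), 600, "P", rng)
    genome = "".join(seq)
    fwd = find_repeats(genome)
    rev = find_repeats(revcomp(genome))

    def counts(pairs):
        return {t: sum(1 for p in pairs if p.rtype == t) for t in "FP"}

    assert counts(fwd) == counts(rev)
    n = len(genome)
    fwd_f = next(p for p in fwd if p.rtype == "F")
    rev_f = next(p for p in rev if p.rtype == "F")
    assert {n - fwd_f.pos1 - fwd_f.length, n - fwd_f.pos2 - fwd_f.length} \
        == {rev_f.pos1, rev_f.pos2}


def test_ir_pair_appears_as_giant_palindrome(midsize_plastome):
    rec, truth = midsize_plastome
    pairs = find_repeats(rec)
    ir_len = truth.partition["ir_length"]
    giants = [p for p in pairs if p.rtype == "P" and p.length >= ir_len]
    assert len(giants) == 1
    g = giants[0]
    irb, ira = truth.partition["irb"], truth.partition["ira"]
    assert g.pos1 <= irb[0] and g.pos1 + g.length >= irb[1] - 1


def test_mask_second_ir_removes_giant_but_keeps_planted(midsize_plastome):
    rec, truth = midsize_plastome
    part = detect_inverted_repeat(rec)
    ir_len = truth.partition["ir_length"]
    pairs = find_repeats(rec, mask_second_ir=True, partition=part)
    assert not any(p.length >= ir_len for p in pairs)
    planted = {(d["rtype"], d["pos1"], d["pos2"], d["length"],
                d["mismatches"]) for d in truth.planted_repeats}
    got = {(p.rtype, p.pos1, p.pos2, p.length, p.mismatches) for p in pairs}
    assert planted <= got


def test_planted_repeats_recovered_exactly(midsize_plastome):
    rec, truth = midsize_plastome
    pairs = find_repeats(rec)
    ir_len = truth.partition["ir_length"]
    dispersed = {(p.rtype, p.pos1, p.pos2, p.length, p.mismatches)
                 for p in pairs if p.length < ir_len}
    planted = {(d["rtype"], d["pos1"], d["pos2"], d["length"],
                d["mismatches"]) for d in truth.planted_repeats}
    assert dispersed == planted


def test_short_sequence_yields_nothing():
    assert find_repeats("ACGTACGT") == []


def test_locate_labels_gene_and_igs():
    rng = np.random.default_rng(8)
    rec = PlastomeRecord(
        id="x", sequence=_random_seq(rng, 1000),
        features=[
            GeneFeature(name="geneA", kind="gene", strand="+",
                        intervals=((100, 300),)),
            GeneFeature(name="geneB", kind="gene", strand="+",
                        intervals=((600, 800),)),
        ],
    )
    assert locate(rec, 150, 200) == "geneA"
    assert locate(rec, 400, 450) == "IGS(geneA-geneB)"
    # majority overlap wins; exact tie joins both labels
    assert locate(rec, 250, 320) == "geneA"
    assert set(locate(rec, 280, 320).split("/")) == \
        {"geneA", "IGS(geneA-geneB)"}


def test_classify_and_location_summary(midsize_plastome):
    rec, truth = midsize_plastome
    part = detect_inverted_repeat(rec)
    rot = rotate_record(rec, part.rotation_offset)
    pairs = find_repeats(rot)
    annotated, summary = classify_repeat_locations(pairs, rot, part)
    assert len(annotated) == len(pairs)
    assert summary["repeat_copies"].sum() == 2 * len(pairs)
    # planted dispersed repeats live in the LSC
    ir_len = truth.partition["ir_length"]
    for p in annotated:
        if p.length < ir_len:
            assert p.region1 == "LSC"


def test_summarize_bins():
    pairs = [
        RepeatPair(rtype="F", pos1=0, pos2=100, length=35, mismatches=0),
        RepeatPair(rtype="F", pos1=0, pos2=400, length=150, mismatches=0),
    ]
    df = summarize_repeats({"g": pairs}).set_index("genome")
    assert df.loc["g", "F_30-59"] == 1
    assert df.loc["g", "F_>=140"] == 1
    assert df.loc["g", "F_60-79"] == 0
    assert df.loc["g", "total"] == 2
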