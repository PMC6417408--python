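import numpy as np
import pytest

from plastcomp.io_formats import GeneFeature, PlastomeRecord, revcomp, rotate_record
from plastcomp.structure import (
    AmbiguousStructure,
    NoQuadripartiteStructure,
    detect_inverted_repeat,
    gc_percent,
    junction_report,
    region_stats,
)
from plastcomp import simulate_plastome
from oracles import longest_inverted_pair


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_planted_partition_recovered_exactly(small_plastome):
    rec, truth = small_plastome
    part = detect_inverted_repeat(rec, min_ir=500)
    assert list(part.lsc) == truth.partition["lsc"]
    assert list(part.irb) == truth.partition["irb"]
    assert list(part.ssc) == truth.partition["ssc"]
    assert list(part.ira) == truth.partition["ira"]
    assert part.ir_length == truth.partition["ir_length"]
    part.validate(rec)


def test_constructed_genome_boundaries():
    """LSC(5 kb) + IR(800) + SSC(700) + revcomp(IR): planted boundaries
    come back exactly."""
    rng = np.random.default_rng(0)
    lsc = _random_seq(rng, 5000)
    ir = _random_seq(rng, 800)
    ssc = _random_seq(rng, 700)
    # break chance extension at each junction (last LSC vs first LSC base
    # across the origin; first SSC vs last SSC base)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if lsc[-1] == comp[lsc[0]]:
        lsc = lsc[:-1] + ("A" if comp[lsc[0]] != "A" else "C")
    if ssc[0] == comp[ssc[-1]]:
        ssc = ("A" if comp[ssc[-1]] != "A" else "C") + ssc[1:]
    rec = PlastomeRecord(id="x", sequence=lsc + ir + ssc + revcomp(ir))
    part = detect_inverted_repeat(rec, min_ir=500)
    assert part.lsc == (0, 5000)
    assert part.irb == (5000, 5800)
    assert part.ssc == (5800, 6500)
    assert part.ira == (6500, 7300)
    assert part.ir_length == 800


def test_detection_matches_bruteforce_oracle():
    """Random 2 kb with a planted 150-bp IR equals the O(n^2) DP oracle."""
    rng = np.random.default_rng(7)
    seq = list(_random_seq(rng, 2000))
    ir = _random_seq(rng, 150)
    seq[300:450] = list(ir)
    seq[1500:1650] = list(revcomp(ir))
    seq = "".join(seq)
    rec = PlastomeRecord(id="x", sequence=seq, circular=False)
    a, b, length = longest_inverted_pair(seq)
    part = detect_inverted_repeat(rec, min_ir=100, rotate=False)
    assert part.ir_length == length
    assert (part.irb[0], part.ira[0]) in {(a, b), (b, a)} or \
        {part.irb[0], part.ira[0]} == {a, b}


def test_rotation_invariance(small_plastome):
    """A circular rotation of the input yields the same canonical
    partition."""
    rec, _ = small_plastome
    base = detect_inverted_repeat(rec, min_ir=500)
    for off in (137, 3000, 6000):
        rot = rotate_record(rec, off)
        part = detect_inverted_repeat(rot, min_ir=500)
        assert part.regions() == base.regions()
        assert part.ir_length == base.ir_length


def test_no_structure_raises():
    rng = np.random.default_rng(3)
    rec = PlastomeRecord(id="x", sequence=_random_seq(rng, 500))
    with pytest.raises(NoQuadripartiteStructure):
        detect_inverted_repeat(rec, min_ir=100)


def test_ambiguous_candidates_raise():
    """Two equal-length candidate IR pairs are reported, not silently
    resolved."""
    rng = np.random.default_rng(9)
    i1 = _random_seq(rng, 200)
    i2 = _random_seq(rng, 200)
    parts = [
        _random_seq(rng, 500), i1, _random_seq(rng, 400), revcomp(i1),
        _random_seq(rng, 500), i2, _random_seq(rng, 400), revcomp(i2),
        _random_seq(rng, 300),
    ]
    rec = PlastomeRecord(id="x", sequence="".join(parts), circular=False)
    with pytest.raises(AmbiguousStructure):
        detect_inverted_repeat(rec, min_ir=150)


def test_region_stats_gc_and_tiling():
    from plastcomp.structure import QuadripartitePartition

    lsc = "G" * 600 + "C" * 600
    rng = np.random.default_rng(1)
    ir = _random_seq(rng, 300)
    ssc = "AT" * 100
    rec = PlastomeRecord(id="x", sequence=lsc + ir + ssc + revcomp(ir))
    part = QuadripartitePartition(
        lsc=(0, 1200), irb=(1200, 1500), ssc=(1500, 1700),
        ira=(1700, 2000), rotation_offset=0, length=2000,
    )
    stats = region_stats(rec, part).set_index("region")
    assert stats.loc["LSC", "gc_pct"] == 100.0
    assert stats.loc["SSC", "gc_pct"] == 0.0
    total = stats.loc["total", "length_bp"]
    assert (
        stats.loc["LSC", "length_bp"] + stats.loc["SSC", "length_bp"]
        + 2 * stats.loc["IR", "length_bp"] == total
    )


def test_ir_proportion_formula():
    """With region sizes 87,606 / 30,940 / 12,045 the IR pair occupies
    2 x 30,940 / 161,531 = 38.31% of the genome."""
    rec, _ = simulate_plastome(
        lsc_len=87_606, ir_len=30_940, ssc_len=12_045, n_ssrs=3,
        n_repeats=2, n_genes=5, seed=2,
    )
    assert rec.length == 161_531
    part = detect_inverted_repeat(rec)
    stats = region_stats(rec, part).set_index("region")
    assert stats.loc["IR", "length_bp"] == 30_940
    assert stats.loc["IR", "proportion_pct"] == 38.31


def test_gc_percent_excludes_n():
    assert gc_percent("GCGCNNNN") == 100.0
    assert gc_percent("ATNN") == 0.0


def test_junction_truncated_fragment(small_plastome):
    """A gene planted to straddle SSC/IRa by 250 bp reports a 250-bp
    truncated fragment."""
    rec, truth = small_plastome
    part = detect_inverted_repeat(rec, min_ir=500)
    report = junction_report(rec, part).set_index("junction")
    assert report.loc["SSC/IRa", "truncated_fragment_len"] == 250
    jgene = next(f for f in truth.planted_features
                 if f.get("junction_overlap"))
    assert report.loc["SSC/IRa", "left_gene"] == jgene["name"]
    # straddler: negative distances on both sides
    assert report.loc["SSC/IRa", "left_dist"] == -250


def test_junction_nearest_genes_match_interval_oracle(midsize_plastome):
    """Nearest-gene calls agree with a brute-force scan over features."""
    rec, _ = midsize_plastome
    part = detect_inverted_repeat(rec)
    report = junction_report(rec, part).set_index("junction")
    rot = rotate_record(rec, part.rotation_offset)
    n = rec.length
    genic = [f for f in rot.features if f.kind in
             {"gene", "CDS", "tRNA", "rRNA"}]
    junctions = {"LSC/IRb": part.irb[0], "IRb/SSC": part.ssc[0],
                 "SSC/IRa": part.ira[0], "IRa/LSC": n}
    for jname, p in junctions.items():
        straddlers = [f for f in genic if f.start < p < f.end]
        if straddlers:
            assert report.loc[jname, "left_gene"] == straddlers[0].name
            continue
        dl = min((p - f.end) % n for f in genic)
        dr = min((f.start - p) % n for f in genic)
        assert report.loc[jname, "left_dist"] == dl
        assert report.loc[jname, "right_dist"] == dr


def test_junction_report_on_featureless_record():
    rng = np.random.default_rng(4)
    lsc, ir, ssc = (_random_seq(rng, 3000), _random_seq(rng, 500),
                    _random_seq(rng, 400))
    rec = PlastomeRecord(id="x", sequence=lsc + ir + ssc + revcomp(ir))
    part = detect_inverted_repeat(rec, min_ir=300)
    report = junction_report(rec, part)
    assert list(report["left_gene"]) == [""] * 4
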