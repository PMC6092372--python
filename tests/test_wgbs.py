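"""Bisulfite methylation calling, context extraction and m5C assignment."""

import numpy as np
import pytest

from bacmeth.genome import Genome, reverse_complement
from bacmeth.motifs import WGBS_MOTIFS, scan_all
from bacmeth.wgbs import (
    CytosineCount,
    assign_m5c,
    call_methylated,
    extract_context,
    meets_thresholds,
    read_cytosine_report,
    write_cytosine_report,
)


def cc(position, n_meth, n_total, strand="+", condition="EP"):
    return CytosineCount("c", position, strand, n_meth, n_total, condition)


# ------------------------------------------------------------------- I/O
def test_report_parsing_converts_coordinates(tmp_path):
    p = tmp_path / "rep.tsv"
    p.write_text("c1\t10\t+\t27\t3\nc1\t11\t-\t0\t0\n")
    counts = read_cytosine_report(p)
    assert counts[0].position == 9
    assert counts[0].n_methylated == 27
    assert counts[0].n_total == 30
    assert counts[1].n_total == 0  # zero-coverage rows retained


def test_report_round_trip(tmp_path):
    counts = [cc(9, 27, 30), cc(50, 0, 40, strand="-")]
    p = tmp_path / "rt.tsv"
    write_cytosine_report(counts, p)
    assert read_cytosine_report(p, condition="EP") == counts


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        CytosineCount("c", 1, "+", -1, 5)
    with pytest.raises(ValueError):
        CytosineCount("c", 1, "+", 6, 5)


# ------------------------------------------------------------- thresholds
@pytest.mark.parametrize(
    "n_meth,n_total,called",
    [
        (23, 25, True),    # 0.92 at exactly 25x: both thresholds met
        (24, 24, False),   # full methylation below 25x coverage
        (89, 100, False),  # 0.89 < 0.90
        (90, 100, True),   # exactly 90%, inclusive
        (9, 10, False),    # coverage too low even at exactly 0.9
        (45, 50, True),
    ],
)
def test_calling_thresholds_inclusive(n_meth, n_total, called):
    assert meets_thresholds(cc(0, n_meth, n_total)) is called


def test_exact_rational_boundary_is_bit_stable():
    # 9/10-scale fractions hit the 0.90 boundary exactly at any coverage
    for k in (3, 7, 31, 101):
        assert meets_thresholds(cc(0, 9 * k, 10 * k), min_cov=1)
        assert not meets_thresholds(cc(0, 9 * k - 1, 10 * k), min_cov=1)


def test_calling_is_monotone_in_thresholds():
    rng = np.random.default_rng(5)
    counts = [
        cc(i, int(rng.integers(0, t + 1)), t)
        for i, t in enumerate(rng.integers(1, 80, size=300))
    ]
    base = len(call_methylated(counts, min_cov=20, min_frac=0.8))
    assert len(call_methylated(counts, min_cov=30, min_frac=0.8)) <= base
    assert len(call_methylated(counts, min_cov=20, min_frac=0.95)) <= base


# ---------------------------------------------------------------- context
def test_context_window_is_41nt_centred():
    seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=41))
    genome = Genome({"c": seq})
    assert extract_context(genome, "c", 20, "+") == seq


def test_context_edge_padding_with_n():
    genome = Genome({"c": "ACGTA" * 20})
    ctx = extract_context(genome, "c", 0, "+")
    assert len(ctx) == 41
    assert ctx[:20] == "N" * 20
    assert ctx[20:] == genome["c"][:21]


def test_minus_strand_context_is_reverse_complement_of_plus_window():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    genome = Genome({"c": seq})
    for pos in (0, 5, 40, 100, 199):
        plus = extract_context(genome, "c", pos, "+")
        minus = extract_context(genome, "c", pos, "-")
        assert minus == reverse_complement(plus)
        # independent slicing oracle for the interior case
        if 20 <= pos <= 179:
            assert plus == seq[pos - 20:pos + 21]


# ------------------------------------------------------------- assignment
def test_assign_m5c_matches_called_sites_exactly():
    genome = Genome({"c": "AACCAGGTTGGCGCCTT"})  # CCWGG at 2, GGCGCC at 9
    occ = scan_all(genome, WGBS_MOTIFS)
    called = call_methylated([cc(3, 48, 50), cc(11, 30, 30), cc(4, 50, 50)])
    status, summary = assign_m5c(occ, called, condition="EP")
    by_motif = status.set_index("motif")
    assert bool(by_motif.loc["motif VI", "detected"])
    assert bool(by_motif.loc["motif VII", "detected"])
    row = summary.set_index("motif").loc["motif VI"]
    assert row["n_detected"] == 1 and row["fraction"] == 1.0


def test_assign_m5c_brute_force_small_instances():
    rng = np.random.default_rng(29)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = Genome({"c": seq})
        occ = scan_all(genome, WGBS_MOTIFS)
        counts = [
            cc(int(p), int(m), 50, strand=rng.choice(["+", "-"]))
            for p, m in zip(
                rng.integers(0, 1000, size=60), rng.integers(0, 51, size=60)
            )
        ]
        called = call_methylated(counts)
        status, _ = assign_m5c(occ, called, "EP")
        called_keys = set(
            zip(called["contig"], called["position"], called["strand"])
        )
        expected = [
            (r.contig, r.methylated_position, r.methylated_strand) in called_keys
            for r in occ.itertuples(index=False)
        ]
        assert status["detected"].tolist() == expected


def test_no_called_cytosines_means_zero_fractions(dataset):
    occ = dataset.wgbs_occurrences
    empty = call_methylated([])
    status, summary = assign_m5c(occ, empty, "EP")
    assert not status["detected"].any()
    assert (summary["fraction"] == 0).all()


def test_mean_modified_read_proportion_high_over_called(dataset):
    """Called sites have >= 90% modified reads by construction; on synthetic
    data emulating the study the mean proportion stays well above 90%."""
    counts = dataset.wgbs_report("EP")
    called = call_methylated(counts)
    assert (called["fraction_modified"] >= 0.9).all()
    assert called["fraction_modified"].mean() > 0.9
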