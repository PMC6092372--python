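"""SMRT modification-call parsing, filtering, assignment and summaries."""

import numpy as np
import pandas as pd
import pytest

from bacmeth.genome import Genome
from bacmeth.motifs import BUILTIN_MOTIFS, MotifSpec, scan_all
from bacmeth.smrt import (
    ModificationCall,
    assign_calls,
    filter_calls,
    format_summary,
    read_modifications,
    round_half_up,
    summarize,
    write_modifications,
)

from conftest import oracle_assign


def make_call(position, strand="+", mod_type="m6A", qv=50.0, **kw):
    defaults = dict(contig="c", ipd_ratio=5.0, coverage=100, condition="EP")
    defaults.update(kw)
    return ModificationCall(
        position=position, strand=strand, mod_type=mod_type, qv=qv, **defaults
    )


# ------------------------------------------------------------------- I/O
def test_gff3_parsing_converts_to_zero_based(tmp_path):
    p = tmp_path / "mods.gff3"
    p.write_text(
        "##gff-version 3\n"
        "c\tkinModCall\tm6A\t82\t82\t213.9\t+\t.\tIPDRatio=5.28;coverage=148\n"
        "c\tkinModCall\tmodified_base\t99\t99\t31\t-\t.\tIPDRatio=2.1;coverage=60\n"
    )
    calls = read_modifications(p, condition="EP")
    assert calls[0].position == 81
    assert calls[0].mod_type == "m6A"
    assert calls[0].qv == pytest.approx(213.9)
    assert calls[0].ipd_ratio == pytest.approx(5.28)
    assert calls[0].coverage == 148
    assert calls[1].mod_type == "unknown"  # generic modified_base retained
    assert calls[1].strand == "-"


@pytest.mark.parametrize("dialect", ["modifications-gff3", "tsv"])
def test_round_trip(tmp_path, dialect):
    calls = [make_call(10), make_call(20, strand="-", mod_type="m4C", qv=31.5)]
    p = tmp_path / "out"
    write_modifications(calls, p, dialect=dialect)
    back = read_modifications(p, dialect=dialect, condition="EP")
    assert back == calls


def test_unknown_contig_rejected_when_genome_given(tmp_path):
    p = tmp_path / "mods.gff3"
    p.write_text("z\tkinModCall\tm6A\t5\t5\t40\t+\t.\tIPDRatio=3;coverage=10\n")
    with pytest.raises(ValueError, match="unknown contig"):
        read_modifications(p, genome=Genome({"c": "ACGT" * 10}))


# ---------------------------------------------------------------- filter
def test_qv_filter_is_inclusive():
    calls = [make_call(1, qv=30.0), make_call(2, qv=29.9), make_call(3, qv=150)]
    kept = filter_calls(calls, min_qv=30)
    assert [c.position for c in kept] == [1, 3]
    assert filter_calls(calls, min_qv=0) == calls
    assert filter_calls(calls, min_qv=1000) == []


def test_raising_min_qv_never_detects_more(dataset):
    occ = dataset.smrt_occurrences
    calls = dataset.smrt_calls("EP")
    prev = None
    for min_qv in (0, 20, 30, 100, 250):
        status, _ = assign_calls(occ, filter_calls(calls, min_qv), "EP")
        n = int(status["detected"].sum())
        if prev is not None:
            assert n <= prev
        prev = n


# ---------------------------------------------------------------- assign
@pytest.fixture
def gatc_occurrences():
    return scan_all(Genome({"c": "GATCAAGATC"}), [BUILTIN_MOTIFS[0]])


def test_call_on_methylated_base_detects(gatc_occurrences):
    status, off = assign_calls(gatc_occurrences, [make_call(1)], "EP")
    assert status.loc[status["methylated_position"] == 1, "detected"].item()
    assert off == []


def test_call_elsewhere_is_off_motif(gatc_occurrences):
    status, off = assign_calls(gatc_occurrences, [make_call(0)], "EP")
    assert not status["detected"].any()
    assert [c.position for c in off] == [0]


def test_minus_strand_call_does_not_match_plus_occurrence(gatc_occurrences):
    status, off = assign_calls(gatc_occurrences, [make_call(1, strand="-")], "EP")
    assert not status["detected"].any()
    assert len(off) == 1


def test_incompatible_mod_type_not_assigned(gatc_occurrences):
    status, _ = assign_calls(gatc_occurrences, [make_call(1, mod_type="m4C")], "EP")
    assert not status["detected"].any()
    status, _ = assign_calls(
        gatc_occurrences, [make_call(1, mod_type="unknown")], "EP"
    )
    assert status.loc[status["methylated_position"] == 1, "detected"].item()


def test_duplicate_calls_resolved_by_max_qv(gatc_occurrences):
    status, _ = assign_calls(
        gatc_occurrences, [make_call(1, qv=40), make_call(1, qv=90)], "EP"
    )
    assert status.loc[status["methylated_position"] == 1, "qv"].item() == 90


def test_assign_agrees_with_cross_join_oracle():
    rng = np.random.default_rng(23)
    registry = [BUILTIN_MOTIFS[0], BUILTIN_MOTIFS[6]]  # GATC + CCWGG
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = Genome({"c": seq})
        occ = scan_all(genome, registry)
        calls = [
            make_call(
                int(rng.integers(0, 1000)),
                strand=rng.choice(["+", "-"]),
                mod_type=rng.choice(["m6A", "m4C", "unknown"]),
                qv=float(rng.uniform(30, 200)),
            )
            for _ in range(40)
        ]
        status, _ = assign_calls(occ, calls, "EP")
        np.testing.assert_array_equal(
            status["detected"].to_numpy(), oracle_assign(occ, calls)
        )


# -------------------------------------------------------------- summarize
def test_summarize_fraction_and_means(gatc_occurrences):
    calls = [make_call(1, qv=40, ipd_ratio=4.0), make_call(7, qv=60, ipd_ratio=6.0)]
    status, _ = assign_calls(gatc_occurrences, calls, "EP")
    s = summarize(status)
    row = s.iloc[0]
    assert row["n_total"] == 2 and row["n_detected"] == 2
    assert row["mean_ipd_ratio"] == pytest.approx(5.0)
    assert row["mean_score"] == pytest.approx(50.0)


def test_summarize_zero_detected(gatc_occurrences):
    status, _ = assign_calls(gatc_occurrences, [], "EP")
    s = summarize(status)
    assert s.iloc[0]["fraction"] == 0.0
    assert np.isnan(s.iloc[0]["mean_score"])


def test_report_rounding_half_up():
    assert round_half_up(37465 / 37500, 3) == 0.999
    assert round_half_up(0.9995, 3) == 1.0
    assert round_half_up(0.0005, 3) == 0.001
    assert round_half_up(213.94, 1) == 213.9
    s = pd.DataFrame(
        {
            "motif": ["m"], "condition": ["EP"], "n_total": [37500],
            "n_detected": [37465], "fraction": [37465 / 37500],
            "mean_score": [213.94], "mean_ipd_ratio": [5.28],
            "mean_coverage": [148.26],
        }
    )
    out = format_summary(s)
    assert out.loc[0, "fraction"] == 0.999
    assert out.loc[0, "mean_coverage"] == 148.3


def test_per_motif_detected_equals_distinct_on_motif_calls(dataset):
    """Bookkeeping identity: summing n_detected over motifs counts each
    qualifying on-motif call once per motif it serves."""
    occ = dataset.smrt_occurrences
    calls = filter_calls(dataset.smrt_calls("EP"), 30)
    status, off = assign_calls(occ, calls, "EP")
    s = summarize(status)
    det = status[status["detected"]]
    distinct_sites = det.groupby(
        ["motif", "contig", "methylated_position", "methylated_strand"]
    ).ngroups
    assert s["n_detected"].sum() == distinct_sites
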