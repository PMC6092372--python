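"""Location classification and promoter-enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from bacmeth.context import (
    classify_location,
    enrichment_table,
    fisher_exact_2x2,
    location_fractions,
    promoter_enrichment,
)
from bacmeth.genome import GeneFeature

from conftest import oracle_fisher, oracle_location, random_2x2


def occ_at(positions, motif="motif I"):
    return pd.DataFrame(
        {
            "motif": motif,
            "contig": "c",
            "start": [p - 1 for p in positions],
            "strand": "+",
            "methylated_position": positions,
            "methylated_strand": "+",
        }
    )


PLUS_GENE = GeneFeature("c", 1000, 2000, "+", "gPlus")
MINUS_GENE = GeneFeature("c", 1000, 2000, "-", "gMinus")


@pytest.mark.parametrize(
    "pos,genes,expected,distance",
    [
        (850, [PLUS_GENE], "promoter", 150),
        (801, [PLUS_GENE], "promoter", 199),   # strictly < 200
        (800, [PLUS_GENE], "intergenic", None),  # exactly 200: excluded
        (999, [PLUS_GENE], "promoter", 1),
        (1000, [PLUS_GENE], "gene_body", None),
        (1999, [PLUS_GENE], "gene_body", None),
        (2000, [PLUS_GENE], "intergenic", None),
        (2100, [MINUS_GENE], "promoter", 101),  # upstream is rightward
        (2198, [MINUS_GENE], "promoter", 199),
        (2199, [MINUS_GENE], "intergenic", None),
        (500, [PLUS_GENE], "intergenic", None),
    ],
)
def test_location_classification_boundaries(pos, genes, expected, distance):
    out = classify_location(occ_at([pos]), genes)
    assert out.loc[0, "location"] == expected
    if distance is not None:
        assert out.loc[0, "distance_to_start"] == distance


def test_promoter_beats_gene_body_for_nested_genes():
    # inside gene A but < 200 bp upstream of gene B
    gene_a = GeneFeature("c", 0, 3000, "+", "gA")
    gene_b = GeneFeature("c", 2050, 2500, "+", "gB")
    out = classify_location(occ_at([1900]), [gene_a, gene_b])
    assert out.loc[0, "location"] == "promoter"
    assert out.loc[0, "nearest_gene"] == "gB"


def test_divergent_genes_report_nearest_start():
    left = GeneFeature("c", 500, 900, "-", "gLeft")    # upstream: [900, 1098]
    right = GeneFeature("c", 1100, 1500, "+", "gRight")  # upstream: [901, 1099]
    out = classify_location(occ_at([1050]), [left, right])
    assert out.loc[0, "location"] == "promoter"
    assert out.loc[0, "nearest_gene"] == "gRight"  # distance 50 beats 151


def test_classification_agrees_with_gene_loop_oracle(dataset):
    occ = dataset.smrt_occurrences
    sample = occ.sample(300, random_state=0).reset_index(drop=True)
    out = classify_location(sample, dataset.genes)
    expected = [
        oracle_location(int(p), c, dataset.genes)
        for p, c in zip(sample["methylated_position"], sample["contig"])
    ]
    assert out["location"].tolist() == expected


def test_classification_is_exhaustive_partition(analysis):
    counts = analysis.located["location"].value_counts()
    assert counts.sum() == len(analysis.located)
    assert set(counts.index) <= {"promoter", "gene_body", "intergenic"}


def test_no_genes_means_all_intergenic():
    out = classify_location(occ_at([5, 50, 500]), [])
    assert (out["location"] == "intergenic").all()


def test_location_fractions_sum_to_one():
    out = classify_location(occ_at([850, 1500, 500]), [PLUS_GENE])
    fr = location_fractions(out)
    assert fr.sum() == pytest.approx(1.0)
    assert fr["promoter"] == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        location_fractions(out.iloc[0:0])


def test_fisher_small_table_exact_values():
    # C(10,5)=252 margin-fixed tables; the two extremes each have p=1/252
    p, odds = fisher_exact_2x2([[5, 0], [0, 5]])
    assert p == pytest.approx(2 / 252, rel=1e-9)
    p, odds = fisher_exact_2x2([[1, 1], [1, 1]])
    assert p == 1.0
    assert odds == 1.0


def test_fisher_invariant_under_row_and_column_swap():
    rng = np.random.default_rng(31)
    for _ in range(25):
        (a, b), (c, d) = random_2x2(rng)
        p1, _ = fisher_exact_2x2([[a, b], [c, d]])
        p2, _ = fisher_exact_2x2([[d, c], [b, a]])  # both rows and columns
        assert p1 == pytest.approx(p2, rel=1e-9)


def test_fisher_agrees_with_enumeration_oracle():
    rng = np.random.default_rng(37)
    for _ in range(40):
        table = random_2x2(rng)
        p, _ = fisher_exact_2x2(table)
        assert p == pytest.approx(float(oracle_fisher(table)), abs=1e-9)


def test_fisher_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, -1], [0, 2]])


def make_located(promoter_flags):
    df = occ_at(list(range(1, len(promoter_flags) * 10, 10))[: len(promoter_flags)])
    df = df.iloc[: len(promoter_flags)].copy()
    df["location"] = [
        "promoter" if f else "intergenic" for f in promoter_flags
    ]
    return df


def test_enrichment_of_subset_equal_to_background_is_null():
    background = make_located([True] * 10 + [False] * 30)
    res = promoter_enrichment(background, background)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == 1.0


def test_promoter_skewed_subset_is_significant():
    rng = np.random.default_rng(41)
    background = make_located(rng.random(400) < 0.15)
    subset = background[background["location"] == "promoter"].head(20)
    res = promoter_enrichment(subset, background)
    assert res.p_value < 0.001
    assert res.subset_promoter == 20


def test_uniform_subset_converges_to_background_fraction():
    """Promoter fraction of uniformly sampled subsets matches background."""
    rng = np.random.default_rng(43)
    background = make_located(rng.random(2000) < 0.2)
    bg_frac = (background["location"] == "promoter").mean()
    fracs = [
        (background.sample(200, random_state=s)["location"] == "promoter").mean()
        for s in range(30)
    ]
    assert np.mean(fracs) == pytest.approx(bg_frac, abs=0.02)


def test_enrichment_table_on_planted_truth(dataset, analysis):
    enr = analysis.enrichment.set_index("motif")
    row = enr.loc["motif I"]
    assert row["subset_promoter"] == dataset.config.protected_promoter
    assert row["p_value"] < 0.001
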