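"""Genomic-context classification and promoter-enrichment statistics.

Each motif occurrence (at its methylated base) is assigned to exactly one of
three classes: *promoter* — strictly within 200 bp upstream of some gene's
start codon, on that gene's upstream side; *gene_body* — inside a gene's
[start, end); *intergenic* — everything else, including regions downstream of
genes. When a position qualifies as both promoter and gene body (overlapping
or nested genes) promoter wins: the categories target regulatory regions.

Enrichment of a subset (e.g. conserved-unmethylated sites) in promoters
relative to all genomic occurrences of the motif is tested with a two-sided
Fisher's exact test on the 2x2 table [subset vs background] x [promoter vs
elsewhere].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome import GeneFeature

LOCATION_CLASSES = ("promoter", "gene_body", "intergenic")


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 promoter-enrichment test result."""

    subset_promoter: int
    subset_elsewhere: int
    background_promoter: int
    background_elsewhere: int
    odds_ratio: float
    p_value: float

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.subset_promoter, self.subset_elsewhere],
            [self.background_promoter, self.background_elsewhere],
        ]


def _promoter_interval(gene: GeneFeature, promoter_bp: int) -> tuple[int, int]:
    """Half-open interval of positions strictly < promoter_bp upstream of the
    start codon (distance >= 1, so the interval excludes the codon itself)."""
    if gene.strand == "+":
        # distance = gene.start - p in [1, promoter_bp - 1]
        return gene.start - (promoter_bp - 1), gene.start
    # minus strand: start codon first base at end - 1; upstream is rightward
    # distance = p - (end - 1) in [1, promoter_bp - 1]
    return gene.end, gene.end + (promoter_bp - 1)


def classify_location(
    occurrences: pd.DataFrame,
    genes: Sequence[GeneFeature],
    promoter_bp: int = 200,
) -> pd.DataFrame:
    """Assign a location class to each occurrence's methylated position.

    Returns the occurrence table with location, nearest_gene and
    distance_to_start columns (distance only for promoter-class sites, to the
    nearest qualifying start codon).
    """
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = _promoter_interval(g, promoter_bp)
        lo = max(lo, 0)
        if hi > lo:
            prom_trees.setdefault(g.contig, IntervalTree()).addi(lo, hi, g)
        body_trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)

    out = occurrences.copy()
    loc = np.empty(len(out), dtype=object)
    nearest = np.empty(len(out), dtype=object)
    dist = np.full(len(out), np.nan)
    for i, (contig, pos) in enumerate(
        zip(out["contig"], out["methylated_position"])
    ):
        pos = int(pos)
        hits = prom_trees.get(contig, IntervalTree())[pos]
        if hits:
            best_gene, best_d = None, None
            for iv in hits:
                g = iv.data
                d = g.start - pos if g.strand == "+" else pos - (g.end - 1)
                if best_d is None or d < best_d:
                    best_gene, best_d = g, d
            loc[i] = "promoter"
            nearest[i] = best_gene.gene_id
            dist[i] = best_d
        else:
            body = body_trees.get(contig, IntervalTree())[pos]
            if body:
                loc[i] = "gene_body"
                nearest[i] = min(body, key=lambda iv: iv.begin).data.gene_id
            else:
                loc[i] = "intergenic"
                nearest[i] = None
    out["location"] = loc
    out["nearest_gene"] = nearest
    out["distance_to_start"] = dist
    return out


def location_fractions(classified: pd.DataFrame) -> pd.Series:
    """Proportions over (promoter, gene_body, intergenic); sums to 1."""
    if classified.empty:
        raise ValueError("empty occurrence subset")
    counts = classified["location"].value_counts()
    total = len(classified)
    return pd.Series(
        {cls: counts.get(cls, 0) / total for cls in LOCATION_CLASSES},
        name="fraction",
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The p-value sums exact hypergeometric probabilities (at fixed margins) of
    every table at most as probable as the observed one. Returns
    (p_two_sided, odds_ratio); odds ratio is the sample cross-product ratio
    (inf/nan on zero cells follow the usual convention).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p), float(odds)


def promoter_enrichment(
    subset: pd.DataFrame, background: pd.DataFrame
) -> EnrichmentResult:
    """Fisher test of promoter membership: subset vs all occurrences of the
    motif (the background includes the subset, mirroring an 'all sites'
    reference row)."""
    if subset.empty:
        raise ValueError("empty subset")
    sp = int((subset["location"] == "promoter").sum())
    se = len(subset) - sp
    bp_ = int((background["location"] == "promoter").sum())
    be = len(background) - bp_
    p, odds = fisher_exact_2x2([[sp, se], [bp_, be]])
    return EnrichmentResult(sp, se, bp_, be, odds, p)


def enrichment_table(
    classes: pd.DataFrame,
    classified_all: pd.DataFrame,
    target_class: str = "conserved_unmethylated",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-motif promoter-enrichment of one cross-condition class vs all
    occurrences of that motif. Optional Benjamini-Hochberg column."""
    merged = classes.merge(
        classified_all[
            ["motif", "contig", "methylated_position", "methylated_strand",
             "location"]
        ],
        on=["motif", "contig", "methylated_position", "methylated_strand"],
        how="left",
    )
    rows = []
    for motif, grp in merged.groupby("motif", sort=True):
        sub = grp[grp["class"] == target_class]
        if sub.empty:
            continue
        res = promoter_enrichment(sub, grp)
        rows.append(
            {
                "motif": motif,
                "subset_promoter": res.subset_promoter,
                "subset_elsewhere": res.subset_elsewhere,
                "background_promoter": res.background_promoter,
                "background_elsewhere": res.background_elsewhere,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        out["p_bh"] = adj
    return out
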