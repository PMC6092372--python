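"""Bisulfite (WGBS) methylation calling from per-cytosine count reports.

Bisulfite conversion leaves 5-methylcytosine unconverted, so the proportion of
reads retaining a C at a cytosine position estimates its methylation level.
A cytosine is called methylated when its coverage reaches 25x or more and at
least 90% of covering reads are unconverted; both thresholds are inclusive and
the fraction test uses exact rational arithmetic so the 90% boundary is
bit-stable. The +/-20 nt strand-oriented context around each called cytosine
can be exported as FASTA for downstream motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Genome, reverse_complement

REPORT_COLUMNS = [
    "contig", "position", "strand", "count_methylated", "count_unmethylated",
]


@dataclass(frozen=True)
class CytosineCount:
    """Read counts at one cytosine (position is 0-based on the plus strand;
    strand says which strand carries the C)."""

    contig: str
    position: int
    strand: str
    n_methylated: int
    n_total: int
    condition: str = ""

    def __post_init__(self):
        if not 0 <= self.n_methylated <= self.n_total:
            raise ValueError("require 0 <= n_methylated <= n_total")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_cytosine_report(
    path: str | Path, condition: str = ""
) -> list[CytosineCount]:
    """Read a Bismark-style cytosine report TSV.

    Columns: contig, 1-based position, strand, count_methylated,
    count_unmethylated (extra columns such as context are ignored).
    Zero-coverage rows are retained with n_total = 0.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if df.shape[1] < 5:
        raise ValueError(f"cytosine report {path} needs >= 5 columns")
    df = df.iloc[:, :5]
    df.columns = REPORT_COLUMNS
    counts = []
    for row in df.itertuples(index=False):
        meth = int(row.count_methylated)
        unmeth = int(row.count_unmethylated)
        if meth < 0 or unmeth < 0:
            raise ValueError(f"negative counts at {row.contig}:{row.position}")
        counts.append(
            CytosineCount(
                contig=str(row.contig),
                position=int(row.position) - 1,
                strand=str(row.strand),
                n_methylated=meth,
                n_total=meth + unmeth,
                condition=condition,
            )
        )
    return counts


def write_cytosine_report(
    counts: Sequence[CytosineCount], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c in counts:
            fh.write(
                f"{c.contig}\t{c.position + 1}\t{c.strand}\t"
                f"{c.n_methylated}\t{c.n_total - c.n_methylated}\n"
            )


def meets_thresholds(
    count: CytosineCount, min_cov: int = 25, min_frac: float = 0.90
) -> bool:
    """Inclusive coverage and methylated-fraction thresholds.

    The fraction comparison is exact: n_methylated/n_total >= min_frac is
    evaluated with rational arithmetic (min_frac read as a decimal literal),
    so e.g. 9/10 meets 0.90 exactly.
    """
    if count.n_total < min_cov:
        return False
    return Fraction(count.n_methylated, count.n_total) >= Fraction(repr(float(min_frac)))


def call_methylated(
    counts: Sequence[CytosineCount],
    min_cov: int = 25,
    min_frac: float = 0.90,
) -> pd.DataFrame:
    """Call methylated cytosines: coverage >= min_cov and fraction >= min_frac.

    Returns a DataFrame (contig, position, strand, n_methylated, n_total,
    fraction_modified, condition) of called sites in input order.
    """
    if min_cov < 1 or not 0 < min_frac <= 1:
        raise ValueError("thresholds out of range")
    rows = [
        {
            "contig": c.contig,
            "position": c.position,
            "strand": c.strand,
            "n_methylated": c.n_methylated,
            "n_total": c.n_total,
            "fraction_modified": c.n_methylated / c.n_total,
            "condition": c.condition,
        }
        for c in counts
        if meets_thresholds(c, min_cov, min_frac)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "position", "strand", "n_methylated", "n_total",
            "fraction_modified", "condition",
        ],
    )


def extract_context(
    genome: Genome, contig: str, position: int, strand: str, flank: int = 20
) -> str:
    """The +/-*flank* nt sequence window centred on a cytosine, strand-oriented.

    Minus-strand sites return the reverse complement of the plus-strand
    window; windows running off a contig edge are padded with N so every
    context has length 2*flank + 1.
    """
    seq = genome[contig]
    if not 0 <= position < len(seq):
        raise ValueError(f"position {position} outside contig {contig!r}")
    lo = position - flank
    hi = position + flank + 1
    window = seq[max(lo, 0):min(hi, len(seq))]
    window = "N" * max(0, -lo) + window + "N" * max(0, hi - len(seq))
    if strand == "-":
        window = reverse_complement(window)
    return window


def write_context_fasta(
    genome: Genome, called: pd.DataFrame, path: str | Path, flank: int = 20
) -> None:
    """Write called-site contexts as FASTA with contig:pos:strand headers."""
    with open(path, "w") as fh:
        for row in called.itertuples(index=False):
            ctx = extract_context(genome, row.contig, row.position, row.strand, flank)
            fh.write(f">{row.contig}:{row.position}:{row.strand}\n{ctx}\n")


def assign_m5c(
    occurrences: pd.DataFrame, called: pd.DataFrame, condition: str = ""
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match called cytosines to m5C motif occurrences.

    An occurrence is detected iff a called cytosine sits exactly at its
    (contig, methylated_position, methylated_strand). Returns the status table
    (same layout as the SMRT one, with coverage and fraction_modified from the
    matching site) and a per-motif summary (n_total, n_detected, fraction,
    mean_coverage, mean_fraction_modified over detected occurrences).
    """
    index: dict[tuple, tuple] = {}
    for row in called.itertuples(index=False):
        key = (row.contig, row.position, row.strand)
        prev = index.get(key)
        if prev is None or row.n_total > prev[0]:
            index[key] = (row.n_total, row.fraction_modified)
    status = occurrences.copy()
    n = len(status)
    detected = np.zeros(n, dtype=bool)
    cov = np.full(n, np.nan)
    frac_mod = np.full(n, np.nan)
    for i, key in enumerate(
        zip(status["contig"], status["methylated_position"],
            status["methylated_strand"])
    ):
        hit = index.get(key)
        if hit is not None:
            detected[i] = True
            cov[i], frac_mod[i] = hit
    status["condition"] = condition or (
        called["condition"].iloc[0] if len(called) else ""
    )
    status["detected"] = detected
    status["qv"] = np.nan
    status["ipd_ratio"] = np.nan
    status["coverage"] = cov
    status["fraction_modified"] = frac_mod
    rows = []
    for (motif, cond), grp in status.groupby(["motif", "condition"], sort=True):
        det = grp[grp["detected"]]
        rows.append(
            {
                "motif": motif,
                "condition": cond,
                "n_total": len(grp),
                "n_detected": len(det),
                "fraction": len(det) / len(grp) if len(grp) else np.nan,
                "mean_coverage": det["coverage"].mean() if len(det) else np.nan,
                "mean_fraction_modified": (
                    det["fraction_modified"].mean() if len(det) else np.nan
                ),
            }
        )
    return status, pd.DataFrame(rows)
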