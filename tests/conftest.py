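"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation's code paths: motif
matching is position-by-position set membership, call assignment is a nested
cross-join, location classification loops over every gene, window counting
recounts each window, and the Fisher p-value is an exhaustive enumeration of
margin-fixed tables in exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from bacmeth.genome import IUPAC_CODES
from bacmeth.pipeline import analyze
from bacmeth.simulate import SimulationConfig, simulate


# --------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def dataset():
    """One default-condition synthetic dataset shared across the suite."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def analysis(dataset):
    """The full pipeline run over the shared dataset."""
    return analyze(dataset)


# ---------------------------------------------------------------- oracles
def oracle_match(seq: str, iupac: str, pos: int) -> bool:
    """Does the window at pos match the IUPAC pattern? (genomic N matches
    only the motif code N)."""
    if pos + len(iupac) > len(seq):
        return False
    for offset, code in enumerate(iupac.upper()):
        allowed = IUPAC_CODES[code] + ("N" if code == "N" else "")
        if seq[pos + offset] not in allowed:
            return False
    return True


def oracle_scan(seq: str, iupac: str) -> list[int]:
    """All plus-strand match starts, by checking every position."""
    return [p for p in range(len(seq)) if oracle_match(seq, iupac, p)]


def oracle_assign(occurrences: pd.DataFrame, calls) -> np.ndarray:
    """Detected flags by cross-joining every occurrence with every call."""
    detected = np.zeros(len(occurrences), dtype=bool)
    for i, row in enumerate(occurrences.itertuples(index=False)):
        for call in calls:
            if (
                call.contig == row.contig
                and call.position == row.methylated_position
                and call.strand == row.methylated_strand
                and (
                    call.mod_type == "unknown"
                    or (row.methylated_base == "A" and call.mod_type == "m6A")
                    or (row.methylated_base == "C" and call.mod_type in ("m4C", "m5C"))
                )
            ):
                detected[i] = True
    return detected


def oracle_location(pos: int, contig: str, genes, promoter_bp: int = 200) -> str:
    """Location class by scanning every gene."""
    promoter = False
    body = False
    for g in genes:
        if g.contig != contig:
            continue
        if g.start <= pos < g.end:
            body = True
        if g.strand == "+":
            d = g.start - pos
        else:
            d = pos - (g.end - 1)
        if 0 < d < promoter_bp:
            promoter = True
    if promoter:
        return "promoter"
    if body:
        return "gene_body"
    return "intergenic"


def oracle_window_counts(starts, win_start: int, size: int) -> int:
    return sum(win_start <= s < win_start + size for s in starts)


def oracle_fisher(table) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration of margin-fixed tables
    (sum exact hypergeometric probabilities <= observed, with the standard
    1e-7 relative slack on the comparison)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    eps = Fraction(1, 10**7)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + eps):
            total += p
    return total


def random_2x2(rng: np.random.Generator, max_n: int = 60):
    """A random non-degenerate 2x2 table with total <= max_n."""
    while True:
        t = rng.integers(0, max_n // 3 + 1, size=(2, 2))
        if t.sum() == 0 or t.sum() > max_n:
            continue
        return t.tolist()
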