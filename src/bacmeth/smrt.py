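"""SMRT base-modification call handling and per-motif summaries.

SMRT sequencing detects m6A and m4C marks through polymerase-kinetics
deviations; the upstream caller assigns each candidate position a modification
QV (-10*log10 of the detection p-value, so QV 30 corresponds to p = 0.001), an
IPD ratio and a read coverage. This module consumes such calls, applies the
QV >= 30 filter, assigns qualifying calls to motif occurrences by exact
(contig, position, strand) match with a compatible base class, and produces
per-motif x per-condition summary tables (fraction detected, mean score, mean
IPD ratio, mean coverage over detected occurrences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import Genome

DIALECTS = ("modifications-gff3", "tsv")

TSV_COLUMNS = [
    "contig", "position", "strand", "mod_type", "qv", "ipd_ratio",
    "coverage", "condition",
]


@dataclass(frozen=True)
class ModificationCall:
    """One strand-specific base-modification record from kinetic detection."""

    contig: str
    position: int  # 0-based
    strand: str
    mod_type: str  # m6A / m4C / unknown
    qv: float
    ipd_ratio: float
    coverage: int
    condition: str = ""

    def __post_init__(self):
        if self.qv < 0:
            raise ValueError("modification QV must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_modifications(
    path: str | Path,
    dialect: str = "modifications-gff3",
    condition: str | None = None,
    genome: Genome | None = None,
) -> list[ModificationCall]:
    """Parse base-modification calls.

    ``modifications-gff3``: PacBio-style GFF3 whose type column is m6A / m4C /
    modified_base, column 6 holds the QV, and attributes carry IPDRatio and
    coverage; coordinates are 1-based and converted here. ``tsv``: the
    package's own 0-based tab dialect (see :func:`write_modifications`).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    calls: list[ModificationCall] = []
    if dialect == "modifications-gff3":
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF columns")
            seqid, _src, ftype, start, _end, score, strand, _phase, attrs = fields
            mod_type = ftype if ftype in ("m6A", "m4C") else "unknown"
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            calls.append(
                ModificationCall(
                    contig=seqid,
                    position=int(start) - 1,
                    strand=strand,
                    mod_type=mod_type,
                    qv=float(score),
                    ipd_ratio=float(attr.get("IPDRatio", "nan")),
                    coverage=int(attr.get("coverage", 0)),
                    condition=condition or "",
                )
            )
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = set(TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"TSV missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            calls.append(
                ModificationCall(
                    contig=str(row.contig),
                    position=int(row.position),
                    strand=str(row.strand),
                    mod_type=str(row.mod_type),
                    qv=float(row.qv),
                    ipd_ratio=float(row.ipd_ratio),
                    coverage=int(row.coverage),
                    condition=condition or str(row.condition),
                )
            )
    if genome is not None:
        for c in calls:
            if c.contig not in genome:
                raise ValueError(f"call on unknown contig {c.contig!r}")
            if not 0 <= c.position < len(genome[c.contig]):
                raise ValueError(
                    f"call position {c.position} outside contig {c.contig!r}"
                )
    return calls


def write_modifications(
    calls: Iterable[ModificationCall], path: str | Path,
    dialect: str = "modifications-gff3",
) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    if dialect == "modifications-gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in calls:
                ftype = c.mod_type if c.mod_type in ("m6A", "m4C") else "modified_base"
                ipd = "" if math.isnan(c.ipd_ratio) else f"{c.ipd_ratio:g}"
                fh.write(
                    f"{c.contig}\tkinModCall\t{ftype}\t{c.position + 1}\t"
                    f"{c.position + 1}\t{c.qv:g}\t{c.strand}\t.\t"
                    f"IPDRatio={ipd};coverage={c.coverage}\n"
                )
    else:
        df = pd.DataFrame([c.__dict__ for c in calls], columns=TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False)


def filter_calls(
    calls: Sequence[ModificationCall], min_qv: float = 30.0
) -> list[ModificationCall]:
    """Keep calls with QV >= min_qv (inclusive threshold); order preserved."""
    if min_qv < 0:
        raise ValueError("min_qv must be >= 0")
    return [c for c in calls if c.qv >= min_qv]


def dedupe_calls(calls: Sequence[ModificationCall]) -> dict[tuple, ModificationCall]:
    """Index calls by (contig, position, strand), keeping the highest QV at ties."""
    best: dict[tuple, ModificationCall] = {}
    for c in calls:
        key = (c.contig, c.position, c.strand)
        if key not in best or c.qv > best[key].qv:
            best[key] = c
    return best


def _compatible(motif_base: str, mod_type: str) -> bool:
    # unknown (generic modified_base) is compatible with either base class
    if mod_type == "unknown":
        return True
    return (motif_base == "A" and mod_type == "m6A") or (
        motif_base == "C" and mod_type in ("m4C", "m5C")
    )


def assign_calls(
    occurrences: pd.DataFrame,
    calls: Sequence[ModificationCall],
    condition: str = "",
) -> tuple[pd.DataFrame, list[ModificationCall]]:
    """Match calls to motif occurrences at the methylated base.

    An occurrence is *detected* iff some call sits exactly at its
    (contig, methylated_position, methylated_strand) with a compatible
    modification class. Returns the per-occurrence status table and the list
    of off-motif calls (those that matched no occurrence).

    Status columns: all occurrence columns plus condition, detected, qv,
    ipd_ratio, coverage (NaN where undetected).
    """
    best = dedupe_calls(calls)
    used: set[tuple] = set()
    status = occurrences.copy()
    n = len(status)
    detected = np.zeros(n, dtype=bool)
    qv = np.full(n, np.nan)
    ipd = np.full(n, np.nan)
    cov = np.full(n, np.nan)
    bases = status["methylated_base"].to_numpy()
    keys = list(
        zip(status["contig"], status["methylated_position"],
            status["methylated_strand"])
    )
    for i, key in enumerate(keys):
        call = best.get(key)
        if call is not None and _compatible(bases[i], call.mod_type):
            detected[i] = True
            qv[i] = call.qv
            ipd[i] = call.ipd_ratio
            cov[i] = call.coverage
            used.add(key)
    status["condition"] = condition or (
        calls[0].condition if calls else ""
    )
    status["detected"] = detected
    status["qv"] = qv
    status["ipd_ratio"] = ipd
    status["coverage"] = cov
    off_motif = [c for k, c in best.items() if k not in used]
    return status, off_motif


def summarize(statuses: pd.DataFrame) -> pd.DataFrame:
    """Per-motif x per-condition summary over occurrence statuses.

    fraction = n_detected / n_total; the means are over detected occurrences
    only. Empty groups yield n_total=0 with NaN fraction/means.
    """
    rows = []
    for (motif, condition), grp in statuses.groupby(
        ["motif", "condition"], sort=True
    ):
        det = grp[grp["detected"]]
        n_total = len(grp)
        rows.append(
            {
                "motif": motif,
                "condition": condition,
                "n_total": n_total,
                "n_detected": len(det),
                "fraction": len(det) / n_total if n_total else np.nan,
                "mean_score": det["qv"].mean() if len(det) else np.nan,
                "mean_ipd_ratio": det["ipd_ratio"].mean() if len(det) else np.nan,
                "mean_coverage": det["coverage"].mean() if len(det) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.0005 -> 0.001), as used in report tables."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Report-layer rounding: fractions to 3 decimals, means to 1 (half-up)."""
    out = summary.copy()
    out["fraction"] = out["fraction"].map(lambda v: round_half_up(v, 3))
    for col in ("mean_score", "mean_ipd_ratio", "mean_coverage"):
        out[col] = out[col].map(lambda v: round_half_up(v, 1))
    return out
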