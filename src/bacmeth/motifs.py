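"""IUPAC degenerate motif definitions and genome scanning.

The built-in registry holds the eight methylation motifs of the P. luminescens
TT01 methylome: the Dam target GATC (m6A), the Dcm target CCWGG (m5C), the
PluTI target GGCGCC (m5C), the bipartite Type I pair GGANNNNNNRTGA /
TCAYNNNNNNTCC (m6A, partners), plus TGGCCA (m6A), AGGCCT (m4C) and CTCGAG
(m6A). Each motif records the 0-based offset of the methylatable base within
the motif string and the modification type carried there.

Scanning reports plus-strand matches of the motif string only; the bipartite
partners are scanned as two separate motifs, so a fully-methylated duplex site
contributes one occurrence per motif string. Overlapping matches are all
reported. A genomic N matches only the motif code N.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .genome import IUPAC_CODES, Genome

MOD_TYPES = ("m6A", "m4C", "m5C")


@dataclass(frozen=True)
class MotifSpec:
    """A named methylation motif: IUPAC string, methylated-base offset, mark type."""

    name: str
    iupac: str
    methylated_offset: int
    mod_type: str
    partner_name: str | None = None

    def __post_init__(self):
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"mod_type must be one of {MOD_TYPES}")
        if not 0 <= self.methylated_offset < len(self.iupac):
            raise ValueError("methylated_offset outside motif")
        base = self.iupac[self.methylated_offset].upper()
        expected = "A" if self.mod_type == "m6A" else "C"
        if base != expected:
            raise ValueError(
                f"motif {self.name!r}: base {base!r} at offset "
                f"{self.methylated_offset} incompatible with {self.mod_type}"
            )
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"illegal IUPAC codes in motif: {sorted(bad)}")

    @property
    def methylated_base(self) -> str:
        return self.iupac[self.methylated_offset].upper()


#: The eight motifs of the TT01 methylome (SMRT motifs I-V, WGBS motifs VI-VII).
BUILTIN_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec("motif I", "GATC", 1, "m6A"),
    MotifSpec("motif II", "TGGCCA", 5, "m6A"),
    MotifSpec("motif IIIa", "GGANNNNNNRTGA", 2, "m6A", partner_name="motif IIIb"),
    MotifSpec("motif IIIb", "TCAYNNNNNNTCC", 2, "m6A", partner_name="motif IIIa"),
    MotifSpec("motif IV", "AGGCCT", 4, "m4C"),
    MotifSpec("motif V", "CTCGAG", 4, "m6A"),
    MotifSpec("motif VI", "CCWGG", 1, "m5C"),
    MotifSpec("motif VII", "GGCGCC", 2, "m5C"),
)

#: SMRT-detectable (m6A/m4C) and bisulfite-detectable (m5C) subsets.
SMRT_MOTIFS = tuple(m for m in BUILTIN_MOTIFS if m.mod_type in ("m6A", "m4C"))
WGBS_MOTIFS = tuple(m for m in BUILTIN_MOTIFS if m.mod_type == "m5C")


class MotifOccurrence(NamedTuple):
    """One plus-strand match of a motif string in the genome."""

    motif: str
    contig: str
    start: int  # 0-based match start
    strand: str  # strand of the match (always "+")
    methylated_position: int  # 0-based genomic position of the methylatable base
    methylated_strand: str  # strand carrying the mark (= match strand)


def compile_iupac(iupac: str) -> re.Pattern:
    """Compile an IUPAC string into a regex matching one window of equal length.

    Genomic N matches only the motif code N (no phantom hits in gap runs).
    """
    if not iupac:
        raise ValueError("empty motif string")
    parts = []
    for code in iupac.upper():
        if code not in IUPAC_CODES:
            raise ValueError(f"illegal IUPAC code {code!r}")
        bases = IUPAC_CODES[code]
        if code == "N":
            bases += "N"
        parts.append(f"[{bases}]" if len(bases) > 1 else bases)
    return re.compile("".join(parts))


def scan_motif(genome: Genome, spec: MotifSpec) -> list[MotifOccurrence]:
    """All plus-strand occurrences of a motif, overlapping matches included.

    Results are sorted by (contig order, position) and are deterministic.
    """
    window = compile_iupac(spec.iupac)
    finder = re.compile(f"(?=({window.pattern}))")  # lookahead => overlaps allowed
    out: list[MotifOccurrence] = []
    for contig, seq in genome.items():
        for m in finder.finditer(seq):
            start = m.start()
            out.append(
                MotifOccurrence(
                    motif=spec.name,
                    contig=contig,
                    start=start,
                    strand="+",
                    methylated_position=start + spec.methylated_offset,
                    methylated_strand="+",
                )
            )
    return out


def scan_all(
    genome: Genome, registry: Sequence[MotifSpec] = BUILTIN_MOTIFS
) -> pd.DataFrame:
    """Scan every motif in the registry; one row per occurrence.

    Columns: motif, contig, start, strand, methylated_position,
    methylated_strand, mod_type, methylated_base.
    """
    frames = []
    for spec in registry:
        occ = scan_motif(genome, spec)
        df = pd.DataFrame(occ, columns=MotifOccurrence._fields)
        df["mod_type"] = spec.mod_type
        df["methylated_base"] = spec.methylated_base
        frames.append(df)
    if not frames:
        raise ValueError("empty motif registry")
    return pd.concat(frames, ignore_index=True)


def count_all_motifs(
    genome: Genome, registry: Sequence[MotifSpec] = BUILTIN_MOTIFS
) -> pd.DataFrame:
    """Per-motif plus-strand occurrence counts (one row per motif)."""
    if not registry:
        raise ValueError("empty motif registry")
    rows = [
        {"motif": spec.name, "iupac": spec.iupac,
         "count": len(scan_motif(genome, spec))}
        for spec in registry
    ]
    return pd.DataFrame(rows)


def read_motif_registry(path: str | Path) -> tuple[MotifSpec, ...]:
    """Read a plain-text motif registry: name<TAB>iupac<TAB>offset<TAB>mod_type
    [<TAB>partner] per line; '#' starts a comment."""
    specs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"malformed motif line: {line!r}")
        name, iupac, offset, mod_type = fields[:4]
        partner = fields[4] if len(fields) > 4 and fields[4] else None
        specs.append(MotifSpec(name, iupac, int(offset), mod_type, partner))
    if not specs:
        raise ValueError(f"no motifs found in {path}")
    return tuple(specs)


def write_motif_registry(specs: Iterable[MotifSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tiupac\toffset\tmod_type\tpartner\n")
        for s in specs:
            fh.write(
                f"{s.name}\t{s.iupac}\t{s.methylated_offset}\t{s.mod_type}\t"
                f"{s.partner_name or ''}\n"
            )


def occurrences_to_bed(occurrences: pd.DataFrame, path: str | Path,
                       registry: Sequence[MotifSpec] = BUILTIN_MOTIFS) -> None:
    """Write occurrences as BED6 (0-based half-open; name=motif, score=0)."""
    lengths = {s.name: len(s.iupac) for s in registry}
    with open(path, "w") as fh:
        for row in occurrences.itertuples(index=False):
            end = row.start + lengths.get(row.motif, 1)
            fh.write(
                f"{row.contig}\t{row.start}\t{end}\t{row.motif}\t0\t{row.strand}\n"
            )
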