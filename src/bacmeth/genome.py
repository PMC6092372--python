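"""Genome sequence and annotation handling with fixed coordinate conventions.

All internal coordinates are 0-based half-open on the plus strand. GFF3 I/O
converts at the boundary (GFF3 is 1-based inclusive); BED output downstream is
0-based half-open natively. Circular chromosomes are treated as linear: no
wrap-around motif matches are reported.
"""

from __future__ import annotations

import tempfile
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
#: IUPAC degenerate nucleotide codes and the bases each one stands for.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

NCBI_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={accession}&rettype=fasta&retmode=text"
)


class Genome:
    """An ordered collection of uppercase DNA contigs (alphabet A/C/G/T/N)."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        clean: dict[str, str] = {}
        for cid, seq in contigs.items():
            if cid in clean:
                raise ValueError(f"duplicate contig id: {cid!r}")
            seq = str(seq).upper()
            if not seq:
                raise ValueError(f"contig {cid!r} has an empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains non-DNA characters: {sorted(bad)}"
                )
            clean[cid] = seq
        self._contigs = clean

    @property
    def contigs(self) -> dict[str, str]:
        return dict(self._contigs)

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self._contigs.items()}

    def __getitem__(self, contig: str) -> str:
        return self._contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def items(self):
        return self._contigs.items()

    def __len__(self) -> int:
        return len(self._contigs)

    def __repr__(self) -> str:
        parts = ", ".join(f"{c}:{len(s)}bp" for c, s in self._contigs.items())
        return f"Genome({parts})"


@dataclass(frozen=True)
class GeneFeature:
    """A gene/CDS feature in 0-based half-open coordinates on the plus strand."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Sequences are uppercased; RNA (U) and any other non-ACGTN characters are
    rejected. Record order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA record id: {rec.id!r}")
        contigs[rec.id] = str(rec.seq)
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gff(
    path: str | Path,
    genome: Genome,
    feature_types: Iterable[str] = ("gene", "CDS"),
) -> list[GeneFeature]:
    """Read gene features from a GFF3 file, converting to 0-based half-open.

    Only rows whose type is in *feature_types* are kept. Features on contigs
    absent from *genome*, or extending beyond contig bounds, raise ValueError.
    """
    wanted = set(feature_types)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features: list[GeneFeature] = []
    seen_ids: set[str] = set()
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in wanted:
            continue
        if feat.seqid not in genome:
            raise ValueError(f"feature {feat.id!r} on unknown contig {feat.seqid!r}")
        start0 = feat.start - 1  # GFF3 is 1-based inclusive
        end0 = feat.end
        if end0 < feat.start:
            raise ValueError(f"feature {feat.id!r} has end < start")
        if start0 < 0 or end0 > len(genome[feat.seqid]):
            raise ValueError(f"feature {feat.id!r} outside contig bounds")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen_ids:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen_ids.add(gene_id)
        features.append(
            GeneFeature(
                contig=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                gene_id=gene_id,
            )
        )
    return features


def write_gff(features: Iterable[GeneFeature], path: str | Path,
              feature_type: str = "gene") -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\tbacmeth\t{feature_type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.gene_id}\n"
            )


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, W<->W, N<->N, ...)."""
    seq = seq.upper()
    bad = set(seq) - set(IUPAC_CODES) - {"N"}
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def fetch_reference_genome(
    accession: str,
    dest: str | Path | None = None,
    timeout: float = 30.0,
) -> Genome:
    """Download a genome from NCBI nucleotide by accession (FASTA via efetch).

    If *dest* is given and already exists, it is read instead of downloading;
    a fresh download is cached there. Requires network access otherwise.
    """
    if dest is not None:
        dest = Path(dest)
        if dest.exists() and dest.stat().st_size > 0:
            return read_fasta(dest)
    url = NCBI_EFETCH.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    if dest is None:
        with tempfile.NamedTemporaryFile("wb", suffix=".fa", delete=False) as tmp:
            tmp.write(data)
            dest = Path(tmp.name)
    else:
        dest.write_bytes(data)
    return read_fasta(dest)
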