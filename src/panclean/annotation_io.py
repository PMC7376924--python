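"""Reading and writing Prokka-style annotated assemblies.

Prokka emits GFF3 files that carry the CDS feature table followed by a
``##FASTA`` section holding the contig sequences.  This module parses that
dialect into :class:`GeneRecord`/:class:`ContigSeq` objects and owns every
coordinate and strand convention used by the rest of the package.

Conventions
-----------
* GFF3 is 1-based inclusive on disk; in memory everything is 0-based
  half-open.  The conversion happens here and nowhere else.
* ``dna_seq`` is always the coding strand read 5'->3' (minus-strand genes are
  reverse complemented at parse time).
* Gene identifiers are prefixed with the genome identifier (``genome|id``)
  because Prokka locus tags are only unique within one file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "GeneRecord",
    "ContigSeq",
    "parse_gff3",
    "write_gff3",
    "translate",
    "reverse_complement",
]

_ID_SEP = "|"


@dataclass
class GeneRecord:
    """One annotated CDS.

    ``start``/``end`` are 0-based half-open positions on the contig;
    ``dna_seq`` is strand-corrected so that it always starts with the start
    codon regardless of ``strand``.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    dna_seq: str
    prot_seq: str
    annotation: str = ""
    position_index: int = 0
    pseudo: bool = False      # CDS length not divisible by 3
    partial: bool = False     # truncated at a contig edge
    refound: bool = False     # added from sequence search, not annotation

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def local_id(self) -> str:
        """The identifier as written in the GFF3 file (genome prefix removed)."""
        return self.gene_id.split(_ID_SEP, 1)[-1]


@dataclass
class ContigSeq:
    genome_id: str
    contig_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


_COMPLEMENT = str.maketrans("ACGTMRWSYKVHDBNacgtmrwsykvhdbn",
                            "TGCAKYWSRMBDHVNtgcakywsrmbdhvn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a coding sequence with the bacterial table (11).

    Internal stop codons are retained as ``*`` (the mistranslation stage uses
    them as a signal); a terminal stop is trimmed.  Codons containing
    ambiguous bases translate to ``X``.  Trailing bases that do not fill a
    codon are ignored.
    """
    if len(dna) < 3:
        raise ValueError("cannot translate a sequence shorter than one codon")
    trimmed = dna[: (len(dna) // 3) * 3]
    aa = str(Seq(trimmed).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_gff3(
    path: str | Path,
    genome_id: str | None = None,
    feature_types: tuple[str, ...] = ("CDS",),
) -> tuple[list[GeneRecord], list[ContigSeq]]:
    """Parse a Prokka-dialect GFF3 file (feature table + ``##FASTA``).

    Returns records ordered by contig then start, with ``position_index``
    numbering genes 0,1,2,... along each contig.  Non-CDS features are ignored
    unless listed in *feature_types*.
    """
    path = Path(path)
    genome_id = genome_id or path.stem
    text = path.read_text()
    if "##FASTA" not in text:
        raise ValueError(f"{path}: no ##FASTA section; contig sequences are required")
    feature_text, _, fasta_text = text.partition("##FASTA")

    contigs: dict[str, ContigSeq] = {}
    for rec in SeqIO.parse(io.StringIO(fasta_text.lstrip("\n")), "fasta"):
        contigs[rec.id] = ContigSeq(genome_id, rec.id, str(rec.seq).upper())

    records: list[GeneRecord] = []
    for line in feature_text.splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            continue
        seqid, _source, ftype, start1, end1, _score, strand, _phase, attr_field = fields
        if ftype not in feature_types:
            continue
        attrs = _parse_attributes(attr_field)
        raw_id = attrs.get("ID") or attrs.get("locus_tag")
        if raw_id is None:
            raise ValueError(f"{path}: {ftype} feature without ID attribute: {line!r}")
        if seqid not in contigs:
            raise ValueError(f"{path}: feature {raw_id} references unknown contig {seqid}")
        start = int(start1) - 1  # GFF3 is 1-based inclusive
        end = int(end1)
        contig = contigs[seqid]
        if start < 0 or end > len(contig):
            raise ValueError(
                f"{path}: feature {raw_id} coordinates [{start1},{end1}] fall outside "
                f"contig {seqid} (length {len(contig)})"
            )
        sub = contig.sequence[start:end]
        dna = reverse_complement(sub) if strand == "-" else sub
        pseudo = (len(dna) % 3) != 0 or attrs.get("pseudo", "").lower() == "true"
        partial = attrs.get("partial", "").lower() == "true"
        prot = translate(dna) if len(dna) >= 3 else ""
        records.append(
            GeneRecord(
                gene_id=f"{genome_id}{_ID_SEP}{raw_id}",
                genome_id=genome_id,
                contig_id=seqid,
                start=start,
                end=end,
                strand=strand,
                dna_seq=dna,
                prot_seq=prot,
                annotation=attrs.get("product", ""),
                pseudo=pseudo,
                partial=partial,
            )
        )

    records.sort(key=lambda r: (r.contig_id, r.start, r.end))
    counters: dict[str, int] = {}
    for rec in records:
        rec.position_index = counters.get(rec.contig_id, 0)
        counters[rec.contig_id] = rec.position_index + 1
    return records, list(contigs.values())


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_gff3(
    records: Iterable[GeneRecord],
    contigs: Iterable[ContigSeq],
    path: str | Path,
) -> None:
    """Write records + contigs back to a Prokka-dialect GFF3 file.

    Inverse of :func:`parse_gff3` for the fields this package uses: CDS
    coordinates, strands, sequences and product strings round-trip exactly.
    """
    path = Path(path)
    contigs = list(contigs)
    recs = sorted(records, key=lambda r: (r.contig_id, r.start, r.end))
    lines = ["##gff-version 3"]
    for c in contigs:
        lines.append(f"##sequence-region {c.contig_id} 1 {len(c)}")
    for r in recs:
        attrs = [f"ID={r.local_id}"]
        if r.annotation:
            attrs.append(f"product={r.annotation}")
        if r.pseudo:
            attrs.append("pseudo=true")
        if r.partial:
            attrs.append("partial=true")
        lines.append(
            "\t".join(
                [
                    r.contig_id,
                    "panclean",
                    "CDS",
                    str(r.start + 1),
                    str(r.end),
                    ".",
                    r.strand,
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    lines.append("##FASTA")
    for c in contigs:
        lines.append(f">{c.contig_id}")
        lines.append(_wrap(c.sequence))
    path.write_text("\n".join(lines) + "\n")
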