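"""Shared domain types and I/O for the cathelicidin mining pipeline.

Coordinate convention: all nucleotide intervals are 0-based, half-open and
always refer to the *forward* strand of the source record, with an explicit
strand flag. Conversion to 1-based inclusive coordinates happens only at the
GFF3 boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codon -> amino acid, stops as '*'; built once from the standard table
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


class Alphabet(str, Enum):
    dna = "dna"
    protein = "protein"


class GeneStatus(str, Enum):
    complete = "complete"
    incomplete = "incomplete"
    nonfunctional = "nonfunctional"


class DefectKind(str, Enum):
    missing_exon2 = "missing_exon2"
    premature_stop = "premature_stop"
    anomalous_acceptor = "anomalous_acceptor"
    truncated_scaffold = "truncated_scaffold"
    n_gap = "n_gap"


#: defect kinds that render a gene nonfunctional (structural lesions) vs
#: merely incomplete (assembly artefacts)
NONFUNCTIONAL_KINDS = {
    DefectKind.missing_exon2,
    DefectKind.premature_stop,
    DefectKind.anomalous_acceptor,
}
INCOMPLETE_KINDS = {DefectKind.truncated_scaffold, DefectKind.n_gap}


class CathmineError(Exception):
    """Base error for the package."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    alphabet: Alphabet
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise CathmineError(f"record {self.id!r}: empty sequence")
        if re.search(r"\s", self.id):
            raise CathmineError(f"record id {self.id!r} contains whitespace")
        allowed = DNA_ALPHABET if self.alphabet == Alphabet.dna else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise CathmineError(
                f"record {self.id!r}: illegal {self.alphabet.value} residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on the forward strand of the source record."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CathmineError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise CathmineError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class DefectFlag:
    kind: DefectKind
    where: Interval | None = None
    note: str = ""


@dataclass
class IntronRecord:
    interval: Interval
    donor5: str
    acceptor3: str

    @property
    def canonical_donor(self) -> bool:
        return self.donor5.startswith("GT")

    @property
    def canonical_acceptor(self) -> bool:
        return self.acceptor3.endswith("AG")

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class GeneModel:
    """A cathelicidin gene: up to four exons in gene orientation.

    ``exons`` maps exon index (1-4) to a forward-strand Interval. Exon 1
    carries the signal peptide and the start of the cathelin domain; exon 4
    encodes the hypervariable mature peptide.
    """

    gene_id: str
    source_id: str
    strand: str
    exons: dict[int, Interval] = field(default_factory=dict)
    introns: list[IntronRecord] = field(default_factory=list)
    status: GeneStatus = GeneStatus.incomplete
    defects: list[DefectFlag] = field(default_factory=list)

    def validate(self) -> None:
        ivs = [self.exons[k] for k in sorted(self.exons)]
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise CathmineError(f"gene {self.gene_id}: overlapping exons")
        # exon indices ascend 5'->3' in gene orientation
        keys = sorted(self.exons)
        ordered = [self.exons[k] for k in keys]
        if self.strand == "-":
            ordered = ordered[::-1]
        if any(a.end > b.start for a, b in zip(ordered, ordered[1:])):
            raise CathmineError(f"gene {self.gene_id}: exons out of order")
        for intron in self.introns:
            if any(intron.interval.overlaps(e) for e in ivs):
                raise CathmineError(f"gene {self.gene_id}: intron overlaps exon")
        if self.status == GeneStatus.complete and (len(self.exons) != 4 or self.defects):
            raise CathmineError(
                f"gene {self.gene_id}: complete status requires 4 exons and no defects"
            )

    @property
    def span(self) -> Interval:
        ivs = list(self.exons.values())
        return Interval(min(i.start for i in ivs), max(i.end for i in ivs), self.strand)


@dataclass
class Prepropeptide:
    """Full precursor translation: signal peptide + cathelin domain + AMP."""

    sequence: str
    signal_span: tuple[int, int]
    cathelin_span: tuple[int, int]
    exon_of_residue: list[int]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        s0, s1 = self.signal_span
        c0, c1 = self.cathelin_span
        if not (0 <= s0 < s1 <= n and 0 <= c0 < c1 <= n):
            raise CathmineError("prepropeptide spans out of range")
        if c0 < s1:
            raise CathmineError("cathelin domain must start after the signal peptide")
        if len(self.exon_of_residue) != n:
            raise CathmineError("exon_of_residue length mismatch")
        if any(b < a for a, b in zip(self.exon_of_residue, self.exon_of_residue[1:])):
            raise CathmineError("exon_of_residue must be non-decreasing")

    def exon_translation(self, exon_index: int) -> str:
        return "".join(
            aa for aa, e in zip(self.sequence, self.exon_of_residue) if e == exon_index
        )


# ---------------------------------------------------------------------------
# sequence utilities


def reverse_complement(dna: str) -> str:
    return dna.translate(COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0) -> str:
    """Translate one reading frame; stops as '*', N-containing codons as 'X'.

    A trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise CathmineError(f"frame must be 0, 1 or 2, got {frame}")
    out = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def infer_alphabet(residues: str) -> Alphabet:
    n = len(residues)
    acgtn = sum(1 for c in residues if c in DNA_ALPHABET)
    return Alphabet.dna if n and acgtn / n >= 0.9 else Alphabet.protein


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into validated records; alphabet inferred per record."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise CathmineError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                alphabet=infer_alphabet(residues),
                description=rec.description,
            )
        )
    if not records:
        raise CathmineError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.description in ("", rec.id) else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _gff_attrs(model: GeneModel) -> str:
    parts = [f"ID={model.gene_id}", f"status={model.status.value}"]
    if model.defects:
        kinds = ",".join(d.kind.value for d in model.defects)
        parts.append(f"defects={kinds}")
    return ";".join(parts)


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon rows, 1-based inclusive, sorted by start."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            m.validate()
            span = m.span
            attrs = _gff_attrs(m)
            src = "cathmine"
            fh.write(
                f"{m.source_id}\t{src}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.source_id}\t{src}\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for idx in sorted(m.exons, key=lambda k: m.exons[k].start):
                e = m.exons[idx]
                fh.write(
                    f"{m.source_id}\t{src}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.exon{idx};Parent={m.gene_id}.t1;"
                    f"exon_index={idx}\n"
                )
            for k, intron in enumerate(sorted(m.introns, key=lambda i: i.interval.start), 1):
                iv = intron.interval
                fh.write(
                    f"{m.source_id}\t{src}\tintron\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.intron{k};Parent={m.gene_id}.t1;"
                    f"donor5={intron.donor5};acceptor3={intron.acceptor3}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read back models written by :func:`write_gff3` (exons + status + defects)."""
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise CathmineError(f"{path}: malformed GFF3 row: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = cols
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr["ID"]
                model = GeneModel(
                    gene_id=gid,
                    source_id=seqid,
                    strand=strand,
                    status=GeneStatus(attr.get("status", "incomplete")),
                )
                for kind in attr.get("defects", "").split(","):
                    if kind:
                        model.defects.append(DefectFlag(kind=DefectKind(kind)))
                genes[gid] = model
            elif ftype == "exon":
                gid = attr["Parent"].rsplit(".t1", 1)[0]
                idx = int(attr["exon_index"])
                genes[gid].exons[idx] = Interval(int(start) - 1, int(end), strand)
            elif ftype == "intron":
                gid = attr["Parent"].rsplit(".t1", 1)[0]
                genes[gid].introns.append(
                    IntronRecord(
                        interval=Interval(int(start) - 1, int(end), strand),
                        donor5=attr.get("donor5", ""),
                        acceptor3=attr.get("acceptor3", ""),
                    )
                )
    out = list(genes.values())
    for m in out:
        m.validate()
    return out
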