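"""Sequence I/O: FASTA/GenBank/GFF3 parsing and a minimal six-frame ORF caller.

Internal coordinates are 0-based half-open on the forward strand; emitted
GFF3 uses the standard 1-based inclusive convention. Gene calling here is a
deliberately simple longest-ORF scan (translation table 11) so nucleotide
input can be processed without an external gene finder; externally called
proteins (protein FASTA, GenBank CDS features, GFF3) are accepted as-is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = set("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

DEFAULT_TRANSLATION_TABLE = 11
START_CODONS = ("ATG", "GTG", "TTG")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class GenomeRecord:
    """A nucleotide contig or genome sequence."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfCall:
    """A called or parsed open reading frame.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of ``contig_id``; ``strand`` is '+' or '-'.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    caller: str = "internal"  # {parsed, internal}
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid ORF interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.caller == "internal" and (self.end - self.start) % 3 != 0:
            raise ValueError("internal ORF length must be divisible by 3")
        if "*" in self.protein:
            raise ValueError(f"ORF {self.id or self.contig_id}: internal stop in protein")
        if not self.id:
            self.id = f"{self.contig_id}_{self.start}_{self.end}_{self.strand}"


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list:
    """Read a FASTA file into :class:`GenomeRecord` or :class:`ProteinRecord`.

    Sequences are upper-cased; duplicate ids and illegal characters raise
    :class:`ParseError` naming the offending record.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"kind must be 'nucleotide' or 'protein', got {kind!r}")
    cls = GenomeRecord if kind == "nucleotide" else ProteinRecord
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if kind == "protein":
            seq = seq.rstrip("*")
        records.append(cls(id=rec.id, sequence=seq, source=str(path)))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_genbank(path: str | Path) -> tuple[GenomeRecord, list[OrfCall]]:
    """Read a GenBank flat file; CDS features become ``caller='parsed'`` ORFs.

    Translations are taken from the ``/translation`` qualifier when present,
    otherwise computed with table 11. A joined (multi-interval) CDS yields a
    single ORF spanning the join, translated from the concatenated exons.
    """
    rec = SeqIO.read(str(path), "genbank")
    if len(rec.seq) == 0:
        raise ParseError(f"{path}: GenBank record has no ORIGIN sequence")
    genome = GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), source=str(path))
    calls: list[OrfCall] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        if "translation" in quals:
            protein = quals["translation"][0]
        else:
            protein = str(feat.extract(rec.seq).translate(table=DEFAULT_TRANSLATION_TABLE)).rstrip("*")
        strand = "-" if feat.location.strand == -1 else "+"
        orf_id = quals.get("locus_tag", quals.get("gene", [""]))[0]
        calls.append(
            OrfCall(
                contig_id=rec.id,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand=strand,
                protein=protein,
                caller="parsed",
                id=orf_id or "",
            )
        )
    calls.sort(key=lambda c: (c.start, c.end))
    return genome, calls


def _translate(codons: str, table: int) -> str:
    return str(Seq(codons).translate(table=table))


def _scan_frame(seq: str, contig_id: str, frame: int, min_aa: int, table: int) -> list[OrfCall]:
    """Scan one forward-strand frame for stop-to-stop ORFs on ``seq``."""
    calls = []
    n = len(seq)
    usable = seq[frame : frame + ((n - frame) // 3) * 3]
    aa = _translate(usable, table)
    seg_start = 0  # codon index where current stop-to-stop segment starts
    for i, ch in enumerate(list(aa) + ["*"]):
        if ch != "*":
            continue
        has_stop = i < len(aa)
        # find first start codon in segment [seg_start, i)
        for j in range(seg_start, i):
            codon = usable[3 * j : 3 * j + 3]
            if codon in START_CODONS:
                length_aa = i - j
                if length_aa >= min_aa:
                    protein = "M" + aa[j + 1 : i]
                    nt_start = frame + 3 * j
                    nt_end = frame + 3 * (i + 1) if has_stop else frame + 3 * i
                    calls.append(
                        OrfCall(
                            contig_id=contig_id,
                            start=nt_start,
                            end=nt_end,
                            strand="+",
                            protein=protein,
                            caller="internal",
                        )
                    )
                break
        seg_start = i + 1
    return calls


def call_orfs(
    genome: GenomeRecord, min_aa: int = 60, table: int = DEFAULT_TRANSLATION_TABLE
) -> list[OrfCall]:
    """Six-frame longest-ORF caller.

    For each stop-to-stop interval the longest ORF beginning at ATG/GTG/TTG
    is reported if its protein is at least ``min_aa`` residues. The stop
    codon, when present, is included in the nucleotide interval.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = genome.sequence
    n = len(seq)
    calls: list[OrfCall] = []
    for frame in range(3):
        calls.extend(_scan_frame(seq, genome.id, frame, min_aa, table))
    rc = str(Seq(seq).reverse_complement())
    for frame in range(3):
        for c in _scan_frame(rc, genome.id, frame, min_aa, table):
            # mirror coordinates back onto the forward strand
            calls.append(
                OrfCall(
                    contig_id=genome.id,
                    start=n - c.end,
                    end=n - c.start,
                    strand="-",
                    protein=c.protein,
                    caller="internal",
                )
            )
    calls.sort(key=lambda c: (c.contig_id, c.start, c.end, c.strand))
    return calls


_GFF_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "%": "%25"}


def _gff_escape(value: str) -> str:
    value = value.replace("%", "%25")
    for ch, rep in _GFF_ESCAPES.items():
        if ch != "%":
            value = value.replace(ch, rep)
    return value


def _gff_unescape(value: str) -> str:
    return re.sub("%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), value)


def write_gff(
    calls: Iterable[OrfCall],
    path: str | Path,
    annotations: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write ORF calls as GFF3 CDS features (1-based inclusive coordinates).

    ``annotations`` maps ORF id to extra attribute key/value pairs. The
    protein sequence and caller are stored as attributes so the file
    round-trips through :func:`read_gff`.
    """
    annotations = annotations or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            attrs = {"ID": c.id, "caller": c.caller, "translation": c.protein}
            attrs.update(annotations.get(c.id, {}))
            attr_str = ";".join(f"{k}={_gff_escape(str(v))}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        c.contig_id,
                        "cdpsmine",
                        "CDS",
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        c.strand,
                        "0",
                        attr_str,
                    ]
                )
                + "\n"
            )


def read_gff(path: str | Path) -> list[OrfCall]:
    """Read GFF3 CDS features written by :func:`write_gff` (or compatible)."""
    calls = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise ParseError(f"{path}: missing ##gff-version pragma")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: malformed GFF line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr_str = fields
            if ftype != "CDS":
                continue
            attrs = {}
            for pair in attr_str.split(";"):
                if "=" in pair:
                    k, v = pair.split("=", 1)
                    attrs[k] = _gff_unescape(v)
            calls.append(
                OrfCall(
                    contig_id=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    protein=attrs.get("translation", ""),
                    caller=attrs.get("caller", "parsed"),
                    id=attrs.get("ID", ""),
                )
            )
    return calls


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
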