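"""Sequence and annotation I/O.

Internally every coordinate is 0-based half-open on the forward strand;
conversion to 1-based inclusive happens only at the GFF3/GenBank boundary.
FASTA and GenBank parsing is delegated to Biopython.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord

__all__ = [
    "SeqRecord",
    "FeatureRow",
    "read_sequences",
    "write_fasta",
    "write_genbank",
    "write_gff3",
    "read_gff3",
    "write_table",
    "read_table",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FeatureRow:
    """One annotated interval on a sequence (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    feature_type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.feature_type}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class SeqRecord:
    """A DNA sequence plus optional gene-level annotation."""

    id: str
    sequence: str
    description: str = ""
    source_format: str = "fasta"
    features: list[FeatureRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_sequences(path: str | Path, fmt: str | None = None) -> list[SeqRecord]:
    """Read FASTA or GenBank into SeqRecords.

    ``fmt`` is "fasta" or "genbank"; when None it is guessed from the
    extension (.gb/.gbk/.genbank -> genbank, else fasta). GenBank gene-like
    features (gene/CDS/misc_feature) are carried into ``features``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sequence file not found: {path}")
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".genbank"} else "fasta"
    if fmt not in {"fasta", "genbank"}:
        raise ValueError(f"unsupported format {fmt!r}")
    records = []
    for rec in SeqIO.parse(str(path), fmt):
        feats = []
        for f in getattr(rec, "features", []):
            if f.type == "source" or f.location is None:
                continue
            attrs = {k: ";".join(map(str, v)) for k, v in f.qualifiers.items()}
            feats.append(
                FeatureRow(
                    seq_id=rec.id,
                    start=int(f.location.start),
                    end=int(f.location.end),
                    strand="-" if f.location.strand == -1 else "+",
                    feature_type=f.type,
                    attributes=attrs,
                )
            )
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(
            SeqRecord(
                id=rec.id,
                sequence=seq,
                description=rec.description,
                source_format=fmt,
                features=feats,
            )
        )
    if not records:
        raise ValueError(f"no records parsed from {path} (format {fmt})")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_genbank(record: SeqRecord, path: str | Path) -> None:
    """Write a SeqRecord with its features as a GenBank flat file."""
    bio = BioSeqRecord(
        Seq(record.sequence),
        id=record.id[:16] or "seq",
        name=record.id[:16] or "seq",
        description=record.description,
        annotations={"molecule_type": "DNA"},
    )
    for f in record.features:
        loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
        qualifiers = {k: [v] for k, v in f.attributes.items()}
        bio.features.append(SeqFeature(loc, type=f.feature_type, qualifiers=qualifiers))
    SeqIO.write([bio], str(Path(path)), "genbank")


def _gff_escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :^*$@!+?|")


def write_gff3(features: Sequence[FeatureRow], path: str | Path, source: str = "tnta") -> None:
    """Write features as GFF3 (1-based inclusive columns 4/5)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={_gff_escape(v)}" for k, v in sorted(f.attributes.items()))
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        source,
                        f.feature_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[FeatureRow]:
    """Parse a GFF3 file written by :func:`write_gff3` back into FeatureRows."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = {}
        if cols[8] != ".":
            for item in cols[8].split(";"):
                k, _, v = item.partition("=")
                attrs[k] = urllib.parse.unquote(v)
        rows.append(
            FeatureRow(
                seq_id=cols[0],
                start=int(cols[3]) - 1,
                end=int(cols[4]),
                strand=cols[6],
                feature_type=cols[2],
                attributes=attrs,
            )
        )
    return rows


def write_table(rows: Sequence[dict], path: str | Path, columns: Sequence[str]) -> None:
    """Write records as a tab-separated table with a header line."""
    path = Path(path)
    for i, row in enumerate(rows):
        for col in columns:
            if col not in row:
                raise KeyError(f"row {i} is missing column {col!r}")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_table(path: str | Path) -> list[dict]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]
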