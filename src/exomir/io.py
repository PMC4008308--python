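"""Readers and writers for the formats the pipeline touches.

Sequence records are normalized on read: RNA ``U`` becomes DNA ``T`` and
case is folded to upper, so downstream code works over a single
``{A,C,G,T,N}`` alphabet regardless of whether a reference shipped in
RNA or DNA spelling.

Coordinates are 0-based half-open everywhere inside the package; the
GFF3 writer/reader is the single place where the 1-based inclusive
convention of the format is applied.  No other module performs +-1
arithmetic on genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed input file."""


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""
    quality: list[int] | None = None  # phred scores, FASTQ only

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def attributes(self) -> dict[str, str]:
        """``key=value`` tokens parsed from the description."""
        out = {}
        for token in self.description.split():
            if "=" in token:
                key, _, val = token.partition("=")
                out[key] = val
        return out


def _check_records(records: list[SequenceRecord], path) -> list[SequenceRecord]:
    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        if not rec.seq:
            raise ParseError(f"{path}: record {i} ({rec.id!r}): empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}: record {i}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        bad = set(rec.seq) - set("ACGTN")
        if bad:
            raise ParseError(
                f"{path}: record {i} ({rec.id!r}): invalid characters {sorted(bad)}"
            )
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; one record per header, normalized to upper/DNA."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, normalize_seq(str(rec.seq)), desc))
    if not records and Path(path).stat().st_size > 0:
        raise ParseError(f"{path}: line 1: not a FASTA file")
    return _check_records(records, path)


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read Sanger (phred+33) FASTQ with qualities."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            SequenceRecord(
                rec.id,
                normalize_seq(str(rec.seq)),
                "",
                quality=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return _check_records(records, path)


def read_seqs(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA or FASTQ, sniffing the leading character."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [40] * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in qual) + "\n")


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GenomicFeature:
    """A located feature; start/end are 0-based half-open internally."""

    chrom: str
    start: int
    end: int
    strand: str
    type: str = "region"
    source: str = "exomir"
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"feature end < start ({self.chrom}:{self.start}-{self.end})"
            )
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")


def write_gff3(features: Sequence[GenomicFeature], path: str | Path) -> None:
    """Write GFF3, converting to the format's 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items()) or "."
            score = "." if feat.score is None else f"{feat.score:g}"
            fh.write(
                "\t".join(
                    [
                        feat.chrom,
                        feat.source,
                        feat.type,
                        str(feat.start + 1),  # 0-based half-open -> 1-based incl.
                        str(feat.end),
                        score,
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GenomicFeature]:
    """Read GFF3 back into internal 0-based half-open coordinates."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            chrom, source, ftype, start, end, score, strand, _, attrs = cols
            attributes = {}
            if attrs != ".":
                for token in attrs.split(";"):
                    if token:
                        key, _, val = token.partition("=")
                        attributes[key] = val
            feats.append(
                GenomicFeature(
                    chrom=chrom,
                    start=int(start) - 1,  # 1-based incl. -> 0-based half-open
                    end=int(end),
                    strand=strand,
                    type=ftype,
                    source=source,
                    score=None if score == "." else float(score),
                    attributes=attributes,
                )
            )
    return feats
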