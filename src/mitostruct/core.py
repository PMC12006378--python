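"""Circular-coordinate sequence model and standard-format I/O.

Plant mitochondrial genomes are frequently multichromosomal, with each
chromosome a circular DNA molecule.  Every downstream stage (repeat
discovery, recombination testing, MTPT detection, marker extraction)
therefore needs a coordinate system that is 1-based, inclusive, stranded,
and aware of intervals that cross the circular origin.  This module
provides that model plus thin readers/writers over Biopython for FASTA,
FASTQ and GFF3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger("mitostruct")

VALID_RESIDUES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class CoordinateError(ValueError):
    """Interval coordinates fall outside the target molecule."""


class TopologyError(ValueError):
    """A circular operation was requested on a linear molecule."""


class AlphabetError(ValueError):
    """Sequence contains characters outside {A,C,G,T,N}."""


class FormatError(ValueError):
    """Malformed input file (empty record, missing attribute, ...)."""


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def load_config(path: str | Path) -> dict:
    """Read a JSON run-configuration file."""
    with open(path) as fh:
        return json.load(fh)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (1/167 of 100% -> 0.60, immune to float ties)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def genome_fraction(part_bp: int, genome_bp: int) -> float:
    """Percentage of a genome covered by part_bp, rounded to 2 decimals."""
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")
    return round_half_up(100.0 * part_bp / genome_bp)


def reverse_complement(s: str) -> str:
    """Watson-Crick complement, reversed.  N complements to N."""
    bad = set(s) - VALID_RESIDUES
    if bad:
        raise AlphabetError(f"non-nucleotide characters: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularSequence:
    """A named DNA molecule, circular by default.

    Coordinates into this molecule are always 1-based inclusive.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeInterval:
    """1-based inclusive stranded interval, optionally crossing the origin.

    ``wraps`` is an explicit flag: a wrapping interval runs from ``start``
    forward through the origin to ``end``.  The normalized (non-wrapping)
    form always has ``start <= end``.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"coordinates must be >= 1: {self}")
        if not self.wraps and self.start > self.end:
            raise CoordinateError(
                f"non-wrapping interval has start > end: {self}"
            )

    def span(self, seq_len: int) -> int:
        """Number of bases covered, given the molecule length."""
        if self.wraps:
            return seq_len - self.start + 1 + self.end
        return self.end - self.start + 1

    def positions(self, seq_len: int) -> Iterator[int]:
        """Yield covered 1-based plus-strand positions in 5'->3' plus order."""
        if self.wraps:
            yield from range(self.start, seq_len + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated feature (gene/exon/CDS/tRNA/rRNA)."""

    seq_id: str
    feature_type: str
    interval: GenomeInterval
    gene_name: str
    exon_rank: int | None = None

    def __post_init__(self) -> None:
        if self.feature_type not in ("gene", "exon", "CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature type {self.feature_type!r}")


def extract_interval(seq: CircularSequence, iv: GenomeInterval) -> str:
    """Residues of ``iv`` read 5'->3' on the requested strand.

    Minus-strand intervals return the reverse complement of the
    plus-strand span.  Wrapping intervals are only legal on circular
    molecules.
    """
    if iv.seq_id != seq.id:
        raise CoordinateError(f"interval targets {iv.seq_id!r}, not {seq.id!r}")
    n = len(seq)
    if iv.start > n or iv.end > n:
        raise CoordinateError(f"interval {iv} out of bounds for length {n}")
    if iv.wraps:
        if not seq.circular:
            raise TopologyError(
                f"wrapping interval on linear molecule {seq.id!r}"
            )
        plus = seq.residues[iv.start - 1 :] + seq.residues[: iv.end]
    else:
        plus = seq.residues[iv.start - 1 : iv.end]
    return plus if iv.strand == "+" else reverse_complement(plus)


def circular_interval(
    seq: CircularSequence, start0: int, length: int, strand: str = "+"
) -> GenomeInterval:
    """Build an interval from a 0-based start (any integer) and a length.

    Negative or >=len starts are taken modulo the molecule length; the
    ``wraps`` flag is set automatically.  Convenience for flank
    arithmetic around repeats.
    """
    n = len(seq)
    if length < 1 or length > n:
        raise CoordinateError(f"length {length} invalid for molecule of {n} bp")
    s0 = start0 % n
    e0 = s0 + length - 1
    if e0 < n:
        return GenomeInterval(seq.id, s0 + 1, e0 + 1, strand, wraps=False)
    if not seq.circular:
        raise TopologyError(f"interval wraps on linear molecule {seq.id!r}")
    return GenomeInterval(seq.id, s0 + 1, e0 % n + 1, strand, wraps=True)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def load_genome(path: str | Path, circular: bool = True) -> list[CircularSequence]:
    """Read a multi-record FASTA into CircularSequences.

    Record ids are the first whitespace-delimited header token; residues
    are uppercased.  Empty files or zero-length records are format errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FormatError(f"record {rec.id!r} in {path} has empty sequence")
        out.append(CircularSequence(rec.id, str(rec.seq).upper(), circular=circular))
    return out


def write_genome(seqs: Iterable[CircularSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def load_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ reads as (id, sequence); qualities are ignored."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_reads(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    as_fastq = path.suffix.lower() in (".fq", ".fastq")
    with open(path, "w") as fh:
        for rid, seq in reads:
            if as_fastq:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            else:
                fh.write(f">{rid}\n{seq}\n")


def _gff_attributes(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def load_features(path: str | Path) -> list[FeatureRecord]:
    """Read gene/exon/CDS/tRNA/rRNA features from GFF3.

    ``gene_name`` comes from the ``gene``, ``Name`` or ``ID`` attribute;
    exon ranks from ``exon_rank`` (or ``rank``).
    """
    feats: list[FeatureRecord] = []
    wanted = {"gene", "exon", "CDS", "tRNA", "rRNA"}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            seq_id, _, ftype, start, end, _, strand, _, attrs = cols[:9]
            if ftype not in wanted:
                continue
            a = _gff_attributes(attrs)
            gene = a.get("gene") or a.get("Name") or a.get("ID") or ""
            rank = a.get("exon_rank") or a.get("rank")
            feats.append(
                FeatureRecord(
                    seq_id=seq_id,
                    feature_type=ftype,
                    interval=GenomeInterval(seq_id, int(start), int(end), strand),
                    gene_name=gene,
                    exon_rank=int(rank) if rank is not None else None,
                )
            )
    return feats


def write_features(feats: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = f"gene={f.gene_name}"
            if f.exon_rank is not None:
                attrs += f";exon_rank={f.exon_rank}"
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        "mitostruct",
                        f.feature_type,
                        str(f.interval.start),
                        str(f.interval.end),
                        ".",
                        f.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
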