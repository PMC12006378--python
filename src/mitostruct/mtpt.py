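"""Mitochondrial plastid sequence (MTPT) detection.

Plastid-to-mitochondrion DNA transfer leaves near-identical plastome
segments inside the mitogenome.  Detection is a seeded nucleotide
homology search (BLASTn, word size 7, e-value < 1e-6) between the two
organelle genomes, followed by length/identity filtering (>= 100 bp and
>= 80% identity, boundaries inclusive), merging of overlapping or
abutting mitogenome intervals into loci, and annotation of plastid genes
contained intact in each locus.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .core import CircularSequence, FeatureRecord, GenomeInterval, write_genome

DEFAULT_WORD_SIZE = 7
DEFAULT_EVALUE = 1e-6
DEFAULT_MIN_LEN = 100
DEFAULT_MIN_IDENTITY = 0.80


@dataclass(frozen=True)
class HomologyHit:
    plastid_iv: GenomeInterval
    mito_iv: GenomeInterval
    aligned_length: int
    identity: float  # fraction in [0, 1]
    score: float  # bit score
    evalue: float


@dataclass
class MTPTLocus:
    locus_id: str
    mito_iv: GenomeInterval
    total_length: int
    hits: list[HomologyHit] = field(default_factory=list)
    contained_features: list[tuple[str, bool]] = field(default_factory=list)


def find_homologous_segments(
    mito: list[CircularSequence],
    plastid: list[CircularSequence],
    word_size: int = DEFAULT_WORD_SIZE,
    evalue_max: float = DEFAULT_EVALUE,
) -> list[HomologyHit]:
    """BLASTn the mitogenome (query) against the plastome (subject).

    Both strands are searched; hits are ordered by mitogenome
    coordinate, then score.
    """
    if not mito or not plastid:
        raise ValueError("both genomes must be non-empty")
    if shutil.which("blastn") is None:
        raise RuntimeError("blastn executable not found on PATH")
    with tempfile.TemporaryDirectory(prefix="mitostruct_blast_") as tmp:
        tmp = Path(tmp)
        qpath, spath = tmp / "mito.fa", tmp / "plastid.fa"
        write_genome(mito, qpath)
        write_genome(plastid, spath)
        cmd = [
            "blastn",
            "-query", str(qpath),
            "-subject", str(spath),
            "-word_size", str(word_size),
            "-evalue", str(evalue_max),
            "-outfmt", "6 qseqid sseqid pident length qstart qend sstart send evalue bitscore",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
    hits = []
    for line in proc.stdout.splitlines():
        if not line.strip():
            continue
        (qseq, sseq, pident, length, qstart, qend,
         sstart, send, evalue, bitscore) = line.split("\t")
        qstart, qend = int(qstart), int(qend)
        sstart, send = int(sstart), int(send)
        # BLAST reports subject minus-strand hits as sstart > send
        if sstart <= send:
            plastid_iv = GenomeInterval(sseq, sstart, send, "+")
        else:
            plastid_iv = GenomeInterval(sseq, send, sstart, "-")
        mito_iv = GenomeInterval(qseq, min(qstart, qend), max(qstart, qend), "+")
        hits.append(
            HomologyHit(
                plastid_iv=plastid_iv,
                mito_iv=mito_iv,
                aligned_length=int(length),
                identity=float(pident) / 100.0,
                score=float(bitscore),
                evalue=float(evalue),
            )
        )
    hits.sort(key=lambda h: (h.mito_iv.seq_id, h.mito_iv.start, -h.score))
    return [h for h in hits if h.evalue < evalue_max]


def filter_hits(
    hits: list[HomologyHit],
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[HomologyHit]:
    """Keep hits with aligned_length >= min_len AND identity >= min_identity."""
    return [
        h for h in hits
        if h.aligned_length >= min_len and h.identity >= min_identity
    ]


def merge_and_summarize(
    hits: list[HomologyHit], mito_len: int, plastid_len: int
) -> tuple[list[MTPTLocus], dict]:
    """Merge overlapping/abutting mitogenome intervals into MTPT loci.

    The summary reports the locus count, total merged length, and the
    total as a percentage of both genome lengths (each rounded to two
    decimals) with explicit denominators.
    """
    from .core import genome_fraction, round_half_up

    per_chrom: dict[str, list[HomologyHit]] = {}
    for h in hits:
        per_chrom.setdefault(h.mito_iv.seq_id, []).append(h)

    merged: list[tuple[GenomeInterval, list[HomologyHit]]] = []
    for chrom in sorted(per_chrom):
        chrom_hits = sorted(per_chrom[chrom], key=lambda h: h.mito_iv.start)
        cur_start = cur_end = None
        cur_hits: list[HomologyHit] = []
        for h in chrom_hits:
            s, e = h.mito_iv.start, h.mito_iv.end
            if cur_start is None:
                cur_start, cur_end, cur_hits = s, e, [h]
            elif s <= cur_end + 1:  # overlap or abut
                cur_end = max(cur_end, e)
                cur_hits.append(h)
            else:
                merged.append((GenomeInterval(chrom, cur_start, cur_end, "+"), cur_hits))
                cur_start, cur_end, cur_hits = s, e, [h]
        if cur_start is not None:
            merged.append((GenomeInterval(chrom, cur_start, cur_end, "+"), cur_hits))

    loci = [
        MTPTLocus(
            locus_id=f"MTPT{i + 1:02d}",
            mito_iv=iv,
            total_length=iv.end - iv.start + 1,
            hits=lhits,
        )
        for i, (iv, lhits) in enumerate(merged)
    ]
    total = sum(l.total_length for l in loci)
    summary = {
        "n_loci": len(loci),
        "total_length": total,
        "mito_len": mito_len,
        "plastid_len": plastid_len,
        "percent_of_mito": genome_fraction(total, mito_len) if mito_len else 0.0,
        "percent_of_plastid": genome_fraction(total, plastid_len) if plastid_len else 0.0,
    }
    return loci, summary


def _plastid_footprint(locus: MTPTLocus) -> dict[str, set[int]]:
    foot: dict[str, set[int]] = {}
    for h in locus.hits:
        foot.setdefault(h.plastid_iv.seq_id, set()).update(
            range(h.plastid_iv.start, h.plastid_iv.end + 1)
        )
    return foot


def annotate_contained(
    loci: list[MTPTLocus], plastid_features: list[FeatureRecord]
) -> list[MTPTLocus]:
    """Mark plastid genes intact iff fully covered by one locus's plastid
    footprint; partial overlaps become (gene, intact=False) fragments."""
    for locus in loci:
        foot = _plastid_footprint(locus)
        seen: set[str] = set()
        contained: list[tuple[str, bool]] = []
        for f in plastid_features:
            if f.feature_type not in ("gene", "tRNA", "rRNA", "CDS"):
                continue
            if f.gene_name in seen:
                continue
            covered = foot.get(f.seq_id, set())
            span = set(range(f.interval.start, f.interval.end + 1))
            if not span & covered:
                continue
            contained.append((f.gene_name, span <= covered))
            seen.add(f.gene_name)
        locus.contained_features = contained
    return loci
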