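"""Mitochondrial intron markers for interspecific identification.

Group II introns of mitochondrial genes diverge faster than exons, so
SNP and indel loci in orthologous introns can distinguish closely
related species.  The pipeline: extract cis-spliced introns (gaps
between consecutive exon ranks, read on the coding strand), align
orthologs across species, call polymorphic columns (SNPs) and maximal
gap runs (indels), and emit target regions of each site plus 300 bp of
flanking intron sequence for primer design.

Intron labels follow the gene + "i" + rank-pair convention: ``nad1i23``
is the intron between exons 2 and 3 of *nad1*.

Multiple alignment is progressive center-star: each non-reference
sequence is aligned globally (affine gaps, Bio.Align.PairwiseAligner)
to the first species' sequence and the pairwise alignments are merged
on reference coordinates ("once a gap, always a gap").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .core import (
    CircularSequence,
    FeatureRecord,
    GenomeInterval,
    extract_interval,
)

logger = logging.getLogger("mitostruct")

MATCH = 2
MISMATCH = -1
GAP_OPEN = -5
GAP_EXTEND = -1
MARKER_FLANK = 300


class AnnotationError(ValueError):
    """Inconsistent exon annotation (overlapping exons, duplicate ranks)."""


@dataclass(frozen=True)
class IntronRecord:
    species: str
    gene: str
    intron_label: str
    sequence: str
    source_iv: GenomeInterval


@dataclass
class MultipleAlignment:
    species: list[str]
    rows: list[str]  # aligned rows, same length, '-' for gaps

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]


@dataclass
class PolymorphicSite:
    intron_label: str
    column_range: tuple[int, int]  # 1-based inclusive alignment columns
    site_type: str  # "SNP" | "indel"
    alleles: dict  # species -> allele string ("" for a full gap run)
    discriminates: set = field(default_factory=set)  # frozenset species pairs


@dataclass
class MarkerRegion:
    intron_label: str
    reference_species: str
    start: int  # 1-based in the reference species' intron
    end: int
    sequence: str
    site_indices: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Intron extraction
# ---------------------------------------------------------------------------


def extract_introns(
    genome: list[CircularSequence],
    features: list[FeatureRecord],
    species: str = "",
) -> list[IntronRecord]:
    """Introns between consecutive exon ranks of each multi-exon gene.

    Minus-strand genes yield coding-strand (reverse-complemented)
    sequences.  Genes whose exons sit on different molecules are
    trans-spliced and skipped with a logged notice.
    """
    by_id = {s.id: s for s in genome}
    exons: dict[str, list[FeatureRecord]] = {}
    for f in features:
        if f.feature_type == "exon" and f.gene_name:
            exons.setdefault(f.gene_name, []).append(f)

    introns: list[IntronRecord] = []
    for gene in sorted(exons):
        fs = exons[gene]
        molecules = {f.seq_id for f in fs}
        if len(molecules) > 1:
            logger.info("gene %s is trans-spliced; skipping", gene)
            continue
        if len(fs) < 2:
            continue
        ranks = [f.exon_rank for f in fs]
        if None in ranks or len(set(ranks)) != len(ranks):
            raise AnnotationError(f"gene {gene!r} exons lack distinct ranks")
        fs = sorted(fs, key=lambda f: f.exon_rank)
        for a, b in zip(fs, fs[1:]):
            ia, ib = a.interval, b.interval
            if ia.strand != ib.strand:
                raise AnnotationError(f"gene {gene!r} exons on mixed strands")
            if _overlap(ia, ib):
                raise AnnotationError(f"gene {gene!r} has overlapping exons")
            strand = ia.strand
            if strand == "+":
                start, end = ia.end + 1, ib.start - 1
            else:
                start, end = ib.end + 1, ia.start - 1
            if start > end:
                raise AnnotationError(
                    f"gene {gene!r}: exons {a.exon_rank}/{b.exon_rank} abut or "
                    "are mis-ordered"
                )
            iv = GenomeInterval(ia.seq_id, start, end, strand)
            seq = extract_interval(by_id[ia.seq_id], iv)
            introns.append(
                IntronRecord(
                    species=species,
                    gene=gene,
                    intron_label=f"{gene}i{a.exon_rank}{b.exon_rank}",
                    sequence=seq,
                    source_iv=iv,
                )
            )
    return introns


def _overlap(a: GenomeInterval, b: GenomeInterval) -> bool:
    return a.start <= b.end and b.start <= a.end


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _aligned_rows(aln) -> tuple[str, str]:
    text = str(aln).splitlines()
    # Bio.Align pretty format: target / match / query lines; use indices
    a = "".join(str(aln[0]))
    b = "".join(str(aln[1]))
    return a, b


def align_introns(seqs: dict[str, str]) -> MultipleAlignment:
    """Deterministic progressive multiple alignment (center-star on the
    first species, guide order = input order)."""
    if len(seqs) < 2:
        raise ValueError("alignment needs at least two sequences")
    for name, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {name!r}")
    names = list(seqs)
    ref_name = names[0]
    ref = seqs[ref_name]
    aligner = _pairwise_aligner()

    # per-pair: gap pattern along the reference + the partner's row chars
    pair_data = []
    for name in names[1:]:
        aln = aligner.align(ref, seqs[name])[0]
        ref_row, other_row = _aligned_rows(aln)
        ins_before = [0] * (len(ref) + 1)  # insertions preceding ref pos i
        other_cols: list[list[str]] = [[] for _ in range(len(ref) + 1)]
        aligned_char: list[str] = []
        rpos = 0
        for rc, oc in zip(ref_row, other_row):
            if rc == "-":
                ins_before[rpos] += 1
                other_cols[rpos].append(oc)
            else:
                aligned_char.append(oc)
                rpos += 1
        pair_data.append((ins_before, other_cols, aligned_char))

    ncols_ins = [max(pd[0][i] for pd in pair_data) for i in range(len(ref) + 1)]
    rows = {name: [] for name in names}
    for i in range(len(ref) + 1):
        block = ncols_ins[i]
        if block:
            rows[ref_name].append("-" * block)
            for name, (ins_before, other_cols, _) in zip(names[1:], pair_data):
                ins = "".join(other_cols[i])
                rows[name].append(ins.ljust(block, "-"))
        if i < len(ref):
            rows[ref_name].append(ref[i])
            for name, (_, _, aligned_char) in zip(names[1:], pair_data):
                rows[name].append(aligned_char[i])
    return MultipleAlignment(
        species=names, rows=["".join(rows[n]) for n in names]
    )


# ---------------------------------------------------------------------------
# Polymorphic sites and marker regions
# ---------------------------------------------------------------------------


def find_polymorphic_sites(
    aln: MultipleAlignment, intron_label: str = ""
) -> list[PolymorphicSite]:
    """SNP columns and maximal gap runs that differ between species.

    A SNP site is a single gap-free column with >= 2 distinct residues.
    An indel site is a maximal run of columns containing at least one
    gap; its per-species alleles are the ungapped strings over the run.
    """
    sites: list[PolymorphicSite] = []
    n = aln.ncols
    i = 0
    while i < n:
        col = aln.column(i)
        if "-" in col:
            j = i
            while j + 1 < n and "-" in aln.column(j + 1):
                j += 1
            alleles = {
                sp: row[i : j + 1].replace("-", "")
                for sp, row in zip(aln.species, aln.rows)
            }
            site = _make_site(intron_label, (i + 1, j + 1), "indel", alleles)
            if site:
                sites.append(site)
            i = j + 1
        else:
            if len(set(col)) >= 2:
                alleles = {sp: c for sp, c in zip(aln.species, col)}
                site = _make_site(intron_label, (i + 1, i + 1), "SNP", alleles)
                if site:
                    sites.append(site)
            i += 1
    return sites


def _make_site(label, column_range, site_type, alleles):
    pairs = {
        frozenset((a, b))
        for a in alleles
        for b in alleles
        if a < b and alleles[a] != alleles[b]
    }
    if not pairs:
        return None
    return PolymorphicSite(label, column_range, site_type, alleles, pairs)


def _column_to_ref_pos(aln: MultipleAlignment, ref_idx: int = 0) -> list[int]:
    """For each alignment column, the 1-based reference position at or
    before it (0 before the first reference residue)."""
    pos = 0
    out = []
    for c in aln.rows[ref_idx]:
        if c != "-":
            pos += 1
        out.append(pos)
    return out


def build_marker_regions(
    sites: list[PolymorphicSite],
    aln: MultipleAlignment,
    intron_seqs: dict[str, str],
    flank: int = MARKER_FLANK,
    reference: str | None = None,
) -> list[MarkerRegion]:
    """Expand each site by ``flank`` bp in the reference species' intron
    coordinates (clamped to the intron) and merge overlapping regions."""
    if not sites:
        return []
    reference = reference or aln.species[0]
    ref_idx = aln.species.index(reference)
    ref_seq = intron_seqs[reference]
    colpos = _column_to_ref_pos(aln, ref_idx)
    n = len(ref_seq)

    expanded = []
    for k, site in enumerate(sites):
        c0, c1 = site.column_range
        start_ref = max(1, colpos[c0 - 1])
        end_ref = max(1, colpos[c1 - 1])
        start = max(1, start_ref - flank)
        end = min(n, end_ref + flank)
        expanded.append((start, end, k))
    expanded.sort()

    regions: list[MarkerRegion] = []
    cur_start, cur_end, cur_sites = None, None, []
    for start, end, k in expanded:
        if cur_start is None:
            cur_start, cur_end, cur_sites = start, end, [k]
        elif start <= cur_end:
            cur_end = max(cur_end, end)
            cur_sites.append(k)
        else:
            regions.append(_region(sites, cur_sites, reference, cur_start, cur_end, ref_seq))
            cur_start, cur_end, cur_sites = start, end, [k]
    if cur_start is not None:
        regions.append(_region(sites, cur_sites, reference, cur_start, cur_end, ref_seq))
    return regions


def _region(sites, site_indices, reference, start, end, ref_seq):
    label = sites[site_indices[0]].intron_label
    return MarkerRegion(
        intron_label=label,
        reference_species=reference,
        start=start,
        end=end,
        sequence=ref_seq[start - 1 : end],
        site_indices=list(site_indices),
    )
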