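"""C-to-U RNA editing site calling, codon-effect annotation, and summaries.

Plant mitochondrial transcripts are edited post-transcriptionally by
cytidine deamination, visible in strand-resolved RNA alignments as C->T
mismatches on the coding strand.  A site is called when the reference
base is C, coverage >= 5, and the T fraction >= 0.1 (both thresholds
inclusive).  Sites coinciding with genomic SNPs (called from DNA reads
with the same thresholds) are excluded.  Codon effects use the standard
genetic code; an edit creating a stop codon is a stop gain, an edit
creating ATG at the first codon is a start gain.

Site names follow the gene-position convention (e.g. ``cox2-615``),
where the number indexes the edited base within the CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .core import CoordinateError
from .core import round_half_up

MIN_DEPTH = 5
MIN_FREQ = 0.1

# Kyte-Doolittle-style binary classes; configurable because summary
# statistics depend on where the boundary is drawn.
HYDROPHOBIC = frozenset("AVLIPFMW")


@dataclass(frozen=True)
class PileupColumn:
    ref_id: str
    pos: int  # 1-based in the reference (CDS + flanks)
    ref_base: str
    depth: int
    counts: dict  # base -> coding-strand read count

    def __post_init__(self):
        if self.depth != sum(self.counts.values()):
            raise ValueError(
                f"depth {self.depth} != sum of counts at {self.ref_id}:{self.pos}"
            )


@dataclass
class EditingSite:
    gene: str
    cds_pos: int  # 1-based position of the edited C within the CDS
    frequency: float
    depth: int
    ref_pos: int | None = None  # position in the CDS+flank reference
    in_cds: bool = True
    site_name: str = ""
    codon_index: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None
    edited_codon: str | None = None
    aa_ref: str | None = None
    aa_edit: str | None = None
    effect: str | None = None  # synonymous|nonsynonymous|stop_gain|start_gain

    def __post_init__(self):
        if not self.site_name:
            self.site_name = f"{self.gene}-{self.cds_pos}"


@dataclass(frozen=True)
class DnaVariant:
    ref_id: str
    pos: int
    alleles: tuple
    frequency: float


@dataclass
class EditingSummary:
    n_total: int = 0
    n_synonymous: int = 0
    n_nonsynonymous: int = 0
    n_stop_gain: int = 0
    n_start_gain: int = 0
    aa_changes: dict = field(default_factory=dict)  # "Pro->Leu" -> count
    codon_positions: dict = field(default_factory=dict)  # 1|2|3 -> count
    n_hydropathy_shift: int = 0  # hydrophilic -> hydrophobic
    percentages: dict = field(default_factory=dict)


def call_editing_sites(
    columns: list[PileupColumn],
    cds_lengths: dict[str, int],
    flank: int = 100,
    min_depth: int = MIN_DEPTH,
    min_freq: float = MIN_FREQ,
) -> list[EditingSite]:
    """Candidate C-to-U sites from coding-sense pileup columns.

    References are CDS plus ``flank`` bp on each side; columns whose CDS
    position falls in a flank are recorded with in_cds=False and skipped
    by codon annotation.  Thresholds are inclusive.
    """
    sites = []
    for col in columns:
        if col.ref_base != "C" or col.depth < min_depth:
            continue
        t = col.counts.get("T", 0)
        freq = t / col.depth
        if freq < min_freq:
            continue
        cds_pos = col.pos - flank
        cds_len = cds_lengths.get(col.ref_id)
        in_cds = cds_len is not None and 1 <= cds_pos <= cds_len
        sites.append(
            EditingSite(
                gene=col.ref_id,
                cds_pos=cds_pos,
                frequency=freq,
                depth=col.depth,
                ref_pos=col.pos,
                in_cds=in_cds,
            )
        )
    return sites


def call_dna_variants(
    columns: list[PileupColumn],
    min_depth: int = MIN_DEPTH,
    min_freq: float = MIN_FREQ,
) -> list[DnaVariant]:
    """Genomic SNPs from DNA pileups with the same inclusive thresholds."""
    variants = []
    for col in columns:
        if col.depth < min_depth:
            continue
        for base, n in sorted(col.counts.items()):
            if base == col.ref_base or base == "N":
                continue
            freq = n / col.depth
            if freq >= min_freq:
                variants.append(
                    DnaVariant(col.ref_id, col.pos, (col.ref_base, base), freq)
                )
    return variants


def annotate_effect(site: EditingSite, cds_sequence: str) -> EditingSite:
    """Fill codon-level fields from the CDS (standard genetic code)."""
    if len(cds_sequence) % 3 != 0:
        raise ValueError(f"CDS for {site.gene!r} is not a multiple of 3")
    if not (1 <= site.cds_pos <= len(cds_sequence)):
        raise CoordinateError(
            f"cds_pos {site.cds_pos} outside CDS of {len(cds_sequence)} bp"
        )
    if cds_sequence[site.cds_pos - 1] != "C":
        raise ValueError(
            f"reference base at {site.gene}-{site.cds_pos} is not C"
        )
    idx = (site.cds_pos - 1) // 3  # 0-based codon index
    codon_position = (site.cds_pos - 1) % 3 + 1
    ref_codon = cds_sequence[idx * 3 : idx * 3 + 3]
    edited = ref_codon[: codon_position - 1] + "T" + ref_codon[codon_position:]
    aa_ref = str(Seq(ref_codon).translate())
    aa_edit = str(Seq(edited).translate())

    if aa_edit == "*" and aa_ref != "*":
        effect = "stop_gain"
    elif idx == 0 and edited == "ATG" and ref_codon != "ATG":
        effect = "start_gain"
    elif aa_ref == aa_edit:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"

    site.codon_index = idx + 1
    site.codon_position = codon_position
    site.ref_codon = ref_codon
    site.edited_codon = edited
    site.aa_ref = aa_ref
    site.aa_edit = aa_edit
    site.effect = effect
    return site


def exclude_dna_variants(
    sites: list[EditingSite], variants: list[DnaVariant]
) -> list[EditingSite]:
    """Drop editing calls that coincide with genomic SNPs.

    Positions are compared in reference coordinates (CDS + flanks) when
    the site carries one, else in CDS coordinates.
    """
    snp_positions = {(v.ref_id, v.pos) for v in variants}
    kept = []
    for s in sites:
        pos = s.ref_pos if s.ref_pos is not None else s.cds_pos
        if (s.gene, pos) not in snp_positions:
            kept.append(s)
    return kept


def _aa_label(aa: str) -> str:
    return "stop" if aa == "*" else seq3(aa)


def summarize_editing(sites: list[EditingSite]) -> EditingSummary:
    """Counts and percentages over annotated sites.

    Effects are mutually exclusive (synonymous + nonsynonymous +
    stop_gain + start_gain == total); every percentage uses the total
    site count as denominator and is rounded half-up to two decimals.
    """
    summary = EditingSummary()
    annotated = [s for s in sites if s.effect is not None]
    summary.n_total = len(annotated)
    for s in annotated:
        if s.effect == "synonymous":
            summary.n_synonymous += 1
        elif s.effect == "nonsynonymous":
            summary.n_nonsynonymous += 1
        elif s.effect == "stop_gain":
            summary.n_stop_gain += 1
        elif s.effect == "start_gain":
            summary.n_start_gain += 1
        if s.aa_ref != s.aa_edit:
            key = f"{_aa_label(s.aa_ref)}->{_aa_label(s.aa_edit)}"
            summary.aa_changes[key] = summary.aa_changes.get(key, 0) + 1
        summary.codon_positions[s.codon_position] = (
            summary.codon_positions.get(s.codon_position, 0) + 1
        )
        if (
            s.effect == "nonsynonymous"
            and s.aa_ref not in HYDROPHOBIC
            and s.aa_edit in HYDROPHOBIC
        ):
            summary.n_hydropathy_shift += 1

    n = summary.n_total
    if n:
        pct = lambda k: round_half_up(100.0 * k / n)
        summary.percentages = {
            "synonymous": pct(summary.n_synonymous),
            "nonsynonymous": pct(summary.n_nonsynonymous),
            "stop_gain": pct(summary.n_stop_gain),
            "start_gain": pct(summary.n_start_gain),
            "hydropathy_shift": pct(summary.n_hydropathy_shift),
            **{f"codon_position_{p}": pct(c) for p, c in sorted(summary.codon_positions.items())},
            **{f"aa_{k}": pct(v) for k, v in sorted(summary.aa_changes.items())},
        }
    return summary


# ---------------------------------------------------------------------------
# Pileup construction from SAM alignments
# ---------------------------------------------------------------------------


def pileup_from_sam(sam_path, references: dict[str, str]) -> list[PileupColumn]:
    """Accumulate per-position base counts from a SAM file.

    ``references`` maps reference name to its sequence (CDS + flanks).
    Only aligned (non-clipped, non-indel) read bases are counted.
    """
    import pysam

    counts: dict[tuple[str, int], dict[str, int]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.query_sequence is None:
                continue
            ref = read.reference_name
            if ref not in references:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = read.query_sequence[qpos].upper()
                key = (ref, rpos + 1)
                counts.setdefault(key, {}).setdefault(base, 0)
                counts[key][base] += 1
    columns = []
    for (ref, pos), base_counts in sorted(counts.items()):
        columns.append(
            PileupColumn(
                ref_id=ref,
                pos=pos,
                ref_base=references[ref][pos - 1],
                depth=sum(base_counts.values()),
                counts=base_counts,
            )
        )
    return columns


def read_pileup_tsv(path) -> list[PileupColumn]:
    """Read the internal pileup table (ref_id, pos, ref_base, A, C, G, T)."""
    columns = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            base_counts = {b: int(f[idx[b]]) for b in "ACGT" if idx.get(b) is not None}
            base_counts = {b: c for b, c in base_counts.items() if c}
            columns.append(
                PileupColumn(
                    ref_id=f[idx["ref_id"]],
                    pos=int(f[idx["pos"]]),
                    ref_base=f[idx["ref_base"]],
                    depth=sum(base_counts.values()),
                    counts=base_counts,
                )
            )
    return columns


def write_pileup_tsv(columns: list[PileupColumn], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tpos\tref_base\tA\tC\tG\tT\n")
        for col in columns:
            row = [col.ref_id, str(col.pos), col.ref_base] + [
                str(col.counts.get(b, 0)) for b in "ACGT"
            ]
            fh.write("\t".join(row) + "\n")
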