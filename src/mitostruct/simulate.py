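"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the inputs of a two-chromosome
plant mitogenome study: circular chromosomes (default 40 kb + 30 kb,
about one fifth of a real Salvia-sized assembly, GC 44%) sharing
dispersed repeat pairs; plastid-derived insertions copied from a
generated plastome at a requested identity; multi-exon gene models;
long reads drawn from a mixture of recombination configurations with a
crude substitution+indel error model; strand-resolved RNA/DNA pileups
with planted C-to-U editing and SNPs; and a trio of diverged species
whose introns carry planted substitutions and indels (including one
65 bp indel, mirroring the kind of length polymorphism used for
species-diagnostic markers).

Everything is reproducible from the seed, and every planted feature is
recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import CircularSequence, FeatureRecord, GenomeInterval, reverse_complement

GC_CONTENT = 0.44


class SpecError(ValueError):
    """Requested features cannot be packed into the genome."""


@dataclass
class RepeatSpec:
    length: int
    orientation: str  # "direct" | "inverted"
    chrom_a: int = 0
    chrom_b: int = 1


@dataclass
class MTPTSpec:
    length: int
    identity: float = 1.0
    chrom: int = 0


@dataclass
class GeneSpec:
    name: str
    n_exons: int = 2
    exon_len: int = 300  # multiple of 3 per exon keeps CDS in frame
    intron_len: int = 800
    strand: str = "+"
    chrom: int = 0


@dataclass
class ReadParams:
    count: int = 500
    mean_length: int = 8000
    sd_length: int = 2000
    error_rate: float = 0.05  # substitutions; indels at a quarter of this


@dataclass
class SimSpec:
    seed: int = 0
    chrom_lengths: tuple = (40000, 30000)
    plastid_length: int = 20000
    repeat_specs: list = field(default_factory=lambda: [RepeatSpec(2000, "direct")])
    mtpt_specs: list = field(default_factory=list)
    gene_specs: list = field(default_factory=list)
    config_mixture: dict = field(default_factory=lambda: {"c1": 0.5, "c2": 0.5})
    read_params: ReadParams = field(default_factory=ReadParams)


def random_sequence(rng: np.random.Generator, length: int, gc: float = GC_CONTENT) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


class _Placer:
    """Non-overlapping placement of feature blocks on one chromosome."""

    def __init__(self, rng, length, margin=200):
        self.rng = rng
        self.length = length
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def place(self, span: int) -> int:
        """0-based start such that [start, start+span) is free (no wrap)."""
        if span + 2 * self.margin > self.length:
            raise SpecError(f"feature of {span} bp cannot fit in {self.length} bp")
        for _ in range(1000):
            start = int(self.rng.integers(self.margin, self.length - span - self.margin))
            if all(
                start + span + self.margin <= s or start >= e + self.margin
                for s, e in self.taken
            ):
                self.taken.append((start, start + span))
                return start
        raise SpecError("could not pack all requested features")


def make_genome(spec: SimSpec):
    """Generate (genome, plastid, features, truth) from the spec."""
    rng = np.random.default_rng(spec.seed)
    chroms = [
        list(random_sequence(rng, L)) for L in spec.chrom_lengths
    ]
    plastid_seq = random_sequence(rng, spec.plastid_length)
    placers = [_Placer(rng, L) for L in spec.chrom_lengths]
    truth = {"repeats": [], "mtpts": [], "genes": []}
    features: list[FeatureRecord] = []

    for i, rs in enumerate(spec.repeat_specs):
        if rs.orientation not in ("direct", "inverted"):
            raise SpecError(f"bad repeat orientation {rs.orientation!r}")
        a0 = placers[rs.chrom_a].place(rs.length)
        b0 = placers[rs.chrom_b].place(rs.length)
        block = random_sequence(rng, rs.length)
        chroms[rs.chrom_a][a0 : a0 + rs.length] = block
        copy = block if rs.orientation == "direct" else reverse_complement(block)
        chroms[rs.chrom_b][b0 : b0 + rs.length] = copy
        truth["repeats"].append(
            {
                "repeat_id": f"R{i + 1:02d}",
                "chrom_a": rs.chrom_a,
                "start_a": a0 + 1,
                "end_a": a0 + rs.length,
                "chrom_b": rs.chrom_b,
                "start_b": b0 + 1,
                "end_b": b0 + rs.length,
                "length": rs.length,
                "orientation": rs.orientation,
            }
        )

    for i, ms in enumerate(spec.mtpt_specs):
        if not (0 < ms.identity <= 1):
            raise SpecError("MTPT identity must be in (0, 1]")
        p0 = int(rng.integers(0, spec.plastid_length - ms.length))
        block = list(plastid_seq[p0 : p0 + ms.length])
        n_subs = int(round((1 - ms.identity) * ms.length))
        sub_pos = rng.choice(ms.length, size=n_subs, replace=False) if n_subs else []
        for sp in sub_pos:
            block[sp] = rng.choice([b for b in "ACGT" if b != block[sp]])
        m0 = placers[ms.chrom].place(ms.length)
        chroms[ms.chrom][m0 : m0 + ms.length] = "".join(block)
        truth["mtpts"].append(
            {
                "locus": f"MTPT{i + 1:02d}",
                "chrom": ms.chrom,
                "mito_start": m0 + 1,
                "mito_end": m0 + ms.length,
                "plastid_start": p0 + 1,
                "plastid_end": p0 + ms.length,
                "length": ms.length,
                "identity": ms.identity,
            }
        )

    for gs in spec.gene_specs:
        if gs.exon_len % 3 and gs.n_exons * gs.exon_len % 3:
            raise SpecError(f"gene {gs.name!r}: CDS length not a multiple of 3")
        span = gs.n_exons * gs.exon_len + (gs.n_exons - 1) * gs.intron_len
        g0 = placers[gs.chrom].place(span)
        chrom_id = gs.chrom
        pos = g0
        exon_ivs = []
        for _ in range(gs.n_exons):
            exon_ivs.append((pos + 1, pos + gs.exon_len))
            pos += gs.exon_len + gs.intron_len
        # rank follows transcription order: ascending coordinates on +,
        # descending on -
        ordered = exon_ivs if gs.strand == "+" else exon_ivs[::-1]
        seq_name = f"chr{chrom_id + 1}"
        for rank, (s, e) in enumerate(ordered, start=1):
            features.append(
                FeatureRecord(
                    seq_id=seq_name,
                    feature_type="exon",
                    interval=GenomeInterval(seq_name, s, e, gs.strand),
                    gene_name=gs.name,
                    exon_rank=rank,
                )
            )
        features.append(
            FeatureRecord(
                seq_id=seq_name,
                feature_type="gene",
                interval=GenomeInterval(seq_name, g0 + 1, g0 + span, gs.strand),
                gene_name=gs.name,
            )
        )
        truth["genes"].append(
            {"gene": gs.name, "chrom": chrom_id, "start": g0 + 1, "end": g0 + span,
             "strand": gs.strand, "exons": ordered}
        )

    genome = [
        CircularSequence(f"chr{i + 1}", "".join(c)) for i, c in enumerate(chroms)
    ]
    plastid = CircularSequence("plastid", plastid_seq)
    return genome, plastid, features, truth


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------


def _mutate_read(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    indel_rate = error_rate / 4
    out = []
    for ch in seq:
        r = rng.random()
        if r < error_rate:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        elif r < error_rate + indel_rate:
            pass  # deletion
        elif r < error_rate + 2 * indel_rate:
            out.append(ch)
            out.append(rng.choice(list("ACGT")))
        else:
            out.append(ch)
    return "".join(out)


def simulate_long_reads(
    templates: dict[str, str],
    mixture: dict[str, float],
    params: ReadParams,
    seed: int,
    circular: bool = False,
):
    """Sample reads from templates chosen by mixture proportions.

    Returns (reads, truth) where reads are (read_id, sequence) and truth
    records the template label per read.  Linear templates yield reads
    fully inside the template; circular ones sample the origin uniformly
    around the circle.
    """
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    labels = sorted(mixture)
    probs = np.array([mixture[l] for l in labels])
    reads = []
    truth = []
    for i in range(params.count):
        label = labels[rng.choice(len(labels), p=probs)]
        template = templates[label]
        n = len(template)
        length = int(rng.normal(params.mean_length, params.sd_length))
        length = max(50, min(length, n))
        if circular:
            start = int(rng.integers(0, n))
            raw = (template + template)[start : start + length]
        else:
            start = int(rng.integers(0, n - length + 1))
            raw = template[start : start + length]
        seq = _mutate_read(rng, raw, params.error_rate)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
            strand = "-"
        else:
            strand = "+"
        rid = f"read{i:05d}"
        reads.append((rid, seq))
        truth.append(
            {"read_id": rid, "label": label, "start": start + 1,
             "length": length, "strand": strand}
        )
    return reads, truth


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------


def simulate_pileups(
    cds_set: dict[str, str],
    editing_truth: list[tuple[str, int, float]],
    snp_truth: list[tuple[str, int, str, float]],
    depth: int,
    seed: int,
    flank: int = 100,
    error_rate: float = 0.005,
):
    """Binomial pileups over CDS+flank references.

    ``editing_truth``: (gene, cds_pos, frequency) C->T events in RNA only.
    ``snp_truth``: (gene, cds_pos, alt_base, frequency) in both DNA and RNA.
    Background sequencing error scatters reads uniformly over the three
    non-reference bases.  Returns (rna_columns, dna_columns, refs, truth).
    """
    from .editing import PileupColumn

    rng = np.random.default_rng(seed)
    refs = {}
    for gene, cds in cds_set.items():
        left = random_sequence(rng, flank)
        right = random_sequence(rng, flank)
        refs[gene] = left + cds + right

    edit_map = {(g, p): f for g, p, f in editing_truth}
    snp_map = {(g, p): (alt, f) for g, p, alt, f in snp_truth}

    def columns(is_rna: bool):
        cols = []
        for gene, ref in refs.items():
            cds_len = len(cds_set[gene])
            for pos in range(1, len(ref) + 1):
                ref_base = ref[pos - 1]
                d = depth
                counts = {ref_base: d}
                cds_pos = pos - flank
                planted = 0.0
                alt = None
                if (gene, cds_pos) in snp_map:
                    alt, f = snp_map[(gene, cds_pos)]
                    planted = f
                elif is_rna and (gene, cds_pos) in edit_map and ref_base == "C":
                    alt, planted = "T", edit_map[(gene, cds_pos)]
                if alt is not None and planted > 0:
                    k = int(rng.binomial(d, planted))
                    counts[ref_base] -= k
                    counts[alt] = counts.get(alt, 0) + k
                # background errors on the remaining ref-supporting reads
                e = int(rng.binomial(counts[ref_base], error_rate))
                if e:
                    counts[ref_base] -= e
                    for _ in range(e):
                        b = rng.choice([x for x in "ACGT" if x != ref_base])
                        counts[b] = counts.get(b, 0) + 1
                counts = {b: c for b, c in counts.items() if c > 0}
                cols.append(
                    PileupColumn(gene, pos, ref_base, sum(counts.values()), counts)
                )
        return cols

    truth = {"editing": list(editing_truth), "snps": list(snp_truth), "flank": flank}
    return columns(True), columns(False), refs, truth


# ---------------------------------------------------------------------------
# Species trio
# ---------------------------------------------------------------------------


@dataclass
class Divergence:
    substitutions: dict = field(default_factory=dict)  # intron_label -> count
    indels: dict = field(default_factory=dict)  # intron_label -> [(length, "ins"|"del")]


def make_species_trio(
    genome: list[CircularSequence],
    features: list[FeatureRecord],
    divergence: dict[str, Divergence],
    seed: int,
    base_species: str = "sp1",
):
    """Derive diverged species by mutating intron interiors only.

    Exon sequences are held constant, so interspecific polymorphism is
    confined to introns.  Mutations are spaced >= 10 bp apart within an
    intron so each planted event yields its own alignment site.  Returns
    ({species: (genome, features)}, truth).
    """
    from .markers import extract_introns

    rng = np.random.default_rng(seed)
    introns = extract_introns(genome, features)
    by_label = {ir.intron_label: ir for ir in introns}

    out = {base_species: (genome, features)}
    truth: dict[str, dict] = {base_species: {}}
    for species in sorted(divergence):
        div = divergence[species]
        events_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        sp_truth: dict[str, dict] = {}
        for label in sorted(set(div.substitutions) | set(div.indels)):
            ir = by_label.get(label)
            if ir is None:
                raise ValueError(f"unknown intron {label!r}")
            n_sub = div.substitutions.get(label, 0)
            indels = div.indels.get(label, [])
            margin = 20
            max_indel = max((ilen for ilen, _ in indels), default=0)
            usable = len(ir.sequence) - 2 * margin - max_indel
            needed = n_sub + len(indels)
            if needed == 0:
                continue
            if usable < needed * 10:
                raise ValueError(f"intron {label!r} too short for mutations")
            # choose well-separated intron positions (1-based, coding strand)
            positions = sorted(
                margin + 1 + int(x)
                for x in rng.choice(usable // 10, size=needed, replace=False) * 10
            )
            rng.shuffle(indel_order := list(range(needed)))
            sub_pos = positions[: n_sub]
            indel_pos = positions[n_sub :]
            subs = []
            for p in sub_pos:
                old = ir.sequence[p - 1]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                subs.append((p, old, new))
            planted_indels = []
            for p, (ilen, kind) in zip(indel_pos, indels):
                planted_indels.append((p, ilen, kind))
            sp_truth[label] = {"substitutions": subs, "indels": planted_indels}
            # convert intron coordinates to chromosome plus-strand events
            for ev in _to_chrom_events(ir, subs, planted_indels, rng):
                events_by_chrom.setdefault(ir.source_iv.seq_id, []).append(ev)
        new_genome, new_features = _apply_events(genome, features, events_by_chrom)
        out[species] = (new_genome, new_features)
        truth[species] = sp_truth
    return out, truth


def _to_chrom_events(ir, subs, indels, rng):
    """Map intron-coordinate mutations to plus-strand replacement events
    (start0, end0, replacement) on the source chromosome."""
    iv = ir.source_iv
    L = len(ir.sequence)

    def chrom_pos(p):  # 1-based intron pos -> 0-based plus-strand pos
        if iv.strand == "+":
            return iv.start - 1 + (p - 1)
        return iv.end - 1 - (p - 1)

    events = []
    for p, old, new in subs:
        c = chrom_pos(p)
        if iv.strand == "-":
            from .core import reverse_complement as rc
            new_plus = rc(new)
        else:
            new_plus = new
        events.append((c, c, new_plus))
    for p, ilen, kind in indels:
        if kind == "del":
            p_end = min(p + ilen - 1, L)
            c1, c2 = sorted((chrom_pos(p), chrom_pos(p_end)))
            events.append((c1, c2, ""))
        else:
            ins = random_sequence(np.random.default_rng(int(p) * 7919 + ilen), ilen)
            c = chrom_pos(p)
            events.append((c, c - 1, ins))  # insert before c, delete nothing
    return events


def _apply_events(genome, features, events_by_chrom):
    """Rebuild chromosomes applying replacement events and shifting all
    feature coordinates downstream of each event."""
    new_genome = []
    offsets: dict[str, list[tuple[int, int]]] = {}
    for seq in genome:
        events = sorted(events_by_chrom.get(seq.id, []))
        s = seq.residues
        out = []
        cursor = 0
        shift_points = []  # (plus position after which shift applies, delta)
        delta = 0
        for start0, end0, repl in events:
            out.append(s[cursor:start0])
            out.append(repl)
            removed = end0 - start0 + 1
            delta += len(repl) - removed
            shift_points.append((end0, delta))
            cursor = end0 + 1
        out.append(s[cursor:])
        new_genome.append(CircularSequence(seq.id, "".join(out), seq.circular))
        offsets[seq.id] = shift_points

    def shifted(seq_id, pos):
        d = 0
        for after, delta in offsets.get(seq_id, []):
            if pos > after + 1:  # 1-based position beyond the edited span
                d = delta
        return pos + d

    new_features = [
        replace(
            f,
            interval=GenomeInterval(
                f.seq_id,
                shifted(f.seq_id, f.interval.start),
                shifted(f.seq_id, f.interval.end),
                f.interval.strand,
                f.interval.wraps,
            ),
        )
        for f in features
    ]
    return new_genome, new_features
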