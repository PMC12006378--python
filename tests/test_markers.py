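"""Intron extraction, trio alignment, polymorphic sites, marker regions."""

import numpy as np
import pytest

from mitostruct.core import (
    CircularSequence,
    FeatureRecord,
    GenomeInterval,
    extract_interval,
    reverse_complement,
)
from mitostruct.markers import (
    AnnotationError,
    align_introns,
    build_marker_regions,
    extract_introns,
    find_polymorphic_sites,
)
from mitostruct.simulate import (
    Divergence,
    GeneSpec,
    SimSpec,
    make_genome,
    make_species_trio,
    random_sequence,
)


def _exon(seq_id, gene, rank, start, end, strand="+"):
    return FeatureRecord(
        seq_id, "exon", GenomeInterval(seq_id, start, end, strand), gene, rank
    )


def test_plus_strand_intron_extraction(rng):
    s = random_sequence(rng, 3000)
    genome = [CircularSequence("c", s)]
    feats = [_exon("c", "cox1", 1, 101, 400), _exon("c", "cox1", 2, 1001, 1300)]
    (ir,) = extract_introns(genome, feats)
    assert ir.intron_label == "cox1i12"
    assert ir.sequence == s[400:1000]


def test_minus_strand_intron_is_reverse_complement(rng):
    s = random_sequence(rng, 3000)
    genome = [CircularSequence("c", s)]
    # rank 1 exon downstream on the plus strand for a minus-strand gene
    feats = [
        _exon("c", "nad4", 1, 2001, 2300, "-"),
        _exon("c", "nad4", 2, 1001, 1300, "-"),
    ]
    (ir,) = extract_introns(genome, feats)
    assert ir.intron_label == "nad4i12"
    assert ir.sequence == reverse_complement(s[1300:2000])


def test_single_exon_gene_has_no_introns(rng):
    genome = [CircularSequence("c", random_sequence(rng, 1000))]
    assert extract_introns(genome, [_exon("c", "atp9", 1, 101, 400)]) == []


def test_overlapping_exons_raise(rng):
    genome = [CircularSequence("c", random_sequence(rng, 1000))]
    feats = [_exon("c", "bad", 1, 101, 400), _exon("c", "bad", 2, 300, 600)]
    with pytest.raises(AnnotationError):
        extract_introns(genome, feats)


def test_trans_spliced_gene_skipped(rng):
    genome = [
        CircularSequence("c1", random_sequence(rng, 1000)),
        CircularSequence("c2", random_sequence(rng, 1000)),
    ]
    feats = [_exon("c1", "nad5", 1, 101, 400), _exon("c2", "nad5", 2, 101, 400)]
    assert extract_introns(genome, feats) == []


def test_exons_plus_introns_reconstruct_gene_span(rng):
    spec = SimSpec(
        seed=77, chrom_lengths=(25000,), repeat_specs=[],
        gene_specs=[GeneSpec("nad7", n_exons=4, exon_len=150, intron_len=500)],
    )
    genome, _, feats, truth = make_genome(spec)
    introns = extract_introns(genome, feats)
    assert [ir.intron_label for ir in introns] == ["nad7i12", "nad7i23", "nad7i34"]
    exon_feats = sorted(
        (f for f in feats if f.feature_type == "exon"),
        key=lambda f: f.interval.start,
    )
    parts = []
    items = sorted(
        [(f.interval.start, extract_interval(genome[0], f.interval)) for f in exon_feats]
        + [(ir.source_iv.start, ir.sequence) for ir in introns]
    )
    rebuilt = "".join(s for _, s in items)
    g = truth["genes"][0]
    assert rebuilt == genome[0].residues[g["start"] - 1 : g["end"]]


# ---------------------------------------------------------------------------
# alignment and sites
# ---------------------------------------------------------------------------


def test_identical_sequences_align_gap_free(rng):
    s = random_sequence(rng, 400)
    aln = align_introns({"a": s, "b": s, "c": s})
    assert aln.rows == [s, s, s]
    assert find_polymorphic_sites(aln) == []


def test_single_deletion_gives_single_gap_run(rng):
    s = random_sequence(rng, 1200)
    deleted = s[:600] + s[665:]
    aln = align_introns({"a": s, "b": deleted, "c": s})
    sites = find_polymorphic_sites(aln, "nad2i12")
    assert len(sites) == 1
    site = sites[0]
    assert site.site_type == "indel"
    assert site.column_range[1] - site.column_range[0] + 1 == 65
    assert site.alleles["b"] == ""
    assert site.discriminates == {frozenset(("a", "b")), frozenset(("b", "c"))}


def test_single_substitution_gives_one_snp(rng):
    s = random_sequence(rng, 500)
    mutated = list(s)
    mutated[250] = "A" if s[250] != "A" else "G"
    aln = align_introns({"a": s, "b": "".join(mutated), "c": s})
    sites = find_polymorphic_sites(aln, "x")
    assert len(sites) == 1
    assert sites[0].site_type == "SNP"
    assert sites[0].column_range == (251, 251)


def test_marker_region_geometry(rng):
    s = random_sequence(rng, 2000)
    mutated = list(s)
    mutated[1000] = "A" if s[1000] != "A" else "G"
    aln = align_introns({"a": s, "b": "".join(mutated)})
    sites = find_polymorphic_sites(aln, "x")
    (region,) = build_marker_regions(sites, aln, {"a": s, "b": "".join(mutated)})
    # interior SNP: 300 + 1 + 300
    assert region.end - region.start + 1 == 601
    assert region.sequence == s[region.start - 1 : region.end]


def test_marker_region_clamped_at_intron_start(rng):
    s = random_sequence(rng, 2000)
    mutated = list(s)
    mutated[49] = "A" if s[49] != "A" else "G"
    aln = align_introns({"a": s, "b": "".join(mutated)})
    sites = find_polymorphic_sites(aln, "x")
    (region,) = build_marker_regions(sites, aln, {"a": s, "b": "".join(mutated)})
    assert region.start == 1


def test_nearby_sites_merge_into_one_region(rng):
    s = random_sequence(rng, 3000)
    mutated = list(s)
    for p in (1000, 1100):
        mutated[p] = "A" if s[p] != "A" else "G"
    aln = align_introns({"a": s, "b": "".join(mutated)})
    sites = find_polymorphic_sites(aln, "x")
    regions = build_marker_regions(sites, aln, {"a": s, "b": "".join(mutated)})
    assert len(regions) == 1
    assert len(regions[0].site_indices) == 2


# ---------------------------------------------------------------------------
# species-trio simulation round trip
# ---------------------------------------------------------------------------


def _trio_sites(seed=13):
    spec = SimSpec(
        seed=seed, chrom_lengths=(25000,), repeat_specs=[],
        gene_specs=[GeneSpec("nad2", n_exons=3, exon_len=300, intron_len=1200)],
    )
    genome, _, feats, _ = make_genome(spec)
    divergence = {
        "sp2": Divergence(substitutions={"nad2i12": 3}),
        "sp3": Divergence(substitutions={"nad2i12": 2},
                          indels={"nad2i12": [(65, "del")]}),
    }
    trio, truth = make_species_trio(genome, feats, divergence, seed=seed + 1)
    seqs = {}
    for sp in ("sp1", "sp2", "sp3"):
        g, f = trio[sp]
        recs = {ir.intron_label: ir for ir in extract_introns(g, f, species=sp)}
        seqs[sp] = recs["nad2i12"].sequence
    aln = align_introns(seqs)
    return find_polymorphic_sites(aln, "nad2i12"), seqs, aln


def test_trio_mutation_recovery():
    sites, seqs, aln = _trio_sites()
    snps = [s for s in sites if s.site_type == "SNP"]
    indels = [s for s in sites if s.site_type == "indel"]
    assert len(snps) == 5  # 3 planted in sp2 + 2 in sp3
    assert len(indels) == 1
    assert indels[0].column_range[1] - indels[0].column_range[0] + 1 == 65
    # the union of sites distinguishes all three species
    pairs = set().union(*(s.discriminates for s in sites))
    assert pairs == {
        frozenset(("sp1", "sp2")), frozenset(("sp1", "sp3")), frozenset(("sp2", "sp3")),
    }


def test_zero_divergence_gives_no_sites():
    spec = SimSpec(
        seed=19, chrom_lengths=(20000,), repeat_specs=[],
        gene_specs=[GeneSpec("cox2", n_exons=2, exon_len=300, intron_len=900)],
    )
    genome, _, feats, _ = make_genome(spec)
    trio, _ = make_species_trio(
        genome, feats, {"sp2": Divergence(), "sp3": Divergence()}, seed=20
    )
    seqs = {
        sp: extract_introns(*trio[sp], species=sp)[0].sequence
        for sp in ("sp1", "sp2", "sp3")
    }
    aln = align_introns(seqs)
    assert find_polymorphic_sites(aln) == []
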