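# Methods

## The model

A multichromosomal plant mitogenome is represented as a set of
`CircularSequence` molecules with 1-based inclusive stranded
coordinates; intervals that cross the circular origin carry an explicit
`wraps` flag rather than a start > end encoding, so the normalized form
always has start ≤ end. All sequences are circular by default; linear
mode exists for derived artifacts (configuration references, marker
regions, CDS references). `N` residues participate in extraction but
never count as matches in identity computations.

## Dispersed repeats

Detection is exact-match seed-and-extend: 21-mers indexed over the
doubled string of every circular chromosome (so repeats spanning the
origin are found), extended maximally in both directions, de-duplicated
by diagonal and by rotation, with contained pairs suppressed and
overlapping copies on one molecule rejected (those are tandem, not
dispersed). Defaults: minimum length 50 bp, minimum identity 0.99,
both exposed on the CLI — the upstream tools this emulates do not
publish their thresholds, so reproducing a specific published pair
count on a real assembly is not promised. Identity of a reported pair
is recomputed from the extracted, orientation-adjusted sequences, and a
test asserts it.

SSRs are maximal perfect tandem runs of primitive 1–6 bp units at
per-unit copy thresholds (10, 5, 4, 3, 3, 3). Motifs are canonicalized
to the lexicographically minimal rotation on the plus strand; compound
or interrupted runs are reported as separate perfect runs; overlapping
candidates are resolved longest-first. Circularity is handled by
scanning a tripled string and de-duplicating by start modulo length.

## Four-configuration test

For a repeat with copies X and Y, copy Y's neighborhood is first
re-oriented so its core reads identically to X's (for inverted repeats
this reverse-complements the neighborhood, swapping and complementing
its flanks — exactly what homologous pairing does physically). With
left/right flanks `l`, `r` of each oriented copy:

    c1 = lX + core + rX        c3 = lX + core + rY
    c2 = lY + core + rY        c4 = lY + core + rX

X's plus-strand reading defines the single core string used in all
four references. Flanks default to 1000 bp (2000 bp when re-used for
MTPT junction validation) and are extracted circularly; copies closer
than one flank length on a single molecule produce a recorded
overlapping-flank warning, never silent truncation.

A read supports configuration ci when the region core ± anchor
(default 100 bp into each flank) occurs as an infix of the read (or its
reverse complement) at ≥ 80% identity, computed with edlib semi-global
alignment; the unique best identity wins and ties are unassigned.
Reads that cannot span are unassigned, not partially attributed. The
recombination frequency is pair-based — parental (c1+c2) versus
recombinant (c3+c4) — because only that reading reproduces all three
published frequencies (40.74, 4.26, 0.60) from the published count
quadruples; rounding is decimal half-up to two decimals (1/167 →
0.60).

## Recombination algebra

A genome configuration is a multiset of segment-cycles; repeat copies
are atomic oriented segments, equality of cycles is up to rotation and
up to reversal-with-orientation-flip. Crossover conserves total length
and per-repeat copy number, and its outcome depends only on copy
placement and relative orientation: different circles fuse; direct
copies on one circle fission it; inverted copies on one circle invert
the enclosed arc. The crossover position inside the repeat is
irrelevant at segment level; the test oracle — concrete strings cut at
the repeat midpoint and rejoined with exchanged arms, compared as
canonical circular strings — fixes it at the midpoint and agrees with
the segment algebra on 200 random instances.

Multi-event products apply events sequentially in ascending repeat
rank; the order is recorded because some repeat sets are
order-dependent. Product naming (Mic1, Mic2, …) follows subset
enumeration order: singletons in rank order, then pairs, then the full
set. For the canonical two-chromosome placements (one copy of each of
three repeats per chromosome; two repeats direct, one inverted) the
algebra yields one chromosome for every single- and double-event
product except the direct+direct pair, which restores two chromosomes
— including one chromosome for the inverted+direct pair, where the
narrative this emulates is self-contradictory; we report what the
algebra yields.

## MTPT detection

The seeded homology search runs BLASTn (word size 7, e-value < 1e-6,
both strands) with the mitogenome as query and the plastome as
subject, then filters hits at aligned length ≥ 100 bp and identity
≥ 80% (boundaries inclusive), merges overlapping or abutting mitogenome
intervals into loci, and reports the total as a percentage of both
genome lengths with explicit denominators — the source narrative's
label order for the two percentages conflicts with its printed lengths,
so both fractions are always reported alongside their denominators. A
plastid gene is intact in a locus iff its interval is fully covered by
that locus's plastid footprint (union of its hits' plastid intervals);
partial overlaps are fragments.

## RNA editing

Only coding-strand C→T evidence is a candidate editing event (the
emulated libraries are strand-specific); template-strand G→A evidence
must be strand-resolved upstream. Thresholds are inclusive: coverage
≥ 5 and T-fraction ≥ 0.1, identical for RNA editing calls and for the
genomic SNP calls used to exclude false positives. Codon effects use
the standard genetic code; effects are mutually exclusive
(stop-gain > start-gain > synonymous > nonsynonymous precedence), so
their counts sum to the total and every percentage uses the total as
denominator — published summary percentages are recomputed rather than
copied where the source's own arithmetic is inconsistent. Site names
index the edited base within the CDS (gene-position); the convention in
the emulated tables is internally ambiguous between base and codon
indexing, and base indexing is the documented choice here. The
hydropathy shift counts nonsynonymous changes from the hydrophilic
class into {A, V, L, I, P, F, M, W}; the class table is configurable
because no published scheme is stated.

## Intron markers

Introns are the gaps between consecutive exon ranks of a gene, read on
the coding strand; labels are gene + "i" + rank pair (`nad1i23` =
between exons 2 and 3). Trans-spliced genes (exons on different
molecules) are skipped with a logged notice. Alignment is progressive
center-star: every non-reference species is aligned globally to the
first species (match +2, mismatch −1, gap open −5, gap extend −1,
Bio.Align.PairwiseAligner) and merged on reference coordinates, once a
gap always a gap; guide order is input order, making the result
deterministic. SNP sites are single gap-free polymorphic columns
(adjacent polymorphic columns are separate loci); indel sites are
maximal runs of gap-containing columns. Marker regions expand each
site by 300 bp in the reference species' intron coordinates, clamp at
intron ends, and merge when expansions overlap.

## Synthetic data

The generator emulates the study conditions at desk scale: two circular
chromosomes of 40 kb + 30 kb (≈ 1/5 of the real two-chromosome
assembly, chosen so every stage runs in seconds), background GC 44% to
mirror the reported genome composition, planted dispersed repeats and
plastid-derived blocks at requested identities, multi-exon gene models
placed without overlap, and a diverged species trio whose mutations are
confined to intron interiors (≥ 10 bp apart, 20 bp end margins, room
reserved for the longest indel — including the 65 bp indel the marker
analysis highlights). Long reads use a crude error model — uniform
substitutions plus insertions and deletions each at a quarter of the
substitution rate — adequate for anchor-based spanning classification
but not flowcell-realistic; quality scores are not modeled. Pileups
are per-position binomial draws with background error ≤ 0.01.

What passing tests show — and do not show. Planted-truth recovery
demonstrates correctness of the algorithms under clean, uniform-error
conditions; it does not demonstrate robustness to real long-read
artifacts (homopolymer errors, chimeras), to diverged repeat copies
near the identity threshold, or to annotation errors in real GFF3.
Published-scale results that require the original sequencing data
(total repeat/SSR/MTPT/editing-site counts on the real assembly) are
out of reach at desk scale and are replaced by the property checks in
`tests/test_acceptance.py`.

## Numerical choices

Percentages are decimal round-half-up to two decimals. Classification
ties (equal best identity across configurations) are unassigned.
Degenerate inputs: empty read sets give all-zero counts; a zero
classified total makes the frequency an error, not 0; empty site lists
give all-zero summaries; zero-length FASTA records are format errors.
E-value calibration inside BLASTn uses its stock nucleotide parameters.
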