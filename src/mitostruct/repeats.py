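"""Dispersed repeat pairs and simple sequence repeats on circular genomes.

Dispersed repeats are the recombination substrate of plant mitogenomes:
two near-identical copies, on the same or different chromosomes, in
direct or inverted relative orientation.  Detection here is exact-match
seed-and-extend over the doubled sequence of each circular chromosome
(so repeats crossing the origin are found), with an optional
mismatch-tolerant extension bounded by a minimum identity.

SSRs are maximal perfect tandem runs of 1-6 bp motifs above per-unit
copy-number thresholds (MISA-style: 10/5/4/3/3/3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    CircularSequence,
    GenomeInterval,
    circular_interval,
    extract_interval,
    reverse_complement,
)

DEFAULT_MIN_LEN = 50
DEFAULT_MIN_IDENTITY = 0.99
SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

_SEED_K = 21


@dataclass(frozen=True)
class RepeatPair:
    """Two genome intervals carrying near-identical sequence."""

    repeat_id: str
    copy1: GenomeInterval
    copy2: GenomeInterval
    core_length: int
    identity: float
    orientation: str  # "direct" | "inverted"


@dataclass(frozen=True)
class SSRRecord:
    interval: GenomeInterval
    motif: str
    unit_length: int
    copies: int


def sequence_identity(a: str, b: str) -> float:
    """Column identity of two equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("identity requires equal-length sequences")
    if not a:
        return 0.0
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != "N"
    )
    return matches / len(a)


def _covered(iv: GenomeInterval, n: int) -> set[int]:
    return set(iv.positions(n))


def find_dispersed_repeats(
    genome: list[CircularSequence],
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[RepeatPair]:
    """All maximal repeated pairs >= min_len within and between chromosomes.

    Both orientations are reported; trivial self-matches and overlapping
    copies on one molecule are excluded.  Output order and R-numbering
    are deterministic: decreasing core length, then coordinates.
    """
    if not genome:
        raise ValueError("empty genome")
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    if not (0.8 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0.8, 1.0]")

    k = min(_SEED_K, min_len)
    # k-mer index over each chromosome's doubled string (seed starts < L)
    index: dict[str, list[tuple[int, int]]] = {}
    doubled: list[str] = []
    lengths: list[int] = []
    rcdoubled: list[str] = []
    for si, seq in enumerate(genome):
        s2 = seq.residues + (seq.residues if seq.circular else "")
        doubled.append(s2)
        rcdoubled.append(reverse_complement(s2))
        lengths.append(len(seq))
        for p in range(len(seq)):
            kmer = s2[p : p + k]
            if len(kmer) < k or "N" in kmer:
                continue
            index.setdefault(kmer, []).append((si, p))

    raw: set[tuple] = set()
    done_diagonals: set[tuple] = set()
    for si, seq in enumerate(genome):
        s2 = doubled[si]
        L = lengths[si]
        for p in range(L):
            kmer = s2[p : p + k]
            if len(kmer) < k or "N" in kmer:
                continue
            for orient, probe in (("direct", kmer), ("inverted", reverse_complement(kmer))):
                for sj, q in index.get(probe, ()):
                    if sj < si:
                        continue  # symmetric; handled from the other side
                    # target-strand coordinate of the seed on molecule j:
                    # forward string for direct, reverse complement for inverted
                    qt = q if orient == "direct" else len(doubled[sj]) - q - k
                    diag = (si, sj, orient, p - qt)
                    if diag in done_diagonals:
                        continue
                    done_diagonals.add(diag)
                    tb = doubled[sj] if orient == "direct" else rcdoubled[sj]
                    hit = _extend_seed(
                        doubled[si], lengths[si], p,
                        tb, len(doubled[sj]), lengths[sj], qt,
                        k, orient, same_mol=(si == sj),
                    )
                    if hit is None:
                        continue
                    a_start, b_start, length = hit
                    if length < min_len:
                        continue
                    key = _normalize_pair(si, a_start, sj, b_start, length,
                                          orient, lengths)
                    if key is not None:
                        raw.add(key)

    pairs = _materialize(raw, genome, min_identity)
    pairs = _suppress_contained(pairs, genome)
    pairs.sort(
        key=lambda pr: (
            -pr.core_length,
            pr.copy1.seq_id,
            pr.copy1.start,
            pr.copy2.seq_id,
            pr.copy2.start,
        )
    )
    width = max(2, len(str(len(pairs))))
    return [
        RepeatPair(f"R{i + 1:0{width}d}", p.copy1, p.copy2, p.core_length,
                   p.identity, p.orientation)
        for i, p in enumerate(pairs)
    ]


def _extend_seed(sa, La, p, tb, tb_len, Lb, q, k, orient, same_mol):
    """Maximal exact extension of a seed match; returns (a0, b0, len) with
    0-based starts on the plus strand of each molecule, or None.

    ``tb`` is the target strand: b's doubled string for direct matches,
    its reverse complement for inverted ones; ``q`` indexes into it.
    """
    if orient == "direct" and same_mol and p == q:
        return None
    cap = min(La, Lb)
    # extend right
    r = k
    while r < cap and p + r < len(sa) and q + r < len(tb) and sa[p + r] == tb[q + r] and sa[p + r] != "N":
        r += 1
    # extend left
    l = 0
    while r + l < cap and p - l - 1 >= 0 and q - l - 1 >= 0 and sa[p - l - 1] == tb[q - l - 1] and sa[p - l - 1] != "N":
        l += 1
    length = r + l
    a0 = p - l
    tb0 = q - l
    if orient == "direct":
        b0 = tb0
    else:
        # map the tb interval [tb0, tb0+length-1] back to b's plus strand
        b0 = tb_len - 1 - (tb0 + length - 1)
    return a0, b0, length


def _normalize_pair(si, a0, sj, b0, length, orient, lengths):
    """Canonical key for a pair: starts taken mod molecule length, copies
    ordered, trivial/overlapping pairs rejected."""
    La, Lb = lengths[si], lengths[sj]
    a = a0 % La
    b = b0 % Lb
    if si == sj:
        if a == b:
            return None
        # overlap on one molecule => not a dispersed pair
        ia = {x % La for x in range(a, a + length)}
        ib = {x % Lb for x in range(b, b + length)}
        if ia & ib:
            return None
        if b < a:
            a, b = b, a
    return (si, a, sj, b, length, orient)


def _materialize(raw, genome, min_identity):
    out = []
    for si, a, sj, b, length, orient in raw:
        c1 = circular_interval(genome[si], a, length, "+")
        strand2 = "+" if orient == "direct" else "-"
        c2 = circular_interval(genome[sj], b, length, strand2)
        s1 = extract_interval(genome[si], c1)
        s2 = extract_interval(genome[sj], c2)
        ident = sequence_identity(s1, s2)
        if ident >= min_identity:
            out.append(RepeatPair("", c1, c2, length, ident, orient))
    return out


def _suppress_contained(pairs, genome):
    """Drop pairs whose both copies lie within another pair's copies."""
    lens = {s.id: len(s) for s in genome}
    kept = []
    for p in pairs:
        contained = False
        for q in pairs:
            if q is p or q.core_length <= p.core_length or q.orientation != p.orientation:
                continue
            if (
                p.copy1.seq_id == q.copy1.seq_id
                and p.copy2.seq_id == q.copy2.seq_id
                and _covered(p.copy1, lens[p.copy1.seq_id]) <= _covered(q.copy1, lens[q.copy1.seq_id])
                and _covered(p.copy2, lens[p.copy2.seq_id]) <= _covered(q.copy2, lens[q.copy2.seq_id])
            ):
                contained = True
                break
        if not contained:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def canonical_motif(unit: str) -> str:
    """Lexicographically minimal rotation of the repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_ssrs(
    genome: list[CircularSequence],
    thresholds: dict[int, int] | None = None,
) -> list[SSRRecord]:
    """Maximal perfect tandem runs of 1-6 bp units meeting their threshold.

    Motifs are reported in canonical (minimal-rotation) form on the plus
    strand; reported SSRs never overlap (longer runs win ties).
    """
    thresholds = dict(SSR_THRESHOLDS if thresholds is None else thresholds)
    missing = [u for u in range(1, 7) if u not in thresholds]
    if missing:
        raise ValueError(f"thresholds missing unit lengths {missing}")

    records: list[SSRRecord] = []
    for seq in genome:
        L = len(seq)
        if seq.circular:
            s3 = seq.residues * 3
            off = L
        else:
            s3 = seq.residues
            off = 0
        candidates = []
        for u in range(1, 7):
            for p in range(off, off + L):
                if p - u >= 0 and p + u <= len(s3) and s3[p - u : p] == s3[p : p + u]:
                    continue  # not a run start
                unit = s3[p : p + u]
                if len(unit) < u or "N" in unit or not _is_primitive(unit):
                    continue
                # count tandem copies forward, capped at the molecule length
                copies = 1
                while (
                    copies * u < L
                    and p + (copies + 1) * u <= len(s3)
                    and s3[p + copies * u : p + (copies + 1) * u] == unit
                ):
                    copies += 1
                if copies >= thresholds[u]:
                    candidates.append((p - off, u, copies, unit))
        # de-duplicate runs seen from multiple circular offsets
        seen = set()
        uniq = []
        for p0, u, copies, unit in candidates:
            key = (p0 % L, u, copies)
            if key not in seen:
                seen.add(key)
                uniq.append((p0 % L, u, copies, unit))
        # greedy non-overlap: longest first, then left-most
        uniq.sort(key=lambda c: (-c[1] * c[2], c[0]))
        taken: set[int] = set()
        chosen = []
        for p0, u, copies, unit in uniq:
            span = {x % L for x in range(p0, p0 + u * copies)}
            if span & taken:
                continue
            taken |= span
            chosen.append((p0, u, copies, unit))
        for p0, u, copies, unit in sorted(chosen):
            iv = circular_interval(seq, p0, u * copies, "+")
            records.append(SSRRecord(iv, canonical_motif(unit), u, copies))
    records.sort(key=lambda r: (r.interval.seq_id, r.interval.start))
    return records
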