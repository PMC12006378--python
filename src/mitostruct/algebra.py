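"""Segment-cycle algebra of repeat-mediated recombination.

A genome configuration is a multiset of circular chromosomes, each a
cyclic list of oriented segments (unique arcs and atomic repeat copies).
Crossover inside a shared repeat has three outcomes, all length- and
copy-conserving:

* copies on two different circles        -> the circles fuse into one;
* copies on one circle, direct relative  -> the circle fissions in two,
  orientation                                each keeping one copy;
* copies on one circle, inverted         -> one circle, the arc between
  relative orientation                       the copies reverse-complemented.

Enumerating products over all non-empty subsets of the recombinogenic
repeats reproduces the major/minor configuration families (one major
two-chromosome arrangement and its seven single/double/triple-event
derivatives, in the three-repeat case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations


@dataclass(frozen=True)
class OrientedSegment:
    segment_id: str
    orientation: str  # "+" | "-"
    length: int
    kind: str = "unique_arc"  # or "repeat_copy"
    repeat_id: str | None = None

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be + or -")
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        if self.kind == "repeat_copy" and not self.repeat_id:
            raise ValueError("repeat_copy segments need a repeat_id")

    def flipped(self) -> "OrientedSegment":
        return OrientedSegment(
            self.segment_id,
            "-" if self.orientation == "+" else "+",
            self.length,
            self.kind,
            self.repeat_id,
        )


class EventError(ValueError):
    """Recombination event references copies absent from the configuration."""


@dataclass(frozen=True)
class SegmentCycle:
    """A circular chromosome: segments in cyclic order.

    Equality is up to rotation and up to reading the circle on the other
    strand (reversal with all orientations flipped).
    """

    segments: tuple[OrientedSegment, ...]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("a cycle must contain at least one segment")

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def rotated(self, i: int) -> tuple[OrientedSegment, ...]:
        return self.segments[i:] + self.segments[:i]

    def reversed_flipped(self) -> tuple[OrientedSegment, ...]:
        return tuple(s.flipped() for s in reversed(self.segments))

    def canonical(self) -> tuple:
        def key(segs):
            return tuple((s.segment_id, s.orientation, s.length, s.kind, s.repeat_id) for s in segs)

        forms = [key(self.rotated(i)) for i in range(len(self.segments))]
        rf = SegmentCycle(self.reversed_flipped())
        forms += [key(rf.rotated(i)) for i in range(len(rf.segments))]
        return min(forms)


def cycles_equal(a: SegmentCycle, b: SegmentCycle) -> bool:
    return a.canonical() == b.canonical()


@dataclass
class GenomeConfiguration:
    name: str
    circles: list[SegmentCycle] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.circles)

    @property
    def n_chromosomes(self) -> int:
        return len(self.circles)

    def repeat_copy_count(self, repeat_id: str) -> int:
        return sum(
            1
            for c in self.circles
            for s in c.segments
            if s.kind == "repeat_copy" and s.repeat_id == repeat_id
        )

    def canonical(self) -> tuple:
        return tuple(sorted(c.canonical() for c in self.circles))


@dataclass(frozen=True)
class RecombinationEvent:
    repeat_id: str
    # optional disambiguation when a repeat has > 2 copies:
    # (circle_index, segment_index) of each copy in the configuration
    copy_pair: tuple[tuple[int, int], tuple[int, int]] | None = None


def _locate_copies(cfg: GenomeConfiguration, ev: RecombinationEvent):
    if ev.copy_pair is not None:
        return list(ev.copy_pair)
    found = [
        (ci, si)
        for ci, cyc in enumerate(cfg.circles)
        for si, seg in enumerate(cyc.segments)
        if seg.kind == "repeat_copy" and seg.repeat_id == ev.repeat_id
    ]
    if len(found) < 2:
        raise EventError(f"repeat {ev.repeat_id!r} has {len(found)} copies")
    if len(found) > 2:
        raise EventError(
            f"repeat {ev.repeat_id!r} has {len(found)} copies; "
            "specify copy_pair explicitly"
        )
    return found


def _orient_at(segments: tuple[OrientedSegment, ...], idx: int):
    """Rotate so idx is first; if that copy reads '-', flip the circle."""
    cyc = SegmentCycle(segments)
    segs = cyc.rotated(idx)
    if segs[0].orientation == "-":
        segs = SegmentCycle(segs).reversed_flipped()
        # reversal puts the copy last; rotate it to front
        segs = (segs[-1],) + segs[:-1]
    return segs


def apply_event(cfg: GenomeConfiguration, ev: RecombinationEvent) -> GenomeConfiguration:
    """Crossover within the repeat: cut both molecules inside the copy and
    rejoin with exchanged arms.  Both copies persist; total length and
    per-repeat copy numbers are conserved."""
    (ci, si), (cj, sj) = _locate_copies(cfg, ev)
    others = [c for k, c in enumerate(cfg.circles) if k not in (ci, cj)]

    if ci != cj:
        # fusion: orient both copies forward, concatenate at the copies
        a = _orient_at(cfg.circles[ci].segments, si)
        b = _orient_at(cfg.circles[cj].segments, sj)
        fused = SegmentCycle(a + b)
        return GenomeConfiguration(cfg.name, others + [fused])

    segs = cfg.circles[ci].segments
    n = len(segs)
    # normalize: pivot copy first and reading '+', tracking the partner index
    if segs[si].orientation == "-":
        segs = SegmentCycle(segs).reversed_flipped()
        si, sj = n - 1 - si, n - 1 - sj
    offset = (sj - si) % n
    segs = SegmentCycle(segs).rotated(si)
    copy2 = segs[offset]
    arc_a = segs[1:offset]
    arc_b = segs[offset + 1 :]
    if copy2.orientation == "+":
        # direct: fission into two circles, one copy each
        left = SegmentCycle((segs[0],) + arc_a)
        right = SegmentCycle((copy2,) + arc_b)
        return GenomeConfiguration(cfg.name, others + [left, right])
    # inverted: single circle with the enclosed arc reverse-complemented
    inverted_arc = tuple(s.flipped() for s in reversed(arc_a))
    new = SegmentCycle((segs[0],) + inverted_arc + (copy2,) + arc_b)
    return GenomeConfiguration(cfg.name, others + [new])


def configuration_from_repeats(genome, repeat_pairs, name="Mac1") -> GenomeConfiguration:
    """Factor a genome into segment cycles around its repeat copies.

    Each chromosome becomes one cycle: repeat copies (atomic segments,
    oriented by their interval strand) separated by unique arcs named
    ``<chrom>.a<i>``.  Wrapping repeat copies are not supported here;
    rotate the assembly origin first.
    """
    copies: dict[str, list] = {s.id: [] for s in genome}
    for pair in repeat_pairs:
        for copy in (pair.copy1, pair.copy2):
            if copy.wraps:
                raise ValueError(
                    f"repeat copy of {pair.repeat_id} wraps the origin; "
                    "rotate the assembly first"
                )
            copies[copy.seq_id].append((copy.start, copy.end, copy.strand, pair))
    circles = []
    for seq in genome:
        placed = sorted(copies[seq.id])
        segments: list[OrientedSegment] = []
        prev_end = 0
        for i, (start, end, strand, pair) in enumerate(placed):
            if start <= prev_end:
                raise ValueError(f"overlapping repeat copies on {seq.id}")
            arc_len = start - prev_end - 1
            if arc_len > 0:
                segments.append(
                    OrientedSegment(f"{seq.id}.a{i}", "+", arc_len)
                )
            segments.append(
                OrientedSegment(
                    f"{pair.repeat_id}@{seq.id}:{start}",
                    strand,
                    end - start + 1,
                    kind="repeat_copy",
                    repeat_id=pair.repeat_id,
                )
            )
            prev_end = end
        tail = len(seq) - prev_end
        if tail > 0:
            segments.append(OrientedSegment(f"{seq.id}.a{len(placed)}", "+", tail))
        if not segments:
            segments = [OrientedSegment(f"{seq.id}.a0", "+", len(seq))]
        circles.append(SegmentCycle(tuple(segments)))
    return GenomeConfiguration(name, circles)


def enumerate_products(
    baseline: GenomeConfiguration, repeat_ids: list[str]
) -> dict[tuple[str, ...], GenomeConfiguration]:
    """Products of every non-empty repeat subset, events applied in
    ascending repeat rank; names Mic1, Mic2, ... in subset order
    ({R1},{R2},{R3},{R1,R2},{R1,R3},{R2,R3},{R1,R2,R3} for three)."""
    for rid in repeat_ids:
        if baseline.repeat_copy_count(rid) < 2:
            raise EventError(f"repeat {rid!r} not paired in baseline")
    ordered = sorted(repeat_ids)
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(ordered) + 1):
        subsets.extend(combinations(ordered, size))
    out: dict[tuple[str, ...], GenomeConfiguration] = {}
    for i, subset in enumerate(subsets, start=1):
        cfg = GenomeConfiguration(f"Mic{i}", list(baseline.circles))
        for rid in subset:  # ascending rank within the subset
            cfg = apply_event(cfg, RecombinationEvent(rid))
        cfg.name = f"Mic{i}"
        out[subset] = cfg
    return out
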