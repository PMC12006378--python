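"""Spanning-read classification over c1-c4 and the recombination frequency.

A long read supports a configuration only if it covers the entire repeat
core plus a minimum anchor into both flanks at a minimum identity, with
a unique best alignment among the four references ("repeat-spanning
reads").  The recombination frequency is the share of spanning reads
supporting the minority configuration pair: parental (c1+c2) versus
recombinant (c3+c4).

The alignment backend is edlib in infix (semi-global) mode: the
core-plus-anchors region of each reference is located inside the read,
and identity is one minus the edit distance over the region length.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .configurations import ConfigurationSet
from .core import reverse_complement, round_half_up

CONFIG_LABELS = ("c1", "c2", "c3", "c4")


@dataclass(frozen=True)
class SpanningCriterion:
    min_flank_anchor: int = 100  # bp into each flank beyond the core
    min_identity: float = 0.80
    require_unique_best: bool = True


@dataclass
class SupportCounts:
    repeat_id: str
    n1: int = 0
    n2: int = 0
    n3: int = 0
    n4: int = 0
    n_unassigned: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n1, self.n2, self.n3, self.n4)


@dataclass(frozen=True)
class RecombFrequency:
    repeat_id: str
    percent: float  # minority pair over all classified reads, in [0, 50]
    minority_pair: str  # "parental" (c1+c2) or "recombinant" (c3+c4)


class UndefinedStatisticError(ValueError):
    """No classified reads: the recombination frequency is undefined."""


def _span_region(cfg: ConfigurationSet, anchor: int) -> tuple[int, int]:
    """0-based [start, end) of core plus anchors within each reference."""
    if anchor > cfg.flank_len:
        raise ValueError(
            f"min_flank_anchor {anchor} exceeds flank_len {cfg.flank_len}"
        )
    start = cfg.flank_len - anchor
    end = cfg.flank_len + cfg.core_length + anchor
    return start, end


def classify_read(
    read: str,
    cfg: ConfigurationSet,
    crit: SpanningCriterion = SpanningCriterion(),
) -> str:
    """Label a read c1/c2/c3/c4 or 'unassigned'.

    The read (or its reverse complement) must contain the reference's
    core-plus-anchor region as an infix at >= min_identity; the unique
    best-scoring configuration wins, ties are unassigned.
    """
    if not read:
        raise ValueError("empty read")
    start, end = _span_region(cfg, crit.min_flank_anchor)
    rc = reverse_complement(read)
    best: list[tuple[float, str]] = []
    for label, ref in cfg.sequences().items():
        region = ref[start:end]
        if len(region) > len(read):
            continue  # read cannot span
        max_dist = int(len(region) * (1.0 - crit.min_identity))
        dist = None
        for target in (read, rc):
            res = edlib.align(region, target, mode="HW", task="distance", k=max_dist)
            d = res["editDistance"]
            if d != -1 and (dist is None or d < dist):
                dist = d
        if dist is None:
            continue
        identity = 1.0 - dist / len(region)
        if identity >= crit.min_identity:
            best.append((identity, label))
    if not best:
        return "unassigned"
    best.sort(key=lambda t: (-t[0], t[1]))
    if crit.require_unique_best and len(best) > 1 and best[0][0] == best[1][0]:
        return "unassigned"
    return best[0][1]


def count_support(
    reads,
    cfg: ConfigurationSet,
    crit: SpanningCriterion = SpanningCriterion(),
) -> SupportCounts:
    """Tally classify_read over reads ((id, seq) pairs or bare strings)."""
    counts = SupportCounts(repeat_id=cfg.repeat.repeat_id)
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read
        label = classify_read(seq, cfg, crit)
        if label == "c1":
            counts.n1 += 1
        elif label == "c2":
            counts.n2 += 1
        elif label == "c3":
            counts.n3 += 1
        elif label == "c4":
            counts.n4 += 1
        else:
            counts.n_unassigned += 1
    return counts


def recombination_frequency(counts: SupportCounts) -> RecombFrequency:
    """Minority-pair share of classified reads, as a percentage.

    parental = n1 + n2, recombinant = n3 + n4;
    percent = 100 * min(parental, recombinant) / (parental + recombinant),
    rounded half-up to two decimals.  Unassigned reads are excluded from
    the denominator.
    """
    parental = counts.n1 + counts.n2
    recombinant = counts.n3 + counts.n4
    total = parental + recombinant
    if total == 0:
        raise UndefinedStatisticError(
            f"no classified reads for {counts.repeat_id!r}"
        )
    minority = "parental" if parental <= recombinant else "recombinant"
    percent = round_half_up(100.0 * min(parental, recombinant) / total)
    return RecombFrequency(counts.repeat_id, percent, minority)
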