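"""Four-configuration reference construction around a repeat pair.

A dispersed repeat with copies on two genomic contexts admits four local
arrangements of (left flank, core, right flank): the two as-assembled
parental contexts c1 and c2, and the two flank-switched recombinant
contexts c3 and c4.  Long reads spanning the core plus both flanks can
then vote between them (see ``read_support``).

The core is always read on copy1's plus strand.  For an inverted repeat
the neighborhood of copy2 is reverse-complemented first, so that its
core reads identically to copy1's; this swaps and complements copy2's
flanks, which is exactly what homologous pairing does physically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    CircularSequence,
    CoordinateError,
    GenomeInterval,
    TopologyError,
    circular_interval,
    extract_interval,
)
from .repeats import RepeatPair

DEFAULT_FLANK = 1000
MTPT_FLANK = 2000  # junction validation around plastid-derived insertions


@dataclass
class ConfigurationSet:
    """The four reference sequences c1-c4 around one repeat."""

    repeat: RepeatPair
    flank_len: int
    c1: str
    c2: str
    c3: str
    c4: str
    provenance: dict = field(default_factory=dict)

    def sequences(self) -> dict[str, str]:
        return {"c1": self.c1, "c2": self.c2, "c3": self.c3, "c4": self.c4}

    @property
    def core_length(self) -> int:
        return self.repeat.core_length


def _oriented_context(
    seq: CircularSequence, copy: GenomeInterval, flank_len: int
) -> tuple[str, str, str]:
    """(left flank, core, right flank) reading the copy 5'->3' on its strand.

    Flanks are extracted circularly.  For a minus-strand copy the reading
    direction is reversed, so the left flank in reading order is the
    reverse complement of the downstream plus-strand neighborhood.
    """
    n = len(seq)
    core = extract_interval(seq, copy)
    span = copy.span(n)
    start0 = copy.start - 1
    if copy.strand == "+":
        left = extract_interval(seq, circular_interval(seq, start0 - flank_len, flank_len, "+"))
        right = extract_interval(seq, circular_interval(seq, start0 + span, flank_len, "+"))
    else:
        left = extract_interval(seq, circular_interval(seq, start0 + span, flank_len, "-"))
        right = extract_interval(seq, circular_interval(seq, start0 - flank_len, flank_len, "-"))
    return left, core, right


def build_configurations(
    genome: list[CircularSequence],
    repeat: RepeatPair,
    flank_len: int = DEFAULT_FLANK,
) -> ConfigurationSet:
    """Build c1/c2 (parental) and c3/c4 (flank-switched recombinant).

    c3 = left(copy1) + core + right(copy2); c4 = left(copy2) + core +
    right(copy1).  All four share the identical core string (copy1's
    reading).  Overlapping-flank situations (copies closer than
    flank_len on one molecule) are recorded in provenance, never
    truncated.
    """
    if flank_len < 1:
        raise ValueError("flank_len must be >= 1")
    by_id = {s.id: s for s in genome}
    try:
        seq1 = by_id[repeat.copy1.seq_id]
        seq2 = by_id[repeat.copy2.seq_id]
    except KeyError as e:
        raise CoordinateError(f"repeat references unknown molecule {e}") from e
    for seq in (seq1, seq2):
        if flank_len >= len(seq):
            raise TopologyError(
                f"flank_len {flank_len} >= molecule {seq.id!r} length {len(seq)}"
            )

    l1, core, r1 = _oriented_context(seq1, repeat.copy1, flank_len)
    l2, _core2, r2 = _oriented_context(seq2, repeat.copy2, flank_len)
    # copy1's plus-strand reading defines the single core used in all four
    # references; for near-identical copies _core2 may differ by a few bases.

    provenance = {
        "c1": ("copy1", "copy1"),
        "c2": ("copy2", "copy2"),
        "c3": ("copy1", "copy2"),
        "c4": ("copy2", "copy1"),
        "warnings": [],
    }
    if repeat.copy1.seq_id == repeat.copy2.seq_id:
        n = len(seq1)
        covered1 = set(repeat.copy1.positions(n))
        covered2 = set(repeat.copy2.positions(n))
        gap = min(
            _circular_gap(repeat.copy1, repeat.copy2, n),
            _circular_gap(repeat.copy2, repeat.copy1, n),
        )
        if gap < flank_len or covered1 & covered2:
            provenance["warnings"].append(
                "flanks overlap the partner copy on the same molecule"
            )

    return ConfigurationSet(
        repeat=repeat,
        flank_len=flank_len,
        c1=l1 + core + r1,
        c2=l2 + core + r2,
        c3=l1 + core + r2,
        c4=l2 + core + r1,
        provenance=provenance,
    )


def _circular_gap(a: GenomeInterval, b: GenomeInterval, n: int) -> int:
    """Plus-strand distance from the end of a forward to the start of b."""
    return (b.start - a.end - 1) % n


def write_configuration_fasta(cfg: ConfigurationSet, path) -> None:
    with open(path, "w") as fh:
        for name, seq in cfg.sequences().items():
            fh.write(f">{cfg.repeat.repeat_id}_{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
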