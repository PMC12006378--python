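"""Segment-cycle recombination algebra vs an independent string-surgery oracle.

The oracle realizes each circle as a concrete DNA string, performs the
crossover by cutting both repeat copies at their midpoint and rejoining
with exchanged arms (pure string surgery), and compares the resulting
molecules as canonical circular strings (minimum over all rotations of
the sequence and its reverse complement).
"""

import numpy as np
import pytest

from mitostruct.algebra import (
    EventError,
    GenomeConfiguration,
    OrientedSegment,
    RecombinationEvent,
    SegmentCycle,
    apply_event,
    configuration_from_repeats,
    cycles_equal,
    enumerate_products,
)
from mitostruct.core import reverse_complement
from mitostruct.simulate import random_sequence


def seg(sid, orient="+", length=50):
    return OrientedSegment(sid, orient, length)


def rep(rid, orient="+", length=40, tag=""):
    return OrientedSegment(f"{rid}{tag}", orient, length, "repeat_copy", rid)


# ---------------------------------------------------------------------------
# cycles_equal
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,equal",
    [
        ((("X", "+"), ("Y", "+"), ("Z", "+")), (("Y", "+"), ("Z", "+"), ("X", "+")), True),
        ((("X", "+"), ("Y", "+")), (("Y", "-"), ("X", "-")), True),
        ((("X", "+"), ("Y", "+")), (("X", "+"), ("Y", "-")), False),
    ],
)
def test_cycles_equal(a, b, equal):
    ca = SegmentCycle(tuple(seg(s, o) for s, o in a))
    cb = SegmentCycle(tuple(seg(s, o) for s, o in b))
    assert cycles_equal(ca, cb) is equal


# ---------------------------------------------------------------------------
# string-surgery oracle
# ---------------------------------------------------------------------------


def canonical_circle(s):
    cands = [s[i:] + s[:i] for i in range(len(s))]
    rc = reverse_complement(s)
    cands += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(cands)


def realize(cfg, seqs):
    """Concrete strings per circle plus repeat-copy locations.

    ``seqs`` maps arc segment_id / repeat_id -> plus-strand sequence.
    Returns [(string, {repeat_id: [(start, end, strand), ...]}), ...].
    """
    out = []
    for cyc in cfg.circles:
        s = []
        locs = {}
        pos = 0
        for sg in cyc.segments:
            raw = seqs[sg.repeat_id if sg.kind == "repeat_copy" else sg.segment_id]
            piece = raw if sg.orientation == "+" else reverse_complement(raw)
            if sg.kind == "repeat_copy":
                locs.setdefault(sg.repeat_id, []).append(
                    (pos, pos + len(piece), sg.orientation)
                )
            s.append(piece)
            pos += len(piece)
        out.append(("".join(s), locs))
    return out


def surgery(realized, repeat_id, rep_len):
    """Perform the crossover on strings; returns the new list of strings."""
    m = rep_len // 2
    carrying = [
        (i, loc) for i, (s, locs) in enumerate(realized)
        for loc in locs.get(repeat_id, [])
    ]
    assert len(carrying) == 2
    (i1, (a1, b1, o1)), (i2, (a2, b2, o2)) = carrying
    passthrough = [s for k, (s, _) in enumerate(realized) if k not in (i1, i2)]

    def cut_point(start, end, orient):
        # midpoint measured along the copy's own reading direction
        return start + m if orient == "+" else end - m

    if i1 != i2:
        s1, s2 = realized[i1][0], realized[i2][0]
        c1 = cut_point(a1, b1, o1)
        c2 = cut_point(a2, b2, o2)
        r1 = s1[c1:] + s1[:c1]
        r2 = s2[c2:] + s2[:c2]
        if o1 != o2:
            r2 = reverse_complement(r2)
        return passthrough + [r1 + r2]

    s = realized[i1][0]
    c1 = cut_point(a1, b1, o1)
    c2 = cut_point(a2, b2, o2)
    c1, o_first = (c1, o1) if c1 < c2 else (c2, o2)
    c2, o_second = (max(cut_point(a1, b1, o1), cut_point(a2, b2, o2)),
                    o2 if cut_point(a1, b1, o1) < cut_point(a2, b2, o2) else o1)
    if o_first == o_second:
        # direct: fission into two circles
        return passthrough + [s[c1:c2], s[c2:] + s[:c1]]
    # inverted: invert the substring between the cut points
    return passthrough + [s[:c1] + reverse_complement(s[c1:c2]) + s[c2:]]


def assert_agrees_with_oracle(cfg, event, seqs, rep_len):
    result = apply_event(cfg, event)
    got = sorted(
        canonical_circle(s) for s, _ in realize(result, seqs)
    )
    expected = sorted(
        canonical_circle(s)
        for s in surgery(realize(cfg, seqs), event.repeat_id, rep_len)
    )
    assert got == expected


# ---------------------------------------------------------------------------
# worked cases
# ---------------------------------------------------------------------------


def _seqs(rng, cfg, rep_lens):
    seqs = {}
    for cyc in cfg.circles:
        for sg in cyc.segments:
            key = sg.repeat_id if sg.kind == "repeat_copy" else sg.segment_id
            if key not in seqs:
                seqs[key] = random_sequence(rng, sg.length)
    return seqs


def test_fusion_of_two_circles():
    cfg = GenomeConfiguration("b", [
        SegmentCycle((rep("R", tag="1"), seg("A", length=500))),
        SegmentCycle((rep("R", tag="2"), seg("B", length=700))),
    ])
    out = apply_event(cfg, RecombinationEvent("R"))
    assert out.n_chromosomes == 1
    assert out.total_length == cfg.total_length
    expected = SegmentCycle(
        (rep("R", tag="1"), seg("A", length=500), rep("R", tag="2"), seg("B", length=700))
    )
    assert cycles_equal(out.circles[0], expected)


def test_fission_of_direct_copies():
    cfg = GenomeConfiguration("b", [SegmentCycle(
        (rep("R", tag="1"), seg("A", length=500), rep("R", tag="2"), seg("B", length=700))
    )])
    out = apply_event(cfg, RecombinationEvent("R"))
    assert out.n_chromosomes == 2
    assert sorted(c.length for c in out.circles) == [540, 740]
    assert out.total_length == cfg.total_length


def test_inversion_of_inverted_copies():
    cfg = GenomeConfiguration("b", [SegmentCycle(
        (rep("R", tag="1"), seg("A", length=500),
         rep("R", "-", tag="2"), seg("B", length=700))
    )])
    out = apply_event(cfg, RecombinationEvent("R"))
    assert out.n_chromosomes == 1
    assert out.total_length == cfg.total_length
    arc_a = [s for c in out.circles for s in c.segments if s.segment_id == "A"]
    assert arc_a[0].orientation == "-"  # enclosed arc reverse-complemented


@pytest.mark.parametrize("case", ["fusion", "fission", "inversion"])
def test_worked_cases_match_string_surgery(case, rng):
    if case == "fusion":
        cfg = GenomeConfiguration("b", [
            SegmentCycle((rep("R", tag="1"), seg("A", length=300))),
            SegmentCycle((rep("R", "-", tag="2"), seg("B", length=400))),
        ])
    elif case == "fission":
        cfg = GenomeConfiguration("b", [SegmentCycle(
            (rep("R", tag="1"), seg("A", length=300), rep("R", tag="2"), seg("B", length=400))
        )])
    else:
        cfg = GenomeConfiguration("b", [SegmentCycle(
            (rep("R", tag="1"), seg("A", length=300),
             rep("R", "-", tag="2"), seg("B", length=400))
        )])
    seqs = _seqs(rng, cfg, {})
    assert_agrees_with_oracle(cfg, RecombinationEvent("R"), seqs, 40)


def test_random_instances_match_string_surgery():
    """Segment algebra agrees with string surgery on 200 random instances."""
    rng = np.random.default_rng(777)
    for trial in range(200):
        n_circles = int(rng.integers(1, 3))
        rep_len = int(rng.integers(20, 60)) * 2
        placements = [[] for _ in range(n_circles)]
        homes = rng.integers(0, n_circles, size=2)
        for copy_i, home in enumerate(homes):
            placements[home].append(copy_i)
        circles = []
        arc_counter = 0
        for ci in range(n_circles):
            segments = []
            for copy_i in placements[ci]:
                orient = "+" if rng.random() < 0.5 else "-"
                segments.append(rep("R", orient, rep_len, tag=str(copy_i)))
                n_arcs = int(rng.integers(1, 3))
                for _ in range(n_arcs):
                    segments.append(seg(f"a{arc_counter}", length=int(rng.integers(30, 200))))
                    arc_counter += 1
            if not segments:
                segments = [seg(f"a{arc_counter}", length=int(rng.integers(30, 200)))]
                arc_counter += 1
            if len(segments) > 6:
                segments = segments[:6]
            circles.append(SegmentCycle(tuple(segments)))
        cfg = GenomeConfiguration("b", circles)
        if cfg.repeat_copy_count("R") != 2:
            continue
        seqs = {}
        for cyc in cfg.circles:
            for sg in cyc.segments:
                key = sg.repeat_id if sg.kind == "repeat_copy" else sg.segment_id
                seqs.setdefault(key, random_sequence(rng, sg.length))
        assert_agrees_with_oracle(cfg, RecombinationEvent("R"), seqs, rep_len)


def test_event_is_involution():
    rng = np.random.default_rng(31)
    cfg = GenomeConfiguration("b", [SegmentCycle(
        (rep("R", tag="1"), seg("A", length=120),
         rep("R", "-", tag="2"), seg("B", length=90))
    )])
    for ev_cfg in (cfg,
                   GenomeConfiguration("b", [SegmentCycle(
                       (rep("R", tag="1"), seg("A", length=120),
                        rep("R", tag="2"), seg("B", length=90)))])):
        once = apply_event(ev_cfg, RecombinationEvent("R"))
        twice = apply_event(once, RecombinationEvent("R"))
        assert twice.canonical() == ev_cfg.canonical()


def test_conservation_over_event_sequences():
    rng = np.random.default_rng(55)
    cfg = GenomeConfiguration("b", [
        SegmentCycle((rep("R1", tag="a"), seg("A", length=100),
                      rep("R2", tag="a"), seg("B", length=150))),
        SegmentCycle((rep("R1", "-", tag="b"), seg("C", length=200),
                      rep("R2", tag="b"), seg("D", length=250))),
    ])
    total = cfg.total_length
    for _ in range(20):
        rid = "R1" if rng.random() < 0.5 else "R2"
        cfg = apply_event(cfg, RecombinationEvent(rid))
        assert cfg.total_length == total
        assert cfg.repeat_copy_count("R1") == 2
        assert cfg.repeat_copy_count("R2") == 2


def test_missing_repeat_raises():
    cfg = GenomeConfiguration("b", [SegmentCycle((seg("A"),))])
    with pytest.raises(EventError):
        apply_event(cfg, RecombinationEvent("R9"))


# ---------------------------------------------------------------------------
# three-repeat enumeration (major-configuration placements)
# ---------------------------------------------------------------------------


@pytest.fixture
def two_chromosome_baseline():
    """Two circles sharing one copy each of three repeats: R01 and R07
    direct, R04 inverted (the recombinogenic placements of a
    two-chromosome mitogenome)."""
    mc1 = SegmentCycle((
        rep("R01", tag="a", length=120), seg("u1", length=1000),
        rep("R04", tag="a", length=80), seg("u2", length=1100),
        rep("R07", tag="a", length=60), seg("u3", length=1200),
    ))
    mc2 = SegmentCycle((
        rep("R01", tag="b", length=120), seg("v1", length=900),
        rep("R04", "-", tag="b", length=80), seg("v2", length=800),
        rep("R07", tag="b", length=60), seg("v3", length=700),
    ))
    return GenomeConfiguration("Mac1", [mc1, mc2])


def test_enumeration_reproduces_minor_configurations(two_chromosome_baseline):
    base = two_chromosome_baseline
    products = enumerate_products(base, ["R01", "R04", "R07"])
    assert len(products) == 7
    names = [cfg.name for cfg in products.values()]
    assert names == [f"Mic{i}" for i in range(1, 8)]
    for subset, cfg in products.items():
        assert cfg.total_length == base.total_length
        for rid in ("R01", "R04", "R07"):
            assert cfg.repeat_copy_count(rid) == 2
    # single-repeat products fuse the two chromosomes into one
    for rid in ("R01",), ("R04",), ("R07",):
        assert products[rid].n_chromosomes == 1
    # R01+R07 (both direct): fuse then fission back into two chromosomes
    assert products[("R01", "R07")].n_chromosomes == 2


def test_empty_repeat_list_yields_no_products(two_chromosome_baseline):
    assert enumerate_products(two_chromosome_baseline, []) == {}


def test_configuration_from_repeats_factors_genome(rng):
    from mitostruct.core import CircularSequence, GenomeInterval
    from mitostruct.repeats import RepeatPair

    core = random_sequence(rng, 200)
    s1 = random_sequence(rng, 1000) + core + random_sequence(rng, 800)
    s2 = random_sequence(rng, 500) + core + random_sequence(rng, 700)
    genome = [CircularSequence("c1", s1), CircularSequence("c2", s2)]
    pair = RepeatPair(
        "R01", GenomeInterval("c1", 1001, 1200), GenomeInterval("c2", 501, 700),
        200, 1.0, "direct",
    )
    cfg = configuration_from_repeats(genome, [pair])
    assert cfg.n_chromosomes == 2
    assert cfg.total_length == len(s1) + len(s2)
    assert cfg.repeat_copy_count("R01") == 2
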