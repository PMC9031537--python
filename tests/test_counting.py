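"""Junction assignment and event counting."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdetect import (
    ASEvent,
    CountConfig,
    assign_read,
    count_events,
    effective_length,
    extract_events,
    read_alignments,
)
from asdetect.counting import alignment_blocks, write_counts_tsv

from conftest import write_sam


def ir_event(intron=(100, 200), exon1=(0, 100), exon2=(200, 300), seqname="chr1"):
    return ASEvent(
        event_id="ev1",
        type="IR",
        gene_id="g1",
        seqname=seqname,
        strand="+",
        coords={"exon1": exon1, "intron": intron, "exon2": exon2},
    )


# ---------------------------------------------------------------------------
# effective length


@pytest.mark.parametrize("L,m,expected", [(150, 8, 135), (101, 8, 86), (16, 8, 1)])
def test_effective_length_formula(L, m, expected):
    assert effective_length(L, m) == expected


def test_effective_length_rejects_small_reads():
    with pytest.raises(ValueError, match="smaller minimum overlap"):
        effective_length(15, 8)


# ---------------------------------------------------------------------------
# alignment decoding


def test_spliced_alignment_yields_two_blocks(tmp_path, sam_writer):
    path = sam_writer(tmp_path / "a.sam", [("r1", 90, "50M60N40M", 0)])
    (read,) = read_alignments(path)
    blocks, gaps = alignment_blocks(read)
    assert blocks == [(90, 140), (200, 240)]
    assert gaps == ["N"]


def test_deletion_splits_block_with_d_gap(tmp_path, sam_writer):
    path = sam_writer(tmp_path / "a.sam", [("r1", 10, "20M5D20M", 0)])
    (read,) = read_alignments(path)
    blocks, gaps = alignment_blocks(read)
    assert blocks == [(10, 30), (35, 55)]
    assert gaps == ["D"]


def test_secondary_and_unmapped_records_excluded(tmp_path, sam_writer):
    path = sam_writer(
        tmp_path / "a.sam",
        [
            ("kept", 10, "50M", 0),
            ("secondary", 10, "50M", 256),
            ("supplementary", 10, "50M", 2048),
            ("unmapped", 10, "50M", 4),
        ],
    )
    assert [r.query_name for r in read_alignments(path)] == ["kept"]


def test_region_query_without_index_raises(tmp_path, sam_writer):
    path = sam_writer(tmp_path / "a.sam", [("r1", 10, "50M", 0)])
    with pytest.raises(ValueError, match="index"):
        list(read_alignments(path, region=("chr1", 0, 100)))


# ---------------------------------------------------------------------------
# junction assignment


def test_block_over_boundary_credits_e1_i():
    assert assign_read([(90, 140)], ir_event(), m=8) == {"E1_I"}


def test_weak_anchor_gets_nothing():
    # only 5 bp on the exon side of the splice junction
    assert assign_read([(95, 100), (200, 240)], ir_event(), m=8) == set()


def test_block_inside_intron_credits_body():
    assert assign_read([(120, 180)], ir_event(), m=8) == {"I"}


def test_exact_splice_junction_credits_e1_e2():
    assert assign_read([(60, 100), (200, 240)], ir_event(), m=8) == {"E1_E2"}


def test_inexact_splice_gap_not_credited():
    assert assign_read([(60, 100), (201, 241)], ir_event(), m=8) == set()


def test_deletion_gap_is_not_a_splice_junction():
    assert (
        assign_read([(60, 100), (200, 240)], ir_event(), m=8, gaps=["D"]) == set()
    )


def test_read_spanning_whole_intron_hits_both_boundaries():
    ev = ir_event(intron=(100, 130))
    assert assign_read([(80, 160)], ev, m=8) == {"E1_I", "I_E2"}


def oracle_assign_ir(blocks, intron, m):
    """Per-base overlap oracle for IR junction assignment."""
    s, e = intron
    labels = set()
    for a, b in blocks:
        left = len(set(range(a, b)) & set(range(s - m, s)))
        right = len(set(range(a, b)) & set(range(s, s + m)))
        if left == m and right == m:
            labels.add("E1_I")
        left = len(set(range(a, b)) & set(range(e - m, e)))
        right = len(set(range(a, b)) & set(range(e, e + m)))
        if left == m and right == m:
            labels.add("I_E2")
        inside = len(set(range(a, b)) & set(range(s, e)))
        if inside == b - a and inside >= m:
            labels.add("I")
    for (a1, z1), (a2, z2) in zip(blocks, blocks[1:]):
        if z1 == s and a2 == e and z1 - a1 >= m and z2 - a2 >= m:
            labels.add("E1_E2")
    return labels


@settings(max_examples=200, derandomize=True)
@given(
    start=st.integers(min_value=60, max_value=240),
    len1=st.integers(min_value=1, max_value=80),
    gap=st.integers(min_value=0, max_value=120),
    len2=st.integers(min_value=0, max_value=80),
)
def test_assignment_matches_per_base_oracle(start, len1, gap, len2):
    blocks = [(start, start + len1)]
    if len2 > 0 and gap > 0:
        blocks.append((start + len1 + gap, start + len1 + gap + len2))
    ev = ir_event()
    assert assign_read(blocks, ev, m=8) == oracle_assign_ir(
        blocks, ev.coords["intron"], 8
    )


# ---------------------------------------------------------------------------
# event counting


def test_no_reads_means_zero_counts(tmp_path, sam_writer):
    path = sam_writer(tmp_path / "a.sam", [("r1", 5000, "150M", 0)])
    counts, dropped = count_events([ir_event()], path, CountConfig(m=8))
    assert not dropped
    assert all(v == 0 for v in counts[0].raw.values())


def test_short_intron_dropped(tmp_path, sam_writer):
    path = sam_writer(tmp_path / "a.sam", [("r1", 0, "150M", 0)])
    ev = ir_event(intron=(100, 105), exon2=(105, 300))
    counts, dropped = count_events([ev], path, CountConfig(m=8))
    assert counts == []
    assert dropped[0].reason == "short_feature"


def test_clean_spanning_reads_counted_and_normalized(tmp_path, sam_writer):
    ev = ir_event(exon1=(0, 100), intron=(100, 200), exon2=(200, 400))
    reads = [(f"r{i}", 50, "50M100N100M", 0) for i in range(10)]
    path = sam_writer(tmp_path / "a.sam", reads)
    counts, _ = count_events([ev], path, CountConfig(m=8, read_length=150))
    assert counts[0].raw["E1_E2"] == 10
    assert counts[0].normalized["E1_E2"] == pytest.approx(10 / 135)
    write_counts_tsv(counts, str(tmp_path / "c.tsv"))  # smoke
    assert (tmp_path / "c.tsv").read_text().count("\n") == 5


def test_chromosome_mismatch_raises(tmp_path, sam_writer):
    path = sam_writer(tmp_path / "a.sam", [("r1", 0, "150M", 0)], chrom="other")
    with pytest.raises(ValueError, match="chromosome"):
        count_events([ir_event(seqname="chr1")], path, CountConfig(m=8))


def test_adding_a_read_never_decreases_counts(tmp_path, sam_writer):
    ev = ir_event(exon1=(0, 100), intron=(100, 200), exon2=(200, 400))
    reads = [("r1", 50, "50M100N100M", 0), ("r2", 60, "150M", 0)]
    p1 = sam_writer(tmp_path / "one.sam", reads[:1])
    p2 = sam_writer(tmp_path / "two.sam", reads)
    c1, _ = count_events([ev], p1, CountConfig(m=8, read_length=150))
    c2, _ = count_events([ev], p2, CountConfig(m=8, read_length=150))
    assert all(c2[0].raw[k] >= c1[0].raw[k] for k in c1[0].raw)


# ---------------------------------------------------------------------------
# brute-force oracle on a shallow simulated dataset


def oracle_counts(events, sam_path, m, L):
    """Naive per-read, per-event double loop, no spatial index."""
    raw = {
        ev.event_id: {label: 0 for label in _junction_labels(ev)}
        for ev in events
    }
    with pysam.AlignmentFile(sam_path) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            blocks, gaps = _blocks(read)
            for ev in events:
                if read.reference_name != ev.seqname:
                    continue
                for label, hit in _assign(blocks, gaps, ev, m).items():
                    raw[ev.event_id][label] += hit
    return raw


def _junction_labels(ev):
    return {
        "IR": ["E1_I", "I", "I_E2", "E1_E2"],
        "ES": ["E1_E2", "E2_E3", "E1_E3"],
        "A5SS": ["long", "short"],
        "A3SS": ["long", "short"],
    }[ev.type]


def _blocks(read):
    blocks, gaps = [], []
    pos, start = read.reference_start, None
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):
            start = pos if start is None else start
            pos += ln
        elif op in (2, 3):
            if start is not None:
                blocks.append((start, pos))
                gaps.append("N" if op == 3 else "D")
                start = None
            pos += ln
    if start is not None:
        blocks.append((start, pos))
    return blocks, gaps[: len(blocks) - 1]


def _gap_hit(blocks, gaps, donor, acceptor, m):
    return int(
        any(
            g == "N" and z1 == donor and a2 == acceptor and z1 - a1 >= m and z2 - a2 >= m
            for (a1, z1), (a2, z2), g in zip(blocks, blocks[1:], gaps)
        )
    )


def _boundary_hit(blocks, b, m):
    return int(any(a <= b - m and z >= b + m for a, z in blocks))


def _assign(blocks, gaps, ev, m):
    c = ev.coords
    if ev.type == "IR":
        s, e = c["intron"]
        return {
            "E1_I": _boundary_hit(blocks, s, m),
            "I": int(any(a >= s and z <= e and z - a >= m for a, z in blocks)),
            "I_E2": _boundary_hit(blocks, e, m),
            "E1_E2": _gap_hit(blocks, gaps, s, e, m),
        }
    if ev.type == "ES":
        u, (s, e), d = c["exon_up"][1], c["exon_skip"], c["exon_down"][0]
        return {
            "E1_E2": _gap_hit(blocks, gaps, u, s, m),
            "E2_E3": _gap_hit(blocks, gaps, e, d, m),
            "E1_E3": _gap_hit(blocks, gaps, u, d, m),
        }
    return {
        "long": _gap_hit(blocks, gaps, *c["intron_short"], m),
        "short": _gap_hit(blocks, gaps, *c["intron_long"], m),
    }


def test_counts_match_naive_double_loop(sim_shallow):
    sam = sim_shallow["paths"]["sam"]
    with pysam.AlignmentFile(sam) as af:
        n_reads = sum(1 for _ in af.fetch(until_eof=True))
    assert n_reads <= 1000
    events = extract_events(sim_shallow["dataset"].annotation)
    counts, _ = count_events(events, sam, CountConfig(m=8, read_length=150))
    expected = oracle_counts(events, sam, m=8, L=150)
    assert {c.event_id: c.raw for c in counts} == expected


def test_thread_count_does_not_change_counts(tmp_path, sim_small):
    sam = sim_small["paths"]["sam"]
    bam = str(tmp_path / "reads.bam")
    pysam.sort("-o", bam, sam)
    pysam.index(bam)
    events = extract_events(sim_small["dataset"].annotation)
    c1, _ = count_events(events, bam, CountConfig(m=8, threads=1))
    c3, _ = count_events(events, bam, CountConfig(m=8, threads=3))
    assert [(c.event_id, c.raw) for c in c1] == [(c.event_id, c.raw) for c in c3]
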