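"""Junction read counting.

Reads are assigned to the junction classes of each event from their
gap-aware alignment blocks.  For an intron-retention event the classes are

* ``E1_I``  — a single block covering the exon–intron boundary with at
  least ``m`` aligned bases on each side,
* ``I``     — a block lying entirely within the intron (>= m bp),
* ``I_E2``  — the intron–exon boundary, mirrored,
* ``E1_E2`` — a spliced read whose gap matches the intron's donor and
  acceptor exactly, anchored by >= m bp on both sides.

Exon-skipping events use the two inclusion junctions ``E1_E2``/``E2_E3``
and the exclusion junction ``E1_E3``; alternative-splice-site events use
the junctions of the short (``long`` mature form) and long (``short``
form) intron.  Raw tallies are normalised by each junction's effective
length L - 2m + 1, the number of distinct read start positions that can
span the junction with the required anchors.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam
from intervaltree import IntervalTree

from .annotation import ASEvent

__all__ = [
    "CountConfig",
    "JunctionCounts",
    "effective_length",
    "read_alignments",
    "alignment_blocks",
    "assign_read",
    "count_events",
    "write_counts_tsv",
]

logger = logging.getLogger(__name__)

# junction kinds
_BOUNDARY = "boundary"
_BODY = "body"
_GAP = "gap"


@dataclass
class CountConfig:
    """Counting parameters.

    Parameters
    ----------
    m
        Minimum overlap in bp between a read and the exon/intron on each
        side of a junction (8 bp recommended).
    read_length
        Read length L; auto-detected from the alignments when None.
    min_mapq
        Minimum mapping quality (default 0: keep everything primary).
    threads
        Worker threads; counting is partitioned by chromosome and merged
        in chromosome order, so results are thread-count independent.
    stranded
        When True, only reads on the gene's strand are counted.
    """

    m: int = 8
    read_length: int | None = None
    min_mapq: int = 0
    threads: int = 1
    stranded: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("minimum overlap m must be >= 1")
        if self.read_length is not None:
            effective_length(self.read_length, self.m)


@dataclass
class JunctionCounts:
    """Raw and effective-length-normalised junction counts for one event."""

    event_id: str
    event: ASEvent
    raw: dict[str, int]
    effective: dict[str, float]

    @property
    def normalized(self) -> dict[str, float]:
        return {k: self.raw[k] / self.effective[k] for k in self.raw}


def effective_length(L: int, m: int) -> int:
    """Number of unique mappable read start positions across a junction.

    A read of length L anchors a junction when at least m bases align on
    each side, which leaves L - 2m + 1 admissible start positions.
    """
    if L < 2 * m:
        raise ValueError(
            f"read length {L} < 2m = {2 * m}; choose a smaller minimum overlap m"
        )
    return L - 2 * m + 1


# ---------------------------------------------------------------------------
# alignment access


def alignment_blocks(read: pysam.AlignedSegment) -> tuple[list[tuple[int, int]], list[str]]:
    """Reference blocks of an alignment and the gap type between them.

    Blocks are maximal runs of aligned reference bases (CIGAR M/=/X);
    insertions do not interrupt a block, while deletions (``D``) and skips
    (``N``) do.  The i-th gap type separates block i from block i+1, so a
    spliced junction is a ``"N"`` gap whose flanking blocks end/start at
    the donor/acceptor.
    """
    blocks: list[tuple[int, int]] = []
    gaps: list[str] = []
    pos = read.reference_start
    cur_start: int | None = None
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if cur_start is None:
                cur_start = pos
            pos += ln
        elif op == 2:  # D: consumes reference, splits the aligned block
            if cur_start is not None:
                blocks.append((cur_start, pos))
                gaps.append("D")
                cur_start = None
            pos += ln
        elif op == 3:  # N: splice gap
            if cur_start is not None:
                blocks.append((cur_start, pos))
                gaps.append("N")
                cur_start = None
            pos += ln
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    # drop trailing gap labels with no following block
    gaps = gaps[: max(len(blocks) - 1, 0)]
    return blocks, gaps


def read_alignments(
    path: str,
    region: tuple[str, int, int] | str | None = None,
    min_mapq: int = 0,
) -> Iterator[pysam.AlignedSegment]:
    """Stream primary, mapped alignment records from a SAM/BAM file.

    Secondary, supplementary and unmapped records are excluded.  Region
    queries require a coordinate-sorted, indexed BAM.
    """
    with pysam.AlignmentFile(path, "r") as af:
        if region is None:
            it: Iterable[pysam.AlignedSegment] = af.fetch(until_eof=True)
        else:
            if not af.has_index():
                raise ValueError(
                    f"region query on {path!r} requires a coordinate-sorted, "
                    "indexed BAM"
                )
            if isinstance(region, str):
                it = af.fetch(region=region)
            else:
                it = af.fetch(region[0], region[1], region[2])
        skipped = 0
        for read in it:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.cigartuples is None:
                skipped += 1
                continue
            yield read
        if skipped:
            logger.warning("skipped %d malformed records in %s", skipped, path)


# ---------------------------------------------------------------------------
# junction assignment


def event_junctions(event: ASEvent) -> dict[str, tuple[str, tuple[int, int]]]:
    """Map each junction label of an event to its (kind, interval) spec."""
    c = event.coords
    if event.type == "IR":
        s, e = c["intron"]
        return {
            "E1_I": (_BOUNDARY, (s, s)),
            "I": (_BODY, (s, e)),
            "I_E2": (_BOUNDARY, (e, e)),
            "E1_E2": (_GAP, (s, e)),
        }
    if event.type == "ES":
        u = c["exon_up"][1]
        s, e = c["exon_skip"]
        d = c["exon_down"][0]
        return {
            "E1_E2": (_GAP, (u, s)),
            "E2_E3": (_GAP, (e, d)),
            "E1_E3": (_GAP, (u, d)),
        }
    # A5SS / A3SS: the short intron is the junction of the longer mRNA
    return {
        "long": (_GAP, c["intron_short"]),
        "short": (_GAP, c["intron_long"]),
    }


def assign_read(
    blocks: list[tuple[int, int]],
    event: ASEvent,
    m: int = 8,
    gaps: list[str] | None = None,
) -> set[str]:
    """Junction labels of one event supported by one read's blocks.

    ``gaps`` gives the gap type between consecutive blocks (from
    :func:`alignment_blocks`); when omitted every gap is treated as a
    splice gap, which matches pre-split spliced blocks.
    """
    if gaps is None:
        gaps = ["N"] * (len(blocks) - 1)
    labels: set[str] = set()
    for label, (kind, (s, e)) in event_junctions(event).items():
        if kind == _BOUNDARY:
            b = s
            if any(a <= b - m and z >= b + m for a, z in blocks):
                labels.add(label)
        elif kind == _BODY:
            if any(a >= s and z <= e and z - a >= m for a, z in blocks):
                labels.add(label)
        else:  # gap junction: exact donor/acceptor match with m-bp anchors
            for i in range(len(blocks) - 1):
                a1, z1 = blocks[i]
                a2, z2 = blocks[i + 1]
                if (
                    gaps[i] == "N"
                    and z1 == s
                    and a2 == e
                    and z1 - a1 >= m
                    and z2 - a2 >= m
                ):
                    labels.add(label)
                    break
    return labels


# ---------------------------------------------------------------------------
# event counting


@dataclass
class DroppedEvent:
    event_id: str
    reason: str


def _filter_events(
    events: list[ASEvent], m: int
) -> tuple[list[ASEvent], list[DroppedEvent]]:
    kept, dropped = [], []
    for ev in events:
        if any(length < m for length in ev.feature_lengths().values()):
            dropped.append(DroppedEvent(ev.event_id, "short_feature"))
        else:
            kept.append(ev)
    return kept, dropped


def _detect_read_length(path: str, sample: int = 1000) -> int:
    longest = 0
    for i, read in enumerate(read_alignments(path)):
        longest = max(longest, read.infer_query_length() or 0)
        if i + 1 >= sample:
            break
    if longest == 0:
        raise ValueError(f"could not detect read length from {path!r}")
    return longest


def _effective_lengths(ev: ASEvent, L: int, m: int) -> dict[str, float]:
    el = float(effective_length(L, m))
    out = {}
    for label, (kind, (s, e)) in event_junctions(ev).items():
        if kind == _BODY:
            # start positions of a full-length read lying inside the intron
            out[label] = float(max(e - s - L + 1, 1))
        else:
            out[label] = el
    return out


def _new_raw(events_by_id: dict[str, ASEvent]) -> dict[str, dict[str, int]]:
    return {
        eid: {label: 0 for label in event_junctions(ev)}
        for eid, ev in events_by_id.items()
    }


def _tally_read(
    read: pysam.AlignedSegment,
    tree: IntervalTree,
    events_by_id: dict[str, ASEvent],
    config: CountConfig,
    raw: dict[str, dict[str, int]],
) -> None:
    blocks, gaps = alignment_blocks(read)
    if not blocks:
        return
    for hit in tree.overlap(blocks[0][0], blocks[-1][1]):
        ev: ASEvent = events_by_id[hit.data]
        if config.stranded and read.is_reverse == (ev.strand == "+"):
            continue
        for label in assign_read(blocks, ev, config.m, gaps):
            raw[ev.event_id][label] += 1


def _count_chrom_fetch(
    path: str,
    chrom: str,
    tree: IntervalTree,
    events_by_id: dict[str, ASEvent],
    config: CountConfig,
) -> dict[str, dict[str, int]]:
    raw = _new_raw(events_by_id)
    for read in read_alignments(path, region=chrom, min_mapq=config.min_mapq):
        _tally_read(read, tree, events_by_id, config, raw)
    return raw


def _count_single_pass(
    path: str,
    trees: dict[str, IntervalTree],
    by_chrom: dict[str, dict[str, ASEvent]],
    config: CountConfig,
) -> dict[str, dict[str, dict[str, int]]]:
    raw = {chrom: _new_raw(by_chrom[chrom]) for chrom in by_chrom}
    for read in read_alignments(path, min_mapq=config.min_mapq):
        chrom = read.reference_name
        if chrom not in trees:
            continue
        _tally_read(read, trees[chrom], by_chrom[chrom], config, raw[chrom])
    return raw


def count_events(
    events: list[ASEvent],
    alignments: str,
    config: CountConfig | None = None,
) -> tuple[list[JunctionCounts], list[DroppedEvent]]:
    """Count junction-supporting reads for every event.

    Events with any defining exon or intron shorter than ``m`` are dropped
    with reason ``short_feature``.  Counting is a single streaming pass per
    chromosome; with several threads the chromosomes are processed
    concurrently (indexed BAM input) and merged in chromosome order, so the
    result does not depend on the thread count.
    """
    config = config or CountConfig()
    kept, dropped = _filter_events(events, config.m)

    with pysam.AlignmentFile(alignments, "r") as af:
        references = set(af.references or ())
        has_index = af.has_index()

    event_chroms = {ev.seqname for ev in kept}
    if kept and references and not (event_chroms & references):
        raise ValueError(
            "no chromosome of the annotation matches the alignment file; "
            f"annotation: {sorted(event_chroms)}, "
            f"alignments: {sorted(references)}"
        )

    L = config.read_length or _detect_read_length(alignments)
    effective_length(L, config.m)

    trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, dict[str, ASEvent]] = {}
    for ev in kept:
        s, e = ev.span
        trees.setdefault(ev.seqname, IntervalTree()).addi(s, e, ev.event_id)
        by_chrom.setdefault(ev.seqname, {})[ev.event_id] = ev

    chroms = sorted(by_chrom)
    raw_by_chrom: dict[str, dict[str, dict[str, int]]]
    if config.threads > 1 and has_index:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            futures = {
                chrom: pool.submit(
                    _count_chrom_fetch,
                    alignments,
                    chrom,
                    trees[chrom],
                    by_chrom[chrom],
                    config,
                )
                for chrom in chroms
            }
            raw_by_chrom = {c: f.result() for c, f in futures.items()}
    else:
        raw_by_chrom = _count_single_pass(alignments, trees, by_chrom, config)

    out: list[JunctionCounts] = []
    for chrom in chroms:
        for eid in sorted(
            by_chrom[chrom], key=lambda i: (by_chrom[chrom][i].span, i)
        ):
            ev = by_chrom[chrom][eid]
            out.append(
                JunctionCounts(
                    event_id=eid,
                    event=ev,
                    raw=raw_by_chrom[chrom][eid],
                    effective=_effective_lengths(ev, L, config.m),
                )
            )
    return out, dropped


def write_counts_tsv(counts: list[JunctionCounts], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\ttype\tjunction\traw\teffective_length\tnormalized\n")
        for jc in counts:
            norm = jc.normalized
            for label in jc.raw:
                fh.write(
                    f"{jc.event_id}\t{jc.event.type}\t{label}\t{jc.raw[label]}\t"
                    f"{jc.effective[label]:g}\t{norm[label]:.6g}\n"
                )
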