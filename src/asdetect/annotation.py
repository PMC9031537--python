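"""Transcript models and alternative-splicing event enumeration.

A genome annotation (GFF3 or GTF) is parsed into genes, transcripts and
exons; introns are derived as the gaps between consecutive exons of a
transcript.  From the transcript models of each gene the four major plant
AS event types are enumerated under strict definitions:

IR
    an intron of one transcript that is retained inside a single exon of a
    sibling transcript (the intron lies strictly interior to that exon).
ES
    an internal (cassette) exon of one transcript that is skipped by a
    sibling transcript whose splice junction joins exactly the flanking
    exon boundaries.
A5SS / A3SS
    two transcripts whose introns share one splice site but differ at the
    other; whether the varying site is the 5' or the 3' one is decided by
    strand.

All internal coordinates are 0-based half-open; GFF/GTF 1-based inclusive
coordinates are converted only at I/O.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gffutils

__all__ = [
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "ASEvent",
    "read_annotation",
    "extract_events",
    "label_clean",
    "enumerate_all_introns",
    "write_events_tsv",
    "write_events_bed",
    "read_events_bed",
]

EVENT_TYPES = ("IR", "ES", "A5SS", "A3SS")

Interval = tuple[int, int]


@dataclass(frozen=True)
class Transcript:
    """One mRNA isoform: ordered, non-overlapping exons plus derived introns."""

    id: str
    exons: tuple[Interval, ...]

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class Gene:
    id: str
    seqname: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> Interval:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))


@dataclass
class GenomeAnnotation:
    genes: dict[str, Gene]
    sequence_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence_names:
            seen: list[str] = []
            for g in self.genes.values():
                if g.seqname not in seen:
                    seen.append(g.seqname)
            self.sequence_names = seen


@dataclass
class ASEvent:
    """A candidate alternative-splicing event.

    ``coords`` holds the type-specific named intervals (0-based half-open):

    * IR     — ``exon1``, ``intron``, ``exon2``
    * ES     — ``exon_up``, ``exon_skip``, ``exon_down``
    * A5SS/A3SS — ``intron_long``, ``intron_short`` (the short intron is the
      junction of the longer mature mRNA; both introns share one boundary)
    """

    event_id: str
    type: str
    gene_id: str
    seqname: str
    strand: str
    coords: dict[str, Interval]
    known: bool = True
    clean: bool = True

    @property
    def span(self) -> Interval:
        starts = [iv[0] for iv in self.coords.values()]
        ends = [iv[1] for iv in self.coords.values()]
        return (min(starts), max(ends))

    def feature_lengths(self) -> dict[str, int]:
        return {k: iv[1] - iv[0] for k, iv in self.coords.items()}


def _event_id(seqname: str, type_: str, coords: dict[str, Interval]) -> str:
    if type_ == "IR":
        s, e = coords["intron"]
        return f"{seqname}:{s}-{e}:IR"
    if type_ == "ES":
        s, e = coords["exon_skip"]
        u = coords["exon_up"][1]
        d = coords["exon_down"][0]
        return f"{seqname}:{u}|{s}-{e}|{d}:ES"
    l1, l2 = coords["intron_long"]
    s1, s2 = coords["intron_short"]
    return f"{seqname}:{l1}-{l2}|{s1}-{s2}:{type_}"


# ---------------------------------------------------------------------------
# parsing


def read_annotation(path: str, format: str | None = None) -> GenomeAnnotation:
    """Parse a GFF3 or GTF file into a :class:`GenomeAnnotation`.

    Parameters
    ----------
    path
        Annotation file. Gene/transcript/exon records with parent links are
        required (EnsemblPlants-style GFF3 with ID/Parent, or GTF with
        gene_id/transcript_id attributes).
    format
        ``"gff3"`` or ``"gtf"``; guessed from the file extension when None.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        low = path.lower()
        if low.endswith((".gtf",)):
            format = "gtf"
        elif low.endswith((".gff", ".gff3")):
            format = "gff3"
        else:
            raise ValueError(f"cannot guess annotation format from {path!r}")
    if format not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation format {format!r}")

    # GTF files frequently lack explicit gene/transcript records, so let
    # gffutils infer them from the exon attributes in that case.
    infer = format == "gtf"
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=not infer,
        disable_infer_transcripts=not infer,
    )

    transcript_kinds = {"mRNA", "transcript"}
    genes: dict[str, Gene] = {}
    seqnames: list[str] = []

    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for t in db.children(g, level=1, order_by="start"):
            if t.featuretype not in transcript_kinds:
                continue
            exons = []
            for ex in db.children(t, featuretype="exon", order_by="start"):
                exons.append((ex.start - 1, ex.end))  # to 0-based half-open
            if not exons:
                continue
            exons.sort()
            for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
                if a2 < b1:
                    raise ValueError(
                        f"overlapping or unsorted exons in transcript {t.id!r}"
                    )
            transcripts.append(Transcript(id=t.id, exons=tuple(exons)))
        if not transcripts:
            continue
        genes[g.id] = Gene(
            id=g.id,
            seqname=g.seqid,
            strand=g.strand if g.strand in "+-" else "+",
            transcripts=tuple(transcripts),
        )
        if g.seqid not in seqnames:
            seqnames.append(g.seqid)

    # orphan exons: an exon whose Parent never resolves to a transcript
    for ex in db.features_of_type("exon"):
        parents = list(db.parents(ex, level=1))
        if not parents:
            raise ValueError(f"exon feature {ex.id!r} has no Parent transcript")

    return GenomeAnnotation(genes=genes, sequence_names=seqnames)


# ---------------------------------------------------------------------------
# event enumeration


def _contains_strictly(outer: Interval, inner: Interval) -> bool:
    return outer[0] < inner[0] and inner[1] < outer[1]


def _flanking_exons(t: Transcript, intron: Interval) -> tuple[Interval, Interval]:
    i = t.introns.index(intron)
    return t.exons[i], t.exons[i + 1]


def _intron_retained(gene: Gene, intron: Interval) -> bool:
    """True when some transcript of the gene holds the intron inside one exon."""
    for t in gene.transcripts:
        for ex in t.exons:
            if _contains_strictly(ex, intron):
                return True
    return False


def extract_events(annotation: GenomeAnnotation) -> list[ASEvent]:
    """Enumerate the strict AS events of every gene.

    Events are deduplicated by coordinates and returned in a deterministic
    order (by seqname, span, type). All events returned here are annotated
    in the transcript models, hence ``known=True``; the ``clean`` label is
    filled in via :func:`label_clean`.
    """
    events: dict[str, ASEvent] = {}

    for gene in annotation.genes.values():
        # IR: intron of one transcript strictly inside an exon of a sibling
        for t in gene.transcripts:
            for intron in t.introns:
                if _intron_retained(gene, intron):
                    e1, e2 = _flanking_exons(t, intron)
                    coords = {"exon1": e1, "intron": intron, "exon2": e2}
                    _add(events, gene, "IR", coords)

        # ES: internal exon skipped by a sibling junction joining its flanks
        for t in gene.transcripts:
            for j in range(1, len(t.exons) - 1):
                up, skip, down = t.exons[j - 1], t.exons[j], t.exons[j + 1]
                junction = (up[1], down[0])
                for o in gene.transcripts:
                    if o is t:
                        continue
                    if junction in o.introns:
                        coords = {
                            "exon_up": up,
                            "exon_skip": skip,
                            "exon_down": down,
                        }
                        _add(events, gene, "ES", coords)
                        break

        # A5SS / A3SS: intron pairs sharing exactly one boundary.  The two
        # alternative sites must fall within the same exon body of the
        # short-intron isoform, otherwise the pair reflects a different
        # structure (e.g. a cassette exon) rather than an alternative
        # splice site.
        introns: dict[Interval, list[tuple[Interval, Interval]]] = {}
        for t in gene.transcripts:
            for idx, intron in enumerate(t.introns):
                introns.setdefault(intron, []).append(
                    (t.exons[idx], t.exons[idx + 1])
                )
        ordered = sorted(introns)
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                i1, i2 = ordered[a], ordered[b]
                share_start = i1[0] == i2[0]
                share_end = i1[1] == i2[1]
                if share_start == share_end:  # both or neither
                    continue
                long_i, short_i = (
                    (i1, i2) if (i1[1] - i1[0]) > (i2[1] - i2[0]) else (i2, i1)
                )
                contexts = introns[short_i]
                if share_start:
                    varying_right = True  # acceptor varies (genomic right)
                    # some short-intron exon must span the long acceptor
                    if all(next_ex[1] <= long_i[1] for _, next_ex in contexts):
                        continue
                else:
                    varying_right = False  # donor varies (genomic left)
                    if all(prev_ex[0] >= long_i[0] for prev_ex, _ in contexts):
                        continue
                if gene.strand == "+":
                    type_ = "A3SS" if varying_right else "A5SS"
                else:
                    type_ = "A5SS" if varying_right else "A3SS"
                coords = {"intron_long": long_i, "intron_short": short_i}
                _add(events, gene, type_, coords)

    out = sorted(
        events.values(), key=lambda e: (e.seqname, e.span, e.type, e.event_id)
    )
    for ev in out:
        ev.clean = label_clean(ev, annotation)
    return out


def _add(
    events: dict[str, ASEvent],
    gene: Gene,
    type_: str,
    coords: dict[str, Interval],
) -> None:
    eid = _event_id(gene.seqname, type_, coords)
    if eid not in events:
        events[eid] = ASEvent(
            event_id=eid,
            type=type_,
            gene_id=gene.id,
            seqname=gene.seqname,
            strand=gene.strand,
            coords=dict(coords),
        )


def _clean_feature(event: ASEvent) -> Interval:
    if event.type == "IR":
        return event.coords["intron"]
    if event.type == "ES":
        return event.coords["exon_skip"]
    # for alternative splice sites the unambiguous region is the intron
    # shared by both isoforms (the shorter one)
    return event.coords["intron_short"]


def label_clean(event: ASEvent, annotation: GenomeAnnotation) -> bool:
    """Decide whether an event's defining feature is unambiguous.

    A feature (retained intron, skipped exon, or shared intron of an
    alternative-splice-site pair) is *clean* when no exon of any transcript
    of the gene **partly** overlaps it.  Full containment of the feature
    inside an exon — the retention isoform itself — does not count as a
    violation; a partial overlap does.
    """
    if event.gene_id not in annotation.genes:
        raise KeyError(f"event {event.event_id} references unknown gene")
    gene = annotation.genes[event.gene_id]
    s, e = _clean_feature(event)
    for t in gene.transcripts:
        for a, b in t.exons:
            if a < e and s < b:  # overlap
                if not (a <= s and e <= b):  # and not containment
                    return False
    return True


def enumerate_all_introns(annotation: GenomeAnnotation) -> list[ASEvent]:
    """One candidate IR event per distinct annotated intron.

    ``known`` is True when some sibling transcript retains the intron (the
    extract_events IR definition); otherwise the intron is a novel-retention
    candidate.  Deduplication is by (seqname, start, end, strand).
    """
    seen: dict[tuple, ASEvent] = {}
    for gene in annotation.genes.values():
        for t in gene.transcripts:
            for intron in t.introns:
                key = (gene.seqname, intron[0], intron[1], gene.strand)
                if key in seen:
                    continue
                e1, e2 = _flanking_exons(t, intron)
                ev = ASEvent(
                    event_id=_event_id(gene.seqname, "IR", {"intron": intron}),
                    type="IR",
                    gene_id=gene.id,
                    seqname=gene.seqname,
                    strand=gene.strand,
                    coords={"exon1": e1, "intron": intron, "exon2": e2},
                    known=_intron_retained(gene, intron),
                )
                ev.clean = label_clean(ev, annotation)
                seen[key] = ev
    return sorted(seen.values(), key=lambda e: (e.seqname, e.span, e.event_id))


# ---------------------------------------------------------------------------
# I/O


_TSV_HEADER = (
    "event_id\ttype\tgene_id\tseqname\tstrand\tfeature\tstart\tend\tknown\tclean"
)


def write_events_tsv(events: list[ASEvent], path: str) -> None:
    """Write events as a long-format TSV, one row per named feature."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for ev in events:
            for name, (s, e) in ev.coords.items():
                fh.write(
                    f"{ev.event_id}\t{ev.type}\t{ev.gene_id}\t{ev.seqname}\t"
                    f"{ev.strand}\t{name}\t{s}\t{e}\t{int(ev.known)}\t{int(ev.clean)}\n"
                )


def write_events_bed(events: list[ASEvent], path: str) -> None:
    """BED6 over each event's span (BED is already 0-based half-open)."""
    with open(path, "w") as fh:
        for ev in events:
            s, e = ev.span
            fh.write(f"{ev.seqname}\t{s}\t{e}\t{ev.event_id}\t0\t{ev.strand}\n")


def read_events_bed(path: str) -> list[tuple[str, int, int, str, str]]:
    """Read back a BED6 written by :func:`write_events_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return out
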