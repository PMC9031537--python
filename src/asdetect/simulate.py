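"""Synthetic RNA-Seq data with a known splicing truth table.

The simulator builds a small random genome in which every gene carries
exactly one strict alternative-splicing event realised as two transcript
isoforms (inclusion and exclusion form).  Isoform abundances follow a
per-gene true PSI drawn from a configurable distribution; error-free
150 bp paired-end reads are sampled uniformly along each isoform and
emitted directly as correctly aligned SAM records (gap-aware blocks
across introns) plus FASTQ, so no external aligner is needed.  The truth
table records, per event, the isoform abundances Ec (inclusion form) and
Er (exclusion form), the true PSI = Ec / (Ec + Er), and the resulting
positive/negative truth label at the 0.1 threshold.

Defaults emulate the benchmark conditions used throughout the package:
150 bp paired reads at about 70-fold coverage per gene, with true PSI
sampled away from the 0.1 decision threshold by a 0.05 margin.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation import (
    ASEvent,
    Gene,
    GenomeAnnotation,
    Transcript,
    _event_id,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "margin_psi_intervals",
    "simulate_annotation",
    "assign_abundances",
    "simulate_reads",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

DEFAULT_MIX = {"IR": 0.25, "ES": 0.25, "A5SS": 0.25, "A3SS": 0.25}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def margin_psi_intervals(event_type: str) -> list[tuple[float, float]]:
    """True-PSI sampling intervals that keep a 0.05 margin around 0.1.

    IR/A5SS/A3SS events are truth-negative below 0.1, so negatives are
    drawn from [0, 0.05] and positives from [0.2, 0.9].  For ES the
    threshold acts on 1 - PSI, hence the mirrored intervals.
    """
    if event_type == "ES":
        return [(0.1, 0.85), (0.95, 1.0)]
    return [(0.0, 0.05), (0.2, 0.9)]


@dataclass
class SimConfig:
    """Simulation parameters.

    ``psi_sampling`` may be ``"margin"`` (type-appropriate intervals from
    :func:`margin_psi_intervals`), ``"uniform"`` (uniform on [0, 1]) or an
    explicit list of (low, high) intervals sampled in proportion to their
    lengths.
    """

    n_genes: int = 100
    event_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    exon_length_range: tuple[int, int] = (150, 300)
    intron_length_range: tuple[int, int] = (80, 200)
    alt_offset_range: tuple[int, int] = (30, 100)
    n_flanking_exons: int = 2
    read_length: int = 150
    mean_depth: float = 70.0
    fragment_mean: float = 280.0
    fragment_sd: float = 40.0
    psi_sampling: str | list[tuple[float, float]] = "margin"
    seed: int = 0
    intergenic_gap: int = 300
    genes_per_chrom: int = 150

    def __post_init__(self) -> None:
        total = sum(self.event_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("event_mix proportions must sum to 1")
        if self.exon_length_range[0] > self.exon_length_range[1] or (
            self.intron_length_range[0] > self.intron_length_range[1]
        ):
            raise ValueError("infeasible length range")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_annotation`."""

    sequences: dict[str, str]
    annotation: GenomeAnnotation
    registry: list[ASEvent]
    # gene_id -> list of (isoform_id, exon list, role in {inclusion, exclusion})
    isoforms: dict[str, list[tuple[str, list[tuple[int, int]], str]]]

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in self.annotation.genes.values():
                gs, ge = gene.span
                fh.write(
                    f"{gene.seqname}\tsim\tgene\t{gs + 1}\t{ge}\t.\t"
                    f"{gene.strand}\t.\tID={gene.id}\n"
                )
                for t in gene.transcripts:
                    ts, te = t.span
                    fh.write(
                        f"{gene.seqname}\tsim\tmRNA\t{ts + 1}\t{te}\t.\t"
                        f"{gene.strand}\t.\tID={t.id};Parent={gene.id}\n"
                    )
                    for k, (es, ee) in enumerate(t.exons, 1):
                        fh.write(
                            f"{gene.seqname}\tsim\texon\t{es + 1}\t{ee}\t.\t"
                            f"{gene.strand}\t.\tID={t.id}.exon{k};Parent={t.id}\n"
                        )


# ---------------------------------------------------------------------------
# gene construction


def _build_gene(
    gene_id: str,
    seqname: str,
    strand: str,
    offset: int,
    event_type: str,
    rng: np.random.Generator,
    cfg: SimConfig,
) -> tuple[Gene, ASEvent, list[tuple[str, list[tuple[int, int]], str]]]:
    exon = lambda: int(rng.integers(*cfg.exon_length_range, endpoint=True))
    intron = lambda: int(rng.integers(*cfg.intron_length_range, endpoint=True))

    # constitutive flanking exons shared by both isoforms, emulating the
    # multi-exon structure (and ~1.5 kb mature length) of typical plant
    # genes; they also keep the event junctions away from isoform ends,
    # where fragment sampling thins the read-start density
    upstream = [(exon(), intron()) for _ in range(cfg.n_flanking_exons)]
    downstream = [(intron(), exon()) for _ in range(cfg.n_flanking_exons)]

    g = offset
    prefix: list[tuple[int, int]] = []
    for e_len, i_len in upstream:
        prefix.append((g, g + e_len))
        g = g + e_len + i_len

    if event_type == "IR":
        e1, i, e2 = exon(), intron(), exon()
        incl = [(g, g + e1 + i + e2)]  # retains the intron
        excl = [(g, g + e1), (g + e1 + i, g + e1 + i + e2)]
        coords = {
            "exon1": (g, g + e1),
            "intron": (g + e1, g + e1 + i),
            "exon2": (g + e1 + i, g + e1 + i + e2),
        }
    elif event_type == "ES":
        eu, i1, es_, i2, ed = exon(), intron(), exon(), intron(), exon()
        a, b = g + eu + i1, g + eu + i1 + es_
        d = b + i2
        incl = [(g, g + eu), (a, b), (d, d + ed)]
        excl = [(g, g + eu), (d, d + ed)]
        coords = {
            "exon_up": (g, g + eu),
            "exon_skip": (a, b),
            "exon_down": (d, d + ed),
        }
    else:
        # alternative splice site: which genomic side varies follows from
        # the requested type and the strand
        e1, i, e2 = exon(), intron(), exon()
        delta = int(rng.integers(*cfg.alt_offset_range, endpoint=True))
        varying_right = (event_type == "A3SS") == (strand == "+")
        if varying_right:
            # shared donor at g+e1; acceptor varies
            short_i = (g + e1, g + e1 + i)
            long_i = (g + e1, g + e1 + i + delta)
            end = g + e1 + i + delta + e2
            incl = [(g, g + e1), (g + e1 + i, end)]
            excl = [(g, g + e1), (g + e1 + i + delta, end)]
        else:
            # shared acceptor; donor varies
            long_i = (g + e1, g + e1 + delta + i)
            short_i = (g + e1 + delta, g + e1 + delta + i)
            end = g + e1 + delta + i + e2
            incl = [(g, g + e1 + delta), (g + e1 + delta + i, end)]
            excl = [(g, g + e1), (g + e1 + delta + i, end)]
        coords = {"intron_long": long_i, "intron_short": short_i}

    tail = max(iv[1] for iv in (incl[-1], excl[-1]))
    suffix: list[tuple[int, int]] = []
    pos = tail
    for i_len, e_len in downstream:
        suffix.append((pos + i_len, pos + i_len + e_len))
        pos = pos + i_len + e_len

    incl = prefix + incl + suffix
    excl = prefix + excl + suffix
    t_incl = Transcript(id=f"{gene_id}.t1", exons=tuple(incl))
    t_excl = Transcript(id=f"{gene_id}.t2", exons=tuple(excl))
    gene = Gene(
        id=gene_id, seqname=seqname, strand=strand, transcripts=(t_incl, t_excl)
    )
    event = ASEvent(
        event_id=_event_id(seqname, event_type, coords),
        type=event_type,
        gene_id=gene_id,
        seqname=seqname,
        strand=strand,
        coords=coords,
        known=True,
        clean=True,
    )
    isoforms = [
        (t_incl.id, list(t_incl.exons), "inclusion"),
        (t_excl.id, list(t_excl.exons), "exclusion"),
    ]
    return gene, event, isoforms


def simulate_annotation(config: SimConfig) -> SimulatedDataset:
    """Random genome + annotation where each gene carries one strict event."""
    rng = np.random.default_rng(config.seed)
    types = list(config.event_mix)
    probs = np.array([config.event_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()

    genes: dict[str, Gene] = {}
    registry: list[ASEvent] = []
    isoforms: dict[str, list[tuple[str, list[tuple[int, int]], str]]] = {}
    chrom_lengths: dict[str, int] = {}

    cursor = config.intergenic_gap
    chrom_idx = 1
    seqname = f"sim{chrom_idx}"
    for k in range(config.n_genes):
        if k and k % config.genes_per_chrom == 0:
            chrom_lengths[seqname] = cursor + config.intergenic_gap
            chrom_idx += 1
            seqname = f"sim{chrom_idx}"
            cursor = config.intergenic_gap
        gene_id = f"G{k + 1:05d}"
        etype = types[int(rng.choice(len(types), p=probs))]
        strand = "+" if rng.random() < 0.5 else "-"
        gene, event, iso = _build_gene(
            gene_id, seqname, strand, cursor, etype, rng, config
        )
        genes[gene_id] = gene
        registry.append(event)
        isoforms[gene_id] = iso
        cursor = gene.span[1] + config.intergenic_gap
    chrom_lengths[seqname] = cursor + config.intergenic_gap

    sequences = {}
    for name, length in chrom_lengths.items():
        codes = rng.integers(0, 4, size=length)
        sequences[name] = (
            np.frombuffer(b"ACGT", dtype="S1")[codes].tobytes().decode()
        )

    annotation = GenomeAnnotation(
        genes=genes, sequence_names=list(chrom_lengths)
    )
    return SimulatedDataset(
        sequences=sequences,
        annotation=annotation,
        registry=registry,
        isoforms=isoforms,
    )


# ---------------------------------------------------------------------------
# abundances and truth labels


def _sample_psi(
    rng: np.random.Generator,
    spec: str | list[tuple[float, float]],
    event_type: str,
) -> float:
    if spec == "margin":
        intervals = margin_psi_intervals(event_type)
    elif spec == "uniform":
        intervals = [(0.0, 1.0)]
    else:
        intervals = list(spec)
    weights = np.array([hi - lo for lo, hi in intervals], dtype=float)
    weights = weights / weights.sum()
    lo, hi = intervals[int(rng.choice(len(intervals), p=weights))]
    return float(rng.uniform(lo, hi))


def true_label(true_psi: float, event_type: str, threshold: float = 0.1) -> str:
    """Truth label at the PSI threshold (inverted rule for ES)."""
    if event_type == "ES":
        return "positive" if true_psi <= 1 - threshold else "negative"
    return "positive" if true_psi >= threshold else "negative"


def assign_abundances(dataset: SimulatedDataset, config: SimConfig):
    """Draw a true PSI per gene and derive isoform abundances Ec and Er.

    Returns a pandas DataFrame (the truth table) with one row per event:
    Ec and Er are the relative expression of the inclusion- and
    exclusion-form isoform, true_psi = Ec / (Ec + Er).
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for event in dataset.registry:
        psi = _sample_psi(rng, config.psi_sampling, event.type)
        scale = 100.0
        ec, er = psi * scale, (1.0 - psi) * scale
        rows.append(
            {
                "event_id": event.event_id,
                "gene_id": event.gene_id,
                "type": event.type,
                "Ec": ec,
                "Er": er,
                "true_psi": ec / (ec + er),
                "true_label": true_label(psi, event.type),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read generation


def _iso_to_blocks(
    exons: list[tuple[int, int]], s: int, e: int
) -> list[tuple[int, int]]:
    """Project the isoform-coordinate interval [s, e) onto genomic blocks."""
    blocks = []
    off = 0
    for a, b in exons:
        ln = b - a
        lo, hi = max(s - off, 0), min(e - off, ln)
        if lo < hi:
            blocks.append((a + lo, a + hi))
        off += ln
    return blocks


def _cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (a, b) in enumerate(blocks):
        if i:
            cig.append((3, a - blocks[i - 1][1]))  # N
        cig.append((0, b - a))  # M
    return cig


def simulate_reads(
    dataset: SimulatedDataset,
    truth,
    config: SimConfig,
    out_dir: str,
    basename: str = "reads",
) -> dict[str, str]:
    """Sample error-free paired reads and write SAM + FASTQ + truth TSV.

    Read pairs per isoform number round(depth * fraction * length / (2L)),
    which reproduces the target fold-coverage; fragment starts are uniform
    along the isoform.  Records are emitted coordinate-sorted, so the SAM
    is ready for counting (and for samtools conversion to indexed BAM).
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)
    L = config.read_length
    psi_by_gene = dict(zip(truth["gene_id"], truth["true_psi"]))

    chroms = list(dataset.sequences)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": len(dataset.sequences[c])} for c in chroms
            ],
        }
    )
    chrom_id = {c: i for i, c in enumerate(chroms)}

    # (chrom_idx, pos, name, flag, cigar, seq, mate_pos, tlen)
    records: list[tuple] = []
    fq1: list[tuple[str, str]] = []
    fq2: list[tuple[str, str]] = []

    for gene_id, iso_list in dataset.isoforms.items():
        gene = dataset.annotation.genes[gene_id]
        seq = dataset.sequences[gene.seqname]
        psi = psi_by_gene[gene_id]
        for iso_id, exons, role in iso_list:
            iso_len = sum(b - a for a, b in exons)
            if iso_len < L:
                logger.warning(
                    "gene %s isoform %s shorter than a read; skipped",
                    gene_id,
                    iso_id,
                )
                continue
            frac = psi if role == "inclusion" else 1.0 - psi
            n_pairs = int(round(config.mean_depth * frac * iso_len / (2 * L)))
            if n_pairs == 0:
                continue
            flens = (
                rng.normal(config.fragment_mean, config.fragment_sd, n_pairs)
                .round()
                .astype(int)
                .clip(L, iso_len)
            )
            starts = rng.integers(0, iso_len - flens + 1)
            for k in range(n_pairs):
                fs, fl = int(starts[k]), int(flens[k])
                name = f"{iso_id}:{k}"
                m1 = _iso_to_blocks(exons, fs, fs + L)
                m2 = _iso_to_blocks(exons, fs + fl - L, fs + fl)
                s1 = "".join(seq[a:b] for a, b in m1)
                s2 = "".join(seq[a:b] for a, b in m2)
                p1, p2 = m1[0][0], m2[0][0]
                tlen = m2[-1][1] - p1
                cid = chrom_id[gene.seqname]
                records.append(
                    (cid, p1, name, 99, _cigar(m1), s1, p2, tlen)
                )
                records.append(
                    (cid, p2, name, 147, _cigar(m2), s2, p1, -tlen)
                )
                fq1.append((name, s1))
                fq2.append((name, _revcomp(s2)))

    records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))

    sam_path = os.path.join(out_dir, f"{basename}.sam")
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for cid, pos, name, flag, cigar, seq_, mpos, tlen in records:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_id = cid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_sequence = seq_
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq_))
            a.next_reference_id = cid
            a.next_reference_start = mpos
            a.template_length = tlen
            out.write(a)

    fq1_path = os.path.join(out_dir, f"{basename}_1.fastq")
    fq2_path = os.path.join(out_dir, f"{basename}_2.fastq")
    for path, reads in ((fq1_path, fq1), (fq2_path, fq2)):
        with open(path, "w") as fh:
            for name, s in reads:
                fh.write(f"@{name}\n{s}\n+\n{'I' * len(s)}\n")

    truth_path = os.path.join(out_dir, f"{basename}.truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "sam": sam_path,
        "fastq_1": fq1_path,
        "fastq_2": fq2_path,
        "truth": truth_path,
    }


def simulate_dataset(config: SimConfig, out_dir: str) -> dict:
    """Full simulation: genome, annotation, abundances, reads and manifest."""
    os.makedirs(out_dir, exist_ok=True)
    dataset = simulate_annotation(config)
    truth = assign_abundances(dataset, config)
    paths = simulate_reads(dataset, truth, config, out_dir)
    fasta = os.path.join(out_dir, "genome.fa")
    gff3 = os.path.join(out_dir, "annotation.gff3")
    dataset.write_fasta(fasta)
    dataset.write_gff3(gff3)
    paths.update({"fasta": fasta, "gff3": gff3})
    manifest = {"seed": config.seed, "n_genes": config.n_genes, "paths": paths}
    manifest_path = os.path.join(out_dir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = manifest_path
    return {
        "dataset": dataset,
        "truth": truth,
        "paths": paths,
    }
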