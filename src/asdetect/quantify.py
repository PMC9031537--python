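"""Percent-spliced-in (PSI) estimation and positive/negative classification.

For an intron-retention event the PSI of the intron is

    PSI = 0.5 * (N_E1_I + N_I_E2) / (0.5 * (N_E1_I + N_I_E2) + N_E1_E2)

on effective-length-normalised junction counts.  Exon skipping follows the
same half-weighted-inclusion pattern over its two inclusion junctions and
one exclusion junction, and alternative splice sites reduce to the two-way
ratio N_long / (N_long + N_short).  The intron-body count N_I is computed
and reported by the counting step but takes no part in PSI.

An event with zero evidence in the denominator has an *undefined* PSI and
is excluded from classification, benchmarking and differential testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .counting import JunctionCounts

__all__ = [
    "PSIRecord",
    "psi_ir",
    "psi_es",
    "psi_altss",
    "event_psi",
    "classify",
    "compute_psi",
    "psi_table",
    "write_psi_table",
    "read_psi_table",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class PSIRecord:
    event_id: str
    sample_id: str
    type: str
    gene_id: str
    psi: float | None
    inclusion_reads: int
    exclusion_reads: int
    classification: str | None
    known: bool = True
    clean: bool = True


def _check_nonneg(values: dict[str, float]) -> None:
    for k, v in values.items():
        if v < 0:
            raise ValueError(f"negative junction count for {k}: {v}")


def psi_ir(counts: JunctionCounts | dict[str, float]) -> float | None:
    """PSI of a retained intron from normalised junction counts."""
    n = counts.normalized if isinstance(counts, JunctionCounts) else counts
    _check_nonneg(n)
    inclusion = 0.5 * (n["E1_I"] + n["I_E2"])
    denom = inclusion + n["E1_E2"]
    if denom == 0:
        return None
    return inclusion / denom


def psi_es(counts: JunctionCounts | dict[str, float]) -> float | None:
    """PSI of a cassette exon: half-weighted flanking junctions over total."""
    n = counts.normalized if isinstance(counts, JunctionCounts) else counts
    _check_nonneg(n)
    inclusion = 0.5 * (n["E1_E2"] + n["E2_E3"])
    denom = inclusion + n["E1_E3"]
    if denom == 0:
        return None
    return inclusion / denom


def psi_altss(counts: JunctionCounts | dict[str, float]) -> float | None:
    """PSI of an alternative splice site: fraction of the long mature form."""
    n = counts.normalized if isinstance(counts, JunctionCounts) else counts
    _check_nonneg(n)
    denom = n["long"] + n["short"]
    if denom == 0:
        return None
    return n["long"] / denom


def event_psi(counts: JunctionCounts) -> float | None:
    if counts.event.type == "IR":
        return psi_ir(counts)
    if counts.event.type == "ES":
        return psi_es(counts)
    return psi_altss(counts)


def classify(
    psi: float | None, type: str, threshold: float = 0.1
) -> str | None:
    """Positive/negative call at the PSI threshold.

    IR/A5SS/A3SS events are positive when PSI >= threshold.  For ES the
    rule is inverted — skipping is the alternative outcome, so the event
    is positive when PSI <= 1 - threshold.  Undefined PSI stays undefined.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("threshold must lie in (0, 0.5]")
    if psi is None:
        return None
    if type == "ES":
        return POSITIVE if psi <= 1 - threshold else NEGATIVE
    return POSITIVE if psi >= threshold else NEGATIVE


_INCLUSION = {
    "IR": ("E1_I", "I_E2"),
    "ES": ("E1_E2", "E2_E3"),
    "A5SS": ("long",),
    "A3SS": ("long",),
}
_EXCLUSION = {
    "IR": ("E1_E2",),
    "ES": ("E1_E3",),
    "A5SS": ("short",),
    "A3SS": ("short",),
}


def compute_psi(
    counts: list[JunctionCounts],
    sample_id: str = "sample",
    threshold: float = 0.1,
) -> list[PSIRecord]:
    """PSI and classification for every counted event of one sample."""
    records = []
    for jc in counts:
        ev = jc.event
        psi = event_psi(jc)
        records.append(
            PSIRecord(
                event_id=jc.event_id,
                sample_id=sample_id,
                type=ev.type,
                gene_id=ev.gene_id,
                psi=psi,
                inclusion_reads=sum(jc.raw[k] for k in _INCLUSION[ev.type]),
                exclusion_reads=sum(jc.raw[k] for k in _EXCLUSION[ev.type]),
                classification=classify(psi, ev.type, threshold),
                known=ev.known,
                clean=ev.clean,
            )
        )
    return records


def psi_table(records: list[PSIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in records],
            "sample_id": [r.sample_id for r in records],
            "type": [r.type for r in records],
            "gene_id": [r.gene_id for r in records],
            "psi": [r.psi for r in records],
            "inclusion_reads": [r.inclusion_reads for r in records],
            "exclusion_reads": [r.exclusion_reads for r in records],
            "classification": [r.classification for r in records],
            "known": [r.known for r in records],
            "clean": [r.clean for r in records],
        }
    )


def write_psi_table(records: list[PSIRecord], path: str) -> None:
    # classification is made at full precision; only the file is rounded
    df = psi_table(records)
    df["psi"] = df["psi"].round(4)
    df.to_csv(path, sep="\t", index=False)


def read_psi_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
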