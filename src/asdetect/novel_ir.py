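"""Novel intron-retention calls at known splice sites.

Annotated introns that no transcript retains are scanned for retention
signal: the usual IR junction counts and PSI are computed, and a
candidate is accepted only when (1) PSI clears the positive threshold
and (2) the two flanking junctions are balanced — with the default
criterion, both the exon-intron and the intron-exon junction must carry
at least one read.  A retention signal supported from one side only
(e.g. reads on I_E2 but none on E1_I) is rejected even if its PSI is
above threshold, since one-sided coverage is the signature of an
alternative transcription start/end rather than a retained intron.

Only *clean* introns are scanned, so the junction evidence cannot be
confounded by overlapping exons of sibling transcripts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .annotation import ASEvent, GenomeAnnotation, enumerate_all_introns
from .counting import CountConfig, alignment_blocks, count_events, read_alignments
from .quantify import psi_ir

__all__ = [
    "NovelIRCall",
    "balance_test",
    "scan_novel_ir",
    "region_depth",
    "plot_ir_event",
]


@dataclass
class NovelIRCall:
    event: ASEvent
    psi: float | None
    raw: dict[str, int]
    normalized: dict[str, float]
    balanced: bool
    accepted: bool


def balance_test(raw_e1_i: int, raw_i_e2: int, rho: float = 0.0) -> bool:
    """Are the two flanking junction counts balanced?

    False whenever either count is zero; otherwise the smaller count must
    be at least ``rho`` times the larger (rho = 0 reduces to the
    both-nonzero rule).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if raw_e1_i < 0 or raw_i_e2 < 0:
        raise ValueError("junction counts must be non-negative")
    if raw_e1_i == 0 or raw_i_e2 == 0:
        return False
    return min(raw_e1_i, raw_i_e2) / max(raw_e1_i, raw_i_e2) >= rho


def scan_novel_ir(
    annotation: GenomeAnnotation,
    alignments: str,
    config: CountConfig | None = None,
    threshold: float = 0.1,
    rho: float = 0.0,
    include_known: bool = False,
) -> list[NovelIRCall]:
    """Score every clean, un-retained annotated intron for retention.

    With ``include_known=True`` the scan also covers introns already
    annotated as retained, which is useful to cross-check PSI values
    against the quantification module.
    """
    config = config or CountConfig()
    candidates = [
        ev
        for ev in enumerate_all_introns(annotation)
        if ev.clean and (include_known or not ev.known)
    ]
    counts, _ = count_events(candidates, alignments, config)
    calls = []
    for jc in counts:
        psi = psi_ir(jc)
        balanced = balance_test(jc.raw["E1_I"], jc.raw["I_E2"], rho)
        accepted = psi is not None and psi >= threshold and balanced
        calls.append(
            NovelIRCall(
                event=jc.event,
                psi=psi,
                raw=dict(jc.raw),
                normalized=jc.normalized,
                balanced=balanced,
                accepted=accepted,
            )
        )
    calls.sort(key=lambda c: (c.event.seqname, c.event.span))
    return calls


# ---------------------------------------------------------------------------
# visualization


def region_depth(
    alignments: str, seqname: str, start: int, end: int
) -> np.ndarray:
    """Per-base aligned read depth over [start, end) from primary records."""
    if end <= start:
        raise ValueError("zero-length region")
    depth = np.zeros(end - start, dtype=int)
    for read in read_alignments(alignments):
        if read.reference_name != seqname:
            continue
        blocks, _ = alignment_blocks(read)
        for a, b in blocks:
            lo, hi = max(a, start), min(b, end)
            if lo < hi:
                depth[lo - start : hi - start] += 1
    return depth


def plot_ir_event(
    event: ASEvent,
    alignments: str,
    output: str,
    config: CountConfig | None = None,
    margin: int = 50,
) -> str:
    """Render the coverage profile and gene model of one IR locus.

    Per-base depth is drawn as bars over the event span; the gene model
    below uses rectangles for the flanking exons and a line for the
    intron.  The inclusion read count (E1_I + I_E2 junction reads) is
    annotated in red and the exclusion count (E1_E2) in blue, matching
    the convention of the published visualizations.  The figure is saved
    to ``output`` (format from the extension; SVG recommended).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    out_dir = os.path.dirname(output) or "."
    if not os.path.isdir(out_dir):
        raise FileNotFoundError(f"output directory {out_dir!r} does not exist")

    config = config or CountConfig()
    start = max(event.span[0] - margin, 0)
    end = event.span[1] + margin
    depth = region_depth(alignments, event.seqname, start, end)

    counts, _ = count_events([event], alignments, config)
    raw = counts[0].raw if counts else {"E1_I": 0, "I_E2": 0, "E1_E2": 0}
    inclusion = raw["E1_I"] + raw["I_E2"]
    exclusion = raw["E1_E2"]

    fig, (ax, ax_model) = plt.subplots(
        2,
        1,
        figsize=(9, 3.5),
        sharex=True,
        gridspec_kw={"height_ratios": [4, 1]},
        layout="constrained",
    )
    x = np.arange(start, end)
    ax.bar(x, depth, width=1.0, color="0.6", linewidth=0)
    ax.set_ylabel("depth")
    ax.set_title(
        f"{event.event_id} ({event.gene_id}, {event.strand})", fontsize=10
    )
    top = max(depth.max(), 1)
    intron = event.coords["intron"]
    ax.text(
        intron[0], top, f"{inclusion}", color="red", ha="right", va="top"
    )
    ax.text(
        intron[1], top, f"{exclusion}", color="blue", ha="left", va="top"
    )

    ax_model.set_ylim(0, 1)
    ax_model.axhline(0.5, color="steelblue", lw=1.5, zorder=1)
    for key in ("exon1", "exon2"):
        a, b = event.coords[key]
        ax_model.add_patch(
            Rectangle((a, 0.25), b - a, 0.5, color="steelblue", zorder=2)
        )
    ax_model.set_yticks([])
    ax_model.set_xlabel(f"{event.seqname}:{start}-{end}")
    ax_model.set_xlim(start, end)

    fig.savefig(output)
    plt.close(fig)
    return output
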