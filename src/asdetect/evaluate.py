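"""Recall/precision benchmarking of event calls against a truth table.

    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)

where TP are truth-positive events predicted positive, FP truth-negative
events predicted positive, and FN truth-positive events predicted
negative.  Following the evaluation protocol, only events labelled
*known* and *clean* are scored by default, and an event whose PSI is
undefined counts as predicted negative.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import pandas as pd

from .annotation import extract_events
from .counting import CountConfig, count_events
from .quantify import PSIRecord, compute_psi, psi_table
from .simulate import SimConfig, assign_abundances, simulate_annotation, simulate_reads

__all__ = [
    "Confusion",
    "evaluate",
    "recall",
    "precision",
    "benchmark",
    "benchmark_by_type",
]


@dataclass
class Confusion:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "Confusion") -> "Confusion":
        return Confusion(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


def recall(c: Confusion) -> float | None:
    """TP / (TP + FN); None (reported as NA) when there are no positives."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def precision(c: Confusion) -> float | None:
    """TP / (TP + FP); None when nothing was predicted positive."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def evaluate(
    predictions: list[PSIRecord] | pd.DataFrame,
    truth: pd.DataFrame,
    restrict_known_clean: bool = True,
) -> dict[str, Confusion]:
    """Confusion counts per AS type (plus ``"all"`` pooled).

    ``predictions`` and ``truth`` are joined on event_id; an empty join is
    an error.  Undefined predictions (PSI with no read evidence) count as
    predicted negative.
    """
    pred = predictions if isinstance(predictions, pd.DataFrame) else psi_table(predictions)
    if restrict_known_clean:
        pred = pred[pred["known"].astype(bool) & pred["clean"].astype(bool)]
    merged = pred.merge(
        truth[["event_id", "true_label"]], on="event_id", how="inner"
    )
    if len(merged) == 0:
        raise ValueError("prediction and truth tables share no event_id")

    out: dict[str, Confusion] = {}
    overall = Confusion()
    for type_, grp in merged.groupby("type"):
        pred_pos = grp["classification"] == "positive"
        true_pos = grp["true_label"] == "positive"
        c = Confusion(
            tp=int((pred_pos & true_pos).sum()),
            fp=int((pred_pos & ~true_pos).sum()),
            fn=int((~pred_pos & true_pos).sum()),
        )
        out[str(type_)] = c
        overall = overall + c
    out["all"] = overall
    return out


def benchmark(
    seed: int = 42,
    n_genes: int = 300,
    event_mix: dict[str, float] | None = None,
    mean_depth: float = 70.0,
    read_length: int = 150,
    m: int = 8,
    threads: int = 1,
    out_dir: str | None = None,
) -> dict:
    """One-seed pipeline: simulate -> count -> PSI -> evaluate.

    Returns the confusion table, per-type recall/precision, the truth
    table and the per-event PSI records.
    """
    cfg = SimConfig(
        n_genes=n_genes,
        event_mix=event_mix or {"IR": 0.25, "ES": 0.25, "A5SS": 0.25, "A3SS": 0.25},
        read_length=read_length,
        mean_depth=mean_depth,
        seed=seed,
    )
    with tempfile.TemporaryDirectory() as tmp:
        work = out_dir or tmp
        dataset = simulate_annotation(cfg)
        truth = assign_abundances(dataset, cfg)
        paths = simulate_reads(dataset, truth, cfg, work)
        events = extract_events(dataset.annotation)
        counts, dropped = count_events(
            events,
            paths["sam"],
            CountConfig(m=m, read_length=read_length, threads=threads),
        )
        records = compute_psi(counts, sample_id=f"sim_seed{seed}")

    confusion = evaluate(records, truth)
    metrics = {
        type_: {
            "recall": recall(c),
            "precision": precision(c),
            "tp": c.tp,
            "fp": c.fp,
            "fn": c.fn,
        }
        for type_, c in confusion.items()
    }
    return {
        "config": cfg,
        "confusion": confusion,
        "metrics": metrics,
        "truth": truth,
        "records": records,
        "n_dropped": len(dropped),
    }


def benchmark_by_type(
    seed: int = 42,
    n_genes_per_type: int = 300,
    mean_depth: float = 70.0,
    m: int = 8,
) -> dict[str, dict]:
    """Recall/precision per AS type from single-type simulations.

    Each type is benchmarked on its own simulation of ``n_genes_per_type``
    genes (margin-sampled true PSI, error-free paired reads), mirroring a
    per-type evaluation design.
    """
    out = {}
    for type_ in ("IR", "ES", "A5SS", "A3SS"):
        mix = {t: (1.0 if t == type_ else 0.0) for t in ("IR", "ES", "A5SS", "A3SS")}
        res = benchmark(
            seed=seed,
            n_genes=n_genes_per_type,
            event_mix=mix,
            mean_depth=mean_depth,
            m=m,
        )
        out[type_] = res["metrics"][type_]
    return out
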