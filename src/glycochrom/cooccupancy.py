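"""Promoter-restricted peak co-occupancy screen.

Given a query peak set (e.g. O-GlcNAc CUT&RUN peaks) the screen keeps only
query peaks at promoters (TSS +/- flank), then for each reference peak set
in a library reports the percentage of those promoter query peaks hit by at
least one reference peak.  Rows are ranked by descending percentage.  Two
screens of the same library (before/after a perturbation) can be paired to
report per-reference fold changes of the percentage.

The statistic is peak-level recall of the query: a reference "hits" a query
peak when they share >= min_bp bases; reference peaks are used genome-wide
but only promoter-overlapping query peaks are scored.  An optional
base-pair mode reports the Jaccard index of covered bases instead.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    PeakSet,
    intersect_regions,
    overlap_mask,
    tss_windows,
    union,
)

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = ["reference", "n_query", "n_overlapped", "percent_overlap"]


def restrict_to_promoters(
    query: PeakSet, genes: Sequence[GeneModel], flank: int = 1000, min_bp: int = 1
) -> PeakSet:
    """Subset of query peaks overlapping >= 1 TSS +/- flank window."""
    if not genes:
        raise ValueError("gene set is empty")
    windows = tss_windows(genes, flank)
    hit = overlap_mask(query, windows, min_bp)
    return PeakSet(
        [iv for iv, h in zip(query, hit) if h],
        label=f"{query.label}@promoters",
        genome=query.genome,
    )


def overlap_percent(
    query: PeakSet, reference: PeakSet, min_bp: int = 1
) -> tuple[int, int, float]:
    """(n, k, 100*k/n): query peaks hit by >= 1 reference peak by >= min_bp."""
    n = len(query)
    if n == 0:
        raise ValueError("no peaks after promoter restriction")
    k = int(overlap_mask(query, reference, min_bp).sum())
    return n, k, 100.0 * k / n


def basepair_jaccard(query: PeakSet, reference: PeakSet) -> float:
    """Jaccard index of covered base pairs (the optional base-pair screen mode)."""
    inter = intersect_regions(query, reference).total_bp()
    uni = union(query, reference).total_bp()
    return inter / uni if uni else 0.0


def screen_library(
    query: PeakSet,
    library: Mapping[str, PeakSet],
    genes: Sequence[GeneModel],
    flank: int = 1000,
    min_bp: int = 1,
    mode: str = "peak",
) -> pd.DataFrame:
    """Screen a reference library against promoter-restricted query peaks.

    Returns one row per reference, sorted by descending percent_overlap with
    lexicographic reference-id tie-breaking for deterministic output.
    """
    if mode not in ("peak", "basepair"):
        raise ValueError(f"unknown screen mode {mode!r}")
    promoter_query = restrict_to_promoters(query, genes, flank, min_bp)
    if len(promoter_query) == 0:
        raise ValueError("no peaks after promoter restriction")
    rows = []
    for ref_id in library:
        try:
            reference = library[ref_id]
            if mode == "peak":
                n, k, pct = overlap_percent(promoter_query, reference, min_bp)
            else:
                n = len(promoter_query)
                k = -1
                pct = 100.0 * basepair_jaccard(promoter_query, reference)
            rows.append({"reference": ref_id, "n_query": n, "n_overlapped": k, "percent_overlap": pct})
        except (ValueError, OSError) as exc:  # unparseable reference: skip, not fatal
            logger.warning("reference %s skipped: %s", ref_id, exc)
    table = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    return table.sort_values(
        ["percent_overlap", "reference"], ascending=[False, True], ignore_index=True
    )


def compare_conditions(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Pair two screens of the same library and add percentage fold changes.

    fold_change = percent_after / percent_before; rows with percent_before = 0
    get NaN fold_change and an explicit "undefined(0->x)" annotation instead
    of a silent infinity.
    """
    ids_before = set(before["reference"])
    ids_after = set(after["reference"])
    if ids_before != ids_after:
        raise ValueError(
            "screens cover different libraries: only-before="
            f"{sorted(ids_before - ids_after)}, only-after={sorted(ids_after - ids_before)}"
        )
    merged = before.merge(after, on="reference", suffixes=("_before", "_after"))
    pb = merged["percent_overlap_before"].to_numpy(dtype=float)
    pa = merged["percent_overlap_after"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(pb > 0, pa / pb, np.nan)
    merged["fold_change"] = fc
    merged["fold_change_note"] = [
        "" if b > 0 else f"undefined(0->{a:g})" for b, a in zip(pb, pa)
    ]
    return merged.sort_values(
        ["percent_overlap_after", "reference"], ascending=[False, True], ignore_index=True
    )


def read_library_manifest(path: str) -> dict[str, str]:
    """TSV manifest of (id, path) -> ordered mapping id -> path."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "path"], dtype=str)
    if df["id"].duplicated().any():
        raise ValueError("duplicate reference ids in library manifest")
    return dict(zip(df["id"], df["path"]))
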