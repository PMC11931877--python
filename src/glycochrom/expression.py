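"""Linking promoter occupancy to gene expression.

Two analyses: (1) stratify promoters by query-peak occupancy into n-matched
groups (occupied / unoccupied / random) and compare expression distributions
with a two-sided Mann-Whitney-Wilcoxon test; (2) intersect an externally
produced differential-expression table with peaks to call direct targets
(significant genes whose promoter overlaps a peak).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, PeakSet, overlap_mask, tss_windows

logger = logging.getLogger(__name__)


def load_expression(path: str) -> dict[str, float]:
    """Headered TSV (gene_id, expression) -> mapping; validates non-negative, unique."""
    df = pd.read_csv(path, sep="\t")
    gene_col, value_col = df.columns[0], df.columns[1]
    if df[gene_col].duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    if (df[value_col] < 0).any():
        raise ValueError("negative expression values")
    return dict(zip(df[gene_col].astype(str), df[value_col].astype(float)))


def load_deg_table(path: str) -> pd.DataFrame:
    """Headered TSV with gene_id, log2FC, adjusted_p columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FC", "adjusted_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns {sorted(missing)}")
    if ((df["adjusted_p"] < 0) | (df["adjusted_p"] > 1)).any():
        raise ValueError("adjusted_p outside [0, 1]")
    return df


def mann_whitney_two_sided(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney-Wilcoxon test; returns (U, p).

    The statistic is min(U_x, U_y), where U_x counts pairs (x_i, y_j) with
    x_i > y_j plus half the ties.  p is exact (full null enumeration) when
    |x| + |y| <= 16 with no ties, otherwise a normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u_x = float(res.statistic)
    u = min(u_x, len(x) * len(y) - u_x)
    return u, float(res.pvalue)


@dataclass
class StratifiedComparison:
    """n-matched occupancy strata with medians and the occupied-vs-unoccupied test."""

    occupied: list[str]
    unoccupied_matched: list[str]
    random_matched: list[str]
    all_genes: list[str]
    medians: dict[str, float]
    u_statistic: float
    p_value: float
    seed: int

    def summary(self) -> dict:
        return {
            "n_per_group": len(self.occupied),
            "n_all": len(self.all_genes),
            "medians": self.medians,
            "U": self.u_statistic,
            "p_two_sided": self.p_value,
            "seed": self.seed,
        }


def stratify_by_occupancy(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    expr: Mapping[str, float],
    flank: int = 1000,
    seed: int = 0,
    min_bp: int = 1,
    top_n: int | None = None,
) -> StratifiedComparison:
    """Compare expression of peak-occupied promoters against matched controls.

    occupied = genes whose TSS +/- flank window overlaps >= 1 peak (optionally
    restricted to the top_n by best overlapping peak score);
    unoccupied_matched = seeded simple random sample of equal size from genes
    with zero overlap; random_matched = seeded sample of equal size from all
    genes.  The reported test is occupied vs unoccupied_matched, two-sided.
    """
    genes_expr = [g for g in genes if g.gene_id in expr]
    dropped = len(genes) - len(genes_expr)
    if dropped:
        logger.warning("%d genes without expression values dropped", dropped)
    if not genes_expr:
        raise ValueError("no genes with expression values")
    windows = tss_windows(genes_expr, flank)
    # windows sort by coordinate: map back to gene ids through window names
    hit_by_gene: dict[str, bool] = {}
    from .intervals import overlaps as _overlaps

    hit = overlap_mask(windows, peaks, min_bp)
    for w, h in zip(windows, hit):
        hit_by_gene[w.name] = bool(h)
    occupied = [g.gene_id for g in genes_expr if hit_by_gene[g.gene_id]]
    unoccupied = [g.gene_id for g in genes_expr if not hit_by_gene[g.gene_id]]
    if top_n is not None and top_n < len(occupied):
        ov = _overlaps(windows, peaks, min_bp)
        best: dict[str, float] = {}
        for w, hits in ov.items():
            if hits:
                best[w.name] = max((h.score or 0.0) for h in hits)
        occupied = sorted(occupied, key=lambda g: (-best.get(g, 0.0), g))[:top_n]
    if not occupied:
        raise ValueError("no occupied promoters (no peak overlaps any TSS window)")
    n = len(occupied)
    if len(unoccupied) < n:
        raise ValueError(
            f"cannot draw {n} unoccupied controls: only {len(unoccupied)} available"
        )
    rng = np.random.default_rng(seed)
    unocc_sample = sorted(rng.choice(unoccupied, size=n, replace=False))
    all_ids = [g.gene_id for g in genes_expr]
    rand_sample = sorted(rng.choice(all_ids, size=n, replace=False))
    vals = lambda ids: [expr[g] for g in ids]
    u, p = mann_whitney_two_sided(vals(occupied), vals(unocc_sample))
    medians = {
        "occupied": float(np.median(vals(occupied))),
        "unoccupied_matched": float(np.median(vals(unocc_sample))),
        "random_matched": float(np.median(vals(rand_sample))),
        "all": float(np.median(vals(all_ids))),
    }
    return StratifiedComparison(
        occupied, list(unocc_sample), list(rand_sample), all_ids, medians, u, p, seed
    )


def call_direct_targets(
    degs: pd.DataFrame,
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    flank: int = 1000,
    alpha: float = 0.05,
    min_bp: int = 1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag significant DEGs whose promoter window overlaps >= 1 peak.

    Returns (per-gene table with direction/direct columns, summary counts).
    DEG rows whose gene_id has no gene model are skipped, counted, logged.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    sig = degs[degs["adjusted_p"] < alpha]
    rows = []
    n_missing = 0
    for rec in sig.itertuples(index=False):
        g = gene_by_id.get(str(rec.gene_id))
        if g is None:
            n_missing += 1
            continue
        window = tss_windows([g], flank)
        direct = bool(overlap_mask(window, peaks, min_bp)[0])
        rows.append(
            {
                "gene_id": g.gene_id,
                "log2FC": float(rec.log2FC),
                "adjusted_p": float(rec.adjusted_p),
                "direction": "up" if rec.log2FC > 0 else "down",
                "direct": direct,
            }
        )
    if n_missing:
        logger.warning("%d significant DEGs without gene models skipped", n_missing)
    table = pd.DataFrame(
        rows, columns=["gene_id", "log2FC", "adjusted_p", "direction", "direct"]
    )
    summary = {
        "n_up": int((table["direction"] == "up").sum()) if len(table) else 0,
        "n_down": int((table["direction"] == "down").sum()) if len(table) else 0,
        "n_up_direct": int(((table["direction"] == "up") & table["direct"]).sum()) if len(table) else 0,
        "n_down_direct": int(((table["direction"] == "down") & table["direct"]).sum()) if len(table) else 0,
        "n_skipped_no_gene_model": n_missing,
    }
    return table, summary
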