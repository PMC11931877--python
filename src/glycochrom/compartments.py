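"""Rule-based functional genomic compartments and multi-membership peak classification.

Seven compartments are built from mark/factor peak sets and gene anchors:

* ActivePromoter — H3K27ac peaks overlapping a TSS +/- 1 kb window (the peak
  intervals are retained);
* TranscriptionInitiation — TSS +/- 1 kb windows overlapping a Ser5P peak
  (the window intervals are retained);
* Heterochromatin — H3K9me3 peak intervals verbatim;
* BivalentPromoter — TSS windows overlapped by both an H3K4me3 and an
  H3K27me3 peak;
* Polycomb — base-pair intersections of Suz12 and RING1B peaks;
* TranscriptionElongation — Ser2P peaks overlapping the gene-body window
  from TSS advanced 1 kb in the direction of transcription to the TES;
* TranscriptionTermination — the 50 bp immediately downstream of each TES.

A query peak set is then classified with multi-membership: each peak carries
the set of compartments it overlaps (possibly empty), and counts are
reported both per exclusive label combination (upset style) and per single
compartment (marginal totals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .intervals import (
    GeneModel,
    GenomeSpec,
    GenomicInterval,
    PeakSet,
    intersect_regions,
    merge,
    overlap_mask,
    overlaps,
    tss_windows,
)

logger = logging.getLogger(__name__)

COMPARTMENT_NAMES = (
    "ActivePromoter",
    "TranscriptionInitiation",
    "Heterochromatin",
    "BivalentPromoter",
    "Polycomb",
    "TranscriptionElongation",
    "TranscriptionTermination",
)

#: Marks each compartment rule needs (TranscriptionTermination needs genes only).
REQUIRED_MARKS = {
    "ActivePromoter": ("H3K27ac",),
    "TranscriptionInitiation": ("Ser5P",),
    "Heterochromatin": ("H3K9me3",),
    "BivalentPromoter": ("H3K4me3", "H3K27me3"),
    "Polycomb": ("Suz12", "RING1B"),
    "TranscriptionElongation": ("Ser2P",),
    "TranscriptionTermination": (),
}


@dataclass
class CompartmentRules:
    """Inputs and window parameters for the seven compartment definitions.

    ``retain`` switches, per promoter-anchored rule, whether the mark peak or
    the TSS window interval is kept; defaults follow the literal rule
    phrasing (peaks for ActivePromoter, windows for TranscriptionInitiation
    and BivalentPromoter).
    """

    marks: Mapping[str, PeakSet]
    genes: Sequence[GeneModel]
    genome: GenomeSpec | None = None
    promoter_flank: int = 1000
    tes_extension: int = 50
    elongation_body_offset: int = 1000
    min_bp: int = 1
    retain: Mapping[str, str] = field(default_factory=dict)
    polycomb_mode: str = "intersection"  # or "reciprocal-union"


@dataclass
class CompartmentMap:
    """Named merged interval sets, one per compartment that could be built."""

    compartments: dict[str, PeakSet]

    def __getitem__(self, name: str) -> PeakSet:
        return self.compartments[name]

    def __contains__(self, name: str) -> bool:
        return name in self.compartments

    def names(self) -> list[str]:
        return list(self.compartments)


@dataclass
class PeakClassification:
    """Per-peak compartment label sets plus exclusive and marginal counts."""

    peaks: PeakSet
    labels: list[frozenset[str]]
    combination_counts: dict[frozenset[str], int]
    single_counts: dict[str, int]

    def per_peak_table(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name or f"peak_{i}",
                "compartments": ",".join(sorted(lab)) if lab else "unassigned",
            }
            for i, (iv, lab) in enumerate(zip(self.peaks, self.labels))
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "compartments"])


def _retained(rules: CompartmentRules, name: str, default: str) -> str:
    mode = rules.retain.get(name, default)
    if mode not in ("peak", "window"):
        raise ValueError(f"retain mode for {name} must be 'peak' or 'window'")
    return mode


def build_compartments(rules: CompartmentRules) -> CompartmentMap:
    """Evaluate the seven compartment rules; missing marks disable a rule.

    All outputs are merged (non-overlapping within each compartment);
    compartments may overlap each other.
    """
    marks = rules.marks
    genes = rules.genes
    genome = rules.genome
    windows = tss_windows(genes, rules.promoter_flank, genome) if genes else PeakSet([])
    out: dict[str, PeakSet] = {}

    def available(name: str) -> bool:
        missing = [m for m in REQUIRED_MARKS[name] if m not in marks]
        if missing:
            logger.warning("compartment %s disabled: missing marks %s", name, missing)
            return False
        return True

    if available("ActivePromoter"):
        peaks = marks["H3K27ac"]
        if _retained(rules, "ActivePromoter", "peak") == "peak":
            hit = overlap_mask(peaks, windows, rules.min_bp)
            kept = [iv for iv, h in zip(peaks, hit) if h]
        else:
            hit = overlap_mask(windows, peaks, rules.min_bp)
            kept = [iv for iv, h in zip(windows, hit) if h]
        out["ActivePromoter"] = merge(PeakSet(kept, "ActivePromoter", genome))

    if available("TranscriptionInitiation"):
        peaks = marks["Ser5P"]
        if _retained(rules, "TranscriptionInitiation", "window") == "window":
            hit = overlap_mask(windows, peaks, rules.min_bp)
            kept = [iv for iv, h in zip(windows, hit) if h]
        else:
            hit = overlap_mask(peaks, windows, rules.min_bp)
            kept = [iv for iv, h in zip(peaks, hit) if h]
        out["TranscriptionInitiation"] = merge(PeakSet(kept, "TranscriptionInitiation", genome))

    if available("Heterochromatin"):
        out["Heterochromatin"] = merge(marks["H3K9me3"].with_label("Heterochromatin"))

    if available("BivalentPromoter"):
        h4 = overlap_mask(windows, marks["H3K4me3"], rules.min_bp)
        h27 = overlap_mask(windows, marks["H3K27me3"], rules.min_bp)
        kept = [iv for iv, a, b in zip(windows, h4, h27) if a and b]
        out["BivalentPromoter"] = merge(PeakSet(kept, "BivalentPromoter", genome))

    if available("Polycomb"):
        suz, ring = marks["Suz12"], marks["RING1B"]
        if rules.polycomb_mode == "intersection":
            out["Polycomb"] = intersect_regions(suz, ring).with_label("Polycomb")
        elif rules.polycomb_mode == "reciprocal-union":
            hs = overlap_mask(suz, ring, rules.min_bp)
            hr = overlap_mask(ring, suz, rules.min_bp)
            kept = [iv for iv, h in zip(suz, hs) if h] + [iv for iv, h in zip(ring, hr) if h]
            out["Polycomb"] = merge(PeakSet(kept, "Polycomb", genome))
        else:
            raise ValueError(f"unknown polycomb_mode {rules.polycomb_mode!r}")

    if available("TranscriptionElongation"):
        bodies = []
        for g in genes:
            # window from TSS advanced by the offset (strand-aware) to the TES;
            # genes shorter than the offset contribute nothing
            if len(range(g.start, g.end)) <= rules.elongation_body_offset:
                continue
            if g.strand == "+":
                bodies.append(GenomicInterval(g.chrom, g.start + rules.elongation_body_offset, g.end, name=g.gene_id))
            else:
                bodies.append(GenomicInterval(g.chrom, g.start, g.end - rules.elongation_body_offset, name=g.gene_id))
        body_set = PeakSet(bodies, genome=genome)
        hit = overlap_mask(marks["Ser2P"], body_set, rules.min_bp)
        kept = [iv for iv, h in zip(marks["Ser2P"], hit) if h]
        out["TranscriptionElongation"] = merge(PeakSet(kept, "TranscriptionElongation", genome))

    # termination needs only gene anchors: 50 bp immediately downstream of TES
    term = []
    for g in genes:
        if g.strand == "+":
            s, e = g.tes + 1, g.tes + 1 + rules.tes_extension
        else:
            s, e = g.tes - rules.tes_extension, g.tes
        if genome is not None:
            limit = genome.chrom_lengths[g.chrom]
            s, e = max(0, s), min(limit, e)
        if s < e:
            term.append(GenomicInterval(g.chrom, s, e, name=g.gene_id))
    out["TranscriptionTermination"] = merge(PeakSet(term, "TranscriptionTermination", genome))

    return CompartmentMap(out)


def classify_peaks(
    query: PeakSet, comp: CompartmentMap, min_bp: int = 1
) -> PeakClassification:
    """Label every query peak with all compartments it overlaps by >= min_bp."""
    if len(query) == 0:
        raise ValueError("query peak set is empty")
    if not comp.compartments:
        logger.warning("empty compartment map: all peaks unassigned")
    masks = {
        name: overlap_mask(query, cset, min_bp)
        for name, cset in comp.compartments.items()
    }
    labels: list[frozenset[str]] = []
    for i in range(len(query)):
        labels.append(frozenset(name for name, m in masks.items() if m[i]))
    combos: dict[frozenset[str], int] = {}
    singles: dict[str, int] = {name: 0 for name in comp.compartments}
    for lab in labels:
        combos[lab] = combos.get(lab, 0) + 1
        for name in lab:
            singles[name] += 1
    return PeakClassification(query, labels, combos, singles)


def upset_table(pc: PeakClassification) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclusive-combination counts (descending) plus marginal per-compartment totals."""
    rows = [
        {
            "combination": "+".join(sorted(lab)) if lab else "unassigned",
            "count": n,
        }
        for lab, n in pc.combination_counts.items()
    ]
    combos = pd.DataFrame(rows, columns=["combination", "count"]).sort_values(
        ["count", "combination"], ascending=[False, True], ignore_index=True
    )
    singles = pd.DataFrame(
        [{"compartment": k, "count": v} for k, v in pc.single_counts.items()],
        columns=["compartment", "count"],
    ).sort_values(["count", "compartment"], ascending=[False, True], ignore_index=True)
    return combos, singles
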