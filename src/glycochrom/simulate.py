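"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here: toy genomes and
gene models, mark peak sets that realize each functional-compartment rule,
query peaks with known compartment labels, reference libraries hitting
planted overlap fractions exactly, fragment sets realizing planted
gain/loss/unchanged occupancy fold changes, and expression tables with a
planted shift for occupied promoters.

Determinism: every generator draws from a sub-stream derived from the single
master seed with a fixed per-generator offset, so outputs are byte-identical
across runs and adding a generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomeSpec, GenomicInterval, PeakSet

# fixed sub-stream offsets (never renumber)
_STREAMS = {
    "genome": 1,
    "marks": 2,
    "query": 3,
    "fragments": 4,
    "library": 5,
    "expression": 6,
    "deg": 7,
}

GENE_COMPARTMENTS = (
    "ActivePromoter",
    "TranscriptionInitiation",
    "BivalentPromoter",
    "TranscriptionElongation",
    "TranscriptionTermination",
)
INTERGENIC_COMPARTMENTS = ("Heterochromatin", "Polycomb")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults sized for fast tests."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 4_000_000
    n_genes: int = 300
    gene_length: tuple[int, int] = (3000, 8000)
    gene_gap: tuple[int, int] = (6000, 12000)
    edge_margin: int = 25_000
    n_query_peaks: int = 200
    peak_width: tuple[int, int] = (200, 400)
    #: fraction of query peaks planted per compartment; remainder unassigned
    compartment_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "ActivePromoter": 0.20,
            "TranscriptionInitiation": 0.15,
            "Heterochromatin": 0.12,
            "BivalentPromoter": 0.10,
            "Polycomb": 0.10,
            "TranscriptionElongation": 0.08,
            "TranscriptionTermination": 0.05,
        }
    )
    planted_fractions: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    expression_shift: float = 1.0  # in log-expression SD units
    expression_sigma: float = 1.0  # SD of log expression
    cluster_classes: Mapping[str, float] = field(
        default_factory=lambda: {"gain": 2.0, "loss": 0.5, "unchanged": 1.0}
    )
    regions_per_class: int = 100
    fragments_per_region: int = 100
    fragment_length: int = 150
    region_spread: int = 300
    noise_cv: float = 0.2

    def __post_init__(self) -> None:
        if sum(self.compartment_mix.values()) > 1 + 1e-9:
            raise ValueError("compartment_mix proportions must sum to <= 1")
        if any(not 0 <= f <= 1 for f in self.planted_fractions):
            raise ValueError("planted fractions must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------


def simulate_genome_and_genes(cfg: SimulationConfig) -> tuple[GenomeSpec, list[GeneModel]]:
    """Non-overlapping genes with random strands and jittered spacing.

    Genes occupy the first 60% of each chromosome; the remainder is a
    gene-free zone reserved for intergenic compartments and background
    peaks.  Raises when the requested genes cannot fit.
    """
    rng = cfg.rng("genome")
    genome = GenomeSpec(
        {f"chr{i + 1}": cfg.chromosome_length for i in range(cfg.n_chromosomes)}
    )
    genes: list[GeneModel] = []
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    genic_limit = int(cfg.chromosome_length * 0.6)
    idx = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = cfg.edge_margin
        for _ in range(per_chrom[c]):
            gap = int(rng.integers(cfg.gene_gap[0], cfg.gene_gap[1] + 1))
            length = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
            start = cursor + gap
            end = start + length
            if end > genic_limit:
                raise ValueError(
                    f"genes cannot fit on {chrom}: need chromosome length >= "
                    f"{int(end / 0.6) + 1}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{idx:04d}", chrom, start, end, strand))
            cursor = end
            idx += 1
    return genome, genes


def intergenic_zone(cfg: SimulationConfig) -> dict[str, tuple[int, int]]:
    """Per-chromosome gene-free span usable for intergenic compartments."""
    lo = int(cfg.chromosome_length * 0.6) + 10_000
    hi = cfg.chromosome_length - cfg.edge_margin
    return {f"chr{i + 1}": (lo, hi) for i in range(cfg.n_chromosomes)}


# ---------------------------------------------------------------------------
# Compartment marks and query peaks
# ---------------------------------------------------------------------------


@dataclass
class PlantedCompartment:
    """One planted instance: the rule's label and where a query peak may sit."""

    label: str
    anchor: GenomicInterval  # placing a query peak inside hits exactly this label


def simulate_compartment_marks(
    cfg: SimulationConfig, genes: Sequence[GeneModel], genome: GenomeSpec
) -> tuple[dict[str, PeakSet], list[PlantedCompartment]]:
    """Place the minimal mark constellation for each planted compartment.

    Gene-anchored compartments are assigned to distinct genes (round-robin),
    intergenic compartments go to the gene-free zone, so planted instances
    are spatially disjoint except for the per-gene transcription-termination
    window every gene carries by construction of the rules.
    """
    rng = cfg.rng("marks")
    n = cfg.n_query_peaks
    counts = {lab: int(round(frac * n)) for lab, frac in cfg.compartment_mix.items()}
    marks: dict[str, list[GenomicInterval]] = {
        m: [] for m in ("H3K27ac", "Ser5P", "H3K9me3", "H3K4me3", "H3K27me3", "Suz12", "RING1B", "Ser2P")
    }
    planted: list[PlantedCompartment] = []

    gene_pool = list(genes)
    rng.shuffle(gene_pool)  # type: ignore[arg-type]
    gi = 0

    def next_gene() -> GeneModel:
        nonlocal gi
        if gi >= len(gene_pool):
            raise ValueError("not enough genes to host all planted compartments")
        g = gene_pool[gi]
        gi += 1
        return g

    for lab in GENE_COMPARTMENTS:
        for _ in range(counts.get(lab, 0)):
            g = next_gene()
            tss, tes = g.tss, g.tes
            if lab == "ActivePromoter":
                # H3K27ac peak inside the TSS window; the peak is the compartment
                peak = GenomicInterval(g.chrom, tss + 50, tss + 650) if g.strand == "+" else GenomicInterval(g.chrom, tss - 650, tss - 50)
                marks["H3K27ac"].append(peak)
                planted.append(PlantedCompartment(lab, peak))
            elif lab == "TranscriptionInitiation":
                peak = GenomicInterval(g.chrom, tss + 50, tss + 650) if g.strand == "+" else GenomicInterval(g.chrom, tss - 650, tss - 50)
                marks["Ser5P"].append(peak)
                # the compartment is the TSS window; anchoring at the peak is safe
                planted.append(PlantedCompartment(lab, peak))
            elif lab == "BivalentPromoter":
                if g.strand == "+":
                    a = GenomicInterval(g.chrom, tss + 50, tss + 450)
                    b = GenomicInterval(g.chrom, tss + 300, tss + 700)
                else:
                    a = GenomicInterval(g.chrom, tss - 450, tss - 50)
                    b = GenomicInterval(g.chrom, tss - 700, tss - 300)
                marks["H3K4me3"].append(a)
                marks["H3K27me3"].append(b)
                planted.append(PlantedCompartment(lab, a))
            elif lab == "TranscriptionElongation":
                # Ser2P peak mid-body, clear of the 1 kb offset and the TES window
                if g.strand == "+":
                    lo = g.start + 1000 + 200
                    peak = GenomicInterval(g.chrom, lo, lo + 600)
                else:
                    hi = g.end - 1000 - 200
                    peak = GenomicInterval(g.chrom, hi - 600, hi)
                marks["Ser2P"].append(peak)
                planted.append(PlantedCompartment(lab, peak))
            else:  # TranscriptionTermination: the rule fires from gene anchors alone
                if g.strand == "+":
                    window = GenomicInterval(g.chrom, tes + 1, tes + 51)
                else:
                    window = GenomicInterval(g.chrom, tes - 50, tes)
                planted.append(PlantedCompartment(lab, window))

    zone = intergenic_zone(cfg)
    chroms = sorted(zone)
    cursor = {c: zone[c][0] for c in chroms}
    ci = 0

    def alloc(width: int) -> GenomicInterval:
        nonlocal ci
        for _ in range(len(chroms)):
            c = chroms[ci % len(chroms)]
            ci += 1
            pos = cursor[c]
            if pos + width <= zone[c][1]:
                cursor[c] = pos + width + 2000
                return GenomicInterval(c, pos, pos + width)
        raise ValueError("insufficient gene-free space for intergenic compartments")

    for _ in range(counts.get("Heterochromatin", 0)):
        iv = alloc(2000)
        marks["H3K9me3"].append(iv)
        planted.append(PlantedCompartment("Heterochromatin", iv))
    for _ in range(counts.get("Polycomb", 0)):
        iv = alloc(1200)
        suz = GenomicInterval(iv.chrom, iv.start, iv.start + 800)
        ring = GenomicInterval(iv.chrom, iv.start + 400, iv.start + 1200)
        marks["Suz12"].append(suz)
        marks["RING1B"].append(ring)
        planted.append(PlantedCompartment("Polycomb", GenomicInterval(iv.chrom, iv.start + 400, iv.start + 800)))

    mark_sets = {m: PeakSet(ivs, label=m, genome=genome) for m, ivs in marks.items()}
    return mark_sets, planted


def simulate_query_peaks(
    cfg: SimulationConfig,
    planted: Sequence[PlantedCompartment],
    genome: GenomeSpec,
) -> tuple[PeakSet, dict[str, str]]:
    """Query peaks placed on planted anchors plus unassigned background peaks.

    Returns the peak set and a mapping peak name -> planted label
    ("unassigned" for background peaks placed in the gene-free zone beyond
    all planted marks).
    """
    rng = cfg.rng("query")
    peaks: list[GenomicInterval] = []
    truth: dict[str, str] = {}
    for i, pc in enumerate(planted):
        w = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
        a = pc.anchor
        width = min(w, len(a))
        start = a.start + int(rng.integers(0, len(a) - width + 1))
        name = f"q{i:04d}"
        peaks.append(GenomicInterval(a.chrom, start, start + width, name=name))
        truth[name] = pc.label
    n_bg = cfg.n_query_peaks - len(planted)
    zone = intergenic_zone(cfg)
    chroms = sorted(zone)
    # background goes to the tail of the gene-free zone, beyond intergenic marks
    for j in range(max(0, n_bg)):
        c = chroms[j % len(chroms)]
        lo, hi = zone[c]
        mid = (lo + hi) // 2 + 50_000
        w = int(rng.integers(cfg.peak_width[0], cfg.peak_width[1] + 1))
        start = mid + j // len(chroms) * 3000
        name = f"q{len(planted) + j:04d}"
        peaks.append(GenomicInterval(c, start, start + w, name=name))
        truth[name] = "unassigned"
    return PeakSet(peaks, label="query", genome=genome), truth


# ---------------------------------------------------------------------------
# Reference library
# ---------------------------------------------------------------------------


def simulate_reference_library(
    cfg: SimulationConfig, promoter_peaks: PeakSet
) -> tuple[dict[str, PeakSet], dict[str, float]]:
    """References hitting planted fractions of the promoter query peaks exactly.

    For fraction f, round(f * n) query peaks are chosen (seeded) and covered
    by one reference interval each; returns (library, id -> planted fraction).
    """
    rng = cfg.rng("library")
    n = len(promoter_peaks)
    if n == 0:
        raise ValueError("promoter query peak set is empty")
    library: dict[str, PeakSet] = {}
    fractions: dict[str, float] = {}
    for i, f in enumerate(cfg.planted_fractions):
        k = int(round(f * n))
        chosen = rng.choice(n, size=k, replace=False)
        ivs = []
        for j in sorted(chosen):
            q = promoter_peaks[int(j)]
            c = (q.start + q.end) // 2
            ivs.append(GenomicInterval(q.chrom, max(0, c - 50), c + 50))
        ref_id = f"ref_{f:.1f}"
        library[ref_id] = PeakSet(ivs, label=ref_id)
        fractions[ref_id] = f
    return library, fractions


# ---------------------------------------------------------------------------
# Occupancy fragments (before/after)
# ---------------------------------------------------------------------------


def plant_occupancy_regions(
    cfg: SimulationConfig, genome: GenomeSpec
) -> tuple[PeakSet, list[str]]:
    """Evenly spaced regions assigned to gain/loss/unchanged classes."""
    classes = sorted(cfg.cluster_classes)
    labels: list[str] = []
    ivs: list[GenomicInterval] = []
    chroms = sorted(genome.chrom_lengths)
    total = cfg.regions_per_class * len(classes)
    spacing = 6000
    per_chrom = -(-total // len(chroms))
    idx = 0
    for lab in classes:
        for _ in range(cfg.regions_per_class):
            c = chroms[idx // per_chrom]
            off = idx % per_chrom
            center = cfg.edge_margin + off * spacing
            ivs.append(
                GenomicInterval(c, center - 150, center + 150, name=f"r{idx:04d}")
            )
            labels.append(lab)
            idx += 1
    # PeakSet sorts internally; keep labels aligned via names
    regions = PeakSet(ivs, label="occupancy_regions", genome=genome)
    by_name = dict(zip([iv.name for iv in ivs], labels))
    return regions, [by_name[iv.name] for iv in regions]


def simulate_fragments(
    cfg: SimulationConfig,
    regions: PeakSet,
    classes: Sequence[str],
    genome: GenomeSpec,
) -> tuple[PeakSet, PeakSet]:
    """Fragment sets (before, after) realizing the planted fold changes.

    Per region a depth factor is drawn once from a unit-mean log-normal with
    coefficient of variation ``noise_cv`` (within-class depth variation); the
    before count is ``fragments_per_region`` times that factor and the after
    count additionally carries the class fold change, so every region
    realizes its planted fold change exactly up to count rounding.
    Fragments are ``fragment_length`` long, centered uniformly within
    ``region_spread`` of the region center.
    """
    rng = cfg.rng("fragments")
    cv = cfg.noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    mu = -0.5 * sigma * sigma  # unit-mean log-normal
    frags = {"before": [], "after": []}  # type: dict[str, list[GenomicInterval]]
    for iv, lab in zip(regions, classes):
        fc = cfg.cluster_classes[lab]
        center = (iv.start + iv.end) // 2
        depth_noise = float(np.exp(rng.normal(mu, sigma))) if cv > 0 else 1.0
        for cond, factor in (("before", 1.0), ("after", fc)):
            count = int(round(cfg.fragments_per_region * depth_noise * factor))
            if count <= 0:
                continue
            centers = rng.integers(
                center - cfg.region_spread, center + cfg.region_spread + 1, size=count
            )
            half = cfg.fragment_length // 2
            limit = genome.chrom_lengths[iv.chrom]
            for fc_pos in centers:
                s = max(0, int(fc_pos) - half)
                e = min(limit, s + cfg.fragment_length)
                frags[cond].append(GenomicInterval(iv.chrom, s, e))
    return (
        PeakSet(frags["before"], label="fragments_before", genome=genome),
        PeakSet(frags["after"], label="fragments_after", genome=genome),
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    occupied: Sequence[str],
) -> dict[str, float]:
    """Log-normal expression; occupied genes shifted by shift x sigma in log space.

    A shift of 0 makes the occupied and unoccupied groups exchangeable.
    """
    rng = cfg.rng("expression")
    occ = set(occupied)
    base_mu = np.log(100.0)
    out: dict[str, float] = {}
    for g in genes:
        mu = base_mu + (cfg.expression_shift * cfg.expression_sigma if g.gene_id in occ else 0.0)
        out[g.gene_id] = float(np.exp(rng.normal(mu, cfg.expression_sigma)))
    return out


def simulate_deg_table(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    n_significant: int = 40,
    frac_down: float = 0.6,
) -> pd.DataFrame:
    """A differential-expression table with planted significant genes.

    The first ``n_significant`` genes (in input order) get adjusted_p drawn
    below 0.05 with signs set by ``frac_down``; the rest are null.
    """
    rng = cfg.rng("deg")
    rows = []
    n_down = int(round(n_significant * frac_down))
    for i, g in enumerate(genes):
        if i < n_significant:
            down = i < n_down
            lfc = float(rng.normal(-1.0 if down else 1.0, 0.25))
            padj = float(rng.uniform(1e-6, 0.049))
        else:
            lfc = float(rng.normal(0.0, 0.2))
            padj = float(rng.uniform(0.05, 1.0))
        rows.append({"gene_id": g.gene_id, "log2FC": lfc, "adjusted_p": padj})
    return pd.DataFrame(rows)
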