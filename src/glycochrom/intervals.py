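"""Genomic interval data model, BED/GTF I/O and the overlap/windowing engine.

All coordinates are BED-style 0-based half-open internally.  GTF input
(1-based inclusive) is converted on read.  Two intervals ``(s1, e1)`` and
``(s2, e2)`` on the same chromosome overlap by ``min(e1, e2) - max(s1, s2)``
base pairs; overlap testing ignores strand.  Set-algebra outputs are always
sorted and non-overlapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GenomeSpec",
    "GeneModel",
    "PeakSet",
    "read_bed",
    "write_bed",
    "read_genes",
    "write_gene_table",
    "overlaps",
    "overlap_mask",
    "window_around_point",
    "tss_windows",
    "merge",
    "intersect_regions",
    "subtract",
    "union",
]

#: Effective genome sizes used for RPGC scaling (deeptools conventions).
EFFECTIVE_GENOME_SIZE = {"mm10": 2_308_125_349, "hg38": 2_701_495_761}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap length in bp; <= 0 means no overlap (half-open convention)."""
        if self.chrom != other.chrom:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes plus the effective (mappable) genome size for RPGC."""

    chrom_lengths: Mapping[str, int]
    effective_size: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.chrom_lengths.values())
        if self.effective_size is None:
            object.__setattr__(self, "effective_size", total)
        elif self.effective_size > total:
            raise ValueError(
                f"effective_size {self.effective_size} exceeds total "
                f"chromosome length {total}"
            )

    @property
    def total_size(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS/TES anchor bases.

    ``tss`` is the first transcribed base, ``tes`` the last: on ``+`` genes
    ``tss == start`` and ``tes == end - 1``; on ``-`` genes ``tss == end - 1``
    and ``tes == start``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class PeakSet:
    """An immutable, sorted collection of :class:`GenomicInterval`.

    Sorting (by chrom, start, end) is established at construction and
    maintained by every transformation.  When a :class:`GenomeSpec` is
    attached, interval ends are validated against chromosome lengths.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        label: str = "",
        genome: GenomeSpec | None = None,
    ) -> None:
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        self.label = label
        self.genome = genome
        if genome is not None:
            for iv in self.intervals:
                limit = genome.chrom_lengths.get(iv.chrom)
                if limit is None:
                    raise ValueError(f"chromosome {iv.chrom!r} not in genome")
                if iv.end > limit:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {limit}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]]:
        """Per-chromosome (starts, ends, intervals) in sorted order."""
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return {
            c: (
                np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs)),
                np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs)),
                ivs,
            )
            for c, ivs in out.items()
        }

    def total_bp(self) -> int:
        """Total merged (non-redundant) base pairs covered."""
        return sum(len(iv) for iv in merge(self))

    def with_label(self, label: str) -> "PeakSet":
        return PeakSet(self.intervals, label=label, genome=self.genome)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, format: str = "bed") -> PeakSet:
    """Read a BED3/BED6 or ENCODE narrowPeak file into a sorted PeakSet.

    narrowPeak summit offsets (column 10) are retained as ``summit`` entries
    of the returned set's ``summits`` attribute, keyed by interval.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown BED format {format!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    summits: dict[GenomicInterval, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if format == "narrowPeak" and len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak requires 10 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand, name, score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
            if format == "narrowPeak":
                summit = int(fields[9])
                if summit >= 0:
                    summits[iv] = summit
    ps = PeakSet(intervals, label=path.stem)
    ps.summits = summits  # type: ignore[attr-defined]
    return ps


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED6 (name/score/strand filled with '.'-style placeholders)."""
    with open(path, "w") as fh:
        for iv in peaks:
            name = iv.name if iv.name is not None else "."
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_genes(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (feature type ``gene``) or a gene-table TSV.

    GTF spans are 1-based inclusive and converted to 0-based half-open by
    ``start -> start - 1`` with ``end`` unchanged.  The gene-table format is
    a headered TSV with columns gene_id, chrom, start, end, strand already in
    0-based half-open coordinates.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    if format == "gtf":
        from gffutils.feature import feature_from_line

        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                try:
                    feat = feature_from_line(line)
                except Exception as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable GTF line") from exc
                if feat.featuretype != "gene":
                    continue
                gene_ids = feat.attributes.get("gene_id")
                if not gene_ids:
                    raise ValueError(f"{path}:{lineno}: gene record lacks gene_id")
                gene_id = gene_ids[0]
                if feat.strand not in ("+", "-"):
                    warnings.warn(
                        f"{path}:{lineno}: gene {gene_id} has no strand; skipped"
                    )
                    continue
                if gene_id in seen:
                    raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
                seen.add(gene_id)
                genes.append(
                    GeneModel(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand)
                )
    elif format == "table":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in {path}")
        for row in df.itertuples(index=False):
            if row.strand not in ("+", "-"):
                warnings.warn(f"gene {row.gene_id} has no strand; skipped")
                continue
            genes.append(
                GeneModel(str(row.gene_id), str(row.chrom), int(row.start), int(row.end), str(row.strand))
            )
    else:
        raise ValueError(f"unknown gene format {format!r}")
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Overlap engine and windows
# ---------------------------------------------------------------------------


def _warn_on_disjoint_chroms(a: PeakSet, b: PeakSet) -> None:
    ca, cb = set(a.chroms()), set(b.chroms())
    if ca and cb and not (ca & cb):
        warnings.warn(
            "no shared chromosome names between interval sets "
            f"(left: {sorted(ca)}, right: {sorted(cb)}); check 'chr' prefixes"
        )


def overlaps(
    a: PeakSet, b: PeakSet, min_bp: int = 1
) -> dict[GenomicInterval, list[GenomicInterval]]:
    """Map each interval of ``a`` to the intervals of ``b`` it overlaps.

    Overlap requires >= ``min_bp`` shared bases under the half-open
    convention; strand is ignored; cross-chromosome pairs never overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    _warn_on_disjoint_chroms(a, b)
    b_idx = b.by_chrom()
    result: dict[GenomicInterval, list[GenomicInterval]] = {}
    for iv in a:
        hits: list[GenomicInterval] = []
        entry = b_idx.get(iv.chrom)
        if entry is not None:
            starts, ends, ivs = entry
            ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
            for j in np.nonzero(ov >= min_bp)[0]:
                hits.append(ivs[j])
        result[iv] = hits
    return result


def overlap_mask(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean array over ``a``'s sorted intervals: hit by >= min_bp in ``b``."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    b_idx = b.by_chrom()
    mask = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        entry = b_idx.get(iv.chrom)
        if entry is None:
            continue
        starts, ends, _ = entry
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        mask[i] = bool(np.any(ov >= min_bp))
    return mask


def window_around_point(
    chrom: str, point: int, flank: int, genome: GenomeSpec | None = None
) -> GenomicInterval:
    """Symmetric window [point - flank, point + flank + 1) around an anchor base.

    Length is ``2 * flank + 1`` unless clipped at chromosome bounds.  The
    default promoter window uses ``flank = 1000`` (TSS +/- 1 kb).
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    limit = None
    if genome is not None:
        limit = genome.chrom_lengths.get(chrom)
        if limit is None:
            raise ValueError(f"chromosome {chrom!r} not in genome")
        if not (0 <= point < limit):
            raise ValueError(f"point {point} outside chromosome {chrom} (len {limit})")
    elif point < 0:
        raise ValueError(f"point {point} is negative")
    start = max(0, point - flank)
    end = point + flank + 1
    if limit is not None:
        end = min(limit, end)
    return GenomicInterval(chrom, start, end)


def tss_windows(
    genes: Sequence[GeneModel], flank: int = 1000, genome: GenomeSpec | None = None
) -> PeakSet:
    """Promoter windows (TSS +/- flank) for a gene set, named by gene_id."""
    ivs = []
    for g in genes:
        w = window_around_point(g.chrom, g.tss, flank, genome)
        ivs.append(replace(w, name=g.gene_id, strand=g.strand))
    return PeakSet(ivs, label=f"tss_windows_{flank}", genome=genome)


# ---------------------------------------------------------------------------
# Set algebra (sorted, non-overlapping outputs)
# ---------------------------------------------------------------------------


def _merged_arrays(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends, _) in peaks.by_chrom().items():
        ms, me = [], []
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlapping or abutting: collapse
                cur_e = max(cur_e, int(e))
            else:
                ms.append(cur_s)
                me.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        ms.append(cur_s)
        me.append(cur_e)
        out[chrom] = (np.array(ms, dtype=np.int64), np.array(me, dtype=np.int64))
    return out


def _from_arrays(
    arrays: dict[str, tuple[np.ndarray, np.ndarray]],
    label: str,
    genome: GenomeSpec | None,
) -> PeakSet:
    ivs = [
        GenomicInterval(chrom, int(s), int(e))
        for chrom in sorted(arrays)
        for s, e in zip(*arrays[chrom])
    ]
    return PeakSet(ivs, label=label, genome=genome)


def merge(a: PeakSet) -> PeakSet:
    """Collapse overlapping or abutting intervals into maximal runs."""
    if len(a) == 0:
        return PeakSet([], label=a.label, genome=a.genome)
    return _from_arrays(_merged_arrays(a), a.label, a.genome)


def intersect_regions(a: PeakSet, b: PeakSet) -> PeakSet:
    """Base-pair intersection of two interval sets (merged inputs)."""
    if len(a) == 0 or len(b) == 0:
        return PeakSet([], label=f"{a.label}&{b.label}")
    ma, mb = _merged_arrays(a), _merged_arrays(b)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in set(ma) & set(mb):
        sa, ea = ma[chrom]
        sb, eb = mb[chrom]
        ss, es = [], []
        i = j = 0
        while i < len(sa) and j < len(sb):
            s = max(sa[i], sb[j])
            e = min(ea[i], eb[j])
            if s < e:
                ss.append(int(s))
                es.append(int(e))
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
        if ss:
            out[chrom] = (np.array(ss, dtype=np.int64), np.array(es, dtype=np.int64))
    return _from_arrays(out, f"{a.label}&{b.label}", a.genome)


def subtract(a: PeakSet, b: PeakSet) -> PeakSet:
    """Base pairs of ``a`` not covered by ``b`` (merged inputs)."""
    if len(a) == 0:
        return PeakSet([], label=a.label)
    if len(b) == 0:
        return merge(a)
    ma, mb = _merged_arrays(a), _merged_arrays(b)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (sa, ea) in ma.items():
        if chrom not in mb:
            out[chrom] = (sa, ea)
            continue
        sb, eb = mb[chrom]
        ss, es = [], []
        j = 0
        for s, e in zip(sa, ea):
            cur = int(s)
            while j < len(sb) and eb[j] <= cur:
                j += 1
            k = j
            while k < len(sb) and sb[k] < e:
                if sb[k] > cur:
                    ss.append(cur)
                    es.append(int(sb[k]))
                cur = max(cur, int(eb[k]))
                k += 1
            if cur < e:
                ss.append(cur)
                es.append(int(e))
        if ss:
            out[chrom] = (np.array(ss, dtype=np.int64), np.array(es, dtype=np.int64))
    return _from_arrays(out, f"{a.label}-{b.label}", a.genome)


def union(a: PeakSet, b: PeakSet) -> PeakSet:
    """Merged union of two interval sets."""
    return merge(PeakSet(list(a) + list(b), label=f"{a.label}|{b.label}", genome=a.genome))
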