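"""Genomic interval data model, BED/GFF3 I/O, interval algebra, peak-to-gene
assignment and interval shuffling.

All internal coordinates are 0-based half-open ``[start, end)``.  GFF3 (1-based
closed) is converted on read and write.  Overlap is strand-blind throughout;
promoter and downstream windows are strand-aware.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

# position-priority order used when a peak overlaps several gene features
CATEGORY_PRIORITY = {
    "promoter": 0,
    "exon": 1,
    "intron": 2,
    "5UTR": 3,
    "3UTR": 4,
    "downstream": 5,
}


class IntervalError(ValueError):
    """Malformed interval or interval file."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open stranded interval: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    extra: tuple = ()

    def __post_init__(self):
        if not self.chrom:
            raise IntervalError("empty chromosome id")
        if self.start < 0:
            raise IntervalError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise IntervalError(
                f"zero-length interval: {self.chrom}:{self.start}-{self.end}"
                if self.start == self.end
                else f"inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise IntervalError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self):
        return (self.chrom, self.start, self.end)


@dataclass
class GeneModel:
    """A gene with strand-aware TSS/TES and ordered feature intervals.

    ``tss``/``tes`` are single base coordinates in the internal 0-based
    system: on ``+`` the TSS is the gene start (tss < tes); on ``-`` the TSS
    is the gene end (tss > tes).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    feature_intervals: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    biotype: str = "coding"
    subgenome: str = "NA"
    triad_id: str | None = None

    def __post_init__(self):
        if self.strand == "+" and not self.tss < self.tes:
            raise IntervalError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise IntervalError(f"{self.gene_id}: - strand requires tss > tes")
        lo, hi = self.span
        for kind, iv in self.feature_intervals:
            if iv.chrom != self.chrom or iv.start < lo or iv.end > hi:
                raise IntervalError(
                    f"{self.gene_id}: {kind} {iv.start}-{iv.end} outside gene span"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    @property
    def span_interval(self) -> GenomicInterval:
        lo, hi = self.span
        return GenomicInterval(self.chrom, lo, hi, self.strand, self.gene_id)


@dataclass
class Genome:
    """Chromosome sizes plus gene and transposable-element annotation."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    tes: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise IntervalError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            lo, hi = g.span
            if hi > self.chrom_sizes[g.chrom]:
                raise IntervalError(f"gene {g.gene_id} beyond end of {g.chrom}")
        for te in self.tes:
            if te.chrom not in self.chrom_sizes or te.end > self.chrom_sizes[te.chrom]:
                raise IntervalError(f"TE {te} outside chromosome bounds")
        self._window_index: dict | None = None

    # --- assignment windows ---------------------------------------------
    def _windows(self, up_bp: int, down_bp: int) -> dict:
        """Per-chrom arrays of candidate (start, end, priority, tss, gene_idx)."""
        key = (up_bp, down_bp)
        if self._window_index and self._window_index.get("key") == key:
            return self._window_index
        per_chrom: dict[str, list] = {}
        for gi, g in enumerate(self.genes):
            rows = per_chrom.setdefault(g.chrom, [])
            size = self.chrom_sizes[g.chrom]
            if g.strand == "+":
                prom = (max(0, g.tss - up_bp), g.tss)
                down = (g.tes, min(size, g.tes + down_bp))
            else:
                prom = (g.tss, min(size, g.tss + up_bp))
                down = (max(0, g.tes - down_bp), g.tes)
            for cat, (s, e) in (("promoter", prom), ("downstream", down)):
                if s < e:
                    rows.append((s, e, CATEGORY_PRIORITY[cat], g.tss, gi, cat))
            for kind, iv in g.feature_intervals:
                if kind in CATEGORY_PRIORITY:
                    rows.append(
                        (iv.start, iv.end, CATEGORY_PRIORITY[kind], g.tss, gi, kind)
                    )
        index = {"key": key}
        for chrom, rows in per_chrom.items():
            rows.sort(key=lambda r: (r[0], r[1]))
            index[chrom] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                rows,
            )
        self._window_index = index
        return index

    def intergenic_domain(self, flank_bp: int = 0) -> list[GenomicInterval]:
        """Chromosome space not covered by gene spans (each padded by flank_bp)."""
        spans = []
        for g in self.genes:
            lo, hi = g.span
            spans.append(
                GenomicInterval(
                    g.chrom,
                    max(0, lo - flank_bp),
                    min(self.chrom_sizes[g.chrom], hi + flank_bp),
                )
            )
        whole = [
            GenomicInterval(c, 0, size) for c, size in sorted(self.chrom_sizes.items())
        ]
        return subtract_intervals(whole, spans)


# ---------------------------------------------------------------------------
# BED / narrowPeak I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak.  narrowPeak columns 7+ are kept in ``extra``."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntervalError(f"{path} line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise IntervalError(f"{path} line {lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 else "."
            extra = tuple(parts[6:])
            try:
                out.append(
                    GenomicInterval(parts[0], start, end, strand, name, score, extra)
                )
            except IntervalError as exc:
                raise IntervalError(f"{path} line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              header: str | None = None) -> None:
    """Write sorted BED6 (+ any extra narrowPeak columns), newline-terminated."""
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in ivs:
            score = "." if iv.score is None else format(iv.score, "g")
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name or ".", score,
                   iv.strand, *iv.extra]
            fh.write("\t".join(row) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def _parse_attrs(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        k, _, v = item.partition("=")
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/UTR features).

    Coordinates convert from 1-based closed to internal 0-based half-open.
    Introns are derived as gaps between consecutive exons of the longest
    transcript (largest summed exon length).
    """
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise IntervalError(f"{path} line {lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, s1, e1, _, strand, _, attr_text = parts
            if strand not in ("+", "-"):
                if ftype in ("gene", "mRNA", "exon",
                             "five_prime_UTR", "three_prime_UTR"):
                    raise IntervalError(f"{path} line {lineno}: unknown strand {strand!r}")
                continue
            start, end = int(s1) - 1, int(e1)
            attrs = _parse_attrs(attr_text)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise IntervalError(f"{path} line {lineno}: gene without ID")
                genes[gid] = {
                    "chrom": chrom, "strand": strand, "start": start, "end": end,
                    "attrs": attrs, "tx": {},
                }
            elif ftype == "mRNA":
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if parent in genes:
                    genes[parent]["tx"][tid] = {"exons": [], "5UTR": [], "3UTR": []}
                    tx_parent[tid] = parent
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attrs.get("Parent")
                key = {"exon": "exons", "five_prime_UTR": "5UTR",
                       "three_prime_UTR": "3UTR"}[ftype]
                if parent in tx_parent:
                    genes[tx_parent[parent]]["tx"][parent][key].append((start, end))
                elif parent in genes:
                    # exon attached directly to the gene: implicit transcript
                    tx = genes[parent]["tx"].setdefault(
                        parent, {"exons": [], "5UTR": [], "3UTR": []})
                    tx[key].append((start, end))
                    tx_parent[parent] = parent

    models = []
    for gid, g in genes.items():
        chrom, strand = g["chrom"], g["strand"]
        tss = g["start"] if strand == "+" else g["end"]
        tes = g["end"] if strand == "+" else g["start"]
        features: list[tuple[str, GenomicInterval]] = []
        if g["tx"]:
            best = max(
                g["tx"].items(),
                key=lambda kv: (sum(e - s for s, e in kv[1]["exons"]), kv[0]),
            )[1]
            exons = sorted(best["exons"])
            for s, e in exons:
                if s < g["start"] or e > g["end"]:
                    raise IntervalError(f"{gid}: exon {s}-{e} outside gene span")
                features.append(("exon", GenomicInterval(chrom, s, e, strand)))
            for (s0, e0), (s1_, _) in zip(exons, exons[1:]):
                if e0 < s1_:
                    features.append(("intron", GenomicInterval(chrom, e0, s1_, strand)))
            for kind in ("5UTR", "3UTR"):
                for s, e in sorted(best[kind]):
                    features.append((kind, GenomicInterval(chrom, s, e, strand)))
        attrs = g["attrs"]
        models.append(
            GeneModel(
                gene_id=gid, chrom=chrom, strand=strand, tss=tss, tes=tes,
                feature_intervals=features,
                biotype=attrs.get("biotype", "coding"),
                subgenome=attrs.get("subgenome", "NA"),
                triad_id=attrs.get("triad_id") or None,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.span[0], m.gene_id))
    return models


def write_gff3(genes: Sequence[GeneModel], path: str | Path,
               header: str | None = None) -> None:
    """Write gene models as GFF3 (gene + one mRNA + exon/UTR rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(genes, key=lambda m: (m.chrom, m.span[0], m.gene_id)):
            lo, hi = g.span
            attrs = [f"ID={g.gene_id}", f"biotype={g.biotype}",
                     f"subgenome={g.subgenome}"]
            if g.triad_id:
                attrs.append(f"triad_id={g.triad_id}")
            fh.write("\t".join([g.chrom, "embryodyn", "gene", str(lo + 1), str(hi),
                                ".", g.strand, ".", ";".join(attrs)]) + "\n")
            tid = f"{g.gene_id}.1"
            fh.write("\t".join([g.chrom, "embryodyn", "mRNA", str(lo + 1), str(hi),
                                ".", g.strand, ".",
                                f"ID={tid};Parent={g.gene_id}"]) + "\n")
            feats = [fk for fk in g.feature_intervals if fk[0] != "intron"]
            if not feats:
                feats = [("exon", GenomicInterval(g.chrom, lo, hi, g.strand))]
            type_map = {"exon": "exon", "5UTR": "five_prime_UTR",
                        "3UTR": "three_prime_UTR"}
            for kind, iv in sorted(feats, key=lambda kv: kv[1].start):
                fh.write("\t".join([g.chrom, "embryodyn", type_map[kind],
                                    str(iv.start + 1), str(iv.end), ".", g.strand,
                                    ".", f"Parent={tid}"]) + "\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def overlap_pairs(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval],
                  min_overlap_bp: int = 1) -> list[tuple[int, int]]:
    """All index pairs (i, j) with >= min_overlap_bp shared bases, strand-blind.

    Output is deterministic and sorted by (i, j).
    """
    if min_overlap_bp < 1:
        raise IntervalError("min_overlap_bp must be >= 1")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for rows in by_chrom.values():
        rows.sort()
    pairs = []
    for i, iv in enumerate(a):
        rows = by_chrom.get(iv.chrom)
        if not rows:
            continue
        starts = [r[0] for r in rows]
        hi = bisect.bisect_left(starts, iv.end)
        for s, e, j in rows[:hi]:
            if min(iv.end, e) - max(iv.start, s) >= min_overlap_bp:
                pairs.append((i, j))
    pairs.sort()
    return pairs


def overlaps_any(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval],
                 min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean mask over ``a``: True where the interval overlaps any in ``b``."""
    mask = np.zeros(len(a), dtype=bool)
    for i, _ in overlap_pairs(a, b, min_overlap_bp):
        mask[i] = True
    return mask


def merge_intervals(intervals: Sequence[GenomicInterval],
                    min_gap: int = 0) -> list[GenomicInterval]:
    """Union of intervals; adjacent intervals closer than ``min_gap`` merge."""
    out = []
    for iv in sorted(intervals, key=GenomicInterval.sort_key):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + min_gap:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(a: Sequence[GenomicInterval],
                       b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Portions of ``a`` not covered by ``b`` (strand-blind)."""
    b_merged = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in sorted(a, key=GenomicInterval.sort_key):
        cursor = iv.start
        for blk in by_chrom.get(iv.chrom, []):
            if blk.end <= cursor or blk.start >= iv.end:
                continue
            if blk.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, blk.start))
            cursor = max(cursor, blk.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


# ---------------------------------------------------------------------------
# Peak-to-gene assignment
# ---------------------------------------------------------------------------

def assign_peak_to_gene(peak: GenomicInterval, genome: Genome,
                        up_bp: int = 3000, down_bp: int = 2500
                        ) -> tuple[str | None, str]:
    """Assign a peak to a gene by position priority, else ``(None, 'distal')``.

    Priority: promoter > exon > intron > 5UTR > 3UTR > downstream.  The
    promoter window is the strand-aware ``up_bp`` before the TSS; downstream
    is the strand-aware ``down_bp`` beyond the TES.  Ties at equal priority
    break by smallest peak-midpoint-to-TSS distance, then gene_id.
    """
    if peak.chrom not in genome.chrom_sizes:
        raise IntervalError(f"peak chrom {peak.chrom!r} absent from genome")
    index = genome._windows(up_bp, down_bp)
    entry = index.get(peak.chrom)
    best = None
    if entry is not None:
        starts, ends, rows = entry
        hi = int(np.searchsorted(starts, peak.end, side="left"))
        mid = peak.midpoint
        for s, e, prio, tss, gi, _cat in rows[:hi]:
            if e <= peak.start:
                continue
            key = (prio, abs(mid - tss), genome.genes[gi].gene_id)
            if best is None or key < best[0]:
                best = (key, gi, _cat)
    if best is None:
        return (None, "distal")
    return (genome.genes[best[1]].gene_id, best[2])


def assign_peaks(peaks: Sequence[GenomicInterval], genome: Genome,
                 up_bp: int = 3000, down_bp: int = 2500
                 ) -> list[tuple[str | None, str]]:
    return [assign_peak_to_gene(p, genome, up_bp, down_bp) for p in peaks]


# ---------------------------------------------------------------------------
# Shuffling
# ---------------------------------------------------------------------------

def shuffle_intervals(intervals: Sequence[GenomicInterval],
                      domain: Sequence[GenomicInterval],
                      seed: int | np.random.Generator,
                      n_shuffles: int = 100) -> list[list[GenomicInterval]]:
    """Place each interval's length uniformly at random inside the domain.

    Each output set preserves the input length multiset; every placed
    interval lies fully inside one domain segment; placements are independent
    (overlaps among placed intervals allowed), uniform over all feasible
    start positions, and deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    segs = merge_intervals(domain)
    if not segs:
        raise IntervalError("empty shuffle domain")
    seg_lens = np.array([len(s) for s in segs], dtype=np.int64)
    out = []
    for _ in range(n_shuffles):
        placed = []
        for iv in intervals:
            L = len(iv)
            slots = seg_lens - L + 1
            feasible = slots > 0
            if not feasible.any():
                raise IntervalError(
                    f"interval {iv.name or iv.chrom + ':' + str(iv.start)} of length "
                    f"{L} exceeds every domain segment"
                )
            total = int(slots[feasible].sum())
            pick = int(rng.integers(0, total))
            for seg, n_slots, ok in zip(segs, slots, feasible):
                if not ok:
                    continue
                if pick < n_slots:
                    start = seg.start + pick
                    placed.append(
                        GenomicInterval(seg.chrom, start, start + L, iv.strand,
                                        iv.name, iv.score)
                    )
                    break
                pick -= int(n_slots)
        out.append(placed)
    return out
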