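"""Genomic-context annotation of rare tandem-repeat expansions.

Every classification here uses the same overlap rule: an expansion belongs
to a context when it overlaps it by at least 1 bp (half-open coordinates,
so abutting intervals share 0 bp).  Gene-part labels are non-exclusive: a
single event can be exonic, intronic and splicing at once.  Strand is
carried on transcripts only to orient the 5'/3' UTRs; overlap itself is
unstranded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .exceptions import DegenerateDataError
from .io import AnnotationTrack

GENE_PARTS = ("exon", "intron", "utr5", "utr3", "splicing")


@dataclass
class Transcript:
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(utr5, utr3) exonic intervals, oriented by strand."""
        left, right = [], []
        for s, e in self.exons:
            if s < self.cds_start:
                left.append((s, min(e, self.cds_start)))
            if e > self.cds_end:
                right.append((max(s, self.cds_end), e))
        if self.strand == "-":
            return right, left
        return left, right

    def splice_regions(self, window: int) -> list[tuple[int, int]]:
        """First/last ``window`` intronic bases of each intron."""
        regions = []
        for s, e in self.introns:
            if e - s <= 2 * window:
                regions.append((s, e))
            else:
                regions.append((s, s + window))
                regions.append((e - window, e))
        return regions


class GeneModel:
    """Transcript collection with per-contig interval indexes."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts = list(transcripts)
        self._tree: dict[str, IntervalTree] = {}
        for i, tx in enumerate(self.transcripts):
            self._tree.setdefault(tx.contig, IntervalTree()).addi(tx.start, tx.end, i)

    @property
    def gene_ids(self) -> list[str]:
        return sorted({tx.gene_id for tx in self.transcripts})

    def overlapping(self, contig: str, start: int, end: int) -> list[Transcript]:
        tree = self._tree.get(contig)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: iv.data)
        return [self.transcripts[iv.data] for iv in hits]

    def coding_track(self) -> AnnotationTrack:
        """Union of CDS-restricted exon intervals across transcripts."""
        track = AnnotationTrack(name="coding")
        for tx in self.transcripts:
            for s, e in tx.exons:
                cs, ce = max(s, tx.cds_start), min(e, tx.cds_end)
                if cs < ce:
                    track.intervals.append((tx.contig, cs, ce))
        return track


# ---------------------------------------------------------------------------
# interval arithmetic


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _intersect(start: int, end: int, intervals: Iterable[tuple[int, int]]):
    """Disjoint pieces of [start,end) covered by the union of ``intervals``."""
    pieces = sorted(
        (max(start, s), min(end, e)) for s, e in intervals if s < end and e > start
    )
    merged: list[tuple[int, int]] = []
    for s, e in pieces:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_bp(contig: str, start: int, end: int, track: AnnotationTrack) -> int:
    ivs = [(s, e) for c, s, e in track.intervals if c == contig]
    return sum(e - s for s, e in _intersect(start, end, ivs))


# ---------------------------------------------------------------------------
# classification operations


def classify_genic(
    contig: str, start: int, end: int, model: GeneModel
) -> tuple[bool, list[str]]:
    """Genic iff the event overlaps any transcript by >=1 bp; returns all
    overlapped gene ids (sorted, deduplicated)."""
    txs = model.overlapping(contig, start, end)
    genes = sorted({tx.gene_id for tx in txs})
    return bool(genes), genes


def classify_parts(
    contig: str,
    start: int,
    end: int,
    model: GeneModel,
    splice_window: int = 8,
) -> set[str]:
    """Non-exclusive gene-part labels for a genic event.

    ``splicing`` means overlap with the first/last ``splice_window`` intronic
    bases of any intron.  Raises on an intergenic event (contract: callers
    classify genic first).
    """
    txs = model.overlapping(contig, start, end)
    if not txs:
        raise DegenerateDataError(
            f"classify_parts called on intergenic event {contig}:{start}-{end}"
        )
    parts: set[str] = set()
    span = (start, end)
    for tx in txs:
        if any(_overlaps(span, iv) for iv in tx.exons):
            parts.add("exon")
        if any(_overlaps(span, iv) for iv in tx.introns):
            parts.add("intron")
        utr5, utr3 = tx.utr_intervals()
        if any(_overlaps(span, iv) for iv in utr5):
            parts.add("utr5")
        if any(_overlaps(span, iv) for iv in utr3):
            parts.add("utr3")
        if any(_overlaps(span, iv) for iv in tx.splice_regions(splice_window)):
            parts.add("splicing")
    return parts


def conserved_bp(
    contig: str,
    start: int,
    end: int,
    conserved: AnnotationTrack,
    coding: AnnotationTrack,
) -> tuple[int, int, int]:
    """(total, coding, noncoding) conserved base pairs hit by the event."""
    cons_ivs = [(s, e) for c, s, e in conserved.intervals if c == contig]
    cod_ivs = [(s, e) for c, s, e in coding.intervals if c == contig]
    pieces = _intersect(start, end, cons_ivs)
    total = sum(e - s for s, e in pieces)
    coding_bp = sum(
        e2 - s2 for s, e in pieces for s2, e2 in _intersect(s, e, cod_ivs)
    )
    return total, coding_bp, total - coding_bp


def annotation_enrichment(
    regions: AnnotationTrack, track: AnnotationTrack, genome_size: int
) -> tuple[float, float]:
    """Base-pair enrichment of region coverage inside an annotation track.

    Builds the 2x2 contingency table {inside regions, outside} x {inside
    track, outside} over genome base pairs, applies a 0.5 continuity
    correction when any cell is zero, and returns (odds ratio, chi-square
    p with 1 df).
    """
    region_bp = regions.total_bp()
    track_bp = track.total_bp()
    if track_bp == 0 or track_bp >= genome_size:
        raise DegenerateDataError("track covers none or all of the genome")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in track.intervals:
        by_contig.setdefault(c, []).append((s, e))
    a = 0  # region bp inside track
    merged_regions = _merge_track(regions)
    for c, s, e in merged_regions:
        a += sum(e2 - s2 for s2, e2 in _intersect(s, e, by_contig.get(c, [])))
    b = region_bp - a
    c_cell = track_bp - a
    d = genome_size - region_bp - c_cell
    cells = np.array([a, b, c_cell, d], dtype=float)
    if (cells <= 0).any():
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    n = cells.sum()
    # Pearson chi-square, 1 df
    row1, row2 = a_ + b_, c_ + d_
    col1, col2 = a_ + c_, b_ + d_
    expected = np.array(
        [row1 * col1, row1 * col2, row2 * col1, row2 * col2], dtype=float
    ) / n
    chi2 = float(((cells - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return float(or_), p


def _merge_track(track: AnnotationTrack) -> list[tuple[str, int, int]]:
    out = []
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in track.intervals:
        by_contig.setdefault(c, []).append((s, e))
    for c in sorted(by_contig):
        ivs = sorted(by_contig[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                out.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        out.append((c, cur_s, cur_e))
    return out


# ---------------------------------------------------------------------------
# whole-table annotation and burden inputs


def annotate_tres(
    tres: pd.DataFrame,
    model: GeneModel,
    conserved: AnnotationTrack | None = None,
    coding: AnnotationTrack | None = None,
    tracks: Mapping[str, AnnotationTrack] | None = None,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    splice_window: int = 8,
) -> pd.DataFrame:
    """Annotate a TRE table (one row per called expansion) in place-free style.

    Input needs columns contig, start, end.  Adds: genic, gene_ids, parts,
    conserved_bp_{total,coding,noncoding}, one ``in_<track>`` flag per
    epigenomic track, and one ``set_<name>`` flag per gene set.
    """
    tracks = tracks or {}
    gene_sets = gene_sets or {}
    out = tres.copy()
    genic, gene_ids, parts_col = [], [], []
    cons = {"total": [], "coding": [], "noncoding": []}
    track_flags = {name: [] for name in tracks}
    for row in tres.itertuples(index=False):
        g, genes = classify_genic(row.contig, row.start, row.end, model)
        genic.append(g)
        gene_ids.append(genes)
        parts_col.append(
            classify_parts(row.contig, row.start, row.end, model, splice_window)
            if g
            else set()
        )
        if conserved is not None and coding is not None:
            t, cb, nb = conserved_bp(row.contig, row.start, row.end, conserved, coding)
        else:
            t = cb = nb = 0
        cons["total"].append(t)
        cons["coding"].append(cb)
        cons["noncoding"].append(nb)
        for name, track in tracks.items():
            track_flags[name].append(
                overlap_bp(row.contig, row.start, row.end, track) > 0
            )
    out["genic"] = genic
    out["gene_ids"] = gene_ids
    out["parts"] = parts_col
    out["conserved_bp_total"] = cons["total"]
    out["conserved_bp_coding"] = cons["coding"]
    out["conserved_bp_noncoding"] = cons["noncoding"]
    for name in tracks:
        out[f"in_{name}"] = track_flags[name]
    known_genes = set(model.gene_ids)
    for name, genes in gene_sets.items():
        members = set(genes)
        unknown = members - known_genes
        if unknown:
            warnings.warn(
                f"gene set {name!r}: {len(unknown)} unknown gene names ignored",
                stacklevel=2,
            )
        out[f"set_{name}"] = [
            bool(members & set(g)) for g in out["gene_ids"]
        ]
    return out


def gene_set_burden_input(
    annotated: pd.DataFrame,
    gene_set: Sequence[str],
    sample_ids: Sequence[str],
) -> pd.Series:
    """Per-sample count of rare TREs hitting >=1 gene of the set.

    A TRE hitting several set genes still counts once per carrier; a sample
    carrying two distinct set-hitting TREs counts 2.
    """
    members = set(gene_set)
    counts = pd.Series(0, index=pd.Index(sample_ids, name="sample_id"), dtype=int)
    for row in annotated.itertuples(index=False):
        if members & set(row.gene_ids):
            for sid in row.carriers:
                if sid in counts.index:
                    counts[sid] += 1
    return counts
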