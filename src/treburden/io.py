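"""Readers and writers for the on-disk formats the pipeline touches.

All tables are tab-delimited with a header row.  All interval formats use
the BED convention internally: 0-based, half-open.  Human-readable loci in
``chr1:100-200`` style are treated as 1-based inclusive and converted at
this boundary.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .calling import canonical_motif
from .exceptions import ParseError, SchemaError

REPEAT_CALL_COLUMNS = [
    "sample_id",
    "contig",
    "start",
    "end",
    "motif",
    "length_bp",
    "anchored_irr",
    "depth",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "sex", "depth"]

GROUPS = {"case", "control", "panel"}
SEXES = {"male", "female", "unknown"}


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (0-based half-open); may overlap."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def total_bp(self) -> int:
        """Base pairs covered by the union of the intervals."""
        total = 0
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, s, e in self.intervals:
            by_contig.setdefault(contig, []).append((s, e))
        for ivs in by_contig.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
        return total


def parse_locus(text: str) -> tuple[str, int, int]:
    """Parse a human-readable ``chr1:100-200`` locus (1-based inclusive)
    into 0-based half-open coordinates."""
    try:
        contig, span = text.split(":")
        s, e = span.replace(",", "").split("-")
        start, end = int(s) - 1, int(e)
    except ValueError as exc:
        raise ParseError(f"unparseable locus {text!r}") from exc
    if not 0 <= start < end:
        raise ParseError(f"degenerate locus {text!r}")
    return contig, start, end


# ---------------------------------------------------------------------------
# repeat calls and sample sheets


def read_repeat_calls(path: str | os.PathLike) -> pd.DataFrame:
    """Read an EHdn-style repeat-profile TSV into a repeat-call table.

    Motifs are canonicalised on ingest.  Malformed rows raise ``ParseError``
    naming the offending line (1-based, header = line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "contig": str, "motif": str})
    missing = [c for c in REPEAT_CALL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not row.start < row.end:
            raise ParseError(f"{path} line {i}: interval start >= end")
        if row.length_bp <= 0:
            raise ParseError(f"{path} line {i}: non-positive length_bp")
        if row.anchored_irr < 0:
            raise ParseError(f"{path} line {i}: negative anchored_irr")
        if not 2 <= len(row.motif) <= 20:
            raise ParseError(f"{path} line {i}: motif length outside 2-20")
    df["motif"] = [canonical_motif(m) for m in df["motif"]]
    return df[REPEAT_CALL_COLUMNS]


def write_repeat_calls(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    calls[REPEAT_CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["group"]) - GROUPS
    if bad:
        raise ParseError(f"{path}: unknown group labels {sorted(bad)}")
    bad = set(df["sex"]) - SEXES
    if bad:
        raise ParseError(f"{path}: unknown sex labels {sorted(bad)}")
    return df[SAMPLE_SHEET_COLUMNS]


def write_sample_sheet(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    samples[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / BED12


def read_bed(path: str | os.PathLike, name: str | None = None) -> AnnotationTrack:
    """Read a 3+ column BED file (0-based half-open) into a track."""
    track = AnnotationTrack(name=name or Path(path).stem)
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path} line {i}: fewer than 3 BED columns")
            try:
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path} line {i}: non-integer coordinates") from exc
            if not 0 <= start < end:
                raise ParseError(f"{path} line {i}: degenerate interval")
            track.intervals.append((contig, start, end))
    return track


def write_bed(track: AnnotationTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for contig, start, end in track.intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_gene_model(path: str | os.PathLike):
    """Read a BED12 gene model; returns ``annotate.GeneModel``.

    The name column carries ``GENE|TRANSCRIPT``; blocks are exons,
    thickStart/thickEnd is the CDS span.
    """
    from .annotate import GeneModel, Transcript  # local import: avoid cycle

    transcripts = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path} line {i}: BED12 requires 12 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name, strand = parts[3], parts[5]
            thick_start, thick_end = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path} line {i}: blockCount mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            if offsets[0] != 0 or exons[-1][1] != end:
                raise ParseError(f"{path} line {i}: blocks do not span the record")
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ParseError(f"{path} line {i}: overlapping exon blocks")
            gene_id, _, tx_id = name.partition("|")
            transcripts.append(
                Transcript(
                    gene_id=gene_id,
                    transcript_id=tx_id or name,
                    contig=contig,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds_start=thick_start,
                    cds_end=thick_end,
                )
            )
    return GeneModel(transcripts)


def write_gene_model(model, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for tx in model.transcripts:
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            offsets = ",".join(str(s - tx.start) for s, _ in tx.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        tx.contig,
                        tx.start,
                        tx.end,
                        f"{tx.gene_id}|{tx.transcript_id}",
                        0,
                        tx.strand,
                        tx.cds_start,
                        tx.cds_end,
                        "0,0,0",
                        len(tx.exons),
                        sizes,
                        offsets,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene sets, constraint scores, truth


def read_gene_sets(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read gene sets: a directory of one-gene-per-line ``*.txt`` files
    (set name = file stem) or a single such file.  Duplicates collapse,
    case-sensitively, preserving first-seen order."""
    p = Path(path)
    files = sorted(p.glob("*.txt")) if p.is_dir() else [p]
    sets = {}
    for f in files:
        seen: dict[str, None] = {}
        for line in f.read_text().splitlines():
            gene = line.strip()
            if gene:
                seen.setdefault(gene)
        sets[f.stem] = list(seen)
    return sets


def write_gene_sets(sets: Mapping[str, Sequence[str]], outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, genes in sets.items():
        (outdir / f"{name}.txt").write_text("".join(g + "\n" for g in genes))


def read_constraint_table(path: str | os.PathLike) -> dict[str, float]:
    """Gene -> constraint score (LOEUF-style; lower = more constrained)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in ("gene", "loeuf") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene rows")
    return dict(zip(df["gene"], df["loeuf"].astype(float)))


def write_constraint_table(scores: Mapping[str, float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"gene": list(scores), "loeuf": [scores[g] for g in scores]}
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth, path: str | os.PathLike) -> None:
    payload = {
        "planted_loci": list(truth.planted_loci),
        "carriers_by_locus": {k: sorted(v) for k, v in truth.carriers_by_locus.items()},
        "generating_or": truth.generating_or,
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
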