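"""Seeded synthetic cohorts with planted tandem-repeat expansions.

The generator emulates the data a catalog-free repeat profiler produces
from a case-control-plus-reference-panel cohort: per sample and locus an
estimated repeat length in bp and an anchored in-repeat-read (IRR) count
that scales with repeat length and sequencing depth.  A configured subset
of loci carries planted right-tail expansions at a case:control carrier
odds ratio; planted loci are absent from the reference panel (rare), while
a few "decoy" expansion loci are common in every group so the rarity
filter has something to remove.  A matching annotation bundle (gene model,
gene sets, conserved/coding intervals, epigenomic tracks, per-gene
constraint scores) is generated on the same genome so every downstream
stage runs with no external data.

Determinism: one seed drives independent, deterministically derived
sub-streams per stage (annotations, samples, lengths, carriers, IRR), so
identical configs give byte-identical output no matter which outputs are
materialised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel, Transcript
from .exceptions import ConfigError
from .io import (
    AnnotationTrack,
    write_bed,
    write_constraint_table,
    write_gene_model,
    write_gene_sets,
    write_repeat_calls,
    write_sample_sheet,
    write_truth,
)

READ_LENGTH = 150  # bp; the short-read detection envelope

DEFAULT_MOTIFS = ("AC", "AT", "AAG", "AGC", "AAT", "CCG", "AGG", "AAAG", "AATG", "AGAT")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Sample sizes default to the discovery design this generator emulates:
    1154 cases, 934 controls and a 2504-sample population panel.  Baseline
    (non-expanded) repeat lengths are truncated normal (floor = motif
    length); expansions sit a shifted exponential above
    ``expansion_length_min``, which must exceed the 150 bp read length so
    planted events are unambiguous right-tail outliers.  Carrier
    frequencies are per locus; the implied case:control odds ratio is
    recorded in the emitted truth.
    """

    n_cases: int = 1154
    n_controls: int = 934
    n_panel: int = 2504
    n_loci: int = 2000
    motif_alphabet: tuple[str, ...] = DEFAULT_MOTIFS
    baseline_length_mean: float = 60.0
    baseline_length_sd: float = 15.0
    expansion_length_min: float = 200.0
    expansion_length_scale: float = 100.0
    n_expansion_loci: int = 50
    case_carrier_freq: float = 0.004
    control_carrier_freq: float = 0.002
    panel_carrier_freq: float = 0.0
    n_decoy_loci: int = 5
    decoy_carrier_freq: float = 0.005
    depth_mean: float = 30.0
    depth_sd: float = 4.0
    seed: int = 0
    genome_length: int = 20_000_000
    n_chromosomes: int = 4

    def validate(self) -> None:
        for name in (
            "case_carrier_freq",
            "control_carrier_freq",
            "panel_carrier_freq",
            "decoy_carrier_freq",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: {v} outside [0, 1]")
        if self.expansion_length_min <= READ_LENGTH:
            raise ConfigError(
                f"expansion_length_min: must exceed read length {READ_LENGTH}"
            )
        if self.n_expansion_loci + self.n_decoy_loci > self.n_loci:
            raise ConfigError("n_expansion_loci: planted + decoy loci exceed n_loci")
        for m in self.motif_alphabet:
            if not 2 <= len(m) <= 20:
                raise ConfigError(f"motif_alphabet: motif {m!r} length outside 2-20")
            if any(c not in "ACGT" for c in m):
                raise ConfigError(f"motif_alphabet: non-ACGT motif {m!r}")
        for name in ("n_cases", "n_controls", "n_panel", "n_loci", "n_chromosomes"):
            if getattr(self, name) < 0 or (name == "n_chromosomes" and getattr(self, name) < 1):
                raise ConfigError(f"{name}: must be non-negative")
        if self.genome_length < 200_000 * self.n_chromosomes:
            raise ConfigError("genome_length: too small to place requested features")

    @property
    def generating_or(self) -> float:
        f1, f0 = self.case_carrier_freq, self.control_carrier_freq
        if f0 == 0.0:
            return 1.0 if f1 == 0.0 else math.inf
        return (f1 / (1 - f1)) / (f0 / (1 - f0))

    @classmethod
    def with_odds_ratio(
        cls, odds_ratio: float, control_carrier_freq: float = 0.002, **kwargs
    ) -> "SimConfig":
        """Config whose case carrier frequency realises a target odds ratio."""
        odds0 = control_carrier_freq / (1 - control_carrier_freq)
        odds1 = odds_ratio * odds0
        return cls(
            case_carrier_freq=odds1 / (1 + odds1),
            control_carrier_freq=control_carrier_freq,
            **kwargs,
        )


@dataclass
class SyntheticTruth:
    """Recovery-test bookkeeping: what was planted, and in whom."""

    planted_loci: list[str]
    carriers_by_locus: dict[str, set[str]]
    generating_or: float
    seed: int


@dataclass
class AnnotationBundle:
    """All annotation fixtures generated alongside a cohort."""

    chromosomes: dict[str, int]
    gene_model: GeneModel
    gene_sets: dict[str, list[str]]
    constraint: dict[str, float]
    conserved: AnnotationTrack
    coding: AnnotationTrack
    tracks: dict[str, AnnotationTrack]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_model(self.gene_model, outdir / "genes.bed12")
        write_gene_sets(self.gene_sets, outdir / "gene_sets")
        write_constraint_table(self.constraint, outdir / "constraint.tsv")
        write_bed(self.conserved, outdir / "conserved.bed")
        write_bed(self.coding, outdir / "coding.bed")
        tracks = outdir / "tracks"
        tracks.mkdir(exist_ok=True)
        for name, track in self.tracks.items():
            write_bed(track, tracks / f"{name}.bed")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def simulate_annotations(config: SimConfig) -> AnnotationBundle:
    """Generate the annotation fixtures for a config's genome.

    Gene structures (multi-exon transcripts on both strands with UTRs),
    two-plus named gene sets, conserved intervals, the derived coding
    track, three epigenomic interval tracks, and a per-gene constraint
    table in which a planted "constrained" gene subset receives lower
    scores by construction.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    chrom_len = config.genome_length // config.n_chromosomes
    chromosomes = {f"chr{i + 1}": chrom_len for i in range(config.n_chromosomes)}

    transcripts: list[Transcript] = []
    gid = 0
    for contig in chromosomes:
        pos = int(rng.integers(2_000, 20_000))
        while True:
            n_exons = int(rng.integers(3, 9))
            exon_lens = rng.integers(120, 400, size=n_exons)
            intron_lens = rng.integers(400, 4_000, size=n_exons - 1)
            tx_len = int(exon_lens.sum() + intron_lens.sum())
            if pos + tx_len > chrom_len - 10_000:
                break
            exons = []
            cursor = pos
            for i in range(n_exons):
                exons.append((cursor, cursor + int(exon_lens[i])))
                cursor += int(exon_lens[i])
                if i < n_exons - 1:
                    cursor += int(intron_lens[i])
            start, end = exons[0][0], exons[-1][1]
            utr5 = int(rng.integers(30, exon_lens[0] - 30))
            utr3 = int(rng.integers(30, exon_lens[-1] - 30))
            gene = f"GENE{gid:04d}"
            transcripts.append(
                Transcript(
                    gene_id=gene,
                    transcript_id=f"TX{gid:04d}",
                    contig=contig,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start,
                    end=end,
                    exons=exons,
                    cds_start=start + utr5,
                    cds_end=end - utr3,
                )
            )
            gid += 1
            pos = end + int(rng.integers(10_000, 60_000))
    if not transcripts:
        raise ConfigError("genome_length: too small to place any gene")
    model = GeneModel(transcripts)
    genes = model.gene_ids

    n_constrained = max(2, len(genes) // 5)
    constrained = sorted(rng.choice(genes, size=n_constrained, replace=False))
    constraint = {}
    for g in genes:
        if g in set(constrained):
            constraint[g] = float(rng.uniform(0.05, 0.35))
        else:
            constraint[g] = float(rng.uniform(0.5, 1.9))
    n_random = max(2, len(genes) // 6)
    gene_sets = {
        "constrained_genes": list(constrained),
        "random_set_a": sorted(rng.choice(genes, size=n_random, replace=False)),
        "random_set_b": sorted(rng.choice(genes, size=n_random, replace=False)),
    }

    def random_track(name: str, n: int, min_len: int, max_len: int) -> AnnotationTrack:
        track = AnnotationTrack(name=name)
        contigs = list(chromosomes)
        picks = rng.integers(0, len(contigs), size=n)
        starts = rng.integers(0, chrom_len - max_len, size=n)
        lens = rng.integers(min_len, max_len, size=n)
        for ci, s, ln in zip(picks, starts, lens):
            track.intervals.append((contigs[ci], int(s), int(s + ln)))
        track.intervals.sort()
        return track

    conserved = random_track(
        "conserved", max(50, config.genome_length // 40_000), 20, 200
    )
    coding = model.coding_track()
    tracks = {
        "atac_peaks": random_track("atac_peaks", 150, 200, 2_000),
        "subtad_boundaries": random_track("subtad_boundaries", 40, 10_000, 40_000),
        "enhancer_promoter_anchors": random_track(
            "enhancer_promoter_anchors", 80, 2_000, 10_000
        ),
    }
    return AnnotationBundle(
        chromosomes=chromosomes,
        gene_model=model,
        gene_sets=gene_sets,
        constraint=constraint,
        conserved=conserved,
        coding=coding,
        tracks=tracks,
    )


@dataclass
class CohortSim:
    """A simulated cohort: sample sheet, locus table, length matrix, truth.

    ``lengths`` is an (n_samples, n_loci) array of per-sample repeat-length
    estimates in bp; ``irr`` (lazy) is the matching anchored in-repeat-read
    count matrix, Poisson with mean depth * max(0, length - 150) / 150.
    """

    config: SimConfig
    samples: pd.DataFrame
    loci: pd.DataFrame
    lengths: np.ndarray
    truth: SyntheticTruth
    annotations: AnnotationBundle
    _irr: np.ndarray | None = field(default=None, repr=False)

    @property
    def irr(self) -> np.ndarray:
        if self._irr is None:
            rng = _rng(self.config.seed, 4)
            depths = self.samples["depth"].to_numpy()[:, None]
            mean = depths * np.maximum(0.0, self.lengths - READ_LENGTH) / READ_LENGTH
            self._irr = rng.poisson(mean).astype(np.int32)
        return self._irr

    def repeat_calls(self) -> pd.DataFrame:
        """Materialise the long-format repeat-call table."""
        n_s, n_l = self.lengths.shape
        sample_ids = np.repeat(self.samples["sample_id"].to_numpy(), n_l)
        depths = np.repeat(self.samples["depth"].to_numpy(), n_l)
        return pd.DataFrame(
            {
                "sample_id": sample_ids,
                "contig": np.tile(self.loci["contig"].to_numpy(), n_s),
                "start": np.tile(self.loci["start"].to_numpy(), n_s),
                "end": np.tile(self.loci["end"].to_numpy(), n_s),
                "motif": np.tile(self.loci["motif"].to_numpy(), n_s),
                "length_bp": np.round(self.lengths.ravel(), 2),
                "anchored_irr": self.irr.ravel(),
                "depth": depths,
            }
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sample_sheet(self.samples, outdir / "samples.tsv")
        write_repeat_calls(self.repeat_calls(), outdir / "repeat_calls.tsv")
        write_truth(self.truth, outdir / "truth.json")
        self.annotations.write(outdir / "annotations")


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Generate one cohort under ``config`` (see module docstring).

    Planted expansion loci are placed inside transcripts (so a genic burden
    signal is recoverable and the intergenic test stays null); decoy and
    null loci are placed uniformly over the genome.
    """
    config.validate()
    from .calling import canonical_motif  # deferred: io imports calling

    bundle = simulate_annotations(config)

    rng_samples = _rng(config.seed, 1)
    n_total = config.n_cases + config.n_controls + config.n_panel
    groups = (
        ["case"] * config.n_cases
        + ["control"] * config.n_controls
        + ["panel"] * config.n_panel
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n_total)],
            "group": groups,
            "sex": rng_samples.choice(["male", "female"], size=n_total),
            "depth": np.maximum(
                5.0,
                np.round(
                    rng_samples.normal(config.depth_mean, config.depth_sd, n_total), 1
                ),
            ),
        }
    )

    rng_loci = _rng(config.seed, 2)
    motifs = [
        canonical_motif(m)
        for m in rng_loci.choice(config.motif_alphabet, size=config.n_loci)
    ]
    contigs_all = list(bundle.chromosomes)
    chrom_len = next(iter(bundle.chromosomes.values()))
    width = 60
    contig_col: list[str] = []
    start_col: list[int] = []
    txs = bundle.gene_model.transcripts
    for j in range(config.n_loci):
        if j < config.n_expansion_loci:
            tx = txs[int(rng_loci.integers(0, len(txs)))]
            contig_col.append(tx.contig)
            hi = max(tx.start + 1, tx.end - width)
            start_col.append(int(rng_loci.integers(tx.start, hi)))
        else:
            contig_col.append(contigs_all[int(rng_loci.integers(0, len(contigs_all)))])
            start_col.append(int(rng_loci.integers(0, chrom_len - width)))
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j:05d}" for j in range(config.n_loci)],
            "contig": contig_col,
            "start": start_col,
            "end": [s + width for s in start_col],
            "motif": motifs,
            "planted": [j < config.n_expansion_loci for j in range(config.n_loci)],
            "decoy": [
                config.n_expansion_loci
                <= j
                < config.n_expansion_loci + config.n_decoy_loci
                for j in range(config.n_loci)
            ],
        }
    )

    rng_lengths = _rng(config.seed, 3)
    motif_floor = np.array([len(m) for m in motifs], dtype=float)
    lengths = rng_lengths.normal(
        config.baseline_length_mean,
        config.baseline_length_sd,
        size=(n_total, config.n_loci),
    )
    lengths = np.maximum(lengths, motif_floor[None, :])

    rng_carriers = _rng(config.seed, 5)
    group_freq = np.where(
        samples["group"] == "case",
        config.case_carrier_freq,
        np.where(
            samples["group"] == "control",
            config.control_carrier_freq,
            config.panel_carrier_freq,
        ),
    ).astype(float)
    carriers_by_locus: dict[str, set[str]] = {}
    planted_idx = np.flatnonzero(loci["planted"].to_numpy())
    if planted_idx.size:
        draw = rng_carriers.random((n_total, planted_idx.size))
        mask = draw < group_freq[:, None]
        exp_lengths = config.expansion_length_min + rng_carriers.exponential(
            config.expansion_length_scale, size=int(mask.sum())
        )
        flat = lengths[:, planted_idx]  # fancy indexing copies
        flat[mask] = exp_lengths
        lengths[:, planted_idx] = flat
        ids = samples["sample_id"].to_numpy()
        for k, j in enumerate(planted_idx):
            carriers_by_locus[loci.at[j, "locus_id"]] = set(ids[mask[:, k]])
    decoy_idx = np.flatnonzero(loci["decoy"].to_numpy())
    if decoy_idx.size:
        dmask = rng_carriers.random((n_total, decoy_idx.size)) < config.decoy_carrier_freq
        dlen = config.expansion_length_min + rng_carriers.exponential(
            config.expansion_length_scale, size=int(dmask.sum())
        )
        flat = lengths[:, decoy_idx]
        flat[dmask] = dlen
        lengths[:, decoy_idx] = flat

    truth = SyntheticTruth(
        planted_loci=list(loci.loc[loci["planted"], "locus_id"]),
        carriers_by_locus=carriers_by_locus,
        generating_or=config.generating_or,
        seed=config.seed,
    )
    return CohortSim(
        config=config,
        samples=samples,
        loci=loci,
        lengths=lengths,
        truth=truth,
        annotations=bundle,
    )
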