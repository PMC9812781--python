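"""Tandem-repeat expansion (TRE) calling from cohort repeat-length profiles.

A tandem-repeat expansion is an allele much longer than the lengths seen at
the same locus-motif across the rest of the cohort.  Calling proceeds
per locus-motif profile: run one-dimensional DBSCAN on the length vector,
treat the density cloud(s) as the normal allele range, and call as expansion
carriers the NOISE points whose length strictly exceeds every clustered
length (right tail only — contractions are not expansions).  Called
expansions are then screened against a population reference panel: an
expansion is *rare* when fewer than 0.1% of panel samples carry it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateDataError

NOISE = -1

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Motifs counted as CpG-containing when found in the circularised motif.
CPG_SUBSTRINGS = ("CG", "GC", "CGC", "CGG", "CCG", "GCC", "GGC", "GCG")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Canonical representative of a repeat motif.

    Rotations of the motif and rotations of its reverse complement all
    describe the same repeat tract on an unstranded genome; the canonical
    form is the lexicographically smallest of them.  Idempotent.
    """
    m = motif.upper()
    if not m or any(c not in "ACGT" for c in m):
        raise ConfigError(f"motif: non-ACGT character in {motif!r}")
    if not 1 <= len(m) <= 20:
        raise ConfigError(f"motif: length {len(m)} outside 1-20 for {motif!r}")
    rc = reverse_complement(m)
    candidates = {m[i:] + m[:i] for i in range(len(m))}
    candidates |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(candidates)


def classify_cpg(motif: str) -> bool:
    """True when the circularised motif contains a CpG-type dinucleotide context.

    The motif is scanned as a circle (motif concatenated with itself) for any
    of ``CPG_SUBSTRINGS``; e.g. "GA" circularises to "GAGA" (no hit) while
    "CG" circularises to "CGCG" (hit).
    """
    doubled = motif.upper() * 2
    return any(s in doubled for s in CPG_SUBSTRINGS)


# ---------------------------------------------------------------------------
# regions


@dataclass(frozen=True)
class Region:
    """Maximal run of repeat calls overlapping by >=1 bp on one contig."""

    contig: str
    start: int
    end: int
    motifs: frozenset[str]


def merge_regions(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge repeat calls into tandem-repeat-containing regions.

    Calls overlapping by at least 1 bp (transitively) collapse into one
    region whose motif set is the union of member motifs.  Half-open
    abutting intervals share 0 bp and stay separate.

    Parameters
    ----------
    calls : DataFrame with columns contig, start, end, motif.

    Returns
    -------
    DataFrame with columns contig, start, end, motifs (frozenset).
    """
    out: list[Region] = []
    for contig, sub in calls.groupby("contig", sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        cur_start = cur_end = None
        cur_motifs: set[str] = set()
        for start, end, motif in zip(sub["start"], sub["end"], sub["motif"]):
            if cur_start is None:
                cur_start, cur_end, cur_motifs = start, end, {motif}
            elif start < cur_end:  # >=1 bp overlap under half-open coordinates
                cur_end = max(cur_end, end)
                cur_motifs.add(motif)
            else:
                out.append(Region(contig, cur_start, cur_end, frozenset(cur_motifs)))
                cur_start, cur_end, cur_motifs = start, end, {motif}
        if cur_start is not None:
            out.append(Region(contig, cur_start, cur_end, frozenset(cur_motifs)))
    return pd.DataFrame(
        {
            "contig": [r.contig for r in out],
            "start": [r.start for r in out],
            "end": [r.end for r in out],
            "motifs": [r.motifs for r in out],
        }
    )


# ---------------------------------------------------------------------------
# 1-D DBSCAN


def dbscan_1d(values: Sequence[float], eps: float, min_samples: int) -> np.ndarray:
    """DBSCAN cluster labels for one-dimensional data.

    Standard DBSCAN semantics: a core point has >= ``min_samples`` points
    (itself included) within ``eps``; clusters are the connected components
    of core points plus their border points; everything else is ``NOISE``
    (-1).  Border points are assigned deterministically to the cluster of
    their nearest core point, with ties broken toward the lower-valued core.
    Cluster ids are numbered by ascending cluster position.

    Runs in O(n log n) via sorting; exactness against a brute-force
    neighbourhood-expansion oracle is asserted in the test suite.
    """
    if eps <= 0:
        raise ConfigError("eps: must be positive")
    if min_samples < 2:
        raise ConfigError("min_samples: must be >= 2")
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return np.empty(0, dtype=int)
    if not np.all(np.isfinite(v)):
        raise ConfigError("values: must be finite")

    order = np.argsort(v, kind="stable")
    sv = v[order]
    lo = np.searchsorted(sv, sv - eps, side="left")
    hi = np.searchsorted(sv, sv + eps, side="right")
    core = (hi - lo) >= min_samples

    labels_sorted = np.full(n, NOISE, dtype=int)
    core_idx = np.flatnonzero(core)
    if core_idx.size:
        core_vals = sv[core_idx]
        starts = np.empty(core_idx.size, dtype=bool)
        starts[0] = True
        # adjacent (in sorted order) core points chain iff within eps
        starts[1:] = np.diff(core_vals) > eps
        cid = np.cumsum(starts) - 1
        labels_sorted[core_idx] = cid

        noncore = np.flatnonzero(~core)
        if noncore.size:
            nv = sv[noncore]
            pos = np.searchsorted(core_vals, nv)
            below = np.maximum(pos - 1, 0)
            above = np.minimum(pos, core_vals.size - 1)
            d_below = np.where(pos > 0, nv - core_vals[below], np.inf)
            d_above = np.where(pos < core_vals.size, core_vals[above] - nv, np.inf)
            take_below = d_below <= d_above  # tie -> lower-valued core
            dist = np.minimum(d_below, d_above)
            assign = np.where(take_below, cid[below], cid[above])
            reach = dist <= eps
            labels_sorted[noncore[reach]] = assign[reach]

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


# ---------------------------------------------------------------------------
# expansion calling


def clustered_ceiling(
    sorted_values: np.ndarray, eps: float, min_samples: int
) -> float | None:
    """Maximum clustered (core-or-border) value of a sorted vector, or None.

    Exact shortcut for right-tail expansion calling: a point is clustered iff
    its value is <= (highest core value + eps), so every value strictly above
    the returned ceiling is a DBSCAN noise point.  Returns None when the
    vector has no core point (no reference cluster).
    """
    sv = sorted_values
    lo = np.searchsorted(sv, sv - eps, side="left")
    hi = np.searchsorted(sv, sv + eps, side="right")
    core = (hi - lo) >= min_samples
    core_where = np.flatnonzero(core)
    if core_where.size == 0:
        return None
    core_max = sv[core_where[-1]]
    t_idx = np.searchsorted(sv, core_max + eps, side="right") - 1
    return float(sv[t_idx])


@dataclass
class CallParams:
    """Tuning knobs for expansion calling.

    eps
        DBSCAN radius in bp.  ``None`` auto-selects
        ``max(50, 3 * MAD(lengths))`` per locus.
    min_samples
        DBSCAN density threshold.  ``None`` auto-selects
        ``max(2, ceil(min_samples_frac * n_with_call))``.  The fraction must
        exceed the plausible carrier frequency of a single expansion, or
        co-carriers with similar lengths would form their own cluster and
        escape the noise label.
    min_cohort
        Minimum number of samples with a call for a locus to be testable.
    rarity_threshold
        Maximum (strict) panel carrier frequency for a rare call.
    qc_k
        Samples whose genome-wide repeat-call count exceeds
        ``median + qc_k * IQR`` are dropped before calling.
    """

    eps: float | None = None
    min_samples: int | None = None
    min_samples_frac: float = 0.01
    min_cohort: int = 10
    rarity_threshold: float = 0.001
    qc_k: float = 3.0

    def resolve_eps(self, values: np.ndarray) -> float:
        if self.eps is not None:
            return float(self.eps)
        mad = float(np.median(np.abs(values - np.median(values))))
        return max(50.0, 3.0 * mad)

    def resolve_min_samples(self, n: int) -> int:
        if self.min_samples is not None:
            return int(self.min_samples)
        return max(2, math.ceil(self.min_samples_frac * n))


@dataclass
class TRECall:
    """One called expansion event at a locus-motif, shared by its carriers."""

    contig: str
    start: int
    end: int
    motif: str
    carriers: frozenset[str]
    panel_carrier_count: int = 0
    is_rare: bool = False
    is_cpg: bool = False
    locus_id: str | None = None


@dataclass
class LocusMotifProfile:
    """Cohort-wide repeat-length vector at one locus-motif.

    ``lengths`` maps sample id -> estimated repeat length in bp; samples
    with no call at the locus are simply absent (absence of evidence is not
    evidence of a short allele).
    """

    contig: str
    start: int
    end: int
    motif: str
    lengths: Mapping[str, float] = field(default_factory=dict)


def call_expansion_carriers(
    values: np.ndarray, params: CallParams | None = None
) -> np.ndarray | None:
    """Indices (into ``values``) of right-tail expansion carriers, or None.

    Carriers are DBSCAN noise points whose length strictly exceeds the
    maximum length among all clustered points.  Returns None when the locus
    is untestable (too few calls, no reference cluster) or carrier-free.
    """
    params = params or CallParams()
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < params.min_cohort:
        return None
    eps = params.resolve_eps(v)
    min_samples = params.resolve_min_samples(n)
    labels = dbscan_1d(v, eps, min_samples)
    clustered = labels != NOISE
    if not clustered.any():
        return None  # every point is noise: no reference allele range
    ceiling = v[clustered].max()
    carriers = np.flatnonzero((labels == NOISE) & (v > ceiling))
    return carriers if carriers.size else None


def call_expansions(
    profile: LocusMotifProfile, params: CallParams | None = None
) -> TRECall | None:
    """Call an expansion on one locus-motif profile (see module docstring)."""
    ids = np.asarray(list(profile.lengths.keys()), dtype=object)
    vals = np.asarray(list(profile.lengths.values()), dtype=float)
    keep = np.isfinite(vals)
    ids, vals = ids[keep], vals[keep]
    idx = call_expansion_carriers(vals, params)
    if idx is None:
        return None
    return TRECall(
        contig=profile.contig,
        start=profile.start,
        end=profile.end,
        motif=profile.motif,
        carriers=frozenset(ids[idx]),
        is_cpg=classify_cpg(profile.motif),
    )


def rarity_filter(
    tre: TRECall,
    panel_ids: Iterable[str],
    n_panel: int,
    threshold: float = 0.001,
) -> TRECall:
    """Set panel carrier count and rarity status on a called expansion.

    Rare means strictly fewer than ``threshold`` of the ``n_panel`` reference
    panel samples carry the expansion.
    """
    if n_panel <= 0:
        raise ConfigError("n_panel: must be positive")
    panel = frozenset(panel_ids)
    count = len(tre.carriers & panel)
    tre.panel_carrier_count = count
    tre.is_rare = (count / n_panel) < threshold
    return tre


def sample_qc_mask(per_sample_counts: pd.Series, k: float = 3.0) -> pd.Series:
    """Keep-mask dropping samples with outlying genome-wide repeat counts.

    A sample is dropped when its count exceeds ``median + k * IQR``.
    """
    med = per_sample_counts.median()
    q1, q3 = per_sample_counts.quantile([0.25, 0.75])
    return per_sample_counts <= med + k * (q3 - q1)


def build_profiles(
    calls: pd.DataFrame, samples: pd.DataFrame | None = None
) -> list[LocusMotifProfile]:
    """Group a repeat-call table into per-locus-motif cohort profiles.

    Loci are keyed by exact (contig, start, end, canonical motif).  A sample
    with several calls at one key keeps the largest length.
    """
    if samples is not None:
        known = set(samples["sample_id"])
        unknown = set(calls["sample_id"]) - known
        if unknown:
            raise DegenerateDataError(
                f"repeat calls reference unknown samples: {sorted(unknown)[:5]}"
            )
    profiles = []
    grouped = calls.groupby(["contig", "start", "end", "motif"], sort=True)
    for (contig, start, end, motif), sub in grouped:
        lengths = sub.groupby("sample_id")["length_bp"].max().to_dict()
        profiles.append(LocusMotifProfile(contig, int(start), int(end), motif, lengths))
    return profiles
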