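"""End-to-end orchestration: simulate/load -> QC -> call -> annotate -> burden.

Stages communicate through plain tables (TSV/BED/JSON on disk when run via
``run_pipeline``; the same pandas/numpy objects in memory via
``analyze_cohort``), so each stage is independently testable and a rerun
with the same config and seed reproduces identical output digests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import GENE_PARTS, annotate_tres
from .calling import (
    CallParams,
    call_expansion_carriers,
    classify_cpg,
    sample_qc_mask,
)
from .exceptions import ConfigError, DegenerateDataError
from .io import (
    read_bed,
    read_constraint_table,
    read_gene_model,
    read_gene_sets,
    read_repeat_calls,
    read_sample_sheet,
    write_sample_sheet,
)
from .simulate import AnnotationBundle, CohortSim, SimConfig, simulate_cohort
from .stats import (
    BurdenResult,
    CarrierExcessResult,
    ConstraintCompareResult,
    bh_adjust,
    burden_test,
    carrier_excess,
    compute_pcs,
    constraint_compare,
    normalize_irr,
    select_covariate_pcs,
)


@dataclass
class AnalysisParams:
    """Stage parameters for one analysis run."""

    call: CallParams = field(default_factory=CallParams)
    splice_window: int = 8
    n_pcs: int = 10
    pc_select: str | list[int] | None = "auto"  # None disables PC covariates
    pc_alpha: float = 0.05
    residual_threshold: float = 0.5
    targets: list[str] | None = None  # None = fit every burden target


@dataclass
class AnalysisResult:
    tres: pd.DataFrame
    burden: pd.DataFrame
    carrier_excess: CarrierExcessResult | None
    constraint: ConstraintCompareResult | None
    counts: dict
    selected_pcs: list[int]


def call_tre_table(
    lengths: np.ndarray,
    samples: pd.DataFrame,
    loci: pd.DataFrame,
    params: CallParams,
) -> pd.DataFrame:
    """Call expansions on every locus of a cohort length matrix.

    Returns one row per called expansion: locus columns, carriers (frozenset
    of sample ids), panel_carrier_count, is_rare, is_cpg.  Uses the exact
    sorted-threshold shortcut (``calling.clustered_ceiling``): every value
    strictly above the maximum clustered value is a noise point, so only
    that ceiling is needed to identify right-tail carriers.  Agreement with
    the per-profile ``call_expansions`` path is asserted in the test suite.
    """
    from .calling import clustered_ceiling

    ids = samples["sample_id"].to_numpy()
    panel = frozenset(ids[(samples["group"] == "panel").to_numpy()])
    n_panel = len(panel)
    n_s, n_l = lengths.shape
    locus_ids = (
        loci["locus_id"].to_numpy()
        if "locus_id" in loci
        else np.array([f"L{j:05d}" for j in range(n_l)])
    )
    contigs = loci["contig"].to_numpy()
    starts = loci["start"].to_numpy()
    ends = loci["end"].to_numpy()
    motifs = loci["motif"].to_numpy()

    cols = np.ascontiguousarray(lengths.T)
    cols_sorted = np.sort(cols, axis=1)  # NaN sorts to the end
    has_nan = bool(np.isnan(lengths).any())
    eps_all = None
    if params.eps is None and not has_nan:
        med = np.median(lengths, axis=0)
        mad = np.median(np.abs(lengths - med[None, :]), axis=0)
        eps_all = np.maximum(50.0, 3.0 * mad)

    rows = []
    for j in range(n_l):
        sv = cols_sorted[j]
        if has_nan:
            sv = sv[np.isfinite(sv)]
        n = sv.size
        if n < params.min_cohort:
            continue
        if params.eps is not None:
            eps = float(params.eps)
        elif eps_all is not None:
            eps = float(eps_all[j])
        else:
            eps = params.resolve_eps(sv)
        min_samples = params.resolve_min_samples(n)
        # fast exit: top point is core -> clustered -> no right-tail noise
        if n - np.searchsorted(sv, sv[-1] - eps, side="left") >= min_samples:
            continue
        ceiling = clustered_ceiling(sv, eps, min_samples)
        if ceiling is None or ceiling == sv[-1]:
            continue
        carrier_mask = cols[j] > ceiling  # NaN compares False
        carrier_ids = frozenset(ids[carrier_mask])
        panel_count = len(carrier_ids & panel)
        if n_panel > 0:
            is_rare = (panel_count / n_panel) < params.rarity_threshold
        else:
            is_rare = True
        rows.append(
            {
                "locus_id": locus_ids[j],
                "contig": contigs[j],
                "start": int(starts[j]),
                "end": int(ends[j]),
                "motif": motifs[j],
                "carriers": carrier_ids,
                "n_carriers": len(carrier_ids),
                "panel_carrier_count": panel_count,
                "is_rare": is_rare,
                "is_cpg": classify_cpg(motifs[j]),
            }
        )
    cols = [
        "locus_id",
        "contig",
        "start",
        "end",
        "motif",
        "carriers",
        "n_carriers",
        "panel_carrier_count",
        "is_rare",
        "is_cpg",
    ]
    return pd.DataFrame(rows, columns=cols)


def _burden_counts(
    annotated: pd.DataFrame, sample_ids: pd.Index, rows_mask=None, weights=None
) -> pd.Series:
    counts = pd.Series(0.0, index=sample_ids)
    sub = annotated if rows_mask is None else annotated[rows_mask]
    for i, row in enumerate(sub.itertuples(index=False)):
        w = 1.0 if weights is None else float(weights.iloc[i])
        if w == 0.0:
            continue
        for sid in row.carriers:
            if sid in counts.index:
                counts[sid] += w
    return counts


def analyze_cohort(
    samples: pd.DataFrame,
    loci: pd.DataFrame,
    lengths: np.ndarray,
    bundle: AnnotationBundle,
    params: AnalysisParams | None = None,
    irr: np.ndarray | None = None,
) -> AnalysisResult:
    """Run QC, expansion calling, annotation and all burden statistics.

    ``lengths`` is an (n_samples, n_loci) matrix aligned with ``samples``
    and ``loci`` (NaN = no call).  ``irr`` (same shape) is only needed when
    PC covariates are requested.
    """
    params = params or AnalysisParams()
    counts_funnel: dict = {"n_samples_in": len(samples), "n_loci": len(loci)}

    # per-sample QC on genome-wide repeat-call count
    call_counts = pd.Series(
        np.isfinite(lengths).sum(axis=1), index=samples.index, dtype=float
    )
    keep = sample_qc_mask(call_counts, k=params.call.qc_k)
    samples = samples[keep.to_numpy()].reset_index(drop=True)
    lengths = lengths[keep.to_numpy()]
    if irr is not None:
        irr = irr[keep.to_numpy()]
    counts_funnel["n_samples_qc"] = len(samples)

    tres = call_tre_table(lengths, samples, loci, params.call)
    counts_funnel["n_tres"] = len(tres)
    rare = tres[tres["is_rare"]].reset_index(drop=True)
    counts_funnel["n_rare_tres"] = len(rare)

    annotated = annotate_tres(
        rare,
        bundle.gene_model,
        conserved=bundle.conserved,
        coding=bundle.coding,
        tracks=bundle.tracks,
        gene_sets=bundle.gene_sets,
        splice_window=params.splice_window,
    )

    cc_mask = samples["group"].isin(["case", "control"]).to_numpy()
    cc = samples[cc_mask].reset_index(drop=True)
    if not ((cc["group"] == "case").any() and (cc["group"] == "control").any()):
        raise DegenerateDataError("need at least one case and one control")
    sample_ids = pd.Index(cc["sample_id"], name="sample_id")
    labels = (cc["group"] == "case").astype(int).to_numpy()

    genic_mask = annotated["genic"].to_numpy(dtype=bool) if len(annotated) else np.array([], bool)
    targets: dict[str, tuple[pd.Series, str, str]] = {}

    def add(name, family, mask=None, weights=None, burden_type="count"):
        targets[name] = (
            _burden_counts(annotated, sample_ids, mask, weights),
            family,
            burden_type,
        )

    add("genome_wide", "global")
    add("genic", "global", genic_mask)
    add("intergenic", "global", ~genic_mask if len(annotated) else None)
    add("genic_cpg", "cpg", genic_mask & annotated["is_cpg"].to_numpy(bool) if len(annotated) else None)
    add("genic_noncpg", "cpg", genic_mask & ~annotated["is_cpg"].to_numpy(bool) if len(annotated) else None)
    for part in GENE_PARTS:
        mask = (
            np.array([part in p for p in annotated["parts"]], bool)
            if len(annotated)
            else None
        )
        add(f"part_{part}", "gene_parts", mask)
    for name in bundle.tracks:
        mask = annotated[f"in_{name}"].to_numpy(bool) if len(annotated) else None
        add(f"track_{name}", "epigenomic_tracks", mask)
    for name in bundle.gene_sets:
        mask = annotated[f"set_{name}"].to_numpy(bool) if len(annotated) else None
        add(f"gene_set_{name}", "gene_sets", mask)
    for kind in ("total", "coding", "noncoding"):
        w = annotated[f"conserved_bp_{kind}"] if len(annotated) else None
        add(f"conserved_bp_{kind}", "conserved_bp", None, w, burden_type="bp")

    # covariates: sex, optional IRR PCs; intergenic count for target tests
    cov = pd.DataFrame(
        {"sex_male": (cc["sex"] == "male").astype(float).to_numpy()},
        index=sample_ids,
    )
    selected: list[int] = []
    if params.pc_select is not None and params.n_pcs > 0 and irr is not None:
        irr_cc = pd.DataFrame(irr[cc_mask], index=sample_ids)
        norm = normalize_irr(irr_cc, cc.set_index("sample_id")["depth"])
        k = min(params.n_pcs, len(cc) - 1, norm.shape[1])
        pcs, _ = compute_pcs(norm, k)
        if isinstance(params.pc_select, str) and params.pc_select == "auto":
            selected = select_covariate_pcs(
                pcs, targets["genome_wide"][0], alpha=params.pc_alpha
            )
        else:
            selected = select_covariate_pcs(pcs, targets["genome_wide"][0], override=list(params.pc_select))
        for i in selected:
            cov[f"PC{i}"] = pcs[f"PC{i}"].to_numpy()

    intergenic_counts = targets["intergenic"][0]
    results: list[BurdenResult] = []
    wanted = params.targets
    for name, (burden, family, btype) in targets.items():
        if wanted is not None and name not in wanted:
            continue
        cov_t = cov
        if family != "global" or name == "genic":
            cov_t = cov.copy()
            cov_t["intergenic_burden"] = intergenic_counts.to_numpy()
        try:
            res = burden_test(
                labels, burden.to_numpy(), cov_t, target=name, burden_type=btype
            )
        except DegenerateDataError:
            res = BurdenResult(
                target=name,
                burden_type=btype,
                n_cases=int(labels.sum()),
                n_controls=int((1 - labels).sum()),
                odds_ratio=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                p=float("nan"),
                beta=float("nan"),
                se=float("nan"),
                separation=False,
                converged=False,
            )
        res.family = family
        results.append(res)

    burden_df = pd.DataFrame([asdict(r) for r in results])
    for family, sub in burden_df.groupby("family"):
        ok = sub["p"].notna()
        if ok.any():
            burden_df.loc[sub.index[ok], "p_bh"] = bh_adjust(sub.loc[ok, "p"])

    excess = None
    try:
        excess = carrier_excess(
            targets["genome_wide"][0],
            labels,
            covariates=cov,
            threshold=params.residual_threshold,
        )
    except DegenerateDataError:
        pass

    constraint_res = None
    if bundle.constraint:
        case_ids = set(cc.loc[cc["group"] == "case", "sample_id"])
        genes_with = set()
        for row in annotated.itertuples(index=False):
            if row.carriers & case_ids:
                genes_with.update(row.gene_ids)
        genes_without = [g for g in bundle.constraint if g not in genes_with]
        try:
            constraint_res = constraint_compare(
                sorted(genes_with), genes_without, bundle.constraint
            )
        except DegenerateDataError:
            pass

    # funnel invariant: genic + intergenic = genome-wide for every sample
    total = targets["genome_wide"][0]
    split = targets["genic"][0] + targets["intergenic"][0]
    counts_funnel["genic_plus_intergenic_equals_total"] = bool(
        np.allclose(total.to_numpy(), split.to_numpy())
    )
    return AnalysisResult(
        tres=annotated,
        burden=burden_df,
        carrier_excess=excess,
        constraint=constraint_res,
        counts=counts_funnel,
        selected_pcs=selected,
    )


# ---------------------------------------------------------------------------
# on-disk runs


@dataclass
class RunConfig:
    """Inputs and stage parameters for a full on-disk run.

    Either ``sim`` (generate a synthetic cohort) or the three input paths
    must be given.
    """

    outdir: str | Path
    sim: SimConfig | None = None
    calls_path: str | Path | None = None
    samples_path: str | Path | None = None
    annotations_dir: str | Path | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def validate(self) -> None:
        if self.sim is None:
            missing = [
                n
                for n in ("calls_path", "samples_path", "annotations_dir")
                if getattr(self, n) is None
            ]
            if missing:
                raise ConfigError(f"run config: need sim or input paths ({missing})")


def load_annotation_bundle(path: str | Path) -> AnnotationBundle:
    """Read a bundle directory written by ``AnnotationBundle.write``."""
    path = Path(path)
    tracks = {}
    tdir = path / "tracks"
    if tdir.is_dir():
        for f in sorted(tdir.glob("*.bed")):
            tracks[f.stem] = read_bed(f)
    return AnnotationBundle(
        chromosomes={},
        gene_model=read_gene_model(path / "genes.bed12"),
        gene_sets=read_gene_sets(path / "gene_sets"),
        constraint=read_constraint_table(path / "constraint.tsv"),
        conserved=read_bed(path / "conserved.bed"),
        coding=read_bed(path / "coding.bed"),
        tracks=tracks,
    )


def pivot_calls(
    calls: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray | None]:
    """Long repeat-call table -> (locus table, length matrix, IRR matrix)."""
    key = ["contig", "start", "end", "motif"]
    wide = calls.pivot_table(
        index="sample_id", columns=key, values="length_bp", aggfunc="max"
    ).reindex(samples["sample_id"])
    irr_wide = calls.pivot_table(
        index="sample_id", columns=key, values="anchored_irr", aggfunc="max"
    ).reindex(samples["sample_id"])[wide.columns]
    loci = pd.DataFrame(list(wide.columns), columns=key)
    loci.insert(0, "locus_id", [f"L{j:05d}" for j in range(len(loci))])
    return loci, wide.to_numpy(dtype=float), irr_wide.to_numpy(dtype=float)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _serialise_tres(tres: pd.DataFrame) -> pd.DataFrame:
    out = tres.copy()
    if len(out):
        out["carriers"] = [",".join(sorted(c)) for c in out["carriers"]]
        if "gene_ids" in out:
            out["gene_ids"] = [",".join(g) for g in out["gene_ids"]]
        if "parts" in out:
            out["parts"] = [",".join(sorted(p)) for p in out["parts"]]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all result tables plus a manifest.

    Returns the manifest dict.  Identical config + seed give identical
    output digests.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim_config = config.sim
        if sim_config.seed != config.seed:
            sim_config = SimConfig(**{**asdict(sim_config), "seed": config.seed})
        sim = simulate_cohort(sim_config)
        samples, loci, lengths = sim.samples, sim.loci, sim.lengths
        bundle = sim.annotations
        need_irr = config.params.pc_select is not None and config.params.n_pcs > 0
        irr = sim.irr if need_irr else None
        inputs_dir = outdir / "inputs"
        sim.write(inputs_dir)
    else:
        samples = read_sample_sheet(config.samples_path)
        calls = read_repeat_calls(config.calls_path)
        bundle = load_annotation_bundle(config.annotations_dir)
        loci, lengths, irr = pivot_calls(calls, samples)

    result = analyze_cohort(
        samples, loci, lengths, bundle, params=config.params, irr=irr
    )

    write_sample_sheet(samples, outdir / "samples_used.tsv")
    _serialise_tres(result.tres).to_csv(outdir / "tres.tsv", sep="\t", index=False)
    result.burden.to_csv(outdir / "burden_results.tsv", sep="\t", index=False)
    extras = {}
    if result.carrier_excess is not None:
        extras["carrier_excess"] = asdict(result.carrier_excess)
    if result.constraint is not None:
        extras["constraint_compare"] = asdict(result.constraint)
    (outdir / "summary.json").write_text(json.dumps(extras, indent=1, sort_keys=True))

    outputs = ["samples_used.tsv", "tres.tsv", "burden_results.tsv", "summary.json"]
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": {
            "splice_window": config.params.splice_window,
            "n_pcs": config.params.n_pcs,
            "pc_select": config.params.pc_select,
            "residual_threshold": config.params.residual_threshold,
            "eps": config.params.call.eps,
            "min_samples": config.params.call.min_samples,
            "rarity_threshold": config.params.call.rarity_threshold,
        },
        "sim": asdict(config.sim) if config.sim is not None else None,
        "counts": result.counts,
        "selected_pcs": result.selected_pcs,
        "digests": {name: _digest(outdir / name) for name in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
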