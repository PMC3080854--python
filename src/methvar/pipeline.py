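"""End-to-end pipeline: simulate -> preprocess -> variability -> VMR calling
-> sequence features -> report.

Every stage reads its inputs from and writes its outputs to a run directory,
so the final report can be regenerated from the intermediate files alone and
a rerun with the same configuration and seed is byte-identical.  All
randomness is funneled through one seeded generator per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import synthetic_data as sd
from . import variability as vb
from . import vmr as vm
from . import seqfeatures as sf

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; every field can be overridden by a CLI flag."""

    outdir: str = "methvar_run"
    simulate: bool = True
    # external inputs (used when simulate is False)
    signals_path: str | None = None
    intensity_path: str | None = None
    reference_signals_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    # preprocessing
    background_mean: float = 100.0
    background_sd: float = 10.0
    k: float = 2.6
    span: float = 0.3
    # calling
    control_group: str = "control"
    q: float = 95.0
    min_probes: int = 1
    max_gap: int = 0
    n_permutations: int = 10000
    # simulation overrides (None -> SimulationConfig defaults)
    sim: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rundir(cfg: RunConfig) -> Path:
    d = Path(cfg.outdir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(cfg: RunConfig) -> dict:
    run = _rundir(cfg)
    sim_cfg = sd.SimulationConfig(**{"seed": cfg.seed, **cfg.sim})
    ds = sd.simulate_dataset(sim_cfg)
    paths = sd.write_dataset(ds, run / "synthetic")
    tss, repeats = sd.synthetic_tracks(ds.annotation, seed=cfg.seed)
    tss.to_csv(run / "synthetic" / "tss.bed", sep="\t", index=False, header=False)
    repeats.to_csv(run / "synthetic" / "repeats.bed", sep="\t", index=False,
                   header=False)
    logger.info("simulate: %d islands, %d probes", sim_cfg.n_islands,
                ds.signals.shape[0])
    return {str(k): str(v) for k, v in paths.items()}


def _input_paths(cfg: RunConfig) -> dict[str, Path]:
    run = _rundir(cfg)
    if cfg.simulate:
        syn = run / "synthetic"
        return {
            "signals": syn / "signals_raw.tsv",
            "intensity": syn / "intensity.tsv",
            "reference_signals": syn / "reference_signals.tsv",
            "design": syn / "design.tsv",
            "annotation": syn / "probes.bed",
            "truth": syn / "truth.tsv",
            "tss": syn / "tss.bed",
            "repeats": syn / "repeats.bed",
        }
    paths = {
        "signals": Path(cfg.signals_path),
        "intensity": Path(cfg.intensity_path),
        "reference_signals": Path(cfg.reference_signals_path),
        "design": Path(cfg.design_path),
        "annotation": Path(cfg.annotation_path),
    }
    for name, p in paths.items():
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} not found: {p}")
    return paths


def stage_preprocess(cfg: RunConfig) -> None:
    run = _rundir(cfg)
    inp = _input_paths(cfg)
    sm = pp.read_signal_matrix(inp["signals"], inp["design"])
    intensity = pd.read_csv(inp["intensity"], sep="\t", index_col="probe_id")
    normalized, report = pp.normalize_signal_matrix(
        sm, intensity, cfg.background_mean, cfg.background_sd, k=cfg.k,
        span=cfg.span)
    pp.write_signal_matrix(normalized, run / "signals_normalized.tsv")
    report["removed_per_array"].rename("n_removed").to_csv(
        run / "qc_removed_per_array.tsv", sep="\t", index_label="array_id")
    pd.DataFrame(report["removed_features"],
                 columns=["probe_id", "array_id"]).to_csv(
        run / "qc_removed_features.tsv", sep="\t", index=False)


def stage_variability(cfg: RunConfig) -> None:
    run = _rundir(cfg)
    inp = _input_paths(cfg)
    sm = pp.read_signal_matrix(run / "signals_normalized.tsv", inp["design"],
                               provenance="normalized")
    ref = pd.read_csv(inp["reference_signals"], sep="\t", index_col="probe_id")
    ann = sd.read_annotation(inp["annotation"])
    table = vb.variability_table(sm, ref, ann)
    table.to_csv(run / "variability_table.tsv", sep="\t", index_label="probe_id")
    summary = vb.pca_dispersion(sm)
    summary.scores.to_csv(run / "pca_scores.tsv", sep="\t",
                          index_label="array_id")
    pd.DataFrame({
        "component": [f"PC{i+1}" for i in
                      range(len(summary.explained_variance_ratio))],
        "variance_explained": summary.explained_variance_ratio,
    }).to_csv(run / "pca_variance.tsv", sep="\t", index=False)
    summary.group_component_sd.assign(volume=summary.group_volume).to_csv(
        run / "pca_dispersion.tsv", sep="\t", index_label="group")


def stage_call_vmr(cfg: RunConfig) -> None:
    run = _rundir(cfg)
    inp = _input_paths(cfg)
    sm = pp.read_signal_matrix(run / "signals_normalized.tsv", inp["design"],
                               provenance="normalized")
    ann = sd.read_annotation(inp["annotation"])
    table = pd.read_csv(run / "variability_table.tsv", sep="\t",
                        index_col="probe_id")
    sd_cols = [c for c in table.columns if c.startswith("sd_")]
    sd_table = table[sd_cols].rename(columns=lambda c: c[3:])
    vmrset = vm.call_vmr(sd_table, sm, ann, control_group=cfg.control_group,
                         q=cfg.q, min_probes=cfg.min_probes,
                         max_gap=cfg.max_gap)
    for group, regions in vmrset.regions.items():
        regions.to_csv(run / f"regions_{group}.tsv", sep="\t", index=False)
        pd.Series(sorted(vmrset.loci[group]), name="locus_id").to_csv(
            run / f"loci_{group}.tsv", sep="\t", index=False)
    vm.export_regions_bed(vmrset, run / "regions.bed")
    with open(run / "vmr_params.json", "w") as fh:
        json.dump({"threshold": vmrset.threshold, "percentile": vmrset.percentile,
                   "min_probes": vmrset.min_probes, "max_gap": vmrset.max_gap},
                  fh, indent=2, sort_keys=True)


def stage_features(cfg: RunConfig) -> None:
    run = _rundir(cfg)
    inp = _input_paths(cfg)
    if "tss" not in inp or not Path(inp["tss"]).exists():
        logger.info("no TSS track available; features stage skipped")
        return
    ann = sd.read_annotation(inp["annotation"])
    table = pd.read_csv(run / "variability_table.tsv", sep="\t",
                        index_col="probe_id")
    ranking = table[f"sd_{cfg.control_group}"]
    tss = sf.read_tss_bed(inp["tss"])
    repeats = sf.read_repeats_bed(inp["repeats"])
    variable, invariant = sf.promoter_windows(
        tss, ranking, ann[["chrom", "start", "end"]], n_top=100, n_bottom=1000)
    report = sf.compare_promoter_features(variable, invariant, repeats)
    report.to_csv(run / "features.tsv", sep="\t", index=False)


def stage_report(cfg: RunConfig) -> dict:
    """Build the summary report from intermediate files only."""
    run = _rundir(cfg)
    inp = _input_paths(cfg)
    sm = pp.read_signal_matrix(run / "signals_normalized.tsv", inp["design"],
                               provenance="normalized")
    table = pd.read_csv(run / "variability_table.tsv", sep="\t",
                        index_col="probe_id")
    groups = [g for g in pd.unique(sm.groups)]

    # SD box-plot table and Welch tests (overall-variability analogues)
    sd_cols = {g: table[f"sd_{g}"].dropna() for g in groups}
    qs = [10, 25, 50, 75, 90]
    box = pd.DataFrame({g: np.append(np.percentile(v, qs), v.mean())
                        for g, v in sd_cols.items()},
                       index=[f"p{q}" for q in qs] + ["mean"])
    box.to_csv(run / "report_sd_boxplot.tsv", sep="\t", index_label="quantile")
    welch = {}
    for a, b in [(cfg.control_group, g) for g in groups
                 if g != cfg.control_group]:
        t, p, _ = vb.sd_distribution_test(sd_cols[a], sd_cols[b])
        welch[f"{a}_vs_{b}"] = {"t": t, "p": p}

    # Bartlett p-value histograms per pairwise comparison
    for col in [c for c in table.columns if c.startswith("bartlett_p_")]:
        hist = vb.pvalue_histogram(table[col].dropna())
        hist.to_csv(run / f"report_hist_{col[len('bartlett_p_'):]}.tsv",
                    sep="\t", index=False)

    # signal frequency histogram per group
    edges = np.linspace(-3, 3, 61)
    sig_hist = {}
    for g in groups:
        vals = sm.values[sm.arrays_of(g)].to_numpy().ravel()
        sig_hist[g], _ = np.histogram(vals[np.isfinite(vals)], bins=edges)
    pd.DataFrame(sig_hist, index=pd.Index(edges[:-1], name="bin_left")).to_csv(
        run / "report_signal_hist.tsv", sep="\t")

    # overlap of locus calls
    loci = {}
    for g in groups:
        path = run / f"loci_{g}.tsv"
        loci[g] = (list(pd.read_csv(path, sep="\t")["locus_id"])
                   if path.exists() and path.stat().st_size > len("locus_id\n")
                   else [])
    ann = sd.read_annotation(inp["annotation"])
    n_total = ann["island_id"].nunique()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    overlap = vm.overlap_test_from_sets(
        loci.get("control", []), loci.get("F1", []), loci.get("F6", []),
        n_total, mode="permutation", n_permutations=cfg.n_permutations, rng=rng)
    # echo analysis parameters; file locations are run-specific, not part of
    # the reproducible report content
    params = {k: v for k, v in cfg.to_dict().items()
              if k != "outdir" and not k.endswith("_path")}
    report = {
        "parameters": params,
        "locus_counts": {g: len(v) for g, v in loci.items()},
        "welch_sd_tests": welch,
        "overlap": {
            "partition": overlap.partition,
            "observed_triple": overlap.observed_triple,
            "expected_triple": overlap.expected_triple,
            "permutation_null_mean": overlap.null_mean,
            "permutation_p": overlap.pvalue,
            "unique_fraction": overlap.unique_fraction,
            "n_total": n_total,
        },
    }
    # truth-based recovery when the run is synthetic
    truth_path = inp.get("truth")
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="locus_id")
        report["recovery"] = {
            g: vm.recovery_metrics(loci[g], truth, group=g) for g in groups}
        gain = {}
        for g in groups:
            reg_path = run / f"regions_{g}.tsv"
            if reg_path.exists():
                regions = pd.read_csv(reg_path, sep="\t")
                if len(regions):
                    gain[g] = vm.gain_fraction(regions)
        report["gain_fraction"] = gain
    with open(run / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    _plots(run, box, sig_hist, edges)
    return report


def _plots(run: Path, box: pd.DataFrame, sig_hist: dict, edges) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = list(box.columns)
    for i, g in enumerate(groups):
        q = box[g]
        ax.vlines(i, q["p10"], q["p90"], color="k")
        ax.add_patch(plt.Rectangle((i - 0.2, q["p25"]), 0.4, q["p75"] - q["p25"],
                                   fill=False))
        ax.hlines(q["p50"], i - 0.2, i + 0.2, color="r")
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel("probe signal SD")
    fig.savefig(run / "report_sd_boxplot.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    centers = (np.asarray(edges[:-1]) + np.asarray(edges[1:])) / 2
    for g, counts in sig_hist.items():
        ax.plot(centers, counts, label=g)
    ax.set_xlabel("normalized log2 ratio")
    ax.set_ylabel("probe count")
    ax.legend()
    fig.savefig(run / "report_signal_hist.png", dpi=100)
    plt.close(fig)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "variability": stage_variability,
    "call-vmr": stage_call_vmr,
    "features": stage_features,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the report dictionary."""
    order = (["simulate"] if cfg.simulate else []) + [
        "preprocess", "variability", "call-vmr", "features", "report"]
    result = None
    for name in order:
        logger.info("stage %s", name)
        try:
            result = STAGES[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return result
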