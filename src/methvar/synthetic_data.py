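"""Simulation of stochastic, partially heritable epiallele drift.

Generates methylation fractions for CpG-island loci in isogenic mice under a
multigenerational drift model: at epigenetically plastic loci, each generation
a signed perturbation is added to the methylation fraction and a fraction
``h`` (heritability) of the parent's deviation from the locus base level is
transmitted to the offspring.  Dietary methyl-donor exposure inflates the
perturbation variance at affected loci and recruits additional loci into the
plastic class, one cohort per exposed generation.  The simulated epialleles
are rendered as two-color unmethylated-fraction enrichment array log-ratios
(test mouse over a pooled reference of unexposed controls) with independent
per-probe technical noise, so an *increase* in signal means relative
hypomethylation.

Three assay groups are emulated: unexposed controls, first-generation exposed
(F1, one diet generation) and sixth-generation exposed (F6, six diet
generations), five mice each, plus a ten-mouse reference pool.  Every lineage
is propagated for the same total number of generations (a burn-in under the
baseline law followed by the final ``n_generations_long`` generations), so
that when the diet has no effect the three groups are draws from exactly the
same law.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUP_CONTROL = "control"
GROUP_F1 = "F1"
GROUP_F6 = "F6"
GROUP_REFERENCE = "reference"

STATUS_INVARIANT = "invariant"
STATUS_BASELINE = "baseline-plastic"
STATUS_RECRUITED = "diet-recruited"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the epiallele drift simulation.

    Methylation-scale parameters are on the [0, 1] methylated-fraction scale;
    ``technical_sd`` is on the log2-ratio scale of the rendered arrays.
    """

    n_islands: int = 16000
    probes_per_island: tuple[int, int] = (4, 9)  # inclusive (min, max)
    n_mice_per_group: int = 5
    n_reference_mice: int = 10
    baseline_plastic_fraction: float = 0.10
    diet_extra_plastic_fraction_per_gen: float = 0.10 / 6
    baseline_sd: float = 0.08
    diet_inflation: float = 3.0
    heritability_h: float = 0.7
    n_generations_long: int = 6
    burn_in_generations: int = 30
    technical_sd: float = 0.10
    eps: float = 0.01  # pseudo-fraction guarding log2 of a zero unmethylated fraction
    # base-level windows: loci gaining methylation start low, loci losing start
    # high (intermediate, metastable epialleles), invariant loci anywhere
    m_base_gain: tuple[float, float] = (0.10, 0.45)
    m_base_loss: tuple[float, float] = (0.55, 0.90)
    m_base_invariant: tuple[float, float] = (0.05, 0.95)
    # raw-intensity fixtures for QC testing
    background_mean: float = 100.0
    background_sd: float = 10.0
    signal_intensity_log10_mean: float = 3.0
    signal_intensity_log10_sd: float = 0.35
    low_signal_fraction: float = 0.02
    dye_bias_amplitude: float = 0.15
    array_median_offset_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_plastic_fraction", "diet_extra_plastic_fraction_per_gen"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = (self.baseline_plastic_fraction
                 + self.n_generations_long * self.diet_extra_plastic_fraction_per_gen)
        if total > 1.0:
            raise ValueError(
                f"plastic fractions sum to {total:.3f} > 1 "
                "(baseline + recruited over all generations)")
        if not 0.0 <= self.heritability_h <= 1.0:
            raise ValueError(f"heritability_h must be in [0, 1], got {self.heritability_h}")
        if self.diet_inflation < 1.0:
            raise ValueError(f"diet_inflation must be >= 1, got {self.diet_inflation}")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EpialleleMatrix:
    """Per-locus methylation fractions for every simulated individual.

    ``m`` is loci x individuals; ``groups`` labels each individual column
    (control / F1 / F6 / reference).  ``m_base`` and ``direction`` are the
    per-locus base level and the locus-fixed sign of perturbations.
    """

    m: pd.DataFrame
    groups: pd.Series
    m_base: np.ndarray
    direction: np.ndarray

    def individuals(self, group: str) -> pd.DataFrame:
        return self.m.loc[:, self.groups[self.groups == group].index]


# ---------------------------------------------------------------------------
# core drift model
# ---------------------------------------------------------------------------

def next_generation(parent_m, m_base, h, delta):
    """One generation of epiallele transmission.

    The offspring methylation fraction is the locus base level plus the
    heritable fraction ``h`` of the parent's deviation plus the current
    generation's perturbation ``delta``, clamped to [0, 1].
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("heritability h must be in [0, 1]")
    return np.clip(np.asarray(m_base) + h * (np.asarray(parent_m) - np.asarray(m_base))
                   + np.asarray(delta), 0.0, 1.0)


def _assign_status(cfg: SimulationConfig, rng: np.random.Generator):
    """i.i.d. per-locus status draw: invariant, baseline-plastic, or recruited
    at diet generation g (1..n_generations_long)."""
    u = rng.random(cfg.n_islands)
    recruit_gen = np.zeros(cfg.n_islands, dtype=int)  # 0 = never recruited
    bp = cfg.baseline_plastic_fraction
    rp = cfg.diet_extra_plastic_fraction_per_gen
    status = np.full(cfg.n_islands, STATUS_INVARIANT, dtype=object)
    status[u < bp] = STATUS_BASELINE
    for g in range(1, cfg.n_generations_long + 1):
        sel = (u >= bp + (g - 1) * rp) & (u < bp + g * rp)
        status[sel] = STATUS_RECRUITED
        recruit_gen[sel] = g
    return status, recruit_gen


def _draw_m_base(cfg: SimulationConfig, status, direction, rng):
    m_base = rng.uniform(*cfg.m_base_invariant, cfg.n_islands)
    variable = status != STATUS_INVARIANT
    gain = variable & (direction > 0)
    loss = variable & (direction < 0)
    m_base[gain] = rng.uniform(*cfg.m_base_gain, int(gain.sum()))
    m_base[loss] = rng.uniform(*cfg.m_base_loss, int(loss.sum()))
    return m_base


def _run_lineages(cfg, status, recruit_gen, direction, m_base, n_ind,
                  diet_generations, rng):
    """Propagate ``n_ind`` independent lineages for burn-in + long generations;
    the final ``diet_generations`` generations are under the supplemented diet."""
    baseline = status == STATUS_BASELINE
    recruited = status == STATUS_RECRUITED
    total = cfg.burn_in_generations + cfg.n_generations_long
    m = np.tile(m_base[:, None], (1, n_ind))
    sgn = direction[:, None]
    for t in range(total):
        d = diet_generations - (total - 1 - t)  # diet generations so far, incl. current
        on_diet = d >= 1
        sd = cfg.baseline_sd * (np.sqrt(cfg.diet_inflation) if on_diet else 1.0)
        active = baseline.copy()
        if on_diet:
            active |= recruited & (recruit_gen <= d)
        delta = sgn * np.abs(rng.normal(0.0, sd, size=m.shape))
        delta[~active] = 0.0
        m = next_generation(m, m_base[:, None], cfg.heritability_h, delta)
    return m


def simulate_epialleles(config: SimulationConfig):
    """Simulate the full cohort and its ground truth.

    Returns an :class:`EpialleleMatrix` (controls, F1, F6 and the reference
    pool) and a truth table with one row per locus: status, generation of
    recruitment (0 if never) and the injected per-generation perturbation
    variance on the methylation scale (0 at invariant loci).
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    status, recruit_gen = _assign_status(config, rng)
    direction = rng.choice(np.array([-1.0, 1.0]), config.n_islands)
    m_base = _draw_m_base(config, status, direction, rng)

    n = config.n_mice_per_group
    blocks, labels = [], []
    for group, n_ind, dg in [
        (GROUP_CONTROL, n, 0),
        (GROUP_F1, n, 1),
        (GROUP_F6, n, config.n_generations_long),
        (GROUP_REFERENCE, config.n_reference_mice, 0),
    ]:
        blocks.append(_run_lineages(config, status, recruit_gen, direction,
                                    m_base, n_ind, dg, rng))
        labels += [(f"{group}_{i + 1}", group) for i in range(n_ind)]

    locus_ids = [f"CGI_{i:05d}" for i in range(config.n_islands)]
    cols = [name for name, _ in labels]
    m = pd.DataFrame(np.hstack(blocks), index=locus_ids, columns=cols)
    groups = pd.Series({name: grp for name, grp in labels}, name="group")

    half_normal_var = 1.0 - 2.0 / np.pi  # variance of |N(0,1)| about its mean
    per_gen_var = np.zeros(config.n_islands)
    per_gen_var[status == STATUS_BASELINE] = config.baseline_sd**2 * half_normal_var
    per_gen_var[status == STATUS_RECRUITED] = (
        config.baseline_sd**2 * config.diet_inflation * half_normal_var)
    truth = pd.DataFrame({
        "locus_id": locus_ids,
        "status": status,
        "recruit_generation": recruit_gen,
        "injected_variance": per_gen_var,
        "direction": np.where(direction > 0, "gain", "loss"),
        "m_base": m_base,
    }).set_index("locus_id")

    return EpialleleMatrix(m=m, groups=groups, m_base=m_base,
                           direction=direction), truth


# ---------------------------------------------------------------------------
# array rendering
# ---------------------------------------------------------------------------

def signals_from_methylation(m_test, m_ref, technical_sd=0.0, eps=0.01, rng=None):
    """Two-color log-ratio of unmethylated-fraction enrichment signals.

    The noiseless value is ``log2((1 - m_test + eps) / (1 - m_ref + eps))``:
    a hypomethylated test sample yields a *positive* log-ratio.  Gaussian
    technical noise of SD ``technical_sd`` is added independently per value.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    m_test = np.asarray(m_test, dtype=float)
    m_ref = np.asarray(m_ref, dtype=float)
    if np.any((m_test < 0) | (m_test > 1)) or np.any((m_ref < 0) | (m_ref > 1)):
        raise ValueError("methylation fractions must be in [0, 1]")
    lr = np.log2((1.0 - m_test + eps) / (1.0 - m_ref + eps))
    if technical_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        lr = lr + rng.normal(0.0, technical_sd, size=lr.shape)
    return lr


@dataclass
class SyntheticDataset:
    """Raw fixtures for the downstream pipeline, probe-level."""

    signals: pd.DataFrame          # raw log-ratios, probes x test arrays
    intensity: pd.DataFrame        # raw mean intensities, probes x test arrays
    reference_signals: pd.DataFrame  # reference-channel log signals, probes x all arrays
    design: pd.DataFrame           # array_id, group
    annotation: pd.DataFrame       # BED6+2 probe annotation
    truth: pd.DataFrame
    config: SimulationConfig


def emit_dataset(epialleles: EpialleleMatrix, config: SimulationConfig,
                 truth: pd.DataFrame | None = None) -> SyntheticDataset:
    """Expand island-level epialleles to probe-level raw array fixtures.

    Probes within an island share the island's methylation state; technical
    noise, raw intensities, dye bias, array median offsets and a configurable
    fraction of near-background low-signal features are added per probe and
    array.  Synthetic genomic coordinates and GC contents (independent of the
    injected variance) are assigned.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])

    lo, hi = config.probes_per_island
    npp = rng.integers(lo, hi + 1, size=config.n_islands)
    island_idx = np.repeat(np.arange(config.n_islands), npp)
    n_probes = island_idx.size
    probe_ids = pd.Index([f"P_{i:07d}" for i in range(n_probes)],
                         name="probe_id")
    island_ids = np.asarray(epialleles.m.index)

    # reference pool: mean unmethylated fraction over the pool, per locus
    ref_cols = epialleles.groups[epialleles.groups == GROUP_REFERENCE].index
    m_ref = epialleles.m[ref_cols].to_numpy().mean(axis=1)

    test_cols = [c for c in epialleles.m.columns if c not in set(ref_cols)]
    m_test = epialleles.m[test_cols].to_numpy()

    # noiseless island log-ratio, expanded to probes, + independent probe noise
    lr_island = signals_from_methylation(m_test, m_ref[:, None], 0.0, config.eps)
    lr = lr_island[island_idx]
    lr = lr + rng.normal(0.0, config.technical_sd, size=lr.shape)

    # raw intensities: lognormal signal with a low-signal subset near background
    log10_a = rng.normal(config.signal_intensity_log10_mean,
                         config.signal_intensity_log10_sd, size=lr.shape)
    intensity = config.background_mean + 10.0 ** log10_a
    low = rng.random(lr.shape) < config.low_signal_fraction
    intensity[low] = rng.normal(config.background_mean, 0.5 * config.background_sd,
                                size=int(low.sum()))

    # intensity-dependent dye bias + per-array median offset (removed by LOESS
    # normalization and median centering downstream)
    x = np.log10(np.clip(intensity, 1.0, None))
    x = (x - x.mean()) / x.std()
    lr = lr + config.dye_bias_amplitude * x
    lr = lr + rng.normal(0.0, config.array_median_offset_sd, size=(1, lr.shape[1]))

    signals = pd.DataFrame(lr, index=probe_ids, columns=test_cols)
    intensity_df = pd.DataFrame(intensity, index=probe_ids, columns=test_cols)

    # reference channel rendered once per test array: same pooled sample, so
    # only technical noise varies across arrays
    ref_log = np.log2(1.0 - m_ref + config.eps)[island_idx]
    ref_signals = pd.DataFrame(
        ref_log[:, None] + rng.normal(0.0, config.technical_sd,
                                      size=(n_probes, len(test_cols))),
        index=probe_ids, columns=test_cols)

    # synthetic coordinates: islands tiled along one chromosome, probes 100 bp
    # apart inside their island; GC independent of everything else
    probe_rank = np.concatenate([np.arange(k) for k in npp])
    start = island_idx * 10_000 + probe_rank * 100
    gc = rng.uniform(0.40, 0.80, n_probes)
    annotation = pd.DataFrame({
        "chrom": "chrS",
        "start": start,
        "end": start + 60,
        "probe_id": probe_ids,
        "score": 0,
        "strand": "+",
        "island_id": island_ids[island_idx],
        "gc": gc,
    }).set_index("probe_id", drop=False)

    design = pd.DataFrame({
        "array_id": test_cols,
        "group": [epialleles.groups[c] for c in test_cols],
    })

    if truth is None:
        truth = pd.DataFrame(index=pd.Index(island_ids, name="locus_id"))
    return SyntheticDataset(signals=signals, intensity=intensity_df,
                            reference_signals=ref_signals, design=design,
                            annotation=annotation, truth=truth, config=config)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Convenience: simulate epialleles and render the probe-level dataset."""
    epi, truth = simulate_epialleles(config)
    return emit_dataset(epi, config, truth)


# ---------------------------------------------------------------------------
# serialization (all plain tab-delimited text)
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": outdir / "signals_raw.tsv",
        "intensity": outdir / "intensity.tsv",
        "reference_signals": outdir / "reference_signals.tsv",
        "design": outdir / "design.tsv",
        "annotation": outdir / "probes.bed",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.txt",
    }
    ds.signals.to_csv(paths["signals"], sep="\t", index_label="probe_id")
    ds.intensity.to_csv(paths["intensity"], sep="\t", index_label="probe_id")
    ds.reference_signals.to_csv(paths["reference_signals"], sep="\t",
                                index_label="probe_id")
    ds.design.to_csv(paths["design"], sep="\t", index=False)
    ds.annotation.to_csv(paths["annotation"], sep="\t", index=False, header=False)
    ds.truth.to_csv(paths["truth"], sep="\t")
    with open(paths["config"], "w") as fh:
        for f in dataclasses.fields(ds.config):
            fh.write(f"{f.name}: {getattr(ds.config, f.name)}\n")
    return paths


def synthetic_tracks(annotation: pd.DataFrame, seed: int = 0,
                     repeat_density: float = 1e-4):
    """Synthetic gene/repeat tracks for exercising the promoter comparison.

    One gene per island with its TSS 500 bp upstream of the island start and
    a random strand; repeat elements of the standard classes placed uniformly
    along the chromosome, independently of any variability label, so the
    promoter feature comparison has no real association to find.

    Returns ``(tss BED6 DataFrame, repeats BED4 DataFrame)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    islands = annotation.groupby("island_id").agg(
        chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
    strand = rng.choice(["+", "-"], len(islands))
    tss_pos = np.where(strand == "+",
                       np.maximum(islands["start"] - 500, 1000),
                       islands["end"] + 500)
    tss = pd.DataFrame({
        "chrom": islands["chrom"],
        "start": tss_pos,
        "end": tss_pos + 1,
        "gene_id": [f"gene_{i}" for i in islands.index],
        "score": 0,
        "strand": strand,
    }).reset_index(drop=True)

    classes = ("LINE", "SINE", "LTR", "Simple_repeat", "Low_complexity",
               "Microsatellite", "DNA")
    span = int(annotation["end"].max()) + 10_000
    n_rep = max(int(span * repeat_density), len(classes))
    starts = rng.integers(0, span, n_rep)
    lengths = rng.integers(100, 600, n_rep)
    repeats = pd.DataFrame({
        "chrom": annotation["chrom"].iloc[0],
        "start": starts,
        "end": starts + lengths,
        "repeat_class": rng.choice(classes, n_rep),
    }).sort_values("start").reset_index(drop=True)
    return tss, repeats


_BED_COLS = ["chrom", "start", "end", "probe_id", "score", "strand", "island_id", "gc"]


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS)
    return ann.set_index("probe_id", drop=False)


def read_config(path) -> SimulationConfig:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition(":")
        kv[key.strip()] = val.strip()
    kwargs = {}
    for f in dataclasses.fields(SimulationConfig):
        if f.name not in kv:
            warnings.warn(f"config missing field {f.name}; using default")
            continue
        raw = kv[f.name]
        if f.name in ("probes_per_island", "m_base_gain", "m_base_loss",
                      "m_base_invariant"):
            parts = raw.strip("()").split(",")
            conv = int if f.name == "probes_per_island" else float
            kwargs[f.name] = tuple(conv(p) for p in parts if p.strip())
        elif f.type in ("int", int):
            kwargs[f.name] = int(raw)
        else:
            kwargs[f.name] = float(raw)
    return SimulationConfig(**kwargs)


def read_dataset(indir) -> SyntheticDataset:
    indir = Path(indir)
    read = lambda name: pd.read_csv(indir / name, sep="\t", index_col="probe_id")
    return SyntheticDataset(
        signals=read("signals_raw.tsv"),
        intensity=read("intensity.tsv"),
        reference_signals=read("reference_signals.tsv"),
        design=pd.read_csv(indir / "design.tsv", sep="\t"),
        annotation=read_annotation(indir / "probes.bed"),
        truth=pd.read_csv(indir / "truth.tsv", sep="\t", index_col="locus_id"),
        config=read_config(indir / "sim_config.txt"),
    )
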