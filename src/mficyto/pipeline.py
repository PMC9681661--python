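"""Configuration-driven pipeline: simulate/read → preprocess → gate →
cluster → quantify → model, with a run manifest for provenance.

Stage order follows standard mass-cytometry processing: normalization before
gating, gating before clustering, clustering before quantification, and
composition tables before any model fit. Re-running with an identical config
reproduces identical output tables (the manifest records wall-clock stamps
and is the only non-deterministic artifact).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp
from . import trends
from .annotation import (
    ClusteringSpec,
    cluster_events,
    compute_cluster_profiles,
    metacluster,
)
from .events import ConfigurationError
from .gating import GateConfig, annotate, gate_audit, qc_leakage
from .io import write_delimited
from .preprocessing import arcsinh_transform, quantile_normalize, subsample_positions
from .synth import (
    BatchDistortion,
    StudyDesign,
    add_batch_effect,
    default_panel,
    default_populations,
    generate_study,
    inject_crossover,
    simulate_leakage_mouse,
    LINEAGE_MARKERS,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "preprocess", "gate", "cluster", "quantify", "model")

#: stage → stages it requires
_DEPENDENCIES = {
    "preprocess": ("simulate",),
    "gate": ("preprocess",),
    "cluster": ("gate",),
    "quantify": ("cluster",),
    "model": ("quantify",),
}


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (flat keys + per-stage sections)."""

    output_dir: str = "mficyto_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    # synthetic study
    events_per_sample: int = 1500
    mice_per_day: int = 2
    days: tuple[float, ...] = (10.5, 12.5, 14.5, 16.5, 18.5)
    batches: int = 1
    scenario: str = "default-gestation"
    # preprocessing
    cofactor: float = 5.0
    n_quantiles: int = 101
    # gating
    gate: dict = field(default_factory=dict)
    # clustering
    cluster_markers: tuple[str, ...] = LINEAGE_MARKERS
    n_neighbors: int = 20
    resolution: float = 1.0
    subsample_cap: int = 500
    metacluster_cut: float = 3.0
    # analysis toggles
    beta_diversity: bool = True
    discriminant: bool = True
    day_regression: bool = True
    trend_fits: bool = True

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        enabled = set(self.stages)
        for stage, needs in _DEPENDENCIES.items():
            if stage in enabled:
                missing = [n for n in needs if n not in enabled]
                if missing:
                    raise ConfigurationError(
                        f"stage {stage!r} requires {missing} to be enabled"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        for key in ("stages", "days", "cluster_markers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class StageRecord:
    name: str
    n_in: int
    n_out: int
    seconds: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    config_hash: str
    stages: list[StageRecord] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    defaults_echo: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "stages": [asdict(s) for s in self.stages],
                "outputs": self.outputs,
                "defaults": self.defaults_echo,
            },
            indent=2,
            default=str,
        )


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _scenario_inputs(config: PipelineConfig):
    """Resolve a named scenario into (design, populations)."""
    pops = default_populations()
    design_kw = dict(
        days=config.days,
        mice_per_day=config.mice_per_day,
        events_per_sample=config.events_per_sample,
        batches=config.batches,
        seed=config.seed,
    )
    if config.scenario == "default-gestation":
        return StudyDesign(**design_kw), pops
    if config.scenario == "crossover-at-14":
        pops = inject_crossover(pops, "MP", "neutrophil", 14.0, "EV",
                                day_range=(min(config.days), max(config.days)))
        return StudyDesign(**design_kw, crossover_day=14.0), pops
    if config.scenario == "perturbation":
        design_kw["treatment_arms"] = {
            "SAL": {},
            "PIC": {"MP": {"TIS": 0.5, "EV": 0.5}, "neutrophil": {"PB": 1.5}},
        }
        return StudyDesign(**design_kw), pops
    if config.scenario == "batch-distortion":
        design_kw["batches"] = max(2, config.batches)
        return StudyDesign(**design_kw), pops
    if config.scenario == "leakage-mouse":
        return StudyDesign(**design_kw), pops
    raise ConfigurationError(f"unknown scenario {config.scenario!r}")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and write every output table."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config),
                           defaults_echo=asdict(config))

    def record(name: str, n_in: int, n_out: int, t0: float, warnings=()) -> None:
        manifest.stages.append(
            StageRecord(name, n_in, n_out, round(time.time() - t0, 3),
                        list(warnings))
        )

    def write(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        manifest.outputs[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]

    # --- simulate -----------------------------------------------------------
    t0 = time.time()
    design, pops = _scenario_inputs(config)
    events, sample_meta, gt = generate_study(design, pops)
    leak_warnings: list[str] = []
    if config.scenario == "leakage-mouse":
        ln_events, ln_meta = simulate_leakage_mouse(design, 0.4, mouse="SAL_E10.5_m1")
        from .events import concat_events

        events = concat_events([events, ln_events])
        sample_meta = pd.concat([sample_meta, ln_meta], ignore_index=True)
    if config.scenario == "batch-distortion":
        distortions = {
            b: BatchDistortion(scale=1.0 + 0.15 * b, offset=0.25 * b)
            for b in range(design.batches)
        }
        events = add_batch_effect(events, distortions)
    record("simulate", 0, events.n_events, t0)

    # --- preprocess ---------------------------------------------------------
    t0 = time.time()
    events = arcsinh_transform(events, cofactor=config.cofactor)
    if design.batches > 1:
        anchors = {
            int(row["batch"]): row["sample_id"]
            for _, row in sample_meta[sample_meta["anchor"]].iterrows()
        }
        events, qmap = quantile_normalize(events, anchors, config.n_quantiles)
        write("quantile_map.csv", qmap.to_frame())
    record("preprocess", events.n_events, events.n_events, t0)

    # --- gate ----------------------------------------------------------------
    t0 = time.time()
    gate_config = GateConfig(**config.gate)
    ann = annotate(events, gate_config)
    leaky_mice: set[str] = set()
    if (events.meta["organ"] == "LN").any():
        for res in qc_leakage(ann, events, gate_config):
            if not res.passed:
                leaky_mice.add(res.mouse)
                leak_warnings.append(f"mouse {res.mouse} excluded: leakage "
                                     f"{res.fraction_above:.3f}")
    write("gate_audit.csv", gate_audit(ann))
    keep = ann["viable"] & (ann["origin"] == "maternal") & ~ann["mouse"].isin(leaky_mice)
    keep &= events.meta["organ"].isin(["PB", "placenta"]).to_numpy()
    gated = events.select(keep.to_numpy())
    gated_ann = ann.loc[keep.to_numpy()].reset_index(drop=True)
    gt_gated = gt.events.loc[keep.to_numpy()].reset_index(drop=True) \
        if len(gt.events) == len(ann) else None
    record("gate", events.n_events, gated.n_events, t0, leak_warnings)

    # --- cluster --------------------------------------------------------------
    t0 = time.time()
    sub_pos = subsample_positions(gated.meta, config.subsample_cap,
                                  ("mouse", "organ"), seed=config.seed)
    sub = gated.select(sub_pos)
    spec = ClusteringSpec(
        markers=tuple(m for m in config.cluster_markers if m in gated.data.columns),
        n_neighbors=config.n_neighbors,
        resolution=config.resolution,
        seed=config.seed,
    )
    labels = cluster_events(sub, spec)
    profiles = compute_cluster_profiles(sub, labels, markers=list(spec.markers))
    mc_map = metacluster(profiles, cut_height=config.metacluster_cut)
    meta_labels = mc_map.apply(labels)
    # name metaclusters by majority ground-truth population when available
    if gt_gated is not None:
        truth_sub = gt_gated["population"].to_numpy()[sub_pos]
        renames = {}
        for mc in pd.unique(meta_labels):
            if mc == "excluded":
                continue
            majority = pd.Series(truth_sub[meta_labels == mc]).mode().iloc[0]
            renames[mc] = majority
        meta_labels = np.array([renames.get(m, m) for m in meta_labels], dtype=object)
    write("metacluster_rules.csv", mc_map.to_frame())
    record("cluster", sub.n_events, int((meta_labels != "excluded").sum()), t0)

    # --- quantify ---------------------------------------------------------------
    t0 = time.time()
    cells = sub.meta.copy()
    cells["cell_type"] = meta_labels
    cells["compartment"] = gated_ann["compartment"].to_numpy()[sub_pos]
    cells = cells[cells["cell_type"] != "excluded"]
    fractions = comp.cell_fractions(
        cells, grouping=("mouse", "day", "compartment", "treatment"),
    )
    write("composition.csv", fractions)
    record("quantify", len(cells), len(fractions), t0)

    # --- model --------------------------------------------------------------------
    t0 = time.time()
    n_model_rows = 0
    wide = comp.fraction_matrix(fractions, index=("mouse", "day", "compartment"))
    comp_of_row = wide.index.get_level_values("compartment")
    if config.beta_diversity:
        rows = []
        mice = wide.index.get_level_values("mouse")
        for pair in (("EV", "TIS"), ("EV", "PB"), ("PB", "TIS")):
            pairs = comp.pairwise_dissimilarity(
                wide, pd.Series(comp_of_row, index=wide.index), pair,
                within=pd.Series(mice, index=wide.index),
            )
            pairs["pair"] = f"{pair[0]}-{pair[1]}"
            rows.append(pairs)
        beta = pd.concat(rows, ignore_index=True)
        beta["a"] = beta["a"].astype(str)
        beta["b"] = beta["b"].astype(str)
        write("dissimilarity.csv", beta)
        n_model_rows += len(beta)
    if config.discriminant:
        model = comp.lda_fit(wide, pd.Series(comp_of_row, index=wide.index))
        write("lda_coefficients.csv", model.coefficients_frame().reset_index(
            names="cell_type"))
        n_model_rows += len(model.coefficients_frame())
    if config.day_regression:
        rows = []
        for compartment in ("PB", "EV", "TIS"):
            sel = wide[comp_of_row == compartment]
            days = sel.index.get_level_values("day").to_numpy(dtype=float)
            for window in ("all", "early", "late"):
                try:
                    res = trends.fit_day_regression(sel, days, window=window,
                                                    seed=config.seed)
                except ConfigurationError:
                    continue
                rows.append(
                    {"compartment": compartment, "window": window,
                     "training_r2": res.training_r2, "cv_r2_mean": res.cv_r2_mean,
                     "n": res.n_samples}
                )
        write("day_regression.csv", pd.DataFrame(rows))
        n_model_rows += len(rows)
    if config.trend_fits:
        rows = []
        for cell_type in ("MP", "neutrophil"):
            if cell_type not in wide.columns:
                continue
            fit = trends.robust_trend_fit(
                wide[cell_type].to_numpy(),
                wide.index.get_level_values("day").to_numpy(dtype=float),
                np.asarray(comp_of_row, dtype=object),
            )
            tab = fit.table.copy()
            tab.insert(0, "response", cell_type)
            rows.append(tab)
        if rows:
            write("trend_fits.csv", pd.concat(rows, ignore_index=True))
            n_model_rows += sum(len(r) for r in rows)
    record("model", len(wide), n_model_rows, t0)

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def make_fixtures(scenario_name: str, seed: int, outdir: str | Path) -> Path:
    """Write a small synthetic dataset with ground truth for a named scenario.

    Scenarios: default-gestation, crossover-at-14, perturbation,
    leakage-mouse, batch-distortion.
    """
    outdir = Path(outdir) / scenario_name
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(scenario=scenario_name, seed=seed,
                            events_per_sample=800, mice_per_day=2,
                            days=(10.5, 12.5, 14.5, 16.5, 18.5))
    design, pops = _scenario_inputs(config)
    events, sample_meta, gt = generate_study(design, pops)
    extra = {}
    if scenario_name == "leakage-mouse":
        ln_events, ln_meta = simulate_leakage_mouse(design, 0.4, mouse="SAL_E10.5_m1")
        from .events import concat_events

        events = concat_events([events, ln_events])
        sample_meta = pd.concat([sample_meta, ln_meta], ignore_index=True)
        pad = pd.DataFrame(
            {"population": "unknown", "origin": "maternal", "compartment": "n/a",
             "viable": True, "sample_id": ln_meta["sample_id"].iloc[0],
             "batch": 0, "treatment": "SAL"},
            index=range(ln_events.n_events),
        )
        gt.events = pd.concat([gt.events, pad], ignore_index=True)
        extra["leaky_mice"] = ["SAL_E10.5_m1"]
    if scenario_name == "batch-distortion":
        distortions = {
            b: BatchDistortion(scale=1.0 + 0.15 * b, offset=0.25 * b)
            for b in range(design.batches)
        }
        events = add_batch_effect(events, distortions)
        extra["distortions"] = {
            b: {"scale": d.scale, "offset": d.offset} for b, d in distortions.items()
        }
    write_delimited(outdir / "events.csv", events, labels=gt.events[
        ["population", "origin", "compartment", "viable"]])
    sample_meta.to_csv(outdir / "samples.csv", index=False)
    gt.fractions.to_csv(outdir / "fractions.csv", index=False)
    info = {
        "scenario": scenario_name,
        "seed": seed,
        "crossover_day": gt.crossover_day,
        "multipliers": gt.multipliers,
        **extra,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(info, indent=2, default=str))
    return outdir
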