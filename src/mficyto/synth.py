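"""Synthetic CyTOF study generator with full ground truth.

Emulates a congenic-cross, injected-antibody mass-cytometry study of the
maternal-fetal interface: ~30-channel panels, CD45.1/CD45.2 channels
separating maternal from fetal leukocytes, an injected anti-CD45 channel
separating endovascular (EV) from tissue-resident (TIS) cells, lineage-defined
populations whose per-compartment abundances follow linear/quadratic
gestational trends (with a configurable mononuclear-phagocyte/neutrophil
cross-over day), batch-specific monotone intensity distortions anchored by a
shared splenocyte sample, and a perturbation arm that contracts or expands
named subsets.

Marker intensities are Gaussian on the arcsinh(x/5) scale, inverse-transformed
to the raw scale and floored at zero. Per-sample population counts are
multinomial draws over the renormalized abundance model, so realized fractions
converge to the configured model as events grow.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import ConfigurationError, EventTable, concat_events

COFACTOR = 5.0
#: day offset used when evaluating abundance models (first day of the study)
DAY_REF = 10.5

ROLE_LINEAGE = "lineage"
ROLE_FUNCTION = "function"
ROLE_UTILITY = "gating-utility"

#: channels every panel must carry for gating
UTILITY_CHANNELS = ("DNA", "viability", "CD45.1", "CD45.2", "RO_CD45")

LINEAGE_MARKERS = (
    "Ly-6G", "CD11c", "TCRb", "F4/80", "CD3", "IgD", "IgM", "CD19", "CD8",
    "CD11b", "Ly-6C", "FceRI", "Siglec-F", "CD68", "CD49b", "CD4", "MHC-II",
)
FUNCTION_MARKERS = (
    "PD-L1", "CD62L", "CD40", "CD80", "CD86", "CD64", "IdU", "CD44", "c-Kit", "B220",
)

# archetype defaults on the arcsinh scale
_BACKGROUND_MEAN = 0.3
_BACKGROUND_SD = 0.3
_DEFAULT_SD = 0.35


@dataclass
class PanelSpec:
    """Ordered channel names with one role per channel."""

    markers: dict[str, str]

    def __post_init__(self) -> None:
        names = list(self.markers)
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate channel names in panel")
        missing = [c for c in UTILITY_CHANNELS if c not in self.markers]
        if missing:
            raise ConfigurationError(f"panel missing gating-utility channels: {missing}")
        bad = {r for r in self.markers.values()} - {ROLE_LINEAGE, ROLE_FUNCTION, ROLE_UTILITY}
        if bad:
            raise ConfigurationError(f"unknown channel roles: {sorted(bad)}")

    @property
    def channels(self) -> list[str]:
        return list(self.markers)

    def by_role(self, role: str) -> list[str]:
        return [m for m, r in self.markers.items() if r == role]


def default_panel(minimal: bool = False) -> PanelSpec:
    """The default ~30-channel panel (or a compact lineage-free variant)."""
    markers: dict[str, str] = {}
    if not minimal:
        for m in LINEAGE_MARKERS:
            markers[m] = ROLE_LINEAGE
        for m in FUNCTION_MARKERS:
            markers[m] = ROLE_FUNCTION
    for m in (*UTILITY_CHANNELS, "Ter119"):
        markers[m] = ROLE_UTILITY
    return PanelSpec(markers)


@dataclass
class AbundanceModel:
    """Per-compartment expected fraction: intercept + slope·t + quad·t²,
    with t = day − 10.5 (fraction units per embryonic day)."""

    intercept: float
    slope: float = 0.0
    quad: float = 0.0

    def __call__(self, day: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(day, dtype=float) - DAY_REF
        out = self.intercept + self.slope * t + self.quad * t * t
        return float(out) if out.ndim == 0 else out


@dataclass
class PopulationSpec:
    """One generative cell type: marker archetype plus abundance trends."""

    name: str
    origin: str  # "maternal" | "fetal"
    archetype: dict[str, tuple[float, float]]
    abundance: dict[str, AbundanceModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.origin not in ("maternal", "fetal"):
            raise ConfigurationError(f"origin must be maternal|fetal, got {self.origin!r}")
        for marker, (_, sd) in self.archetype.items():
            if sd <= 0:
                raise ConfigurationError(f"{self.name}/{marker}: sd must be > 0")

    def mean_sd(self, marker: str) -> tuple[float, float]:
        return self.archetype.get(marker, (_BACKGROUND_MEAN, _BACKGROUND_SD))


@dataclass
class BatchDistortion:
    """Strictly monotone per-batch distortion, affine on the arcsinh scale:
    y = scale·x + offset (optionally per-marker overrides)."""

    scale: float = 1.0
    offset: float = 0.0
    per_marker: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scales = [self.scale] + [s for s, _ in self.per_marker.values()]
        if any(s <= 0 for s in scales):
            raise ConfigurationError("distortion must be strictly monotone (scale > 0)")

    def params_for(self, marker: str) -> tuple[float, float]:
        return self.per_marker.get(marker, (self.scale, self.offset))


@dataclass
class StudyDesign:
    """Experimental design of a synthetic study."""

    days: tuple[float, ...] = (10.5, 11.5, 12.5, 13.5, 14.5, 15.5, 16.5, 17.5, 18.5)
    mice_per_day: int = 3
    compartments: tuple[str, ...] = ("PB", "EV", "TIS")
    events_per_sample: int = 2000
    treatment_arms: dict[str, dict] = field(default_factory=lambda: {"SAL": {}})
    batches: int = 1
    seed: int = 0
    dead_fraction: float = 0.02
    mouse_sd: float = 0.15
    anchor_events: int = 1000
    crossover_day: float | None = None

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        if any(b >= a for a, b in zip(days[1:], days)):
            raise ConfigurationError("days must be strictly increasing")
        if self.events_per_sample <= 0:
            raise ConfigurationError("events_per_sample must be > 0")
        if not 0 <= self.dead_fraction < 1:
            raise ConfigurationError("dead_fraction must lie in [0, 1)")
        if self.batches < 1:
            raise ConfigurationError("batches must be >= 1")
        self.days = days


def default_populations() -> list[PopulationSpec]:
    """Eight maternal lineages plus two rare fetal populations.

    Compartment abundances mirror the field's expectations for the pregnant
    mouse: MPs dominate the endovascular space and decline with day while
    neutrophils rise (their trajectories cross mid-gestation), T and B cells
    dominate blood, and neutrophils are tissue-enriched. Fetal cells appear
    only at the maternal-fetal interface and ramp from ~0.1% to ~0.8%.
    """
    A = AbundanceModel

    def arch(**kw: float) -> dict[str, tuple[float, float]]:
        return {m: (v, _DEFAULT_SD) for m, v in kw.items()}

    pops = [
        PopulationSpec(
            "B", "maternal",
            arch(CD19=4.5, IgD=4.0, IgM=3.5, B220=4.5, **{"MHC-II": 4.0}),
            {"PB": A(0.25), "EV": A(0.10), "TIS": A(0.08)},
        ),
        PopulationSpec(
            "CD4 T", "maternal", arch(CD3=4.5, TCRb=4.5, CD4=4.5),
            {"PB": A(0.15), "EV": A(0.06), "TIS": A(0.05)},
        ),
        PopulationSpec(
            "CD8 T", "maternal", arch(CD3=4.5, TCRb=4.5, CD8=4.5),
            {"PB": A(0.10), "EV": A(0.05), "TIS": A(0.04)},
        ),
        PopulationSpec(
            "NK", "maternal", arch(CD49b=4.5, CD11b=3.0),
            {"PB": A(0.05), "EV": A(0.06), "TIS": A(0.07)},
        ),
        PopulationSpec(
            "neutrophil", "maternal",
            arch(**{"Ly-6G": 5.0, "CD11b": 4.5, "Ly-6C": 3.0, "CD44": 3.5}),
            {"PB": A(0.25), "EV": A(0.15, 0.030), "TIS": A(0.35, 0.010)},
        ),
        PopulationSpec(
            "MP", "maternal",
            arch(
                CD11b=4.5, CD68=3.5, CD64=3.0, CD11c=3.0,
                **{"Ly-6C": 4.5, "F4/80": 3.5, "MHC-II": 3.5, "PD-L1": 2.0},
            ),
            {"PB": A(0.12), "EV": A(0.45, -0.030), "TIS": A(0.30, -0.010)},
        ),
        PopulationSpec(
            "eosinophil", "maternal",
            arch(**{"Siglec-F": 4.5, "CD11b": 4.0}),
            {"PB": A(0.05), "EV": A(0.09), "TIS": A(0.07)},
        ),
        PopulationSpec(
            "basophil", "maternal", arch(FceRI=4.0, CD49b=3.0),
            {"PB": A(0.03), "EV": A(0.04), "TIS": A(0.04)},
        ),
        PopulationSpec(
            "fetal MP", "fetal",
            arch(
                CD11b=4.5, CD68=3.5, CD64=3.0,
                **{"Ly-6C": 4.0, "F4/80": 3.5, "MHC-II": 3.0},
            ),
            {"EV": A(4e-4, 4e-4), "TIS": A(4e-4, 4e-4)},
        ),
        PopulationSpec(
            "fetal neutrophil", "fetal",
            arch(**{"Ly-6G": 5.0, "CD11b": 4.5}),
            {"EV": A(2e-4, 2e-4), "TIS": A(2e-4, 2e-4)},
        ),
    ]
    return pops


def strong_early_populations() -> list[PopulationSpec]:
    """Default populations with steep early / flat late endovascular trends.

    MP and neutrophil trajectories in EV follow quadratics whose vertex sits
    at the last study day, so composition changes fast in early gestation
    (E10.5-E13.5) and flattens toward term — the regime in which embryonic
    day is predictable from early but not late composition.
    """
    pops = default_populations()
    by_name = {p.name: p for p in pops}
    # slope -0.05/day at E10.5 decaying linearly to 0 at E18.5 (vertex t = 8)
    by_name["MP"].abundance["EV"] = AbundanceModel(0.45, -0.05, 0.05 / 16)
    by_name["neutrophil"].abundance["EV"] = AbundanceModel(0.15, 0.05, -0.05 / 16)
    return pops


@dataclass
class GroundTruth:
    """Per-event generating labels plus study-level bookkeeping."""

    events: pd.DataFrame  # population, origin, compartment, viable, batch, treatment
    fractions: pd.DataFrame  # realized per-sample live-cell fractions
    crossover_day: float | None = None
    multipliers: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# abundance helpers


def expected_fractions(
    populations: list[PopulationSpec],
    day: float,
    compartment: str,
    multipliers: dict[str, float | dict[str, float]] | None = None,
) -> pd.Series:
    """Renormalized expected fractions at one (day, compartment).

    Abundance values are clipped at zero before renormalization; a
    configuration in which every population clips to zero is an error.
    """
    raw = {}
    for pop in populations:
        model = pop.abundance.get(compartment)
        if model is None:
            continue
        v = max(0.0, float(model(day)))
        if multipliers and pop.name in multipliers:
            m = multipliers[pop.name]
            if isinstance(m, dict):
                m = m.get(compartment, 1.0)
            v *= float(m)
        raw[pop.name] = v
    total = sum(raw.values())
    if total <= 0:
        raise ConfigurationError(
            f"all expected fractions non-positive at day {day} in {compartment}"
        )
    return pd.Series({k: v / total for k, v in raw.items()}, name="fraction")


def inject_crossover(
    populations: list[PopulationSpec],
    cell_a: str,
    cell_b: str,
    day_star: float,
    compartment: str = "EV",
    day_range: tuple[float, float] = (10.5, 18.5),
) -> list[PopulationSpec]:
    """Force ``cell_a`` to decrease and ``cell_b`` to increase linearly in one
    compartment so their (pre-normalization) abundances are equal exactly at
    ``day_star``. Other populations keep their models and are renormalized at
    generation time.
    """
    lo, hi = day_range
    if not lo <= day_star <= hi:
        raise ConfigurationError(f"day_star {day_star} outside day range {day_range}")
    pops = copy.deepcopy(populations)
    by_name = {p.name: p for p in pops}
    for cell in (cell_a, cell_b):
        if cell not in by_name:
            raise ConfigurationError(f"unknown population {cell!r}")
    ma = by_name[cell_a].abundance.get(compartment)
    mb = by_name[cell_b].abundance.get(compartment)
    if ma is None or mb is None:
        raise ConfigurationError(f"{cell_a}/{cell_b} have no abundance in {compartment}")
    level = 0.5 * (max(0.0, ma(day_star)) + max(0.0, mb(day_star)))
    span = max(day_star - lo, hi - day_star)
    delta = 0.8 * level / span  # keeps both trajectories positive on the range
    t_star = day_star - DAY_REF
    by_name[cell_a].abundance[compartment] = AbundanceModel(level + delta * t_star, -delta)
    by_name[cell_b].abundance[compartment] = AbundanceModel(level - delta * t_star, delta)
    return pops


def inject_perturbation(
    populations: list[PopulationSpec],
    arm_effects: dict[str, float | dict[str, float]],
) -> list[PopulationSpec]:
    """Scale named populations' abundance models by positive multipliers
    (per compartment when a dict is given), for use as a treated arm."""
    pops = copy.deepcopy(populations)
    by_name = {p.name: p for p in pops}
    for name, effect in arm_effects.items():
        if name not in by_name:
            raise ConfigurationError(f"unknown population {name!r} in arm effects")
        comp_mult = (
            effect if isinstance(effect, dict)
            else {c: effect for c in by_name[name].abundance}
        )
        for comp, mult in comp_mult.items():
            if mult <= 0:
                raise ConfigurationError(f"multiplier for {name}/{comp} must be > 0")
            model = by_name[name].abundance.get(comp)
            if model is None:
                continue
            by_name[name].abundance[comp] = AbundanceModel(
                model.intercept * mult, model.slope * mult, model.quad * mult
            )
    return pops


# ---------------------------------------------------------------------------
# event synthesis


def _asinh_to_raw(v: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, COFACTOR * np.sinh(v))


def _draw_events(
    rng: np.random.Generator,
    pop: PopulationSpec,
    n: int,
    panel: PanelSpec,
    compartment: str,
    dead: np.ndarray | None = None,
) -> np.ndarray:
    """Draw n events for one population, on the arcsinh scale."""
    channels = panel.channels
    out = np.empty((n, len(channels)))
    for j, ch in enumerate(channels):
        if ch == "DNA":
            mean, sd = 5.5, 0.3
        elif ch == "viability":
            mean, sd = 0.5, 0.3
        elif ch == "Ter119":
            mean, sd = 0.3, 0.3
        elif ch == "CD45.2":
            mean, sd = 5.0, 0.35
        elif ch == "CD45.1":
            mean, sd = (4.5, 0.35) if pop.origin == "fetal" else (0.3, 0.3)
        elif ch == "RO_CD45":
            mean, sd = (6.0, 0.5) if compartment in ("PB", "EV") else (0.5, 0.5)
        else:
            mean, sd = pop.mean_sd(ch)
        out[:, j] = rng.normal(mean, sd, size=n)
    if dead is not None and dead.any():
        j = channels.index("viability")
        out[dead, j] = rng.normal(4.0, 0.5, size=int(dead.sum()))
    return out


def _splenocyte_mix(populations: list[PopulationSpec]) -> pd.Series:
    """Fixed anchor-material composition (common across batches)."""
    maternal = [p.name for p in populations if p.origin == "maternal"]
    return pd.Series(1.0 / len(maternal), index=maternal)


def generate_study(
    design: StudyDesign,
    populations: list[PopulationSpec] | None = None,
    panel: PanelSpec | None = None,
) -> tuple[EventTable, pd.DataFrame, GroundTruth]:
    """Generate a full multi-sample study with ground truth.

    For every (arm, day, mouse, compartment) sample, population counts are
    multinomial over the renormalized abundance model (with per-mouse
    log-normal intercept noise), and per-event marker values are Gaussian on
    the arcsinh scale, inverse-transformed to raw counts. One anchor
    (splenocyte) sample per batch is appended when ``design.batches > 1``.
    Identical (design, populations, seed) give identical output.
    """
    populations = default_populations() if populations is None else populations
    panel = default_panel() if panel is None else panel
    _check_degenerate_days(design, populations)

    rng = np.random.default_rng(int(design.seed))
    by_name = {p.name: p for p in populations}
    tables, metas, truths, frac_rows = [], [], [], []
    multipliers_used: dict[str, dict] = {}
    mouse_counter = 0

    for arm, effects in design.treatment_arms.items():
        arm_pops = inject_perturbation(populations, effects) if effects else populations
        multipliers_used[arm] = dict(effects)
        for day in design.days:
            for m in range(design.mice_per_day):
                mouse = f"{arm}_E{day}_m{m + 1}"
                batch = mouse_counter % design.batches
                mouse_counter += 1
                # per-mouse log-normal intercepts, shared across compartments
                eps = {
                    p.name: float(np.exp(rng.normal(0.0, design.mouse_sd)))
                    for p in arm_pops
                }
                for comp in design.compartments:
                    fr = expected_fractions(arm_pops, day, comp)
                    fr = fr * pd.Series({k: eps[k] for k in fr.index})
                    fr = fr / fr.sum()
                    counts = rng.multinomial(design.events_per_sample, fr.to_numpy())
                    sample_id = f"{mouse}_{comp}"
                    organ = "PB" if comp == "PB" else "placenta"
                    blocks, labels = [], []
                    for name, n in zip(fr.index, counts):
                        if n == 0:
                            continue
                        pop = by_name[name]
                        dead = rng.random(n) < design.dead_fraction
                        blocks.append(_draw_events(rng, pop, n, panel, comp, dead))
                        lab = pd.DataFrame(
                            {
                                "population": name,
                                "origin": pop.origin,
                                "compartment": comp,
                                "viable": ~dead,
                            }
                        )
                        labels.append(lab)
                    values = _asinh_to_raw(np.vstack(blocks))
                    truth = pd.concat(labels, ignore_index=True)
                    truth["sample_id"] = sample_id
                    truth["batch"] = batch
                    truth["treatment"] = arm
                    meta = pd.DataFrame(
                        {
                            "sample_id": sample_id,
                            "mouse": mouse,
                            "day": day,
                            "organ": organ,
                            "batch": batch,
                            "treatment": arm,
                        },
                        index=range(len(truth)),
                    )
                    tables.append(
                        EventTable(pd.DataFrame(values, columns=panel.channels), meta)
                    )
                    truths.append(truth)
                    for name, n in zip(fr.index, counts):
                        frac_rows.append(
                            {
                                "sample_id": sample_id,
                                "mouse": mouse,
                                "day": day,
                                "compartment": comp,
                                "treatment": arm,
                                "population": name,
                                "count": int(n),
                                "fraction": n / design.events_per_sample,
                            }
                        )

    anchor_rows = []
    if design.batches > 1:
        mix = _splenocyte_mix(populations)
        counts = rng.multinomial(design.anchor_events, mix.to_numpy())
        blocks, labels = [], []
        for name, n in zip(mix.index, counts):
            if n == 0:
                continue
            blocks.append(_draw_events(rng, by_name[name], n, panel, "PB"))
            labels.extend([name] * n)
        anchor_values = _asinh_to_raw(np.vstack(blocks))
        for b in range(design.batches):
            sample_id = f"anchor_b{b}"
            meta = pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "mouse": f"anchor_b{b}",
                    "day": np.nan,
                    "organ": "spleen",
                    "batch": b,
                    "treatment": "anchor",
                },
                index=range(len(labels)),
            )
            tables.append(
                EventTable(pd.DataFrame(anchor_values.copy(), columns=panel.channels), meta)
            )
            truths.append(
                pd.DataFrame(
                    {
                        "population": labels,
                        "origin": "maternal",
                        "compartment": "n/a",
                        "viable": True,
                        "sample_id": sample_id,
                        "batch": b,
                        "treatment": "anchor",
                    }
                )
            )
            anchor_rows.append(sample_id)

    events = concat_events(tables)
    truth = pd.concat(truths, ignore_index=True)
    sample_meta = (
        events.meta.drop_duplicates("sample_id").reset_index(drop=True).copy()
    )
    sample_meta["anchor"] = sample_meta["sample_id"].isin(anchor_rows)
    fractions = pd.DataFrame(frac_rows)
    gt = GroundTruth(
        events=truth,
        fractions=fractions,
        crossover_day=design.crossover_day,
        multipliers=multipliers_used,
    )
    return events, sample_meta, gt


def _check_degenerate_days(design: StudyDesign, populations: list[PopulationSpec]) -> None:
    if len(design.days) > 1:
        return
    for pop in populations:
        for comp, model in pop.abundance.items():
            if comp in design.compartments and (model.slope != 0 or model.quad != 0):
                raise ConfigurationError(
                    f"single-day design cannot identify the day trend of "
                    f"{pop.name!r} in {comp}"
                )


def add_batch_effect(
    events: EventTable, batch_params: dict[int, BatchDistortion]
) -> EventTable:
    """Apply per-batch strictly monotone distortions (affine on arcsinh scale).

    All events of a batch — anchor samples included — receive the same map,
    so anchor-based normalization can recover the reference scale.
    """
    if events.transformed:
        raise ConfigurationError("batch effects are applied to raw-scale events")
    out = events.copy()
    values = out.data.to_numpy()
    batches = out.meta["batch"].to_numpy()
    for b, dist in batch_params.items():
        mask = batches == b
        if not mask.any():
            continue
        block = np.arcsinh(values[mask] / COFACTOR)
        for j, marker in enumerate(out.data.columns):
            a, c = dist.params_for(marker)
            block[:, j] = a * block[:, j] + c
        values[mask] = _asinh_to_raw(block)
    out.data = pd.DataFrame(values, columns=out.data.columns)
    return out


def simulate_leakage_mouse(
    design: StudyDesign,
    fraction_leaked: float,
    mouse: str = "leaky_m1",
    n_events: int = 2000,
    populations: list[PopulationSpec] | None = None,
    panel: PanelSpec | None = None,
) -> tuple[EventTable, pd.DataFrame]:
    """A lymph-node control sample in which ``fraction_leaked`` of events carry
    injected-CD45 above the endovascular threshold (antibody leakage)."""
    if not 0 <= fraction_leaked <= 1:
        raise ConfigurationError("fraction_leaked must lie in [0, 1]")
    populations = default_populations() if populations is None else populations
    panel = default_panel() if panel is None else panel
    rng = np.random.default_rng(int(design.seed) + 10_007)
    mix = _splenocyte_mix(populations)
    by_name = {p.name: p for p in populations}
    counts = rng.multinomial(n_events, mix.to_numpy())
    blocks = []
    for name, n in zip(mix.index, counts):
        if n == 0:
            continue
        blocks.append(_draw_events(rng, by_name[name], n, panel, "TIS"))
    block = np.vstack(blocks)
    leaked = rng.random(n_events) < fraction_leaked
    j = panel.channels.index("RO_CD45")
    block[leaked, j] = rng.normal(6.0, 0.5, size=int(leaked.sum()))
    block[~leaked, j] = np.abs(rng.normal(0.2, 0.15, size=int((~leaked).sum())))
    values = _asinh_to_raw(block)
    sample_id = f"{mouse}_LN"
    meta = pd.DataFrame(
        {
            "sample_id": sample_id,
            "mouse": mouse,
            "day": design.days[0],
            "organ": "LN",
            "batch": 0,
            "treatment": "SAL",
        },
        index=range(n_events),
    )
    table = EventTable(pd.DataFrame(values, columns=panel.channels), meta)
    sample_meta = meta.drop_duplicates("sample_id").reset_index(drop=True).copy()
    sample_meta["anchor"] = False
    return table, sample_meta
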