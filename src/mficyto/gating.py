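"""Rule-based gating: viability, maternal/fetal origin, endovascular vs.
tissue compartment, and injected-antibody leakage QC.

All gates are pure functions of arcsinh-scale intensities and a
:class:`GateConfig`. The compartment rule applies the per-event injected
anti-CD45 intensity against a fixed threshold of 3.5 (arcsinh, cofactor 5):
values at or above the threshold are endovascular (EV), below are tissue
(TIS); peripheral-blood samples are labeled PB regardless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import ConfigurationError, EventTable

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
FETAL = "fetal"
OTHER = "other"


@dataclass
class GateConfig:
    """Channel bindings and thresholds (arcsinh scale, cofactor 5)."""

    dna_channel: str = "DNA"
    viability_channel: str = "viability"
    ter119_channel: str = "Ter119"
    cd45_2_channel: str = "CD45.2"
    cd45_1_channel: str = "CD45.1"
    injected_channel: str = "RO_CD45"

    dna_threshold: float = 3.0
    viability_threshold: float = 2.0  # cisplatin: below = live
    ter119_threshold: float = 2.0
    cd45_2_threshold: float = 2.5
    cd45_1_threshold: float = 2.0
    ev_threshold: float = 3.5
    leakage_threshold: float = 0.05

    auto_thresholds: tuple[str, ...] = field(default_factory=tuple)
    placental_organs: tuple[str, ...] = ("placenta",)

    def __post_init__(self) -> None:
        if self.ev_threshold <= 0:
            raise ConfigurationError("EV threshold must be > 0")

    def bound_channels(self) -> dict[str, str]:
        return {
            "dna": self.dna_channel,
            "viability": self.viability_channel,
            "ter119": self.ter119_channel,
            "cd45_2": self.cd45_2_channel,
            "cd45_1": self.cd45_1_channel,
            "injected": self.injected_channel,
        }


def _require_transformed(events: EventTable) -> None:
    if not events.transformed:
        raise ConfigurationError("gating operates on arcsinh-transformed events")


def _require_channels(events: EventTable, names: list[str]) -> None:
    missing = [c for c in names if c not in events.data.columns]
    if missing:
        raise ConfigurationError(f"events missing bound channels: {missing}")


def fit_valley_threshold(values: np.ndarray, default: float, seed: int = 0) -> float:
    """Threshold at the valley between two fitted 1-D Gaussian components.

    Falls back to ``default`` (with a warning) when the channel looks
    unimodal, i.e. the fitted component means are closer than the pooled sd.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=2).fit(v)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(means)
    if means[hi] - means[lo] < (sds[lo] + sds[hi]):
        logger.warning(
            "auto threshold: channel looks unimodal, falling back to %.3g", default
        )
        return default
    grid = np.linspace(means[lo], means[hi], 512)
    dens = np.exp(gm.score_samples(grid.reshape(-1, 1)))
    return float(grid[np.argmin(dens)])


def resolve_auto_thresholds(events: EventTable, config: GateConfig, seed: int = 0) -> GateConfig:
    """Replace thresholds listed in ``config.auto_thresholds`` with mixture fits."""
    updates = {}
    channel_of = {
        "dna": (config.dna_channel, "dna_threshold"),
        "viability": (config.viability_channel, "viability_threshold"),
        "ter119": (config.ter119_channel, "ter119_threshold"),
        "cd45_2": (config.cd45_2_channel, "cd45_2_threshold"),
        "cd45_1": (config.cd45_1_channel, "cd45_1_threshold"),
    }
    for gate in config.auto_thresholds:
        if gate not in channel_of:
            raise ConfigurationError(f"unknown auto-threshold gate {gate!r}")
        channel, attr = channel_of[gate]
        updates[attr] = fit_valley_threshold(
            events.data[channel].to_numpy(), getattr(config, attr), seed=seed
        )
    return replace(config, **updates) if updates else config


def gate_viable(events: EventTable, config: GateConfig) -> pd.Series:
    """Viable = DNA-high AND cisplatin-low AND Ter119-low (erythrocytes out)."""
    _require_transformed(events)
    _require_channels(
        events, [config.dna_channel, config.viability_channel, config.ter119_channel]
    )
    viable = (
        (events.data[config.dna_channel] >= config.dna_threshold)
        & (events.data[config.viability_channel] < config.viability_threshold)
        & (events.data[config.ter119_channel] < config.ter119_threshold)
    )
    return viable.rename("viable")


def assign_origin(events: EventTable, config: GateConfig) -> pd.Series:
    """CD45.2+ single-positive → maternal; CD45.2+CD45.1+ → fetal; else other."""
    _require_transformed(events)
    _require_channels(events, [config.cd45_2_channel, config.cd45_1_channel])
    cd45_2 = events.data[config.cd45_2_channel] >= config.cd45_2_threshold
    cd45_1 = events.data[config.cd45_1_channel] >= config.cd45_1_threshold
    origin = np.where(cd45_2 & ~cd45_1, MATERNAL, np.where(cd45_2 & cd45_1, FETAL, OTHER))
    return pd.Series(origin, index=events.data.index, name="origin")


def assign_compartment(
    events: EventTable, config: GateConfig, origin: pd.Series | None = None
) -> pd.Series:
    """Injected-channel intensity ≥ EV threshold ⇒ EV, < ⇒ TIS (placental
    samples); PB samples are PB regardless. The threshold is boundary
    inclusive. Fetal events are never assigned EV/TIS by this rule
    (returned as "n/a")."""
    _require_transformed(events)
    _require_channels(events, [config.injected_channel])
    organ = events.meta["organ"].astype(str).to_numpy()
    injected = events.data[config.injected_channel].to_numpy()
    comp = np.full(len(injected), "n/a", dtype=object)
    comp[organ == "PB"] = "PB"
    placental = np.isin(organ, config.placental_organs)
    comp[placental & (injected >= config.ev_threshold)] = "EV"
    comp[placental & (injected < config.ev_threshold)] = "TIS"
    if origin is not None:
        comp[placental & (origin.to_numpy() == FETAL)] = "n/a"
    return pd.Series(comp, index=events.data.index, name="compartment")


def annotate(events: EventTable, config: GateConfig) -> pd.DataFrame:
    """Full gate hierarchy: viability → origin → compartment, as one table."""
    viable = gate_viable(events, config)
    origin = assign_origin(events, config)
    origin[~viable] = OTHER
    comp = assign_compartment(events, config, origin=origin)
    ann = pd.DataFrame({"viable": viable, "origin": origin, "compartment": comp})
    for col in ("sample_id", "mouse", "day", "organ", "batch", "treatment"):
        ann[col] = events.meta[col].to_numpy()
    return ann


@dataclass
class LeakageResult:
    mouse: str
    fraction_above: float
    threshold: float
    passed: bool
    warning: str | None = None


def qc_leakage(
    ln_annotation: pd.DataFrame,
    events: EventTable,
    config: GateConfig,
) -> list[LeakageResult]:
    """Flag mice whose lymph-node control shows injected-antibody leakage.

    A mouse fails when the fraction of viable LN immune events with injected
    intensity at or above the EV threshold exceeds ``leakage_threshold``.
    Mice without an LN sample pass with a warning.
    """
    _require_transformed(events)
    results = []
    injected = events.data[config.injected_channel].to_numpy()
    organ = events.meta["organ"].astype(str).to_numpy()
    mice = events.meta["mouse"].to_numpy()
    viable = ln_annotation["viable"].to_numpy()
    immune = ln_annotation["origin"].isin([MATERNAL, FETAL]).to_numpy()
    for mouse in pd.unique(mice):
        sel = (mice == mouse) & (organ == "LN") & viable & immune
        if not sel.any():
            results.append(
                LeakageResult(mouse, 0.0, config.leakage_threshold, True,
                              warning="no LN control sample")
            )
            continue
        frac = float((injected[sel] >= config.ev_threshold).mean())
        results.append(
            LeakageResult(mouse, frac, config.leakage_threshold,
                          passed=frac <= config.leakage_threshold)
        )
    return results


def gate_audit(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-sample counts through each gate (events in/out audit log)."""
    rows = []
    for sid, g in annotation.groupby("sample_id"):
        viable = g["viable"]
        rows.append(
            {
                "sample_id": sid,
                "events_in": len(g),
                "viable": int(viable.sum()),
                "maternal": int(((g["origin"] == MATERNAL) & viable).sum()),
                "fetal": int(((g["origin"] == FETAL) & viable).sum()),
                "ev": int((g["compartment"] == "EV").sum()),
                "tis": int((g["compartment"] == "TIS").sum()),
                "pb": int((g["compartment"] == "PB").sum()),
            }
        )
    return pd.DataFrame(rows)
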