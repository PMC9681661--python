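"""Preprocessing: arcsinh transform, anchor-based quantile normalization,
and capped per-group subsampling.

Normalization follows the anchor-sample design: every staining batch carries
one aliquot of a common material (splenocytes); for each batch and marker a
monotone map is built that sends the batch anchor's empirical quantiles onto
the reference batch anchor's quantiles and is then applied to all events of
that batch. The map is piecewise linear between quantile knots; beyond the
anchor's observed range the terminal linear segment is continued, which keeps
the map strictly increasing (rank-preserving) without extrapolation blow-ups.
Normalization operates on the arcsinh scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import ConfigurationError, EventTable

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0
DEFAULT_N_QUANTILES = 101


def arcsinh_transform(events: EventTable, cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Replace every intensity x by asinh(x / cofactor).

    Refuses to transform an already-transformed table.
    """
    if events.transformed:
        raise ConfigurationError("events are already arcsinh-transformed")
    if cofactor <= 0:
        raise ConfigurationError("cofactor must be positive")
    out = events.copy()
    out.data = pd.DataFrame(
        np.arcsinh(out.data.to_numpy() / cofactor), columns=out.data.columns
    )
    out.transformed = True
    out.cofactor = cofactor
    return out


def inverse_arcsinh(events: EventTable) -> EventTable:
    """Map a transformed table back to the raw scale (cofactor · sinh(y))."""
    if not events.transformed:
        raise ConfigurationError("events are not transformed")
    out = events.copy()
    out.data = pd.DataFrame(
        events.cofactor * np.sinh(out.data.to_numpy()), columns=out.data.columns
    )
    out.transformed = False
    out.cofactor = None
    return out


@dataclass
class QuantileMap:
    """Per-batch, per-marker monotone knot maps (source → reference quantiles)."""

    probs: np.ndarray
    knots: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)
    reference_batch: int | None = None

    def apply(self, values: np.ndarray, batch: int, marker: str) -> np.ndarray:
        src, ref = self.knots[batch][marker]
        return _interp_extrapolate(values, src, ref)

    def to_frame(self) -> pd.DataFrame:
        """Serialize knots to a tidy, human-readable table."""
        rows = []
        for batch, markers in self.knots.items():
            for marker, (src, ref) in markers.items():
                for p, s, r in zip(self.probs, src, ref):
                    rows.append(
                        {"batch": batch, "marker": marker, "prob": p,
                         "source": s, "reference": r}
                    )
        return pd.DataFrame(rows)


def _interp_extrapolate(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Piecewise-linear map through (xp, fp) with terminal-segment extrapolation."""
    xp, idx = np.unique(xp, return_index=True)
    fp = fp[idx]
    if len(xp) == 1:  # degenerate anchor marker: pure shift
        return x + (fp[0] - xp[0])
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + slope * (x[lo] - xp[0])
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return y


def quantile_normalize(
    events: EventTable,
    anchor_sample_ids: dict[int, str] | list[str],
    n_quantiles: int = DEFAULT_N_QUANTILES,
    reference_batch: int | None = None,
) -> tuple[EventTable, QuantileMap]:
    """Harmonize batches by mapping each batch anchor onto the reference anchor.

    Parameters
    ----------
    events:
        Transformed events covering all batches (anchors included).
    anchor_sample_ids:
        Mapping batch → anchor sample id (or a list, resolved via metadata).
    n_quantiles:
        Number of quantile knots (default 101, i.e. percentile grid).
    reference_batch:
        Batch whose anchor defines the target distribution (default: lowest
        batch id). Events of the reference batch pass through unchanged.
    """
    if not events.transformed:
        raise ConfigurationError("quantile normalization operates on transformed events")
    batches = events.meta["batch"].to_numpy()
    if isinstance(anchor_sample_ids, dict):
        anchors = {int(b): s for b, s in anchor_sample_ids.items()}
    else:
        anchors = {}
        for sid in anchor_sample_ids:
            b = events.meta.loc[events.meta["sample_id"] == sid, "batch"]
            if b.empty:
                raise ConfigurationError(f"anchor sample {sid!r} not found")
            anchors[int(b.iloc[0])] = sid
    present = sorted(set(int(b) for b in np.unique(batches)))
    missing = [b for b in present if b not in anchors]
    if missing:
        raise ConfigurationError(f"batches without an anchor sample: {missing}")
    if reference_batch is None:
        reference_batch = present[0]

    probs = np.linspace(0.0, 1.0, n_quantiles)
    sample_ids = events.meta["sample_id"].to_numpy()

    def anchor_values(batch: int) -> np.ndarray:
        mask = sample_ids == anchors[batch]
        if mask.sum() < n_quantiles:
            raise ConfigurationError(
                f"anchor for batch {batch} has {int(mask.sum())} events "
                f"(< n_quantiles={n_quantiles})"
            )
        return events.data.to_numpy()[mask]

    ref_vals = anchor_values(reference_batch)
    ref_q = np.quantile(ref_vals, probs, axis=0)

    qmap = QuantileMap(probs=probs, reference_batch=reference_batch)
    out = events.copy()
    values = out.data.to_numpy()
    for b in present:
        src_q = ref_q if b == reference_batch else np.quantile(anchor_values(b), probs, axis=0)
        qmap.knots[b] = {}
        mask = batches == b
        for j, marker in enumerate(out.data.columns):
            qmap.knots[b][marker] = (src_q[:, j].copy(), ref_q[:, j].copy())
            if b != reference_batch:
                values[mask, j] = _interp_extrapolate(
                    values[mask, j], src_q[:, j], ref_q[:, j]
                )
    out.data = pd.DataFrame(values, columns=out.data.columns)
    return out, qmap


def subsample_positions(
    meta: pd.DataFrame,
    per_group_cap: int,
    group_keys: tuple[str, ...] = ("mouse", "organ"),
    seed: int = 0,
) -> np.ndarray:
    """Positions of min(cap, n) events per group, uniform without replacement."""
    if per_group_cap < 1:
        raise ConfigurationError("per_group_cap must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    grouped = meta.groupby(list(group_keys), sort=True, dropna=False).indices
    for key in sorted(grouped, key=str):
        idx = np.sort(grouped[key])
        if len(idx) > per_group_cap:
            idx = np.sort(rng.choice(idx, size=per_group_cap, replace=False))
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def subsample_events(
    events: EventTable,
    per_group_cap: int,
    group_keys: tuple[str, ...] = ("mouse", "organ"),
    seed: int = 0,
) -> EventTable:
    """Retain min(cap, n) events per group, uniformly without replacement.

    Mirrors the "subsampling up to N cells per mouse organ" convention:
    groups at or under the cap are kept whole. Deterministic under ``seed``.
    """
    return events.select(
        subsample_positions(events.meta, per_group_cap, group_keys, seed)
    )
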