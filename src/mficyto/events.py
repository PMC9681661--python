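"""Core in-memory containers for mass-cytometry event data.

An :class:`EventTable` pairs a cells × channels intensity matrix with
row-aligned provenance (sample, mouse, embryonic day, organ, batch,
treatment) and records exactly once whether intensities are on the raw
or the arcsinh-transformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: provenance columns every event must carry
PROVENANCE_COLUMNS = ("sample_id", "mouse", "day", "organ", "batch", "treatment")

#: columns of a sample-metadata table
METADATA_COLUMNS = ("sample_id", "mouse", "day", "organ", "batch", "treatment", "anchor")


class MficytoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MficytoError):
    """Invalid configuration (design, panel, gate, or pipeline)."""


@dataclass
class EventTable:
    """Cells × channels intensities plus per-event provenance.

    Parameters
    ----------
    data:
        Float intensity matrix, one row per event, one column per channel.
    meta:
        Per-event provenance with at least :data:`PROVENANCE_COLUMNS`,
        index-aligned with ``data``.
    transformed:
        True when intensities are arcsinh-transformed.
    cofactor:
        Arcsinh cofactor used if ``transformed`` (None on raw scale).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    transformed: bool = False
    cofactor: float | None = None
    extra_channels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.meta):
            raise ConfigurationError(
                f"data has {len(self.data)} rows but meta has {len(self.meta)}"
            )
        missing = [c for c in PROVENANCE_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ConfigurationError(f"meta missing provenance columns: {missing}")
        if self.transformed and self.cofactor is None:
            raise ConfigurationError("transformed EventTable must record its cofactor")
        self.data = self.data.reset_index(drop=True)
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "EventTable":
        return EventTable(
            self.data.copy(),
            self.meta.copy(),
            transformed=self.transformed,
            cofactor=self.cofactor,
            extra_channels=self.extra_channels,
        )

    def select(self, mask: np.ndarray) -> "EventTable":
        """Row-subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        return EventTable(
            self.data.iloc[mask] if mask.dtype.kind in "iu" else self.data.loc[mask],
            self.meta.iloc[mask] if mask.dtype.kind in "iu" else self.meta.loc[mask],
            transformed=self.transformed,
            cofactor=self.cofactor,
            extra_channels=self.extra_channels,
        )


def concat_events(tables: list[EventTable]) -> EventTable:
    """Concatenate event tables with identical channels and transform state."""
    if not tables:
        raise ConfigurationError("nothing to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if t.transformed != first.transformed:
            raise ConfigurationError("cannot mix raw and transformed tables")
        if list(t.data.columns) != list(first.data.columns):
            raise ConfigurationError("channel panels differ between tables")
    return EventTable(
        pd.concat([t.data for t in tables], ignore_index=True),
        pd.concat([t.meta for t in tables], ignore_index=True),
        transformed=first.transformed,
        cofactor=first.cofactor,
        extra_channels=first.extra_channels,
    )


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table and return it with canonical columns."""
    meta = meta.copy()
    if "anchor" not in meta.columns:
        meta["anchor"] = False
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"sample metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ConfigurationError("duplicate sample ids in metadata")
    return meta
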