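"""Flow-cytometry event ingest: reading, noise gating and downsampling.

Events are kept on the raw instrument scale (arbitrary fluorescence units,
no logicle/asinh display transform); all downstream clustering operates on
these untransformed intensities.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel layout per staining panel: scatter, DNA dye, 4 markers
PANEL_CHANNELS: dict[str, list[str]] = {
    "immunoglobulin": ["FSC", "SSC", "DNA", "IgA1", "IgA2", "IgM", "IgG"],
    "lectin": ["FSC", "SSC", "DNA", "PNA", "WGA", "STL", "ConA"],
}
PANELS = tuple(PANEL_CHANNELS)
N_CHANNELS = 7


class SchemaError(ValueError):
    """A required channel or column is missing or mismatched."""


@dataclass
class EventTable:
    """Per-cell channel intensities for one sample and one staining panel."""

    sample_id: str
    panel: str
    channels: list[str]
    intensities: np.ndarray  # (n_events, n_channels), nonnegative reals

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != len(self.channels):
            raise SchemaError(
                f"channel count {len(self.channels)} does not match matrix "
                f"width {self.intensities.shape[1]}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise SchemaError(f"channel {name!r} not present") from None
        return self.intensities[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, columns=self.channels)


@dataclass
class GateConfig:
    """Noise/DNA gating and downsampling settings (thresholds in MFI units).

    Threshold comparisons are strict: an event is kept only if its value
    exceeds the threshold, so events exactly at the threshold are dropped.
    """

    scatter_min: float = 1.0
    dna_min: float = 10.0
    target_events: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scatter_min < 0 or self.dna_min < 0:
            raise ValueError("gate thresholds must be nonnegative")
        if self.target_events < 1:
            raise ValueError("target_events must be >= 1")


def read_events(
    path: str | Path,
    panel: str,
    channel_map: dict[str, str] | None = None,
) -> EventTable:
    """Read one sample's events from an FCS 3.0/3.1 or TSV file.

    ``channel_map`` maps file channel names to canonical names; after
    renaming, columns are re-ordered to the canonical panel layout. Values
    are passed through untransformed.
    """
    path = Path(path)
    if panel not in PANEL_CHANNELS:
        raise ValueError(f"unknown panel {panel!r}")
    if path.suffix.lower() == ".fcs":
        from .fcsio import read_fcs

        names, data = read_fcs(path)
    else:
        df = pd.read_csv(path, sep="\t")
        names, data = list(df.columns), df.to_numpy(dtype=float)
    if channel_map:
        names = [channel_map.get(n, n) for n in names]
    canonical = PANEL_CHANNELS[panel]
    missing = [c for c in canonical if c not in names]
    if missing:
        raise SchemaError(f"missing channel(s) {missing} in {path.name}")
    order = [names.index(c) for c in canonical]
    return EventTable(
        sample_id=path.stem, panel=panel,
        channels=list(canonical), intensities=data[:, order],
    )


def gate_noise(events: EventTable, cfg: GateConfig) -> EventTable:
    """Drop instrument noise: keep only events with FSC and SSC above the
    scatter threshold (strict >). Row order is preserved."""
    fsc, ssc = events.channel("FSC"), events.channel("SSC")
    keep = (fsc > cfg.scatter_min) & (ssc > cfg.scatter_min)
    if not keep.any():
        logger.warning("noise gate removed all %d events of %s/%s",
                       events.n_events, events.sample_id, events.panel)
    return EventTable(events.sample_id, events.panel, list(events.channels),
                      events.intensities[keep])


def gate_dna_positive(events: EventTable, cfg: GateConfig) -> EventTable:
    """Keep DNA-dye-positive events (DNA intensity strictly above threshold)."""
    keep = events.channel("DNA") > cfg.dna_min
    if not keep.any():
        logger.warning("DNA gate removed all %d events of %s/%s",
                       events.n_events, events.sample_id, events.panel)
    return EventTable(events.sample_id, events.panel, list(events.channels),
                      events.intensities[keep])


def subsample_events(events: EventTable, cfg: GateConfig) -> EventTable:
    """Uniformly subsample (without replacement) to ``target_events`` rows.

    Samples with fewer events are passed through whole with a warning,
    rather than rejected.
    """
    if events.n_events <= cfg.target_events:
        if events.n_events < cfg.target_events:
            warnings.warn(
                f"{events.sample_id}/{events.panel}: only {events.n_events} "
                f"events available (< target {cfg.target_events}); using all",
                stacklevel=2,
            )
        return events
    rng = np.random.default_rng(cfg.seed)
    idx = np.sort(rng.choice(events.n_events, size=cfg.target_events,
                             replace=False))
    return EventTable(events.sample_id, events.panel, list(events.channels),
                      events.intensities[idx])


def gate_and_subsample(events: EventTable, cfg: GateConfig) -> EventTable:
    """Fixed ingest order: noise gate, then DNA gate, then downsampling."""
    return subsample_events(gate_dna_positive(gate_noise(events, cfg), cfg), cfg)
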