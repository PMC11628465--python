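"""Self-organizing-map phenotype fingerprinting.

A per-panel SOM is trained on untransformed event intensities pooled across
samples. The trained codebook defines a fixed dictionary of phenotype
clusters; every sample is then mapped against it and described by its
relative cell abundance per cluster. Concatenating both panels' abundance
blocks yields the sample's phenotype fingerprint (4050-dimensional at the
default 45x45 grids).

The SOM is the classic online Kohonen algorithm on a hexagonal lattice with
a Gaussian neighborhood kernel exp(-d_grid^2 / (2 sigma^2)); learning rate
and neighborhood radius decay linearly over the presentation steps. Training
is fully deterministic given the seed: initial codebook rows are drawn from
the training events and the presentation order is a seeded permutation per
epoch.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numba import njit

from .flow import EventTable, SchemaError


def hex_positions(grid_rows: int, grid_cols: int) -> np.ndarray:
    """2-D lattice coordinates of each node of a hexagonal grid.

    Odd rows are offset by half a unit and rows are sqrt(3)/2 apart, so
    every node is at unit distance from its (up to six) neighbors. Node
    index is row-major: k = r * grid_cols + c.
    """
    pos = np.empty((grid_rows * grid_cols, 2), dtype=float)
    for r in range(grid_rows):
        for c in range(grid_cols):
            k = r * grid_cols + c
            pos[k, 0] = c + 0.5 * (r % 2)
            pos[k, 1] = r * math.sqrt(3.0) / 2.0
    return pos


@njit(cache=True)
def _kohonen_train(codebook, X, order, pos, lr0, lr1, s0, s1):  # pragma: no cover
    n_steps = order.size
    n_nodes, n_ch = codebook.shape
    denom = n_steps - 1 if n_steps > 1 else 1
    for t in range(n_steps):
        frac = t / denom
        lr = lr0 + (lr1 - lr0) * frac
        sigma = s0 + (s1 - s0) * frac
        x = X[order[t]]
        best = 0
        bestd = np.inf
        for k in range(n_nodes):
            d = 0.0
            for c in range(n_ch):
                diff = codebook[k, c] - x[c]
                d += diff * diff
            if d < bestd:
                bestd = d
                best = k
        two_s2 = 2.0 * sigma * sigma
        for k in range(n_nodes):
            dx = pos[k, 0] - pos[best, 0]
            dy = pos[k, 1] - pos[best, 1]
            h = math.exp(-(dx * dx + dy * dy) / two_s2)
            if h > 1e-12:
                a = lr * h
                for c in range(n_ch):
                    codebook[k, c] += a * (x[c] - codebook[k, c])


@dataclass
class SOMCodebook:
    """Trained prototype vectors defining one panel's cluster dictionary."""

    panel: str
    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (grid_rows*grid_cols, n_channels)
    channels: list[str]
    topology: str = "hexagonal"
    training_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[0] != self.grid_rows * self.grid_cols:
            raise ValueError("codebook row count must equal grid size")
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("codebook entries must be finite")

    @property
    def n_clusters(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class ClusterAbundance:
    """Per-sample event counts over one panel's SOM clusters."""

    sample_id: str
    panel: str
    counts: np.ndarray
    n_mapped: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.sum() != self.n_mapped or (self.counts < 0).any():
            raise ValueError("counts must be nonnegative and sum to n_mapped")


@dataclass
class Fingerprint:
    """Concatenated per-panel relative cluster abundances for one sample."""

    sample_id: str
    values: np.ndarray
    block_sizes: tuple[int, int]
    normalization: str = "per_panel_relative"


@dataclass
class OccupancyReport:
    threshold: float
    min_fraction_observed: float
    n_below_threshold: int
    fractions: np.ndarray


def train_som(
    training_events: EventTable,
    grid_rows: int = 45,
    grid_cols: int = 45,
    epochs: int = 10,
    lr: tuple[float, float] = (0.05, 0.01),
    radius: tuple[float | None, float] = (None, 0.2),
    seed: int = 0,
) -> SOMCodebook:
    """Train the hexagonal SOM on pooled, gated, untransformed events.

    ``radius[0]=None`` uses half the grid diagonal (in lattice units) as the
    starting neighborhood radius. Refuses to train when there are fewer
    events than grid cells, since the codebook is seeded from distinct
    events.
    """
    n_nodes = grid_rows * grid_cols
    X = np.ascontiguousarray(training_events.intensities)
    if X.shape[0] < n_nodes:
        raise ValueError(
            f"need at least {n_nodes} training events for a "
            f"{grid_rows}x{grid_cols} grid, got {X.shape[0]}"
        )
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    pos = hex_positions(grid_rows, grid_cols)
    s0 = radius[0]
    if s0 is None:
        span = pos.max(axis=0) - pos.min(axis=0)
        s0 = max(float(np.hypot(*span)) / 2.0, 1.0)
    s1 = float(radius[1])

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(X.shape[0], size=n_nodes, replace=False)
    codebook = X[init_idx].astype(float).copy()
    order = np.concatenate(
        [rng.permutation(X.shape[0]) for _ in range(epochs)]
    ).astype(np.int64)
    idx0 = _assign(codebook, X)
    qe_initial = float(np.linalg.norm(X - codebook[idx0], axis=1).mean())
    _kohonen_train(codebook, X, order, pos, float(lr[0]), float(lr[1]),
                   float(s0), s1)
    idx1 = _assign(codebook, X)
    qe_final = float(np.linalg.norm(X - codebook[idx1], axis=1).mean())
    meta = {
        "epochs": epochs, "lr": list(lr), "radius": [s0, s1], "seed": seed,
        "n_training_events": int(X.shape[0]),
        "qe_initial": qe_initial, "qe_final": qe_final,
    }
    return SOMCodebook(training_events.panel, grid_rows, grid_cols, codebook,
                       list(training_events.channels), training_meta=meta)


def _assign(codebook: np.ndarray, X: np.ndarray,
            chunk: int = 8192) -> np.ndarray:
    """Nearest-codebook-row index per event (Euclidean, ties -> lowest index)."""
    out = np.empty(X.shape[0], dtype=np.int64)
    sq = (codebook ** 2).sum(axis=1)
    for start in range(0, X.shape[0], chunk):
        block = X[start:start + chunk]
        d = sq[None, :] - 2.0 * block @ codebook.T
        out[start:start + chunk] = np.argmin(d, axis=1)
    return out


def quantization_error(codebook: SOMCodebook, events: EventTable) -> float:
    """Mean Euclidean distance between events and their assigned prototype."""
    X = events.intensities
    idx = _assign(codebook.codebook, X)
    return float(np.linalg.norm(X - codebook.codebook[idx], axis=1).mean())


def map_events(codebook: SOMCodebook, events: EventTable) -> ClusterAbundance:
    """Assign every event to its nearest cluster and tally counts."""
    if list(events.channels) != list(codebook.channels):
        raise SchemaError(
            f"event channels {events.channels} do not match codebook "
            f"channels {codebook.channels}"
        )
    counts = np.zeros(codebook.n_clusters, dtype=int)
    if events.n_events:
        idx = _assign(codebook.codebook, events.intensities)
        counts += np.bincount(idx, minlength=codebook.n_clusters)
    return ClusterAbundance(events.sample_id, events.panel, counts,
                            int(events.n_events))


def check_occupancy(codebook: SOMCodebook, training_events: EventTable,
                    threshold: float = 5e-4) -> OccupancyReport:
    """Report how well the training events populate the clusters.

    A cluster is flagged when its share of the training events falls below
    ``threshold`` (default 0.05%, i.e. 150 cells of a 3x10^5 training set).
    Advisory only; the codebook is not modified.
    """
    ab = map_events(codebook, training_events)
    frac = ab.counts / max(ab.n_mapped, 1)
    n_below = int((frac < threshold).sum()) if threshold > 0 else int(
        (ab.counts == 0).sum())
    return OccupancyReport(threshold=threshold,
                           min_fraction_observed=float(frac.min()),
                           n_below_threshold=n_below, fractions=frac)


def build_fingerprint(ig: ClusterAbundance, lectin: ClusterAbundance) -> Fingerprint:
    """Concatenate per-panel relative abundances into the sample fingerprint."""
    if ig.sample_id != lectin.sample_id:
        raise ValueError(
            f"panel abundances come from different samples: "
            f"{ig.sample_id!r} vs {lectin.sample_id!r}"
        )
    blocks = []
    for ab in (ig, lectin):
        if ab.n_mapped == 0:
            warnings.warn(f"{ab.sample_id}/{ab.panel}: no mapped events; "
                          "fingerprint block is all-zero", stacklevel=2)
            blocks.append(np.zeros(len(ab.counts)))
        else:
            blocks.append(ab.counts / ab.n_mapped)
    return Fingerprint(ig.sample_id, np.concatenate(blocks),
                       (len(ig.counts), len(lectin.counts)))


def cluster_marker_profiles(codebook: SOMCodebook) -> np.ndarray:
    """Per-channel min-max normalized marker profile of each cluster.

    Each channel is rescaled to [0, 1] across clusters; a channel constant
    across the map is set to all zeros by convention.
    """
    cb = codebook.codebook
    lo = cb.min(axis=0)
    span = cb.max(axis=0) - lo
    out = np.zeros_like(cb)
    nz = span > 0
    out[:, nz] = (cb[:, nz] - lo[nz]) / span[nz]
    return out
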