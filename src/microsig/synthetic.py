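"""Synthetic cohorts with planted, age-stratified case/control structure.

Flow-cytometry samples are simulated as mixtures of latent phenotype
populations: an event picks a population by weight, then draws a log-normal
intensity per channel (independent channels, log10 scale), which reproduces
the positive, right-skewed event clouds of real acquisitions while keeping
closed-form oracles. Case samples in the age groups named by the effect map
get their population weights multiplied and/or their mean log-intensities
shifted before renormalization. The two staining panels are simulated
independently (they are stained as separate aliquots, so no cell-level
linkage exists).

Taxa count tables are drawn per sample as Dirichlet-multinomial: the
composition comes from Dirichlet(base_composition * overdispersion) — with
planted natural-log fold effects applied to the base composition of case
samples in the named age group before renormalization — and counts from a
multinomial at a depth drawn uniformly from ``depth_range``.

Everything is deterministic given the design seed; the ground-truth record
states exactly which populations/taxa were perturbed in which age group.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .flow import PANEL_CHANNELS, PANELS, EventTable


class ConfigurationError(ValueError):
    """The synthetic design is internally inconsistent."""


@dataclass
class PhenotypePopulation:
    """One latent bacterial phenotype population of a staining panel."""

    label: str
    mean_log_intensity: np.ndarray  # log10 arbitrary-fluorescence units
    sd_log_intensity: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.mean_log_intensity = np.asarray(self.mean_log_intensity, float)
        self.sd_log_intensity = np.asarray(self.sd_log_intensity, float)
        if (self.mean_log_intensity.shape != self.sd_log_intensity.shape
                or len(self.mean_log_intensity) != len(self.channels)):
            raise ConfigurationError(
                f"population {self.label!r}: mean/sd/channel lengths differ")
        if np.any(self.sd_log_intensity < 0):
            raise ConfigurationError(
                f"population {self.label!r}: sd must be >= 0")


@dataclass
class FlowEffect:
    """Planted case/control perturbation of one population in one age group."""

    age_group: int
    population: str
    weight_multiplier: float = 1.0
    intensity_shift: float = 0.0  # added to mean log10 intensity, markers only
    cohort: str = "case"


@dataclass
class TaxaEffect:
    """Planted differential abundance: natural-log fold effect on one taxon."""

    age_group: int
    taxon_index: int
    log_fold: float
    cohort: str = "case"


@dataclass
class CohortMetadata:
    sample_id: str
    cohort: str  # case | control
    age_group: int  # 1 | 2 | 3
    age: float
    batch: str = "B1"


@dataclass
class SyntheticDesign:
    """Full description of a synthetic study: populations, cohort sizes,
    planted effects, taxa composition and sequencing-depth model."""

    populations: dict[str, list[PhenotypePopulation]]
    base_weights: dict[str, np.ndarray]
    effect_map: list[FlowEffect] = field(default_factory=list)
    n_case: dict[int, int] = field(default_factory=lambda: {1: 10, 2: 10, 3: 10})
    n_control: dict[int, int] = field(default_factory=lambda: {1: 10, 2: 10, 3: 10})
    events_per_sample: int = 10_000
    flow_overdispersion: float = 100.0  # Dirichlet concentration scale for
    # per-sample population weights (inter-individual variability)
    taxa_base_composition: np.ndarray | None = None
    planted_taxa_effects: list[TaxaEffect] = field(default_factory=list)
    overdispersion: float = 100.0
    depth_range: tuple[int, int] = (20_000, 50_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for panel, w in self.base_weights.items():
            w = np.asarray(w, dtype=float)
            self.base_weights[panel] = w
            if abs(w.sum() - 1.0) > 1e-12 or np.any(w < 0):
                raise ConfigurationError(
                    f"base_weights[{panel}] must be a probability vector")
            if len(w) != len(self.populations[panel]):
                raise ConfigurationError(
                    f"base_weights[{panel}] length mismatch")
        if self.taxa_base_composition is not None:
            c = np.asarray(self.taxa_base_composition, dtype=float)
            self.taxa_base_composition = c
            if abs(c.sum() - 1.0) > 1e-12 or np.any(c < 0):
                raise ConfigurationError(
                    "taxa_base_composition must be a probability vector")
        if self.overdispersion <= 0:
            raise ConfigurationError("overdispersion must be > 0")
        if self.flow_overdispersion <= 0:
            raise ConfigurationError("flow_overdispersion must be > 0")
        if self.events_per_sample < 1:
            raise ConfigurationError("events_per_sample must be >= 1")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ConfigurationError("invalid depth_range")
        for g, n in {**self.n_case, **self.n_control}.items():
            if n < 0:
                raise ConfigurationError(f"negative cohort size for group {g}")
        valid_groups = set(self.n_case) | set(self.n_control)
        for eff in self.effect_map:
            if eff.age_group not in valid_groups:
                raise ConfigurationError(
                    f"effect references unknown age group {eff.age_group}")
            known = {p.label for pops in self.populations.values() for p in pops}
            if eff.population not in known:
                raise ConfigurationError(
                    f"effect references unknown population {eff.population!r}")
        if self.taxa_base_composition is not None:
            n_taxa = len(self.taxa_base_composition)
            for te in self.planted_taxa_effects:
                if te.age_group not in valid_groups:
                    raise ConfigurationError(
                        f"taxa effect references unknown age group {te.age_group}")
                if not 0 <= te.taxon_index < n_taxa:
                    raise ConfigurationError(
                        f"taxa effect index {te.taxon_index} out of range")


# ---------------------------------------------------------------------------
# default study-shaped design

_GEOMETRY_SEED = 20240914  # fixes the latent population geometry, not sampling

#: age ranges (years, inclusive) per age group
AGE_RANGES = {1: (1, 5), 2: (6, 11), 3: (12, 18)}


def default_populations(panel: str, n_populations: int = 8
                        ) -> list[PhenotypePopulation]:
    """Fixed latent population geometry for one panel.

    Mean log10 intensities span 0.8-3.5 (above the noise/DNA gates) with
    per-channel spread 0.12-0.28; drawn once from a constant geometry seed
    so the same populations define the study conditions in every run.
    """
    channels = PANEL_CHANNELS[panel]
    rng = np.random.default_rng(_GEOMETRY_SEED + PANELS.index(panel))
    pops = []
    for i in range(n_populations):
        mean = rng.uniform(0.8, 3.5, size=len(channels))
        # scatter and DNA channels sit comfortably above the gates
        mean[0:3] = rng.uniform(1.5, 3.2, size=3)
        sd = rng.uniform(0.12, 0.28, size=len(channels))
        pops.append(PhenotypePopulation(
            label=f"{panel[:3]}_pop{i}", mean_log_intensity=mean,
            sd_log_intensity=sd, channels=list(channels)))
    return pops


def default_base_weights(n_populations: int = 8) -> np.ndarray:
    w = np.array([0.25, 0.20, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04][:n_populations])
    return w / w.sum()


def default_taxa_composition(n_taxa: int = 150) -> np.ndarray:
    """Power-law-ish base composition typical of stool communities."""
    ranks = np.arange(1, n_taxa + 1, dtype=float)
    comp = ranks ** -1.3
    return comp / comp.sum()


def default_design(seed: int = 0, n_populations: int = 8,
                   n_taxa: int = 150) -> SyntheticDesign:
    """Study-shaped null design: 10 case + 10 control per age group, 10^4
    events/sample, 8 populations/panel, 150 taxa, no planted effects."""
    pops = {p: default_populations(p, n_populations) for p in PANELS}
    weights = {p: default_base_weights(n_populations) for p in PANELS}
    return SyntheticDesign(
        populations=pops, base_weights=weights,
        taxa_base_composition=default_taxa_composition(n_taxa), seed=seed)


# ---------------------------------------------------------------------------

def make_metadata(design: SyntheticDesign) -> list[CohortMetadata]:
    """Deterministic sample roster shared by the flow and taxa simulators."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 17]))
    meta = []
    idx = 1
    for group in sorted(set(design.n_case) | set(design.n_control)):
        lo, hi = AGE_RANGES.get(group, (group, group))
        for cohort, n in (("case", design.n_case.get(group, 0)),
                          ("control", design.n_control.get(group, 0))):
            for _ in range(n):
                age = float(rng.integers(lo, hi + 1))
                meta.append(CohortMetadata(
                    sample_id=f"S{idx:04d}", cohort=cohort,
                    age_group=group, age=age))
                idx += 1
    return meta


def metadata_frame(meta: list[CohortMetadata]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in meta])


def _effective_panel(design: SyntheticDesign, panel: str,
                     cohort: str, age_group: int
                     ) -> tuple[np.ndarray, list[PhenotypePopulation]]:
    """Population weights and (possibly intensity-shifted) populations for
    one sample, after applying matching planted effects and renormalizing."""
    pops = design.populations[panel]
    weights = design.base_weights[panel].astype(float).copy()
    shifted = list(pops)
    labels = [p.label for p in pops]
    for eff in design.effect_map:
        if eff.cohort != cohort or eff.age_group != age_group:
            continue
        if eff.population not in labels:
            continue
        i = labels.index(eff.population)
        weights[i] *= eff.weight_multiplier
        if eff.intensity_shift:
            p = shifted[i]
            mean = p.mean_log_intensity.copy()
            mean[3:] += eff.intensity_shift  # markers only, not scatter/DNA
            shifted[i] = PhenotypePopulation(p.label, mean,
                                             p.sd_log_intensity.copy(),
                                             list(p.channels))
    total = weights.sum()
    if total <= 0:
        raise ConfigurationError("effects drove all population weights to 0")
    return weights / total, shifted


def simulate_event_sample(
    design: SyntheticDesign,
    sample_weights: np.ndarray,
    panel: str,
    n_events: int,
    seed: int,
    sample_id: str = "sample",
    populations: list[PhenotypePopulation] | None = None,
) -> EventTable:
    """Draw one sample's event cloud from the population mixture."""
    pops = populations if populations is not None else design.populations[panel]
    w = np.asarray(sample_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ConfigurationError("sample_weights must be a probability vector")
    if len(w) != len(pops):
        raise ConfigurationError("sample_weights length mismatch")
    n_ch = {len(p.channels) for p in pops}
    if len(n_ch) != 1:
        raise ConfigurationError("populations disagree on channel count")
    if n_events < 1:
        raise ConfigurationError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    pop_idx = rng.choice(len(pops), size=n_events, p=w)
    means = np.stack([p.mean_log_intensity for p in pops])
    sds = np.stack([p.sd_log_intensity for p in pops])
    log10_int = rng.normal(means[pop_idx], sds[pop_idx])
    return EventTable(sample_id=sample_id, panel=panel,
                      channels=list(pops[0].channels),
                      intensities=10.0 ** log10_int)


def simulate_flow_cohort(design: SyntheticDesign
                         ) -> tuple[dict[str, dict[str, EventTable]],
                                    list[CohortMetadata], dict]:
    """Simulate both panels' event clouds for every sample of the cohort."""
    meta = make_metadata(design)
    ss = np.random.SeedSequence([design.seed, 29])
    child_seeds = ss.generate_state(len(meta) * len(PANELS)) % (2 ** 31)
    events: dict[str, dict[str, EventTable]] = {}
    for i, m in enumerate(meta):
        events[m.sample_id] = {}
        for j, panel in enumerate(PANELS):
            w, pops = _effective_panel(design, panel, m.cohort, m.age_group)
            seed = int(child_seeds[i * len(PANELS) + j])
            # inter-individual variability of the community structure
            wrng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
            nz = w > 0
            ws = np.zeros_like(w)
            ws[nz] = wrng.dirichlet(w[nz] * design.flow_overdispersion)
            events[m.sample_id][panel] = simulate_event_sample(
                design, ws, panel, design.events_per_sample,
                seed=seed, sample_id=m.sample_id, populations=pops)
    truth = {
        "flow_effects": [asdict(e) for e in design.effect_map],
        "perturbed_populations": sorted({e.population
                                         for e in design.effect_map}),
        "perturbed_age_groups": sorted({e.age_group
                                        for e in design.effect_map}),
    }
    return events, meta, truth


def simulate_taxa_counts(design: SyntheticDesign
                         ) -> tuple[pd.DataFrame, list[CohortMetadata], dict]:
    """Dirichlet-multinomial taxa counts with planted age-stratified effects."""
    if design.taxa_base_composition is None:
        raise ConfigurationError("design has no taxa_base_composition")
    meta = make_metadata(design)
    base = design.taxa_base_composition
    n_taxa = len(base)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 43]))
    rows = np.empty((len(meta), n_taxa), dtype=np.int64)
    for i, m in enumerate(meta):
        comp = base.copy()
        for te in design.planted_taxa_effects:
            if te.cohort == m.cohort and te.age_group == m.age_group:
                comp[te.taxon_index] *= np.exp(te.log_fold)
        comp = comp / comp.sum()
        alpha = comp * design.overdispersion
        p = rng.dirichlet(alpha)
        depth = int(rng.integers(design.depth_range[0],
                                 design.depth_range[1] + 1))
        rows[i] = rng.multinomial(depth, p)
    df = pd.DataFrame(rows, index=[m.sample_id for m in meta],
                      columns=[f"taxon_{t:03d}" for t in range(n_taxa)])
    df.index.name = "sample_id"
    truth = {
        "taxa_effects": [asdict(t) for t in design.planted_taxa_effects],
        "planted_taxa": sorted({f"taxon_{t.taxon_index:03d}"
                                for t in design.planted_taxa_effects}),
        "perturbed_age_groups": sorted({t.age_group
                                        for t in design.planted_taxa_effects}),
    }
    return df, meta, truth


def write_events(events: EventTable, path: str | Path, format: str = "tsv",
                 channel_order: list[str] | None = None) -> None:
    """Write one sample's events as TSV or FCS 3.1.

    ``channel_order`` optionally permutes the written column order; a
    reader supplying a channel map realigns to the canonical order.
    """
    if events.n_events == 0:
        raise ValueError("refusing to write an empty event table")
    names = list(events.channels)
    data = events.intensities
    if channel_order is not None:
        if sorted(channel_order) != sorted(names):
            raise ValueError("channel_order must permute the event channels")
        idx = [names.index(c) for c in channel_order]
        names, data = list(channel_order), data[:, idx]
    path = Path(path)
    if format == "tsv":
        pd.DataFrame(data, columns=names).to_csv(path, sep="\t", index=False,
                                                 float_format="%.9g")
    elif format == "fcs":
        from .fcsio import write_fcs

        write_fcs(path, names, data)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def write_metadata_tsv(meta: list[CohortMetadata], path: str | Path) -> None:
    metadata_frame(meta).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# YAML config mirroring SyntheticDesign

def design_from_yaml(path: str | Path) -> SyntheticDesign:
    """Build a design from a YAML document mirroring SyntheticDesign.

    Omitted population/taxa sections fall back to the package defaults.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    n_pop = int(doc.get("n_populations", 8))
    n_taxa = int(doc.get("n_taxa", 150))
    design = default_design(seed=int(doc.get("seed", 0)),
                            n_populations=n_pop, n_taxa=n_taxa)
    if "n_case" in doc:
        design.n_case = {int(k): int(v) for k, v in doc["n_case"].items()}
    if "n_control" in doc:
        design.n_control = {int(k): int(v) for k, v in doc["n_control"].items()}
    if "events_per_sample" in doc:
        design.events_per_sample = int(doc["events_per_sample"])
    if "overdispersion" in doc:
        design.overdispersion = float(doc["overdispersion"])
    if "depth_range" in doc:
        design.depth_range = tuple(int(v) for v in doc["depth_range"])
    for e in doc.get("effect_map", []):
        design.effect_map.append(FlowEffect(
            age_group=int(e["age_group"]), population=e["population"],
            weight_multiplier=float(e.get("weight_multiplier", 1.0)),
            intensity_shift=float(e.get("intensity_shift", 0.0)),
            cohort=e.get("cohort", "case")))
    for t in doc.get("planted_taxa_effects", []):
        design.planted_taxa_effects.append(TaxaEffect(
            age_group=int(t["age_group"]), taxon_index=int(t["taxon_index"]),
            log_fold=float(t["log_fold"]), cohort=t.get("cohort", "case")))
    # re-validate planted references against the final design
    SyntheticDesign.__post_init__(design)
    return design
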