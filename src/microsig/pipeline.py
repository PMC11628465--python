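"""Study-shaped end-to-end orchestration.

Runs simulate/ingest -> gate -> SOM fingerprinting -> taxa normalization ->
age stratification -> per-stratum and overall signature selection ->
beta-diversity evaluation and signature cross-application, writing every
artifact plus a hashed run manifest under an output directory.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, selection, som, synthetic
from .flow import PANELS, EventTable, GateConfig, gate_and_subsample, read_events
from .selection import FeatureMatrix, RFEConfig
from .taxa import TaxaTable, filter_prevalence_abundance, normalize_total

logger = logging.getLogger(__name__)

#: default age bins in years, inclusive on both ends (group 3 is open-ended)
DEFAULT_AGE_BINS: dict[int, tuple[float, float]] = {
    1: (1, 5), 2: (6, 11), 3: (12, math.inf),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | files
    output_dir: str = "run"
    seed: int = 0
    # synthetic mode
    design: synthetic.SyntheticDesign | None = None
    # files mode
    events_dir: str | None = None
    events_format: str = "tsv"
    taxa_path: str | None = None
    metadata_path: str | None = None
    channel_map: dict[str, str] | None = None
    # stage settings
    gate: GateConfig = field(default_factory=GateConfig)
    som_grid: tuple[int, int] = (45, 45)
    som_epochs: int = 10
    som_training_events: int = 300_000
    prevalence_min: float = 0.05
    abundance_min: float = 1e-4
    alpha: float = 0.05
    rfe: RFEConfig = field(default_factory=RFEConfig)
    case_label: str = "case"
    control_label: str = "control"
    n_permutations: int = 199
    signature_on: tuple[str, ...] = ("taxa", "phenotype")
    age_bins: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BINS))
    external_signature: str | None = None


@dataclass
class RunManifest:
    config_hash: str
    outputs: dict[str, str]  # path -> sha256
    signatures: list[str]
    warnings: list[str]
    stages_completed: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1,
                                         sort_keys=True))


def stratify(metadata: pd.DataFrame,
             bins: dict[int, tuple[float, float]] | None = None
             ) -> dict[int, list[str]]:
    """Partition sample_ids into age groups.

    Uses the ``age`` column against the bins (inclusive on both edges);
    falls back to a pre-assigned ``age_group`` column. Samples outside all
    bins are flagged and left out.
    """
    bins = bins or DEFAULT_AGE_BINS
    keys = sorted(bins)
    for a, b in zip(keys, keys[1:]):
        if bins[a][1] >= bins[b][0]:
            raise ConfigurationError(f"age bins {a} and {b} overlap")
    out: dict[int, list[str]] = {g: [] for g in keys}
    if "age" in metadata.columns and metadata["age"].notna().all():
        for _, row in metadata.iterrows():
            age = float(row["age"])
            for g in keys:
                lo, hi = bins[g]
                if lo <= age <= hi:
                    out[g].append(str(row["sample_id"]))
                    break
            else:
                logger.warning("sample %s age %.1f outside all bins",
                               row["sample_id"], age)
    elif "age_group" in metadata.columns:
        for _, row in metadata.iterrows():
            g = int(row["age_group"])
            if g in out:
                out[g].append(str(row["sample_id"]))
            else:
                logger.warning("sample %s has unknown age_group %s",
                               row["sample_id"], g)
    else:
        raise ConfigurationError("metadata needs an age or age_group column")
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_doc(cfg: PipelineConfig) -> dict:
    doc = {
        "mode": cfg.mode, "seed": cfg.seed,
        "gate": asdict(cfg.gate), "som_grid": list(cfg.som_grid),
        "som_epochs": cfg.som_epochs,
        "som_training_events": cfg.som_training_events,
        "prevalence_min": cfg.prevalence_min,
        "abundance_min": cfg.abundance_min, "alpha": cfg.alpha,
        "rfe": {"cv_folds": cfg.rfe.cv_folds, "n_trees": cfg.rfe.n_trees,
                "seed": cfg.rfe.seed, "subset_sizes": cfg.rfe.subset_sizes},
        "case_label": cfg.case_label, "n_permutations": cfg.n_permutations,
        "signature_on": list(cfg.signature_on),
        "age_bins": {str(k): [v[0], "inf" if math.isinf(v[1]) else v[1]]
                     for k, v in cfg.age_bins.items()},
    }
    if cfg.design is not None:
        d = cfg.design
        doc["design"] = {
            "seed": d.seed, "events_per_sample": d.events_per_sample,
            "n_case": {str(k): v for k, v in d.n_case.items()},
            "n_control": {str(k): v for k, v in d.n_control.items()},
            "overdispersion": d.overdispersion,
            "depth_range": list(d.depth_range),
            "effect_map": [asdict(e) for e in d.effect_map],
            "planted_taxa_effects": [asdict(t)
                                     for t in d.planted_taxa_effects],
        }
    return doc


def fingerprint_matrix(fingerprints: list[som.Fingerprint]) -> FeatureMatrix:
    """Stack per-sample fingerprints into a samples x clusters matrix with
    block-prefixed feature names (ig_0001..., lec_0001...)."""
    if not fingerprints:
        raise ValueError("no fingerprints")
    b_ig, b_lec = fingerprints[0].block_sizes
    cols = ([f"ig_{i + 1:04d}" for i in range(b_ig)]
            + [f"lec_{i + 1:04d}" for i in range(b_lec)])
    values = np.stack([fp.values for fp in fingerprints])
    return FeatureMatrix([fp.sample_id for fp in fingerprints], cols, values,
                         feature_kind="phenotype_cluster")


def _load_files_events(cfg: PipelineConfig, sample_ids: list[str]
                       ) -> dict[str, dict[str, EventTable]]:
    events: dict[str, dict[str, EventTable]] = {}
    root = Path(cfg.events_dir)
    for sid in sample_ids:
        events[sid] = {}
        for panel in PANELS:
            path = root / f"{sid}_{panel}.{cfg.events_format}"
            ev = read_events(path, panel, cfg.channel_map)
            ev.sample_id = sid
            events[sid][panel] = ev
    return events


def run_full(cfg: PipelineConfig) -> RunManifest:
    """Execute the full pipeline and write all artifacts.

    Per-stratum signatures are derived independently on each age group's
    samples; the overall signature uses unstratified labels. Each signature
    is evaluated by PERMANOVA on the full versus signature-restricted
    matrix and by the per-sample distance-to-control statistic. Identical
    config (including seeds) reproduces byte-identical outputs.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    stages: list[str] = []
    outputs: dict[str, str] = {}

    def emit(path: Path) -> None:
        outputs[str(path.relative_to(out))] = _sha256(path)

    # --- stage: inputs -----------------------------------------------------
    taxa_counts = None
    events = None
    if cfg.mode == "synthetic":
        design = cfg.design or synthetic.default_design(seed=cfg.seed)
        events, meta, flow_truth = synthetic.simulate_flow_cohort(design)
        taxa_df, _, taxa_truth = synthetic.simulate_taxa_counts(design)
        taxa_counts = TaxaTable.from_frame(taxa_df, stage="counts")
        meta_df = synthetic.metadata_frame(meta)
        truth = {**flow_truth, **taxa_truth}
        synthetic.write_ground_truth(truth, out / "ground_truth.json")
        emit(out / "ground_truth.json")
    elif cfg.mode == "files":
        if cfg.metadata_path is None:
            raise ConfigurationError("files mode requires metadata_path")
        meta_df = pd.read_csv(cfg.metadata_path, sep="\t")
        if cfg.taxa_path:
            taxa_counts = TaxaTable.read_tsv(cfg.taxa_path, stage="counts")
        if cfg.events_dir:
            events = _load_files_events(
                cfg, list(meta_df["sample_id"].astype(str)))
    else:
        raise ConfigurationError(f"unknown mode {cfg.mode!r}")
    meta_df.to_csv(out / "metadata.tsv", sep="\t", index=False)
    emit(out / "metadata.tsv")
    stages.append("inputs")

    labels_by_id = dict(zip(meta_df["sample_id"].astype(str),
                            meta_df["cohort"].astype(str)))
    strata = stratify(meta_df, cfg.age_bins)
    stages.append("stratify")

    # --- stage: flow fingerprints -----------------------------------------
    matrices: dict[str, FeatureMatrix] = {}
    if events is not None:
        sample_ids = sorted(events)
        gated: dict[str, dict[str, EventTable]] = {}
        ss = np.random.SeedSequence([cfg.seed, 71])
        sub_seeds = ss.generate_state(len(sample_ids) * len(PANELS)) % (2 ** 31)
        for i, sid in enumerate(sample_ids):
            gated[sid] = {}
            for j, panel in enumerate(PANELS):
                g = GateConfig(cfg.gate.scatter_min, cfg.gate.dna_min,
                               cfg.gate.target_events,
                               seed=int(sub_seeds[i * len(PANELS) + j]))
                gated[sid][panel] = gate_and_subsample(events[sid][panel], g)

        codebooks: dict[str, som.SOMCodebook] = {}
        rng_pool = np.random.default_rng(np.random.SeedSequence([cfg.seed, 83]))
        for panel in PANELS:
            pool = np.concatenate([gated[sid][panel].intensities
                                   for sid in sample_ids])
            if pool.shape[0] > cfg.som_training_events:
                idx = np.sort(rng_pool.choice(pool.shape[0],
                                              cfg.som_training_events,
                                              replace=False))
                pool = pool[idx]
            train_tab = EventTable("pooled", panel,
                                   list(gated[sample_ids[0]][panel].channels),
                                   pool)
            cb = som.train_som(train_tab, cfg.som_grid[0], cfg.som_grid[1],
                               epochs=cfg.som_epochs, seed=cfg.seed)
            occ = som.check_occupancy(cb, train_tab)
            if occ.n_below_threshold:
                warnings_log.append(
                    f"{panel}: {occ.n_below_threshold} cluster(s) below "
                    f"{occ.threshold:.2%} training occupancy")
            codebooks[panel] = cb
            pd.DataFrame(cb.codebook, columns=cb.channels).to_csv(
                out / f"codebook_{panel}.tsv", sep="\t", index=False,
                float_format="%.10g")
            (out / f"codebook_{panel}.json").write_text(json.dumps(
                {"grid_rows": cb.grid_rows, "grid_cols": cb.grid_cols,
                 "topology": cb.topology, **cb.training_meta},
                indent=1, sort_keys=True))
            emit(out / f"codebook_{panel}.tsv")
            emit(out / f"codebook_{panel}.json")

        fingerprints = []
        for sid in sample_ids:
            ab = {panel: som.map_events(codebooks[panel], gated[sid][panel])
                  for panel in PANELS}
            fingerprints.append(som.build_fingerprint(
                ab["immunoglobulin"], ab["lectin"]))
        fp = fingerprint_matrix(fingerprints)
        df = fp.to_frame()
        df.index.name = "sample_id"
        df.to_csv(out / "fingerprints.tsv", sep="\t", float_format="%.10g")
        emit(out / "fingerprints.tsv")
        matrices["phenotype"] = fp
        stages.append("fingerprint")

    # --- stage: taxa -------------------------------------------------------
    if taxa_counts is not None:
        rel = normalize_total(taxa_counts)
        filt = filter_prevalence_abundance(rel, cfg.prevalence_min,
                                           cfg.abundance_min)
        filt.write_tsv(out / "taxa_filtered.tsv")
        emit(out / "taxa_filtered.tsv")
        matrices["taxa"] = FeatureMatrix(list(filt.sample_ids),
                                         list(filt.taxon_labels),
                                         filt.values, feature_kind="taxon")
        stages.append("taxa")

    # --- stage: signatures + evaluation ------------------------------------
    scopes: list[tuple[str, list[str] | None]] = [("overall", None)]
    scopes += [(f"g{g}", ids) for g, ids in sorted(strata.items())]
    signature_files: list[str] = []
    for kind in cfg.signature_on:
        if kind not in matrices:
            continue
        mat = matrices[kind]
        for scope, ids in scopes:
            sub = mat if ids is None else mat.subset_samples(
                [s for s in ids if s in set(mat.sample_ids)])
            labels = np.array([labels_by_id[s] for s in sub.sample_ids])
            n_case = int((labels == cfg.case_label).sum())
            n_ctrl = int((labels == cfg.control_label).sum())
            if n_case < 2 or n_ctrl < 2:
                warnings_log.append(
                    f"{kind}/{scope}: too few samples per cohort; skipped")
                continue
            kept, pvals = selection.wilcoxon_filter(sub, labels,
                                                    alpha=cfg.alpha)
            pvals.to_csv(out / f"pvalues_{kind}_{scope}.tsv", sep="\t",
                         index=False, float_format="%.10g")
            emit(out / f"pvalues_{kind}_{scope}.tsv")
            if len(kept.feature_ids) == 0:
                warnings_log.append(
                    f"{kind}/{scope}: no features pass the Wilcoxon filter")
                sig = selection.Signature([], np.empty(0), gfc=np.empty(0),
                                          alpha=cfg.alpha,
                                          cv_folds=cfg.rfe.cv_folds,
                                          seed=cfg.seed,
                                          provenance={"note": "empty"})
            else:
                rfe_cfg = RFEConfig(cv_folds=cfg.rfe.cv_folds,
                                    subset_sizes=cfg.rfe.subset_sizes,
                                    n_trees=cfg.rfe.n_trees, seed=cfg.seed)
                rfe_sig = selection.rfe_select(kept, labels, rfe_cfg)
                sig = selection.assemble_signature(kept, rfe_sig, labels,
                                                   cfg.case_label,
                                                   alpha=cfg.alpha)
            sig_path = out / f"signature_{kind}_{scope}.json"
            sig.to_json(sig_path)
            emit(sig_path)
            signature_files.append(sig_path.name)

            # evaluation within scope
            perm = {}
            if len(set(labels)) == 2:
                dist_full = diversity.bray_curtis(sub)
                res_full = diversity.permanova(dist_full, labels,
                                               cfg.n_permutations, cfg.seed)
                perm["full"] = asdict(res_full)
                if sig.feature_ids:
                    restricted = diversity.apply_signature(sig, sub)
                    dist_sig = diversity.bray_curtis(restricted)
                    res_sig = diversity.permanova(dist_sig, labels,
                                                  cfg.n_permutations, cfg.seed)
                    perm["signature"] = asdict(res_sig)
                    case_ids = [s for s, l in zip(sub.sample_ids, labels)
                                if l == cfg.case_label]
                    ctrl_ids = [s for s, l in zip(sub.sample_ids, labels)
                                if l == cfg.control_label]
                    dres = diversity.distance_to_reference(
                        restricted, case_ids, ctrl_ids,
                        groups={s: scope for s in case_ids},
                        reference_id=f"{scope}:{cfg.control_label}",
                        signature_id=sig_path.name)
                    dres.to_frame().to_csv(
                        out / f"distances_{kind}_{scope}.tsv", sep="\t",
                        index=False, float_format="%.10g")
                    emit(out / f"distances_{kind}_{scope}.tsv")
            (out / f"permanova_{kind}_{scope}.json").write_text(
                json.dumps(perm, indent=1, sort_keys=True))
            emit(out / f"permanova_{kind}_{scope}.json")
    stages.append("signatures")

    # cross-application of an external signature, stratified by age group
    if cfg.external_signature:
        ext = selection.Signature.from_json(cfg.external_signature)
        kind = ext.provenance.get("feature_kind", "taxon")
        key = "taxa" if kind == "taxon" else "phenotype"
        if key in matrices and ext.feature_ids:
            mat = matrices[key]
            restricted = diversity.apply_signature(ext, mat)
            case_ids = [s for s in mat.sample_ids
                        if labels_by_id[s] == cfg.case_label]
            ctrl_ids = [s for s in mat.sample_ids
                        if labels_by_id[s] == cfg.control_label]
            grp = {}
            for g, ids in strata.items():
                for s in ids:
                    grp[s] = f"g{g}"
            dres = diversity.distance_to_reference(
                restricted, case_ids, ctrl_ids, groups=grp,
                reference_id=cfg.control_label,
                signature_id=Path(cfg.external_signature).name)
            dres.to_frame().to_csv(out / f"distances_{key}_external.tsv",
                                   sep="\t", index=False,
                                   float_format="%.10g")
            emit(out / f"distances_{key}_external.tsv")
            stages.append("external_signature")

    cfg_doc = _config_doc(cfg)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_doc, sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, outputs=outputs,
                           signatures=signature_files,
                           warnings=warnings_log, stages_completed=stages)
    manifest.to_json(out / "manifest.json")
    return manifest


def config_from_yaml(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    for key in ("mode", "output_dir", "seed", "events_dir", "events_format",
                "taxa_path", "metadata_path", "som_epochs",
                "som_training_events", "prevalence_min", "abundance_min",
                "alpha", "case_label", "control_label", "n_permutations",
                "external_signature"):
        if key in doc:
            setattr(cfg, key, doc[key])
    if "channel_map" in doc:
        cfg.channel_map = dict(doc["channel_map"])
    if "som_grid" in doc:
        cfg.som_grid = tuple(int(v) for v in doc["som_grid"])
    if "signature_on" in doc:
        cfg.signature_on = tuple(doc["signature_on"])
    if "gate" in doc:
        cfg.gate = GateConfig(**doc["gate"])
    if "rfe" in doc:
        cfg.rfe = RFEConfig(**doc["rfe"])
    if "age_bins" in doc:
        cfg.age_bins = {
            int(k): (float(v[0]),
                     math.inf if str(v[1]).lower() in ("inf", ".inf")
                     else float(v[1]))
            for k, v in doc["age_bins"].items()}
    if "design" in doc:
        if isinstance(doc["design"], str):
            cfg.design = synthetic.design_from_yaml(doc["design"])
        else:
            tmp = Path(path).parent / "_design_tmp.yaml"
            tmp.write_text(yaml.safe_dump(doc["design"]))
            try:
                cfg.design = synthetic.design_from_yaml(tmp)
            finally:
                tmp.unlink(missing_ok=True)
    return cfg
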