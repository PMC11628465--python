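"""Two-stage discriminative signature selection.

Stage 1 is a per-feature two-sided Wilcoxon rank-sum pre-filter at an
unadjusted alpha (0.05 by default): features that do not differ between the
two cohorts are discarded. Stage 2 is recursive feature elimination (RFE)
under 10-fold cross-validation: within each fold the estimator (random
forest) is fitted, features are ranked by importance and pruned down a grid
of subset sizes while held-out balanced accuracy is recorded; the final
subset size is the one maximizing mean held-out accuracy and the features
are chosen by their consensus (mean) rank across folds. Selected features
are annotated with the generalized fold change (gFC), the mean difference
between corresponding quantiles of the two groups — a signed, outlier-robust
effect size (positive = enriched in the case group).
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))


class GroupingError(ValueError):
    """Labels do not define two usable groups."""


@dataclass
class FeatureMatrix:
    """Samples x features matrix of nonnegative values (no missing data)."""

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_kind: str = "taxon"  # taxon | phenotype_cluster

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite values")

    def subset_features(self, feature_ids: list[str]) -> "FeatureMatrix":
        missing = [f for f in feature_ids if f not in set(self.feature_ids)]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return FeatureMatrix(list(self.sample_ids), list(feature_ids),
                             self.values[:, idx], self.feature_kind)

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureMatrix(list(sample_ids), list(self.feature_ids),
                             self.values[idx], self.feature_kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update("\x1f".join(self.sample_ids).encode())
        h.update("\x1f".join(self.feature_ids).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()


@dataclass
class RFEConfig:
    cv_folds: int = 10
    subset_sizes: list[int] | None = None  # default: powers of 2 + full set
    estimator: str = "random_forest_importance"
    n_trees: int = 100
    selection_rule: str = "best_mean_accuracy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class Signature:
    """Ordered selected features with importances, effect sizes, provenance."""

    feature_ids: list[str]
    importance: np.ndarray
    gfc: np.ndarray | None = None
    alpha: float | None = None
    cv_folds: int | None = None
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_ids": self.feature_ids,
            "importance": [float(v) for v in self.importance],
            "gfc": None if self.gfc is None else [float(v) for v in self.gfc],
            "alpha": self.alpha, "cv_folds": self.cv_folds, "seed": self.seed,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Signature":
        doc = json.loads(Path(path).read_text())
        return cls(
            feature_ids=doc["feature_ids"],
            importance=np.asarray(doc["importance"], dtype=float),
            gfc=None if doc.get("gfc") is None
            else np.asarray(doc["gfc"], dtype=float),
            alpha=doc.get("alpha"), cv_folds=doc.get("cv_folds"),
            seed=doc.get("seed"), provenance=doc.get("provenance", {}),
        )


def _two_groups(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise GroupingError(f"need exactly 2 groups, got {list(uniq)}")
    a, b = labels == uniq[0], labels == uniq[1]
    if a.sum() == 0 or b.sum() == 0:
        raise GroupingError("one group is empty")
    return a, b


def rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses full enumeration of all C(n1+n2, n1) group assignments of the
    pooled ranks when both groups have at most ``exact_max`` observations
    (correct under ties), otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise GroupingError("empty group")
    if n1 <= exact_max and n2 <= exact_max:
        ranks = stats.rankdata(np.concatenate([x, y]))
        obs = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        dev = abs(obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            s = ranks[list(idx)].sum()
            if abs(s - mu) >= dev - 1e-9:
                count += 1
            total += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


def wilcoxon_filter(
    features: FeatureMatrix,
    labels: np.ndarray,
    alpha: float = 0.05,
    exact_max: int = 10,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Keep features with two-sided rank-sum p <= alpha (unadjusted)."""
    a, b = _two_groups(labels)
    if a.sum() < 2 or b.sum() < 2:
        raise GroupingError("both groups need >= 2 samples")
    pvals = np.array([
        rank_sum_p(features.values[a, j], features.values[b, j],
                   exact_max=exact_max)
        for j in range(len(features.feature_ids))
    ])
    table = pd.DataFrame({"feature_id": features.feature_ids, "p_value": pvals})
    keep = [f for f, p in zip(features.feature_ids, pvals) if p <= alpha]
    if keep:
        kept = features.subset_features(keep)
    else:
        kept = FeatureMatrix(list(features.sample_ids), [],
                             np.empty((len(features.sample_ids), 0)),
                             features.feature_kind)
    return kept, table


def default_subset_sizes(n_features: int) -> list[int]:
    sizes = []
    s = 1
    while s < n_features:
        sizes.append(s)
        s *= 2
    sizes.append(n_features)
    return sizes


def rfe_select(features: FeatureMatrix, labels: np.ndarray,
               cfg: RFEConfig | None = None) -> Signature:
    """Cross-validated RFE with consensus feature ranking.

    Per fold: fit the random forest on the training split, rank features by
    impurity importance, recursively refit down the subset-size grid and
    record held-out balanced accuracy at every size. The winning size
    maximizes mean held-out balanced accuracy (ties go to the smaller set);
    the returned features are the top-ranked ones under the consensus (mean
    across folds) elimination rank.
    """
    cfg = cfg or RFEConfig()
    p = len(features.feature_ids)
    if p < 1:
        raise ValueError("no features to select from")
    if p == 1:
        return Signature(list(features.feature_ids), np.ones(1),
                         cv_folds=cfg.cv_folds, seed=cfg.seed,
                         provenance={"note": "single feature, RFE skipped"})
    labels = np.asarray(labels)
    _two_groups(labels)

    sizes = sorted(set(cfg.subset_sizes or default_subset_sizes(p)))
    clipped = [s for s in sizes if s > p]
    if clipped:
        warnings.warn(f"subset sizes {clipped} exceed feature count {p}; "
                      "clipped", stacklevel=2)
        sizes = sorted({min(s, p) for s in sizes})
    sizes_desc = sorted(sizes, reverse=True)
    if sizes_desc[0] != p:
        sizes_desc = [p] + sizes_desc

    _, counts = np.unique(labels, return_counts=True)
    folds = min(cfg.cv_folds, int(counts.min()))
    if folds < cfg.cv_folds:
        warnings.warn(f"reducing cv_folds {cfg.cv_folds} -> {folds} "
                      "(smallest class size)", stacklevel=2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)

    X, y = features.values, labels
    rank_acc = np.zeros(p)            # consensus elimination rank per feature
    imp_acc = np.zeros(p)             # mean importance in the full-size fit
    acc_by_size: dict[int, list[float]] = {s: [] for s in sizes_desc}

    for fold_i, (tr, te) in enumerate(skf.split(X, y)):
        active = np.arange(p)
        fold_rank = np.empty(p)
        for size_i, size in enumerate(sizes_desc):
            rf = RandomForestClassifier(
                n_estimators=cfg.n_trees, n_jobs=1,
                random_state=(cfg.seed * 1009 + fold_i) % (2 ** 31),
            )
            rf.fit(X[np.ix_(tr, active)], y[tr])
            acc = balanced_accuracy_score(y[te], rf.predict(X[np.ix_(te, active)]))
            acc_by_size[size].append(acc)
            imp = rf.feature_importances_
            if size_i == 0:
                imp_acc[active] += imp
            order = np.argsort(-imp, kind="stable")  # best first
            if size_i + 1 < len(sizes_desc):
                next_size = sizes_desc[size_i + 1]
                # dropped features get worse (higher) rank than survivors
                for j, f in enumerate(active[order]):
                    if j >= next_size:
                        fold_rank[f] = j + 1
                active = np.sort(active[order[:next_size]])
            else:
                for j, f in enumerate(active[order]):
                    fold_rank[f] = j + 1
        rank_acc += fold_rank

    mean_rank = rank_acc / folds
    mean_imp = imp_acc / folds
    mean_acc = {s: float(np.mean(v)) for s, v in acc_by_size.items()}
    best_size = min(
        (s for s in mean_acc),
        key=lambda s: (-round(mean_acc[s], 12), s),
    )
    order = np.lexsort((np.arange(p), mean_rank))  # rank asc, index tiebreak
    selected = order[:best_size]
    sel_ids = [features.feature_ids[i] for i in selected]
    return Signature(
        feature_ids=sel_ids,
        importance=mean_imp[selected],
        cv_folds=folds, seed=cfg.seed,
        provenance={
            "estimator": cfg.estimator, "n_trees": cfg.n_trees,
            "subset_sizes": sizes_desc, "mean_cv_accuracy": mean_acc,
            "best_size": int(best_size),
            "consensus_rank": {features.feature_ids[i]: float(mean_rank[i])
                               for i in selected},
            "input_hash": features.content_hash(),
        },
    )


def generalized_fold_change(
    values: np.ndarray,
    labels: np.ndarray,
    case_label,
    quantile_grid=DEFAULT_QUANTILE_GRID,
) -> float:
    """gFC: mean over the quantile grid of Q_case(q) - Q_control(q).

    Quantiles use linear interpolation. Positive values mean enrichment in
    the case group.
    """
    grid = np.asarray(quantile_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("quantile grid must be non-empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("quantile grid values must lie in (0, 1)")
    labels = np.asarray(labels)
    case = np.asarray(values)[labels == case_label]
    ctrl = np.asarray(values)[labels != case_label]
    if len(case) < 2 or len(ctrl) < 2:
        raise GroupingError("both groups need >= 2 samples")
    qc = np.quantile(case, grid)
    qk = np.quantile(ctrl, grid)
    return float(np.mean(qc - qk))


def assemble_signature(
    filtered: FeatureMatrix,
    rfe: Signature,
    labels: np.ndarray,
    case_label,
    alpha: float = 0.05,
    quantile_grid=DEFAULT_QUANTILE_GRID,
) -> Signature:
    """Annotate an RFE signature with per-feature gFC and full provenance."""
    missing = [f for f in rfe.feature_ids if f not in set(filtered.feature_ids)]
    if missing:
        raise KeyError(f"signature features missing from matrix: {missing}")
    gfc = np.array([
        generalized_fold_change(
            filtered.values[:, filtered.feature_ids.index(f)], labels,
            case_label, quantile_grid)
        for f in rfe.feature_ids
    ])
    prov = dict(rfe.provenance)
    prov.update({
        "case_label": str(case_label),
        "quantile_grid": [float(q) for q in quantile_grid],
        "input_hash": filtered.content_hash(),
        "feature_kind": filtered.feature_kind,
    })
    return Signature(list(rfe.feature_ids), rfe.importance.copy(), gfc=gfc,
                     alpha=alpha, cv_folds=rfe.cv_folds, seed=rfe.seed,
                     provenance=prov)
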