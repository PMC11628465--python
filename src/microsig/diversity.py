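"""Beta-diversity evaluation: Bray-Curtis, PCoA, PERMANOVA and the
per-sample distance-to-reference statistic used for signature transfer.

Bray-Curtis dissimilarity BC(x, y) = 1 - 2 sum_i min(x_i, y_i) /
sum_i (x_i + y_i) lies in [0, 1] on nonnegative data (0 = identical
composition, 1 = disjoint support). PCoA is classical scaling of the
dissimilarity matrix; PERMANOVA partitions the squared dissimilarities into
between- and within-group components and assesses the pseudo-F statistic by
label permutation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .selection import FeatureMatrix, GroupingError, Signature, rank_sum_p


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class Ordination:
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variance: np.ndarray  # per returned axis, % of positive-eigenvalue sum


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class SignatureDistanceResult:
    """Per-query-sample mean Bray-Curtis distance to a reference cohort."""

    sample_ids: list[str]
    distances: np.ndarray
    groups: list[str]
    reference_id: str = ""
    signature_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "distance": self.distances,
                             "group": self.groups})


def _bray_curtis_pairs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """BC between every row of A and every row of B (dense, vectorized)."""
    num = np.minimum(A[:, None, :], B[None, :, :]).sum(axis=2)
    den = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = 1.0 - 2.0 * num / den
    if np.isnan(bc).any():
        warnings.warn("both-zero sample pair(s); Bray-Curtis set to 0",
                      stacklevel=3)
        bc = np.nan_to_num(bc, nan=0.0)
    return bc


def bray_curtis(features: FeatureMatrix) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarity of the sample rows.

    A pair of all-zero samples has an undefined (0/0) dissimilarity; it is
    defined as 0 with a warning so batch runs do not abort.
    """
    X = features.values
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires nonnegative data")
    zero_rows = X.sum(axis=1) == 0
    if zero_rows.sum() >= 2 or (zero_rows.sum() == 1 and X.shape[0] > 1):
        # scipy emits nan for 0/0 pairs; handle explicitly
        D = _bray_curtis_pairs(X, X)
        np.fill_diagonal(D, 0.0)
    else:
        D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(list(features.sample_ids), D)


def pcoa(dist: DistanceMatrix, k: int | None = None) -> Ordination:
    """Classical scaling (principal coordinates analysis).

    Double-centers -1/2 D^2, eigendecomposes, and returns coordinates
    eigvec * sqrt(eigval) on the positive-eigenvalue axes. Negative
    eigenvalues (Bray-Curtis is generally non-Euclidean) are reported but
    not corrected; % variance is taken over positive eigenvalues only.
    """
    D = dist.values
    n = D.shape[0]
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValueError("k must be <= n - 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(initial=0.0), 1.0) * 1e-12
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalue(s); returning "
                      f"{n_pos} axes instead of {k}", stacklevel=2)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pos_sum = evals[:n_pos].sum()
    pct = 100.0 * evals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return Ordination(coordinates=coords, eigenvalues=evals, pct_variance=pct)


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_within, SS_total) from squared distances for given labels."""
    n = D2.shape[0]
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        m = labels == g
        ng = int(m.sum())
        ss_within += D2[np.ix_(m, m)].sum() / (2.0 * ng)
    return ss_within, ss_total


def permanova(dist: DistanceMatrix, labels, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    R^2 = SS_between / SS_total; pseudo-F = (SS_between/(g-1)) /
    (SS_within/(n-g)); the p-value is (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations) under seeded free label permutation.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise GroupingError("need >= 2 groups")
    if counts.min() < 2:
        raise GroupingError("every group needs >= 2 samples")
    D2 = dist.values ** 2
    n, g = D2.shape[0], len(groups)

    def pseudo_f(lab):
        ss_w, ss_t = _permanova_ss(D2, lab)
        ss_b = ss_t - ss_w
        return (ss_b / (g - 1)) / (ss_w / (n - g)), ss_b / ss_t

    f_obs, r2 = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = pseudo_f(rng.permutation(labels))
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(r_squared=float(r2), pseudo_f=float(f_obs),
                           p_value=float(p), n_permutations=n_permutations,
                           seed=seed)


def permanova_exact(dist: DistanceMatrix, labels) -> PermanovaResult:
    """PERMANOVA with full enumeration of the distinct label arrangements.

    Feasible for small n; the p-value is the exact fraction of arrangements
    (including the observed one) whose pseudo-F meets or exceeds the
    observed statistic.
    """
    from itertools import permutations as _perms

    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or counts.min() < 2:
        raise GroupingError("need >= 2 groups with >= 2 samples each")
    D2 = dist.values ** 2
    n, g = D2.shape[0], len(groups)

    def pseudo_f(lab):
        ss_w, ss_t = _permanova_ss(D2, lab)
        ss_b = ss_t - ss_w
        return (ss_b / (g - 1)) / (ss_w / (n - g)), ss_b / ss_t

    f_obs, r2 = pseudo_f(labels)
    arrangements = set(_perms(labels.tolist()))
    hits = sum(1 for a in arrangements
               if pseudo_f(np.array(a))[0] >= f_obs - 1e-12)
    return PermanovaResult(r_squared=float(r2), pseudo_f=float(f_obs),
                           p_value=hits / len(arrangements),
                           n_permutations=len(arrangements), seed=0)


def apply_signature(signature: Signature, features: FeatureMatrix) -> FeatureMatrix:
    """Restrict a feature matrix to the signature's features (its order,
    original values, no renormalization)."""
    if not signature.feature_ids:
        raise ValueError("signature is empty")
    missing = [f for f in signature.feature_ids
               if f not in set(features.feature_ids)]
    if missing:
        raise KeyError(f"signature features missing from matrix: {missing}")
    return features.subset_features(list(signature.feature_ids))


def distance_to_reference(
    features: FeatureMatrix,
    query_ids: list[str],
    reference_ids: list[str],
    groups: dict[str, str] | None = None,
    reference_id: str = "",
    signature_id: str = "",
) -> SignatureDistanceResult:
    """Mean Bray-Curtis distance of each query sample to a reference cohort.

    For every query sample the statistic is the mean of its pairwise
    Bray-Curtis dissimilarities to all reference samples, computed on the
    (typically signature-restricted) feature matrix.
    """
    if not reference_ids or len(reference_ids) < 2:
        raise GroupingError("reference needs >= 2 samples")
    overlap = set(query_ids) & set(reference_ids)
    if overlap:
        raise GroupingError(f"query and reference overlap: {sorted(overlap)}")
    idx = {s: i for i, s in enumerate(features.sample_ids)}
    Q = features.values[[idx[s] for s in query_ids]]
    R = features.values[[idx[s] for s in reference_ids]]
    bc = _bray_curtis_pairs(Q, R)
    grp = [groups.get(s, "") if groups else "" for s in query_ids]
    return SignatureDistanceResult(list(query_ids), bc.mean(axis=1), grp,
                                   reference_id=reference_id,
                                   signature_id=signature_id)


def compare_group_distances(result: SignatureDistanceResult) -> pd.DataFrame:
    """Pairwise two-sided unpaired Wilcoxon tests between the distance
    distributions of the query groups (unadjusted p-values)."""
    groups = sorted(set(result.groups))
    if len(groups) < 2:
        raise GroupingError("need >= 2 query groups")
    garr = np.asarray(result.groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = result.distances[garr == groups[i]]
            b = result.distances[garr == groups[j]]
            if len(a) < 2 or len(b) < 2:
                raise GroupingError("every compared group needs >= 2 samples")
            rows.append({"group_a": groups[i], "group_b": groups[j],
                         "n_a": len(a), "n_b": len(b),
                         "p_value": rank_sum_p(a, b)})
    return pd.DataFrame(rows)
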