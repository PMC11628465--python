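"""Species-level count-table normalization and filtering.

The pipeline consumes taxa count tables produced upstream by any amplicon
workflow (samples as rows, taxa as columns). Counts are total-sum scaled to
relative abundances, then low-prevalence and low-abundance taxa are removed
and rows re-normalized so that beta-diversity operates on compositions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyTableError(ValueError):
    """Filtering removed every taxon."""


@dataclass
class TaxaTable:
    """Samples x taxa abundance matrix with a processing-stage tag."""

    sample_ids: list[str]
    taxon_labels: list[str]
    values: np.ndarray
    stage: str = "counts"  # counts | relative | filtered

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_labels)):
            raise ValueError("matrix shape does not match ids/labels")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ValueError("duplicate taxon labels")
        if np.any(self.values < 0):
            raise ValueError("abundances must be nonnegative")
        if self.stage in ("relative", "filtered"):
            sums = self.values.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0))
            if bad.any():
                raise ValueError("relative table rows must sum to 1 "
                                 "(all-zero rows are allowed but flagged)")
            if (sums == 0).any():
                logger.warning("%d all-zero row(s) in %s-stage table",
                               int((sums == 0).sum()), self.stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.taxon_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage: str = "counts") -> "TaxaTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float), stage=stage)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, stage: str = "counts") -> "TaxaTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(df, stage=stage)


def normalize_total(counts: TaxaTable) -> TaxaTable:
    """Total-sum scaling: divide each sample's counts by its library size.

    Zero-sum samples cannot be scaled; they are excluded with a warning.
    """
    if counts.stage != "counts":
        raise ValueError("normalize_total expects a counts-stage table")
    sums = counts.values.sum(axis=1)
    keep = sums > 0
    if not keep.all():
        dropped = [s for s, k in zip(counts.sample_ids, keep) if not k]
        logger.warning("excluding %d zero-sum sample(s): %s",
                       len(dropped), dropped)
    vals = counts.values[keep] / sums[keep, None]
    ids = [s for s, k in zip(counts.sample_ids, keep) if k]
    return TaxaTable(ids, list(counts.taxon_labels), vals, stage="relative")


def filter_prevalence_abundance(
    rel: TaxaTable,
    prevalence_min: float = 0.05,
    abundance_min: float = 1e-4,
    abundance_rule: str = "mean",
) -> TaxaTable:
    """Drop rare and low-abundance taxa, then re-normalize rows.

    A taxon is kept when it is present (>0) in at least ``prevalence_min``
    of the samples and its mean (or, with ``abundance_rule='max'``, maximum)
    relative abundance is at least ``abundance_min`` (defaults: 5%
    prevalence, 0.01% abundance).
    """
    if rel.stage != "relative":
        raise ValueError("filter expects a relative-stage table")
    if abundance_rule not in ("mean", "max"):
        raise ValueError("abundance_rule must be 'mean' or 'max'")
    prevalence = (rel.values > 0).mean(axis=0)
    level = (rel.values.mean(axis=0) if abundance_rule == "mean"
             else rel.values.max(axis=0))
    keep = (prevalence >= prevalence_min) & (level >= abundance_min)
    if not keep.any():
        raise EmptyTableError("all taxa removed by prevalence/abundance filter")
    vals = rel.values[:, keep]
    sums = vals.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning("%d sample(s) have zero retained abundance", zero.sum())
        sums[zero] = 1.0
    vals = vals / sums[:, None]
    labels = [t for t, k in zip(rel.taxon_labels, keep) if k]
    return TaxaTable(list(rel.sample_ids), labels, vals, stage="filtered")
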