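"""Rarity cutoffs, biosphere partitioning, and rarity-type classification.

The rare biosphere of a sample is the set of taxa whose relative abundance
is no greater than a rarity cutoff; everything detected above the cutoff is
the common biosphere.  Cutoffs are either fixed fractions (the conventional
0.2% / 0.1% / 0.05% set) or sample-specific, derived from the rank abundance
curve by an h-index-style crossing rule and optionally recalibrated by
sampling completeness (S_obs / S_chao1).

Across samples, every detected ASV is then classified into one of four
rarity/commonness types:

* permanently_common  -- detected and common in every sample
* conditionally_rare_common -- common in at least one sample, rare in at
  least one other (or common somewhere and merely undetected elsewhere)
* permanently_rare    -- never common, rare in two or more samples
* transiently_rare    -- never common, rare in exactly one sample
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import FeatureTable, ValidationError, chao1

logger = logging.getLogger("rarescape")

DEFAULT_CUTOFFS = (0.002, 0.001, 0.0005)  # 0.2%, 0.1%, 0.05%

RARITY_TYPES = (
    "permanently_rare",
    "transiently_rare",
    "conditionally_rare_common",
    "permanently_common",
)


@dataclass(frozen=True)
class CutoffSpec:
    """Provenance-carrying rarity cutoff.

    ``mode`` is ``"fixed"`` (one fraction for all samples) or
    ``"sample_specific"`` (per-sample fractions from the rank-abundance
    crossing rule).  ``recalibration`` records whether sample-specific
    values were shrunk by the completeness ratio S_obs/S_chao1.
    """

    mode: str  # "fixed" | "sample_specific"
    value: float | None = None
    per_sample_values: dict | None = None
    recalibration: str = "none"  # "none" | "completeness_ratio"

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.value is None or not (0 < self.value < 1):
                raise ValueError("fixed cutoff must satisfy 0 < value < 1")
        elif self.mode == "sample_specific":
            if not self.per_sample_values:
                raise ValueError("sample_specific cutoff needs per_sample_values")
            if any(v <= 0 for v in self.per_sample_values.values()):
                raise ValueError("per-sample cutoffs must be positive")
        else:
            raise ValueError(f"unknown cutoff mode {self.mode!r}")

    def for_sample(self, sample_id) -> float:
        if self.mode == "fixed":
            return self.value
        return self.per_sample_values[sample_id]


@dataclass(frozen=True)
class BiospherePartition:
    """Rare/common split of a feature table under one cutoff.

    ``rare_table + common_table`` reconstructs the input entrywise; every
    detected ASV-sample occurrence sits in exactly one component.
    """

    rare_table: FeatureTable
    common_table: FeatureTable
    cutoff: CutoffSpec

    @property
    def sample_ids(self) -> pd.Index:
        return self.rare_table.sample_ids


def partition_biospheres(table: FeatureTable, cutoff: CutoffSpec) -> BiospherePartition:
    """Split each sample into rare (0 < rel. abundance <= cutoff) and
    common (rel. abundance > cutoff) components.

    The boundary is inclusive on the rare side: a taxon exactly at the
    cutoff is rare.  Requires a rarefied table so relative abundance is
    count / depth.
    """
    if not table.is_rarefied:
        raise ValidationError("partitioning requires a rarefied table")
    rel = table.counts / table.depth
    thresholds = pd.Series(
        {s: cutoff.for_sample(s) for s in table.sample_ids}, dtype=float
    )
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("cutoffs must lie strictly inside (0, 1)")
    rare_mask = (rel.gt(0)) & (rel.le(thresholds, axis=1))
    common_mask = rel.gt(thresholds, axis=1)
    rare = table.counts.where(rare_mask, 0)
    common = table.counts.where(common_mask, 0)
    return BiospherePartition(
        rare_table=FeatureTable(rare, is_rarefied=False),
        common_table=FeatureTable(common, is_rarefied=False),
        cutoff=cutoff,
    )


def sample_specific_cutoff(sample_counts, recalibrate: bool = False) -> float:
    """Rank-abundance crossing cutoff for one sample, as a fraction.

    Counts are sorted descending; the raw cutoff count h* is the abundance
    at the first rank r whose abundance is <= r (the h-index crossing).
    The returned fraction is h*/total, optionally multiplied by the
    completeness ratio S_obs/S_chao1 (shrinking the cutoff for
    under-sampled communities).
    """
    v = np.asarray(sample_counts)
    v = v[v > 0]
    if v.size == 0:
        raise ValidationError("sample has no positive counts")
    total = int(v.sum())
    desc = np.sort(v)[::-1]
    ranks = np.arange(1, desc.size + 1)
    crossing = np.nonzero(desc <= ranks)[0]
    if crossing.size == 0:
        logger.warning(
            "no rank-abundance crossing found; falling back to smallest abundance"
        )
        h_star = int(desc[-1])
    else:
        h_star = int(desc[crossing[0]])
    frac = h_star / total
    if recalibrate:
        s_obs = desc.size
        frac *= s_obs / chao1(v)
    return frac


def sample_specific_cutoffs(table: FeatureTable, recalibrate: bool = True) -> CutoffSpec:
    """Per-sample crossing cutoffs for every sample of a table."""
    values = {
        s: sample_specific_cutoff(table.counts[s].to_numpy(), recalibrate=recalibrate)
        for s in table.sample_ids
    }
    return CutoffSpec(
        mode="sample_specific",
        per_sample_values=values,
        recalibration="completeness_ratio" if recalibrate else "none",
    )


@dataclass(frozen=True)
class RarityTypeAssignment:
    """Per-ASV rarity/commonness labels plus edge-case flags."""

    labels: pd.Series  # ASV -> type
    flagged: tuple = ()  # ASVs labelled by the common-or-absent fallback rule

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(RARITY_TYPES, fill_value=0)


def classify_rarity_types(partition: BiospherePartition) -> RarityTypeAssignment:
    """Classify every detected ASV into one of the four rarity types.

    ASVs that are common in some samples and absent (undetected) in all
    others — a case the four rules do not cover — are labelled
    conditionally_rare_common, treating sub-detection absence as rarity,
    and reported in ``flagged``.
    """
    rare = partition.rare_table.counts
    common = partition.common_table.counts
    if rare.shape[1] < 2:
        raise ValidationError("rarity-type classification needs >= 2 samples")
    n_rare = (rare > 0).sum(axis=1)
    n_common = (common > 0).sum(axis=1)
    n_samples = rare.shape[1]
    detected = (n_rare + n_common) > 0
    if (~detected).any():
        logger.warning(
            "%d ASV(s) never detected; excluded from typing", int((~detected).sum())
        )
    n_rare, n_common = n_rare[detected], n_common[detected]

    labels = pd.Series(index=n_rare.index, dtype=object)
    labels[n_common == n_samples] = "permanently_common"
    labels[(n_common >= 1) & (n_rare >= 1)] = "conditionally_rare_common"
    labels[(n_common == 0) & (n_rare >= 2)] = "permanently_rare"
    labels[(n_common == 0) & (n_rare == 1)] = "transiently_rare"
    fallback = (n_common >= 1) & (n_rare == 0) & (n_common < n_samples)
    labels[fallback] = "conditionally_rare_common"
    return RarityTypeAssignment(labels=labels, flagged=tuple(labels.index[fallback]))


def rare_fraction(partition: BiospherePartition) -> float:
    """Total relative abundance captured by the rare biosphere."""
    total = (
        partition.rare_table.counts.to_numpy().sum()
        + partition.common_table.counts.to_numpy().sum()
    )
    return partition.rare_table.counts.to_numpy().sum() / total
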