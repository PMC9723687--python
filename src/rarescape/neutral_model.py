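"""Sloan neutral community model: fit, prediction, and deviation typing.

Under neutral birth-death-immigration dynamics, the probability that a
taxon with mean metacommunity relative abundance p is detected (at or
above a detection limit of d reads) in a local community of N_T reads is

    F(p) = 1 - BetaCDF(d / N_T; N_T m p, N_T m (1 - p))

where m is the migration (immigration) probability.  m is estimated by
least squares of observed occurrence frequencies on F(p) across taxa;
fit quality is the R^2 of that regression.  Each taxon is then classed
as above / within / below the neutral prediction using a binomial
(Wilson) confidence band around F(p) at n = number of samples, and the
classes can be cross-tabulated against rarity types.

The model is meaningful for whole communities; fitting it to rare- or
common-biosphere subsets distorts the occurrence-abundance relationship,
so the pipeline only ever fits the whole table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import FeatureTable, ValidationError
from .rarity import RARITY_TYPES, RarityTypeAssignment

logger = logging.getLogger("rarescape")

DEVIATION_CLASSES = ("above", "within", "below")


def predict_frequency(p, m: float, n_reads: int, detection_limit: int = 1):
    """Neutral expected detection frequency for mean relative abundance p.

    Vectorized over ``p``; monotone non-decreasing in both p and m.
    """
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p must lie strictly inside (0, 1)")
    if m <= 0:
        raise ValueError("migration parameter m must be positive")
    a = n_reads * m * p
    b = n_reads * m * (1.0 - p)
    out = 1.0 - stats.beta.cdf(detection_limit / n_reads, a, b)
    return out if out.shape else float(out)


def _wilson_interval(freq, n: int, level: float = 0.95):
    """Wilson score interval for a proportion ``freq`` observed over n trials."""
    z = stats.norm.ppf(0.5 + level / 2)
    freq = np.asarray(freq, dtype=float)
    denom = 1 + z * z / n
    center = (freq + z * z / (2 * n)) / denom
    half = z * np.sqrt(freq * (1 - freq) / n + z * z / (4 * n * n)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


@dataclass(frozen=True)
class NeutralFit:
    """Fitted neutral model with per-taxon predictions and deviations."""

    m: float
    n_reads: int              # local community size N_T (the rarefaction depth)
    detection_limit: int
    r_squared: float
    per_asv: pd.DataFrame     # p, freq_obs, freq_pred, ci_low, ci_high, deviation

    @property
    def ntm(self) -> float:
        """The composite N_T * m, the scale the model is usually reported on."""
        return self.n_reads * self.m


def fit_sloan(
    table: FeatureTable,
    detection_limit: int = 1,
    ci_level: float = 0.95,
) -> NeutralFit:
    """Fit the neutral model to occurrence frequency vs. mean abundance.

    Requires a rarefied table with at least 5 samples; N_T is fixed to the
    rarefaction depth.  Taxa observed in no sample are dropped.
    """
    if not table.is_rarefied:
        raise ValidationError("neutral fit requires a rarefied table")
    n_samples = table.shape[1]
    if n_samples < 5:
        raise ValidationError("neutral fit needs >= 5 samples")
    table = table.drop_empty_asvs()
    counts = table.counts
    n_reads = int(table.depth)
    p = (counts / n_reads).mean(axis=1).to_numpy()
    freq = (counts >= detection_limit).mean(axis=1).to_numpy()

    def sse(m):
        return float(np.sum(
            (freq - predict_frequency(p, m, n_reads, detection_limit)) ** 2
        ))

    res = optimize.minimize_scalar(
        sse, bounds=(1e-7, 1.0 - 1e-7), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"neutral-model optimization failed: {res.message}")
    m = float(res.x)
    pred = predict_frequency(p, m, n_reads, detection_limit)
    sst = float(np.sum((freq - freq.mean()) ** 2))
    if sst == 0:
        logger.warning("zero variance in occurrence frequencies; R^2 set to 0")
        r2 = 0.0
    else:
        r2 = 1.0 - res.fun / sst
    low, high = _wilson_interval(pred, n_samples, ci_level)
    deviation = np.where(freq > high, "above", np.where(freq < low, "below", "within"))
    per_asv = pd.DataFrame(
        {
            "p": p,
            "freq_obs": freq,
            "freq_pred": pred,
            "ci_low": low,
            "ci_high": high,
            "deviation": deviation,
        },
        index=counts.index,
    )
    return NeutralFit(
        m=m, n_reads=n_reads, detection_limit=detection_limit,
        r_squared=r2, per_asv=per_asv,
    )


def crosstab_deviation_by_type(
    fit: NeutralFit, types: RarityTypeAssignment
) -> pd.DataFrame:
    """Counts of neutral-deviation class x rarity type.

    Rows are deviation classes, columns rarity types; empty classes keep
    zero rows/columns so marginals always match the classified inputs.
    """
    shared = fit.per_asv.index.intersection(types.labels.index)
    if shared.empty:
        raise ValidationError("fit and rarity typing share no ASVs")
    tab = pd.crosstab(
        fit.per_asv.loc[shared, "deviation"], types.labels.loc[shared]
    )
    return tab.reindex(
        index=list(DEVIATION_CLASSES), columns=list(RARITY_TYPES), fill_value=0
    )
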