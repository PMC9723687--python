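"""Bray-Curtis dissimilarity and its abundance-based Raup-Crick
standardization (RC_bray).

For each pair of communities a null distribution of Bray-Curtis values is
built by probabilistically re-assembling both communities from the
metacommunity while preserving each sample's observed richness and read
total: taxon identities are drawn without replacement with probability
proportional to metacommunity occurrence frequency, then the remaining
reads are distributed with replacement proportional to metacommunity
relative abundance.  The observed dissimilarity is ranked against the null
and rescaled to [-1, +1]:

    RC_bray = ( (n_below + 0.5 * n_equal) / n_null - 0.5 ) * 2

RC_bray > +0.95 signals dispersal limitation coupled with drift (more
turnover than the null); RC_bray < -0.95 signals homogenizing dispersal;
values in between are consistent with undominated processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import FeatureTable, ValidationError

logger = logging.getLogger("rarescape")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two empty communities")
    return float(np.abs(x - y).sum() / denom)


@dataclass(frozen=True)
class MetacommunityPool:
    """Occurrence frequencies and relative abundances of the species pool."""

    occurrence: np.ndarray  # per-taxon occurrence probability weights
    abundance: np.ndarray   # per-taxon relative abundance weights
    taxa: pd.Index

    @classmethod
    def from_table(cls, table: FeatureTable) -> "MetacommunityPool":
        counts = table.counts
        occ = (counts > 0).sum(axis=1).to_numpy(dtype=float)
        ab = counts.sum(axis=1).to_numpy(dtype=float)
        return cls(
            occurrence=occ / occ.sum(), abundance=ab / ab.sum(), taxa=counts.index
        )


def _assemble_null_community(
    richness: int,
    reads: int,
    pool: MetacommunityPool,
    rng: np.random.Generator,
    identity_weighting: str = "occurrence",
    fill_weighting: str = "abundance",
) -> np.ndarray:
    """One null community with the given richness and read total."""
    S = pool.taxa.size
    p_id = pool.occurrence if identity_weighting == "occurrence" else None
    chosen = rng.choice(S, size=richness, replace=False, p=p_id)
    out = np.zeros(S, dtype=np.int64)
    out[chosen] = 1  # each drawn taxon is seeded with one read
    remaining = reads - richness
    if remaining > 0:
        if fill_weighting == "abundance":
            w = pool.abundance[chosen]
        else:
            w = np.ones(richness)
        out[chosen] += rng.multinomial(remaining, w / w.sum())
    return out


def rc_bray_pair(
    x,
    y,
    pool: MetacommunityPool,
    n_null: int = 999,
    rng: np.random.Generator | int = 0,
    identity_weighting: str = "occurrence",
    fill_weighting: str = "abundance",
    return_nulls: bool = False,
):
    """(observed BC, RC_bray) for one pair of count vectors.

    With ``return_nulls=True`` the null Bray-Curtis draws are appended to
    the return tuple (useful for auditing the rank statistic).
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x)
    y = np.asarray(y)
    bc_obs = bray_curtis(x, y)
    rich_x, rich_y = int((x > 0).sum()), int((y > 0).sum())
    reads_x, reads_y = int(x.sum()), int(y.sum())
    nulls = np.empty(n_null)
    for i in range(n_null):
        nx = _assemble_null_community(
            rich_x, reads_x, pool, rng, identity_weighting, fill_weighting
        )
        ny = _assemble_null_community(
            rich_y, reads_y, pool, rng, identity_weighting, fill_weighting
        )
        nulls[i] = bray_curtis(nx, ny)
    below = int((nulls < bc_obs).sum())
    equal = int((nulls == bc_obs).sum())
    rc = ((below + 0.5 * equal) / n_null - 0.5) * 2.0
    if return_nulls:
        return bc_obs, rc, nulls
    return bc_obs, rc


@dataclass(frozen=True)
class RCMatrix:
    """Pairwise RC_bray with the observed Bray-Curtis values retained."""

    rc: pd.DataFrame      # N x N, NaN diagonal, values in [-1, +1]
    bc_obs: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        ids = list(self.rc.index)
        rows = []
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                rows.append(
                    {
                        "sample_a": ids[a],
                        "sample_b": ids[b],
                        "bc_obs": self.bc_obs.iat[a, b],
                        "rc_bray": self.rc.iat[a, b],
                    }
                )
        return pd.DataFrame(rows)


def rc_bray(
    table: FeatureTable,
    n_null: int = 999,
    seed: int | np.random.Generator = 0,
    pool: MetacommunityPool | None = None,
    identity_weighting: str = "occurrence",
    fill_weighting: str = "abundance",
) -> RCMatrix:
    """RC_bray for every sample pair of ``table``.

    The metacommunity pool defaults to the analyzed table itself, so when
    the table is a rare- or common-biosphere component the null assembles
    from that component's pool; pass ``pool`` to use an external one.
    The null is simulated independently for each pair (999 replicates by
    default); deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    table = table.drop_empty_asvs()
    counts = table.counts
    if counts.shape[1] < 2:
        raise ValidationError("RC_bray needs at least 2 samples")
    if pool is None:
        pool = MetacommunityPool.from_table(table)
    elif not pool.taxa.equals(counts.index):
        raise ValidationError("pool taxa must match table taxa (same order)")
    N = counts.shape[1]
    C = counts.to_numpy()
    rc = np.full((N, N), np.nan)
    bc = np.full((N, N), np.nan)
    for a in range(N):
        for b in range(a + 1, N):
            bc_obs, rc_val = rc_bray_pair(
                C[:, a], C[:, b], pool, n_null, rng,
                identity_weighting, fill_weighting,
            )
            bc[a, b] = bc[b, a] = bc_obs
            rc[a, b] = rc[b, a] = rc_val
    ids = list(counts.columns)
    return RCMatrix(
        rc=pd.DataFrame(rc, index=ids, columns=ids),
        bc_obs=pd.DataFrame(bc, index=ids, columns=ids),
    )
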