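"""Abundance-weighted betaMNTD and its tip-shuffling standardization (betaNTI).

Between-community mean nearest taxon distance for communities k and m:

    betaMNTD(k, m) = 0.5 * [ sum_i f_ik * min_j D(i, j in m)
                           + sum_i f_im * min_j D(i, j in k) ]

where f_ik is the relative abundance of taxon i in community k and D is
the patristic distance matrix.  betaNTI standardizes the observed value
against a null distribution built by shuffling taxa across the tips of
the phylogeny (999 permutations by default):

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null)

betaNTI < -2 indicates less phylogenetic turnover than expected
(homogeneous selection); betaNTI > +2 indicates more (variable selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import FeatureTable, ValidationError, cophenetic, prune_tree

logger = logging.getLogger("rarescape")


def _nearest_taxon_matrix(D: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[i, s] = min over taxa j present in sample s of D[i, j].

    D is (S x S); presence is boolean (S x N).  Columns of samples with no
    taxa are left as +inf (caller validates non-empty communities).
    """
    S, N = presence.shape
    M = np.full((S, N), np.inf)
    for s in range(N):
        idx = np.flatnonzero(presence[:, s])
        if idx.size:
            M[:, s] = D[:, idx].min(axis=1)
    return M


def _beta_mntd_all_pairs(F: np.ndarray, D: np.ndarray) -> np.ndarray:
    """betaMNTD for every sample pair.

    F is the relative-abundance matrix (S taxa x N samples, columns sum
    to 1); returns a symmetric (N x N) matrix with zero diagonal only if
    each sample's nearest taxon in itself is itself (always true since
    D has zero diagonal).
    """
    M = _nearest_taxon_matrix(D, F > 0)
    # G[k, m] = sum_i f_ik * min_j-in-m D(i, j): directed turnover of k onto m
    G = F.T @ M
    return 0.5 * (G + G.T)


def beta_mntd(f_k: pd.Series, f_m: pd.Series, D: pd.DataFrame) -> float:
    """betaMNTD for one pair of communities.

    ``f_k`` and ``f_m`` map taxon -> abundance (any positive scale; each is
    renormalized to sum to 1 over its positive entries); ``D`` is the
    cophenetic matrix covering all the pair's taxa.
    """
    f_k = f_k[f_k > 0]
    f_m = f_m[f_m > 0]
    if f_k.empty or f_m.empty:
        raise ValidationError("betaMNTD undefined for an empty community")
    taxa = f_k.index.union(f_m.index)
    missing = taxa.difference(D.index)
    if len(missing):
        raise ValidationError(f"taxa absent from distance matrix: {list(missing)[:5]}")
    F = pd.DataFrame(0.0, index=taxa, columns=["k", "m"])
    F.loc[f_k.index, "k"] = (f_k / f_k.sum()).to_numpy()
    F.loc[f_m.index, "m"] = (f_m / f_m.sum()).to_numpy()
    sub = D.loc[taxa, taxa].to_numpy(dtype=float)
    return float(_beta_mntd_all_pairs(F.to_numpy(), sub)[0, 1])


@dataclass(frozen=True)
class BetaNTIMatrix:
    """Pairwise betaNTI with the per-pair null summaries retained for audit."""

    bnti: pd.DataFrame        # N x N, NaN diagonal
    bmntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered sample pair."""
        ids = list(self.bnti.index)
        rows = []
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                rows.append(
                    {
                        "sample_a": ids[a],
                        "sample_b": ids[b],
                        "bmntd_obs": self.bmntd_obs.iat[a, b],
                        "null_mean": self.null_mean.iat[a, b],
                        "null_sd": self.null_sd.iat[a, b],
                        "bnti": self.bnti.iat[a, b],
                    }
                )
        return pd.DataFrame(rows)


def beta_nti(
    table: FeatureTable,
    tree_or_D,
    n_null: int = 999,
    seed: int | np.random.Generator = 0,
    weighted: bool = True,
    prune: bool = True,
) -> BetaNTIMatrix:
    """betaNTI for every pair of samples in ``table``.

    The null shuffles the taxon -> tip assignment; one permutation per
    null replicate is shared across all pairs.  By default the shuffle is
    restricted to the taxa present in the analyzed table (pruned tree),
    preserving null richness and abundance structure exactly.  Relative
    abundances are renormalized within the analyzed table, so when the
    table is a rare- or common-biosphere component each community's f sums
    to 1 within that component.

    Pass ``weighted=False`` for the presence/absence variant (every present
    taxon gets equal weight).
    """
    rng = np.random.default_rng(seed)
    table = table.drop_empty_asvs()
    counts = table.counts
    if (counts.sum(axis=0) == 0).any():
        raise ValidationError("every sample must contain at least one taxon")

    if isinstance(tree_or_D, pd.DataFrame):
        D_full = tree_or_D
    else:
        tree = prune_tree(tree_or_D, counts.index) if prune else tree_or_D
        D_full = cophenetic(tree)
    missing = counts.index.difference(D_full.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} table taxa missing from tree/distances"
        )
    order = counts.index if prune else D_full.index
    # keep the shuffle universe = analyzed taxa under prune, full tree otherwise
    order = order.intersection(D_full.index) if prune else order
    D = D_full.loc[order, order].to_numpy(dtype=float)
    C = counts.reindex(order, fill_value=0).to_numpy(dtype=float)
    if not weighted:
        C = (C > 0).astype(float)
    F = C / C.sum(axis=0)

    obs = _beta_mntd_all_pairs(F, D)
    S = D.shape[0]
    mean_acc = np.zeros_like(obs)
    m2_acc = np.zeros_like(obs)
    for r in range(1, n_null + 1):
        perm = rng.permutation(S)
        null = _beta_mntd_all_pairs(F, D[np.ix_(perm, perm)])
        delta = null - mean_acc
        mean_acc += delta / r
        m2_acc += delta * (null - mean_acc)
    sd = np.sqrt(m2_acc / (n_null - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean_acc) / sd
    degenerate = sd == 0
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        logger.warning(
            "%d pair(s) with zero null sd; betaNTI set to NaN",
            int(degenerate.sum()) // 2,
        )
        z[degenerate] = np.nan
    np.fill_diagonal(z, np.nan)

    ids = list(counts.columns)
    wrap = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return BetaNTIMatrix(
        bnti=wrap(z), bmntd_obs=wrap(obs), null_mean=wrap(mean_acc), null_sd=wrap(sd)
    )
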