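"""Ordination and permutation statistics on community distance matrices.

Classical principal coordinate analysis (metric MDS) on Bray-Curtis or
Jaccard distances, and one-factor PERMANOVA with the usual pseudo-F
permutation test.  Both operate on plain symmetric distance matrices, so
they compose with any metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import FeatureTable

logger = logging.getLogger("rarescape")


def distance_matrix(table: FeatureTable, metric: str = "bray_curtis") -> pd.DataFrame:
    """Pairwise sample distances (``bray_curtis`` or ``jaccard``)."""
    X = table.counts.to_numpy().T.astype(float)
    if metric == "bray_curtis":
        d = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        d = pdist(X > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ids = list(table.sample_ids)
    return pd.DataFrame(squareform(d), index=ids, columns=ids)


def _check_square_symmetric(D: pd.DataFrame | np.ndarray) -> np.ndarray:
    A = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return A


@dataclass(frozen=True)
class PCoAResult:
    """Coordinates, the full eigenvalue spectrum, and axis percentages."""

    coordinates: pd.DataFrame       # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # lambda_i / sum(positive lambda), per axis


def pcoa(D: pd.DataFrame) -> PCoAResult:
    """Classical scaling of a distance matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and returns coordinates
    scaled by sqrt(eigenvalue) for the positive axes.  Negative
    eigenvalues (non-Euclidean input) are reported in ``eigenvalues``
    rather than silently dropped; axis percentages are relative to the
    positive part of the spectrum.
    """
    A = _check_square_symmetric(D)
    n = A.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least 2 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (A ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.max() > 0 else np.zeros(n, bool)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    ids = list(D.index) if isinstance(D, pd.DataFrame) else list(range(n))
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=vals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(pseudo-F, R^2) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    f = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    D: pd.DataFrame,
    groups,
    n_permutations: int = 9999,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within pools the analogous
    within-group sums; pseudo-F compares among- to within-group mean
    squares and the p-value counts label permutations with F >= F_obs,
    including the observed statistic ("add one" convention).
    """
    A = _check_square_symmetric(D)
    groups = np.asarray(
        pd.Series(list(groups)).to_numpy()
    )
    if len(groups) != A.shape[0]:
        raise ValueError("group labels must match matrix size")
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if pd.Series(codes).value_counts().min() < 1:
        raise ValueError("every group needs >= 1 sample")
    d2 = A ** 2
    f_obs, r2 = _permanova_stats(d2, codes, len(uniques))
    rng = np.random.default_rng(seed)
    hits = 1  # the observed statistic counts as one permutation
    for _ in range(n_permutations):
        f_perm, _ = _permanova_stats(d2, rng.permutation(codes), len(uniques))
        if f_perm >= f_obs:
            hits += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=hits / (n_permutations + 1),
        n_permutations=n_permutations,
    )
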