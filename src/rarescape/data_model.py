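"""Input artifacts and their basic transformations.

The pipeline consumes three artifacts: an ASV-by-sample count table, a
sample metadata table describing the sampling design (successional stage
x sampling time x replicate), and a rooted phylogenetic tree with branch
lengths covering the ASVs.  This module reads and cross-validates them,
rarefies counts to a uniform depth, and provides the richness estimator
(Chao1) and the patristic (cophenetic) distance matrix that downstream
stages need.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("rarescape")

#: tokens in the first header cell that mark a taxa-by-samples orientation
_TAXA_ROW_TOKENS = {
    "#otu id", "otu id", "otu_id", "#asv id", "asv id", "asv_id", "asv",
    "feature id", "feature_id", "featureid", "taxon", "taxon_id", "",
}
#: tokens that mark a samples-by-taxa orientation (table gets transposed)
_SAMPLE_ROW_TOKENS = {"sample", "sample_id", "sampleid", "sample id"}

REQUIRED_METADATA_COLUMNS = ("sample_id", "stage", "time", "replicate")


class ValidationError(ValueError):
    """An input artifact violates a structural contract."""


@dataclass(frozen=True)
class FeatureTable:
    """ASV x sample count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, rows indexed by ASV id, columns by
        sample id.
    is_rarefied : bool
        True when every column sums to ``depth``.
    depth : int or None
        Reads per sample when rarefied.
    """

    counts: pd.DataFrame
    is_rarefied: bool = False
    depth: int | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate ASV ids in feature table")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in feature table")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("feature table contains non-integer counts")
            object.__setattr__(self, "counts", c.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("feature table contains negative counts")
        if self.is_rarefied:
            sums = arr.sum(axis=0)
            if self.depth is None or not (sums == self.depth).all():
                raise ValidationError(
                    "rarefied table must have every column summing to depth"
                )

    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.counts.sum(axis=0)
        if (sums == 0).any():
            raise ValidationError("cannot normalize a sample with zero total")
        return self.counts / sums

    def drop_empty_asvs(self) -> "FeatureTable":
        keep = self.counts.sum(axis=1) > 0
        return replace(self, counts=self.counts.loc[keep])

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return replace(self, counts=self.counts.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Sampling design: one row per sample with stage/time/replicate labels."""

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        for col in ("stage", "time", "replicate"):
            if col not in self.frame.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        if self.frame.index.has_duplicates:
            raise ValidationError("duplicate sample_id in metadata")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def validate_against(self, table: FeatureTable) -> None:
        missing = table.sample_ids.difference(self.frame.index)
        if len(missing):
            raise ValidationError(
                "samples absent from metadata: " + ", ".join(map(str, missing))
            )


# ---------------------------------------------------------------------------
# readers


def read_feature_table(path_or_buf) -> FeatureTable:
    """Read a TSV feature table (rows = ASVs, columns = samples).

    BIOM-TSV dialect comment lines (``# Constructed from biom file``) are
    skipped.  If the first header token names a sample axis the table is
    transposed, with a log message.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    lines = [
        ln for ln in text.splitlines()
        if not (ln.startswith("#") and "constructed from biom" in ln.lower())
    ]
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0)
    token = (df.index.name or "").strip().lower()
    if token in _SAMPLE_ROW_TOKENS:
        logger.info("feature table recognized as samples-by-taxa; transposing")
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(counts=df)


def read_metadata(path_or_buf) -> SampleMetadata:
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a sample_id column")
    return SampleMetadata(frame=df.set_index("sample_id"))


def read_tree(path_or_buf) -> TreeNode:
    tree = TreeNode.read(path_or_buf, format="newick")
    for tip in tree.tips():
        if tip.name is None:
            raise ValidationError("tree contains an unlabeled tip")
        if tip.length is None:
            raise ValidationError(f"tip {tip.name!r} lacks a branch length")
    return tree


def load_dataset(
    feature_path,
    metadata_path,
    tree_path,
    missing_tip_policy: str = "warn",
) -> tuple[FeatureTable, SampleMetadata, TreeNode]:
    """Read and cross-validate the three input artifacts.

    ``missing_tip_policy`` controls ASVs present in the table but absent
    from the tree: ``"warn"`` keeps them (turnover stages will fail if they
    reach the tree), ``"drop"`` removes them from the table, ``"error"``
    raises.
    """
    table = read_feature_table(feature_path)
    metadata = read_metadata(metadata_path)
    tree = read_tree(tree_path)
    metadata.validate_against(table)
    tip_names = {t.name for t in tree.tips()}
    missing = [a for a in table.asv_ids if a not in tip_names]
    if missing:
        msg = f"{len(missing)} ASV(s) in table but not in tree: {missing[:5]}..."
        if missing_tip_policy == "error":
            raise ValidationError(msg)
        logger.warning(msg)
        if missing_tip_policy == "drop":
            table = FeatureTable(counts=table.counts.drop(index=missing))
    return table, metadata, tree


# ---------------------------------------------------------------------------
# rarefaction


def rarefy_table(
    table: FeatureTable, depth: int, seed: int | np.random.Generator = 0
) -> FeatureTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning;
    all-zero ASV rows are removed afterwards.  Deterministic under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    if (totals < depth).all():
        raise ValidationError(f"no sample reaches depth {depth}")
    dropped = list(totals.index[totals < depth])
    if dropped:
        logger.warning(
            "dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    kept = table.counts.loc[:, totals >= depth]
    out = np.empty(kept.shape, dtype=np.int64)
    for j, s in enumerate(kept.columns):
        col = kept[s].to_numpy()
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    result = FeatureTable(
        counts=pd.DataFrame(out, index=kept.index, columns=kept.columns),
        is_rarefied=True,
        depth=depth,
    )
    return result.drop_empty_asvs()


# ---------------------------------------------------------------------------
# richness


def chao1(sample_counts) -> float:
    """Chao1 estimated richness from singleton/doubleton counts.

    ``S_obs + F1^2 / (2 F2)``; when no doubletons exist the bias-corrected
    form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` is used.  Always >= S_obs.
    """
    v = np.asarray(sample_counts)
    if (v < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((v > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


# ---------------------------------------------------------------------------
# tree distances


def cophenetic(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix (sum of branch lengths on path)."""
    for tip in tree.tips():
        if tip.name is None:
            raise ValidationError("tree contains an unlabeled tip")
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def prune_tree(tree: TreeNode, tip_names) -> TreeNode:
    """Tree restricted to ``tip_names`` (shear), branch lengths preserved."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tree.shear(list(tip_names))
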