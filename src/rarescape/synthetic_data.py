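"""Synthetic communities with known ground-truth assembly regimes.

Emulates the state of an amplicon study after denoising and rarefaction:
a count table over a stage x time x replicate design, a matching
phylogeny, and metadata.  Scenarios wire the generator so a single
assembly process dominates, giving the inference pipeline a known answer
to recover.

The phylogeny is two-level, mirroring the structure of 16S gene trees:
a pure-birth backbone separates "crowns" (clusters of nearly identical
sister taxa, think species within genera) by long stems, while each
crown is a very shallow recent radiation.  A niche trait evolves by
Brownian motion over the whole tree, so crown-mates are ecologically
near-equivalent while crowns differ — strong phylogenetic niche
conservatism, the assumption the nearest-taxon inference rests on.

Communities assemble hierarchically:

* between crowns, a Gaussian environmental filter on the crown trait
  sets each crown's expected share of the community;
* within crowns, ecologically equivalent sisters compete: their shares
  are a symmetric Dirichlet draw with small concentration, so a largely
  arbitrary winner takes most of the crown's share in each sample.

This yields the fingerprints the null models detect.  Under a shared
environment (homogeneous selection) composition turns over between
samples mostly among crown-mates, so observed between-community mean
nearest taxon distances fall far below the tip-shuffling null.  Under
stage-separated environments (variable selection) different stages
occupy different crowns and phylogenetic turnover exceeds the null.
Disjoint regional crown pools (dispersal limitation) force taxonomic
turnover beyond the taxonomic null without a phylogenetic signal, and
serial resampling chains from one pool (neutral drift with high
connectivity) keep both turnover statistics within null expectations.
The within-crown competitive asymmetry plus the Gaussian niche tail give
every sample a long-tailed abundance distribution and hence a rare
biosphere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import FeatureTable, SampleMetadata

logger = logging.getLogger("rarescape")

SCENARIOS = (
    "homogeneous_selection",
    "variable_selection",
    "neutral_drift",
    "dispersal_limitation",
    "mixed",
)

#: the dominant process each scenario is wired to produce
SCENARIO_TRUTH = {
    "homogeneous_selection": "homogeneous_selection",
    "variable_selection": "variable_selection",
    "neutral_drift": "undominated_or_homogenizing_dispersal",
    "dispersal_limitation": "dispersal_limitation",
    "mixed": "variable_selection",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings.

    The default design mirrors a succession chronosequence survey: five
    successional stages sampled at four times with three replicates
    (60 samples) at a post-rarefaction depth of 31 500 reads.

    ``sigma_w`` is the niche width of the shared filter as a fraction of
    the crown-trait spread (homogeneous selection); ``env_separation``
    is the spacing of stage environments in units of the niche width
    (variable selection; the mixed scenario halves it).
    ``crown_fraction`` controls crown granularity (crowns per taxon);
    ``crown_depth`` is the crown radiation depth as a fraction of the
    backbone depth; ``competition_alpha`` is the symmetric-Dirichlet
    concentration of within-crown shares (small = winner-take-most);
    ``crown_noise`` is the lognormal sd of per-sample crown-level
    fluctuations; ``crown_capacity_sigma`` adds static lognormal
    crown-capacity differences (0 = even crowns);
    ``carrying_capacity_sigma`` is the per-taxon lognormal sd of the
    neutral scenarios' species pool (long-tailed, guaranteeing a rare
    biosphere under drift).
    """

    scenario: str = "homogeneous_selection"
    n_taxa: int = 1000
    n_stages: int = 5
    n_times: int = 4
    n_replicates: int = 3
    depth: int = 31500
    sigma_w: float = 0.5
    env_separation: float = 4.0
    birth_rate: float = 1.0
    bm_rate: float = 1.0
    crown_fraction: float = 0.5
    crown_depth: float = 0.01
    competition_alpha: float = 0.05
    crown_noise: float = 0.25
    crown_capacity_sigma: float = 0.0
    carrying_capacity_sigma: float = 2.0
    n_pools: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if min(self.n_taxa, self.n_stages, self.n_times,
               self.n_replicates, self.depth) < 1:
            raise ValueError("sizes must be positive")
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.sigma_w == 0:
            raise ValueError("sigma_w = 0 with distinct traits is degenerate")

    @property
    def n_samples(self) -> int:
        return self.n_stages * self.n_times * self.n_replicates


@dataclass
class SyntheticDataset:
    table: FeatureTable
    metadata: SampleMetadata
    tree: TreeNode
    traits: pd.Series
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out = self.table.counts.copy()
        out.index.name = "asv_id"
        out.to_csv(outdir / "table.tsv", sep="\t")
        self.metadata.frame.reset_index().to_csv(
            outdir / "metadata.tsv", sep="\t", index=False
        )
        self.tree.write(str(outdir / "tree.nwk"))
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, default=str) + "\n"
        )


# ---------------------------------------------------------------------------
# trees and traits


def _yule_topology(n_taxa: int, birth_rate: float, rng: np.random.Generator) -> TreeNode:
    """Ultrametric pure-birth tree; tips unnamed."""
    root = TreeNode(name=None, length=None)
    active = [root]
    birth = {id(root): 0.0}
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        if node.parent is not None:
            node.length = t - birth[id(node)]
        children = [TreeNode(), TreeNode()]
        for c in children:
            birth[id(c)] = t
        node.extend(children)
        active.extend(children)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for tip in active:
        tip.length = t_end - birth[id(tip)]
    return root


def _evolve_bm(tree: TreeNode, bm_rate: float, rng: np.random.Generator) -> pd.Series:
    """Brownian trait along the tree: covariance = shared branch length."""
    values = {id(tree): 0.0}
    traits = {}
    for node in tree.preorder(include_self=False):
        sd = np.sqrt(bm_rate * max(node.length, 0.0)) if bm_rate > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + (
            rng.normal(0.0, sd) if sd > 0 else 0.0
        )
        if node.is_tip():
            traits[node.name] = values[id(node)]
    return pd.Series(traits, name="trait")


def simulate_tree_and_traits(
    n_taxa: int,
    birth_rate: float = 1.0,
    bm_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[TreeNode, pd.Series]:
    """Plain pure-birth (Yule) ultrametric tree plus a Brownian trait.

    Lineages split at exponential waiting times (rate = birth_rate per
    lineage); all tips end at the present.  The trait accrues Gaussian
    increments with variance ``bm_rate * branch_length``, so trait
    variance grows with root-to-tip depth and ``bm_rate = 0`` leaves all
    traits equal.  Deterministic under ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    tree = _yule_topology(n_taxa, birth_rate, rng)
    for i, tip in enumerate(tree.tips()):
        tip.name = f"ASV{i:04d}"
    return tree, _evolve_bm(tree, bm_rate, rng)


def crown_tree(
    n_taxa: int,
    n_crowns: int,
    crown_depth: float = 0.01,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> TreeNode:
    """Two-level tree: Yule backbone over crowns, shallow crown radiations.

    Crown sizes are 1 plus a uniform multinomial spread of the remaining
    taxa, so most crowns hold a couple of near-identical sisters.  Crown
    radiations are rescaled to ``crown_depth`` of the backbone depth.
    """
    if n_crowns < 3 or n_crowns > n_taxa:
        raise ValueError("need 3 <= n_crowns <= n_taxa")
    rng = np.random.default_rng(seed)
    backbone = _yule_topology(n_crowns, birth_rate, rng)
    T = max(backbone.distance(t) for t in backbone.tips())
    eps = crown_depth * T
    sizes = np.ones(n_crowns, dtype=int)
    for e in rng.integers(n_crowns, size=n_taxa - n_crowns):
        sizes[e] += 1
    k = 0
    for ci, tip in enumerate(list(backbone.tips())):
        c = int(sizes[ci])
        if c == 1:
            tip.name = f"ASV{k:04d}"
            k += 1
            continue
        tip.length = max(tip.length - eps, eps * 1e-3)
        tip.name = None
        if c == 2:
            for _ in range(2):
                tip.append(TreeNode(name=f"ASV{k:04d}", length=eps))
                k += 1
        else:
            crown = _yule_topology(c, birth_rate, rng)
            ch = max(crown.distance(t) for t in crown.tips())
            for node in crown.preorder(include_self=False):
                node.length = node.length / ch * eps
            for t in crown.tips():
                t.name = f"ASV{k:04d}"
                k += 1
            for child in list(crown.children):
                tip.append(child)
    return backbone


def crown_membership(tree: TreeNode) -> pd.Series:
    """Tip -> crown id, grouping tips that share an immediate parent."""
    ids = {}
    for i, node in enumerate(tree.non_tips(include_self=True)):
        ids[id(node)] = i
    return pd.Series({t.name: ids[id(t.parent)] for t in tree.tips()})


# ---------------------------------------------------------------------------
# community assembly


def _design_frame(cfg: ScenarioConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f"S{s}T{tm}R{r}",
            "stage": f"stage{s}",
            "time": f"time{tm}",
            "replicate": f"rep{r}",
        }
        for s in range(cfg.n_stages)
        for tm in range(cfg.n_times)
        for r in range(cfg.n_replicates)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _crown_shares(
    member_idx: dict, cw: np.ndarray, n_taxa: int,
    alpha: float, rng: np.random.Generator,
) -> np.ndarray:
    """Taxon weights from crown weights + within-crown Dirichlet shares."""
    w = np.zeros(n_taxa)
    for ci, mem in enumerate(member_idx.values()):
        if cw[ci] == 0:
            continue
        if len(mem) == 1:
            w[mem] = cw[ci]
        else:
            w[mem] = cw[ci] * rng.dirichlet(np.full(len(mem), alpha))
    return w


def simulate_dataset(cfg: ScenarioConfig) -> SyntheticDataset:
    """Count table + metadata + tree under one assembly scenario.

    Counts are one multinomial draw per sample at ``cfg.depth``, so the
    table is already rarefied.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_crowns = max(3, int(round(cfg.n_taxa * cfg.crown_fraction)))
    tree = crown_tree(cfg.n_taxa, n_crowns, cfg.crown_depth, cfg.birth_rate, rng)
    traits = _evolve_bm(tree, cfg.bm_rate, rng)
    meta = _design_frame(cfg)
    n = len(meta)
    stage_idx = meta["stage"].str.removeprefix("stage").astype(int).to_numpy()

    crowns = crown_membership(tree).reindex(traits.index)
    crown_ids = crowns.unique()
    member_idx = {
        c: np.flatnonzero(crowns.to_numpy() == c) for c in crown_ids
    }
    ct = np.array([traits.to_numpy()[member_idx[c]].mean() for c in crown_ids])
    n_c = len(crown_ids)
    counts = np.zeros((cfg.n_taxa, n), dtype=np.int64)
    alpha = cfg.competition_alpha

    if cfg.scenario in ("homogeneous_selection", "variable_selection", "mixed"):
        if cfg.scenario == "homogeneous_selection":
            envs = np.full(cfg.n_stages, float(np.quantile(ct, 0.5)))
            sw = cfg.sigma_w * float(np.std(ct))
        else:
            # stage environments at evenly spaced crown-trait quantiles so
            # every stage has crowns available; niche width from adjacent
            # spacing so stages sit env_separation niche widths apart
            qs = (np.arange(cfg.n_stages) + 0.5) / cfg.n_stages
            envs = np.quantile(ct, qs)
            sep = (
                cfg.env_separation
                if cfg.scenario == "variable_selection"
                else cfg.env_separation / 2.0
            )
            spacing = np.diff(envs).min() if cfg.n_stages > 1 else np.std(ct)
            sw = max(spacing / sep, 1e-9)
        K = rng.lognormal(0.0, cfg.crown_capacity_sigma, n_c)
        for j in range(n):
            cw = (
                np.exp(-((ct - envs[stage_idx[j]]) ** 2) / (2 * sw * sw))
                * K
                * rng.lognormal(0.0, cfg.crown_noise, n_c)
            )
            w = _crown_shares(member_idx, cw, cfg.n_taxa, alpha, rng)
            counts[:, j] = rng.multinomial(cfg.depth, w / w.sum())
    elif cfg.scenario == "dispersal_limitation":
        # disjoint regional pools partition whole crowns, assignment random
        # with respect to the phylogeny; stages cycle through pools
        pool_of_crown = rng.integers(cfg.n_pools, size=n_c)
        K = rng.lognormal(0.0, cfg.crown_capacity_sigma, n_c)
        for j in range(n):
            pool = stage_idx[j] % cfg.n_pools
            cw = np.where(
                pool_of_crown == pool,
                K * rng.lognormal(0.0, cfg.crown_noise, n_c),
                0.0,
            )
            if cw.sum() == 0:
                raise ValueError("a regional pool received no crowns")
            w = _crown_shares(member_idx, cw, cfg.n_taxa, alpha, rng)
            counts[:, j] = rng.multinomial(cfg.depth, w / w.sum())
    elif cfg.scenario == "neutral_drift":
        # uniform fitness; serial multinomial resampling chain from a
        # long-tailed common pool (drift with full connectivity)
        K = rng.lognormal(0.0, cfg.carrying_capacity_sigma, cfg.n_taxa)
        p = K / K.sum()
        for j in range(n):
            draw = rng.multinomial(cfg.depth, p)
            counts[:, j] = draw
            p = draw / cfg.depth
    else:  # pragma: no cover - guarded by ScenarioConfig
        raise ValueError(cfg.scenario)

    table = FeatureTable(
        counts=pd.DataFrame(counts, index=traits.index, columns=meta.index),
        is_rarefied=True,
        depth=cfg.depth,
    )
    truth = {
        "scenario": cfg.scenario,
        "dominant_process": SCENARIO_TRUTH[cfg.scenario],
        "config": asdict(cfg),
    }
    return SyntheticDataset(
        table=table,
        metadata=SampleMetadata(meta),
        tree=tree,
        traits=traits,
        truth=truth,
    )
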