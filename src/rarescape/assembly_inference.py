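"""Five-process classification of pairwise turnover and its aggregation.

Each unordered sample pair carries a (betaNTI, RC_bray) coordinate that is
mapped to one of five assembly processes:

* betaNTI > +2                      -> variable_selection
* betaNTI < -2                      -> homogeneous_selection
* |betaNTI| <= 2 and RC > +0.95     -> dispersal_limitation
* |betaNTI| <= 2 and RC < -0.95     -> homogenizing_dispersal
* otherwise                         -> undominated

Boundary values (betaNTI = +/-2, RC = +/-0.95) fall to the weaker claim:
all comparisons are strict, so a pair exactly at a threshold is not
assigned the selection/dispersal class.  The relative influence of each
process is the percentage of pairs assigned to it, computed over all
pairs, over temporal pairs (same successional stage), or over spatial
pairs (same sampling time, different stages).

``run_full_analysis`` orchestrates the whole pipeline: rarefaction,
rarity cutoffs, biosphere partitioning, rarity typing, betaNTI and
RC_bray per biosphere component, classification and aggregation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    FeatureTable,
    SampleMetadata,
    ValidationError,
    load_dataset,
    rarefy_table,
)
from .phylo_turnover import beta_nti
from .rarity import (
    CutoffSpec,
    classify_rarity_types,
    partition_biospheres,
    rare_fraction,
    sample_specific_cutoffs,
)
from .raup_crick import rc_bray

logger = logging.getLogger("rarescape")

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def classify_pair(bnti: float, rc: float | None = None) -> str:
    """Map one (betaNTI, RC_bray) pair to its assembly process."""
    if bnti is None or math.isnan(bnti):
        raise ValidationError("betaNTI is NaN; pair is unclassifiable")
    if bnti > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc is None or math.isnan(rc):
        raise ValidationError("RC_bray required when |betaNTI| <= 2")
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def pairwise_turnover(
    bnti_matrix,
    rc_matrix,
    metadata: SampleMetadata,
    component: str = "whole",
) -> pd.DataFrame:
    """Join betaNTI and RC_bray into the per-pair long table with group labels.

    Pairs with NaN betaNTI are excluded from classification and marked
    ``unclassifiable`` (they are dropped from aggregation denominators).
    """
    long = bnti_matrix.to_long().merge(
        rc_matrix.to_long()[["sample_a", "sample_b", "bc_obs", "rc_bray"]],
        on=["sample_a", "sample_b"],
        how="left",
    )
    meta = metadata.frame
    for side in ("a", "b"):
        long[f"stage_{side}"] = long[f"sample_{side}"].map(meta["stage"]).to_numpy()
        long[f"time_{side}"] = long[f"sample_{side}"].map(meta["time"]).to_numpy()
    long["component"] = component

    def _safe(row):
        try:
            return classify_pair(row.bnti, row.rc_bray)
        except ValidationError:
            return "unclassifiable"

    long["process"] = [ _safe(r) for r in long.itertuples() ]
    n_bad = int((long["process"] == "unclassifiable").sum())
    if n_bad:
        logger.warning("%d pair(s) unclassifiable (NaN betaNTI)", n_bad)
    return long


GROUPINGS = ("all", "within_stage", "within_time")


def aggregate_processes(pairs: pd.DataFrame, grouping: str = "all") -> pd.DataFrame:
    """Percentage influence of each process for one grouping.

    ``within_stage`` (temporal) keeps pairs with equal stages and reports
    one row per stage; ``within_time`` (spatial) keeps pairs at the same
    sampling time but different stages, one row per time; ``all`` pools
    every pair into one row.  Each row's five percentages sum to 100;
    unclassifiable pairs are excluded from the denominator and reported
    in an ``unclassifiable`` count column.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    df = pairs
    if grouping == "within_stage":
        df = df[df["stage_a"] == df["stage_b"]]
        keys = df["stage_a"]
    elif grouping == "within_time":
        df = df[(df["time_a"] == df["time_b"]) & (df["stage_a"] != df["stage_b"])]
        keys = df["time_a"]
    else:
        keys = pd.Series("all", index=df.index)
    if df.empty:
        logger.warning("grouping %r matched no pairs; empty report", grouping)
        cols = ["component", "grouping", "group", "n_pairs", "unclassifiable",
                *PROCESSES]
        return pd.DataFrame(columns=cols)
    rows = []
    for (component, group), sub in df.groupby([df["component"], keys], sort=True):
        classified = sub[sub["process"] != "unclassifiable"]
        n = len(classified)
        row = {
            "component": component,
            "grouping": grouping,
            "group": group,
            "n_pairs": n,
            "unclassifiable": len(sub) - n,
        }
        vc = classified["process"].value_counts()
        for proc in PROCESSES:
            row[proc] = 100.0 * vc.get(proc, 0) / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the end-to-end analysis."""

    depth: int | None = None          # None: table assumed already rarefied
    seed: int = 0
    cutoffs: tuple = (0.002, 0.001, 0.0005)
    sample_specific: bool = False     # add a sample-specific cutoff set
    recalibrate: bool = True
    nulls_bnti: int = 999
    nulls_rc: int = 999
    components: tuple = ("rare", "common", "whole")
    groupings: tuple = GROUPINGS
    missing_tip_policy: str = "drop"

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class AssemblyResult:
    """Everything one pipeline run produces."""

    report: pd.DataFrame              # process percentages per component x grouping
    pairwise: pd.DataFrame            # per-pair turnover records
    types: pd.DataFrame               # ASV -> rarity type per cutoff
    cutoffs: pd.DataFrame             # per-sample cutoff provenance
    rare_fractions: dict              # cutoff label -> rare-biosphere abundance share
    manifest: dict


def run_full_analysis(
    table: FeatureTable,
    metadata: SampleMetadata,
    tree,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> AssemblyResult:
    """Execute the full inference pipeline on in-memory inputs.

    Sequence: rarefy -> cutoffs -> partition -> rarity types -> betaNTI and
    RC_bray per biosphere component -> classification -> aggregation.  With
    ``outdir`` every intermediate table plus a run manifest is written as
    TSV/JSON.  Deterministic under ``config.seed``.
    """
    metadata.validate_against(table)
    if config.depth is not None:
        table = rarefy_table(table, config.depth, seed=config.seed)
        metadata = SampleMetadata(metadata.frame.loc[table.sample_ids])
    elif not table.is_rarefied:
        totals = table.counts.sum(axis=0)
        if totals.nunique() == 1:
            # a freshly read table with uniform column sums is rarefied
            table = FeatureTable(
                table.counts, is_rarefied=True, depth=int(totals.iloc[0])
            )
            logger.info("table has uniform depth %d; treating as rarefied",
                        table.depth)
        else:
            raise ValidationError("table must be rarefied or config.depth set")

    cutoff_specs: dict[str, CutoffSpec] = {
        f"fixed_{c:g}": CutoffSpec(mode="fixed", value=float(c))
        for c in config.cutoffs
    }
    if config.sample_specific:
        cutoff_specs["sample_specific"] = sample_specific_cutoffs(
            table, recalibrate=config.recalibrate
        )

    reports, pair_frames, type_frames, cutoff_rows = [], [], [], []
    rare_fracs = {}

    def _analyze_component(label, comp, comp_table):
        """betaNTI + RC_bray + classification + aggregation for one table."""
        comp_table = comp_table.drop_empty_asvs()
        occupied = comp_table.counts.sum(axis=0) > 0
        if not occupied.all():
            logger.warning(
                "cutoff %s component %s: dropping %d empty sample(s)",
                label, comp, int((~occupied).sum()),
            )
            comp_table = comp_table.subset_samples(comp_table.sample_ids[occupied])
        if comp_table.shape[1] < 2:
            logger.warning("component %s has <2 samples; skipped", comp)
            return
        bnti = beta_nti(
            comp_table, tree, n_null=config.nulls_bnti,
            seed=np.random.default_rng([config.seed, 1]),
        )
        rc = rc_bray(
            comp_table, n_null=config.nulls_rc,
            seed=np.random.default_rng([config.seed, 2]),
        )
        pairs = pairwise_turnover(bnti, rc, metadata, component=comp)
        pairs.insert(0, "cutoff", label)
        pair_frames.append(pairs)
        for grouping in config.groupings:
            rep = aggregate_processes(pairs, grouping)
            if not rep.empty:
                rep.insert(0, "cutoff", label)
                reports.append(rep)

    for label, cutoff in cutoff_specs.items():
        part = partition_biospheres(table, cutoff)
        rare_fracs[label] = rare_fraction(part)
        typing = classify_rarity_types(part)
        type_frames.append(
            pd.DataFrame(
                {"cutoff": label, "asv_id": typing.labels.index,
                 "rarity_type": typing.labels.to_numpy()}
            )
        )
        for s in table.sample_ids:
            cutoff_rows.append(
                {"cutoff": label, "sample_id": s, "fraction": cutoff.for_sample(s)}
            )
        for comp, comp_table in (("rare", part.rare_table),
                                 ("common", part.common_table)):
            if comp in config.components:
                _analyze_component(label, comp, comp_table)
    # the whole community does not depend on any cutoff; analyzed once
    if "whole" in config.components:
        _analyze_component("-", "whole", table)

    result = AssemblyResult(
        report=pd.concat(reports, ignore_index=True) if reports else pd.DataFrame(),
        pairwise=pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame(),
        types=pd.concat(type_frames, ignore_index=True) if type_frames else pd.DataFrame(),
        cutoffs=pd.DataFrame(cutoff_rows),
        rare_fractions=rare_fracs,
        manifest={
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "rarescape_version": __version__,
            "n_samples": int(table.shape[1]),
            "n_asvs": int(table.shape[0]),
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.report.to_csv(outdir / "assembly_report.tsv", sep="\t", index=False)
        result.pairwise.to_csv(outdir / "pairwise.tsv", sep="\t", index=False)
        result.types.to_csv(outdir / "types.tsv", sep="\t", index=False)
        result.cutoffs.to_csv(outdir / "cutoffs.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(result.manifest, indent=2, default=str) + "\n"
        )
    return result


def run_from_paths(
    feature_path, metadata_path, tree_path,
    config: PipelineConfig = PipelineConfig(),
    outdir=None,
) -> AssemblyResult:
    """File-based entry point used by the CLI."""
    table, metadata, tree = load_dataset(
        feature_path, metadata_path, tree_path,
        missing_tip_policy=config.missing_tip_policy,
    )
    return run_full_analysis(table, metadata, tree, config=config, outdir=outdir)
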