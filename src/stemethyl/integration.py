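"""Joining methylation with expression.

Expression bins follow the FPKM thresholds None (<= 1), Low (1, 10],
Moderate (10, 100], High (> 100) — half-open and disjoint.  Gene-level
methylation is the pooled level per region (promoter / gene_body /
downstream_2kb) x context; methylated genes are split into tertile bins
per region x context.  The Spearman stage correlates per-gene methylation
with expression, and the DMG/DEG stage intersects the two differential
gene lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS, overlap_join

EXPR_BINS = ("None", "Low", "Moderate", "High")
GENE_REGIONS = ("promoter", "gene_body", "downstream_2kb")


def bin_expression(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Assign every gene to one expression bin per sample.

    ``fpkm`` needs columns gene_id and fpkm (optionally sample); replicate
    rows are averaged per gene (and sample) first.  Negative FPKM is a
    validation error.
    """
    if (fpkm["fpkm"] < 0).any():
        bad = fpkm[fpkm["fpkm"] < 0].iloc[0]
        raise ValueError(f"negative FPKM for gene {bad['gene_id']}")
    keys = [c for c in ("gene_id", "sample") if c in fpkm.columns]
    df = fpkm.groupby(keys, as_index=False)["fpkm"].mean()
    v = df["fpkm"].to_numpy()
    df["expr_bin"] = np.select(
        [v <= 1.0, v <= 10.0, v <= 100.0], ["None", "Low", "Moderate"], "High")
    return df


def _tertile_sizes(n: int) -> tuple[int, int, int]:
    """Split n into (low, moderate, high) thirds with |low - high| <= 1."""
    k, r = divmod(n, 3)
    if r == 0:
        return k, k, k
    if r == 1:
        return k, k + 1, k
    return k + 1, k, k + 1


def gene_methylation(sites: pd.DataFrame, features: pd.DataFrame,
                     min_coverage: int = 4) -> pd.DataFrame:
    """Pooled methylation level per gene x region x context, with tertile bins.

    Regions are the gene-linked kinds promoter, gene_body and
    downstream_2kb from the derived feature set.  The meth_bin is ``None``
    for a gene with zero covered context sites in the region; otherwise
    genes are ranked by level (ties broken by gene_id) and split into
    Low/Moderate/High thirds per region x context.
    """
    feats = features[features["kind"].isin(GENE_REGIONS)]
    covered = sites[sites["total_count"] >= min_coverage]
    joined = overlap_join(covered, feats)
    agg = (joined.groupby(["gene_id", "kind", "context"])
           .agg(mc=("mc_count", "sum"), total=("total_count", "sum"),
                n_sites=("pos", "size")).reset_index())
    all_genes = feats["gene_id"].unique()
    grid = pd.MultiIndex.from_product(
        [all_genes, GENE_REGIONS, CONTEXTS],
        names=["gene_id", "kind", "context"]).to_frame(index=False)
    out = grid.merge(agg, how="left", on=["gene_id", "kind", "context"])
    out[["mc", "total", "n_sites"]] = (
        out[["mc", "total", "n_sites"]].fillna(0).astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(out["total"] > 0, out["mc"] / out["total"], np.nan)
    out["meth_bin"] = "None"
    for (kind, ctx), idx in out.groupby(["kind", "context"]).groups.items():
        block = out.loc[idx]
        meth = block[block["n_sites"] > 0].sort_values(
            ["level", "gene_id"], kind="stable")
        lo, mod, hi = _tertile_sizes(len(meth))
        labels = ["Low"] * lo + ["Moderate"] * mod + ["High"] * hi
        out.loc[meth.index, "meth_bin"] = labels
    return out.rename(columns={"kind": "region"})


def stratified_levels(gene_meth: pd.DataFrame,
                      expression: pd.DataFrame) -> pd.DataFrame:
    """Pooled methylation per expression bin x region x context.

    ``gene_meth`` is a :func:`gene_methylation` result, ``expression`` a
    :func:`bin_expression` result for the same sample; they join on
    gene_id.  Only populated strata are returned; an empty join yields an
    empty frame.
    """
    joined = gene_meth.merge(expression[["gene_id", "expr_bin"]], on="gene_id")
    joined = joined[joined["total"] > 0]
    agg = (joined.groupby(["expr_bin", "region", "context"])
           .agg(mc=("mc", "sum"), total=("total", "sum"),
                n_genes=("gene_id", "nunique")).reset_index())
    agg["mean_level"] = agg["mc"] / agg["total"]
    return agg


def methylation_expression_correlation(gene_meth: pd.DataFrame,
                                       expression: pd.DataFrame,
                                       region: str = "gene_body",
                                       context: str = "CG"
                                       ) -> tuple[float, float]:
    """Spearman rank correlation of per-gene methylation with expression.

    Uses average-rank tie handling and the large-sample p approximation.
    Refuses fewer than 10 joined genes.
    """
    sub = gene_meth[(gene_meth["region"] == region)
                    & (gene_meth["context"] == context)
                    & (gene_meth["n_sites"] > 0)]
    joined = sub.merge(expression[["gene_id", "fpkm"]], on="gene_id")
    if len(joined) < 10:
        raise ValueError(
            f"only {len(joined)} genes with both methylation and expression; "
            "need >= 10 for a Spearman estimate")
    rho, p = stats.spearmanr(joined["level"], joined["fpkm"])
    return float(rho), float(p)


def call_degs_fold_change(expression: pd.DataFrame, sample_a: str,
                          sample_b: str, min_abs_log2fc: float = 1.0,
                          min_fpkm: float = 1.0) -> pd.DataFrame:
    """Simple fold-change DEG rule for synthetic fixtures.

    A gene is differentially expressed when |log2(mean FPKM in B / mean
    FPKM in A)| >= ``min_abs_log2fc`` and both means exceed ``min_fpkm``.
    Direction is up when B is higher.
    """
    mean = (expression.groupby(["gene_id", "sample"])["fpkm"].mean()
            .unstack("sample"))
    a, b = mean[sample_a], mean[sample_b]
    with np.errstate(divide="ignore"):
        lfc = np.log2(b / a)
    deg = (np.abs(lfc) >= min_abs_log2fc) & (a > min_fpkm) & (b > min_fpkm)
    out = pd.DataFrame({
        "gene_id": mean.index[deg],
        "direction": np.where(lfc[deg] > 0, "up", "down"),
        "log2fc": lfc[deg].to_numpy(),
    })
    return out.reset_index(drop=True)


def intersect_dmg_deg(dmgs: pd.DataFrame, degs: pd.DataFrame
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Intersect the differentially methylated and expressed gene lists.

    Returns the common genes (with both directions) and the Venn counts
    {dmg_only, deg_only, common}.  Duplicate gene ids within either table
    are a validation error.
    """
    for name, df in (("DMG", dmgs), ("DEG", degs)):
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in the {name} table")
    common = (dmgs[["gene_id", "direction"]]
              .rename(columns={"direction": "dmg_direction"})
              .merge(degs[["gene_id", "direction"]]
                     .rename(columns={"direction": "deg_direction"}),
                     on="gene_id")
              .sort_values("gene_id").reset_index(drop=True))
    counts = {
        "dmg_only": int(len(dmgs) - len(common)),
        "deg_only": int(len(degs) - len(common)),
        "common": int(len(common)),
    }
    return common, counts
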