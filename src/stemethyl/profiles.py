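"""Descriptive methylation statistics: feature levels, metaprofiles,
level histograms, mC context proportions, and per-sample genome summaries.

All level aggregation is count-pooled — a feature's (or bin's) level is
``sum(mc) / sum(total)`` over the context sites it contains — so deeper
sites weigh more and every comparison in the package uses the same
arithmetic.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import CONTEXTS, overlap_join


def feature_levels(sites: pd.DataFrame, features: pd.DataFrame,
                   min_coverage: int = 4,
                   by_te_class: bool = False) -> pd.DataFrame:
    """Pooled methylation level per feature kind and context.

    ``sites`` carries replicate-pooled counts; sites below ``min_coverage``
    are dropped.  Sites inside overlapping features count toward every kind
    they fall in.  With ``by_te_class`` the TE kinds are additionally split
    by class and superfamily.  Kinds with zero covered sites are omitted.
    """
    covered = sites[sites["total_count"] >= min_coverage]
    joined = overlap_join(covered, features)
    group = ["kind", "context"]
    if by_te_class:
        group = ["kind", "te_class", "te_superfamily", "context"]
    agg = (joined.groupby(group, dropna=False)
           .agg(mc=("mc_count", "sum"), total=("total_count", "sum"),
                n_sites=("pos", "size")).reset_index())
    agg = agg[agg["total"] > 0].reset_index(drop=True)
    agg["mean_level"] = agg["mc"] / agg["total"]
    return agg


def metaprofile(sites: pd.DataFrame, features: pd.DataFrame,
                context: str = "CG", body_bins: int = 20, flank: int = 2000,
                flank_bin: int = 100, min_coverage: int = 4) -> pd.DataFrame:
    """Average methylation across length-normalized bodies plus fixed flanks.

    Each feature body is scaled to ``body_bins`` equal-width bins; each
    flank is cut into ``flank / flank_bin`` fixed-width bins.  Bins are
    ordered 5'->3' in the feature's own orientation (minus-strand features
    are reversed), indexed ``0 .. n_flank + body_bins + n_flank - 1``, with
    the body occupying indices ``n_flank .. n_flank + body_bins - 1``.
    Levels are pooled (sum mc / sum total) across all features per bin.
    """
    if body_bins <= 0:
        raise ValueError("body_bins must be positive")
    n_flank = flank // flank_bin
    sub = sites[(sites["context"] == context)
                & (sites["total_count"] >= min_coverage)]
    records = []
    for f in features.itertuples():
        if f.end - f.start <= body_bins:
            continue
        region = sub[(sub["chrom"] == f.chrom)
                     & (sub["pos"] >= f.start - flank)
                     & (sub["pos"] < f.end + flank)]
        if len(region) == 0:
            continue
        pos = region["pos"].to_numpy()
        bins = np.empty(len(pos), dtype=np.int64)
        up = pos < f.start
        down = pos >= f.end
        body = ~(up | down)
        bins[up] = (pos[up] - (f.start - flank)) // flank_bin
        bins[body] = n_flank + ((pos[body] - f.start) * body_bins
                                // (f.end - f.start))
        bins[down] = n_flank + body_bins + (pos[down] - f.end) // flank_bin
        if f.strand == "-":
            bins = (2 * n_flank + body_bins - 1) - bins
        records.append(pd.DataFrame({
            "bin_index": bins,
            "mc": region["mc_count"].to_numpy(),
            "total": region["total_count"].to_numpy()}))
    total_bins = 2 * n_flank + body_bins
    base = pd.DataFrame({"bin_index": np.arange(total_bins)})
    base["region"] = np.where(
        base["bin_index"] < n_flank, "upstream",
        np.where(base["bin_index"] < n_flank + body_bins, "body", "downstream"))
    if records:
        cat = pd.concat(records, ignore_index=True)
        agg = cat.groupby("bin_index")[["mc", "total"]].sum()
        base = base.join(agg, on="bin_index")
    else:
        base["mc"] = 0
        base["total"] = 0
    base[["mc", "total"]] = base[["mc", "total"]].fillna(0).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        base["mean_level"] = np.where(base["total"] > 0,
                                      base["mc"] / base["total"], np.nan)
    base["context"] = context
    return base


def level_histogram(sites: pd.DataFrame, context: str,
                    min_coverage: int = 4) -> pd.DataFrame:
    """Fraction of sites per 10%-wide methylation-level bin.

    Per-site level is ``mc/total``; bins are [0,10%), [10,20%), ...,
    [90,100%] with the final bin closed so a fully methylated site lands in
    bin 10.  Fractions sum to 1.
    """
    sub = sites[(sites["context"] == context)
                & (sites["total_count"] >= min_coverage)]
    level = sub["mc_count"].to_numpy() / sub["total_count"].to_numpy()
    idx = np.minimum((level * 10).astype(np.int64), 9)
    counts = np.bincount(idx, minlength=10)
    out = pd.DataFrame({
        "bin": np.arange(1, 11),
        "low": np.arange(10) / 10,
        "high": np.arange(1, 11) / 10,
        "n_sites": counts,
        "fraction": counts / counts.sum() if counts.sum() else np.zeros(10),
    })
    out["context"] = context
    return out


def context_proportions(calls: pd.DataFrame) -> dict[str, float]:
    """Relative proportions of mCG/mCHG/mCHH among all called mC sites."""
    mc = calls[calls["is_methylated"]] if "is_methylated" in calls else calls
    n = len(mc)
    if n == 0:
        raise ValueError("no methylated sites; proportions undefined")
    counts = mc["context"].value_counts()
    return {ctx: float(counts.get(ctx, 0)) / n for ctx in CONTEXTS}


def genome_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-context (and overall) covered-site and methylated-site counts with
    the percentage of covered cytosines called methylated."""
    rows = []
    for ctx in CONTEXTS + ("all",):
        sub = calls if ctx == "all" else calls[calls["context"] == ctx]
        n = len(sub)
        n_mc = int(sub["is_methylated"].sum()) if n else 0
        rows.append((ctx, n, n_mc, 100.0 * n_mc / n if n else 0.0))
    return pd.DataFrame(rows, columns=["context", "n_covered", "n_methylated",
                                       "percent_methylated"])
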