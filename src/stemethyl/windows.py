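"""Sliding-window methylation levels, chi-square DMR detection, DMG annotation.

Replicates of a sample are merged by summing read counts per site, sites
are collapsed onto 200 bp windows advancing in 100 bp steps, and two
samples are compared window by window with a 2x2 Pearson chi-square test
(no continuity correction) on pooled methylated/unmethylated read counts.
A window is a DMR when its context-specific criteria all hold:

======== =============== ============== =========
context  min sites/window  min |delta|   max q
======== =============== ============== =========
CG, CHG        5              0.25        0.05
CHH           15              0.15        0.05
ALL_C         20              0.20        0.05
======== =============== ============== =========

Overlapping surviving windows of the same direction are merged into one
reported DMR spanning their union.  For a comparison "A vs B", *hyper*
means higher methylation in B.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import pool_replicates

#: per-context (minimum covered context sites per window, minimum |delta|)
DMR_CRITERIA: dict[str, tuple[int, float]] = {
    "CG": (5, 0.25),
    "CHG": (5, 0.25),
    "CHH": (15, 0.15),
    "ALL_C": (20, 0.20),
}

WINDOW_SIZE = 200
WINDOW_STEP = 100


def enumerate_windows(length: int, window: int = WINDOW_SIZE,
                      step: int = WINDOW_STEP) -> list[tuple[int, int]]:
    """All (start, end) windows on a chromosome of ``length`` bp.

    Full-width windows advance by ``step``; if sequence remains past the
    last full window a single short tail window closes the chromosome.
    """
    if step <= 0 or window < step:
        raise ValueError("need step > 0 and window >= step")
    wins = []
    start = 0
    while start + window <= length:
        wins.append((start, start + window))
        start += step
    covered = wins[-1][1] if wins else 0
    if covered < length:
        wins.append((start, length))
    return wins


def build_windows(replicates: Sequence[pd.DataFrame],
                  chrom_sizes: Mapping[str, int], context: str = "CG",
                  window: int = WINDOW_SIZE, step: int = WINDOW_STEP,
                  min_site_coverage: int = 4) -> pd.DataFrame:
    """Pool replicate counts into sliding windows for one sample.

    Counts are summed across replicates per site; the two strands of a
    symmetric CG or CHG site are pooled into one site unit (CHH stays
    strand-specific); units below ``min_site_coverage`` pooled reads are
    dropped; remaining units contribute their counts to every window
    containing them.  Every window is emitted, empty ones with
    ``n_sites = 0`` and undefined (NaN) level.

    Returns chrom, start, end, context, n_sites, mc, total, level.
    """
    if context not in DMR_CRITERIA:
        raise ValueError(f"unknown context {context!r}")
    pooled = pool_replicates(replicates)
    if context != "ALL_C":
        pooled = pooled[pooled["context"] == context]
    units = _strand_merge(pooled)
    units = units[units["total_count"] >= min_site_coverage]

    out_frames = []
    for chrom, size in chrom_sizes.items():
        wins = enumerate_windows(size, window, step)
        base = pd.DataFrame(wins, columns=["start", "end"])
        base.insert(0, "chrom", chrom)
        sub = units[units["chrom"] == chrom]
        if len(sub) and len(wins):
            p = sub["anchor"].to_numpy()
            k_min = np.maximum(0, (p - window) // step + 1)
            k_max = np.minimum(len(wins) - 1, p // step)
            counts = (k_max - k_min + 1).astype(np.int64)
            rep_idx = np.repeat(np.arange(len(p)), counts)
            cum = np.cumsum(counts)
            k = (np.repeat(k_min, counts)
                 + np.arange(counts.sum()) - np.repeat(cum - counts, counts))
            assigned = pd.DataFrame({
                "k": k,
                "mc": sub["mc_count"].to_numpy()[rep_idx],
                "total": sub["total_count"].to_numpy()[rep_idx],
            })
            agg = assigned.groupby("k").agg(
                n_sites=("mc", "size"), mc=("mc", "sum"), total=("total", "sum"))
            base = base.join(agg, how="left")
        else:
            base["n_sites"] = 0
            base["mc"] = 0
            base["total"] = 0
        base[["n_sites", "mc", "total"]] = (
            base[["n_sites", "mc", "total"]].fillna(0).astype(np.int64))
        out_frames.append(base)
    out = pd.concat(out_frames, ignore_index=True)
    out["context"] = context
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(out["total"] > 0, out["mc"] / out["total"], np.nan)
    return out[["chrom", "start", "end", "context", "n_sites", "mc", "total",
                "level"]]


def _strand_merge(pooled: pd.DataFrame) -> pd.DataFrame:
    """Collapse symmetric CG/CHG strand pairs onto their + strand anchor."""
    df = pooled.copy()
    anchor = df["pos"].to_numpy().copy()
    minus = (df["strand"] == "-").to_numpy()
    ctx = df["context"].to_numpy()
    anchor[minus & (ctx == "CG")] -= 1
    anchor[minus & (ctx == "CHG")] -= 2
    df["anchor"] = anchor
    key = ["chrom", "anchor", "context"]
    df["unit_strand"] = np.where(ctx == "CHH", df["strand"], ".")
    merged = (df.groupby(key + ["unit_strand"], as_index=False, sort=True)
              [["mc_count", "total_count"]].sum())
    return merged


# ---------------------------------------------------------------------------
# Chi-square test
# ---------------------------------------------------------------------------

def chi_square_test(mc_a, u_a, mc_b, u_b):
    """2x2 Pearson chi-square without continuity correction.

    Rows are the two samples, columns methylated/unmethylated read counts.
    Returns ``(chi2, p)`` with p from the df=1 upper tail; degenerate
    margins give ``(nan, nan)``.  Accepts scalars or aligned arrays.
    """
    a = np.asarray(mc_a, float)
    b = np.asarray(u_a, float)
    c = np.asarray(mc_b, float)
    d = np.asarray(u_b, float)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / np.where(denom > 0, denom, 1.0),
                        np.nan)
        p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(chi2, df=1))
    if np.ndim(mc_a) == 0:
        return float(chi2), float(p)
    return chi2, p


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def dmr_window_tests(windows_a: pd.DataFrame, windows_b: pd.DataFrame,
                     q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-window chi-square comparison of two samples' window tables.

    Windows with a degenerate 2x2 margin (a sample with no reads, or no
    methylated/unmethylated reads across both samples) are skipped.
    q-values are Benjamini-Hochberg across all tested windows.
    """
    key = ["chrom", "start", "end", "context"]
    m = windows_a.merge(windows_b, on=key, suffixes=("_a", "_b"))
    mc_a, tot_a = m["mc_a"].to_numpy(), m["total_a"].to_numpy()
    mc_b, tot_b = m["mc_b"].to_numpy(), m["total_b"].to_numpy()
    u_a, u_b = tot_a - mc_a, tot_b - mc_b
    testable = ((tot_a > 0) & (tot_b > 0)
                & (mc_a + mc_b > 0) & (u_a + u_b > 0))
    m = m[testable].reset_index(drop=True)
    if len(m) == 0:
        for col in ("delta", "chi2_stat", "p_value", "q_value"):
            m[col] = np.empty(0)
        return m
    chi2, p = chi_square_test(m["mc_a"], m["total_a"] - m["mc_a"],
                              m["mc_b"], m["total_b"] - m["mc_b"])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    m["delta"] = m["level_b"] - m["level_a"]
    m["chi2_stat"] = chi2
    m["p_value"] = p
    m["q_value"] = q
    return m


def call_dmrs(windows_a: pd.DataFrame, windows_b: pd.DataFrame,
              context: str, q_threshold: float = 0.05,
              min_sites: int | None = None,
              min_delta: float | None = None) -> pd.DataFrame:
    """Detect DMRs of ``context`` between sample A and sample B.

    Applies the context criteria (site count in both samples, |delta|,
    q <= ``q_threshold``) to the tested windows, then merges overlapping
    surviving windows of the same direction into one DMR spanning their
    union.  ``direction`` is hyper when B is more methylated than A.
    """
    if context not in DMR_CRITERIA:
        raise ValueError(f"unknown context {context!r}")
    crit_sites, crit_delta = DMR_CRITERIA[context]
    min_sites = crit_sites if min_sites is None else min_sites
    min_delta = crit_delta if min_delta is None else min_delta

    tested = dmr_window_tests(windows_a, windows_b, q_threshold)
    keep = ((tested["n_sites_a"] >= min_sites)
            & (tested["n_sites_b"] >= min_sites)
            & (tested["delta"].abs() >= min_delta)
            & (tested["q_value"] <= q_threshold))
    surv = tested[keep].sort_values(["chrom", "start"]).reset_index(drop=True)
    surv["direction"] = np.where(surv["delta"] > 0, "hyper", "hypo")

    merged: list[dict] = []
    for row in surv.itertuples():
        last = merged[-1] if merged else None
        if (last is not None and last["chrom"] == row.chrom
                and row.start < last["end"] and last["direction"] == row.direction):
            last["end"] = max(last["end"], row.end)
            last["n_windows"] += 1
            if row.q_value < last["q_value"]:
                last.update(q_value=row.q_value, p_value=row.p_value,
                            chi2_stat=row.chi2_stat, delta=row.delta)
        else:
            merged.append(dict(chrom=row.chrom, start=row.start, end=row.end,
                               context=context, direction=row.direction,
                               delta=row.delta, chi2_stat=row.chi2_stat,
                               p_value=row.p_value, q_value=row.q_value,
                               n_windows=1))
    cols = ["chrom", "start", "end", "context", "direction", "delta",
            "chi2_stat", "p_value", "q_value", "n_windows"]
    out = pd.DataFrame(merged, columns=cols)
    out["dmr_id"] = [f"{r.chrom}:{r.start}-{r.end}" for r in out.itertuples()]
    return out


# ---------------------------------------------------------------------------
# DMG annotation
# ---------------------------------------------------------------------------

def annotate_dmgs(dmrs: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000,
                  min_overlap: int = 2) -> pd.DataFrame:
    """Associate DMRs with genes: overlap of the DMR span with the gene body
    extended by ``flank`` bp on both sides must exceed 1 nt (>= 2 nt).

    Genes hit by both hyper and hypo DMRs are labeled ``mixed``.
    Returns one row per DMG: gene_id, direction, n_dmrs, n_hyper, n_hypo,
    and a ``;``-joined list of supporting DMR ids.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        ivs = []
        for g in sub.itertuples():
            s = max(0, g.start - flank)
            ivs.append((s, g.end + flank, g.Index))
        trees[chrom] = IntervalTree.from_tuples(ivs)
    hits: dict[str, dict] = {}
    for d in dmrs.itertuples():
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(d.start, d.end):
            overlap = min(d.end, iv.end) - max(d.start, iv.begin)
            if overlap < min_overlap:
                continue
            gid = genes.loc[iv.data, "gene_id"]
            rec = hits.setdefault(gid, {"gene_id": gid, "n_dmrs": 0,
                                        "n_hyper": 0, "n_hypo": 0, "dmr_ids": []})
            rec["n_dmrs"] += 1
            rec["n_hyper" if d.direction == "hyper" else "n_hypo"] += 1
            dmr_id = getattr(d, "dmr_id", f"{d.chrom}:{d.start}-{d.end}")
            rec["dmr_ids"].append(dmr_id)
    rows = []
    for rec in hits.values():
        if rec["n_hyper"] and rec["n_hypo"]:
            direction = "mixed"
        elif rec["n_hyper"]:
            direction = "hyper"
        else:
            direction = "hypo"
        rows.append((rec["gene_id"], direction, rec["n_dmrs"], rec["n_hyper"],
                     rec["n_hypo"], ";".join(rec["dmr_ids"])))
    out = pd.DataFrame(rows, columns=["gene_id", "direction", "n_dmrs",
                                      "n_hyper", "n_hypo", "dmr_ids"])
    return out.sort_values("gene_id").reset_index(drop=True)


def chromosome_density(calls: pd.DataFrame, bin_size: int = 100_000,
                       chrom_sizes: Mapping[str, int] | None = None
                       ) -> pd.DataFrame:
    """Methylated-site counts per fixed bin, per chromosome/strand/context.

    ``calls`` is a site-calling result; only ``is_methylated`` rows count.
    When ``chrom_sizes`` is given the full all-bin grid is emitted so that
    zero-density bins appear explicitly.
    """
    mc = calls[calls["is_methylated"]] if "is_methylated" in calls else calls
    counted = (mc.assign(bin=mc["pos"] // bin_size)
               .groupby(["chrom", "strand", "context", "bin"])
               .size().rename("n_mc").reset_index())
    if chrom_sizes is None:
        return counted
    grids = []
    for chrom, size in chrom_sizes.items():
        n_bins = max(1, -(-size // bin_size))
        grid = pd.MultiIndex.from_product(
            [[chrom], ["+", "-"], ["CG", "CHG", "CHH"], range(n_bins)],
            names=["chrom", "strand", "context", "bin"]).to_frame(index=False)
        grids.append(grid)
    full = pd.concat(grids, ignore_index=True)
    out = full.merge(counted, how="left",
                     on=["chrom", "strand", "context", "bin"])
    out["n_mc"] = out["n_mc"].fillna(0).astype(np.int64)
    out["start"] = out["bin"] * bin_size
    return out
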