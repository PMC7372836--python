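"""Conversion-rate estimation and binomial 5mC site calling.

The unmethylated lambda spike-in measures the bisulfite non-conversion
rate; that rate is the null success probability of a one-sided upper-tail
binomial test applied to every covered cytosine, with Benjamini-Hochberg
control of the false discovery rate across all tested sites of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ConversionStats:
    sample_id: str
    converted_reads: int
    total_reads: int

    @property
    def conversion_rate(self) -> float:
        return self.converted_reads / self.total_reads

    @property
    def non_conversion_rate(self) -> float:
        return 1.0 - self.conversion_rate


def estimate_conversion(lambda_calls: pd.DataFrame,
                        sample_id: str = "sample") -> ConversionStats:
    """Pooled conversion rate over all lambda cytosines:
    ``sum(total - mc) / sum(total)``."""
    if len(lambda_calls) == 0:
        raise ValueError("lambda call table is empty")
    total = int(lambda_calls["total_count"].sum())
    mc = int(lambda_calls["mc_count"].sum())
    if total == 0:
        raise ValueError("lambda call table has zero total reads")
    return ConversionStats(sample_id, total - mc, total)


def call_sites(sites: pd.DataFrame, non_conversion_rate: float,
               q_threshold: float = 0.05, min_coverage: int = 4) -> pd.DataFrame:
    """Binomial test of every covered site against the non-conversion null.

    ``sites`` carries replicate-pooled counts.  Sites with
    ``total_count < min_coverage`` are excluded from testing.  Per site,
    ``p = P(X >= mc_count | X ~ Binomial(total_count, non_conversion_rate))``;
    q-values are Benjamini-Hochberg over all tested sites; a site is called
    methylated iff ``q <= q_threshold``.

    Returns the tested sites with added p_value, q_value, is_methylated.
    """
    if not 0.0 < non_conversion_rate < 1.0:
        raise ValueError("non_conversion_rate must lie in (0, 1)")
    out = sites[sites["total_count"] >= min_coverage].reset_index(drop=True).copy()
    if len(out) == 0:
        out["p_value"] = out["q_value"] = np.empty(0)
        out["is_methylated"] = np.empty(0, bool)
        return out
    mc = out["mc_count"].to_numpy()
    total = out["total_count"].to_numpy()
    p = stats.binom.sf(mc - 1, total, non_conversion_rate)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out["p_value"] = p
    out["q_value"] = q
    out["is_methylated"] = q <= q_threshold
    return out
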