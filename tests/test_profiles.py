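"""Feature levels, metaprofiles, level histograms, context proportions."""

import numpy as np
import pandas as pd
import pytest

from stemethyl import profiles as P
from stemethyl.io import FEATURE_COLUMNS


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "mc_count", "total_count"])


def _features(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end",
                                     "strand", "kind"])
    df["gene_id"] = df["feature_id"]
    df["te_class"] = ""
    df["te_superfamily"] = ""
    return df[FEATURE_COLUMNS]


class TestFeatureLevels:
    def test_pooled_arithmetic(self):
        sites = _sites([("chr1", 10, "+", "CG", 3, 10),
                        ("chr1", 20, "+", "CG", 7, 10)])
        feats = _features([("f1", "chr1", 0, 100, "+", "gene_body")])
        out = P.feature_levels(sites, feats)
        assert out["mean_level"].iloc[0] == pytest.approx(0.5)

    def test_all_zero_sites_give_zero_levels(self):
        sites = _sites([("chr1", p, "+", "CG", 0, 10) for p in range(0, 50, 5)])
        feats = _features([("f1", "chr1", 0, 100, "+", "gene_body")])
        out = P.feature_levels(sites, feats)
        assert (out["mean_level"] == 0).all()

    def test_whole_genome_feature_equals_pooled_level(self):
        rng = np.random.default_rng(1)
        total = rng.poisson(30, 100) + 4
        sites = _sites([("chr1", i * 7, "+", "CG", m, t) for i, (m, t) in
                        enumerate(zip(rng.binomial(total, 0.4), total))])
        feats = _features([("all", "chr1", 0, 10_000, "+", "gene_body")])
        out = P.feature_levels(sites, feats)
        assert out["mean_level"].iloc[0] == pytest.approx(
            sites["mc_count"].sum() / sites["total_count"].sum())

    def test_te_boosted_genome_ranks_ltr_above_genome_mean(
            self, small_config, small_genome):
        from stemethyl.synthetic import generate_methylome
        from stemethyl.io import derive_features
        _, reps = generate_methylome(small_config, small_genome, 0)
        from stemethyl.io import pool_replicates
        pooled = pool_replicates(reps)
        feats = derive_features(small_genome.genes, small_genome.gene_parts,
                                small_genome.tes, small_genome.chrom_sizes)
        te_feats = feats[feats["kind"] == "TE"]
        out = P.feature_levels(pooled, te_feats, by_te_class=True)
        genome_level = {
            ctx: pooled.loc[pooled["context"] == ctx, "mc_count"].sum()
            / pooled.loc[pooled["context"] == ctx, "total_count"].sum()
            for ctx in ("CG", "CHG", "CHH")}
        ltr = out[out["te_class"] == "LTR"]
        assert len(ltr) > 0
        for row in ltr.itertuples():
            assert row.mean_level > genome_level[row.context]


def brute_force_metaprofile(sites, features, body_bins, flank, flank_bin):
    """Per-feature loop computing each site's bin index from first principles."""
    n_flank = flank // flank_bin
    total_bins = 2 * n_flank + body_bins
    mc = np.zeros(total_bins)
    tot = np.zeros(total_bins)
    for f in features.itertuples():
        for s in sites.itertuples():
            if s.chrom != f.chrom or not (f.start - flank <= s.pos
                                          < f.end + flank):
                continue
            if s.pos < f.start:
                b = (s.pos - (f.start - flank)) // flank_bin
            elif s.pos >= f.end:
                b = n_flank + body_bins + (s.pos - f.end) // flank_bin
            else:
                b = n_flank + (s.pos - f.start) * body_bins // (f.end - f.start)
            if f.strand == "-":
                b = total_bins - 1 - b
            mc[b] += s.mc_count
            tot[b] += s.total_count
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, mc / tot, np.nan)


class TestMetaprofile:
    def _uniform_sites(self, level, n=400, chrom_len=20_000):
        pos = np.arange(0, chrom_len, chrom_len // n)
        return _sites([("chr1", int(p), "+", "CG", int(level * 10), 10)
                       for p in pos])

    def test_uniform_level_gives_flat_profile(self):
        sites = self._uniform_sites(0.3)
        feats = _features([("g1", "chr1", 5000, 9000, "+", "gene_body")])
        prof = P.metaprofile(sites, feats, "CG")
        assert np.allclose(prof["mean_level"].dropna(), 0.3)

    def test_body_enrichment_gives_step_profile(self):
        pos = np.arange(0, 20_000, 50)
        rows = [("chr1", int(p), "+", "CG",
                 8 if 5000 <= p < 9000 else 2, 10) for p in pos]
        feats = _features([("g1", "chr1", 5000, 9000, "+", "gene_body")])
        prof = P.metaprofile(_sites(rows), feats, "CG")
        body = prof[prof["region"] == "body"]["mean_level"]
        flank = prof[prof["region"] != "body"]["mean_level"]
        assert np.allclose(body.dropna(), 0.8)
        assert np.allclose(flank.dropna(), 0.2)

    def test_matches_brute_force_oracle_on_random_genes(self):
        rng = np.random.default_rng(6)
        total = rng.poisson(20, 2000) + 4
        sites = _sites([("chr1", int(p), "+", "CG", int(m), int(t))
                        for p, m, t in zip(
                            rng.choice(200_000, 2000, replace=False),
                            rng.binomial(total, 0.4), total)])
        starts = rng.choice(150_000, 20, replace=False)
        feats = _features([(f"g{i}", "chr1", int(s), int(s) + int(l),
                            str(st), "gene_body")
                           for i, (s, l, st) in enumerate(zip(
                               starts, rng.integers(1000, 8000, 20),
                               rng.choice(["+", "-"], 20)))])
        prof = P.metaprofile(sites, feats, "CG")
        oracle = brute_force_metaprofile(sites, feats, 20, 2000, 100)
        got = prof["mean_level"].to_numpy()
        assert np.allclose(got, oracle, equal_nan=True)

    def test_strand_reversal_reverses_bins(self):
        rng = np.random.default_rng(7)
        total = rng.poisson(20, 500) + 4
        sites = _sites([("chr1", int(p), "+", "CG", int(m), int(t))
                        for p, m, t in zip(
                            rng.choice(30_000, 500, replace=False),
                            rng.binomial(total, 0.4), total)])
        feats = _features([("g1", "chr1", 8000, 15_000, "+", "gene_body")])
        fwd = P.metaprofile(sites, feats, "CG")["mean_level"].to_numpy()
        feats_rev = feats.assign(strand="-")
        rev = P.metaprofile(sites, feats_rev, "CG")["mean_level"].to_numpy()
        assert np.allclose(fwd, rev[::-1], equal_nan=True)

    def test_invalid_body_bins_rejected(self):
        with pytest.raises(ValueError):
            P.metaprofile(_sites([]), _features([]), "CG", body_bins=0)


class TestLevelHistogram:
    def test_edge_conventions(self):
        sites = _sites([("chr1", 1, "+", "CG", 1, 20),    # level 0.05 -> bin 1
                        ("chr1", 2, "+", "CG", 20, 20)])  # level 1.0  -> bin 10
        h = P.level_histogram(sites, "CG")
        assert h.loc[h["bin"] == 1, "n_sites"].iloc[0] == 1
        assert h.loc[h["bin"] == 10, "n_sites"].iloc[0] == 1

    def test_mass_conservation_and_single_assignment(self):
        rng = np.random.default_rng(8)
        total = rng.poisson(30, 500) + 4
        sites = _sites([("chr1", i, "+", "CHH", int(m), int(t))
                        for i, (m, t) in enumerate(
                            zip(rng.binomial(total, rng.beta(1, 5, 500)),
                                total))])
        h = P.level_histogram(sites, "CHH")
        assert h["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert h["n_sites"].sum() == 500


class TestContextProportions:
    def _calls(self, n_cg, n_chg, n_chh):
        ctx = ["CG"] * n_cg + ["CHG"] * n_chg + ["CHH"] * n_chh
        return pd.DataFrame({"chrom": "chr1", "pos": range(len(ctx)),
                             "strand": "+", "context": ctx,
                             "is_methylated": True})

    def test_simple_arithmetic(self):
        p = P.context_proportions(self._calls(28, 28, 44))
        assert p == {"CG": pytest.approx(0.28), "CHG": pytest.approx(0.28),
                     "CHH": pytest.approx(0.44)}

    def test_single_context(self):
        p = P.context_proportions(self._calls(10, 0, 0))
        assert p == {"CG": 1.0, "CHG": 0.0, "CHH": 0.0}

    def test_no_methylated_sites_is_error(self):
        with pytest.raises(ValueError):
            P.context_proportions(self._calls(0, 0, 0))

    def test_site_abundance_times_methylation_rate(self):
        # with context site counts 59.65 : 96.05 : 904.5 and methylated
        # fractions 0.4764 / 0.2885 / 0.0485, the CHH share of all mC is
        # n_i * f_i / sum(n_j * f_j) ~= 0.4387
        n = {"CG": 596_500, "CHG": 960_500, "CHH": 9_045_000}
        f = {"CG": 0.4764, "CHG": 0.2885, "CHH": 0.0485}
        counts = {c: int(round(n[c] * f[c] / 100)) for c in n}
        p = P.context_proportions(self._calls(counts["CG"], counts["CHG"],
                                              counts["CHH"]))
        assert p["CHH"] == pytest.approx(0.4387, abs=0.001)
        assert p["CG"] == pytest.approx(0.2842, abs=0.001)
        assert p["CHG"] == pytest.approx(0.2771, abs=0.001)


class TestGenomeSummary:
    def test_all_null_genome_is_zero_percent(self):
        calls = pd.DataFrame({"chrom": "chr1", "pos": range(100),
                              "strand": "+",
                              "context": ["CG", "CHG", "CHH", "CG"] * 25,
                              "is_methylated": False})
        s = P.genome_summary(calls)
        assert (s["percent_methylated"] == 0).all()

    def test_percentages_bounded(self):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame({"chrom": "chr1", "pos": range(300),
                              "strand": "+",
                              "context": rng.choice(["CG", "CHG", "CHH"], 300),
                              "is_methylated": rng.random(300) < 0.3})
        s = P.genome_summary(calls)
        assert ((s["percent_methylated"] >= 0)
                & (s["percent_methylated"] <= 100)).all()
        overall = s.set_index("context").loc["all"]
        assert overall["n_methylated"] == calls["is_methylated"].sum()
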