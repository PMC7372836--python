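"""Sliding windows, replicate merging, chi-square DMR calling, DMG overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemethyl import windows as W


def brute_force_windows(length, window=200, step=100):
    """Enumerate windows directly from the definition: every step-aligned
    full window, plus one short tail if sequence remains."""
    out = [(s, s + window) for s in range(0, length - window + 1, step)
           if s % step == 0]
    end = out[-1][1] if out else 0
    if end < length:
        out.append((len(out) * 0 + (out[-1][0] + step if out else 0), length))
    return out


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "mc_count", "total_count"])


class TestEnumerateWindows:
    def test_1000bp_chromosome_yields_nine_windows(self):
        wins = W.enumerate_windows(1000)
        assert wins == [(s, s + 200) for s in range(0, 900, 100)]
        assert len(wins) == 9

    @pytest.mark.parametrize("length", [1, 150, 199, 200, 250, 1000, 1050,
                                        1234, 4999])
    def test_matches_brute_force(self, length):
        assert W.enumerate_windows(length) == brute_force_windows(length)

    def test_tail_window_is_short(self):
        wins = W.enumerate_windows(1050)
        assert wins[-1] == (900, 1050)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            W.enumerate_windows(1000, window=50, step=100)
        with pytest.raises(ValueError):
            W.enumerate_windows(1000, step=0)


class TestBuildWindows:
    def test_replicate_pooling_arithmetic(self):
        r1 = _sites([("chr1", 50, "+", "CG", 10, 40)])
        r2 = _sites([("chr1", 50, "+", "CG", 20, 60)])
        win = W.build_windows([r1, r2], {"chr1": 200}, "CG")
        assert win["level"].iloc[0] == pytest.approx(0.30)
        assert win["mc"].iloc[0] == 30 and win["total"].iloc[0] == 100

    def test_empty_windows_emitted_with_undefined_level(self):
        r = _sites([("chr1", 950, "+", "CG", 5, 10)])
        win = W.build_windows([r], {"chr1": 1000}, "CG")
        assert len(win) == 9
        empty = win[win["n_sites"] == 0]
        assert len(empty) == 8  # site at 950 falls only in [800,1000)
        assert empty["level"].isna().all()

    def test_pooling_conserves_integer_counts(self):
        rng = np.random.default_rng(3)
        reps = []
        for _ in range(3):
            n = 200
            pos = rng.choice(5000, size=n, replace=False)
            total = rng.poisson(30, n) + 1
            reps.append(_sites(list(zip(
                ["chr1"] * n, pos, ["+"] * n, ["CHH"] * n,
                rng.binomial(total, 0.3), total))))
        win = W.build_windows(reps, {"chr1": 5000}, "CHH", min_site_coverage=0)
        # integer identity: every site's counts appear once per window
        # containing it (brute-force count over the enumerated windows)
        wins = W.enumerate_windows(5000)
        cat = pd.concat(reps)
        expected_mc = sum(
            int(r.mc_count) * sum(1 for s, e in wins if s <= r.pos < e)
            for r in cat.itertuples())
        assert int(win["mc"].sum()) == expected_mc

    def test_symmetric_cg_strands_pool_into_one_site(self):
        # a CpG dyad at 100/101 is one unit: counts sum, n_sites = 1
        r = _sites([("chr1", 100, "+", "CG", 3, 10),
                    ("chr1", 101, "-", "CG", 4, 10)])
        win = W.build_windows([r], {"chr1": 300}, "CG")
        first = win.iloc[0]
        assert first["n_sites"] == 1
        assert first["mc"] == 7 and first["total"] == 20

    def test_chh_stays_strand_specific(self):
        r = _sites([("chr1", 100, "+", "CHH", 3, 10),
                    ("chr1", 101, "-", "CHH", 4, 10)])
        win = W.build_windows([r], {"chr1": 300}, "CHH")
        assert win.iloc[0]["n_sites"] == 2

    def test_site_coverage_floor_applied_to_pooled_counts(self):
        r1 = _sites([("chr1", 50, "+", "CG", 1, 2)])
        r2 = _sites([("chr1", 50, "+", "CG", 1, 2)])
        win = W.build_windows([r1, r2], {"chr1": 200}, "CG",
                              min_site_coverage=4)
        assert win.iloc[0]["n_sites"] == 1  # pooled depth 4 passes
        win = W.build_windows([r1], {"chr1": 200}, "CG", min_site_coverage=4)
        assert win.iloc[0]["n_sites"] == 0


class TestChiSquare:
    def test_hand_evaluated_example(self):
        chi2, p = W.chi_square_test(30, 70, 60, 40)
        expected = 200 * (30 * 40 - 70 * 60) ** 2 / (100 * 100 * 90 * 110)
        assert chi2 == pytest.approx(expected)
        assert chi2 == pytest.approx(18.1818, abs=1e-3)
        assert p == pytest.approx(2.0e-5, rel=0.05)

    def test_no_association_gives_zero(self):
        chi2, p = W.chi_square_test(50, 50, 50, 50)
        assert chi2 == 0.0 and p == 1.0

    def test_symmetric_under_sample_swap(self):
        a = W.chi_square_test(12, 34, 56, 8)
        b = W.chi_square_test(56, 8, 12, 34)
        assert a == pytest.approx(b)

    def test_degenerate_margin_is_nan(self):
        chi2, p = W.chi_square_test(0, 0, 5, 5)
        assert np.isnan(chi2) and np.isnan(p)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        tables = rng.integers(1, 200, size=(200, 4))
        chi2, p = W.chi_square_test(*tables.T)
        for (a, b, c, d), x, pv in zip(tables, chi2, p):
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert x == pytest.approx(ref.statistic, abs=1e-10)
            assert pv == pytest.approx(ref.pvalue, abs=1e-10)


def _window_frame(rows):
    """rows: (chrom, start, end, n_sites, mc, total)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                     "mc", "total"])
    df["context"] = "CG"
    df["level"] = df["mc"] / df["total"]
    return df


class TestCallDmrs:
    def test_site_count_floor_rejects_strong_window(self):
        # 4 CG sites: below the >=5 floor however extreme the difference
        wa = _window_frame([("chr1", 0, 200, 4, 10, 100)])
        wb = _window_frame([("chr1", 0, 200, 4, 60, 100)])
        assert len(W.call_dmrs(wa, wb, "CG")) == 0

    def test_delta_floor_rejects_small_difference(self):
        wa = _window_frame([("chr1", 0, 200, 20, 100, 1000)])
        wb = _window_frame([("chr1", 0, 200, 20, 240, 1000)])
        wa["context"] = wb["context"] = "CHH"
        assert len(W.call_dmrs(wa, wb, "CHH")) == 0  # delta 0.14 < 0.15

    def test_passing_window_is_reported_with_direction(self):
        wa = _window_frame([("chr1", 0, 200, 8, 50, 1000)])
        wb = _window_frame([("chr1", 0, 200, 8, 400, 1000)])
        dmrs = W.call_dmrs(wa, wb, "CG")
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["direction"] == "hyper"
        assert dmrs.iloc[0]["delta"] == pytest.approx(0.35)

    def test_sample_order_flip_inverts_direction_only(self):
        rows_a = [("chr1", s, s + 200, 10, 100 + 10 * i, 1000)
                  for i, s in enumerate(range(0, 800, 100))]
        rows_b = [("chr1", s, s + 200, 10, 500, 1000)
                  for s in range(0, 800, 100)]
        wa, wb = _window_frame(rows_a), _window_frame(rows_b)
        fwd = W.call_dmrs(wa, wb, "CG")
        rev = W.call_dmrs(wb, wa, "CG")
        assert len(fwd) > 0
        assert list(fwd["start"]) == list(rev["start"])
        assert list(fwd["end"]) == list(rev["end"])
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [flip[d] for d in fwd["direction"]] == list(rev["direction"])
        assert np.allclose(fwd["delta"], -rev["delta"])

    def test_overlapping_same_direction_windows_merge(self):
        rows_a = [("chr1", s, s + 200, 10, 100, 1000)
                  for s in range(0, 400, 100)]
        rows_b = [("chr1", s, s + 200, 10, 500, 1000)
                  for s in range(0, 400, 100)]
        dmrs = W.call_dmrs(_window_frame(rows_a), _window_frame(rows_b), "CG")
        assert len(dmrs) == 1
        assert (dmrs.iloc[0]["start"], dmrs.iloc[0]["end"]) == (0, 500)
        assert dmrs.iloc[0]["n_windows"] == 4


def brute_force_dmg(dmrs, genes, flank=2000):
    hits = set()
    for d in dmrs.itertuples():
        for g in genes.itertuples():
            if d.chrom != g.chrom:
                continue
            s, e = max(0, g.start - flank), g.end + flank
            if min(d.end, e) - max(d.start, s) >= 2:
                hits.add(g.gene_id)
    return hits


class TestAnnotateDmgs:
    genes = pd.DataFrame([("g1", "chr1", 2999, 4000, "+")],
                         columns=["gene_id", "chrom", "start", "end", "strand"])

    def _dmrs(self, spans, direction="hyper"):
        return pd.DataFrame(
            [("chr1", s, e, "CG", direction) for s, e in spans],
            columns=["chrom", "start", "end", "context", "direction"])

    def test_overlap_with_flank_region(self):
        # DMR 1-based [1000,1200] vs gene 1-based [3000,4000]+-2kb
        dmgs = W.annotate_dmgs(self._dmrs([(999, 1200)]), self.genes)
        assert list(dmgs["gene_id"]) == ["g1"]

    def test_single_nucleotide_overlap_is_not_enough(self):
        # flank starts at 999 (0-based); [989,1001) overlaps 2 nt -> DMG,
        # [989,1000) overlaps 1 nt -> no DMG
        assert len(W.annotate_dmgs(self._dmrs([(989, 1001)]), self.genes)) == 1
        assert len(W.annotate_dmgs(self._dmrs([(989, 1000)]), self.genes)) == 0

    def test_mixed_direction_label(self):
        dmrs = pd.concat([self._dmrs([(3000, 3300)], "hyper"),
                          self._dmrs([(3600, 3900)], "hypo")],
                         ignore_index=True)
        dmgs = W.annotate_dmgs(dmrs, self.genes)
        assert list(dmgs["direction"]) == ["mixed"]

    def test_matches_quadratic_oracle_on_random_intervals(self):
        rng = np.random.default_rng(9)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "chrom": rng.choice(["chr1", "chr2"], 200),
            "start": rng.integers(0, 900_000, 200),
            "strand": "+",
        })
        genes["end"] = genes["start"] + rng.integers(500, 5000, 200)
        dmrs = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 500),
            "start": rng.integers(0, 900_000, 500),
            "context": "CG", "direction": "hyper",
        })
        dmrs["end"] = dmrs["start"] + rng.integers(100, 600, 500)
        got = set(W.annotate_dmgs(dmrs, genes)["gene_id"])
        assert got == brute_force_dmg(dmrs, genes)


class TestChromosomeDensity:
    def _calls(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])
        df["is_methylated"] = True
        return df

    def test_empty_input_gives_all_zero_track(self):
        track = W.chromosome_density(self._calls([]), 100, {"chr1": 500})
        assert len(track) == 5 * 2 * 3
        assert (track["n_mc"] == 0).all()

    def test_single_site_lands_in_second_bin(self):
        track = W.chromosome_density(self._calls([("chr1", 150, "+", "CG")]),
                                     100, {"chr1": 500})
        hit = track[track["n_mc"] > 0]
        assert len(hit) == 1
        assert hit.iloc[0]["bin"] == 1

    def test_total_over_bins_conserved(self):
        rng = np.random.default_rng(2)
        rows = [("chr1", int(p), s, c) for p, s, c in zip(
            rng.integers(0, 10_000, 300),
            rng.choice(["+", "-"], 300),
            rng.choice(["CG", "CHG", "CHH"], 300))]
        track = W.chromosome_density(self._calls(rows), 1000, {"chr1": 10_000})
        assert int(track["n_mc"].sum()) == 300
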