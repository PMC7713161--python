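import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_genotypes
from polyat.io import GenotypeMatrix, RegionSet, SiteTable, site_table
from polyat.sitecomp import (
    accession_composition,
    base_sums,
    filter_sites,
    group_summary,
    site_stats,
    stratified_at,
    window_at,
    window_difference,
)


class TestSiteStats:
    def test_hand_enumeration(self):
        sites = site_table(["1A"], [5], ["A"], ["C"])
        d = np.array([[0.0], [0.0], [0.0], [0.5]])
        st_ = site_stats(GenotypeMatrix(list("wxyz"), sites, d))
        assert st_["maf"].iloc[0] == pytest.approx(0.125)

    def test_monomorphic_and_missing(self):
        sites = site_table(["1A", "1A"], [5, 6], ["A", "C"], ["C", "G"])
        d = np.full((10, 2), 0.0)
        d[:3, 1] = np.nan
        st_ = site_stats(GenotypeMatrix([f"s{i}" for i in range(10)], sites, d))
        assert st_["maf"].iloc[0] == 0.0
        assert st_["missing_rate"].iloc[1] == pytest.approx(0.3)

    def test_all_missing_site(self):
        sites = site_table(["1A"], [5], ["A"], ["C"])
        d = np.full((4, 1), np.nan)
        st_ = site_stats(GenotypeMatrix(list("abcd"), sites, d))
        assert np.isnan(st_["maf"].iloc[0])
        assert st_["missing_rate"].iloc[0] == 1.0


class TestFilterSites:
    def test_threshold_semantics(self):
        # maf 0.04 < 5% removed; missing 0.30 > 20% removed; boundary kept
        sites = site_table(["1A"] * 3, [1, 2, 3], ["A"] * 3, ["C"] * 3)
        n = 50
        d = np.zeros((n, 3))
        d[:2, 0] = 1.0          # maf 0.04
        d[:20, 1] = 1.0         # maf 0.40
        d[:15, 2] = np.nan      # missing 0.30
        d[15:40, 2] = 1.0
        geno = GenotypeMatrix([f"s{i}" for i in range(n)], sites, d)
        kept = filter_sites(geno)
        assert list(kept.sites.df["pos"]) == [2]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            geno = random_genotypes(rng, n_acc=20, n_sites=100, missing=0.25)
            kept = filter_sites(geno)
            expected = []
            for j in range(geno.n_sites):
                col = geno.dosage[:, j]
                obs = col[~np.isnan(col)]
                if len(obs) == 0:
                    continue
                f = obs.mean()
                maf = min(f, 1 - f)
                miss = np.isnan(col).mean()
                if maf >= 0.05 and miss <= 0.20:
                    expected.append(geno.sites.df["pos"].iloc[j])
            assert list(kept.sites.df["pos"]) == expected


class TestAccessionComposition:
    def test_hand_enumeration(self, toy_geno):
        prof = accession_composition(toy_geno).df
        # a1: A/G hom-ref, C/T het, G/T hom-alt -> A=1, C=0.5, T=1.5
        a1 = prof.loc["a1"]
        assert (a1.sumA, a1.sumC, a1.sumG, a1.sumT) == (1.0, 0.5, 0.0, 1.5)
        assert a1.at_value == pytest.approx(2.5 / 3)
        # a4 misses site 1: denominator is 2
        assert prof.loc["a4", "n_sites_used"] == 2

    def test_all_at_sites_give_at_one(self):
        sites = site_table(["1A", "1A"], [1, 2], ["A", "T"], ["T", "A"])
        d = np.array([[0.0, 1.0]])
        prof = accession_composition(GenotypeMatrix(["x"], sites, d)).df
        assert prof["at_value"].iloc[0] == 1.0

    def test_accession_with_no_calls_is_undefined(self):
        sites = site_table(["1A"], [1], ["A"], ["C"])
        d = np.array([[np.nan], [0.0]])
        prof = accession_composition(GenotypeMatrix(["x", "y"], sites, d)).df
        assert np.isnan(prof.loc["x", "at_value"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mass_conservation(self, seed):
        """sumA+sumC+sumG+sumT equals the non-missing site count, always."""
        rng = np.random.default_rng(seed)
        geno = random_genotypes(rng, n_acc=6, n_sites=30)
        sums, n_used = base_sums(geno)
        np.testing.assert_allclose(sums.sum(axis=1), n_used, atol=1e-9)

    def test_invariant_under_ref_alt_swap(self):
        rng = np.random.default_rng(21)
        geno = random_genotypes(rng, n_acc=10, n_sites=50)
        sdf = geno.sites.df.copy()
        swapped = site_table(sdf["chrom"], sdf["pos"], sdf["alt"], sdf["ref"])
        geno2 = GenotypeMatrix(geno.accessions, swapped, 1.0 - geno.dosage)
        p1 = accession_composition(geno).df["at_value"]
        p2 = accession_composition(geno2).df["at_value"]
        np.testing.assert_allclose(p1, p2)

    def test_invariant_under_site_reordering(self):
        rng = np.random.default_rng(22)
        geno = random_genotypes(rng, n_acc=8, n_sites=40)
        perm = rng.permutation(geno.n_sites)
        geno2 = geno.subset_sites(perm)  # SiteTable re-sorts; dosage follows
        p1 = accession_composition(geno).df["at_value"]
        p2 = accession_composition(geno2).df["at_value"]
        np.testing.assert_allclose(p1, p2)


class TestGroupSummary:
    def test_single_accession_group(self, toy_geno):
        from polyat.io import AccessionPanel
        panel = AccessionPanel({"a1": "variety", "a2": "durum",
                                "a3": "durum", "a4": "durum"})
        prof = accession_composition(toy_geno)
        summ = group_summary(prof, panel)
        assert summ.loc["variety", "n"] == 1
        assert np.isnan(summ.loc["variety", "sd"])
        assert summ.loc["variety", "mean"] == prof.df.loc["a1", "at_value"]

    def test_two_equal_groups(self, toy_geno):
        from polyat.io import AccessionPanel
        panel = AccessionPanel({"a1": "variety", "a2": "variety",
                                "a3": "durum", "a4": "durum"})
        prof = accession_composition(toy_geno)
        prof.df.loc[:, "at_value"] = [0.4, 0.6, 0.4, 0.6]
        summ = group_summary(prof, panel)
        assert summ.loc["variety", "mean"] == summ.loc["durum", "mean"]
        assert summ.loc["variety", "sd"] == summ.loc["durum", "sd"]


class TestWindows:
    def _windows_oracle(self, geno, panel, group, lengths, window, step, min_sites):
        """Independent per-window recomputation from scratch."""
        out = []
        members = panel.members(group)
        for chrom, length in lengths.items():
            start = 1
            while start <= length:
                end = min(start + window - 1, length)
                sdf = geno.sites.df
                in_win = ((sdf["chrom"] == chrom) & (sdf["pos"] >= start)
                          & (sdf["pos"] <= end))
                idx = np.flatnonzero(in_win.to_numpy())
                if len(idx) < min_sites:
                    out.append(np.nan)
                else:
                    vals = []
                    for a in members:
                        i = geno.accessions.index(a)
                        sums = np.zeros(4)
                        used = 0
                        for j in idx:
                            d = geno.dosage[i, j]
                            if np.isnan(d):
                                continue
                            used += 1
                            for b, w in ((sdf["ref"].iloc[j], 1 - d),
                                         (sdf["alt"].iloc[j], d)):
                                sums["ACGT".index(b)] += w
                        vals.append((sums[0] + sums[3]) / used if used else np.nan)
                    out.append(np.nanmean(vals))
                start += step
        return np.array(out)

    def test_matches_brute_force(self, sim_small):
        geno = sim_small.geno
        panel = sim_small.panel
        sub = geno.subset_sites((geno.sites.df["chrom"] == "1A").to_numpy())
        lengths = {"1A": 400_000}
        tracks = window_at(sub, panel, ["variety"], lengths,
                           window=150_000, step=100_000, min_sites=5)
        got = tracks["variety"].df["at_value"].to_numpy()
        exp = self._windows_oracle(sub, panel, "variety", lengths, 150_000, 100_000, 5)
        np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_sparse_window_flagged_missing(self):
        sites = site_table(["1A"] * 3, [10, 20, 1_500_000], ["A"] * 3, ["C"] * 3)
        d = np.tile([0.0, 1.0, 0.5], (4, 1))
        geno = GenotypeMatrix(list("abcd"), sites, d)
        from polyat.io import AccessionPanel
        panel = AccessionPanel({a: "variety" for a in "abcd"})
        tracks = window_at(geno, panel, ["variety"], {"1A": 2_000_000},
                           window=2_000_000, step=1_000_000, min_sites=10)
        assert tracks["variety"].df["at_value"].isna().all()

    def test_chromosome_profile_equals_weighted_window_combination(self, sim_small):
        """Non-overlapping windows partition the chromosome: site-weighted
        combination of window base sums reproduces the whole-chromosome sums."""
        geno = sim_small.geno
        mask = (geno.sites.df["chrom"] == "1A").to_numpy()
        sub = geno.subset_sites(mask)
        whole, whole_used = base_sums(sub)
        parts = np.zeros_like(whole)
        used = np.zeros_like(whole_used)
        for start in range(1, 400_001, 100_000):
            end = start + 99_999
            in_win = ((sub.sites.df["pos"] >= start) & (sub.sites.df["pos"] <= end)).to_numpy()
            if in_win.any():
                s, u = base_sums(sub, np.flatnonzero(in_win))
                parts += s
                used += u
        np.testing.assert_allclose(parts, whole, atol=1e-9)
        np.testing.assert_allclose(used, whole_used, atol=1e-9)

    def test_window_difference_trivia(self):
        df = pd.DataFrame({"chrom": ["1A"] * 3, "start": [1, 2, 3],
                           "end": [10, 11, 12], "n_sites": [5, 5, 5],
                           "at_value": [0.5, 0.5, 0.5]})
        from polyat.sitecomp import WindowTrack
        t1 = WindowTrack(df.copy(), "dom")
        t2 = WindowTrack(df.copy(), "wild")
        out, summary = window_difference(t1, t2)
        assert (out["delta_at"] == 0).all()
        assert summary["frac_positive"] == 0.0
        t3 = WindowTrack(df.assign(at_value=df["at_value"] + 0.12), "dom")
        _, s2 = window_difference(t3, t2)
        assert s2["frac_positive"] == 1.0
        assert s2["frac_above_boundary"] == 1.0

    def test_window_difference_requires_matching_windows(self):
        from polyat.sitecomp import WindowTrack
        a = WindowTrack(pd.DataFrame({"chrom": ["1A"], "start": [1], "end": [10],
                                      "n_sites": [5], "at_value": [0.5]}))
        b = WindowTrack(pd.DataFrame({"chrom": ["1A"], "start": [2], "end": [11],
                                      "n_sites": [5], "at_value": [0.5]}))
        with pytest.raises(ValueError):
            window_difference(a, b)


class TestStratified:
    def test_full_stratum_equals_unstratified(self, sim_small):
        geno = sim_small.geno
        full = RegionSet(pd.DataFrame({
            "chrom": list(sim_small.genome.lengths),
            "start": 1,
            "end": [l for l in sim_small.genome.lengths.values()],
        }))
        strata = stratified_at(geno, sim_small.panel, full)
        assert "outside" not in strata  # no sites outside (skipped, logged)
        np.testing.assert_allclose(
            strata["inside"].df["at_value"],
            accession_composition(geno).df["at_value"], equal_nan=True)

    def test_small_stratum_skipped(self, sim_small):
        geno = sim_small.geno
        pos = geno.sites.df.iloc[0]
        tiny = RegionSet(pd.DataFrame({
            "chrom": [pos.chrom], "start": [pos.pos], "end": [pos.pos]}))
        strata = stratified_at(geno, sim_small.panel, tiny, min_sites=10)
        assert "inside" not in strata  # 1 SNP < min_sites, mirrors the 6-SNP sweep rule
        assert "outside" in strata

    def test_sweep_elevation_recovered(self, sim_small):
        """Planted sweeps carry extra high-[AT] derived variants: bread wheat
        [AT] inside sweeps exceeds outside."""
        geno = sim_small.geno
        panel = sim_small.panel
        strata = stratified_at(geno, panel, sim_small.sweeps, min_sites=5)
        bw = [a for a in geno.accessions
              if panel.group_of(a) in ("landrace_east", "landrace_west", "variety")]
        inside = strata["inside"].df.loc[bw, "at_value"].mean()
        outside = strata["outside"].df.loc[bw, "at_value"].mean()
        assert inside > outside
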