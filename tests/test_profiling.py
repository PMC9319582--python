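"""Context composition, genic assignment, TSS profiles, and CGI census —
each checked against brute-force recomputation on small fixtures."""

import numpy as np
import pandas as pd
import pytest

from methlink import io as mio
from methlink.profiling import (
    assign_genic,
    cgi_census_and_classify,
    classify_meth,
    context_composition,
    flag_islands,
    methylation_interval_profile,
    per_nt_density,
    position_profile,
    site_mean_methylation,
)
from conftest import make_calls, make_genes


class TestContextComposition:
    def test_hand_example(self):
        calls = make_calls(
            [
                ("c1", 10, "+", "CpG", "s1", 10, 0),
                ("c1", 20, "+", "CpG", "s1", 0, 10),
                ("c1", 30, "+", "CHH", "s1", 5, 5),
            ]
        )
        out = context_composition(calls).set_index("context")
        assert out.loc["CpG", "share"] == pytest.approx(2 / 3)
        assert out.loc["CHH", "share"] == pytest.approx(1 / 3)
        assert out.loc["CpG", "mean_meth_pct"] == pytest.approx(50.0)
        assert out.loc["CHH", "mean_meth_pct"] == pytest.approx(50.0)

    def test_single_context_share_is_one(self):
        calls = make_calls([("c1", i, "+", "CHG", "s1", 1, 1) for i in range(5)])
        out = context_composition(calls)
        assert out["share"].tolist() == [1.0]

    def test_empty_input_gives_empty_summary(self):
        out = context_composition(make_calls([]))
        assert out.empty

    def test_matches_brute_force_groupby(self, rng):
        contexts = rng.choice(["CpG", "CHG", "CHH"], size=1000)
        samples = rng.choice(["s1", "s2", "s3", "s4"], size=1000)
        nm = rng.integers(0, 20, size=1000)
        nu = rng.integers(0, 20, size=1000)
        calls = make_calls(
            [
                ("c1", i + 1, "+", contexts[i], samples[i], int(nm[i]), int(nu[i]))
                for i in range(1000)
            ]
        )
        out = context_composition(calls)
        for s in np.unique(samples):
            rows = [i for i in range(1000) if samples[i] == s]
            for ctx in np.unique(contexts[rows]):
                sub = [i for i in rows if contexts[i] == ctx]
                share = len(sub) / len(rows)
                ms = [nm[i] / (nm[i] + nu[i]) for i in sub if nm[i] + nu[i] > 0]
                got = out[(out["sample_id"] == s) & (out["context"] == ctx)].iloc[0]
                assert got["share"] == pytest.approx(share)
                assert got["mean_meth_pct"] == pytest.approx(100 * np.mean(ms))


class TestAssignGenic:
    def test_offset_sign_conventions(self):
        genes = make_genes([("gp", "c1", "+", 50_000), ("gm", "c2", "-", 50_000)])
        sites = pd.DataFrame({"chrom": ["c1", "c2"], "pos": [49_500, 50_500]})
        out = assign_genic(sites, genes).set_index("gene_id")
        assert out.loc["gp", "d"] == -500
        assert out.loc["gm", "d"] == -500  # minus-strand mirror

    def test_window_boundary(self):
        genes = make_genes([("g", "c1", "+", 50_000)])
        sites = pd.DataFrame({"chrom": "c1", "pos": [60_000, 60_001, 40_000, 39_999]})
        out = assign_genic(sites, genes)
        assert sorted(out["d"]) == [-10_000, 10_000]

    def test_multi_assignment(self):
        genes = make_genes([("g1", "c1", "+", 50_000), ("g2", "c1", "-", 55_000)])
        sites = pd.DataFrame({"chrom": ["c1"], "pos": [52_000]})
        out = assign_genic(sites, genes)
        assert len(out) == 2
        d = out.set_index("gene_id")["d"]
        assert d["g1"] == 2000 and d["g2"] == 3000

    def test_intergenic_sites_excluded(self):
        genes = make_genes([("g", "c1", "+", 50_000)])
        sites = pd.DataFrame({"chrom": ["c1", "c9"], "pos": [500_000, 50_000]})
        assert assign_genic(sites, genes).empty

    def test_mirror_symmetry(self, rng):
        """Flipping strands and reflecting positions about the TSS leaves
        every offset (hence every profile) unchanged."""
        genes = make_genes([("g1", "c1", "+", 50_000), ("g2", "c1", "-", 100_000)])
        pos = rng.integers(40_001, 110_000, size=300)
        sites = pd.DataFrame({"chrom": "c1", "pos": pos}).drop_duplicates()
        out1 = assign_genic(sites, genes)

        flipped = genes.copy()
        flipped["strand"] = flipped["strand"].map({"+": "-", "-": "+"})
        # reflect each site about the TSS of its assigned gene
        tss = genes.set_index("gene_id")["tss"]
        refl = out1.copy()
        refl["pos"] = 2 * refl["gene_id"].map(tss) - refl["pos"]
        out2 = assign_genic(refl[["chrom", "pos"]], flipped)
        h1 = np.sort(out1["d"].to_numpy())
        h2 = np.sort(out2["d"].to_numpy())
        assert (h1 == h2).all()


class TestPositionProfile:
    def test_full_window_single_bin_density(self):
        genes = make_genes([("g", "c1", "+", 50_000)])
        sites = pd.DataFrame({"chrom": "c1", "pos": [49_000, 50_000, 51_000, 55_000]})
        asn = assign_genic(sites, genes)
        prof = position_profile(asn, bin_nt=20_001)
        assert len(prof) == 1
        assert prof.loc[0, "d_lo"] == -10_000 and prof.loc[0, "d_hi"] == 10_000
        assert prof.loc[0, "density"] == pytest.approx(4 / 20_001)

    def test_sparse_placement(self):
        genes = make_genes([("g", "c1", "+", 50_000)])
        sites = pd.DataFrame({"chrom": "c1", "pos": [49_999, 50_000, 50_001]})
        prof = position_profile(assign_genic(sites, genes), bin_nt=1)
        nonzero = prof[prof["n_cpgs"] > 0]
        assert sorted(nonzero["d_lo"]) == [-1, 0, 1]
        assert (nonzero["density"] == 1.0).all()
        assert prof["n_cpgs"].sum() == 3

    def test_conservation_and_oracle_on_random_fixture(self, rng):
        genes = make_genes([("g1", "c1", "+", 50_000), ("g2", "c1", "-", 90_000)])
        pos = np.unique(rng.integers(35_000, 105_000, size=800))
        sites = pd.DataFrame({"chrom": "c1", "pos": pos})
        asn = assign_genic(sites, genes)
        prof = position_profile(asn, bin_nt=1)
        assert prof["n_cpgs"].sum() == len(asn)
        # naive double loop
        from collections import Counter

        counts = Counter()
        for p in pos:
            for _, g in genes.iterrows():
                d = p - g.tss if g.strand == "+" else g.tss - p
                if abs(d) <= 10_000:
                    counts[d] += 1
        byd = prof.set_index("d_lo")["n_cpgs"]
        for d in range(-10_000, 10_001):
            assert byd[d] == counts.get(d, 0)

    def test_mean_methylation_respects_coverage_floor(self):
        genes = make_genes([("g", "c1", "+", 50_000)])
        calls = make_calls(
            [
                ("c1", 50_000, "+", "CpG", "s1", 10, 0),   # kept, m=100
                ("c1", 50_000, "+", "CpG", "s2", 1, 4),    # below 10x, dropped
                ("c1", 50_100, "+", "CpG", "s1", 0, 10),   # kept, m=0
            ]
        )
        asn = assign_genic(calls[["chrom", "pos"]].drop_duplicates(), genes)
        prof = position_profile(asn, calls, bin_nt=20_001, min_coverage=10)
        assert prof.loc[0, "mean_meth_pct"] == pytest.approx(50.0)

    def test_whole_window_density_helper(self):
        assert per_nt_density(2_916_293) == pytest.approx(145.8, abs=0.05)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError, match="bin width"):
            position_profile(pd.DataFrame({"d": []}), bin_nt=0)


class TestIntervalProfile:
    def _fixture(self):
        genes = make_genes([("g", "c1", "+", 50_000)])
        calls = make_calls(
            [
                ("c1", 50_000, "+", "CpG", "s1", 1, 19),   # mean m = 5% -> [0,10)
                ("c1", 50_500, "+", "CpG", "s1", 20, 0),   # 100% -> [90,100]
            ]
        )
        return genes, calls

    def test_interval_boundaries(self):
        genes, calls = self._fixture()
        asn = assign_genic(calls[["chrom", "pos"]].drop_duplicates(), genes)
        tab = methylation_interval_profile(asn, calls)
        by_pos = tab.set_index("interval")
        assert 0 in by_pos.index and 9 in by_pos.index  # [0,10) and [90,100]
        assert by_pos.loc[9, "interval_label"] == "[90,100]"

    def test_counts_sum_to_bin_counts(self, rng):
        genes = make_genes([("g", "c1", "+", 50_000)])
        pos = np.unique(rng.integers(40_000, 60_001, size=100))
        rows = []
        for p in pos:
            for s in ("s1", "s2"):
                nm = int(rng.integers(0, 30))
                rows.append(("c1", int(p), "+", "CpG", s, nm, 30 - nm))
        calls = make_calls(rows)
        asn = assign_genic(calls[["chrom", "pos"]].drop_duplicates(), genes)
        tab = methylation_interval_profile(asn, calls, offset_bin_nt=1000)
        prof = position_profile(asn, bin_nt=1000)
        merged = tab.groupby("offset_bin")["n_cpgs"].sum()
        byb = prof.set_index(((prof["d_lo"] + 10_000) / 1000).astype(int))["n_cpgs"]
        for b, n in merged.items():
            assert byb[b] == n

    def test_matches_brute_force_binning(self, rng):
        genes = make_genes([("g", "c1", "+", 50_000)])
        pos = np.unique(rng.integers(40_000, 60_001, size=100))
        rows = []
        for p in pos:
            nm = int(rng.integers(0, 21))
            rows.append(("c1", int(p), "+", "CpG", "s1", nm, 20 - nm))
        calls = make_calls(rows)
        asn = assign_genic(calls[["chrom", "pos"]].drop_duplicates(), genes)
        tab = methylation_interval_profile(asn, calls, offset_bin_nt=1000)
        # brute force: mean methylation per site -> decile-of-100 histogram
        from collections import Counter

        expect = Counter()
        for _, row in calls.iterrows():
            m = 100 * row.n_meth / (row.n_meth + row.n_unmeth)
            iv = min(int(m // 10), 9)
            ob = (row.pos - 50_000 + 10_000) // 1000
            expect[(ob, iv)] += 1
        for _, r in tab.iterrows():
            assert expect[(r.offset_bin, r.interval)] == r.n_cpgs


class TestIslandsAndClasses:
    def test_classification_thresholds(self):
        assert classify_meth(30.0) == "hypo"
        assert classify_meth(44.0) == "hypo"
        assert classify_meth(44.01) == "moderate"
        assert classify_meth(97.0) == "moderate"
        assert classify_meth(98.0) == "hyper"

    def test_island_membership_bed_convention(self):
        islands = pd.DataFrame(
            {"island_id": ["i1"], "chrom": ["c1"], "start": [100], "end": [200]}
        )
        sites = pd.DataFrame({"chrom": "c1", "pos": [100, 101, 200, 201]})
        out = flag_islands(sites, islands)
        assert out["in_island"].tolist() == [False, True, True, False]

    def _census_fixture(self):
        """20 genes with a gene-body CGI; 3 of them also promoter CGIs."""
        genes = make_genes([(f"g{i}", "c1", "+", 100_000 + 30_000 * i) for i in range(20)])
        rows, islands = [], []
        for i in range(20):
            tss = 100_000 + 30_000 * i
            # gene-body island [+100, +300) with 3 CpGs
            islands.append((f"body{i}", "c1", tss + 99, tss + 299))
            for off in (120, 150, 180):
                rows.append(("c1", tss + off, "+", "CpG", "s1", 15, 5))
            if i < 3:  # promoter island [-300, -100) with 2 CpGs
                islands.append((f"prom{i}", "c1", tss - 301, tss - 101))
                for off in (-250, -200):
                    rows.append(("c1", tss + off, "+", "CpG", "s1", 2, 18))
        islands = pd.DataFrame(islands, columns=["island_id", "chrom", "start", "end"])
        return genes, islands, make_calls(rows)

    def test_census_promoter_percentage(self):
        genes, islands, calls = self._census_fixture()
        sites = calls[["chrom", "pos"]].drop_duplicates()
        census, classes = cgi_census_and_classify(sites, islands, genes, calls)
        assert census["n_genes_with_cgi"] == 20
        assert census["n_promoter_genes"] == 3
        assert census["promoter_cgi_gene_pct"] == pytest.approx(15.0)
        assert census["n_island_cpgs"] == 20 * 3 + 3 * 2

    def test_classes_by_stratum(self):
        genes, islands, calls = self._census_fixture()
        sites = calls[["chrom", "pos"]].drop_duplicates()
        _, classes = cgi_census_and_classify(sites, islands, genes, calls)
        body = classes[classes["island_id"].str.startswith("body")]
        assert (body["region"] == "[0,+2]kb").all()
        assert (body["cls"] == "moderate").all()  # m = 75%
        prom = classes[classes["island_id"].str.startswith("prom")]
        assert (prom["region"] == "[-2,0)kb").all()
        assert (prom["cls"] == "hypo").all()  # m = 10%

    def test_island_on_absent_chromosome_warns(self):
        genes, islands, calls = self._census_fixture()
        islands = pd.concat(
            [islands, pd.DataFrame([{"island_id": "x", "chrom": "c9", "start": 0, "end": 10}])],
            ignore_index=True,
        )
        sites = calls[["chrom", "pos"]].drop_duplicates()
        with pytest.warns(UserWarning, match="zero CpGs"):
            cgi_census_and_classify(sites, islands, genes, calls)


class TestSiteMeanMethylation:
    def test_unweighted_across_samples(self):
        calls = make_calls(
            [
                ("c1", 10, "+", "CpG", "s1", 10, 0),   # m=1 at 10x
                ("c1", 10, "+", "CpG", "s2", 10, 30),  # m=0.25 at 40x
            ]
        )
        out = site_mean_methylation(calls)
        # unweighted mean of 100 and 25, not pooled counts
        assert out.loc[0, "mean_meth_pct"] == pytest.approx(62.5)
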