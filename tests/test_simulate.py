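"""Synthetic-data generators: calibration, ground-truth wiring, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loop2target import chrom3d, simulate
from loop2target.util import bh_adjust

from conftest import dosage_r2


class TestPanel:
    def test_no_ld_limit(self):
        """With rho = 0 the mean off-diagonal r2 is near its null value 1/n."""
        panel = simulate.simulate_panel(400, 2, 40, 0.0, seed=3)
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(1000):
            i, j = rng.choice(panel.n_var, size=2, replace=False)
            r2s.append(dosage_r2(panel, int(i), int(j)))
        assert np.mean(r2s) == pytest.approx(1 / 400, rel=0.5)

    def test_adjacent_r2_under_strong_ar(self):
        """rho = 0.9 gives strong adjacent dosage LD, decaying with distance.

        Thresholding a latent Gaussian attenuates the dosage-scale
        correlation below the latent rho (phi ~ (2/pi) arcsin(rho) at
        eaf 0.5), so the adjacent dosage r2 concentrates near 0.5 for
        common variants rather than at rho^2.
        """
        panel = simulate.simulate_panel(
            500, 5, 10, 0.9, seed=5, eaf_range=(0.3, 0.5)
        )
        adjacent = [dosage_r2(panel, b * 10, b * 10 + 1) for b in range(5)]
        distant = [dosage_r2(panel, b * 10, b * 10 + 8) for b in range(5)]
        assert np.median(adjacent) > 0.35
        assert np.median(adjacent) > 4 * np.median(distant)

    def test_cross_block_independence(self):
        panel = simulate.simulate_panel(2000, 2, 10, 0.9, seed=9)
        assert dosage_r2(panel, 5, 15) < 0.01

    def test_deterministic_given_seed(self):
        a = simulate.simulate_panel(60, 2, 5, 0.4, seed=42)
        b = simulate.simulate_panel(60, 2, 5, 0.4, seed=42)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            simulate.simulate_panel(10, 2, 5, 0.4, seed=1)  # too few individuals
        with pytest.raises(ValueError):
            simulate.simulate_panel(60, 0, 5, 0.4, seed=1)
        with pytest.raises(ValueError):
            simulate.simulate_panel(60, 2, 5, 1.0, seed=1)

    def test_positions_strictly_increasing_invariant(self):
        panel = simulate.simulate_panel(60, 3, 4, 0.2, seed=2)
        pos = panel.variants["pos"].to_numpy()
        assert np.all(np.diff(pos) > 0)


class TestEqtl:
    def test_null_pvalue_calibration(self, nold_panel):
        """beta_x_sd = 0: the cis scan is a pure null, ~5% of p < 0.05."""
        genes = simulate.simulate_genes(nold_panel, 25, seed=1)
        ss, _ = simulate.simulate_eqtl_sumstats(
            nold_panel, genes, k_causal=1, beta_x_sd=0.0, n_eqtl=600, seed=4
        )
        assert len(ss) >= 2000
        frac = float((ss["pvalue"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(ss))
        assert abs(frac - 0.05) < 4 * se + 0.005

    def test_single_causal_effect_recovery(self, nold_panel):
        """Marginal beta at an isolated causal variant recovers the planted
        effect on the standardized-expression scale within 3 SE."""
        genes = simulate.simulate_genes(nold_panel, 1, seed=2)
        gid = genes["gene_id"].iloc[0]
        ss, arch = simulate.simulate_eqtl_sumstats(
            nold_panel, genes, k_causal=1, beta_x_sd=0.0, n_eqtl=2000, seed=6,
            planted_effects={gid: [0.5]},
        )
        (snp, beta_std) = arch[gid][0]
        row = ss[(ss["gene_id"] == gid) & (ss["snp_id"] == snp)].iloc[0]
        assert row["beta"] == pytest.approx(beta_std, abs=3 * row["se"])
        # and the standardized truth is the raw effect over the expression SD
        eaf = nold_panel.variants.set_index("snp_id").loc[snp, "eaf"]
        sd_pop = np.sqrt(0.5**2 * 2 * eaf * (1 - eaf) + 1.0)
        assert beta_std == pytest.approx(0.5 / sd_pop, rel=0.1)

    def test_pvalue_consistent_with_z(self, small_panel):
        genes = simulate.simulate_genes(small_panel, 5, seed=3)
        ss, _ = simulate.simulate_eqtl_sumstats(
            small_panel, genes, k_causal=2, beta_x_sd=0.3, n_eqtl=400, seed=8
        )
        z = (ss["beta"] / ss["se"]).abs()
        expected = 2 * stats.norm.sf(z)
        mask = expected > 1e-12
        np.testing.assert_allclose(
            ss["pvalue"][mask], expected[mask], rtol=0.1
        )

    def test_deterministic_tsv(self, small_panel, tmp_path):
        genes = simulate.simulate_genes(small_panel, 4, seed=3)
        out = []
        for rep in range(2):
            ss, _ = simulate.simulate_eqtl_sumstats(
                small_panel, genes, 2, 0.3, 300, seed=99
            )
            path = tmp_path / f"e{rep}.tsv"
            simulate.write_sumstats(ss, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]


class TestGwas:
    def test_null_gwas_has_no_genomewide_hits(self):
        """With eta = 0 everywhere, a small genome almost never reaches 5e-8."""
        panel = simulate.simulate_panel(300, 10, 10, 0.5, seed=13)
        clean = 0
        for rep in range(20):
            gwas = simulate.simulate_gwas_sumstats(
                panel, simulate.TrueModel(), {}, n_gwas=2000, seed=100 + rep
            )
            if gwas["pvalue"].min() > 5e-8:
                clean += 1
        assert clean >= 19

    def test_causal_variants_carry_top_signal(self):
        """One gene with eta = 0.3: the max |z| variant is causal in >= 9/10."""
        panel = simulate.simulate_panel(300, 20, 10, 0.5, seed=17)
        genes = simulate.simulate_genes(panel, 1, seed=1)
        gid = genes["gene_id"].iloc[0]
        hits = 0
        for rep in range(10):
            ss, arch = simulate.simulate_eqtl_sumstats(
                panel, genes, 3, 0.3, 1000, seed=rep,
                planted_effects={gid: [0.45, 0.45, 0.45]},
            )
            truth = simulate.TrueModel(gene_effects={gid: 0.3}, causal_eqtl=arch)
            gwas = simulate.simulate_gwas_sumstats(
                panel, truth, arch, n_gwas=20000, seed=1000 + rep
            )
            z = (gwas["beta"] / gwas["se"]).abs()
            top = gwas["snp_id"].iloc[int(np.argmax(z))]
            causal = {s for s, _ in arch[gid]}
            hits += top in causal
        assert hits >= 9

    def test_marginal_logistic_matches_statsmodels(self):
        """The vectorized Newton scan agrees with statsmodels Logit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        g = rng.integers(0, 3, size=(500, 4)).astype(np.int8)
        y = (rng.random(500) < 1 / (1 + np.exp(-(-1.0 + 0.4 * g[:, 2])))).astype(np.int8)
        beta, se, p = simulate._logistic_marginal_scan(g, y)
        for j in range(4):
            fit = sm.Logit(y, sm.add_constant(g[:, j].astype(float))).fit(disp=0)
            assert beta[j] == pytest.approx(fit.params[1], abs=1e-6)
            assert se[j] == pytest.approx(fit.bse[1], rel=1e-4)

    def test_gene_set_must_be_subset(self, small_panel):
        truth = simulate.TrueModel(gene_effects={"GENE_X": 0.2})
        with pytest.raises(ValueError):
            simulate.simulate_gwas_sumstats(small_panel, truth, {}, 1000, seed=1)

    def test_determinism(self, small_panel):
        a = simulate.simulate_gwas_sumstats(small_panel, simulate.TrueModel(), {}, 500, seed=5)
        b = simulate.simulate_gwas_sumstats(small_panel, simulate.TrueModel(), {}, 500, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestLoopsPeaks:
    def _genes(self):
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(20)],
                "chrom": "chr1",
                "tss": np.arange(100_001, 100_001 + 20 * 40_000, 40_000),
                "strand": "+",
            }
        )

    def test_no_hubs_gives_flat_degree(self):
        loops, _, hubs = simulate.simulate_loops_and_peaks(
            self._genes(), 0.2, hub_fraction=0.0, seed=1, loops_per_gene=3,
            ee_loop_fraction=1.0,
        )
        assert hubs == set()
        deg = chrom3d.anchor_degrees(loops)
        vals = sorted(deg.values())
        assert max(vals) / np.median(vals) < 3

    def test_designated_hubs_are_called_hubs(self):
        """Cross-module check: planted hubs land in the >= 90th-percentile set."""
        loops, _, hub_truth = simulate.simulate_loops_and_peaks(
            self._genes(), 0.2, hub_fraction=0.05, seed=2, hub_extra_partners=20,
        )
        assert len(hub_truth) >= 1
        called = chrom3d.hub_enhancers(loops, percentile=90)
        assert hub_truth <= called

    def test_anchors_on_bin_grid(self):
        loops, _, _ = simulate.simulate_loops_and_peaks(
            self._genes(), 0.15, 0.05, bin_size=5000, seed=3
        )
        for lp in loops:
            assert lp.anchor1.start % 5000 == 0
            assert lp.anchor2.start % 5000 == 0
            assert len(lp.anchor1) == 5000 and len(lp.anchor2) == 5000

    def test_wired_genes_get_promoter_loops(self):
        genes = self._genes()
        wired = {"G3": [genes.loc[3, "tss"] + 123_000]}
        loops, _, _ = simulate.simulate_loops_and_peaks(
            genes, 0.15, 0.0, seed=4, wired=wired, frac_significant=1.0
        )
        pbin = ((genes.loc[3, "tss"] - 1) // 5000) * 5000
        tbin = ((genes.loc[3, "tss"] + 123_000 - 1) // 5000) * 5000
        assert any(
            {lp.anchor1.start, lp.anchor2.start} == {pbin, tbin} for lp in loops
        )

    def test_hub_fraction_validation(self):
        with pytest.raises(ValueError):
            simulate.simulate_loops_and_peaks(self._genes(), 0.1, hub_fraction=1.5, seed=1)


class TestPpiDrugPhewas:
    def _genes(self, n=50):
        return pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(n)],
                "chrom": "chr1",
                "tss": np.arange(1, n + 1) * 10_000,
                "strand": "+",
            }
        )

    def test_phewas_has_requested_trait_count(self):
        _, _, ph = simulate.simulate_ppi_drug_phewas(
            self._genes(), [], 2.5, n_traits=778, seed=1, snps=["rs1", "rs2"]
        )
        assert ph["trait"].nunique() == 778

    def test_planted_adverse_survives_bh(self):
        """A planted p = 1e-9 among 777 nulls is the unique BH-5% discovery."""
        _, _, ph = simulate.simulate_ppi_drug_phewas(
            self._genes(), [], 2.5, n_traits=778, seed=2, snps=["rs9"],
            planted_adverse={"rs9": ("trait_005", -0.05, 1e-9)},
        )
        sub = ph[ph["snp"] == "rs9"]
        adj = bh_adjust(sub["p"].to_numpy())
        flagged = sub["trait"].to_numpy()[adj < 0.05]
        assert list(flagged) == ["trait_005"]

    def test_degree_distribution_slope(self):
        """gamma = 3 on 1000 nodes: log-log LS slope of the degree histogram."""
        edges, _, _ = simulate.simulate_ppi_drug_phewas(
            self._genes(1000), [], gamma=3.0, n_traits=5, seed=3
        )
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(edges.itertuples(index=False))
        deg = np.array([d for _, d in g.degree()])
        ks, counts = np.unique(deg[deg > 0], return_counts=True)
        # drop bins with < 3 nodes: log counts there are too noisy for LS
        mask = counts >= 3
        slope = np.polyfit(np.log(ks[mask]), np.log(counts[mask]), 1)[0]
        assert -3.6 < slope < -2.4

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            simulate.simulate_ppi_drug_phewas(self._genes(), [], gamma=1.0, n_traits=5, seed=1)

    def test_planted_drugs_present(self):
        _, drugs, _ = simulate.simulate_ppi_drug_phewas(
            self._genes(), [], 2.5, 5, seed=4, planted_drugs={"G7": "agonist"}
        )
        sub = drugs[(drugs["gene"] == "G7") & (drugs["interaction_type"] == "agonist")]
        assert len(sub) >= 1


class TestRoundTrips:
    def test_sumstats_roundtrip(self, small_panel, tmp_path):
        genes = simulate.simulate_genes(small_panel, 3, seed=5)
        ss, _ = simulate.simulate_eqtl_sumstats(small_panel, genes, 2, 0.3, 300, seed=1)
        path = tmp_path / "ss.tsv"
        simulate.write_sumstats(ss, path)
        back = simulate.read_sumstats(path)
        pd.testing.assert_frame_equal(
            ss.reset_index(drop=True), back, check_dtype=False, rtol=1e-12
        )

    def test_bedpe_roundtrip(self, tmp_path):
        genes = pd.DataFrame(
            {"gene_id": ["A", "B"], "chrom": "chr1", "tss": [50_001, 250_001], "strand": "+"}
        )
        loops, peaks, _ = simulate.simulate_loops_and_peaks(genes, 0.2, 0.0, seed=6)
        lpath, bpath = tmp_path / "l.bedpe", tmp_path / "p.bed"
        simulate.write_bedpe(loops, lpath)
        simulate.write_bed(peaks, bpath)
        back = simulate.read_bedpe(lpath)
        assert len(back) == len(loops)
        for a, b in zip(loops, back):
            assert (a.anchor1, a.anchor2) == (b.anchor1, b.anchor2)
            assert b.qvalue == pytest.approx(a.qvalue, rel=1e-5)
        assert simulate.read_bed(bpath) == peaks

    def test_malformed_bedpe_reports_line(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t0\t5000\tchr1\t10000\t15000\tloop1\t1e-8\nchr1\t0\n")
        with pytest.raises(ValueError, match="line 2"):
            simulate.read_bedpe(path)

    def test_panel_roundtrip(self, tmp_path):
        panel = simulate.simulate_panel(60, 2, 5, 0.4, seed=8)
        simulate.write_panel(panel, tmp_path / "panel")
        back = simulate.read_panel(tmp_path / "panel")
        assert np.array_equal(panel.dosages, back.dosages)
        assert list(panel.variants["snp_id"]) == list(back.variants["snp_id"])
        assert np.array_equal(panel.blocks, back.blocks)
        assert np.allclose(back.rho, panel.rho)
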