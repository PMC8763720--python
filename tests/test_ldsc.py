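"""LD scores and LD-score regression (heritability, genetic correlation)."""

import numpy as np
import pandas as pd
import pytest

from gwaskit import (
    SimConfig,
    StudyMetadata,
    SumstatsTable,
    compute_ld_scores,
    estimate_h2,
    genetic_correlation,
    gwas_scan,
    simulate_panel,
    simulate_phenotype,
)
from gwaskit.ldsc import LdScores, read_ld_scores, write_ld_scores
from gwaskit.simulate import concat_panels
from gwaskit.types import ReferencePanel


@pytest.fixture(scope="module")
def ld_panel():
    """Heterogeneous LD: 20 blocks ("chromosomes") of 40 SNPs whose adjacent
    correlation cycles over 0..0.9, giving the LD-score spread the
    regression needs for leverage."""
    blocks = [
        simulate_panel(
            SimConfig(n_individuals=2000, m_snps=40, n_causal=1, ld_rho=r, seed=300 + i)
        )
        for i, r in enumerate([0.0, 0.3, 0.5, 0.7, 0.9] * 4)
    ]
    return concat_panels(blocks)


@pytest.fixture(scope="module")
def ld_scores(ld_panel):
    return compute_ld_scores(ld_panel, window=50)


class TestLdScores:
    def test_window_zero_gives_self_only(self, ld_panel):
        scores = compute_ld_scores(ld_panel, window=0)
        np.testing.assert_array_equal(scores.df["L2"], 1.0)

    def test_perfect_correlation_counts_fully(self):
        # two identical SNP columns -> each scores 1 + 1
        rng = np.random.default_rng(3)
        col = (rng.random(200) < 0.3).astype(np.int8)
        H = np.column_stack([col, col])
        snp_map = pd.DataFrame(
            {"SNP": ["rs1", "rs2"], "CHR": "1", "POS": [1, 2],
             "REF": "A", "ALT": "G", "AF": H.mean(0)}
        )
        scores = compute_ld_scores(ReferencePanel(snp_map, H), window=1)
        np.testing.assert_allclose(scores.df["L2"], [2.0, 2.0])

    def test_independent_snps_mean_near_one(self):
        panel = simulate_panel(
            SimConfig(n_individuals=500, m_snps=800, ld_rho=0.0, seed=4)
        )
        scores = compute_ld_scores(panel, window=50)
        # adjusted r2 is unbiased for 0 under independence
        assert abs(scores.df["L2"].mean() - 1.0) < 0.05

    def test_small_panel_rejected(self):
        panel = simulate_panel(SimConfig(n_individuals=10, m_snps=20, n_causal=5, seed=5))
        with pytest.raises(ValueError):
            compute_ld_scores(panel)

    def test_tsv_round_trip(self, ld_scores, tmp_path):
        p = tmp_path / "scores.l2.ldscore"
        write_ld_scores(ld_scores, p)
        back = read_ld_scores(p)
        np.testing.assert_allclose(back.df["L2"], ld_scores.df["L2"], atol=1e-6)


def _scan(panel, cfg):
    y, _ = simulate_phenotype(panel, cfg)
    return gwas_scan(panel, y)


class TestH2:
    def test_constant_chisq_gives_zero_slope(self, ld_panel, ld_scores):
        df = ld_panel.snp_map.rename(
            columns={"REF": "OA", "ALT": "EA", "AF": "EAF"}
        ).copy()
        df["BETA"] = np.nan
        df["SE"] = np.nan
        df["P"] = np.nan
        df["Z"] = 1.0
        df["N"] = 2000.0
        t = SumstatsTable(StudyMetadata("c", "c", "complex_trait"), df)
        est = estimate_h2(t, ld_scores, m=800, n=2000)
        assert est.h2 == pytest.approx(0.0, abs=1e-10)
        assert est.intercept == pytest.approx(1.0, abs=1e-10)

    def test_recovery_coverage(self, ld_panel, ld_scores):
        """The +-2 jackknife-SE interval covers the true h2 in most seeds."""
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.5,
                            n_causal=800, seed=400 + seed)
            est = estimate_h2(_scan(ld_panel, cfg), ld_scores, m=800, n=2000)
            assert est.h2_se > 0 and est.intercept_se > 0
            hits += abs(est.h2 - 0.5) <= 2 * est.h2_se
        assert hits >= 8

    def test_null_trait_recovery(self, ld_panel, ld_scores):
        """Null traits give h2 ~ 0 and intercept ~ 1 in most seeds."""
        h_hits = i_hits = 0
        for seed in range(10):
            cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.0,
                            n_causal=800, seed=500 + seed)
            est = estimate_h2(_scan(ld_panel, cfg), ld_scores, m=800, n=2000)
            h_hits += abs(est.h2) <= 2 * est.h2_se
            i_hits += abs(est.intercept - 1.0) <= 2 * est.intercept_se
        assert h_hits >= 8 and i_hits >= 8

    def test_snp_order_invariance(self, ld_panel, ld_scores):
        cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.4,
                        n_causal=800, seed=24)
        t = _scan(ld_panel, cfg)
        shuffled = SumstatsTable(
            t.metadata, t.df.sample(frac=1, random_state=9).reset_index(drop=True)
        )
        a = estimate_h2(t, ld_scores, m=800, n=2000)
        b = estimate_h2(shuffled, ld_scores, m=800, n=2000)
        assert a.h2 == pytest.approx(b.h2, rel=1e-12)
        assert a.h2_se == pytest.approx(b.h2_se, rel=1e-12)

    def test_too_many_blocks_rejected(self, ld_panel, ld_scores):
        cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.4,
                        n_causal=800, seed=25)
        with pytest.raises(ValueError, match="n_blocks"):
            estimate_h2(_scan(ld_panel, cfg), ld_scores, m=800, n=2000, n_blocks=150)

    def test_intercept_one_null_slope_unbiased(self, ld_panel, ld_scores):
        ests = []
        for seed in range(30):
            cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.0,
                            n_causal=10, seed=100 + seed)
            est = estimate_h2(_scan(ld_panel, cfg), ld_scores, m=800, n=2000,
                              intercept_one=True)
            ests.append(est.h2)
        ests = np.array(ests)
        sem = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean()) < 2.5 * sem


class TestRg:
    def test_self_correlation_is_exactly_one(self, ld_panel, ld_scores):
        cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.5,
                        n_causal=800, seed=26)
        t = _scan(ld_panel, cfg)
        est = genetic_correlation(t, t, ld_scores, m=800, n1=2000, n2=2000)
        assert est.rg == pytest.approx(1.0, abs=1e-12)
        assert abs(est.cross_intercept - 1.0) < 0.5

    def test_symmetry_and_scaling(self, ld_panel, ld_scores):
        cfg1 = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.5,
                         n_causal=800, seed=27)
        panel = ld_panel
        y, truth = simulate_phenotype(panel, cfg1)
        t1 = gwas_scan(panel, y)
        rng = np.random.default_rng(28)
        y2 = y + 0.5 * rng.standard_normal(len(y))
        t2 = gwas_scan(panel, (y2 - y2.mean()) / y2.std())
        a = genetic_correlation(t1, t2, ld_scores, m=800, n1=2000, n2=2000)
        b = genetic_correlation(t2, t1, ld_scores, m=800, n1=2000, n2=2000)
        assert a.rg == pytest.approx(b.rg, rel=1e-9)

        t2_scaled = t2.copy()
        t2_scaled.df["BETA"] *= 3.0
        t2_scaled.df["SE"] *= 3.0
        c = genetic_correlation(t1, t2_scaled, ld_scores, m=800, n1=2000, n2=2000)
        assert c.rg == pytest.approx(a.rg, rel=1e-9)

        t2_neg = t2.copy()
        t2_neg.df["BETA"] *= -1.0
        t2_neg.df["Z"] *= -1.0
        d = genetic_correlation(t1, t2_neg, ld_scores, m=800, n1=2000, n2=2000)
        assert d.rg == pytest.approx(-a.rg, rel=1e-9)

    def test_shared_architecture_rg_near_one(self, ld_panel, ld_scores):
        # same genetic component, independent environments
        cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.6,
                        n_causal=800, seed=29)
        panel = ld_panel
        G = panel.dosages().astype(float)
        rng = np.random.default_rng(30)
        causal = rng.choice(800, 80, replace=False)
        betas = rng.normal(0, np.sqrt(0.6 / 80), 80)
        Gs = (G[:, causal] - G[:, causal].mean(0)) / G[:, causal].std(0)
        g = Gs @ betas
        y1 = g + rng.standard_normal(2000) * np.sqrt(0.4)
        y2 = 2.0 * g + rng.standard_normal(2000) * np.sqrt(1.6)
        t1 = gwas_scan(panel, (y1 - y1.mean()) / y1.std())
        t2 = gwas_scan(panel, (y2 - y2.mean()) / y2.std())
        est = genetic_correlation(t1, t2, ld_scores, m=800, n1=2000, n2=2000)
        assert abs(est.rg - 1.0) <= max(2 * est.rg_se, 0.1)

    def test_independent_traits_rg_near_zero(self, ld_panel, ld_scores):
        cfg1 = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.5,
                         n_causal=800, seed=31)
        cfg2 = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.5,
                         n_causal=800, seed=32)
        t1 = _scan(ld_panel, cfg1)
        t2 = _scan(ld_panel, cfg2)
        est = genetic_correlation(t1, t2, ld_scores, m=800, n1=2000, n2=2000)
        assert abs(est.rg) <= max(2 * est.rg_se, 0.2)

    def test_disjoint_snps_rejected(self, ld_panel, ld_scores):
        cfg = SimConfig(n_individuals=2000, m_snps=800, ld_rho=0.5, h2=0.5,
                        n_causal=800, seed=33)
        t1 = _scan(ld_panel, cfg)
        t2 = t1.copy()
        t2.df["SNP"] = "x_" + t2.df["SNP"]
        with pytest.raises(ValueError):
            genetic_correlation(t1, t2, ld_scores, m=800, n1=2000, n2=2000)
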