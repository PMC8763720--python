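"""SMR, HEIDI and θ on simulated regions."""

import numpy as np
import pytest
from scipy import stats

from gwaskit import SimConfig, gwas_scan, simulate_panel, smr_test, theta_metric
from gwaskit.coloc import (
    RegionProfiles,
    build_region,
    coloc_region,
    heidi_test,
    ld_matrix,
    select_heidi_snps,
)


def region_from_sim(seed, causal1, causal2, b1=0.15, b2=0.2, n=2000, m=50, rho=0.9):
    """Two traits driven by (possibly different) causal SNPs of one locus."""
    cfg = SimConfig(n_individuals=n, m_snps=m, ld_rho=rho, n_causal=1, seed=seed)
    panel = simulate_panel(cfg)
    G = panel.dosages().astype(float)
    rng = np.random.default_rng(seed + 10_000)

    def trait(idx, b):
        x = G[:, idx]
        sd = x.std()
        if sd == 0:
            return None
        x = (x - x.mean()) / sd
        y = b * x + rng.standard_normal(n)
        return (y - y.mean()) / y.std()

    y1 = trait(causal1, b1)
    y2 = trait(causal2, b2)
    if y1 is None or y2 is None:
        return None
    t1 = gwas_scan(panel, y1)
    t2 = gwas_scan(panel, y2)
    return build_region(t1, t2, panel)


class TestSmr:
    @pytest.mark.parametrize(
        "z1,z2,expected", [(2, 2, 2.0), (4, 3, 5.76), (-4, 3, 5.76)]
    )
    def test_closed_forms(self, z1, z2, expected):
        t, p = smr_test(z1, z2)
        assert t == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_limit_is_smaller_chisq(self):
        t, _ = smr_test(4.0, 1e9)
        assert t == pytest.approx(16.0, rel=1e-6)
        for z1, z2 in [(1.5, 2.5), (3, 3), (0.5, 7)]:
            t, _ = smr_test(z1, z2)
            assert t < min(z1**2, z2**2)

    def test_degenerate_zero(self):
        t, p = smr_test(0.0, 0.0)
        assert np.isnan(t) and np.isnan(p)


class TestHeidiSelection:
    def test_only_top_when_nothing_passes(self):
        region = RegionProfiles(
            snp_ids=["a", "b", "c"],
            z_trait1=[1.0, 0.5, 0.2],
            z_trait2=[8.0, 1.0, 0.5],  # b, c not significant
            ld=np.eye(3) * 0.5 + 0.5,
            top_index=0,
        )
        assert select_heidi_snps(region) == [0]

    def test_perfect_ld_pruned(self):
        k = 5
        region = RegionProfiles(
            snp_ids=[f"s{i}" for i in range(k)],
            z_trait1=np.full(k, 5.0),
            z_trait2=np.full(k, 8.0),
            ld=np.ones((k, k)),  # r2 = 1 with top: above r2_max
            top_index=0,
        )
        assert select_heidi_snps(region) == [0]

    def test_selected_set_obeys_all_rules(self):
        region = region_from_sim(3, 25, 25)
        sel = select_heidi_snps(region)
        sel2 = select_heidi_snps(region)
        assert sel == sel2  # deterministic
        t = region.top_index
        assert sel[0] == t and len(sel) <= 20
        p2 = 2 * stats.norm.sf(np.abs(region.z_trait2))
        for i in sel[1:]:
            assert p2[i] < 1.6e-4
            assert 0.05 <= region.ld[t, i] ** 2 <= 0.9
        for a in sel[1:]:
            for b in sel[1:]:
                if a != b:
                    assert region.ld[a, b] ** 2 <= 0.9


class TestHeidi:
    def test_no_heterogeneity_gives_p_one(self):
        # z1 exactly proportional to z2 -> all ratios equal -> T = 0
        k = 6
        R = 0.6 * np.ones((k, k)) + 0.4 * np.eye(k)
        z2 = np.array([9.0, 8.0, 7.0, 6.5, 6.0, 5.5])
        region = RegionProfiles(
            snp_ids=[f"s{i}" for i in range(k)],
            z_trait1=0.5 * z2,
            z_trait2=z2,
            ld=R,
            top_index=0,
        )
        p, n_used = heidi_test(region, list(range(k)), seed=1)
        assert p == 1.0 and n_used == k

    def test_too_few_snps_missing(self):
        region = region_from_sim(4, 25, 25)
        p, n_used = heidi_test(region, [region.top_index], seed=1)
        assert p is None and n_used == 1

    def test_seeded_reproducibility_and_mc_stability(self):
        region = region_from_sim(5, 25, 30)
        sel = select_heidi_snps(region)
        if len(sel) < 3:
            pytest.skip("selection too small for this locus")
        p_a, _ = heidi_test(region, sel, seed=7)
        p_b, _ = heidi_test(region, sel, seed=7)
        assert p_a == p_b  # bit-identical under one seed
        p_c, _ = heidi_test(region, sel, seed=8)
        assert abs(p_a - p_c) < 0.01 + 0.1 * p_a

    def test_invariant_to_global_sign_flip(self):
        region = region_from_sim(6, 25, 25)
        sel = select_heidi_snps(region)
        if len(sel) < 3:
            pytest.skip("selection too small for this locus")
        flipped = RegionProfiles(
            snp_ids=region.snp_ids,
            z_trait1=-region.z_trait1,
            z_trait2=-region.z_trait2,
            ld=region.ld,
            top_index=region.top_index,
        )
        p1, _ = heidi_test(region, sel, seed=3)
        p2, _ = heidi_test(flipped, sel, seed=3)
        assert p1 == p2

    def test_type_one_error_shared_causal(self):
        """Under one shared causal variant, HEIDI rejects at ~nominal rate."""
        n_sig = n_done = 0
        seed = 0
        while n_done < 60 and seed < 120:
            region = region_from_sim(seed, 25, 25)
            seed += 1
            if region is None:
                continue
            sel = select_heidi_snps(region)
            if len(sel) < 3:
                continue
            p, _ = heidi_test(region, sel, mc_draws=20_000, seed=seed)
            n_done += 1
            n_sig += p < 0.05
        assert n_done >= 50
        assert 0.0 <= n_sig / n_done <= 0.15

    def test_power_distinct_causal(self):
        """Two distinct causal variants in LD: heterogeneity detected."""
        ps = []
        seed = 1000
        while len(ps) < 40 and seed < 1120:
            region = region_from_sim(seed, 30, 25, b1=0.2)
            seed += 1
            if region is None:
                continue
            sel = select_heidi_snps(region)
            if len(sel) < 3:
                continue
            p, _ = heidi_test(region, sel, mc_draws=20_000, seed=seed)
            ps.append(p)
        assert np.median(ps) < 0.05


class TestTheta:
    def test_identical_negated_orthogonal(self):
        base = RegionProfiles(
            snp_ids=["a", "b"], z_trait1=[1.0, 0.0], z_trait2=[1.0, 0.0],
            ld=np.eye(2), top_index=0,
        )
        assert theta_metric(base) == pytest.approx(1.0)
        neg = RegionProfiles(
            snp_ids=["a", "b"], z_trait1=[1.0, 2.0], z_trait2=[-1.0, -2.0],
            ld=np.eye(2), top_index=0,
        )
        assert theta_metric(neg) == pytest.approx(-1.0)
        orth = RegionProfiles(
            snp_ids=["a", "b"], z_trait1=[1.0, 0.0], z_trait2=[0.0, 1.0],
            ld=np.eye(2), top_index=0,
        )
        assert theta_metric(orth) == pytest.approx(0.0)

    def test_scale_and_orientation_invariance(self, rng):
        z1 = rng.normal(0, 2, 30)
        z2 = 0.5 * z1 + rng.normal(0, 1, 30)
        mk = lambda a, b: RegionProfiles(
            snp_ids=[f"s{i}" for i in range(30)], z_trait1=a, z_trait2=b,
            ld=np.eye(30), top_index=0,
        )
        base = theta_metric(mk(z1, z2))
        assert theta_metric(mk(3 * z1, z2)) == pytest.approx(base, rel=1e-12)
        # jointly flipping one SNP's orientation leaves theta unchanged
        z1f, z2f = z1.copy(), z2.copy()
        z1f[4] *= -1
        z2f[4] *= -1
        assert theta_metric(mk(z1f, z2f)) == pytest.approx(
            base - 2 * (z1[4] * z2[4]) / np.sqrt((z1**2).sum() * (z2**2).sum())
            + 2 * (z1f[4] * z2f[4]) / np.sqrt((z1**2).sum() * (z2**2).sum()),
            rel=1e-9,
        )
        assert theta_metric(mk(z1f, z2f)) == pytest.approx(base, rel=1e-9)

    def test_zero_vector_missing(self):
        region = RegionProfiles(
            snp_ids=["a", "b"], z_trait1=[0.0, 0.0], z_trait2=[1.0, 1.0],
            ld=np.eye(2), top_index=0,
        )
        assert np.isnan(theta_metric(region))


class TestRegion:
    def test_ld_matrix_properties(self):
        panel = simulate_panel(
            SimConfig(n_individuals=300, m_snps=30, ld_rho=0.7, n_causal=1, seed=9)
        )
        R = ld_matrix(panel)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1.0)

    def test_coloc_region_end_to_end(self):
        region = region_from_sim(11, 25, 25)
        res = coloc_region(region, mc_draws=20_000, seed=2)
        assert res.t_smr > 0 and 0 < res.p_smr <= 1
        assert -1 <= res.theta <= 1
        # shared signal: profiles strongly similar
        assert res.theta > 0.5
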