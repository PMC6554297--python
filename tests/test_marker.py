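import numpy as np
import pytest

import bsascan as b
from bsascan.genome import GenomeMap


class TestBulkAlleleFrequency:
    def test_degenerate_and_mixed_pools(self):
        assert b.bulk_allele_frequency([2] * 20) == (1.0, 0.0)
        assert b.bulk_allele_frequency([2] * 10 + [0] * 10) == (0.5, 0.5)
        # 12 BB, 6 het, 2 aa -> 30/40 donor alleles, the pattern seen at a
        # validated starch-synthase marker in the high pool
        donor, other = b.bulk_allele_frequency([2] * 12 + [1] * 6 + [0] * 2)
        assert (donor, other) == (0.75, 0.25)

    def test_missing_handling(self):
        donor, _ = b.bulk_allele_frequency([2.0, np.nan, 0.0])
        assert donor == 0.5
        with pytest.raises(ValueError):
            b.bulk_allele_frequency([np.nan, np.nan])
        with pytest.raises(ValueError):
            b.bulk_allele_frequency([3, 0])


class TestSingleMarker:
    def test_flat_phenotype_gives_zero_lod_pve(self):
        codes = np.tile([0, 1, 2], 30)
        # varies, but exactly orthogonal to the (-1, 0, +1) coding
        res = b.single_marker(codes, np.tile([1.0, 2.0, 1.0], 30))
        assert res.lod == pytest.approx(0.0, abs=1e-6)
        assert res.pve == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_additive_effect_is_half_homozygote_gap(self):
        # homozygote means differ by 0.21 -> additive effect 0.105
        codes = np.tile([0, 1, 2], 20)
        phen = 1.5 + 0.105 * (codes - 1.0)
        res = b.single_marker(codes, phen, marker="SSIIa")
        assert res.additive_effect == pytest.approx(0.105, abs=1e-12)
        assert res.donor == "donor"
        assert res.pve == pytest.approx(100.0, abs=1e-9)

    def test_lod_closed_form_at_published_scale(self):
        # construct data with n=170 and R^2 ~ 0.1858, then check the
        # regression-LOD identity LOD = -(n/2) log10(1 - R^2)
        rng = np.random.default_rng(41)
        codes = rng.integers(0, 3, 170)
        phen = 0.1 * (codes - 1.0) + rng.normal(0, 0.2, 170)
        res = b.single_marker(codes, phen)
        r2 = res.pve / 100
        assert res.lod == pytest.approx(-(170 / 2) * np.log10(1 - r2), abs=1e-10)
        # frozen closed form at the published PVE: -(170/2) log10(1-0.1858)
        assert -(170 / 2) * np.log10(1 - 0.1858) == pytest.approx(7.5879, abs=1e-4)

    def test_lod_identity_against_two_model_rss(self):
        rng = np.random.default_rng(43)
        codes = rng.integers(0, 3, 120).astype(float)
        phen = 0.3 * (codes - 1) + rng.normal(0, 1, 120)
        res = b.single_marker(codes, phen)
        x = codes - 1
        slope, intercept = np.polyfit(x, phen, 1)
        rss1 = np.sum((phen - intercept - slope * x) ** 2)
        rss0 = np.sum((phen - phen.mean()) ** 2)
        lod_rss = (len(phen) / 2) * np.log10(rss0 / rss1)
        assert res.lod == pytest.approx(lod_rss, abs=1e-10)

    def test_donor_flips_under_phenotype_negation(self):
        rng = np.random.default_rng(47)
        codes = rng.integers(0, 3, 80)
        phen = 0.5 * (codes - 1.0) + rng.normal(0, 0.5, 80)
        res = b.single_marker(codes, phen, donor_name="P1", other_name="P2")
        flipped = b.single_marker(codes, -phen, donor_name="P1", other_name="P2")
        assert res.donor == "P1" and flipped.donor == "P2"
        assert res.lod == pytest.approx(flipped.lod, abs=1e-12)

    def test_listwise_deletion_and_errors(self):
        codes = np.array([0, 1, 2, np.nan, 2])
        phen = np.array([0.1, 0.2, 0.3, 0.4, np.nan])
        res = b.single_marker(codes, phen)
        assert res.n == 3
        with pytest.raises(ValueError):
            b.single_marker([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            b.single_marker([0, 2], [0.1, 0.2])

    def test_genotypic_model_captures_dominance(self):
        codes = np.tile([0, 1, 2], 30)
        phen = np.where(codes == 0, -1.0, 1.0)  # fully dominant, noiseless
        add = b.single_marker(codes, phen, model="additive")
        dom = b.single_marker(codes, phen, model="genotypic")
        assert dom.pve == pytest.approx(100.0, abs=1e-9)
        assert add.pve < dom.pve
        assert dom.additive_effect == pytest.approx(1.0, abs=1e-12)


class TestJointPve:
    def test_collinear_markers_equal_single(self):
        rng = np.random.default_rng(53)
        codes = rng.integers(0, 3, 100).astype(float)
        phen = 0.4 * codes + rng.normal(0, 1, 100)
        single = b.single_marker(codes, phen).pve
        joint = b.joint_pve(np.column_stack([codes, codes]), phen,
                            marker_names=["m1", "m2"])
        assert joint.pve == pytest.approx(single, abs=1e-9)
        assert joint.dropped == ("m2",)

    def test_orthogonal_noiseless_markers_sum(self):
        # 3x3 factorial: the two dosage columns are exactly orthogonal
        g1, g2 = np.meshgrid([0, 1, 2], [0, 1, 2])
        g1, g2 = g1.ravel().astype(float), g2.ravel().astype(float)
        phen = (g1 - 1) + 2 * (g2 - 1)
        pve1 = b.single_marker(g1, phen).pve
        pve2 = b.single_marker(g2, phen).pve
        joint = b.joint_pve(np.column_stack([g1, g2]), phen)
        assert joint.pve == pytest.approx(pve1 + pve2, abs=1e-9)
        assert joint.pve == pytest.approx(100.0, abs=1e-9)

    def test_joint_at_least_max_single(self):
        rng = np.random.default_rng(59)
        X = rng.integers(0, 3, size=(150, 3)).astype(float)
        phen = 0.3 * X[:, 0] - 0.2 * X[:, 2] + rng.normal(0, 1, 150)
        singles = [b.single_marker(X[:, j], phen).pve for j in range(3)]
        assert b.joint_pve(X, phen).pve >= max(singles) - 1e-12

    def test_two_qtl_simulation_recovers_heritability(self):
        # two unlinked QTLs, a=0.5 each, h2=0.4, n=170; the joint PVE of the
        # two causal markers recovers the simulated heritability on average
        gm = GenomeMap(
            (("c1", 1_000_000), ("c2", 1_000_000)),
            {"c1": np.array([500_000]), "c2": np.array([500_000])},
        )
        qtls = [b.QTLSpec("c1", 500_000, 0.5), b.QTLSpec("c2", 500_000, 0.5)]
        pves = []
        for seed in range(100):
            dos = b.simulate_f2(gm, 170, seed=seed)
            phen = b.simulate_phenotypes(dos, gm, qtls, 0.4, seed=seed + 10_000)
            pves.append(b.joint_pve(dos.astype(float), phen).pve)
        assert abs(np.mean(pves) - 40.0) < 5.0


class TestGeRatio:
    def test_parental_scale_ratios(self):
        # replicate means at the parental scale: 14.47/6.38 and 11.09/7.36 mm
        basmati_milled = [[6.38 - 0.1, 6.38, 6.38 + 0.1]] * 3
        basmati_cooked = [[14.47 - 0.2, 14.47, 14.47 + 0.2]] * 3
        mean, sd = b.ge_ratio(basmati_milled, basmati_cooked)
        assert mean == pytest.approx(14.47 / 6.38, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)
        mean, _ = b.ge_ratio([[7.36] * 10] * 3, [[11.09] * 10] * 3)
        assert mean == pytest.approx(11.09 / 7.36, abs=1e-12)

    def test_identity_and_scale_invariance(self):
        lengths = [[5.0, 6.0], [5.5, 6.5], [6.0, 7.0]]
        mean, sd = b.ge_ratio(lengths, lengths)
        assert mean == 1.0 and sd == 0.0
        scaled = [[x * 3.7 for x in rep] for rep in lengths]
        cooked = [[x * 2.0 for x in rep] for rep in lengths]
        cooked_scaled = [[x * 3.7 for x in rep] for rep in cooked]
        assert b.ge_ratio(lengths, cooked) == pytest.approx(
            b.ge_ratio(scaled, cooked_scaled)
        )

    def test_invalid_measurements_rejected(self):
        with pytest.raises(ValueError):
            b.ge_ratio([[0.0, 5.0]], [[10.0, 11.0]])
        with pytest.raises(ValueError):
            b.ge_ratio([], [])
        with pytest.raises(ValueError):
            b.ge_ratio([[5.0]], [[10.0], [11.0]])
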