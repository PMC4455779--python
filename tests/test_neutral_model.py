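"""Coalescent null model: Watterson arithmetic, simulator statistics,
reference ascertainment, spectrum comparison."""

import numpy as np
import pytest

from soysv import neutral_model as nm
from soysv.segments_sfs import Spectrum


class TestClosedForms:
    def test_ne_from_theta(self):
        # theta_W = 4 Ne mu with mu = 7e-9 and the reported theta gives the
        # reported effective size of 29,642 (truncated)
        assert nm.estimate_ne(8.3e-4, 7e-9) == 29_642

    def test_ne_identity_and_linearity(self):
        assert nm.estimate_ne(4 * 7e-9, 7e-9) == 1
        assert nm.estimate_ne(2 * 8.3e-4, 7e-9) == 2 * 29_642 or (
            nm.estimate_ne(2 * 8.3e-4, 7e-9) in (59_284, 59_285)
        )

    def test_ne_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nm.estimate_ne(0.0)

    def test_watterson_theta(self):
        assert nm.estimate_theta_locus(0, 42) == 0.0
        assert nm.estimate_theta_locus(10, 2) == pytest.approx(10.0)
        # 547 observed Down segments in a sample of 42 chromosomes:
        # a_41 = sum_{i<42} 1/i = 4.3030, theta ~ 127.1
        a41 = sum(1.0 / i for i in range(1, 42))
        assert nm.estimate_theta_locus(547, 42) == pytest.approx(547 / a41)
        assert nm.estimate_theta_locus(547, 42) == pytest.approx(127.1, abs=0.1)


class TestSimulator:
    def test_zero_theta_no_sites(self):
        haps = nm.simulate_neutral(
            nm.PopGenParams(n_chrom=10, theta_locus=0.0, rho_locus=0.0,
                            n_loci=20, seed=1)
        )
        assert all(h.n_sites == 0 for h in haps)

    def test_pairwise_expected_segregating_sites(self):
        # n=2, rho=0: E[S] = theta (a_1 = 1)
        theta = 3.0
        haps = nm.simulate_neutral(
            nm.PopGenParams(n_chrom=2, theta_locus=theta, rho_locus=0.0,
                            n_loci=4000, seed=2)
        )
        S = np.array([h.n_sites for h in haps])
        se = S.std(ddof=1) / np.sqrt(len(S))
        assert abs(S.mean() - theta) < 3.5 * se

    def test_unascertained_sfs_theta_over_k(self):
        haps = nm.simulate_neutral(
            nm.PopGenParams(n_chrom=10, theta_locus=2.0, rho_locus=0.0,
                            n_loci=4000, seed=3)
        )
        k = np.arange(1, 10)
        expected = (1.0 / k) / np.sum(1.0 / k)
        z = nm.sfs_class_z_scores(haps, expected, ascertained=False)
        assert np.abs(z).max() < 3.5

    def test_recombination_preserves_expected_s(self):
        theta = 2.0
        expect = theta * nm.harmonic(9)
        haps = nm.simulate_neutral(
            nm.PopGenParams(n_chrom=10, theta_locus=theta, rho_locus=5.0,
                            n_loci=1200, seed=4)
        )
        S = np.array([h.n_sites for h in haps])
        se = S.std(ddof=1) / np.sqrt(len(S))
        assert abs(S.mean() - expect) < 3.5 * se

    def test_matches_msprime_ascertained_shape(self):
        """Independent oracle: msprime's simulator ascertained the same way."""
        import msprime

        n, theta, L = 10, 2.0, 4000
        counts = np.zeros(n - 1)
        seed_rng = np.random.default_rng(101)
        reps = msprime.sim_ancestry(
            samples=n, ploidy=1, sequence_length=1, num_replicates=L,
            random_seed=103,
        )
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=theta / 2, discrete_genome=False,
                random_seed=int(seed_rng.integers(1, 2**31)),
            )
            mat = mts.genotype_matrix().T  # samples x sites
            if mat.shape[1] == 0:
                continue
            keep = mat[0] == 0
            ks = mat[1:, keep].sum(axis=0)
            ks = ks[ks > 0]
            counts += np.bincount(ks, minlength=n)[1:n]
        ours = nm.ascertain_reference(
            nm.simulate_neutral(
                nm.PopGenParams(n_chrom=n, theta_locus=theta, rho_locus=0.0,
                                n_loci=L, seed=5)
            )
        )
        p_ms = counts / counts.sum()
        p_us = ours.proportions()
        assert np.abs(p_ms - p_us).max() < 0.03


class TestAscertainment:
    def test_column_rules(self):
        mat = np.array(
            [
                [1, 0, 0],
                [0, 1, 0],
                [1, 1, 0],
                [0, 1, 1],
            ],
            dtype=np.uint8,
        )
        spec = nm.ascertain_reference([nm.HaplotypeMatrix(matrix=mat)])
        # col0 discarded (ref derived); col1 -> k=3; col2 -> k=1
        assert list(spec.counts) == [1, 0, 1]

    def test_column_conservation(self):
        haps = nm.simulate_neutral(
            nm.PopGenParams(n_chrom=8, theta_locus=2.0, rho_locus=0.0,
                            n_loci=500, seed=6)
        )
        total = sum(h.n_sites for h in haps)
        kept = sum(int((h.matrix[0] == 0).sum()) for h in haps if h.n_sites)
        discarded = sum(int((h.matrix[0] == 1).sum()) for h in haps if h.n_sites)
        assert kept + discarded == total

    def test_discard_probability_is_k_over_n(self):
        """Brute-force scan at n=4: a class-k column is discarded with
        probability k/n by exchangeability, giving the (n-k)/(n k) shape."""
        n = 4
        haps = nm.simulate_neutral(
            nm.PopGenParams(n_chrom=n, theta_locus=1.0, rho_locus=0.0,
                            n_loci=20_000, seed=7)
        )
        kept = np.zeros(n)
        seen = np.zeros(n)
        for h in haps:
            if not h.n_sites:
                continue
            ktot = h.matrix.sum(axis=0)
            ref = h.matrix[0]
            for k, r in zip(ktot, ref):
                seen[k - 1] += 1
                kept[k - 1] += 1 - r
        for k in (1, 2, 3):
            frac = kept[k - 1] / seen[k - 1]
            expect = (n - k) / n
            se = np.sqrt(expect * (1 - expect) / seen[k - 1])
            assert abs(frac - expect) < 4 * se

    def test_ascertained_shape_closed_form(self):
        n = 10
        haps = nm.simulate_neutral(
            nm.PopGenParams(n_chrom=n, theta_locus=2.0, rho_locus=0.0,
                            n_loci=4000, seed=8)
        )
        z = nm.sfs_class_z_scores(
            haps, nm.expected_ascertained_shape(n), ascertained=True
        )
        assert np.abs(z).max() < 3.5


class TestCompare:
    def test_identical_spectra(self):
        spec = Spectrum(counts=np.array([30, 20, 10, 5]))
        cmp = nm.compare_spectra(spec, Spectrum(counts=spec.counts * 10))
        assert np.allclose(cmp.per_class_diff, 0)
        assert cmp.singleton_excess == 0.0
        assert cmp.p_value > 0.5

    def test_singleton_excess_sign(self):
        emp = Spectrum(counts=np.array([100, 0, 0, 0]))
        sim = Spectrum(counts=np.array([40, 30, 20, 10]))
        cmp = nm.compare_spectra(emp, sim)
        assert cmp.singleton_excess > 0
        assert cmp.p_value < 0.01

    def test_empty_spectrum_raises(self):
        with pytest.raises(ValueError):
            nm.compare_spectra(
                Spectrum(counts=np.zeros(4, dtype=int)),
                Spectrum(counts=np.array([1, 1, 1, 1])),
            )

    def test_planted_double_singleton_weight_detected(self):
        rng = np.random.default_rng(9)
        n = 8
        base = nm.expected_ascertained_shape(n + 1)[:n]
        base = base / base.sum()
        boosted = base * np.r_[2.0, np.ones(n - 1)]
        boosted /= boosted.sum()
        emp = Spectrum(counts=rng.multinomial(500, boosted))
        sim = Spectrum(counts=(base * 100_000).astype(int))
        cmp = nm.compare_spectra(emp, sim)
        planted_excess = boosted[0] - base[0]
        assert cmp.singleton_excess == pytest.approx(planted_excess, abs=0.06)


class TestMsOutput:
    def test_round_trippable_text(self, tmp_path):
        params = nm.PopGenParams(n_chrom=5, theta_locus=1.5, rho_locus=0.0,
                                 n_loci=10, seed=10)
        haps = nm.simulate_neutral(params)
        path = tmp_path / "out.ms"
        nm.write_ms(haps, path, params)
        text = path.read_text().splitlines()
        assert text[0].startswith("soysv-coalescent 5 10")
        assert sum(1 for line in text if line == "//") == 10
        seg_lines = [int(l.split()[1]) for l in text if l.startswith("segsites")]
        assert seg_lines == [h.n_sites for h in haps]
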