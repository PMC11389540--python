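"""Binned depth, panel normalisation, and the tumor-fraction HMM."""

import numpy as np
import pytest

import plasmafrac as pf
from plasmafrac import cna
from plasmafrac.fragments import FragmentRecord
from conftest import make_profile


class TestBins:
    def test_bin_tiling(self):
        bins = cna.make_bins({"chr1": 1_000_000}, bin_width=100_000)
        assert len(bins) == 10
        assert not bins["partial"].any()

    def test_partial_trailing_bin_flagged(self):
        bins = cna.make_bins({"chr1": 1_050_000}, bin_width=100_000)
        assert len(bins) == 11
        assert bins["partial"].iloc[-1]

    def test_mito_excluded(self):
        bins = cna.make_bins({"chr1": 1_000_000, "chrM": 16_000}, bin_width=100_000)
        assert set(bins["contig"]) == {"chr1"}

    def test_midpoint_rule(self):
        frag = FragmentRecord("chr1", 99_950, 100_150, 200, 60)  # midpoint 100,050
        bc = cna.bin_counts([frag], {"chr1": 1_000_000}, bin_width=100_000)
        assert bc.counts[1] == 1 and bc.counts.sum() == 1

    def test_uniform_coverage_poisson_spread(self, tiny_genome):
        profile = make_profile(n_fragments=100_000, mtdna_prob=0.0, seed=41,
                               end_bias=np.ones(64))
        frags = pf.simulate_sample(profile, tiny_genome)
        bc = cna.bin_counts(frags, tiny_genome, bin_width=10_000)
        full = ~bc.bins["partial"].to_numpy()
        mean = bc.counts[full].mean()
        assert np.all(np.abs(bc.counts[full] - mean) <= 5 * np.sqrt(mean))

    def test_bin_width_validated(self):
        with pytest.raises(ValueError):
            cna.make_bins({"chr1": 10_000}, bin_width=500)


def _binned(counts, sample_id="s"):
    bins = cna.make_bins({"chr1": 100_000 * len(counts)}, bin_width=100_000)
    return cna.BinnedCounts(sample_id=sample_id, bins=bins, counts=np.asarray(counts))


class TestPanelOfNormals:
    def test_identical_normals_reproduce_profile(self):
        normals = [_binned([100, 200, 100, 400]) for _ in range(3)]
        panel = cna.build_panel_of_normals(normals)
        np.testing.assert_allclose(panel.reference, np.array([100, 200, 100, 400]) / 200)

    def test_median_robust_to_one_outlier(self):
        normals = [_binned([100, 100, 100, 100]) for _ in range(4)]
        normals.append(_binned([100, 200, 100, 100]))  # doubled bin in one normal
        panel = cna.build_panel_of_normals(normals)
        assert panel.reference[1] == pytest.approx(panel.reference[0], rel=0.03)

    def test_zero_median_bins_masked_and_counted(self):
        normals = [_binned([100, 0, 100, 100]) for _ in range(3)]
        panel = cna.build_panel_of_normals(normals)
        assert panel.n_masked == 1 and panel.mask[1]

    def test_requires_three_normals(self):
        with pytest.raises(ValueError):
            cna.build_panel_of_normals([_binned([1, 2]), _binned([1, 2])])


class TestLog2Ratios:
    def test_sample_matching_panel_is_zero(self):
        normals = [_binned([100, 200, 100, 400]) for _ in range(3)]
        panel = cna.build_panel_of_normals(normals)
        lr = cna.log2_ratios(_binned([100, 200, 100, 400]), panel)
        np.testing.assert_allclose(lr, 0.0, atol=1e-12)

    def test_doubled_bin_noiseless(self):
        normals = [_binned([100] * 50) for _ in range(3)]
        panel = cna.build_panel_of_normals(normals)
        counts = np.full(50, 100)
        counts[7] = 200
        lr = cna.log2_ratios(_binned(counts), panel)
        # depth normalisation shifts all bins by the mean; difference is exact
        assert lr[7] - lr[0] == pytest.approx(1.0)

    def test_closed_form_mixture_ratio(self):
        """TF=0.4 with CN=3: expected log2((0.4*3 + 0.6*2)/2) = log2(1.2)."""
        normals = [_binned([1000] * 60) for _ in range(3)]
        panel = cna.build_panel_of_normals(normals)
        counts = np.full(60, 1000.0)
        counts[:6] *= 1.2
        lr = cna.log2_ratios(cna.BinnedCounts("s", normals[0].bins, counts.astype(int)), panel)
        # depth normalisation shifts every bin by log2(sample mean factor);
        # the altered-minus-neutral difference is exactly log2(1.2)
        assert lr[0] - lr[30] == pytest.approx(np.log2(1.2), abs=1e-9)
        assert lr[0] == pytest.approx(np.log2(1.2 / 1.02), abs=1e-9)

    def test_masked_bins_propagate_nan(self):
        normals = [_binned([100, 0, 100, 100]) for _ in range(3)]
        panel = cna.build_panel_of_normals(normals)
        lr = cna.log2_ratios(_binned([100, 50, 100, 100]), panel)
        assert np.isnan(lr[1]) and np.isfinite(lr[[0, 2, 3]]).all()


class TestTumorFractionHMM:
    def test_null_sample(self, rng):
        x = rng.normal(0, 0.05, size=300)
        est, prof = cna.estimate_tumor_fraction(x)
        assert est.tumor_fraction <= 0.03
        assert (prof.state == 2).all()

    def test_noiseless_gain_recovers_tf(self):
        x = np.concatenate([np.full(100, np.log2(1.2)), np.zeros(100)])
        est, prof = cna.estimate_tumor_fraction(x)
        assert est.tumor_fraction == pytest.approx(0.40, abs=0.02)
        assert (prof.state[:100] == 3).all() and (prof.state[100:] == 2).all()

    def test_noiseless_loss_recovers_tf(self):
        x = np.concatenate([np.full(67, np.log2(0.9)), np.zeros(133)])
        est, prof = cna.estimate_tumor_fraction(x)
        assert est.tumor_fraction == pytest.approx(0.20, abs=0.02)
        assert (prof.state[:67] == 1).all()

    def test_scaling_counts_leaves_estimate_unchanged(self, panel, default_genome):
        profs = pf.build_cohort(1, pf.CohortConfig(seed=50, n_fragments=200_000,
                                                   tumor_fraction_range=(0.2, 0.2)))
        frags = pf.simulate_sample(profs[0], default_genome)
        bc = cna.bin_counts(frags, default_genome)
        est1, _ = cna.estimate_tumor_fraction(cna.log2_ratios(bc, panel))
        scaled = cna.BinnedCounts(bc.sample_id, bc.bins, bc.counts * 7)
        est2, _ = cna.estimate_tumor_fraction(cna.log2_ratios(scaled, panel))
        assert est1.tumor_fraction == est2.tumor_fraction

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            cna.estimate_tumor_fraction(np.zeros(30))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cna.estimate_tumor_fraction(np.zeros(100))

    def test_restart_values_present_in_grid(self):
        grid = cna.default_tf_grid()
        for tf in (0.05, 0.01, 0.005, 0.001):
            assert np.any(np.isclose(grid, tf))

    def test_forward_loglik_matches_hmmlearn(self, rng):
        """The grid likelihood agrees with an independent HMM implementation
        at fixed parameters."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        x = np.concatenate([rng.normal(0, 0.05, 150), rng.normal(np.log2(1.2), 0.05, 50)])
        tf, sigma = 0.4, 0.05
        model = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        model.startprob_ = np.full(3, 1 / 3)
        hmm = cna.TumorFractionHMM()
        model.transmat_ = hmm._transition()
        model.means_ = cna.state_means(tf).reshape(-1, 1)
        model.covars_ = np.full((3, 1), sigma**2)
        expected = model.score(x.reshape(-1, 1))
        E = hmm._emission_loglik(x, cna.state_means(np.array([tf])), np.array([sigma]))
        got, _ = hmm._forward(E)
        assert got[0] == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_true_tf(self, panel, default_genome):
        """Replicate-mean estimates increase with the simulated tumor
        fraction."""
        means = []
        for tf in (0.1, 0.2, 0.4):
            ests = []
            for rep in range(3):
                profs = pf.build_cohort(1, pf.CohortConfig(seed=60 + rep, n_fragments=200_000,
                                                           tumor_fraction_range=(tf, tf)))
                frags = pf.simulate_sample(profs[0], default_genome)
                lr = cna.log2_ratios(cna.bin_counts(frags, default_genome), panel)
                ests.append(cna.estimate_tumor_fraction(lr)[0].tumor_fraction)
            means.append(np.mean(ests))
        assert means[0] < means[1] < means[2]
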