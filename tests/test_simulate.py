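"""Synthetic-data generator: determinism, sampling correctness, cohorts."""

import filecmp

import numpy as np
import pytest

import plasmafrac as pf
from plasmafrac.genome import GenomeSpec
from conftest import make_profile


class TestGenerateReference:
    def test_contig_lengths_exact(self, tmp_path):
        spec = GenomeSpec(contigs=(("chr1", 30_000), ("chrM", 16_000)), seed=7)
        genome = pf.generate_reference(spec, path=tmp_path / "ref.fasta")
        assert genome.lengths == {"chr1": 30_000, "chrM": 16_000}
        import pyfaidx

        fa = pyfaidx.Fasta(str(tmp_path / "ref.fasta"))
        assert {k: len(fa[k]) for k in fa.keys()} == {"chr1": 30_000, "chrM": 16_000}

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        spec = GenomeSpec(contigs=(("chr1", 30_000), ("chrM", 16_000)), seed=7)
        pf.generate_reference(spec, path=tmp_path / "a.fasta")
        pf.generate_reference(spec, path=tmp_path / "b.fasta")
        assert filecmp.cmp(tmp_path / "a.fasta", tmp_path / "b.fasta", shallow=False)

    def test_duplicate_contig_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenomeSpec(contigs=(("chr1", 1000), ("chr1", 2000), ("chrM", 100)))

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(contigs=(("chr1", 0), ("chrM", 100)))


class TestSimulateSample:
    def test_fragment_count_contract(self, tiny_genome):
        frags = pf.simulate_sample(make_profile(n_fragments=1_000), tiny_genome)
        assert len(frags) == 1_000

    def test_zero_mtdna_prob_means_no_chrm_fragments(self, tiny_genome):
        frags = pf.simulate_sample(make_profile(mtdna_prob=0.0, n_fragments=2_000), tiny_genome)
        mito_idx = frags.contig_names.index("chrM")
        assert (frags.contig_idx == mito_idx).sum() == 0

    def test_same_seed_reproducible(self, tiny_genome):
        a = pf.simulate_sample(make_profile(seed=5), tiny_genome)
        b = pf.simulate_sample(make_profile(seed=5), tiny_genome)
        np.testing.assert_array_equal(a.start, b.start)
        np.testing.assert_array_equal(a.length, b.length)
        np.testing.assert_array_equal(a.contig_idx, b.contig_idx)

    def test_mtdna_proportion_recovers_parameter(self, tiny_genome):
        n, p = 100_000, 0.031
        frags = pf.simulate_sample(make_profile(mtdna_prob=p, n_fragments=n, seed=3), tiny_genome)
        mito_idx = frags.contig_names.index("chrM")
        observed = (frags.contig_idx == mito_idx).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se

    def test_cn_segment_enrichment_matches_mixture_weight(self):
        """With TF=0.4 and a CN=3 segment over half of chr1, the expected
        fraction of chr1 fragments in the segment is
        (0.4*3 + 0.6*2) / ((0.4*3 + 0.6*2) + 2) = 0.545..."""
        spec = GenomeSpec(contigs=(("chr1", 1_000_000), ("chrM", 16_000)), seed=9)
        genome = pf.generate_reference(spec)
        seg = pf.CNASegment("chr1", 0, 500_000, 3)
        n = 200_000
        profile = make_profile(n_fragments=n, tumor_fraction=0.4, cna_segments=(seg,),
                               mtdna_prob=0.0, end_bias=np.ones(64), seed=21)
        frags = pf.simulate_sample(profile, genome)
        mid = frags.start + frags.length // 2
        in_seg = (mid < 500_000).mean()
        expected = 2.4 / (2.4 + 2.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(in_seg - expected) <= 3 * se

    def test_size_mixture_modes_recovered(self, tiny_genome):
        frags = pf.simulate_sample(make_profile(group="fr1_5", n_fragments=100_000, seed=4),
                                   tiny_genome)
        dist = pf.size_distribution(frags)
        assert pf.modal_length(dist) == 167
        # the di-nucleosomal mode is a local maximum near 334
        dens = dist.density
        window = dens[330 - dist.low : 340 - dist.low]
        assert window.max() > dens[250 - dist.low]
        assert (frags.length > 1000).sum() > 0  # long component present

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            make_profile(n_fragments=0)
        with pytest.raises(ValueError):
            make_profile(mtdna_prob=1.5)
        with pytest.raises(ValueError):
            make_profile(end_bias=np.zeros(64))


class TestInjectNoise:
    @pytest.fixture()
    def sample_sam(self, tiny_genome, tmp_path):
        path = tmp_path / "clean.sam"
        pf.simulate_sample(make_profile(n_fragments=1_000, seed=8), tiny_genome, out_path=path)
        return path

    def test_zero_rates_identity(self, sample_sam, tmp_path):
        import pysam

        out = tmp_path / "noisy.sam"
        pf.inject_noise(sample_sam, out, 0.0, 0.0, seed=1)
        with pysam.AlignmentFile(str(sample_sam)) as a, pysam.AlignmentFile(str(out)) as b:
            for ra, rb in zip(a, b):
                assert ra.to_string() == rb.to_string()

    def test_exact_duplicate_pair_count(self, sample_sam, tmp_path):
        import pysam

        out = tmp_path / "noisy.sam"
        pf.inject_noise(sample_sam, out, dup_rate=0.1, lowmapq_rate=0.0, seed=1)
        with pysam.AlignmentFile(str(out)) as fh:
            dup_pairs = {r.query_name for r in fh if r.is_duplicate}
        assert len(dup_pairs) == 100

    def test_all_lowmapq_yields_zero_fragments(self, sample_sam, tmp_path):
        out = tmp_path / "noisy.sam"
        pf.inject_noise(sample_sam, out, dup_rate=0.0, lowmapq_rate=1.0, seed=1)
        frags, stats = pf.read_fragments(out)
        assert len(frags) == 0
        assert stats.dropped["low_mapq"] == 1_000

    def test_record_count_unchanged(self, sample_sam, tmp_path):
        out = tmp_path / "noisy.sam"
        pf.inject_noise(sample_sam, out, dup_rate=0.3, lowmapq_rate=0.2, seed=1)
        import pysam

        with pysam.AlignmentFile(str(sample_sam)) as a, pysam.AlignmentFile(str(out)) as b:
            assert sum(1 for _ in a) == sum(1 for _ in b)

    def test_rates_out_of_range_rejected(self, sample_sam, tmp_path):
        with pytest.raises(ValueError):
            pf.inject_noise(sample_sam, tmp_path / "x.sam", dup_rate=-0.1, lowmapq_rate=0, seed=1)


class TestBuildCohort:
    def test_counts_and_shared_patient_state(self):
        cfg = pf.CohortConfig(seed=2, n_fragments=1_000)
        profiles = pf.build_cohort(16, cfg)
        assert len(profiles) == 80
        by_patient = {}
        for p in profiles:
            by_patient.setdefault(p.patient_id, []).append(p)
        assert len(by_patient) == 16
        cna_profiles = set()
        for plist in by_patient.values():
            assert len({q.tumor_fraction for q in plist}) == 1
            assert len({q.cna_segments for q in plist}) == 1
            cna_profiles.add(plist[0].cna_segments)
        assert len(cna_profiles) == 16

    def test_long_component_only_in_fr1_5(self):
        for p in pf.build_cohort(3, pf.CohortConfig(seed=2, n_fragments=100)):
            long_w = p.size_mixture.component_weight("long")
            assert (long_w > 0) == (p.group == "fr1_5")

    def test_group_mtdna_defaults(self):
        probs = {p.group: p.mtdna_prob for p in pf.build_cohort(1, pf.CohortConfig(seed=0, n_fragments=100))}
        assert probs["cfDNA"] == pytest.approx(0.0069)
        assert probs["fr1_5"] == pytest.approx(0.031)

    def test_manifest_determinism(self, tmp_path):
        from plasmafrac.simulate import cohort_manifest

        cfg = pf.CohortConfig(seed=5, n_fragments=100)
        m1 = cohort_manifest(pf.build_cohort(2, cfg), tmp_path)
        m2 = cohort_manifest(pf.build_cohort(2, cfg), tmp_path)
        assert m1.equals(m2)

    def test_n_patients_validated(self):
        with pytest.raises(ValueError):
            pf.build_cohort(0)
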