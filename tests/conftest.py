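import numpy as np
import pytest

import plasmafrac as pf
from plasmafrac import cna
from plasmafrac.genome import Genome, GenomeSpec


@pytest.fixture(scope="session")
def tiny_spec() -> GenomeSpec:
    return GenomeSpec(
        contigs=(("chr1", 300_000), ("chr2", 300_000), ("chrM", 16_000)),
        mito_contig="chrM",
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_spec) -> Genome:
    return pf.generate_reference(tiny_spec)


@pytest.fixture(scope="session")
def default_genome() -> Genome:
    """The cohort-scale reference: 3 x 8 Mb autosome-like contigs + chrM."""
    return pf.generate_reference(pf.default_genome_spec(seed=1))


@pytest.fixture(scope="session")
def panel(default_genome):
    """Panel of normals at cohort depth, shared across copy-number tests."""
    cfg = pf.CohortConfig(seed=11, n_fragments=200_000)
    normals = [
        cna.bin_counts(pf.simulate_sample(p, default_genome), default_genome)
        for p in pf.build_panel_profiles(cfg)
    ]
    return cna.build_panel_of_normals(normals)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240814)


def make_profile(group="cfDNA", n_fragments=5_000, seed=7, tumor_fraction=0.0,
                 cna_segments=(), mtdna_prob=0.0069, end_bias=None, patient="P01"):
    """Convenience profile builder used across test modules."""
    return pf.SampleProfile(
        patient_id=patient,
        group=group,
        tumor_fraction=tumor_fraction,
        cna_segments=tuple(cna_segments),
        size_mixture=pf.default_mixture(group),
        mtdna_prob=mtdna_prob,
        end_bias=tuple(end_bias) if end_bias is not None else pf.default_end_bias(group),
        n_fragments=n_fragments,
        seed=seed,
    )
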