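import numpy as np
import pytest

import meichip as m


@pytest.fixture(scope="session")
def toy_genome():
    return m.make_genome("toy")


@pytest.fixture(scope="session")
def sk1_genome():
    return m.make_genome("sk1-like")


@pytest.fixture(scope="session")
def toy_blocks(toy_genome):
    """A small, well-separated block set on the toy genome."""
    # block centers keep clear of the telomeric/pericentric background
    # windows so background-peak apexes never receive allele signal
    return [
        m.HotspotBlock("chr1", 40_000, 40_180, 12.0, "hs0"),
        m.HotspotBlock("chr1", 90_000, 90_300, 40.0, "hs1"),
        m.HotspotBlock("chr1", 200_000, 200_250, 5.0, "hs2"),
        m.HotspotBlock("chr1", 240_000, 240_150, 25.0, "hs3"),
        m.HotspotBlock("chr2", 50_000, 50_200, 18.0, "hs4"),
        m.HotspotBlock("chr2", 140_000, 140_400, 60.0, "hs5"),
    ]


@pytest.fixture(scope="session")
def sk1_dataset(sk1_genome):
    """Default full-genome synthetic dataset (blocks, axis sites,
    background peaks) as produced by the generator defaults."""
    blocks = m.generate_hotspots(sk1_genome, m.HotspotGeneratorConfig(seed=0))
    axis = m.generate_axis_sites(sk1_genome, blocks, seed=1)
    background = m.generate_background_peaks(sk1_genome, 30, seed=2)
    return blocks, axis, background


@pytest.fixture(scope="session")
def sk1_noise_free_profiles(sk1_genome, sk1_dataset):
    blocks, axis, background = sk1_dataset
    cfg = m.AlleleEffectConfig(noise_sigma=0.0)
    return m.simulate_alleles(sk1_genome, blocks, axis, background, cfg)


@pytest.fixture(scope="session")
def sk1_pipeline_result():
    """One full default pipeline run shared by the acceptance tests."""
    return m.run_pipeline(m.PipelineConfig(seed=1))


def make_profile(genome, chrom_values, spacing=50, **meta):
    """Build a TilingProfile from {chrom: values array} on a regular grid."""
    data = {}
    for chrom, values in chrom_values.items():
        values = np.asarray(values, dtype=float)
        pos = np.arange(values.size) * spacing
        data[chrom] = (pos, values)
    return m.TilingProfile(genome=genome, data=data, **meta)
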