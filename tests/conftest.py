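import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def marine_bundle():
    """A small streamlined clade: 4 genomes, no paralog families."""
    from magstream.simulate import CladeSpec, generate_genomes

    spec = CladeSpec(
        "marine_I", 4, 200_000, 30.0, 96.5, 0, n_singleton_proteins=8
    )
    return generate_genomes(spec, seed=11)


@pytest.fixture(scope="session")
def organic_bundle():
    """A paralog-rich clade: 3 genomes, 4 planted families of 3 copies."""
    from magstream.simulate import CladeSpec, generate_genomes

    spec = CladeSpec(
        "organic_carbon", 3, 400_000, 55.0, 88.0, 4,
        cn_bias="high_N", n_singleton_proteins=8,
    )
    return generate_genomes(spec, seed=11)


@pytest.fixture(scope="session")
def ecology_tables(marine_bundle):
    """Counts/samples/env for a two-clade depth-partitioned niche."""
    from magstream.simulate import NicheSpec, generate_ecology
    from magstream.streamlining import GenomeRecord

    genomes = list(marine_bundle.genomes)
    genomes += [
        GenomeRecord(
            g.genome_id.replace("marine_I", "marine_II"), g.contigs,
            g.completeness, g.contamination, "marine_II",
        )
        for g in marine_bundle.genomes
    ]
    counts, samples, env = generate_ecology(NicheSpec(), genomes, seed=11)
    lengths = {g.genome_id: g.assembly_length for g in genomes}
    return genomes, counts, samples, env, lengths
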