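"""The synthetic generator must hit its stated targets and be fully
deterministic under a fixed seed."""

import numpy as np
import pytest

from magstream import (
    build_profile,
    duplication_events_from_hits,
    gc_content,
    proteome_cn_ratio,
)
from magstream.errors import InputError
from magstream.simulate import (
    CladeSpec,
    NicheSpec,
    aa_frequencies,
    default_clade_specs,
    generate_ecology,
    generate_genomes,
    generate_rhodopsins,
)


def test_same_seed_is_byte_identical(marine_bundle):
    spec = CladeSpec("marine_I", 4, 200_000, 30.0, 96.5, 0,
                     n_singleton_proteins=8)
    again = generate_genomes(spec, seed=11)
    for g1, g2 in zip(marine_bundle.genomes, again.genomes):
        assert g1.contigs == g2.contigs
        assert g1.completeness == g2.completeness
    assert marine_bundle.proteins == again.proteins
    assert generate_genomes(spec, seed=12).genomes[0].contigs != (
        marine_bundle.genomes[0].contigs
    )


def test_gc_and_density_hit_targets(marine_bundle, organic_bundle):
    for bundle, gc_t, dens_t in ((marine_bundle, 30.0, 96.5),
                                 (organic_bundle, 55.0, 88.0)):
        for g in bundle.genomes:
            prof = build_profile(g, bundle.cds[g.genome_id])
            assert prof.gc_percent == pytest.approx(gc_t, abs=2.0)
            assert prof.coding_density_percent == pytest.approx(dens_t, abs=2.0)


def test_truncation_completeness_is_exactly_recoverable(marine_bundle):
    for g in marine_bundle.genomes:
        truth = marine_bundle.truth[g.genome_id]
        est = g.assembly_length / (g.completeness / 100.0)
        assert est == pytest.approx(truth["true_size_bp"], rel=1e-6)
        lo, hi = 50.0, 100.0
        assert lo <= g.completeness <= hi


def test_quality_values_satisfy_genome_invariants(marine_bundle):
    for g in marine_bundle.genomes:
        assert g.assembly_length == sum(len(s) for _, s in g.contigs)
        assert 0 < g.completeness <= 100
        assert g.contamination >= 0


def test_cn_bias_direction():
    low = aa_frequencies("low_N")
    high = aa_frequencies("high_N")
    assert low.sum() == pytest.approx(1.0)
    # nitrogen-rich residues rarer under low_N than high_N
    from magstream.simulate import AA, _N_RICH
    for i, aa in enumerate(AA):
        if aa in _N_RICH:
            assert low[i] < high[i]


def test_streamlining_contrast_on_all_five_traits(marine_bundle,
                                                  organic_bundle):
    """Marine-type clade: smaller size, lower GC, higher C/N, higher
    density, fewer duplication events than the organic-type clade."""
    def traits(bundle):
        sizes, gcs, cns, dens, events = [], [], [], [], []
        for g in bundle.genomes:
            p = build_profile(g, bundle.cds[g.genome_id])
            sizes.append(p.estimated_genome_size)
            gcs.append(p.gc_percent)
            dens.append(p.coding_density_percent)
            cns.append(proteome_cn_ratio(
                bundle.proteins[g.genome_id].values()).cn_ratio)
            events.append(
                duplication_events_from_hits(bundle.hits[g.genome_id])[0]
            )
        return map(np.mean, (sizes, gcs, cns, dens, events))

    m_size, m_gc, m_cn, m_dens, m_ev = traits(marine_bundle)
    o_size, o_gc, o_cn, o_dens, o_ev = traits(organic_bundle)
    assert m_size < o_size
    assert m_gc < o_gc
    assert m_cn > o_cn
    assert m_dens > o_dens
    assert m_ev < o_ev


def test_infeasible_spec_rejected():
    with pytest.raises(InputError):
        CladeSpec("x", 1, 5000, 30.0, 96.0, 0)
    with pytest.raises(InputError):
        CladeSpec("x", 1, 200_000, 30.0, 96.0, 0, cn_bias="mid")
    with pytest.raises(InputError):
        NicheSpec(boundary_depth=500.0)


def test_default_specs_are_valid_and_contrasting():
    specs = {s.clade: s for s in default_clade_specs()}
    assert specs["marine_I"].n_paralog_families == 0
    assert specs["marine_I"].true_genome_size < specs["organic_carbon"].true_genome_size
    assert specs["marine_I"].gc_target < specs["organic_carbon"].gc_target


def test_ecology_above_boundary_dominance(ecology_tables):
    genomes, counts, samples, env, lengths = ecology_tables
    clade = {g.genome_id: g.clade for g in genomes}
    merged = counts.merge(samples.reset_index()[["sample_id", "depth"]],
                          on="sample_id")
    merged["clade"] = merged.genome_id.map(clade)
    per = merged.pivot_table(index=["sample_id", "depth"], columns="clade",
                             values="reads", aggfunc="sum").reset_index()
    above = per[per.depth < 100]
    below = per[per.depth > 100]
    assert (above.marine_I > above.marine_II).all()
    assert (below.marine_II > below.marine_I).all()
    # >= 80% of clade reads on the home side at the shallowest depths
    shallow = per[per.depth <= 40]
    share = shallow.marine_I / (shallow.marine_I + shallow.marine_II)
    assert (share >= 0.8).all()


def test_env_gradients_without_noise_are_exact():
    niche = NicheSpec(env_gradients={"lin": (2.0, 0.5, 0.0)},
                      patchy_param=None, duplicate_cast_prob=0.0)
    from magstream.streamlining import GenomeRecord
    genomes = [GenomeRecord("marine_I_00", [("c", "ACGT" * 10)], 90, 1, "marine_I"),
               GenomeRecord("marine_II_00", [("c", "ACGT" * 10)], 90, 1, "marine_II")]
    _, _, env = generate_ecology(niche, genomes, seed=0)
    np.testing.assert_allclose(env["lin"], 2.0 + 0.5 * env["depth"])


def test_rhodopsin_generator_truth_and_determinism():
    seqs1, truth1 = generate_rhodopsins(seed=4)
    seqs2, truth2 = generate_rhodopsins(seed=4)
    assert seqs1 == seqs2 and truth1.equals(truth2)
    assert (truth1.tuning == "blue").sum() == 7
    assert (truth1.tuning == "green").sum() == 1
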