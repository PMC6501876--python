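"""Generator behaviour: founder pools, mosaics, planting, outgroups."""

import numpy as np
import pytest
from scipy import stats

from spvtools import io as spvio
from spvtools.io import GT_HET, GT_HOM_ALT, GT_HOM_REF
from spvtools.simulate import (DEFAULT_SPECTRUM, FOLDED_CLASSES,
                               SimulationConfig, build_founder_pool,
                               plant_private_mutations, simulate_fixture,
                               simulate_strain_mosaics, simulate_wild_derived,
                               simulate_wild_outgroup, strains_to_matrix,
                               true_ibd_segments)


class TestFounderPool:
    def test_two_founders_every_site_biallelic(self):
        pool = build_founder_pool(n_founders=2, chrom_length=100_000,
                                  snp_density=1e-3, seed=3)
        counts = pool.founder_alleles.sum(axis=0)
        assert ((counts > 0) & (counts < 2)).all()

    def test_determinism(self):
        a = build_founder_pool(4, 200_000, 1e-3, seed=9)
        b = build_founder_pool(4, 200_000, 1e-3, seed=9)
        assert a.ref_sequence == b.ref_sequence
        assert np.array_equal(a.founder_alleles, b.founder_alleles)
        assert np.array_equal(a.snp_positions, b.snp_positions)

    def test_gc_content_within_binomial_noise(self):
        L = 1_000_000
        pool = build_founder_pool(4, L, 1e-4, gc_content=0.5, seed=5)
        gc = sum(pool.ref_sequence.count(b) for b in "GC")
        sd = np.sqrt(L * 0.25)
        assert abs(gc - 0.5 * L) < 3 * sd

    def test_too_few_founders_rejected(self):
        with pytest.raises(ValueError):
            build_founder_pool(n_founders=1)


class TestMosaics:
    def test_huge_blocks_give_single_founder_strains(self):
        pool = build_founder_pool(3, 100_000, 1e-3, seed=1)
        strains = simulate_strain_mosaics(pool, 6,
                                          mean_block_length=1e7 * 100,
                                          seed=1)
        single = [s for s in strains if len(s.blocks) == 1]
        assert len(single) >= 5
        for a in single:
            for b in single:
                if a.blocks[0][2] == b.blocks[0][2]:
                    assert np.array_equal(a.haplotype, b.haplotype)

    def test_blocks_tile_chromosome(self):
        pool = build_founder_pool(4, 500_000, 1e-3, seed=2)
        for s in simulate_strain_mosaics(pool, 4, 50_000, seed=2):
            assert s.blocks[0][0] == 1
            assert s.blocks[-1][1] == pool.chrom_length
            for (s1, e1, _), (s2, _, _) in zip(s.blocks, s.blocks[1:]):
                assert s2 == e1 + 1

    def test_haplotype_matches_covering_block(self):
        pool = build_founder_pool(4, 500_000, 1e-3, seed=2)
        for s in simulate_strain_mosaics(pool, 3, 50_000, seed=4):
            for i, pos in enumerate(pool.snp_positions):
                founder = next(f for bs, be, f in s.blocks
                               if bs <= pos <= be)
                assert s.haplotype[i] == pool.founder_alleles[founder, i]

    def test_site_sharing_probability_near_inverse_founders(self):
        # P(two strains share a founder at a site) ~ 1/n_founders
        pool = build_founder_pool(4, 2_000_000, 5e-4, seed=6)
        matches = trials = 0
        for seed in range(8):
            strains = simulate_strain_mosaics(pool, 8, 200_000, seed=seed)
            probe = pool.chrom_length // 2
            founders = []
            for s in strains:
                founders.append(next(f for bs, be, f in s.blocks
                                     if bs <= probe <= be))
            for i in range(len(founders)):
                for j in range(i + 1, len(founders)):
                    trials += 1
                    matches += founders[i] == founders[j]
        assert abs(matches / trials - 0.25) < 0.08

    def test_needs_two_strains(self):
        pool = build_founder_pool(2, 100_000, 1e-3, seed=1)
        with pytest.raises(ValueError):
            simulate_strain_mosaics(pool, 1, 10_000)


@pytest.fixture(scope="module")
def pool_and_strains():
    pool = build_founder_pool(4, 2_000_000, 5e-4, seed=11)
    strains = simulate_strain_mosaics(pool, 4, 500_000, seed=11)
    return pool, strains


class TestPlanting:
    def test_zero_mutations_changes_nothing(self, pool_and_strains):
        pool, strains = pool_and_strains
        truth = plant_private_mutations(pool, strains, 0, seed=1)
        assert truth.mutations == []
        m = strains_to_matrix(pool, strains, truth)
        assert m.n_sites == pool.n_sites

    def test_pure_ct_spectrum_constrains_ancestral_base(self,
                                                        pool_and_strains):
        pool, strains = pool_and_strains
        spec = {"C>A": 0, "C>G": 0, "C>T": 1.0, "T>A": 0, "T>C": 0, "T>G": 0}
        truth = plant_private_mutations(pool, strains, 50, spec, seed=2)
        assert all(m.ancestral in "CG" for m in truth.mutations)
        assert all(m.folded_class == "C>T" for m in truth.mutations)

    def test_class_counts_match_multinomial(self, pool_and_strains):
        pool, strains = pool_and_strains
        p = np.array([DEFAULT_SPECTRUM[c] for c in FOLDED_CLASSES])
        truth = plant_private_mutations(pool, strains[:1], 1000,
                                        DEFAULT_SPECTRUM, seed=3)
        counts = np.array([sum(m.folded_class == c for m in truth.mutations)
                           for c in FOLDED_CLASSES])
        assert counts.sum() == 1000
        assert stats.chisquare(counts, 1000 * p).pvalue > 0.001

    def test_het_fraction_near_nominal(self, pool_and_strains):
        pool, strains = pool_and_strains
        truth = plant_private_mutations(pool, strains, 500,
                                        het_fraction=0.083, seed=4)
        frac = np.mean([m.zygosity == "heterozygous"
                        for m in truth.mutations])
        assert 0.05 < frac < 0.12

    def test_planted_alleles_are_private_and_polarizable(self,
                                                         pool_and_strains):
        pool, strains = pool_and_strains
        truth = plant_private_mutations(pool, strains, 30, seed=5)
        matrix = strains_to_matrix(pool, strains, truth)
        idx = matrix.site_index()
        for m in truth.mutations:
            row = idx[(m.chrom, m.pos)]
            focal = matrix.strain_index(m.strain)
            assert str(matrix.ref[row]) == m.ancestral
            assert str(matrix.alt[row]) == m.derived
            for j in range(matrix.n_strains):
                expected = GT_HOM_REF if j != focal else (
                    GT_HET if m.zygosity == "heterozygous" else GT_HOM_ALT)
                assert matrix.gt[row, j] == expected

    def test_mutation_inside_exactly_one_block(self, pool_and_strains):
        pool, strains = pool_and_strains
        truth = plant_private_mutations(pool, strains, 30, seed=6)
        for m in truth.mutations:
            covering = [b for b in truth.blocks[m.strain]
                        if b[0] <= m.pos <= b[1]]
            assert len(covering) == 1


class TestTrueIBD:
    def test_identical_single_founder_strains_share_everything(self):
        pool = build_founder_pool(2, 1_000_000, 1e-3, seed=1)
        strains = simulate_strain_mosaics(pool, 8, 1e12, seed=3)
        same = [(a, b) for i, a in enumerate(strains)
                for b in strains[i + 1:]
                if a.blocks[0][2] == b.blocks[0][2]
                and len(a.blocks) == len(b.blocks) == 1]
        assert same, "expected at least one single-founder pair"
        a, b = same[0]
        assert true_ibd_segments(a, b, 0) == [(1, pool.chrom_length)]


class TestWildOutgroup:
    def test_deterministic(self):
        pool = build_founder_pool(4, 1_000_000, 1e-3, seed=8)
        w1 = simulate_wild_outgroup(pool, 8, seed=2, n_private_sites=100)
        w2 = simulate_wild_outgroup(pool, 8, seed=2, n_private_sites=100)
        assert w1 == w2

    def test_requires_positive_diversity(self):
        pool = build_founder_pool(4, 1_000_000, 1e-3, seed=8)
        with pytest.raises(ValueError):
            simulate_wild_outgroup(pool, 8, extra_diversity=0.0)

    def test_wild_derived_panel_covers_every_founder_allele(self):
        pool = build_founder_pool(4, 1_000_000, 1e-3, seed=8)
        wd = simulate_wild_derived(pool)
        assert wd.n_strains == pool.n_founders
        # any alt allele among founders appears in the wild-derived panel
        has_alt = (wd.gt == GT_HOM_ALT).any(axis=1)
        assert np.array_equal(has_alt,
                              pool.founder_alleles.any(axis=0))


class TestFixtureSet:
    def test_emit_round_trips_and_truth_parses(self, small_fixture,
                                               tmp_path):
        from spvtools.simulate import emit_fixture_set
        import pandas as pd
        fx = emit_fixture_set(tmp_path, small_fixture.config, seed=7)
        assert spvio.read_genotypes(tmp_path / "strains.vcf") == fx.matrix
        assert spvio.read_genotypes(tmp_path / "wild.vcf") == fx.wild
        ref = spvio.read_fasta(tmp_path / "ref.fa")
        assert ref.contigs() == {fx.pool.chrom: fx.pool.chrom_length}
        truth = pd.read_csv(tmp_path / "truth_mutations.tsv", sep="\t")
        assert len(truth) == len(fx.truth.mutations)
        repeats = spvio.read_interval_track(tmp_path / "repeats.bed")
        assert repeats.intervals() == fx.repeats.intervals()

    def test_config_from_toml(self, tmp_path):
        path = tmp_path / "cfg.toml"
        path.write_text('chrom_length = 1000000\nn_strains = 5\n'
                        'het_fraction = 0.1\n')
        cfg = SimulationConfig.from_toml(path)
        assert cfg.chrom_length == 1_000_000
        assert cfg.n_strains == 5
        assert cfg.het_fraction == 0.1

    def test_same_seed_same_fixture(self):
        cfg = SimulationConfig(chrom_length=2_000_000, n_strains=4,
                               n_founders=3, mutations_per_strain=20,
                               n_genes=5, n_score_background=100, n_wild=5,
                               n_wild_private_sites=50)
        a = simulate_fixture(cfg, seed=13)
        b = simulate_fixture(cfg, seed=13)
        assert a.matrix == b.matrix
        assert a.truth.mutations == b.truth.mutations
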