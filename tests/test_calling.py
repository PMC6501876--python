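"""Singleton identification, the filter stack, polarization and contexts."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_matrix
from spvtools import calling, ibd
from spvtools.calling import (FILTER_RULES, chi2_bias_test, cpg_annotate,
                              fold_class, polarize, trinucleotide_context)
from spvtools.io import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING,
                         IntervalTrack, ReferenceStore)
from spvtools.simulate import SimulationConfig, simulate_fixture

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestSingletons:
    def test_fixed_het_and_common_patterns(self):
        m = make_matrix([
            [GT_HOM_ALT, GT_HOM_REF, GT_HOM_REF],   # fixed singleton
            [GT_HET, GT_HOM_REF, GT_HOM_REF],       # het singleton
            [GT_HOM_ALT, GT_HET, GT_HOM_REF],       # two carriers: common
            [GT_HOM_REF, GT_HOM_REF, GT_HOM_REF],   # invariant
            [GT_HOM_ALT, GT_MISSING, GT_HOM_REF],   # missing others ok
        ])
        assert list(calling.identify_singletons(m)) == [0, 1, 4]


class TestBiasTest:
    def test_balanced_counts_give_p_one(self):
        assert chi2_bias_test((10, 10, 10, 10)) == pytest.approx(1.0)

    def test_allele_bias_detected(self):
        # all reads support ref: expected under 50/50 alleles differs
        p = chi2_bias_test((20, 20, 0, 0))
        # closed form: p_fwd=0.5, E=(10,10,10,10), chi2 = 4*10 = 40
        assert p == pytest.approx(float(stats.chi2.sf(40.0, 3)))
        assert p < 0.05

    def test_strand_bias_detected(self):
        p = chi2_bias_test((2, 18, 18, 2))
        assert p < 0.05

    def test_no_reads_rejected(self):
        with pytest.raises(ValueError):
            chi2_bias_test((0, 0, 0, 0))


class TestPolarize:
    def test_fixed_singleton(self):
        m = make_matrix([[GT_HOM_ALT, GT_HOM_REF, GT_HOM_REF]],
                        ref=["G"], alt=["T"])
        assert polarize(m, 0, "s0") == ("G", "T")

    def test_het_singleton(self):
        m = make_matrix([[GT_HET, GT_HOM_REF, GT_HOM_REF]],
                        ref=["C"], alt=["A"])
        assert polarize(m, 0, "s0") == ("C", "A")

    def test_reference_private_pattern_rejected(self):
        m = make_matrix([[GT_HOM_REF, GT_HOM_ALT, GT_HOM_ALT]])
        with pytest.raises(ValueError):
            polarize(m, 0, "s0")


class TestFoldAndContext:
    @pytest.mark.parametrize("anc,der,folded,flipped", [
        ("C", "A", "C>A", False), ("C", "G", "C>G", False),
        ("C", "T", "C>T", False), ("T", "A", "T>A", False),
        ("T", "C", "T>C", False), ("T", "G", "T>G", False),
        ("G", "T", "C>A", True), ("G", "C", "C>G", True),
        ("G", "A", "C>T", True), ("A", "T", "T>A", True),
        ("A", "G", "T>C", True), ("A", "C", "T>G", True),
    ])
    def test_fold_class_complete_map(self, anc, der, folded, flipped):
        assert fold_class(anc, der) == (folded, flipped)

    def test_fold_rejects_identity(self):
        with pytest.raises(ValueError):
            fold_class("C", "C")

    def test_context_extraction(self):
        ref = ReferenceStore({"chr1": "AACGTAA"})
        assert trinucleotide_context(ref, "chr1", 3) == "ACG"
        with pytest.raises(ValueError):
            trinucleotide_context(ref, "chr1", 1)   # no 5' flank

    def test_cpg_forward_strand(self):
        # ...A[C]G...: C>T at a CpG
        assert cpg_annotate("ACG", "C>T", flipped=False)
        assert not cpg_annotate("ACT", "C>T", flipped=False)

    def test_cpg_reverse_strand(self):
        # reference C[G]A: G>A maps to C>T with the CpG on the other strand
        assert cpg_annotate("CGA", "C>T", flipped=True)
        assert not cpg_annotate("TGA", "C>T", flipped=True)

    def test_cpg_matches_reverse_complement_enumeration(self):
        # oracle: build the pyrimidine-strand context explicitly and ask
        # whether its 3' neighbour is G
        for five in "ACGT":
            for three in "ACGT":
                for anc in ("C", "G"):
                    context = five + anc + three
                    folded, flipped = fold_class(anc,
                                                 "T" if anc == "C" else "A")
                    pyr_context = context if anc == "C" else "".join(
                        COMPLEMENT[b] for b in reversed(context))
                    expected = pyr_context[2] == "G"
                    assert cpg_annotate(context, folded, flipped) == expected


# ---------------------------------------------------------------------------
# filter stack on the corruption fixture
# ---------------------------------------------------------------------------

AUDIT_CONFIG = SimulationConfig(
    chrom_length=20_000_000, n_strains=6, n_founders=4,
    mean_block_length=8e6, snp_density=5e-4, mutations_per_strain=0,
    repeat_fraction=0.0, segdup_fraction=0.0, n_genes=20,
    n_score_background=1000, n_wild=12, n_wild_private_sites=200,
    corrupt_rules=("qual", "gq", "dp_low", "dp_high", "missing", "segdup",
                   "repeat", "pl_margin", "wild", "ibd", "allele_balance",
                   "strand_bias", "none", "none"))


@pytest.fixture(scope="module")
def audit_run():
    fx = simulate_fixture(AUDIT_CONFIG, seed=303)
    panel = ibd.build_ibd_panel(fx.matrix)
    segments = ibd.filter_segments(ibd.detect_ibd(panel))
    site_idx = fx.matrix.site_index()
    candidates = np.array(sorted(site_idx[(m.chrom, m.pos)]
                                 for m in fx.truth.mutations))
    records, audit = calling.apply_filter_stack(
        candidates, fx.matrix, fx.repeats, fx.segdups, fx.wild,
        fx.wild_derived, segments, fx.pool.ref_store())
    return fx, segments, records, audit


def hand_applied_rules(fx, segments, row):
    """Independent, literal re-statement of the filter rules for one row."""
    m = fx.matrix
    j = int(np.flatnonzero((m.gt[row] == GT_HET)
                           | (m.gt[row] == GT_HOM_ALT))[0])
    focal = m.strains[j]
    chrom, pos = str(m.chrom[row]), int(m.pos[row])
    mean_dp = np.nanmean(np.where(m.dp < 0, np.nan, m.dp.astype(float)),
                         axis=0)[j]
    if not m.qual[row] > 50:
        return "qual"
    if not m.gq[row, j] > 60:
        return "gq"
    if not (m.dp[row, j] > 10 and m.dp[row, j] < 1.9 * mean_dp):
        return "dp"
    if not (m.gt[row] == GT_MISSING).sum() / m.n_strains < 0.15:
        return "missing"
    if fx.segdups.point_in_track(chrom, pos):
        return "segdup"
    if fx.repeats.point_in_track(chrom, pos):
        return "repeat"
    if not m.pl_margin[row, j] > 20:
        return "pl_margin"
    widx = fx.wild.site_index().get((chrom, pos))
    if widx is not None:
        g = fx.wild.gt[widx]
        if (((g == GT_HET) | (g == GT_HOM_ALT)).any()
                and ((g == GT_HET) | (g == GT_HOM_REF)).any()):
            return "wild"
    wdidx = fx.wild_derived.site_index().get((chrom, pos))
    if wdidx is not None and ((fx.wild_derived.gt[wdidx] == GT_HET)
                              | (fx.wild_derived.gt[wdidx]
                                 == GT_HOM_ALT)).any():
        return "wild"
    in_ibd = any(s.start_pos <= pos <= s.end_pos for s in segments
                 if focal in (s.strain_a, s.strain_b) and s.chrom == chrom)
    if not in_ibd:
        return "ibd"
    if m.gt[row, j] == GT_HET:
        ar, aa = int(m.ad_ref[row, j]), int(m.ad_alt[row, j])
        if not min(ar, aa) / (ar + aa) > 0.3:
            return "allele_balance"
        if not chi2_bias_test(m.strand[row, j]) > 0.05:
            return "strand_bias"
    return None


class TestFilterStack:
    def test_exactly_one_failure_per_corrupted_rule(self, audit_run):
        fx, segments, records, audit = audit_run
        tag_to_rule = {"dp_low": "dp", "dp_high": "dp"}
        expected = {r: 0 for r in FILTER_RULES}
        for m in fx.truth.mutations:
            if m.tag != "none":
                expected[tag_to_rule.get(m.tag, m.tag)] += 1
        assert audit.failures == expected
        assert all(n == 1 for r, n in expected.items() if r != "dp")
        assert expected["dp"] == 2
        assert audit.survivors == 2                  # the two clean records
        assert audit.check_conservation()

    def test_matches_hand_applied_rule_oracle(self, audit_run):
        fx, segments, records, audit = audit_run
        site_idx = fx.matrix.site_index()
        survivors = {(r.strain, r.pos) for r in records}
        for m in fx.truth.mutations:
            row = site_idx[(m.chrom, m.pos)]
            verdict = hand_applied_rules(fx, segments, row)
            assert ((m.strain, m.pos) in survivors) == (verdict is None), \
                (m.tag, verdict)

    def test_boundary_gq_equal_threshold_fails(self, audit_run):
        fx, _, _, _ = audit_run
        gq_mut = next(m for m in fx.truth.mutations if m.tag == "gq")
        row = fx.matrix.site_index()[(gq_mut.chrom, gq_mut.pos)]
        j = fx.matrix.strain_index(gq_mut.strain)
        assert fx.matrix.gq[row, j] == 60        # exactly at threshold

    def test_empty_segments_rejected(self):
        m = make_matrix([[GT_HOM_ALT, GT_HOM_REF]])
        empty = IntervalTrack("e")
        ref = ReferenceStore({"chr1": "A" * 2000})
        with pytest.raises(ValueError, match="IBD"):
            calling.apply_filter_stack(np.array([0]), m, empty, empty, m, m,
                                       [], ref)

    def test_survivor_records_polarized_with_context(self, audit_run):
        fx, _, records, _ = audit_run
        ref = fx.pool.ref_store()
        for r in records:
            assert r.ancestral != r.derived
            ctx = trinucleotide_context(ref, r.chrom, r.pos)
            assert ctx == r.trinucleotide_context
            assert ctx[1] == r.ancestral


class TestCommonVariants:
    def test_two_plus_carriers_with_masking(self):
        m = make_matrix([
            [GT_HOM_ALT, GT_HOM_ALT, GT_HOM_REF],    # common
            [GT_HOM_ALT, GT_HOM_REF, GT_HOM_REF],    # singleton
            [GT_HET, GT_HET, GT_HOM_REF],            # common (het carriers)
        ], pos=[100, 200, 300])
        common = calling.define_common_variants(m)
        assert list(common) == [0, 2]
        repeat = IntervalTrack("rep", [("chr1", 99, 100)])  # masks pos 100
        common = calling.define_common_variants(m, repeat_track=repeat)
        assert list(common) == [2]

    def test_spv_and_common_sets_disjoint(self):
        m = make_matrix([
            [GT_HOM_ALT, GT_HOM_REF, GT_HOM_REF],
            [GT_HOM_ALT, GT_HOM_ALT, GT_HOM_REF],
        ])
        spv = set(calling.identify_singletons(m))
        common = set(calling.define_common_variants(m))
        assert not spv & common

    def test_parsimony_ancestral_states(self):
        m = make_matrix([[GT_HOM_ALT, GT_HOM_ALT], [GT_HOM_ALT, GT_HET]],
                        ref=["G", "C"], alt=["T", "A"], pos=[10, 20])
        # wild-derived fixed ref at pos 10; segregating at pos 20
        wd = make_matrix([[GT_HOM_REF, GT_HOM_REF],
                          [GT_HOM_REF, GT_HOM_ALT]],
                         ref=["G", "C"], alt=["T", "A"], pos=[10, 20],
                         strains=["wd0", "wd1"])
        anc = calling.polarize_common(m, np.array([0, 1]), wd)
        assert anc[0] == "G"
        assert anc[1] is None

    def test_wild_derived_fixed_alt_is_ancestral(self):
        m = make_matrix([[GT_HOM_REF, GT_HOM_ALT]], ref=["G"], alt=["T"])
        wd = make_matrix([[GT_HOM_ALT, GT_HOM_ALT]], ref=["G"], alt=["T"],
                         strains=["wd0", "wd1"])
        anc = calling.polarize_common(m, np.array([0]), wd)
        assert anc[0] == "T"
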