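"""Shared fixtures: hand-built matrices and session-scoped simulations."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from spvtools import calling, ibd
from spvtools.io import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING,
                         GenotypeMatrix)
from spvtools.simulate import SimulationConfig, simulate_fixture

PASSING = dict(qual=200.0, gq=99, dp=40, pl=100)


def make_matrix(gt_rows, pos=None, ref=None, alt=None, qual=None,
                strains=None, chrom="chr1", **overrides):
    """Build a small GenotypeMatrix with clean passing quality fields.

    ``gt_rows`` is a list of per-site genotype-code lists; every call gets
    QUAL=200, GQ=99, DP=40, PL margin=100 and consistent AD/strand counts
    unless overridden via keyword arrays.
    """
    gt = np.asarray(gt_rows, dtype=np.int8)
    n, k = gt.shape
    strains = strains or [f"s{i}" for i in range(k)]
    pos = pos if pos is not None else np.arange(1, n + 1) * 1000
    ref = ref if ref is not None else ["A"] * n
    alt = alt if alt is not None else ["T"] * n
    qual = qual if qual is not None else np.full(n, PASSING["qual"])
    gq = overrides.get("gq", np.full((n, k), PASSING["gq"], dtype=np.int32))
    dp = overrides.get("dp", np.full((n, k), PASSING["dp"], dtype=np.int32))
    pl = overrides.get("pl", np.full((n, k), PASSING["pl"], dtype=np.int32))
    ad_ref = np.where(gt == GT_HOM_REF, 40, np.where(gt == GT_HET, 20, 0))
    ad_alt = np.where(gt == GT_HOM_ALT, 40, np.where(gt == GT_HET, 20, 0))
    ad_ref = overrides.get("ad_ref", ad_ref.astype(np.int32))
    ad_alt = overrides.get("ad_alt", ad_alt.astype(np.int32))
    sb = np.zeros((n, k, 4), dtype=np.int32)
    sb[gt == GT_HOM_REF] = (20, 20, 0, 0)
    sb[gt == GT_HOM_ALT] = (0, 0, 20, 20)
    sb[gt == GT_HET] = (10, 10, 10, 10)
    sb = overrides.get("sb", sb)
    return GenotypeMatrix(strains, [chrom] * n, pos, ref, alt, qual, gt,
                          gq, dp, pl, ad_ref, ad_alt, sb,
                          overrides.get("filters"))


def random_matrix(rng, n_sites, n_strains, span=1_000_000, p_missing=0.05,
                  p_het=0.05):
    """A random small genotype matrix for detector/oracle comparisons."""
    gt = rng.choice([GT_HOM_REF, GT_HOM_ALT, GT_HET, GT_MISSING],
                    size=(n_sites, n_strains),
                    p=[(1 - p_missing - p_het) * 0.6,
                       (1 - p_missing - p_het) * 0.4, p_het, p_missing])
    pos = np.sort(rng.choice(np.arange(1, span), size=n_sites,
                             replace=False))
    return make_matrix(gt, pos=pos)


def naive_pairwise_ibd(panel, strain_a, strain_b, min_seed_bp):
    """Per-site Python scan oracle for 0-mismatch IBD detection."""
    ja = panel.strain_index(strain_a)
    jb = panel.strain_index(strain_b)
    a_name, b_name = sorted((strain_a, strain_b))
    order = np.lexsort((panel.pos, panel.chrom.astype(str)))
    segments = []
    run = []
    prev_chrom = None
    for i in order:
        chrom = str(panel.chrom[i])
        ga, gb = int(panel.gt[i, ja]), int(panel.gt[i, jb])
        hom = {GT_HOM_REF, GT_HOM_ALT}
        match = ga in hom and gb in hom and ga == gb
        if chrom != prev_chrom or not match:
            if run:
                segments.append((prev_chrom, run))
            run = []
        if match:
            run.append(int(panel.pos[i]))
        prev_chrom = chrom
    if run:
        segments.append((prev_chrom, run))
    out = []
    for chrom, positions in segments:
        if positions[-1] - positions[0] + 1 >= min_seed_bp:
            out.append(ibd.IBDSegment(
                strain_a=a_name, strain_b=b_name, chrom=chrom,
                start_pos=positions[0], end_pos=positions[-1],
                n_sites=len(positions)))
    return out


@pytest.fixture(scope="session")
def default_fixture():
    """The standard study fixture: 60 Mb, 12 strains, 8 founders."""
    return simulate_fixture(SimulationConfig(), seed=101)


@pytest.fixture(scope="session")
def default_pipeline(default_fixture):
    """Full pipeline results on the standard fixture."""
    fx = default_fixture
    panel = ibd.build_ibd_panel(fx.matrix)
    segments = ibd.filter_segments(ibd.detect_ibd(panel))
    records, audit = calling.call_spvs(
        fx.matrix, fx.repeats, fx.segdups, fx.wild, fx.wild_derived,
        segments, fx.pool.ref_store())
    return SimpleNamespace(fx=fx, panel=panel, segments=segments,
                           records=records, audit=audit)


@pytest.fixture(scope="session")
def small_fixture():
    """A fast 10 Mb fixture for file-level and CLI tests."""
    cfg = SimulationConfig(chrom_length=10_000_000, n_strains=6,
                           n_founders=4, mean_block_length=3e6,
                           snp_density=1e-3, mutations_per_strain=60,
                           n_genes=30, n_score_background=2000,
                           n_wild=10, n_wild_private_sites=200)
    return simulate_fixture(cfg, seed=7)
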