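"""Synthetic mosaic-genome generator with full ground truth.

Laboratory mouse genomes are modelled as mosaics of a small pool of founder
haplotypes: each simulated strain is a tiling of founder blocks (block
lengths from an exponential renewal process, founder per block uniform),
with all genotypes homozygous as expected for fully inbred lines. Recent
germline mutations are then planted on top as strain-private alleles drawn
from configurable per-strain folded 6-class spectra, ~91.7% fixed and 8.3%
heterozygous. A diverse wild outgroup (per-site independent sampling from
population allele frequencies, so no long shared haplotypes) and a
wild-derived panel carrying the founder haplotypes provide the outgroup
matrices the ancestral-variant filter consumes.

Every stochastic step is reproducible from a single integer seed, and the
generator returns a :class:`TruthTable` recording planted mutations and
mosaic block boundaries so that recovery can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as spvio
from .io import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, GenotypeMatrix,
                 IntervalTrack, ReferenceStore, ScoreTrack)

logger = logging.getLogger(__name__)

FOLDED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: default folded spectrum: transition-dominated, C>T about half of events,
#: as seen for recent germline mutations in rodents
DEFAULT_SPECTRUM = {"C>A": 0.08, "C>G": 0.05, "C>T": 0.50,
                    "T>A": 0.10, "T>C": 0.20, "T>G": 0.07}

# quality annotations written for a clean, filter-passing record
PASS_QUAL = 200.0
PASS_GQ = 99
PASS_DP = 40
PASS_PL_MARGIN = 100

#: corruption rule names, matching the filter-stack rule names in
#: :mod:`spvtools.calling` (plus "none" for an uncorrupted in-IBD record)
CORRUPTION_RULES = ("qual", "gq", "dp_low", "dp_high", "missing", "segdup",
                    "repeat", "pl_margin", "wild", "ibd", "allele_balance",
                    "strand_bias", "none")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All generator parameters; defaults define the standard study fixture."""

    chrom: str = "chr1"
    chrom_length: int = 60_000_000
    gc_content: float = 0.5
    snp_density: float = 5e-4
    n_founders: int = 8
    n_strains: int = 12
    mean_block_length: float = 10e6
    mutations_per_strain: int = 300
    het_fraction: float = 0.083
    spectrum: Mapping[str, float] | None = None       # shared default
    spectrum_per_strain: Mapping[str, Mapping[str, float]] | None = None
    n_wild: int = 27
    wild_extra_diversity: float = 0.2
    n_wild_private_sites: int = 1000
    repeat_fraction: float = 0.08
    segdup_fraction: float = 0.04
    mask_mean_interval: float = 20_000.0
    n_genes: int = 150
    cds_length: int = 999
    n_trait_replicates: int = 8
    trait_effect: tuple[str, str, float] | None = None  # (trait, class, slope)
    n_score_background: int = 20_000
    plant_in_ibd: bool = False          # confine mutations to true IBD
    corrupt_rules: Sequence[str] = ()

    @classmethod
    def from_toml(cls, path) -> "SimulationConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FounderPool:
    """A small pool of founder haplotypes over a simulated chromosome."""

    chrom: str
    chrom_length: int
    n_founders: int
    snp_positions: np.ndarray          # 1-based, sorted
    founder_alleles: np.ndarray        # (n_founders, n_sites) 0=ref, 1=alt
    alt_bases: np.ndarray              # per-site alt allele
    ref_sequence: str

    @property
    def n_sites(self) -> int:
        return len(self.snp_positions)

    def ref_store(self) -> ReferenceStore:
        return ReferenceStore({self.chrom: self.ref_sequence})


@dataclass
class MosaicStrain:
    """One inbred strain: an ordered founder-block tiling plus haplotype."""

    name: str
    blocks: list[tuple[int, int, int]]   # (start, end, founder), 1-based incl
    haplotype: np.ndarray                # allele (0/1) at each pool SNP


@dataclass
class PlantedMutation:
    strain: str
    chrom: str
    pos: int
    ancestral: str
    derived: str
    zygosity: str                       # "fixed" | "heterozygous"
    folded_class: str
    tag: str | None = None              # corruption rule, if any


@dataclass
class TruthTable:
    """Simulator ground truth for recovery tests."""

    mutations: list[PlantedMutation] = field(default_factory=list)
    blocks: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def positions(self, strain: str | None = None) -> set[int]:
        return {m.pos for m in self.mutations
                if strain is None or m.strain == strain}


# ---------------------------------------------------------------------------
# founder pool
# ---------------------------------------------------------------------------

def _random_sequence(length: int, gc_content: float,
                     rng: np.random.Generator) -> str:
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _sample_positions(n: int, low: int, high: int, exclude: set[int],
                      rng: np.random.Generator) -> np.ndarray:
    """``n`` distinct 1-based positions in [low, high] avoiding ``exclude``."""
    chosen: set[int] = set()
    span = high - low + 1
    if n > span - len(exclude):
        raise ValueError("not enough eligible positions")
    while len(chosen) < n:
        draw = rng.integers(low, high + 1, size=2 * (n - len(chosen)))
        for p in draw:
            p = int(p)
            if p not in exclude and p not in chosen:
                chosen.add(p)
                if len(chosen) == n:
                    break
    return np.sort(np.fromiter(chosen, dtype=np.int64))


def build_founder_pool(n_founders: int = 8, chrom_length: int = 60_000_000,
                       snp_density: float = 5e-4, gc_content: float = 0.5,
                       seed: int = 0, chrom: str = "chr1") -> FounderPool:
    """Simulate a chromosome and a pool of founder haplotypes over it.

    Every SNP is polymorphic among the founders (minor allele count >= 1),
    emulating a pool of fewer than ten ancestral haplotypes from which the
    laboratory strains descend.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0,1)")
    if snp_density <= 0:
        raise ValueError("snp_density must be > 0")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(chrom_length, gc_content, rng)
    n_snps = max(1, int(round(snp_density * chrom_length)))
    # keep one flanking base on each side so trinucleotide contexts exist
    positions = _sample_positions(n_snps, 2, chrom_length - 1, set(), rng)

    # founder alleles: per-site alt frequency drawn, then polymorphism forced
    q = rng.uniform(0.1, 0.9, size=n_snps)
    alleles = (rng.random((n_founders, n_snps)) < q).astype(np.int8)
    mono = np.where((alleles.sum(axis=0) == 0)
                    | (alleles.sum(axis=0) == n_founders))[0]
    for s in mono:
        alleles[rng.integers(n_founders), s] ^= 1

    seq_arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    ref_bases = seq_arr[positions - 1].astype("U1")
    alt_bases = np.empty(n_snps, dtype="U1")
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    pick = rng.integers(0, 3, size=n_snps)
    for i in range(n_snps):
        alt_bases[i] = others[str(ref_bases[i])][pick[i]]
    return FounderPool(chrom=chrom, chrom_length=chrom_length,
                       n_founders=n_founders, snp_positions=positions,
                       founder_alleles=alleles, alt_bases=alt_bases,
                       ref_sequence=seq)


# ---------------------------------------------------------------------------
# strain mosaics
# ---------------------------------------------------------------------------

def simulate_strain_mosaics(pool: FounderPool, n_strains: int,
                            mean_block_length: float, seed: int = 0,
                            allow_single_founder: bool = False
                            ) -> list[MosaicStrain]:
    """Tile each strain's chromosome with founder blocks.

    Block lengths follow an exponential renewal process with the given mean;
    the founder of each block is uniform over the pool. Genotypes are
    homozygous founder alleles (fully inbred strains).
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains (IBD is pairwise)")
    if mean_block_length <= 0:
        raise ValueError("mean_block_length must be > 0")
    if pool.n_founders < 2 and not allow_single_founder:
        raise ValueError("single-founder pool makes all strains identical; "
                         "pass allow_single_founder=True if intended")
    rng = np.random.default_rng(seed)
    L = pool.chrom_length
    strains = []
    for i in range(n_strains):
        blocks = []
        start = 1
        while start <= L:
            length = max(1, int(round(rng.exponential(mean_block_length))))
            end = min(L, start + length - 1)
            founder = int(rng.integers(pool.n_founders))
            blocks.append((start, end, founder))
            start = end + 1
        starts = np.array([b[0] for b in blocks])
        founders = np.array([b[2] for b in blocks])
        per_site = founders[np.searchsorted(starts, pool.snp_positions,
                                            side="right") - 1]
        hap = pool.founder_alleles[per_site, np.arange(pool.n_sites)]
        strains.append(MosaicStrain(name=f"strain{i:02d}", blocks=blocks,
                                    haplotype=hap.astype(np.int8)))
    return strains


def true_ibd_segments(strain_a: MosaicStrain, strain_b: MosaicStrain,
                      min_length_bp: float = 5e6
                      ) -> list[tuple[int, int]]:
    """Maximal same-founder runs >= min_length_bp for one strain pair.

    Computed directly from block structure (ground truth, independent of the
    genotype-based detector).
    """
    edges = sorted({b[0] for b in strain_a.blocks}
                   | {b[0] for b in strain_b.blocks})
    ends = max(b[1] for b in strain_a.blocks)
    fa = _founder_at_edges(strain_a, edges)
    fb = _founder_at_edges(strain_b, edges)
    runs = []
    run_start = None
    for i, e in enumerate(edges):
        seg_end = edges[i + 1] - 1 if i + 1 < len(edges) else ends
        if fa[i] == fb[i]:
            if run_start is None:
                run_start = e
            run_end = seg_end
        else:
            if run_start is not None:
                runs.append((run_start, run_end))
            run_start = None
    if run_start is not None:
        runs.append((run_start, run_end))
    return [(s, e) for s, e in runs if e - s + 1 >= min_length_bp]


def _founder_at_edges(strain: MosaicStrain, edges: list[int]) -> np.ndarray:
    starts = np.array([b[0] for b in strain.blocks])
    founders = np.array([b[2] for b in strain.blocks])
    return founders[np.searchsorted(starts, np.array(edges),
                                    side="right") - 1]


def true_ibd_union(strains: Sequence[MosaicStrain],
                   min_length_bp: float = 5e6
                   ) -> dict[str, list[tuple[int, int]]]:
    """Per-strain union of same-founder runs >= min_length_bp (ground truth)."""
    union: dict[str, list[tuple[int, int]]] = {s.name: [] for s in strains}
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            for seg in true_ibd_segments(a, b, min_length_bp):
                union[a.name].append(seg)
                union[b.name].append(seg)
    return {name: _merge_intervals(ivs) for name, ivs in union.items()}


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _in_intervals(pos: int, ivs: list[tuple[int, int]],
                  margin: int = 0) -> bool:
    import bisect
    if not ivs:
        return False
    starts = [s for s, _ in ivs]
    i = bisect.bisect_right(starts, pos) - 1
    if i < 0:
        return False
    s, e = ivs[i]
    return s + margin <= pos <= e - margin


# ---------------------------------------------------------------------------
# mutation planting
# ---------------------------------------------------------------------------

def _normalize_spectrum(spec) -> np.ndarray:
    """Accept a class->prob mapping or a 6-vector in folded-class order."""
    if isinstance(spec, Mapping):
        p = np.array([spec[c] for c in FOLDED_CLASSES], dtype=float)
    else:
        p = np.asarray(spec, dtype=float)
        if p.shape != (6,):
            raise ValueError("spectrum vector must have 6 entries")
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("spectrum must be a probability vector over the "
                         "six folded classes summing to 1")
    return p


def _derived_base(ancestral: str, folded_class: str) -> str:
    root, target = folded_class.split(">")
    if ancestral == root:
        return target
    if ancestral == COMPLEMENT[root]:
        return COMPLEMENT[target]
    raise ValueError(f"base {ancestral} cannot host class {folded_class}")


def plant_private_mutations(pool: FounderPool,
                            strains: Sequence[MosaicStrain],
                            mutations_per_strain: int,
                            spectrum_per_strain: Mapping[str, Mapping[str, float]] | Mapping[str, float] | None = None,
                            het_fraction: float = 0.083,
                            seed: int = 0,
                            restrict_to: Mapping[str, list[tuple[int, int]]] | None = None,
                            avoid_tracks: Sequence[IntervalTrack] = (),
                            used_positions: set[int] | None = None,
                            margin: int = 0) -> TruthTable:
    """Plant strain-private mutations with known folded-class spectra.

    Positions are uniform over bases whose reference state permits the
    sampled class (C/G for C-rooted classes, A/T for T-rooted), excluding
    panel SNPs and previously used positions, so planted alleles are private
    by construction. ``restrict_to`` optionally confines a strain's
    mutations to given intervals (e.g. its true IBD territory), with
    ``margin`` bases kept clear of interval edges.
    """
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    if used_positions is None:
        used_positions = set()
    used = set(int(p) for p in pool.snp_positions) | used_positions
    seq = pool.ref_sequence
    L = pool.chrom_length

    if spectrum_per_strain is None:
        spectra = {s.name: _normalize_spectrum(DEFAULT_SPECTRUM)
                   for s in strains}
    elif (isinstance(spectrum_per_strain, Mapping)
          and all(k in FOLDED_CLASSES for k in spectrum_per_strain)):
        p = _normalize_spectrum(spectrum_per_strain)
        spectra = {s.name: p for s in strains}
    elif isinstance(spectrum_per_strain, Mapping):
        spectra = {name: _normalize_spectrum(sp)
                   for name, sp in spectrum_per_strain.items()}
    else:
        p = _normalize_spectrum(spectrum_per_strain)
        spectra = {s.name: p for s in strains}

    truth = TruthTable(blocks={s.name: list(s.blocks) for s in strains})
    for strain in strains:
        p = spectra[strain.name]
        classes = rng.choice(6, size=mutations_per_strain, p=p)
        ivs = restrict_to.get(strain.name) if restrict_to else None
        for c in classes:
            folded = FOLDED_CLASSES[c]
            roots = ("C", "G") if folded.startswith("C") else ("A", "T")
            pos = _draw_eligible(rng, seq, L, roots, used, ivs, avoid_tracks,
                                 pool.chrom, margin)
            anc = seq[pos - 1]
            mut = PlantedMutation(
                strain=strain.name, chrom=pool.chrom, pos=pos, ancestral=anc,
                derived=_derived_base(anc, folded),
                zygosity=("heterozygous" if rng.random() < het_fraction
                          else "fixed"),
                folded_class=folded)
            truth.mutations.append(mut)
            used.add(pos)
    truth.mutations.sort(key=lambda m: m.pos)
    return truth


def _draw_eligible(rng, seq, L, roots, used, ivs, avoid_tracks, chrom,
                   margin, max_tries: int = 200_000) -> int:
    for _ in range(max_tries):
        if ivs:
            s, e = ivs[rng.integers(len(ivs))]
            lo, hi = max(2, s + margin), min(L - 1, e - margin)
            if lo > hi:
                continue
            pos = int(rng.integers(lo, hi + 1))
        else:
            pos = int(rng.integers(2, L))
        if pos in used or seq[pos - 1] not in roots:
            continue
        if any(t.point_in_track(chrom, pos) for t in avoid_tracks):
            continue
        return pos
    raise ValueError("no eligible site remains for the requested class")


# ---------------------------------------------------------------------------
# genotype matrix assembly (strains VCF contents)
# ---------------------------------------------------------------------------

def _default_call_fields(gt_code: int):
    """(gq, dp, pl, ad_ref, ad_alt, sb) for a clean call of the given code."""
    if gt_code == GT_HOM_REF:
        return PASS_GQ, PASS_DP, PASS_PL_MARGIN, PASS_DP, 0, (20, 20, 0, 0)
    if gt_code == GT_HOM_ALT:
        return PASS_GQ, PASS_DP, PASS_PL_MARGIN, 0, PASS_DP, (0, 0, 20, 20)
    if gt_code == GT_HET:
        return PASS_GQ, PASS_DP, PASS_PL_MARGIN, 20, 20, (10, 10, 10, 10)
    return (spvio.MISSING_QUAL,) * 5 + ((spvio.MISSING_QUAL,) * 4,)


def strains_to_matrix(pool: FounderPool, strains: Sequence[MosaicStrain],
                      truth: TruthTable | None = None) -> GenotypeMatrix:
    """Assemble the laboratory-strain genotype matrix (panel SNPs + SPVs).

    All records carry clean filter-passing quality annotations; corruption
    tags recorded in the truth table flip one named field per record to just
    beyond its filter threshold. Records containing a heterozygous call are
    flagged with the ``Het`` FILTER, which the SPV filter stack ignores.
    """
    names = [s.name for s in strains]
    muts = list(truth.mutations) if truth else []
    mut_pos = np.array([m.pos for m in muts], dtype=np.int64)
    all_pos = np.concatenate([pool.snp_positions, mut_pos]) if len(muts) \
        else pool.snp_positions.copy()
    order = np.argsort(all_pos, kind="stable")
    all_pos = all_pos[order]
    n = len(all_pos)
    k = len(strains)
    is_mut = np.concatenate([np.zeros(pool.n_sites, bool),
                             np.ones(len(muts), bool)])[order]
    src_idx = np.concatenate([np.arange(pool.n_sites),
                              np.arange(len(muts))])[order]

    seq = pool.ref_sequence
    ref = np.array([seq[p - 1] for p in all_pos], dtype="U1")
    alt = np.empty(n, dtype="U1")
    gt = np.zeros((n, k), dtype=np.int8)
    name_to_col = {s.name: j for j, s in enumerate(strains)}

    for i in range(n):
        if is_mut[i]:
            m = muts[src_idx[i]]
            alt[i] = m.derived
            gt[i, :] = GT_HOM_REF
            gt[i, name_to_col[m.strain]] = (
                GT_HET if m.zygosity == "heterozygous" else GT_HOM_ALT)
        else:
            s_i = src_idx[i]
            alt[i] = pool.alt_bases[s_i]
            for j, strain in enumerate(strains):
                gt[i, j] = GT_HOM_ALT if strain.haplotype[s_i] else GT_HOM_REF

    qual = np.full(n, PASS_QUAL)
    gq = np.full((n, k), PASS_GQ, dtype=np.int32)
    dp = np.full((n, k), PASS_DP, dtype=np.int32)
    pl = np.full((n, k), PASS_PL_MARGIN, dtype=np.int32)
    ad_ref = np.where(gt == GT_HOM_REF, PASS_DP,
                      np.where(gt == GT_HET, 20, 0)).astype(np.int32)
    ad_alt = np.where(gt == GT_HOM_ALT, PASS_DP,
                      np.where(gt == GT_HET, 20, 0)).astype(np.int32)
    sb = np.zeros((n, k, 4), dtype=np.int32)
    sb[gt == GT_HOM_REF] = (20, 20, 0, 0)
    sb[gt == GT_HOM_ALT] = (0, 0, 20, 20)
    sb[gt == GT_HET] = (10, 10, 10, 10)

    # corruption overrides
    pos_to_row = {int(p): i for i, p in enumerate(all_pos)}
    rng = np.random.default_rng(0)  # deterministic choice of missing strains
    for m in muts:
        if not m.tag or m.tag in ("none", "segdup", "repeat", "wild", "ibd"):
            continue
        i = pos_to_row[m.pos]
        j = name_to_col[m.strain]
        if m.tag == "qual":
            qual[i] = 50.0
        elif m.tag == "gq":
            gq[i, j] = 60
        elif m.tag == "dp_low":
            dp[i, j] = 10
        elif m.tag == "dp_high":
            dp[i, j] = 5 * PASS_DP
        elif m.tag == "missing":
            k_missing = int(np.floor(0.15 * k)) + 1
            others = [c for c in range(k) if c != j]
            for c in others[:k_missing]:
                gt[i, c] = GT_MISSING
                gq[i, c] = dp[i, c] = pl[i, c] = spvio.MISSING_QUAL
                ad_ref[i, c] = ad_alt[i, c] = spvio.MISSING_QUAL
                sb[i, c] = spvio.MISSING_QUAL
        elif m.tag == "pl_margin":
            pl[i, j] = 20
        elif m.tag == "allele_balance":
            ad_ref[i, j], ad_alt[i, j] = 31, 9
            sb[i, j] = (16, 15, 5, 4)
        elif m.tag == "strand_bias":
            ad_ref[i, j], ad_alt[i, j] = 20, 20
            sb[i, j] = (2, 18, 18, 2)
        else:
            raise ValueError(f"unknown corruption tag {m.tag!r}")

    filters = [None if not (gt[i] == GT_HET).any() else "Het"
               for i in range(n)]
    return GenotypeMatrix(names, [pool.chrom] * n, all_pos, ref, alt, qual,
                          gt, gq, dp, pl, ad_ref, ad_alt, sb, filters)


# ---------------------------------------------------------------------------
# wild outgroup and wild-derived panel
# ---------------------------------------------------------------------------

def simulate_wild_outgroup(pool: FounderPool, n_samples: int = 27,
                           extra_diversity: float = 0.2,
                           n_private_sites: int = 1000, seed: int = 0,
                           exclude_positions: set[int] | None = None,
                           extra_polymorphic: Sequence[int] = ()
                           ) -> GenotypeMatrix:
    """Simulate a diverse wild sample with no long shared haplotypes.

    Genotypes at pool SNPs are drawn independently per sample from per-site
    population allele frequencies centred on the founder frequency and
    jittered by ``extra_diversity``; additional wild-private low-frequency
    sites are sprinkled in. Per-site independence guarantees that no sample
    pair shares a multi-megabase identical-genotype run at default density.
    """
    if extra_diversity <= 0:
        raise ValueError("extra_diversity must be > 0")
    rng = np.random.default_rng(seed)
    f = pool.founder_alleles.mean(axis=0)
    q = np.clip(f + rng.normal(0, extra_diversity, size=pool.n_sites),
                0.02, 0.98)
    positions = [pool.snp_positions]
    freqs = [q]
    refs = [np.array([pool.ref_sequence[p - 1]
                      for p in pool.snp_positions], dtype="U1")]
    alts = [pool.alt_bases]

    exclude = set(int(p) for p in pool.snp_positions)
    if exclude_positions:
        exclude |= exclude_positions
    if n_private_sites:
        priv = _sample_positions(n_private_sites, 2, pool.chrom_length - 1,
                                 exclude, rng)
        pref = np.array([pool.ref_sequence[p - 1] for p in priv], dtype="U1")
        palt = np.empty(len(priv), dtype="U1")
        others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
        for i, b in enumerate(pref):
            palt[i] = others[str(b)][rng.integers(3)]
        positions.append(priv)
        freqs.append(rng.uniform(0.02, 0.3, size=len(priv)))
        refs.append(pref)
        alts.append(palt)
    for p in extra_polymorphic:
        positions.append(np.array([p], dtype=np.int64))
        freqs.append(np.array([0.5]))
        b = pool.ref_sequence[p - 1]
        positions[-1], freqs[-1] = positions[-1], freqs[-1]
        refs.append(np.array([b], dtype="U1"))
        alts.append(np.array([[x for x in "ACGT" if x != b][0]], dtype="U1"))

    pos = np.concatenate(positions)
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    freq = np.concatenate(freqs)[order]
    ref = np.concatenate(refs)[order]
    alt = np.concatenate(alts)[order]
    n = len(pos)
    dose = rng.binomial(2, freq[:, None], size=(n, n_samples))
    gt = dose.astype(np.int8)  # codes coincide with dosage for 0/1/2
    names = [f"wild{i:02d}" for i in range(n_samples)]
    qual = np.full(n, PASS_QUAL)
    return GenotypeMatrix(names, [pool.chrom] * n, pos, ref, alt, qual, gt)


def simulate_wild_derived(pool: FounderPool, seed: int = 0) -> GenotypeMatrix:
    """Wild-derived inbred panel: one homozygous genome per founder haplotype.

    Carrying every founder haplotype makes the panel a faithful record of
    the ancestry of the laboratory founder pool, so the ancestral-variant
    filter can recognise any allele inherited from the founders.
    """
    names = [f"wd{f}" for f in range(pool.n_founders)]
    n = pool.n_sites
    gt = np.where(pool.founder_alleles.T == 1, GT_HOM_ALT,
                  GT_HOM_REF).astype(np.int8)
    ref = np.array([pool.ref_sequence[p - 1]
                    for p in pool.snp_positions], dtype="U1")
    qual = np.full(n, PASS_QUAL)
    return GenotypeMatrix(names, [pool.chrom] * n, pool.snp_positions.copy(),
                          ref, pool.alt_bases.copy(), qual, gt)


# ---------------------------------------------------------------------------
# masks, scores, traits
# ---------------------------------------------------------------------------

def simulate_mask_track(name: str, chrom: str, chrom_length: int,
                        genome_fraction: float, mean_interval: float,
                        seed: int = 0) -> IntervalTrack:
    """Random merged intervals covering ~genome_fraction of the chromosome."""
    rng = np.random.default_rng(seed)
    target = genome_fraction * chrom_length
    track = IntervalTrack(name)
    covered = 0.0
    while covered < target:
        length = max(100, int(rng.exponential(mean_interval)))
        start = int(rng.integers(0, max(1, chrom_length - length)))
        track.add(chrom, start, min(start + length, chrom_length))
        covered += length
    track.normalize()
    return track


def simulate_scores(pool: FounderPool, gene_models, variant_positions,
                    n_background: int, seed: int = 0) -> ScoreTrack:
    """Conservation-like scores: elevated inside coding regions."""
    rng = np.random.default_rng(seed)
    gene_ivs = sorted((g.start, g.end) for g in gene_models)
    starts = [s for s, _ in gene_ivs]

    def in_gene(p: int) -> bool:
        return _in_intervals(p, gene_ivs)

    scores = {}
    bg = rng.integers(1, pool.chrom_length + 1, size=n_background)
    for p in list(variant_positions) + [int(x) for x in bg]:
        if in_gene(p):
            s = rng.beta(3, 1.5)
        else:
            s = rng.beta(0.6, 4)
        scores[(pool.chrom, int(p))] = float(np.clip(s, 0.0, 1.0))
    return ScoreTrack(scores)


def simulate_traits(strains: Sequence[MosaicStrain],
                    spectra: Mapping[str, np.ndarray] | None,
                    n_replicates: int = 8,
                    trait_effect: tuple[str, str, float] | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Per-strain replicate breeding traits (days), long format.

    ``trait_effect=(trait, folded_class, slope)`` plants a linear dependence
    of the strain trait mean on that class's spectrum probability.
    """
    rng = np.random.default_rng(seed)
    params = {"dam_age_first_litter": (90.0, 12.0, 6.0),
              "interbirth_interval": (35.0, 6.0, 3.0)}
    rows = []
    for strain in strains:
        for trait, (mu, between, within) in params.items():
            mean = mu + rng.normal(0, between)
            if trait_effect and trait_effect[0] == trait and spectra:
                _, cls, slope = trait_effect
                mean += slope * float(
                    spectra[strain.name][FOLDED_CLASSES.index(cls)])
            for _ in range(n_replicates):
                rows.append({"strain": strain.name, "trait": trait,
                             "value": round(mean + rng.normal(0, within), 2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# corruption records
# ---------------------------------------------------------------------------

def plant_corruption_records(pool: FounderPool,
                             strains: Sequence[MosaicStrain],
                             rules: Sequence[str],
                             truth_ibd: Mapping[str, list[tuple[int, int]]],
                             avoid_tracks: Sequence[IntervalTrack],
                             used_positions: set[int], seed: int = 0,
                             margin: int = 50_000) -> list[PlantedMutation]:
    """One planted record per named filter rule, failing exactly that rule.

    Records are placed well inside the focal strain's true IBD territory
    (except the ``ibd`` rule, placed well outside it) and outside masked
    tracks, so that the template record passes every filter and the flipped
    field is the first and only failure.
    """
    rng = np.random.default_rng(seed)
    seq = pool.ref_sequence
    used = set(int(p) for p in pool.snp_positions) | set(used_positions)
    records = []
    strain_cycle = [s for s in strains if truth_ibd.get(s.name)]
    if not strain_cycle:
        raise ValueError("no strain has true IBD territory to corrupt")
    for r_i, rule in enumerate(rules):
        if rule not in CORRUPTION_RULES:
            raise ValueError(f"unknown corruption rule {rule!r}")
        strain = strain_cycle[r_i % len(strain_cycle)]
        ivs = truth_ibd[strain.name]
        if rule == "ibd":
            comp = _complement_intervals(ivs, pool.chrom_length)
            comp = [(s, e) for s, e in comp if e - s + 1 > 2 * margin + 2]
            if not comp:
                raise ValueError("no territory outside IBD for 'ibd' rule")
            pos = _draw_eligible(rng, seq, pool.chrom_length, ("A", "C", "G",
                                 "T"), used, comp, avoid_tracks, pool.chrom,
                                 margin)
        else:
            pos = _draw_eligible(rng, seq, pool.chrom_length,
                                 ("A", "C", "G", "T"), used, ivs,
                                 avoid_tracks, pool.chrom, margin)
        used.add(pos)
        anc = seq[pos - 1]
        folded, derived = _fold_from_ref(anc, rng)
        zyg = ("heterozygous" if rule in ("allele_balance", "strand_bias")
               else "fixed")
        records.append(PlantedMutation(
            strain=strain.name, chrom=pool.chrom, pos=pos, ancestral=anc,
            derived=derived, zygosity=zyg, folded_class=folded,
            tag=rule))
    return records


def _fold_from_ref(base: str, rng) -> tuple[str, str]:
    root = base if base in ("C", "T") else COMPLEMENT[base]
    targets = [b for b in "ACGT" if b != root]
    target = targets[rng.integers(3)]
    folded = f"{root}>{target}"
    derived = target if base == root else COMPLEMENT[target]
    return folded, derived


def _complement_intervals(ivs: list[tuple[int, int]], length: int
                          ) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for s, e in sorted(ivs):
        if s > prev + 1:
            out.append((prev + 1, s - 1))
        prev = max(prev, e)
    if prev < length:
        out.append((prev + 1, length))
    return out


# ---------------------------------------------------------------------------
# full fixture assembly
# ---------------------------------------------------------------------------

@dataclass
class FixtureSet:
    """In-memory bundle of everything one simulated study comprises."""

    config: SimulationConfig
    pool: FounderPool
    strains: list[MosaicStrain]
    truth: TruthTable
    matrix: GenotypeMatrix
    wild: GenotypeMatrix
    wild_derived: GenotypeMatrix
    repeats: IntervalTrack
    segdups: IntervalTrack
    gene_models: list
    scores: ScoreTrack
    traits: pd.DataFrame
    truth_ibd: dict[str, list[tuple[int, int]]]


def simulate_fixture(config: SimulationConfig, seed: int = 0) -> FixtureSet:
    """Run the whole generator and return every object in memory."""
    from . import neutrality

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(10)]

    pool = build_founder_pool(config.n_founders, config.chrom_length,
                              config.snp_density, config.gc_content,
                              seed=seeds[0], chrom=config.chrom)
    gene_models = neutrality.place_gene_models(
        pool, n_genes=config.n_genes, cds_length=config.cds_length,
        seed=seeds[1])
    strains = simulate_strain_mosaics(pool, config.n_strains,
                                      config.mean_block_length,
                                      seed=seeds[2])
    repeats = simulate_mask_track("repeats", config.chrom, config.chrom_length,
                          config.repeat_fraction, config.mask_mean_interval,
                          seed=seeds[3])
    segdups = simulate_mask_track("segdups", config.chrom, config.chrom_length,
                          config.segdup_fraction, config.mask_mean_interval,
                          seed=seeds[4])
    truth_ibd = true_ibd_union(strains)

    if config.spectrum_per_strain is not None:
        spectra = {name: _normalize_spectrum(sp)
                   for name, sp in config.spectrum_per_strain.items()}
    else:
        base = config.spectrum or DEFAULT_SPECTRUM
        spectra = {s.name: _normalize_spectrum(base) for s in strains}

    truth = plant_private_mutations(
        pool, strains, config.mutations_per_strain, spectra,
        het_fraction=config.het_fraction, seed=seeds[5],
        restrict_to=truth_ibd if config.plant_in_ibd else None)

    extra_wild = []
    if config.corrupt_rules:
        corrupt = plant_corruption_records(
            pool, strains, config.corrupt_rules, truth_ibd,
            avoid_tracks=(repeats, segdups),
            used_positions=truth.positions(), seed=seeds[6])
        truth.mutations.extend(corrupt)
        truth.mutations.sort(key=lambda m: m.pos)
        for m in corrupt:
            if m.tag == "segdup":
                segdups.add(config.chrom, m.pos - 1, m.pos)
            elif m.tag == "repeat":
                repeats.add(config.chrom, m.pos - 1, m.pos)
            elif m.tag == "wild":
                extra_wild.append(m.pos)
        segdups.normalize()
        repeats.normalize()

    matrix = strains_to_matrix(pool, strains, truth)
    wild = simulate_wild_outgroup(
        pool, config.n_wild, config.wild_extra_diversity,
        config.n_wild_private_sites, seed=seeds[7],
        exclude_positions=truth.positions(),
        extra_polymorphic=extra_wild)
    wild_derived = simulate_wild_derived(pool, seed=seeds[8])
    scores = simulate_scores(pool, gene_models,
                             [int(p) for p in matrix.pos],
                             config.n_score_background, seed=seeds[9])
    traits = simulate_traits(strains, spectra, config.n_trait_replicates,
                             config.trait_effect, seed=seeds[6] + 1)
    return FixtureSet(config=config, pool=pool, strains=strains, truth=truth,
                      matrix=matrix, wild=wild, wild_derived=wild_derived,
                      repeats=repeats, segdups=segdups,
                      gene_models=gene_models, scores=scores, traits=traits,
                      truth_ibd=truth_ibd)


def emit_fixture_set(outdir: str | Path, config: SimulationConfig,
                     seed: int = 0) -> FixtureSet:
    """Write a complete study fixture to ``outdir`` and return the objects."""
    from . import neutrality

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = simulate_fixture(config, seed)
    contigs = {config.chrom: config.chrom_length}
    spvio.write_fasta({config.chrom: fx.pool.ref_sequence},
                      outdir / "ref.fa")
    spvio.write_genotypes(fx.matrix, outdir / "strains.vcf", contigs)
    spvio.write_genotypes(fx.wild, outdir / "wild.vcf", contigs)
    spvio.write_genotypes(fx.wild_derived, outdir / "wild_derived.vcf",
                          contigs)
    spvio.write_interval_track(fx.repeats, outdir / "repeats.bed")
    spvio.write_interval_track(fx.segdups, outdir / "segdups.bed")
    spvio.write_score_track(fx.scores, outdir / "scores.tsv")
    neutrality.write_gene_models(fx.gene_models, outdir / "genes.gff3")
    spvio.write_trait_table(fx.traits, outdir / "traits.tsv")
    pd.DataFrame([{
        "strain": m.strain, "chrom": m.chrom, "pos": m.pos,
        "ancestral": m.ancestral, "derived": m.derived,
        "zygosity": m.zygosity, "folded_class": m.folded_class,
        "tag": m.tag or ""} for m in fx.truth.mutations
    ]).to_csv(outdir / "truth_mutations.tsv", sep="\t", index=False)
    rows = []
    for name, blocks in fx.truth.blocks.items():
        for s, e, f in blocks:
            rows.append({"strain": name, "start": s, "end": e, "founder": f})
    pd.DataFrame(rows).to_csv(outdir / "truth_blocks.tsv", sep="\t",
                              index=False)
    logger.info("fixture written to %s (%d strains, %d planted mutations)",
                outdir, config.n_strains, len(fx.truth.mutations))
    return fx
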