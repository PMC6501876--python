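"""Strain-private variant calling on identical-by-descent haplotypes.

A strain-private variant (SPV) is an allele carried by exactly one inbred
strain at a site where every other strain shares the major allele. When the
site lies on a haplotype otherwise shared identical-by-descent with other
strains, the private allele is best explained as a single recent germline
mutation in the focal strain's breeding history.

Candidates (singletons) are passed through a stringent filter stack applied
in a fixed order for deterministic audits:

    a. site QUAL > 50
    b. focal-strain GQ > 60
    c. focal DP > 10 and DP < 1.9 x that strain's mean depth
    d. fraction of missing genotypes across strains < 0.15
    e. site outside segmental duplications
    f. site not repeat-masked
    g. focal genotype-likelihood margin > 20
    h. site neither polymorphic in the wild panel nor carrying the
       alternative allele in any wild-derived genome (removes ancestral
       variants, and with them sites of frequent recurrent mutation)
    i. position inside a retained (>= 5 Mb) IBD segment of the focal strain
    j. heterozygous only: allele balance min(ad)/(total) > 0.3
    k. heterozygous only: chi-square test of no allele and no strand bias,
       p > 0.05

Survivors are polarized (the non-private major allele is ancestral), given
their reference-strand trinucleotide context, and folded onto the six
pyrimidine-rooted substitution classes. The survivor set is independent of
rule order; only the audit's attribution of first failures depends on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ibd import IBDSegment, position_in_segments, strain_ibd_intervals
from .io import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, GenotypeMatrix,
                 IntervalTrack, ReferenceStore)

logger = logging.getLogger(__name__)

FOLDED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: filter-stack rule names in evaluation order
FILTER_RULES = ("qual", "gq", "dp", "missing", "segdup", "repeat",
                "pl_margin", "wild", "ibd", "allele_balance", "strand_bias")


@dataclass
class FilterParams:
    """Thresholds of the SPV filter stack (defaults are the study values)."""

    min_qual: float = 50.0
    min_gq: int = 60
    min_dp: int = 10
    max_dp_factor: float = 1.9
    max_missing_fraction: float = 0.15
    min_pl_margin: int = 20
    min_allele_balance: float = 0.3
    min_bias_p: float = 0.05
    honor_het_filter_exception: bool = True


@dataclass
class SPVRecord:
    """A filtered, polarized strain-private variant."""

    strain: str
    chrom: str
    pos: int
    ancestral: str
    derived: str
    zygosity: str                    # "fixed" | "heterozygous"
    trinucleotide_context: str       # reference strand, centred on the site
    folded_class: str
    cpg_flag: bool

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles must differ")
        if self.folded_class not in FOLDED_CLASSES:
            raise ValueError(f"bad folded class {self.folded_class!r}")


@dataclass
class FilterAudit:
    """Per-rule counters: every candidate survives or fails exactly once."""

    candidates_in: int = 0
    survivors: int = 0
    failures: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FILTER_RULES})
    excluded_candidates: int = 0     # e.g. FILTER flags other than Het

    def check_conservation(self) -> bool:
        return (self.candidates_in
                == self.survivors + sum(self.failures.values())
                + self.excluded_candidates)


# ---------------------------------------------------------------------------
# candidate identification
# ---------------------------------------------------------------------------

def identify_singletons(matrix: GenotypeMatrix) -> np.ndarray:
    """Row indices of sites where exactly one strain carries the alt allele.

    The carrier may be heterozygous or homozygous-alternative; all other
    non-missing strains must be homozygous-reference.
    """
    carries = (matrix.gt == GT_HET) | (matrix.gt == GT_HOM_ALT)
    ok_others = (matrix.gt == GT_HOM_REF) | (matrix.gt == GT_MISSING)
    single = carries.sum(axis=1) == 1
    clean = (carries | ok_others).all(axis=1)
    return np.where(single & clean)[0]


# ---------------------------------------------------------------------------
# per-record tests
# ---------------------------------------------------------------------------

def chi2_bias_test(strand_counts) -> float:
    """Goodness-of-fit chi-square (df=3) for joint allele and strand bias.

    Observed (ref_fwd, ref_rev, alt_fwd, alt_rev) counts are compared with
    expectations under a 50/50 allele fraction and the observed overall
    forward/reverse read ratio. Returns the upper-tail p-value.
    """
    obs = np.asarray(strand_counts, dtype=float)
    if obs.shape != (4,) or (obs < 0).any():
        raise ValueError("strand_counts must be 4 non-negative counts")
    n = obs.sum()
    if n == 0:
        raise ValueError("no reads: all strand counts are zero")
    p_fwd = (obs[0] + obs[2]) / n
    exp = n * 0.5 * np.array([p_fwd, 1 - p_fwd, p_fwd, 1 - p_fwd])
    mask = exp > 0
    chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    return float(stats.chi2.sf(chi2, df=3))


def polarize(matrix: GenotypeMatrix, row: int, focal: str
             ) -> tuple[str, str]:
    """(ancestral, derived) for a singleton: the non-private allele is
    ancestral, the focal strain's private allele derived."""
    j = matrix.strain_index(focal)
    code = int(matrix.gt[row, j])
    if code not in (GT_HET, GT_HOM_ALT):
        raise ValueError(
            f"{focal} does not carry the alternative allele at row {row}; "
            "reference-private patterns are excluded upstream")
    others = np.delete(matrix.gt[row], j)
    others = others[others != GT_MISSING]
    if len(others) and not (others == GT_HOM_REF).all():
        raise ValueError("site is not private to the focal strain")
    return str(matrix.ref[row]), str(matrix.alt[row])


def trinucleotide_context(ref_store: ReferenceStore, chrom: str,
                          pos: int) -> str:
    """Reference-strand 3-mer centred on a 1-based position."""
    return ref_store.fetch(chrom, pos - 1, pos + 1)


def fold_class(ancestral: str, derived: str) -> tuple[str, bool]:
    """Fold a substitution onto the pyrimidine-rooted classes.

    Returns (folded class, flipped) where ``flipped`` records that the
    ancestral base was a purine on the reference strand and the event was
    mapped through its reverse complement.
    """
    if ancestral == derived:
        raise ValueError("ancestral and derived alleles must differ")
    if ancestral in ("C", "T"):
        return f"{ancestral}>{derived}", False
    return f"{COMPLEMENT[ancestral]}>{COMPLEMENT[derived]}", True


def cpg_annotate(context: str, folded_class: str, flipped: bool) -> bool:
    """Is a C-rooted event at a CpG dinucleotide?

    On the reference strand the pyrimidine-strand CpG shows as the base 3'
    of an ancestral C being G; for folded (purine-ancestral) events the
    mutated C sits on the reverse strand, so the reference base 5' of the
    ancestral G must be C.
    """
    if len(context) != 3:
        raise ValueError("context must be a 3-mer")
    if not folded_class.startswith("C"):
        return False
    return context[0] == "C" if flipped else context[2] == "G"


# ---------------------------------------------------------------------------
# the filter stack
# ---------------------------------------------------------------------------

def mean_sample_depth(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-strain mean DP over all processed sites (missing DP excluded)."""
    dp = matrix.dp.astype(float)
    dp[matrix.dp < 0] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(dp, axis=0)


def _wild_lookup(wild: GenotypeMatrix) -> dict[tuple[str, int], bool]:
    """(chrom,pos) -> site is polymorphic (both alleles observed)."""
    out = {}
    for i in range(wild.n_sites):
        gt = wild.gt[i]
        has_alt = ((gt == GT_HET) | (gt == GT_HOM_ALT)).any()
        has_ref = ((gt == GT_HET) | (gt == GT_HOM_REF)).any()
        out[(str(wild.chrom[i]), int(wild.pos[i]))] = bool(has_alt
                                                           and has_ref)
    return out


def _wild_derived_lookup(wd: GenotypeMatrix) -> set[tuple[str, int]]:
    """Sites where any wild-derived genome carries the alternative allele."""
    carries = ((wd.gt == GT_HET) | (wd.gt == GT_HOM_ALT)).any(axis=1)
    return {(str(c), int(p))
            for c, p, k in zip(wd.chrom, wd.pos, carries) if k}


def apply_filter_stack(candidates: np.ndarray, matrix: GenotypeMatrix,
                       repeat_track: IntervalTrack,
                       segdup_track: IntervalTrack,
                       wild_matrix: GenotypeMatrix,
                       wild_derived_matrix: GenotypeMatrix,
                       segments: list[IBDSegment],
                       ref_store: ReferenceStore,
                       params: FilterParams | None = None
                       ) -> tuple[list[SPVRecord], FilterAudit]:
    """Apply the full SPV filter stack to candidate singleton rows.

    ``segments`` must already be restricted to the >= 5 Mb retention set.
    The audit records, for every rejected candidate, the first rule in the
    fixed evaluation order that failed.
    """
    if params is None:
        params = FilterParams()
    if not segments:
        raise ValueError("no IBD territory; SPV calling undefined")
    audit = FilterAudit(candidates_in=len(candidates))
    mean_dp = mean_sample_depth(matrix)
    wild_poly = _wild_lookup(wild_matrix)
    wd_alt = _wild_derived_lookup(wild_derived_matrix)
    ibd_by_strain = {s: strain_ibd_intervals(segments, s)
                     for s in matrix.strains}
    records: list[SPVRecord] = []

    for row in candidates:
        row = int(row)
        carriers = np.where((matrix.gt[row] == GT_HET)
                            | (matrix.gt[row] == GT_HOM_ALT))[0]
        if len(carriers) != 1:
            raise ValueError(f"row {row} is not a singleton")
        j = int(carriers[0])
        focal = matrix.strains[j]
        chrom, pos = str(matrix.chrom[row]), int(matrix.pos[row])
        het = matrix.gt[row, j] == GT_HET

        flt = matrix.filters[row]
        if flt and params.honor_het_filter_exception:
            names = set(flt.split(";")) - {"Het", "PASS"}
            if names:
                audit.excluded_candidates += 1
                continue

        failed = None
        if not matrix.qual[row] > params.min_qual:
            failed = "qual"
        elif not matrix.gq[row, j] > params.min_gq:
            failed = "gq"
        elif not (matrix.dp[row, j] > params.min_dp
                  and matrix.dp[row, j] < params.max_dp_factor * mean_dp[j]):
            failed = "dp"
        elif not ((matrix.gt[row] == GT_MISSING).mean()
                  < params.max_missing_fraction):
            failed = "missing"
        elif segdup_track.point_in_track(chrom, pos):
            failed = "segdup"
        elif repeat_track.point_in_track(chrom, pos):
            failed = "repeat"
        elif not matrix.pl_margin[row, j] > params.min_pl_margin:
            failed = "pl_margin"
        elif wild_poly.get((chrom, pos), False) or (chrom, pos) in wd_alt:
            failed = "wild"
        elif not position_in_segments(ibd_by_strain[focal], chrom, pos):
            failed = "ibd"
        elif het:
            ad_r, ad_a = int(matrix.ad_ref[row, j]), int(matrix.ad_alt[row, j])
            total = ad_r + ad_a
            balance = min(ad_r, ad_a) / total if total > 0 else -1.0
            if not balance > params.min_allele_balance:
                failed = "allele_balance"
            elif not (chi2_bias_test(matrix.strand[row, j])
                      > params.min_bias_p):
                failed = "strand_bias"

        if failed is not None:
            audit.failures[failed] += 1
            continue

        ancestral, derived = polarize(matrix, row, focal)
        context = trinucleotide_context(ref_store, chrom, pos)
        folded, flipped = fold_class(ancestral, derived)
        records.append(SPVRecord(
            strain=focal, chrom=chrom, pos=pos, ancestral=ancestral,
            derived=derived,
            zygosity="heterozygous" if het else "fixed",
            trinucleotide_context=context, folded_class=folded,
            cpg_flag=cpg_annotate(context, folded, flipped)))
        audit.survivors += 1

    if not audit.check_conservation():
        raise AssertionError("filter audit does not conserve candidates")
    return records, audit


def call_spvs(matrix: GenotypeMatrix, repeat_track: IntervalTrack,
              segdup_track: IntervalTrack, wild_matrix: GenotypeMatrix,
              wild_derived_matrix: GenotypeMatrix,
              segments: list[IBDSegment], ref_store: ReferenceStore,
              params: FilterParams | None = None
              ) -> tuple[list[SPVRecord], FilterAudit]:
    """Identify singletons and run them through the filter stack."""
    candidates = identify_singletons(matrix)
    return apply_filter_stack(candidates, matrix, repeat_track, segdup_track,
                              wild_matrix, wild_derived_matrix, segments,
                              ref_store, params)


# ---------------------------------------------------------------------------
# common variants
# ---------------------------------------------------------------------------

def define_common_variants(matrix: GenotypeMatrix,
                           repeat_track: IntervalTrack | None = None,
                           segdup_track: IntervalTrack | None = None,
                           include_reference: bool = True) -> np.ndarray:
    """Row indices of biallelic SNPs segregating in >= 2 laboratory strains.

    The alternative allele must be present in at least two strains; repeat
    and segmental-duplication masking matches the SPV filters when tracks
    are supplied. ``include_reference`` is accepted for interface symmetry:
    the implicit reference sample carries no alternative alleles, so it
    never changes membership of this set.
    """
    carries = ((matrix.gt == GT_HET) | (matrix.gt == GT_HOM_ALT)).sum(axis=1)
    keep = carries >= 2
    if repeat_track is not None or segdup_track is not None:
        for i in np.where(keep)[0]:
            chrom, pos = str(matrix.chrom[i]), int(matrix.pos[i])
            if ((repeat_track is not None
                 and repeat_track.point_in_track(chrom, pos))
                    or (segdup_track is not None
                        and segdup_track.point_in_track(chrom, pos))):
                keep[i] = False
    return np.where(keep)[0]


def polarize_common(matrix: GenotypeMatrix, sites: np.ndarray,
                    wild_derived_matrix: GenotypeMatrix
                    ) -> dict[int, str | None]:
    """Parsimony ancestral states for common variants.

    A site's ancestral allele is the one fixed across the wild-derived
    panel; sites segregating (or absent) in that panel are undetermined
    (``None``) and excluded from polarized analyses.
    """
    wd_index = wild_derived_matrix.site_index()
    out: dict[int, str | None] = {}
    for row in sites:
        row = int(row)
        key = (str(matrix.chrom[row]), int(matrix.pos[row]))
        i = wd_index.get(key)
        if i is None:
            out[row] = None
            continue
        gt = wild_derived_matrix.gt[i]
        called = gt[gt != GT_MISSING]
        if len(called) == 0:
            out[row] = None
        elif (called == GT_HOM_REF).all():
            out[row] = str(wild_derived_matrix.ref[i])
        elif (called == GT_HOM_ALT).all():
            out[row] = str(wild_derived_matrix.alt[i])
        else:
            out[row] = None
    return out
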