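"""Pairwise identical-by-descent segment detection for inbred genomes.

Inbred strains are homozygous almost everywhere, so IBD between two strains
reduces to long runs of identical homozygous genotypes over a panel of
shared SNPs. The detector scans each strain pair for maximal runs of
identical non-missing homozygous calls (a configurable mismatch budget is
supported; the default of 0 means a single discordant site terminates a
run) and keeps runs spanning at least ``min_seed_bp``. Downstream analyses
retain only segments of at least 5 Mb, the scale at which wild mouse
populations show no IBD at all — segments that long must reflect descent
from a single laboratory founder.

Design choices: missing genotypes and heterozygous calls both terminate
runs (conservative for nominally inbred genomes), and segment coordinates
snap to the outermost matching panel SNPs, so lengths are reproducible from
the panel alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEED_BP = 200_000       # GERMLINE-style minimum block size
DEFAULT_MIN_KEEP_BP = 5_000_000     # retention threshold for SPV analyses
DEFAULT_MAF_MIN = 0.05


@dataclass(frozen=True)
class IBDSegment:
    """A maximal identical-genotype interval shared by a strain pair."""

    strain_a: str
    strain_b: str
    chrom: str
    start_pos: int      # 1-based inclusive, at panel SNP positions
    end_pos: int
    n_sites: int        # panel SNPs spanned

    def __post_init__(self):
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def build_ibd_panel(matrix: GenotypeMatrix, maf_min: float = DEFAULT_MAF_MIN,
                    min_minor_strains: int = 2,
                    include_reference: bool = True) -> GenotypeMatrix:
    """Select the SNP panel used for IBD inference.

    Sites are kept when their minor allele frequency across non-missing
    strain genotypes is strictly greater than ``maf_min`` and the minor
    allele is observed in at least ``min_minor_strains`` strains. The second
    condition is the sample-size-invariant core of the frequency cutoff:
    restricting the panel to alleles shared by two or more strains is what
    keeps private alleles out of the panel so that a private variant can sit
    *inside* an IBD segment rather than interrupting it. The implicit
    all-homozygous-reference sample contributed by the reference strain
    counts toward frequencies when ``include_reference`` is set.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    dose = matrix.alt_dosage()
    called = ~np.isnan(dose)
    n_called = called.sum(axis=1).astype(float)
    alt_sum = np.nansum(dose, axis=1)
    denom = 2.0 * (n_called + (1 if include_reference else 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(denom > 0, alt_sum / denom, np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    carries_alt = ((matrix.gt == GT_HET) | (matrix.gt == GT_HOM_ALT)
                   ).sum(axis=1)
    carries_ref = ((matrix.gt == GT_HET) | (matrix.gt == GT_HOM_REF)
                   ).sum(axis=1) + (1 if include_reference else 0)
    minor_carriers = np.where(alt_freq <= 0.5, carries_alt, carries_ref)

    keep = (maf > maf_min) & (minor_carriers >= min_minor_strains)
    keep &= n_called > 0
    if not keep.any():
        raise ValueError("no sites remain after MAF filtering; "
                         "IBD panel is empty")
    logger.info("IBD panel: %d of %d sites kept (MAF > %.3g, minor allele "
                "in >= %d strains)", int(keep.sum()), matrix.n_sites,
                maf_min, min_minor_strains)
    return matrix.take(np.where(keep)[0])


# ---------------------------------------------------------------------------
# pairwise detection
# ---------------------------------------------------------------------------

def _match_vector(gt_a: np.ndarray, gt_b: np.ndarray) -> np.ndarray:
    """True where both calls are homozygous, non-missing and equal."""
    hom_a = (gt_a == GT_HOM_REF) | (gt_a == GT_HOM_ALT)
    hom_b = (gt_b == GT_HOM_REF) | (gt_b == GT_HOM_ALT)
    return hom_a & hom_b & (gt_a == gt_b)


def _match_runs(match: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized maximal runs of True: (start indices, end indices)."""
    padded = np.concatenate(([False], match, [False]))
    d = np.diff(padded.astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1


def _maximal_windows(match: np.ndarray, max_mismatches: int
                     ) -> Iterable[tuple[int, int]]:
    """Maximal index windows containing <= max_mismatches non-matching sites.

    Windows are trimmed to start and end on matching sites; with a budget of
    0 this reduces to plain maximal runs of matches.
    """
    if max_mismatches == 0:
        yield from zip(*(arr.tolist() for arr in _match_runs(match)))
        return
    n = len(match)
    mism = np.flatnonzero(~match)
    bounds = np.concatenate(([-1], mism, [n]))
    k = max_mismatches
    n_m = len(mism)
    for i in range(n_m - k + 1) if n_m >= k else range(1):
        lo = bounds[i] + 1                       # after previous mismatch
        hi = bounds[i + k + 1] - 1 if i + k + 1 < len(bounds) else n - 1
        # trim to matching endpoints
        while lo <= hi and not match[lo]:
            lo += 1
        while hi >= lo and not match[hi]:
            hi -= 1
        if lo <= hi:
            yield lo, hi


def detect_pairwise_ibd(panel: GenotypeMatrix, strain_a: str, strain_b: str,
                        min_seed_bp: int = DEFAULT_MIN_SEED_BP,
                        max_mismatches: int = 0) -> list[IBDSegment]:
    """Maximal shared segments between two strains spanning >= min_seed_bp.

    Output is symmetric in the two strains; segment strain labels are stored
    in sorted order.
    """
    ja = panel.strain_index(strain_a)
    jb = panel.strain_index(strain_b)
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    a_name, b_name = sorted((strain_a, strain_b))
    segments: list[IBDSegment] = []
    for chrom in pd.unique(panel.chrom):
        idx = np.where(panel.chrom == chrom)[0]
        pos = panel.pos[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        match = _match_vector(panel.gt[idx, ja], panel.gt[idx, jb])
        seen: set[tuple[int, int]] = set()
        for lo, hi in _maximal_windows(match, max_mismatches):
            key = (lo, hi)
            if key in seen:
                continue
            seen.add(key)
            start, end = int(pos[lo]), int(pos[hi])
            if end - start + 1 >= min_seed_bp:
                segments.append(IBDSegment(
                    strain_a=a_name, strain_b=b_name, chrom=str(chrom),
                    start_pos=start, end_pos=end, n_sites=hi - lo + 1))
    return segments


def detect_ibd(panel: GenotypeMatrix,
               min_seed_bp: int = DEFAULT_MIN_SEED_BP,
               max_mismatches: int = 0) -> list[IBDSegment]:
    """Run the pairwise detector over every unordered strain pair."""
    segments = []
    for a, b in combinations(panel.strains, 2):
        segments.extend(detect_pairwise_ibd(panel, a, b, min_seed_bp,
                                            max_mismatches))
    return segments


def filter_segments(segments: Sequence[IBDSegment],
                    min_length_bp: float = DEFAULT_MIN_KEEP_BP
                    ) -> list[IBDSegment]:
    """Keep segments with length_bp >= min_length_bp (inclusive)."""
    return [s for s in segments if s.length_bp >= min_length_bp]


# ---------------------------------------------------------------------------
# per-strain summaries
# ---------------------------------------------------------------------------

def strain_ibd_intervals(segments: Sequence[IBDSegment], strain: str
                         ) -> dict[str, list[tuple[int, int]]]:
    """Merged per-chromosome union of segments involving ``strain``."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        if strain in (s.strain_a, s.strain_b):
            by_chrom.setdefault(s.chrom, []).append((s.start_pos, s.end_pos))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for a, b in ivs[1:]:
            if a <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        merged[chrom] = [tuple(x) for x in out]
    return merged


def strain_ibd_coverage(segments: Sequence[IBDSegment], strain: str,
                        genome_length: int) -> float:
    """Fraction of the genome covered by the strain's IBD union."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    total = 0
    for ivs in strain_ibd_intervals(segments, strain).values():
        total += sum(e - s + 1 for s, e in ivs)
    return total / genome_length


def position_in_segments(intervals: dict[str, list[tuple[int, int]]],
                         chrom: str, pos: int) -> bool:
    import bisect
    ivs = intervals.get(chrom)
    if not ivs:
        return False
    starts = [s for s, _ in ivs]
    i = bisect.bisect_right(starts, pos) - 1
    return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


def longest_pairwise_run(matrix: GenotypeMatrix) -> int:
    """Longest identical-genotype run (bp) over all sample pairs.

    Identity here is genotype identity including heterozygous matches —
    the quantity used to verify that a wild outgroup carries no long shared
    haplotypes. Missing calls break runs.
    """
    if matrix.n_strains < 2:
        raise ValueError("need at least two samples")
    longest = 0
    for chrom in pd.unique(matrix.chrom):
        idx = np.where(matrix.chrom == chrom)[0]
        pos = matrix.pos[idx]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        gt = matrix.gt[idx][order]
        for ja, jb in combinations(range(matrix.n_strains), 2):
            match = ((gt[:, ja] == gt[:, jb]) & (gt[:, ja] != GT_MISSING))
            lo, hi = _match_runs(match)
            if len(lo):
                longest = max(longest, int((pos[hi] - pos[lo] + 1).max()))
    return longest


# ---------------------------------------------------------------------------
# segment table I/O
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["strain_a", "strain_b", "chrom", "start", "end",
                   "n_sites"]


def write_segments(segments: Sequence[IBDSegment], path: str | Path) -> None:
    pd.DataFrame(
        [{"strain_a": s.strain_a, "strain_b": s.strain_b, "chrom": s.chrom,
          "start": s.start_pos, "end": s.end_pos, "n_sites": s.n_sites}
         for s in segments],
        columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[IBDSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [IBDSegment(strain_a=r.strain_a, strain_b=r.strain_b,
                       chrom=r.chrom, start_pos=int(r.start),
                       end_pos=int(r.end), n_sites=int(r.n_sites))
            for r in df.itertuples(index=False)]
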