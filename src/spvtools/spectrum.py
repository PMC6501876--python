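"""Folded, opportunity-standardized mutation spectra.

Because the mutated strand is unknown, substitutions are folded onto the
six pyrimidine-rooted classes (C>A, C>G, C>T, T>A, T>C, T>G). Raw class
counts are then standardized by mutational opportunity — the number of
bases within the focal strain's retained IBD territory at which each class
could have occurred (C/G bases for C-rooted classes, A/T for T-rooted) —
and scaled to sum to one:

    rate_i = count_i / opportunity_i,  frequency_i = rate_i / sum_j rate_j

An optional 7-category version splits C>T by CpG context (CpG>TpG versus
nonCpG>T), with CpG opportunity counted as the number of bases lying in a
CpG dinucleotide on either strand. Composition is measured on the reference
sequence of the IBD intervals: private variants are vanishingly rare
relative to interval size, so the strain's own alleles would change the
counts negligibly.

Heterozygous and fixed variants contribute one event each — either way the
most parsimonious history is a single mutational event in the focal
strain's breeding line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import SPVRecord
from .ibd import IBDSegment, strain_ibd_intervals
from .io import ReferenceStore

logger = logging.getLogger(__name__)

FOLDED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SPLIT_CLASSES = ("C>A", "C>G", "CpG>TpG", "nonCpG>T", "T>A", "T>C", "T>G")


def class_names(split_cpg: bool) -> tuple[str, ...]:
    return SPLIT_CLASSES if split_cpg else FOLDED_CLASSES


@dataclass
class MutationSpectrum:
    """Per-strain class counts, opportunities and standardized frequencies."""

    strain: str
    counts: dict[str, int]
    opportunities: dict[str, int]
    frequencies: dict[str, float] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"strain": self.strain, "class": c,
              "count": self.counts.get(c, 0),
              "opportunity": self.opportunities.get(c, 0),
              "frequency": self.frequencies.get(c, 0.0),
              "proportion": self.proportions.get(c, 0.0)}
             for c in self.counts])


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_classes(spvs: Sequence[SPVRecord], strain: str,
                  split_cpg: bool = False) -> dict[str, int]:
    """Tally folded classes for one strain's variants.

    With ``split_cpg``, C>T events divide by CpG context into CpG>TpG and
    nonCpG>T (7 categories).
    """
    counts = {c: 0 for c in class_names(split_cpg)}
    for r in spvs:
        if r.strain != strain:
            continue
        cls = r.folded_class
        if split_cpg and cls == "C>T":
            cls = "CpG>TpG" if r.cpg_flag else "nonCpG>T"
        counts[cls] += 1
    return counts


# ---------------------------------------------------------------------------
# opportunities
# ---------------------------------------------------------------------------

def _interval_composition(ref_store: ReferenceStore, chrom: str, start: int,
                          end: int) -> tuple[int, int, int]:
    """(#C+#G, #A+#T, #CpG-positions) for [start, end] 1-based inclusive.

    CpG positions are counted on both strands: each CG dinucleotide whose C
    lies within the interval contributes its C, and each whose G lies
    within contributes that G, including pairs straddling interval edges.
    """
    seq = ref_store.fetch(chrom, start, end)
    cg = seq.count("C") + seq.count("G")
    at = seq.count("A") + seq.count("T")
    contig_len = ref_store.contigs()[chrom]
    ext_start = max(1, start - 1)
    ext_end = min(contig_len, end + 1)
    ext = ref_store.fetch(chrom, ext_start, ext_end)
    offset = start - ext_start
    arr = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
    pair_idx = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    lo, hi = offset, offset + len(seq)
    c_inside = ((pair_idx >= lo) & (pair_idx < hi)).sum()
    g_inside = ((pair_idx + 1 >= lo) & (pair_idx + 1 < hi)).sum()
    return cg, at, int(c_inside + g_inside)


def ibd_composition(ref_store: ReferenceStore,
                    segments: Sequence[IBDSegment], strain: str,
                    split_cpg: bool = False) -> dict[str, int]:
    """Mutational opportunities over the strain's retained IBD territory."""
    cg_total = at_total = cpg_total = 0
    for chrom, ivs in strain_ibd_intervals(segments, strain).items():
        for start, end in ivs:
            cg, at, cpg = _interval_composition(ref_store, chrom, start, end)
            cg_total += cg
            at_total += at
            cpg_total += cpg
    if not split_cpg:
        return {"C>A": cg_total, "C>G": cg_total, "C>T": cg_total,
                "T>A": at_total, "T>C": at_total, "T>G": at_total}
    return {"C>A": cg_total, "C>G": cg_total, "CpG>TpG": cpg_total,
            "nonCpG>T": cg_total - cpg_total, "T>A": at_total,
            "T>C": at_total, "T>G": at_total}


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(counts: Mapping[str, int],
                opportunities: Mapping[str, int]) -> dict[str, float]:
    """Composition-standardized class frequencies scaled to sum to one.

    Classes with zero opportunity and zero count get frequency 0; a nonzero
    count with zero opportunity is contradictory and raises.
    """
    rates = {}
    for cls, n in counts.items():
        opp = opportunities.get(cls, 0)
        if opp <= 0:
            if n:
                raise ValueError(
                    f"class {cls} has {n} events but zero opportunity")
            rates[cls] = 0.0
        else:
            rates[cls] = n / opp
    total = sum(rates.values())
    if total == 0:
        logger.warning("no events in any class; frequencies all zero")
        return {cls: 0.0 for cls in counts}
    return {cls: r / total for cls, r in rates.items()}


def proportions(counts: Mapping[str, int]) -> dict[str, float]:
    """Unstandardized class proportions (for comparison with de novo sets)."""
    total = sum(counts.values())
    if total == 0:
        return {cls: 0.0 for cls in counts}
    return {cls: n / total for cls, n in counts.items()}


def strain_spectrum(spvs: Sequence[SPVRecord], strain: str,
                    ref_store: ReferenceStore,
                    segments: Sequence[IBDSegment],
                    split_cpg: bool = False) -> MutationSpectrum:
    counts = count_classes(spvs, strain, split_cpg)
    opps = ibd_composition(ref_store, segments, strain, split_cpg)
    return MutationSpectrum(strain=strain, counts=counts, opportunities=opps,
                            frequencies=standardize(counts, opps),
                            proportions=proportions(counts))


def spectrum_table(spvs: Sequence[SPVRecord], strains: Sequence[str],
                   ref_store: ReferenceStore,
                   segments: Sequence[IBDSegment],
                   split_cpg: bool = False) -> pd.DataFrame:
    """Long-format table: strain, class, count, opportunity, frequency."""
    frames = [strain_spectrum(spvs, s, ref_store, segments,
                              split_cpg).to_frame() for s in strains]
    return pd.concat(frames, ignore_index=True)


def total_variation(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """Total-variation distance between two class distributions."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
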