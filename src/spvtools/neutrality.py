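"""Tests of whether private variants behave like unselected new mutations.

Recent mutations have had no time to feel purifying selection, so their
coding-consequence composition should approach the expectation for uniform
mutation over coding sites, and their conservation-score distribution
should track the genome-wide distribution rather than the depleted
distribution of old, common variants. This module provides:

* a codon-table consequence annotator over single-exon CDS gene models,
* the uniform-mutation null (exhaustive enumeration of all nine single-base
  changes at every CDS position),
* the likelihood-ratio G-test of independence, G = 2 * sum O ln(O/E),
* percentile bootstrap confidence intervals for consequence-class
  percentages, and
* two-sample Kolmogorov-Smirnov comparison of conservation-score CDFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .io import ReferenceStore

logger = logging.getLogger(__name__)

CONSEQUENCES = ("synonymous", "missense", "nonsense")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class GeneModel:
    """A single-exon, forward-strand CDS with frame anchored at its start."""

    name: str
    chrom: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    strand: str = "+"

    def __post_init__(self):
        if self.strand != "+":
            raise ValueError("only forward-strand models are supported")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(f"CDS length of {self.name} not divisible by 3")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def validate_gene_model(model: GeneModel, ref_store: ReferenceStore) -> None:
    """Check the encoded peptide has no internal stop codon."""
    seq = ref_store.fetch(model.chrom, model.start, model.end)
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in STOP_CODONS:
            raise ValueError(
                f"{model.name}: internal stop codon at offset {i}")


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"{m.chrom}\tspvtools\tCDS\t{m.start}\t{m.end}\t.\t"
                     f"{m.strand}\t0\tID={m.name}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    models = []
    for feat in db.features_of_type("CDS"):
        name = feat.attributes.get("ID", [feat.id])[0]
        models.append(GeneModel(name=name, chrom=feat.seqid,
                                start=feat.start, end=feat.end,
                                strand=feat.strand))
    models.sort(key=lambda m: (m.chrom, m.start))
    return models


# ---------------------------------------------------------------------------
# gene placement on a simulated chromosome
# ---------------------------------------------------------------------------

def place_gene_models(pool, n_genes: int, cds_length: int,
                      seed: int = 0) -> list[GeneModel]:
    """Place non-overlapping forward-strand single-exon ORFs on a pool.

    The pool's reference sequence is edited in place to remove stop codons
    inside each chosen CDS (third codon base set to C, which de-stops all
    three stop codons); candidates whose edits would touch a SNP panel
    position are skipped so panel alleles stay intact.
    """
    if cds_length % 3 != 0:
        raise ValueError("cds_length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    seq = bytearray(pool.ref_sequence, "ascii")
    panel = set(int(p) for p in pool.snp_positions)
    occupied: list[tuple[int, int]] = []
    models: list[GeneModel] = []
    tries = 0
    while len(models) < n_genes and tries < 50 * n_genes:
        tries += 1
        start = int(rng.integers(2, pool.chrom_length - cds_length))
        end = start + cds_length - 1
        if any(s <= end and start <= e for s, e in occupied):
            continue
        edits = []
        ok = True
        for off in range(0, cds_length, 3):
            codon = seq[start - 1 + off:start + 2 + off].decode("ascii")
            if codon in STOP_CODONS:
                edit_pos = start + off + 2      # third base, 1-based
                if edit_pos in panel:
                    ok = False
                    break
                edits.append(edit_pos)
        if not ok:
            continue
        for p in edits:
            seq[p - 1] = ord("C")
        occupied.append((start, end))
        models.append(GeneModel(name=f"gene{len(models):03d}",
                                chrom=pool.chrom, start=start, end=end))
    if len(models) < n_genes:
        logger.warning("placed only %d of %d requested genes", len(models),
                       n_genes)
    pool.ref_sequence = seq.decode("ascii")
    models.sort(key=lambda m: m.start)
    return models


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

def _covering_model(models: Sequence[GeneModel], chrom: str,
                    pos: int) -> GeneModel | None:
    for m in models:
        if m.chrom == chrom and m.start <= pos <= m.end:
            return m
    return None


def classify_consequence(chrom: str, pos: int, derived: str,
                         gene_models: Sequence[GeneModel],
                         ref_store: ReferenceStore) -> str:
    """Standard-codon-table consequence of a single-base substitution.

    Returns one of synonymous / missense / nonsense / noncoding. Stop-gain
    is nonsense; stop-loss is protein-altering and counted as missense.
    """
    model = _covering_model(gene_models, chrom, pos)
    if model is None:
        return "noncoding"
    codon_idx = (pos - model.start) // 3
    codon_start = model.start + 3 * codon_idx
    codon = ref_store.fetch(chrom, codon_start, codon_start + 2)
    offset = pos - codon_start
    new_codon = codon[:offset] + derived + codon[offset + 1:]
    aa_old = _CODON_TO_AA[codon]
    aa_new = _CODON_TO_AA[new_codon]
    if aa_new == aa_old:
        return "synonymous"
    if aa_new == "*":
        return "nonsense"
    return "missense"


def null_consequence_fractions(gene_models: Sequence[GeneModel],
                               ref_store: ReferenceStore
                               ) -> dict[str, float]:
    """Consequence fractions under uniform mutation over all CDS sites.

    All nine single-base changes at every coding position are enumerated;
    the returned synonymous/missense/nonsense fractions sum to one.
    """
    counts = {c: 0 for c in CONSEQUENCES}
    for m in gene_models:
        seq = ref_store.fetch(m.chrom, m.start, m.end)
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            aa_old = _CODON_TO_AA[codon]
            for off in range(3):
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    new = codon[:off] + b + codon[off + 1:]
                    aa_new = _CODON_TO_AA[new]
                    if aa_new == aa_old:
                        counts["synonymous"] += 1
                    elif aa_new == "*":
                        counts["nonsense"] += 1
                    else:
                        counts["missense"] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no coding sites in the supplied gene models")
    return {c: n / total for c, n in counts.items()}


def consequence_table(variants, gene_models, ref_store,
                      label: str) -> dict[str, int]:
    """Count consequences for an iterable of (chrom, pos, derived)."""
    counts = {c: 0 for c in CONSEQUENCES}
    for chrom, pos, derived in variants:
        cons = classify_consequence(chrom, pos, derived, gene_models,
                                    ref_store)
        if cons != "noncoding":
            counts[cons] += 1
    logger.info("%s: %s", label, counts)
    return counts


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def g_test(table) -> tuple[float, int, float]:
    """Likelihood-ratio G-test of independence for an r x c count table.

    G = 2 * sum O ln(O/E) with expectations from the row/column margins,
    0*ln(0) taken as 0; df = (r-1)(c-1); p is the upper chi-square tail.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    n = obs.sum()
    if n == 0:
        raise ValueError("empty table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    g = float(2.0 * terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return g, df, float(stats.chi2.sf(g, df))


def bootstrap_fraction_ci(n_total: int, class_counts: Sequence[int],
                          n_reps: int = 1000, level: float = 0.95,
                          seed: int = 0) -> list[tuple[float, float]]:
    """Percentile bootstrap CIs for class percentages.

    ``n_total`` labelled variants are resampled with replacement ``n_reps``
    times; for each class the (1-level)/2 and 1-(1-level)/2 percentiles of
    its resampled percentage are returned.
    """
    counts = np.asarray(class_counts, dtype=int)
    if counts.sum() != n_total:
        raise ValueError("class counts must sum to n_total")
    if n_total == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    probs = counts / n_total
    draws = rng.multinomial(n_total, probs, size=n_reps)
    pct = draws / n_total * 100.0
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(pct, 100 * alpha, axis=0)
    hi = np.percentile(pct, 100 * (1 - alpha), axis=0)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


@dataclass
class CDFComparison:
    cdf: pd.DataFrame           # grid x group empirical CDFs
    ks_statistic: float
    p_value: float


def conservation_cdf_compare(spv_scores, common_scores,
                             genome_scores=None,
                             grid: np.ndarray | None = None
                             ) -> CDFComparison:
    """Compare conservation-score distributions of private vs common sites.

    A two-sample Kolmogorov-Smirnov test (asymptotic p) contrasts the SPV
    and common-variant score distributions; empirical CDFs are evaluated on
    a fixed score grid for tabular output, optionally including the
    genome-wide background. Scores must already be restricted to
    non-repeat-masked sites by the caller.
    """
    spv = np.asarray(spv_scores, dtype=float)
    common = np.asarray(common_scores, dtype=float)
    for name, arr in (("spv", spv), ("common", common)):
        if len(arr) == 0:
            raise ValueError(f"{name} score sample is empty")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError(f"{name} scores outside [0,1]")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    res = stats.ks_2samp(spv, common, method="asymp")
    data = {"score": grid,
            "spv": [(spv <= g).mean() for g in grid],
            "common": [(common <= g).mean() for g in grid]}
    if genome_scores is not None:
        genome = np.asarray(genome_scores, dtype=float)
        data["genome"] = [(genome <= g).mean() for g in grid]
    return CDFComparison(cdf=pd.DataFrame(data),
                         ks_statistic=float(res.statistic),
                         p_value=float(res.pvalue))
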