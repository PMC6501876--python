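"""Readers, writers and shared coordinate conventions.

Coordinates follow the usual conventions of each format: VCF and FASTA
positions are 1-based inclusive, BED intervals are 0-based half-open.
:func:`pos_to_interval` / :func:`interval_to_pos` convert between the two and
are inverses of each other.

Genotype data are held in a :class:`GenotypeMatrix`, a dense sites × strains
container of biallelic SNP calls plus the per-call quality annotations the
strain-private-variant filters consume (GQ, DP, genotype-likelihood margin,
allele depths, and DP4-style strand counts carried in a per-sample ``SB``
FORMAT field). Missing FORMAT values are stored as ``-1`` so that every
strictly-greater-than quality filter fails on them — a record that does not
report a quantity never passes a filter that depends on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

# Genotype codes used throughout the package.
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

#: sentinel for absent FORMAT values; fails every ``> threshold`` filter
MISSING_QUAL = -1

GT_NAMES = {GT_HOM_REF: "hom_ref", GT_HET: "het", GT_HOM_ALT: "hom_alt",
            GT_MISSING: "missing"}

BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base interval."""
    if pos < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos}")
    return pos - 1, pos


def interval_to_pos(start: int) -> int:
    """0-based interval start -> 1-based position of its first base."""
    if start < 0:
        raise ValueError(f"0-based start must be >= 0, got {start}")
    return start + 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCall:
    """A single strain's call at one site, with its quality annotations."""

    gt: str
    gq: int = MISSING_QUAL
    dp: int = MISSING_QUAL
    pl_margin: int = MISSING_QUAL
    ad_ref: int = MISSING_QUAL
    ad_alt: int = MISSING_QUAL
    strand_counts: tuple[int, int, int, int] = (
        MISSING_QUAL, MISSING_QUAL, MISSING_QUAL, MISSING_QUAL)

    def __post_init__(self) -> None:
        if self.gt not in GT_NAMES.values():
            raise ValueError(f"unknown genotype {self.gt!r}")


@dataclass
class VariantSite:
    """One biallelic SNP with per-strain calls."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float
    per_strain: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in BASES:
                raise ValueError(f"not a single A/C/G/T base: {allele!r}")


class GenotypeMatrix:
    """Sites × strains biallelic SNP genotypes with quality annotations.

    Arrays are row-aligned: row i of every per-site array describes the same
    site. Per-call arrays have shape ``(n_sites, n_strains)``; the strand
    count array has shape ``(n_sites, n_strains, 4)`` ordered
    (ref_fwd, ref_rev, alt_fwd, alt_rev).
    """

    def __init__(self, strains: Sequence[str], chrom, pos, ref, alt, qual,
                 gt, gq=None, dp=None, pl_margin=None, ad_ref=None,
                 ad_alt=None, strand=None, filters=None):
        self.strains = list(strains)
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate sample names")
        n = len(pos)
        k = len(self.strains)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype="U1")
        self.alt = np.asarray(alt, dtype="U1")
        self.qual = np.asarray(qual, dtype=float)
        self.gt = np.asarray(gt, dtype=np.int8)

        def _fill(a, shape, dtype=np.int32):
            if a is None:
                return np.full(shape, MISSING_QUAL, dtype=dtype)
            return np.asarray(a, dtype=dtype)

        self.gq = _fill(gq, (n, k))
        self.dp = _fill(dp, (n, k))
        self.pl_margin = _fill(pl_margin, (n, k))
        self.ad_ref = _fill(ad_ref, (n, k))
        self.ad_alt = _fill(ad_alt, (n, k))
        self.strand = _fill(strand, (n, k, 4))
        # FILTER column per site; None means PASS/absent
        self.filters = (list(filters) if filters is not None
                        else [None] * n)
        if self.gt.shape != (n, k):
            raise ValueError("genotype array shape mismatch")

    # -- basic interface ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None

    def site(self, i: int) -> VariantSite:
        """Materialize row ``i`` as a :class:`VariantSite`."""
        calls = {}
        for j, s in enumerate(self.strains):
            calls[s] = GenotypeCall(
                gt=GT_NAMES[int(self.gt[i, j])],
                gq=int(self.gq[i, j]), dp=int(self.dp[i, j]),
                pl_margin=int(self.pl_margin[i, j]),
                ad_ref=int(self.ad_ref[i, j]), ad_alt=int(self.ad_alt[i, j]),
                strand_counts=tuple(int(x) for x in self.strand[i, j]))
        return VariantSite(chrom=str(self.chrom[i]), pos=int(self.pos[i]),
                           ref_allele=str(self.ref[i]),
                           alt_allele=str(self.alt[i]),
                           qual=float(self.qual[i]), per_strain=calls)

    def take(self, idx) -> "GenotypeMatrix":
        """Row subset (site selection), preserving strain order."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.strains, self.chrom[idx], self.pos[idx], self.ref[idx],
            self.alt[idx], self.qual[idx], self.gt[idx], self.gq[idx],
            self.dp[idx], self.pl_margin[idx], self.ad_ref[idx],
            self.ad_alt[idx], self.strand[idx],
            [self.filters[int(i)] for i in idx])

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(str(c), int(p)): i
                for i, (c, p) in enumerate(zip(self.chrom, self.pos))}

    def alt_dosage(self) -> np.ndarray:
        """Per-call alt-allele dosage in [0, 2]; NaN where missing."""
        d = self.gt.astype(float)
        d[self.gt == GT_MISSING] = np.nan
        return d

    def __eq__(self, other) -> bool:  # used by round-trip tests
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.strains == other.strains
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.ref, other.ref)
                and np.array_equal(self.alt, other.alt)
                and np.allclose(self.qual, other.qual)
                and np.array_equal(self.gt, other.gt)
                and np.array_equal(self.gq, other.gq)
                and np.array_equal(self.dp, other.dp)
                and np.array_equal(self.pl_margin, other.pl_margin)
                and np.array_equal(self.ad_ref, other.ad_ref)
                and np.array_equal(self.ad_alt, other.ad_alt)
                and np.array_equal(self.strand, other.strand))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _pl_margin_from_pl(pl, gt_code: int) -> int:
    """Difference between the second-best and best phred genotype likelihood."""
    vals = sorted(v for v in pl if v is not None)
    if len(vals) < 2:
        return MISSING_QUAL
    return int(vals[1] - vals[0])


def read_genotypes(vcf_path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; the number of excluded records
    is logged. Missing FORMAT fields become sentinel values that fail any
    quality filter depending on them.
    """
    vcf_path = str(vcf_path)
    try:
        vf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    samples = list(vf.header.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample names in {vcf_path}")

    chrom, pos, ref, alt, qual, filters = [], [], [], [], [], []
    gt_rows, gq_rows, dp_rows, pl_rows, adr_rows, ada_rows, sb_rows = (
        [], [], [], [], [], [], [])
    n_excluded = 0
    for lineno, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        if (len(alts) != 1 or rec.ref is None or len(rec.ref) != 1
                or len(alts[0]) != 1 or rec.ref.upper() not in BASES
                or alts[0].upper() not in BASES):
            n_excluded += 1
            continue
        chrom.append(rec.chrom)
        pos.append(rec.pos)
        ref.append(rec.ref.upper())
        alt.append(alts[0].upper())
        qual.append(rec.qual if rec.qual is not None else MISSING_QUAL)
        flt = list(rec.filter.keys())
        filters.append(";".join(flt) if flt else None)
        gt_r, gq_r, dp_r, pl_r, adr_r, ada_r, sb_r = [], [], [], [], [], [], []
        for s in samples:
            call = rec.samples[s]
            alleles = call.get("GT", (None, None))
            if alleles is None or any(a is None for a in alleles):
                gt_r.append(GT_MISSING)
            else:
                dose = sum(alleles)
                gt_r.append({0: GT_HOM_REF, 1: GT_HET, 2: GT_HOM_ALT}[dose])
            gq = call.get("GQ")
            gq_r.append(gq if gq is not None else MISSING_QUAL)
            dp = call.get("DP")
            dp_r.append(dp if dp is not None else MISSING_QUAL)
            pl = call.get("PL")
            pl_r.append(_pl_margin_from_pl(pl, gt_r[-1])
                        if pl is not None else MISSING_QUAL)
            ad = call.get("AD")
            if ad is not None and len(ad) == 2 and None not in ad:
                adr_r.append(ad[0])
                ada_r.append(ad[1])
            else:
                adr_r.append(MISSING_QUAL)
                ada_r.append(MISSING_QUAL)
            sb = call.get("SB")
            if sb is not None and len(sb) == 4 and None not in sb:
                sb_r.append(list(sb))
            else:
                sb_r.append([MISSING_QUAL] * 4)
        gt_rows.append(gt_r)
        gq_rows.append(gq_r)
        dp_rows.append(dp_r)
        pl_rows.append(pl_r)
        adr_rows.append(adr_r)
        ada_rows.append(ada_r)
        sb_rows.append(sb_r)
    vf.close()
    if n_excluded:
        logger.info("%s: excluded %d non-biallelic-SNP records",
                    vcf_path, n_excluded)
    n = len(pos)
    if n == 0:
        return GenotypeMatrix(samples, [], [], [], [], [],
                              np.zeros((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(samples, chrom, pos, ref, alt, qual,
                          gt_rows, gq_rows, dp_rows, pl_rows,
                          adr_rows, ada_rows, sb_rows, filters)


def write_genotypes(matrix: GenotypeMatrix, vcf_path: str | Path,
                    contig_lengths: Mapping[str, int]) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file.

    PL is emitted as a biallelic triple reconstructed from the stored
    best-vs-second-best margin; read_genotypes recovers the margin exactly.
    """
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.filters.add("Het", None, None, "Heterozygous call flag")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("PL", "G", "Integer", "Phred genotype likelihoods")
    header.formats.add("AD", "R", "Integer", "Allele depths")
    header.formats.add("SB", 4, "Integer",
                       "Strand counts: ref_fwd,ref_rev,alt_fwd,alt_rev")
    for s in matrix.strains:
        header.add_sample(s)
    gt_alleles = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1),
                  GT_MISSING: (None, None)}
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for i in range(matrix.n_sites):
            rec = out.new_record(
                contig=str(matrix.chrom[i]), start=int(matrix.pos[i]) - 1,
                alleles=(str(matrix.ref[i]), str(matrix.alt[i])),
                qual=float(matrix.qual[i]))
            flt = matrix.filters[i]
            if flt:
                for name in flt.split(";"):
                    rec.filter.add(name)
            for j, s in enumerate(matrix.strains):
                call = rec.samples[s]
                code = int(matrix.gt[i, j])
                call["GT"] = gt_alleles[code]
                if matrix.gq[i, j] != MISSING_QUAL:
                    call["GQ"] = int(matrix.gq[i, j])
                if matrix.dp[i, j] != MISSING_QUAL:
                    call["DP"] = int(matrix.dp[i, j])
                m = int(matrix.pl_margin[i, j])
                if m != MISSING_QUAL:
                    # best genotype at 0, runner-up at the stored margin
                    pls = {GT_HOM_REF: (0, m, 2 * m), GT_HET: (m, 0, m),
                           GT_HOM_ALT: (2 * m, m, 0),
                           GT_MISSING: (0, m, 2 * m)}[code]
                    call["PL"] = pls
                if matrix.ad_ref[i, j] != MISSING_QUAL:
                    call["AD"] = (int(matrix.ad_ref[i, j]),
                                  int(matrix.ad_alt[i, j]))
                if matrix.strand[i, j, 0] != MISSING_QUAL:
                    call["SB"] = tuple(int(x) for x in matrix.strand[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# interval tracks (BED)
# ---------------------------------------------------------------------------

class IntervalTrack:
    """Normalized, merged genomic intervals with point-membership queries."""

    def __init__(self, name: str,
                 intervals: Iterable[tuple[str, int, int]] = ()):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)
        self.normalize()

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(
                f"BED interval must have start < end, got {start} >= {end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def normalize(self) -> None:
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    def point_in_track(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        start, _ = pos_to_interval(pos)
        return tree.overlaps_point(start) or bool(tree.at(start))

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals())

    def __len__(self) -> int:
        return len(self.intervals())


def read_interval_track(bed_path: str | Path, name: str | None = None
                        ) -> IntervalTrack:
    """Read a 3+-column BED file into a normalized :class:`IntervalTrack`."""
    track = IntervalTrack(name or Path(bed_path).stem)
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{bed_path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            try:
                track.add(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: {exc}") from exc
    track.normalize()
    return track


def write_interval_track(track: IntervalTrack, bed_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for chrom, start, end in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# reference sequence store (FASTA)
# ---------------------------------------------------------------------------

class ReferenceStore:
    """In-memory reference sequences with 1-based inclusive fetch."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper()
                      for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceStore":
        seqs = {rec.id: str(rec.seq)
                for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in FASTA {path}")
        return cls(seqs)

    def contigs(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], both 1-based inclusive."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown contig {chrom!r}")
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"range {start}-{end} outside contig {chrom} "
                f"(length {len(seq)})")
        return seq[start - 1:end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


def read_fasta(path: str | Path) -> ReferenceStore:
    return ReferenceStore.from_fasta(path)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

SPV_COLUMNS = ["strain", "chrom", "pos", "ancestral", "derived",
               "folded_class", "trinucleotide_context", "zygosity",
               "cpg_flag"]


def write_spv_table(spvs, path: str | Path) -> None:
    """Write SPV records as a tab-delimited table (one row per variant)."""
    rows = [{"strain": r.strain, "chrom": r.chrom, "pos": r.pos,
             "ancestral": r.ancestral, "derived": r.derived,
             "folded_class": r.folded_class,
             "trinucleotide_context": r.trinucleotide_context,
             "zygosity": r.zygosity, "cpg_flag": r.cpg_flag}
            for r in spvs]
    pd.DataFrame(rows, columns=SPV_COLUMNS).to_csv(path, sep="\t",
                                                   index=False)


def read_spv_table(path: str | Path):
    from .calling import SPVRecord  # local import to avoid a cycle
    df = pd.read_csv(path, sep="\t",
                     dtype={"chrom": str, "ancestral": str, "derived": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(SPVRecord(
            strain=row.strain, chrom=row.chrom, pos=int(row.pos),
            ancestral=row.ancestral, derived=row.derived,
            zygosity=row.zygosity,
            trinucleotide_context=row.trinucleotide_context,
            folded_class=row.folded_class, cpg_flag=bool(row.cpg_flag)))
    return records


def read_trait_table(path: str | Path,
                     known_strains: Sequence[str] | None = None
                     ) -> pd.DataFrame:
    """Read a long-format trait table: strain, trait, value (replicates).

    Strains absent from ``known_strains`` are retained with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trait table must have columns {sorted(required)}")
    if known_strains is not None:
        extra = sorted(set(df["strain"]) - set(known_strains))
        if extra:
            logger.warning("trait table strains absent from genotype "
                           "matrix: %s", ", ".join(extra))
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


class ScoreTrack:
    """Per-base conservation scores in [0, 1] keyed by (chrom, pos)."""

    def __init__(self, scores: Mapping[tuple[str, int], float]):
        for (chrom, pos), s in scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"score at {chrom}:{pos} outside [0,1]: {s}")
        self._scores = dict(scores)

    def get(self, chrom: str, pos: int) -> float | None:
        return self._scores.get((chrom, pos))

    def items(self):
        return self._scores.items()

    def values(self) -> np.ndarray:
        return np.array(list(self._scores.values()), dtype=float)

    def __len__(self) -> int:
        return len(self._scores)


def read_score_track(path: str | Path) -> ScoreTrack:
    """Read a 3-column (chrom, pos, score) per-base score table."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "score"], dtype={"chrom": str})
    return ScoreTrack({(r.chrom, int(r.pos)): float(r.score)
                       for r in df.itertuples(index=False)})


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), score in sorted(track.items()):
            fh.write(f"{chrom}\t{pos}\t{score:.6g}\n")
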