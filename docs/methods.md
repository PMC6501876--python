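# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `spvtools`, and what the synthetic fixtures do and do
not establish about real data.

## Identity-by-descent detection

Inbred strains are homozygous essentially everywhere, so pairwise IBD
reduces to long runs of identical homozygous genotypes. The detector scans
a SNP panel per strain pair and reports maximal runs whose spanned length
(first to last panel SNP, 1-based inclusive) is at least `min_seed_bp`
(default 200 kb). A mismatch budget is supported via a maximal-window scan
over discordance positions; the default budget of 0 makes a single
discordant site terminate a run. Correctness is defined by equivalence
with a naive per-site scanning oracle, which the test suite enforces on
hundreds of random panels; the fast vectorized scan is an implementation
detail.

Conventions chosen where behaviour was genuinely open:

* **Missing genotypes terminate runs.** Treating absence of evidence as
  evidence of identity would let low-quality regions stitch spurious
  segments together.
* **Heterozygous calls terminate runs.** In nominally inbred genomes a
  heterozygote indicates residual heterozygosity or error, not shared
  descent.
* **Segment coordinates snap to the outermost matching panel SNPs.** No
  extension into flanking SNP-free sequence, so segment lengths are
  reproducible from the panel alone. Boundary error relative to the true
  ancestry switch-point is therefore at most one inter-SNP gap.
* **Run identity for the wild-outgroup diagnostic** (`longest_pairwise_run`)
  counts heterozygote-heterozygote agreement as identity, since wild
  samples are outbred and the question is whether any two genomes share a
  long haplotype at all.

### The IBD panel and private alleles

The panel keeps sites with minor allele frequency strictly above
`maf_min = 0.05` (the implicit all-homozygous-reference sample contributed
by the reference strain counts toward frequencies by default) **and**
whose minor allele is observed in at least `min_minor_strains = 2`
strains. The second condition is the sample-size-invariant core of the
frequency cutoff: at the 29-strain scale of real panels, MAF > 0.05
already excludes every private allele (1/29 ≈ 0.034), and that exclusion
is load-bearing — it is what lets a private variant sit *inside* an IBD
segment rather than splitting it at its own position. A bare MAF cutoff
loses this property for panels of fewer than ~21 strains, so the
shared-variation requirement is stated explicitly rather than left as an
accident of sample size.

Only segments ≥ 5 Mb are retained for mutation analyses. The rationale is
empirical: wild mouse populations show no IBD runs of that length, so a
≥ 5 Mb identical run between two laboratory strains can only reflect
descent from a single founder, and a variant private to one strain inside
such a run must postdate the strains' divergence.

## The SPV filter stack

Candidates are singletons: sites where exactly one strain carries the
alternative allele (heterozygous or homozygous) and all other non-missing
strains are homozygous reference. Eleven rules are applied in a fixed
order (a–k in the module docstring) so that the audit's attribution of
"first failing rule" is deterministic; the survivor set itself is
order-independent. Decisions worth recording:

* **Mean sample depth** for the DP upper bound (1.9× mean) is the mean of
  non-missing per-call DP over all processed sites for that sample,
  computed in a first pass.
* **Missing-data fraction** (< 0.15) is computed over all strains
  including the focal one.
* **Allele balance** is `min(ad_ref, ad_alt) / (ad_ref + ad_alt)`; the
  rarer allele must exceed 30% of reads, the standard heterozygote QC
  reading.
* **The bias test** for heterozygotes is a goodness-of-fit chi-square on
  the four strand counts (ref_fwd, ref_rev, alt_fwd, alt_rev) against
  expectations built from a 50/50 allele fraction and the observed overall
  forward/reverse ratio, referred to a chi-square with 3 degrees of
  freedom; cells with zero expectation are skipped, and an all-zero count
  vector is an error. Strand counts travel in a per-sample `SB` FORMAT
  field (GATK-style ordering).
* **Missing FORMAT fields fail the dependent rule** rather than passing
  silently: sentinels of −1 lose every strictly-greater-than comparison.
* **A `Het` FILTER flag is ignored** (heterozygous singletons are exactly
  the records such a flag marks); any other FILTER name excludes the
  candidate before the rule stack and is counted separately in the audit.
* **IBD residence** requires only that the position fall inside a retained
  segment of the focal strain; no further condition is placed on the
  partner strain's genotype at the site.
* The audit conserves candidates exactly: every candidate is a survivor,
  a first-failure of exactly one rule, or a FILTER-excluded record.

Polarization assigns the shared (major) allele as ancestral and the
private allele as derived; for singletons passing the stack the ancestral
allele always equals the reference base, so the reference trinucleotide
context is centred on the ancestral state. Folding maps purine-ancestral
events through the reverse complement; a C>T event is CpG-flagged when the
base 3′ of the pyrimidine-strand C is G (equivalently, for folded events,
when the reference base 5′ of the ancestral G is C).

## Spectrum standardization

For class *i* with count *nᵢ* and opportunity *oᵢ*,

    rate_i = n_i / o_i,    frequency_i = rate_i / Σ_j rate_j.

Opportunities are the C+G (for C-rooted classes) or A+T (for T-rooted)
base counts over the union of the strain's retained IBD intervals,
measured on the reference sequence — private variants are ~10⁻⁴ of
interval length, so using the strain's own alleles would change the counts
negligibly. With the CpG split, the C>T opportunity divides into bases
lying in a CpG dinucleotide on either strand (pairs straddling interval
edges included) versus all other C/G bases. A class with zero opportunity
and zero count gets frequency 0; zero opportunity with a nonzero count is
contradictory and raises. Heterozygous and fixed variants contribute one
event each: either way the parsimonious history is a single mutation.
Unstandardized proportions are emitted alongside for comparability with
de novo mutation datasets.

## Statistics

* **G-test**: `G = 2 Σ O ln(O/E)` with margins-based expectations,
  `0·ln 0 := 0`, df `(r−1)(c−1)`, upper chi-square tail. The test suite
  cross-checks against an independent likelihood-ratio implementation.
* **Bootstrap CIs**: percentile method on 1,000 multinomial resamples of
  the labelled variants (equivalent to resampling individuals with
  replacement); no bias correction or acceleration — the simplest method
  consistent with a percentile interval, and it reproduces published
  intervals within Monte-Carlo error.
* **Uniform-mutation null**: exhaustive enumeration of all nine single-base
  changes at every CDS position of the supplied gene models; the null is
  computed from the models actually provided, never assumed.
* **Consequence classes**: stop-gain is nonsense; stop-loss is
  protein-altering and counted as missense (a three-way classification
  forces the choice).
* **KS comparison** of conservation-score CDFs uses the asymptotic
  two-sample p-value; callers must pre-restrict scores to
  non-repeat-masked sites.
* **PCA** follows the R `prcomp(scale.=TRUE)` convention: columns
  zero-centred and divided by their sample standard deviation (ddof 1),
  components from the SVD of the scaled matrix, variance fractions from
  squared singular values. Zero-variance columns are dropped with a
  warning (scaling undefined). Sign convention: the largest-magnitude
  loading of each component is positive. Default input is the 6-class
  frequencies; the 7-class CpG-split table is accepted the same way.
* **Pairwise spectrum tests** run on raw integer counts (a likelihood-ratio
  test needs observations, not normalized frequencies) with df = 5 and no
  multiple-testing correction, and report the significant-pair fraction.
* **Trait correlations**: per-strain replicate means, Spearman rho with
  average ranks and the t approximation for p; a trait or predictor
  constant across strains yields an undefined correlation reported as
  missing. One-way ANOVA treats strain as the single factor and refuses a
  zero-total-variance input.

## The synthetic generator

The generator emulates the statistical structure the analysis relies on,
not mouse biology in detail:

* **Founder pool** — `n_founders = 8` haplotypes (within the "fewer than
  ten" regime) over a single 60 Mb chromosome; SNP density 5×10⁻⁴/bp
  (one panel SNP per ~2 kb); every site polymorphic among founders.
* **Strain mosaics** — `n_strains = 12`; block lengths exponential with
  mean 10 Mb and uniform founder choice, giving each strain pair
  same-founder runs long enough that multiple ≥ 5 Mb IBD segments exist at
  this chromosome size. The exponential renewal process is a modelling
  convenience: nothing is claimed about the true block-length distribution
  of laboratory strains.
* **Planted mutations** — 300 per strain by default, class drawn from a
  configurable folded spectrum (default transition-dominated with C>T =
  0.50), position uniform over bases whose reference state permits the
  class, excluding panel SNPs and previously used positions — so planted
  alleles are private and non-recurrent by construction. Heterozygous
  fraction 0.083, matching the fixed/heterozygous split expected of
  variants drifting through inbreeding colonies.
* **Base composition** — GC content 0.5 by default, which makes the C- and
  T-rooted opportunities equal, so planted class probabilities and
  standardized frequencies coincide and spectrum recovery is a clean test
  of the counting/standardization chain. Real mouse sequence (~0.42 GC,
  CpG depletion, isochores) is deliberately not emulated.
* **Quality fields** — passing records carry QUAL 200, GQ 99, DP 40,
  likelihood margin 100 and balanced strand counts; the corruption option
  plants one extra record per named filter rule with exactly one field
  pushed to just beyond its threshold (e.g. GQ = 60 against a strict
  GQ > 60), enabling per-rule audits against a hand-applied oracle.
* **Wild outgroup** — 27 samples, genotypes drawn independently per site
  from jittered founder allele frequencies plus low-frequency
  wild-private sites; per-site independence guarantees no multi-megabase
  identical runs, reproducing the empirical contrast with laboratory
  strains.
* **Wild-derived panel** — one inbred genome per founder haplotype. Since
  laboratory diversity is a subset of founder diversity, a panel carrying
  every founder haplotype makes the ancestral-variant filter exact: every
  ancestral singleton is recognized and removed deterministically. Real
  wild-derived panels are an incomplete sample of ancestry, so real-data
  precision depends on outgroup completeness in a way these fixtures do
  not probe.
* **Gene models** — non-overlapping forward-strand single-exon ORFs
  (150 × 999 bp by default); internal stop codons are removed by editing
  the third codon base to C, skipping any candidate whose edit would touch
  a panel SNP. This keeps the codon annotator exact without splice
  handling.
* **Traits** — per-strain replicate breeding measurements (dam age at
  first litter ~90 ± 12 d between strains, ±6 d within; interbirth
  interval ~35 ± 6 d, ±3 d) with an optional planted linear dependence of
  a trait mean on one spectrum class, used by the correlation-recovery
  tests.

Everything is reproducible from one integer seed via spawned child seeds.

### What passing tests do and do not show

On these fixtures the pipeline achieves precision and recall 1.0 for
planted mutations within retained-IBD, unmasked territory, and recovers
planted spectra to total-variation distance < 0.05 at 2,000 mutations per
strain. That validates the logic of every stage — panel construction,
detection, the filter stack, polarization, context handling,
standardization — under the structural assumptions stated above. It does
not bound real-data error rates, which additionally depend on sequencing
artefacts, incomplete outgroups, recurrent mutation at hypermutable sites
and reference bias, none of which the generator models.

## Problem sizes

The standard fixture is one 60 Mb chromosome with 12 strains (~33,600
sites); the whole simulation-plus-pipeline run takes on the order of ten
seconds, and the statistical calibrations use 1,000–2,000 replicates —
sizes chosen so the full validation suite runs comfortably on a laptop
while leaving every threshold at its study value (200 kb seed, 5 Mb
retention, MAF 0.05, the full filter thresholds). A strain with no ≥ 5 Mb
IBD territory has no defined spectrum (its opportunities are empty); at
very small strain counts such strains can occur, which is why
spectrum-level validations run at the standard 12-strain scale.

## Known limitations

* Autosomal, biallelic SNPs only; no indels, no X/Y handling.
* IBD detection assumes homozygous-dominant genomes; no phasing or
  probabilistic IBD model, and no genetic-map distances.
* Gene models are single-exon and forward-strand; splice, UTR and
  regulatory consequences are out of scope.
* The 96-context spectrum is not aggregated (contexts are recorded per
  variant but summarized at 6/7 classes).
* Exact small-sample KS p-values are not computed.
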