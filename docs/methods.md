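# Methods

## Coordinate system and reference

All coordinates are 1-based inclusive rCRS positions (the field's `m.`
notation) on the 16,569 bp circular molecule; BED inputs (0-based
half-open) are converted on read, and the D-loop interval (m.16024–m.576)
is handled by wrap-aware interval arithmetic.  The locus map bundles the
standard NC_012920 gene coordinates: 13 protein-coding genes (MTND6 on the
light strand), 22 tRNAs, 2 rRNAs and the D-loop.  Positions inside the
MTATP8/MTATP6 and MTND4L/MTND4 overlaps belong to both genes and contribute
once to *each* gene's stratum in burden tables — per-gene tests are then
self-consistent, at the cost of locus-stratified counts summing to slightly
more than the coding total.

The bundled *sequence* is a synthetic stand-in (`rcrs_synthetic.fa`, seeded
build in `mthet/_refbuild.py`): pseudo-random bases with mtDNA-like
composition, poly-C runs in the masked homopolymer tracts, ATG starts and
stop-free internal codons in each gene's own frame (codons shared with a
previously laid overlapping gene are left as laid, as in the real molecule
where MTATP8's stop sits inside MTATP6).  Everything coordinate-level —
overlaps, wrap, frames, incomplete stops — therefore behaves exactly as on
the real reference, while base-level identities are synthetic; analyses of
real data should supply the genuine rCRS FASTA
(`load_locus_map(fasta=...)`).

## Consequence annotation

Codons are reconstructed from the reference in the locus's own frame;
light-strand loci are translated from the reverse complement; genes ending
in 1–2 nt incomplete stop codons are completed with A's (mirroring
post-transcriptional polyadenylation).  Translation uses NCBI table 2
(vertebrate mitochondrial: TGA=Trp; AGA/AGG are stops) via Biopython's
codon tables.  A change is nonsynonymous iff the encoded amino acid
changes; substitutions are transitions iff both alleles share the
purine/pyrimidine class.  Changes to or from a stop codon are treated as
nonsynonymous with maximal surrogate severity.

## Calling model and thresholds

The caller operates on strand-split per-site allele counts that have
already passed per-read base-quality (≥ 30) and mapping-quality (≥ 20)
filters upstream — read-level quality is deliberately out of scope.  A
non-reference base is called when depth ≥ 1500×, supporting reads ≥ 10 and
VAF ≥ 1% (all inclusive: the "call at exactly 1.0%" convention keeps
boundary behaviour total); heteroplasmic means VAF in [1%, 99%),
homoplasmic ≥ 99%.  Zero depth raises a distinct no-coverage signal so
absence of data is never read as absence of variation.

The strand-bias filter rejects a call only when the two-sided Fisher exact
test on the ref/alt × fwd/rev table gives p < α **and** the alt allele's
strand skew exceeds a limit (defaults α = 0.05, skew 0.90).  The skew guard
exists because at mtDNA depths (thousands of reads) trivially small strand
imbalances are statistically significant; the published parameters of the
original callers' bias filters are not stated, so these defaults are
declared surrogates.  A `concordance_hook` intersects two call sets for
tandem-caller workflows; a second caller's quality model is not
re-implemented.

## Sample and pair QC

A sample passes coverage QC when ≥ 99% of the 16,569 positions have
depth ≥ 1500×.  Haplogroups are assigned from a small bundled
macro-haplogroup marker panel (H as root plus V, U, K, J, T, W, X, I) by
the fraction of defining homoplasmic variants present, ties broken toward
the larger defining set (most derived) then lexicographically; a sample
matching no marker is root-labelled.  This is sufficient for its only use
here — checking that the two tissues of one individual agree — and is not
a fine-clade classifier.  Pair QC applies haplogroup concordance first,
then coverage; a pair failing both is ledgered once under discordance, and
retained + excluded always equals input.  The panel's marker *positions*
follow standard macro-haplogroup motifs; the alt alleles are defined
relative to the bundled synthetic sequence and are regenerated for a real
panel in real-data use.

## Burden statistics

Burdens are per-sample counts of qualifying calls within a stratum (a
locus, a region class, or "total"), with variants in masked low-complexity
tracts (defaults m.302–316, m.513–526, m.16181–16194 — the rCRS
homopolymer runs; replaceable by BED) and strand-filtered calls excluded
throughout.  Group comparisons use the two-sided Mann–Whitney U test with
midrank ties.  For group sizes ≤ 8 the p-value is exact: U is enumerated
over all label assignments of the fixed rank vector, which remains valid
under ties where classical no-tie tables do not; the two-sided p doubles
the smaller tail (capped at 1; the permutation distribution of U is
symmetric about n₁n₂/2, so this equals the symmetric-tail rule).  Larger
groups use the tie-corrected normal approximation.  Bonferroni correction
is applied per family, the family being the set of locus strata tested
within one tissue and variant type.

Sparse high-heteroplasmy comparisons (share of coding heteroplasmies with
VAF strictly > 0.10) use Fisher's exact two-sided test — defined by
summation of hypergeometric outcomes no more probable than the observed
table — because that convention reproduces the published p-values on the
published tables.  Pearson's chi-squared (uncorrected, 1 df) is used for
the somatic per-locus distribution tests.  Ti/Tv is reported with the
transversion fraction (identically ratio = (1−f)/f); zero transversions
yield an explicit infinite-ratio signal rather than an error.

The default pathogenicity scorer is an explicit surrogate: 0 for
synonymous/noncoding changes, the Grantham (1974) physicochemical distance
of the amino-acid change rescaled by 215 to [0, 1] for nonsynonymous ones
(computed from the published composition/polarity/volume properties, not a
hard-coded matrix), 1.0 for stop gain/loss.  A user score table keyed on
(position, alt) takes precedence; missing entries fall back to the
surrogate, are skipped, or take a default, by configuration.

## Somatic taxonomy

Classes are defined on *presence of calls*: a variant called in SNpc but
not FC is de-novo, called in FC but not SNpc is a loss — so a variant at
0.9% in FC and 1.2% in SNpc is a de-novo gain, not a shift.  Variants
called in both tissues are positive/negative shifts by the sign of
Δhet = het_SNpc − het_FC when |Δhet| clears the shift band, else
unchanged; variants homoplasmic in both tissues (the germline backbone)
are excluded from shift classes, having no room to move.  The pipeline's
default band is 1 VAF point, chosen to suppress binomial sampling noise at
~2000× (noise sd of a VAF difference at 5% VAF and 5000× is ≈ 0.4 points);
the band is configurable and echoed in all outputs.  Classification is
order-independent and exactly antisymmetric under tissue swap
(de-novo ↔ loss, positive ↔ negative shift).

## Synthetic cohort generator

The generator's defaults encode the paired-cohort conditions the analysis
targets: 97 case and 23 control pairs; negative-binomial depth
(mean 5000×, dispersion 8, floored at 1500×); a germline backbone per
individual (haplogroup from European-like frequencies, its panel markers
homoplasmic at VAF 0.999, plus Poisson(8) private homoplasmies); FC
heteroplasmy counts Poisson(7) in cases vs Poisson(5) in controls with
Beta(1.3, 30) VAFs truncated to [0.03, 0.90] (~85% of draws below 10%);
case variants placed with 3× weight in MTCO1/MTCO2/MTCYB, giving the
case-specific nonsynonymous enrichment in those genes; transitions drawn
with 9:1 odds; FC→SNpc retention probability 0.75 (failures are losses);
retained variants unchanged with probability 0.40 or shifted by
|Δ| = 0.05 + Exp(0.05) with positive sign probability 0.28; de-novo SNpc
gains Poisson(6) in cases vs Poisson(3) in controls; per-base sequencing
error 10⁻³.  Read evidence is binomial at the effective allele fraction
with a 50:50 strand split; depth and read draws come from per-sample child
seeds so allele-count tables are regenerated lazily and byte-identically.

Two margins are deliberate: true VAFs never fall below 3% (versus the 1%
calling threshold) and true shift deltas are exactly 0 or ≥ 5 VAF points.
At the default depth these margins are ≥ 4 standard deviations of binomial
VAF noise away from the calling threshold and from a classification band
of 2.5 points, so at zero sequencing error the caller and a classifier
using that band recover the generated truth labels exactly — making
recovery assertable as equality rather than approximately.  Recovery
analyses therefore use `min_shift_delta = 0.025`; the pipeline's 1-point
default remains the real-data choice, where no such margins exist.  This
is also the honest statement of what passing recovery tests shows: the
machinery is correct under the generative model; boundary-straddling
variants in real data will still be subject to sampling noise.

The generator does not model amplicon structure (a twofold-depth overlap
mask is available but off by default), PCR chimeras, index hopping,
contamination, or read-level errors correlated along molecules, and its
haplogroup backbone is a marker panel rather than a full phylogeny.

Deterministic bookkeeping fixtures accompany the generator: a 120-pair
cohort-QC composition (8 haplogroup-discordant, 9 coverage-failed,
disjoint, split 13/4 between cases and controls so that 84 cases and 19
controls remain) and an 18,114-record reference-collection composition
(458 pathogenic, 7 non-human, 7,051 non-European-marker carriers, 663
truncated, 2,206 minor-haplogroup, 7,729 clean), each record failing at
most one filter so survivor sets are order-invariant.

## Reference filter chain and codon usage

Filters apply in a fixed order — pathogenic carriers, non-human,
non-European markers, truncated (< 16,500 bp), minor haplogroups (outside
H, V, J, T, U, K, W, X, I, R, N) — each record ledgered under the first
filter it fails; input always equals survivors plus removals.  Whether the
three non-European markers (m.8701A, m.8540T, m.10873T) must all be
present or any one suffices is ambiguous in the field's usage; "any" is
the default, "all" is available.  Codon usage is reported per group as a
2×3 table (synonymous/nonsynonymous × codon position) in percent of that
group's coding variants, summing to 100; a group with zero coding variants
raises an explicit undefined-table signal.

## Numerical and testing choices

Problem sizes were chosen so the full suite runs in well under ten minutes
on one core: the exhaustive Fisher-vs-enumeration sweep covers every 2×2
table with N ≤ 60 through one canonical representative per
row/column/transpose symmetry class (the invariance itself is verified on
random tables); Mann–Whitney exactness is checked against full permutation
enumeration for every group-size pair up to 8 per group; annotation is
checked against an independent whole-gene translation oracle at every
coding position; somatic invariants run on 1,000 random pairs; recovery
runs on a 100-pair cohort.  Exact-test comparisons use absolute tolerances
of 10⁻⁸–10⁻¹² (floating summation order); Grantham spot-checks allow ±1
against the published matrix, which was rounded from the same property
tables.

## Known limitations

Indels, read-level processing (alignment, duplicates, quality), fine-clade
haplogrouping, phylogenetic placement of somatic variants and
trinucleotide mutational signatures are out of scope.  The bundled
reference sequence is synthetic: consequence annotations on it are
internally consistent and fully tested, but not biologically meaningful
until a real rCRS FASTA is supplied.  The pathogenicity surrogate ranks
amino-acid changes only; it is not a trained pathogenicity predictor.
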