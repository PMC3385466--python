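# Methods

## Problem and model

A frame-preserving insertion or deletion (indel) in a protein-coding gene is
a large jump in sequence space.  If the post-indel sequence sits on the slope
of a fitness peak rather than on its summit, a burst of positively selected
amino-acid substitutions — an adaptive walk — should follow, concentrated
near the indel and soon after it.  This package implements the comparative
machinery needed to detect and size such walks in *Drosophila* proteins, and
a generator that produces data with exactly the structure the estimators
assume, so that every estimator can be exercised against known truth.

The design is a case/control contrast on a fixed six-species topology,
(((((melanogaster, sechellia), erecta), ananassae), pseudoobscura), virilis):
an indel placed on a branch of the clade containing *D. melanogaster* (case)
is compared with the same indel placement on the sister branch (control).
Substitutions are always counted on the terminal *D. melanogaster* segment,
so only in the case could they have been triggered by the indel.

## Indel identification and polarization

Candidate indels are maximal runs of alignment columns sharing a
presence/absence vector over the six focal species.  Polarization is Dollo
parsimony constrained to a single event: both outgroups (*D. pseudoobscura*,
*D. virilis*) must agree on the ancestral state; if both carry sequence, the
gap is a deletion in the species lacking it; if both are gapped, the material
is an insertion in the species carrying it.  Exactly 12 of the 64 possible
presence vectors are explained by one event on one of the six labelled
branches (the four youngest terminals and the two internal branches below
the ananassae split); everything else — including single events on
unlabelled branches such as the (mel,sec,ere,ana) stem — is rejected.  The
test suite verifies this against an exhaustive single-event enumeration over
the tree's edges.

Filters: the exonic gap length must be a multiple of three (frameshifting
indels are only ever counted, to bound the indel-call error rate as the
ratio of coding frameshifts to non-multiple-of-three indels in short
introns); the 10 nt on each side of the gap must be gap-free and A/C/G/T in
all six species (which also rejects coincident or overlapping indels); and
the window must fit inside the alignment.  The window length is a parameter
(default 10 nt).

## Site classes

Degeneracy is assessed on the focal-species codon under the standard genetic
code.  A position is *non-degenerate* (non-synonymous class) when all three
alternative nucleotides change the amino acid, and *four-fold* (synonymous
class) when none does; everything else is excluded from both classes.  Two
deliberate conventions: positions at which a single change can create a stop
codon are excluded ("other"), and codons containing N or gaps are "other".
A site is *conservative* when the encoded amino acid is identical across the
six basal species (pseudoobscura, persimilis, willistoni, virilis,
mojavensis, grimshawi); a gap or X among the six counts as non-conservative
rather than missing — a deterministic choice that can only deflate the
conservative fraction.

Eligibility: a nucleotide site enters any count only when every column
within 10 nt of it is gap-free and A/C/G/T in all six focal species, the
focal indel's own gap columns being exempt.

## Distance bins and lineage-specific counting

Distance is measured in codons from the nearest gap-block edge (adjacent
codon = 1), out to 100 codons on each side, in ten 10-codon bins per side (20
bins per indel); codons overlapping the block are excluded everywhere.  The
edge convention (rather than midpoint) is well defined for both insertions
and deletions, including control configurations where the focal species
lacks the inserted material.

For indels younger than the mel–sec split (configurations a, a', b, b'),
divergence is counted as mel-vs-sec mismatches restricted to sites where
sechellia matches erecta, isolating melanogaster-specific changes, with
weight 1.  For older indels (c–f') every eligible site is counted; amino-acid
substitution counts are divided by two to express them per terminal lineage,
while the Dn/Ds mismatch *fractions* are used un-halved.  No multiple-hit
correction is applied at these divergences; all rates are plain fractions of
mismatching sites.  Polymorphism is counted over the same eligible site set
as divergence (including the sechellia==erecta restriction for the young
configurations), so that the MK contrast compares like with like; a site is
polymorphic only when biallelic with each allele in at least two lines, and
sites with more than half the lines missing are excluded (the missing-data
rule stated for indels, extended to SNPs for symmetry).

alpha = 1 − (Pn/Ps)/(Dn/Ds), computed from counts pooled across indel
regions (per bin or over a bin mask); it is reported as an undefined
sentinel whenever Dn, Ds or Ps is zero.  Gene-level averaging is available
by pooling per-region counts differently, but pooled counting is the
default.

## Walk length

The walk length is the per-bin difference between the mean (per indel)
amino-acid substitution count in case regions and in control regions, summed
over the 20 bins; insertions combine the (a − a') and (c − c') estimates,
deletions the (b − b') and (d − d') estimates, and the (e − f') contrast
serves as the ancient-indel null.  Confidence intervals are percentile
2.5/97.5 over 1000 bootstrap resamples of whole indel regions, case and
control resampled independently (jointly across configuration pairs for the
combined estimate).

Positional contrasts use Fisher's exact test on 2×2 tables: the nearest
10-codon bin upstream vs downstream (case vs control), and substitutions at
conservative vs non-conservative sites (case vs control).  Halved
substitution weights are summed before rounding to integers.  The odds ratio
is the sample odds ratio ad/bc; the two-sided p sums hypergeometric
probabilities of tables at most as probable as the observed one.  Distance
decay is tested by Spearman rank correlation between bin distance and the
per-bin substitution rate, with an exact permutation p-value for up to eight
pairs and the t-approximation otherwise.

## Indel polymorphism

The unfolded site-frequency spectrum of polarized polymorphic indels is
compared with the neutral infinite-sites expectation: the sojourn density
f(x) = 1/x gives expected counts proportional to 1/i at derived count i, and
a mean derived-allele frequency of ((n−1)/n)/H(n−1) — 0.1755 at n = 162.
Tajima's D is computed from the spectrum with the standard normalization; it
assumes a constant sample size, so n is taken as the modal number of called
lines, and records with more than half the lines missing are excluded.

## The generator

`synthetic_data.simulate_dataset` produces per-gene alignments of all ten
species, a truth record, and SNP/indel polymorphism tables.  Defaults are
the study conditions: 220-codon genes; branch lengths (per four-fold site)
of 0.05/0.05 for mel/sec — i.e. ~0.1 silent mel–sec divergence — 0.08 for
erecta and the (mel,sec) stem, 0.15 for ananassae, and longer outgroup
branches; baseline omega = 0.1 implemented as acceptance-thinning of
non-synonymous proposals (stops rejected); one indel per gene, uniform over
the twelve configurations, lengths mostly one codon (0.65/0.20/0.08/0.04/
0.03 for 1–5 codons); burst sizes per configuration equal to the
configuration-level excesses the analysis is meant to recover (insertions
0.33 and 0.71; deletions 2.60 and 2.17), exponentially decaying with a
25-codon scale, 70% placed upstream, with a 2× preference for conservative
sites; half of all codons conservative across the basal six; SNP
polymorphism at rate theta = 0.01 per four-fold site (theta×omega at
non-degenerate sites, so the baseline MK alpha is zero in expectation) with
derived counts proportional to 1/i in a sample of 162; and polymorphic
indels whose spectra get a singleton boost (2× insertions, 4× deletions) so
deletions segregate at lower frequencies.

Burst placement details that matter for parameter recovery: each burst event
is a non-synonymous change at a non-degenerate position of a codon at which
melanogaster, sechellia and erecta agree beforehand (so the counting rules
register exactly one new substitution), the resulting codon keeps the
position non-degenerate, events land on distinct codons, and they are placed
at least 4 codons from the gene ends so the clean-flank rule can observe
them — hence the injected burst size equals the expected countable excess.
For configurations whose indel predates the mel–sec split, the burst is
drawn independently for both terminal lineages, matching the halving rule.
Control configurations receive the same burst on their own (sister) lineage,
which the counting rules must not register.

What the generator does **not** emulate: real indel mutational spectra,
rate heterogeneity along genes, codon bias, linkage among polymorphic sites,
alignment error, and annotation noise.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to real-data pathologies.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally, 1-based inclusive in
  emitted tables.
* All randomness flows from one explicit seed through
  `numpy.random.default_rng`; identical configuration and seed give
  byte-identical JSON summaries.
* Bootstrap CIs are plain percentile intervals; with all-identical inputs
  they degenerate to a point, and fewer than two resampling units yield an
  undefined sentinel rather than an interval.
* Tajima's D returns 0 when the numerator is exactly zero but the variance
  estimate degenerates (n = 2), and a sentinel when S = 0.
* Empty bins are excluded from pooled fractions; alpha is a sentinel on any
  zero denominator.

## Problem sizes

The test suite exercises parameter recovery on datasets of 500 genes per
burst size (0, 1, 5 extra substitutions) restricted to the recent-deletion
configurations, bootstrap coverage on 500 known-truth replicates of 150
case/control regions, and the neutral-spectrum goodness of fit at 100,000
variants; the analysis scripts use a single 600-gene dataset across all
twelve configurations.  These sizes give stable estimates (bootstrap CIs a
few tenths of a substitution wide) while keeping any single script or test
run in the tens of seconds.

## Known limitations

* Degeneracy is assessed on the focal-species codon only; sites whose class
  differs between species are not reconciled.
* Polymorphism counting treats each inbred line as haploid (heterozygous
  calls are not modelled).
* Tajima's D on variable per-record sample sizes uses a single nominal n.
* The conservative-site call requires data in all six basal rows; absent
  rows make every site non-conservative rather than missing.
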