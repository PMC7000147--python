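# Methods

## Scope and model

`splicescope` works at the level of splice junctions, not reconstructed
isoforms: short-read data supports junction counts directly, while whole
transcripts must be inferred.  A junction is identified by its intron's
1-based genomic coordinates and strand; `'.'` (unknown strand, as emitted
for unstranded libraries) matches either strand when datasets are
intersected, since demanding strand agreement against an unstranded dataset
would discard every match.  All in-memory coordinates are 1-based inclusive
(the native convention of both `SJ.out.tab` and GTF); only the BED export
converts to 0-based half-open.

## PSI estimation

Inclusion is estimated by the empirical ratio of a junction's pooled unique
reads to the pooled reads of the junction plus all junctions sharing either
of its splice sites.  This is a deliberate stand-in for Bayesian posterior
E(PSI) estimators: it has no prior and no credible intervals, but on
deeply sequenced events it converges to the same quantity, and its
transparency makes the planted-truth recovery tests exact.  Replicates are
pooled by summing counts before the ratio (a `mean` option exists for
averaging instead; summing weights replicates by depth, which is the
behaviour wanted when replicate depths are unequal).  A junction with zero
total reads over target and competitors is *unquantifiable* — reported as
missing, never as PSI 0, because absence of signal is not evidence of
exclusion.  The same logic drives the cassette-exon formula
`PSI = NEIJ/(2·CEJ + NEIJ)`: the two inclusion junctions flanking a
cassette exon are balanced against the single skipping junction, and the
denominator form keeps the estimate in [0, 1].

Filters precede quantification: unique-read support ≥ 6 and intron length
≥ 60 nt (both inclusive; genuine mammalian introns shorter than 60 nt are
rare enough that shorter calls are treated as artifacts).

## Tissue-specificity scoring

For each tissue T the oriented differences `PSI_T − PSI_other` are
thresholded at 0.2 (inclusive) into binary tables, one entry per
comparison; a tissue's score is the row sum, so with five tissues the
ceiling is 4 and the orientation makes "included in T" positive.  All n−1
oriented comparisons per tissue are used.  Labels require a strict maximum;
ties and all-zero rows give NA.  Missing comparisons (a junction
unquantifiable in some tissue) are stored as absent rather than 0 so that
NA-by-missing-data is distinguishable from NA-by-tie; a junction needs at
least one scorable comparison to be labelled.

## Junction windows and translation

Windows take 66 nt of raw genomic sequence on each side of the intron —
novel junctions have no trustworthy exon chain to walk, so genomic flanks
are the only construction that treats annotated and novel junctions
identically.  Windows are reverse-complemented for `'-'`-strand genes;
junctions with no known orientation are translated on both strands (six
frames).  Within a frame, a stop codon at or before the codon containing
the splice boundary kills the candidate (the upstream flank is then not
translated across the junction); a stop after the boundary truncates the
peptide, which must still pass the 22/22 boundary check (junction offset
between 1 and 22 residues from the start, ≥ 22 residues after) or be
dropped.  Codons containing N translate to X.  Windows clipped by a
chromosome end are retained and flagged rather than discarded.  Novel-exon
and intron-retention sequences go through the same translator with a ≥ 7 aa
length floor and no boundary requirement.

Decoys are per-target uniform permutations of the residues (seeded), so
length and residue multiset are preserved exactly, target-by-target and
globally.  De-duplication runs before decoy generation; the database
therefore always contains exactly 2× its target count.

## MS post-processing

The evidence filter reads "2 peptides and/or 13 spectral counts" as an
inclusive OR — an AND would contradict admitting 1-peptide/13-spectra
proteins.  FDR uses the targets-only denominator (DTASelect-style), with a
`denominator="all"` flag for the targets+decoys convention.  dNSAF follows
the standard distributed definition: spectra of shared peptides are
apportioned in proportion to each claimant's unique spectral counts
(equally when no claimant has unique evidence), the distributed count is
divided by protein length, and factors are normalized to sum to 1.
Parsimony is deliberately not applied: a junction-peptide entry is usually
a subsequence context of an annotated protein, and removing subset proteins
would remove exactly the entries of interest.  A peptide supports a
junction only when an occurrence in a junction entry overlaps the splice
boundary with at least one residue on each side; peptides matching several
junction entries are reported for each and flagged ambiguous.

## Expression cutoff and enrichment

The default expression transform is log2(median-of-ratios-normalized mean
count + 1); it is a plug-in slot, since the cutoff procedure — not the
transform — is the interesting step.  The calibration curve (retained genes
versus cutoff) falls steeply while the cutoff crosses the unexpressed mode
and then plateaus.  The cutoff is placed at the upper edge of the last
falling step of the contiguous drop region that contains the maximum
single-step drop, on a 200-point grid; flat runs shorter than 5% of the
grid are bridged.  Taking the *end* of the fall (rather than the maximum
drop itself, which with count data sits on the zero-count atom) is what
makes the cutoff separate the modes, and looking only at that region makes
the rule insensitive to extra genes far above the cutoff.  Grid size and
gap fraction are exposed.  The TPM ≥ 1 alternative is provided; note that a
fixed TPM floor only separates modes when the average expressed gene sits
far above the TPM contributed by a single stray read, i.e. at realistic
sequencing depth relative to the number of genes.

Splicing enrichment compares, across condition pairs, the NE proportion of
expressed-gene unions against the NE proportion of differentially spliced
genes with a two-sample Kolmogorov–Smirnov test over the two proportion
collections.  The KS null assumes the two collections are identically
distributed, so the calibration simulations use equal-sized gene sets; with
unequal sizes the test also reacts to the difference in sampling variance,
which is a limitation of comparing proportion dots directly.

Intrinsic disorder: a protein is disordered when ≥ 20 residues score
> 0.5.  Two readings of this rule exist — a total count and a contiguous
stretch; the total-count reading is the default and `consecutive=True`
implements the stretch reading, since the two differ for proteins with
scattered high-scoring residues and neither is obviously intended.
Enrichment uses Fisher's exact test (two-sided) on the (NE / non-NE) ×
(disordered / not) table; the reported odds ratio is the sample odds ratio
`ad/bc` with a Woolf log-OR interval (Haldane 0.5 correction when any cell
is zero).

## Synthetic data: what it emulates and what it does not

The generator mirrors a five-tissue body map (brain, heart, liver, muscle,
testes) observed by two independently noised datasets, with defaults: 3
replicates per tissue, 60 genes, 20% NE, 4 planted tissue-specific cassette
events per tissue, inclusion 0.8 in the labelled tissue versus 0.05
elsewhere, mean junction depth 100, negative-binomial dispersion 0.01
(variance = m + 0.01 m², the modest extra-Poisson spread of junction counts
across same-tissue replicates), and per-table noise junctions with < 6
reads to exercise the support filter.  Planted events convert an annotated
intron into a cassette: the novel inclusion junction shares the annotated
junction's donor site, so the two compete in PSI exactly as a real cassette
does.  Count matrices mix unexpressed genes (Poisson mean 0.1) with
expressed genes (log-normal means, log2 mean 6, sd 1.5), giving the
calibration curve its knee; disorder tracks plant one ≥ 20-residue
high-scoring stretch in flagged proteins so both disorder readings agree
with the truth flags.

What passing recovery tests does *not* show: the simulator has no mappability
or GC structure, no shared-donor complexity beyond one competitor per
planted event, no annotation errors, and PSI differences are planted as
clean two-level profiles — real tissues show graded inclusion.  Recovery at
0.95+ sensitivity/precision on this generator demonstrates the scoring
logic, not performance on real body-map data.

## Problem sizes and numerical choices

The test suite runs the recovery analysis over 20 simulated studies at
depth 100 and the PSI-accuracy analysis over 200 simulations at depth 1000
(3 pooled replicates each); enrichment calibration uses 1000 replicates of
20 comparisons with 100-gene sets; the exact-test cross-check enumerates
all 2×2 tables with margins ≤ 30.  These sizes give stable Monte-Carlo
estimates at interactive runtimes.  Thresholds are inclusive (≥) wherever
the rule is stated as "at least".  Ties in tissue scores resolve to NA,
never to an arbitrary tissue.  Degenerate inputs fail loudly: zero-signal
PSI, empty disorder tracks, all-zero samples in TPM, and empty target sets
raise instead of returning defaults.

## Known limitations

- The empirical PSI estimator gives no uncertainty; at low depth a single
  read can cross the 0.2 dPSI threshold.
- Strand-blind matching of `'.'` junctions can, in principle, merge
  distinct antisense junctions at identical coordinates.
- The junction-window construction ignores exon chains, so peptides across
  an annotated junction may differ from the true spliced protein when the
  flanking exon is shorter than 66 nt.
- Intron-retention quantification from coverage, LSV-style event modelling
  and GO enrichment of labelled genes are out of scope.
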