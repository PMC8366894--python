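# Methods

## The identification problem

*Pennisetum setaceum* and *P. advena* are closely related fountain
grasses; only the former is a regulated invasive, so assigning a traded
plant to one of the two — or recognizing it as their hybrid — matters in
practice. The package types each specimen at three barcode loci. The two
chloroplast loci carry a small number of fixed between-species
substitutions (2 in rbcL, 4 in the trnH-psbA spacer) and act as
diagnostic markers and as a maternal-lineage tracer, because plastids
are maternally inherited in grasses (an explicit, documented assumption
of the seed-parent inference). The nuclear ribosomal ITS region is
multi-copy: one genome carries several sequence variants at once, here
two per species (aI/aII at 3 SNPs; sI/sII at 2 SNPs), and the two
species' ITS sequences are only ~90% identical. A hybrid is recognized
by nuclear additivity — ITS variants of both species present in one
plant — and its seed parent by the chloroplast haplotype.

## Pairwise alignment and diagnostic sites

All comparisons are pairwise global alignments under one scoring scheme:
match +1, mismatch −1, gap open −3 (first gap base), gap extend −1.
With these scores, near-identical barcode amplicons align gaplessly
unless an indel is real. The implementation delegates the dynamic
program to Bio.Align.PairwiseAligner configured with these scores;
among co-optimal alignments the aligner's first-reported one is used,
which is deterministic, prefers substitutions over gaps at these scores,
and places gaps leftmost. An independent recursive-enumeration oracle in
the test suite certifies score optimality for short sequences.

Percent identity counts matching columns over all alignment columns
after stripping terminal overhangs; internal gap columns count as
compared and non-matching. The published between-species ITS figure does
not state how indel columns are counted; this is one defensible,
reproducible definition, and the synthetic ITS divergence is realized as
substitutions only so the generator's identity is analytically exact.

Diagnostic sites are the alignment columns at which the two species'
references differ; each site records both alleles and its position in
each ungapped sequence. Coordinates are 0-based, half-open throughout.

## Synthetic data generator

The generator is the package's study stand-in and defines the test
conditions; it emulates divergence structure, not chromatogram physics.

- **Panel.** Sequences are i.i.d. uniform over {A,C,G,T} at amplicon
  scale (rbcL 550 nt, trnH-psbA 400 nt, ITS 600 nt). Substitution
  positions are drawn without replacement, excluding 30 nt at each end
  (primer-proximal regions stay clean), and the between-species,
  advena-internal, and setaceum-internal substitution sets are disjoint,
  so the configured counts (2, 4; 90% identity = 60 ITS substitutions;
  3 and 2 intra-specific SNPs) hold exactly. An optional setaceum
  trnH-psbA haplotype pair differs by a single 1-nt insertion placed in
  the middle third of the locus.
- **Genotypes.** A specimen is a chloroplast species plus an ITS variant
  mixture (proportions summing to 1), optionally with the 50/50
  chloroplast indel pair. The 13 bundled scenarios mirror the study
  design: advena specimens at 55/45 aI/aII, the two hybrid cultivars at
  45/15/40 and 20/50/30 (aI/aII/sI), setaceum accessions at 70/30 and
  30/70 sI/sII, and four setaceum specimens for which only variant
  presence is reported — these default to 50/50, an assumption labelled
  as such, not a reported value.
- **Short reads.** 150 nt single-end reads at a configured mean coverage
  (default 1000×; a desk-scale stand-in for a production short-read
  run). Each read's template is drawn with probability equal to its
  mixture proportion, its start uniformly, and each base is substituted
  independently at the error rate (default 0.001).
- **Sanger pairs.** Reads of up to 500 nt per strand, primer sequence
  prepended. Emission is per-position: any base whose summed template
  proportion reaches the secondary-peak threshold (0.20, a typical
  basecaller visibility level) appears in the emitted IUPAC code. The
  quality profile is a Q50 plateau decaying linearly to Q10 over the
  last 50 bases, which forces the trimming code to do real work. When
  the mixture contains two templates offset by an indel, every position
  downstream of the indel in each strand's reading direction is emitted
  as a random base at Q8 — the frameshifted double trace of a real mixed
  template — so each strand keeps only the upstream half and
  bidirectional assembly has no credible overlap.
- **Determinism.** All randomness flows from one master seed through
  deterministic per-specimen, per-locus streams (NumPy seed sequences
  keyed by specimen id and locus); identical configuration yields
  byte-identical FASTQ and report output.

What the generator does *not* emulate — real chromatogram noise, PCR
chimeras, copy-number mechanisms behind unequal ITS ratios, paired-end
insert geometry, cross-species mapping references — bounds what passing
tests show: the pipeline's logic is correct under the stated read model,
not that it is robust to every artifact of production data.

## Sanger processing

Quality trimming keeps the longest contiguous run in which every
sliding window (width 10) has mean quality above the floor (PHRED 30),
then strips residual end bases individually at or below the floor. The
windowed rule alone can retain a low-quality base at a run edge (a
window straddling it may still pass on its mean); the per-base edge
strip removes it, keeps the operation idempotent, and preserves the
invariant that retained end bases meet the floor, while an isolated
interior dip does not fragment an otherwise good read. Primer trimming
removes a prefix or suffix matching either amplification primer or its
reverse complement with at most 2 mismatches (IUPAC-aware); the read
interior is never edited.

Assembly reverse-complements the reverse read (IUPAC-aware) and aligns
it to the forward read with free end gaps. Per overlap column: equal
calls sum their qualities (capped at 93); disagreeing concrete bases
resolve to the higher-quality call when the PHRED gap is ≥10, otherwise
to the covering IUPAC code; an ambiguity covering the other call wins.
Flanks covered by one strand are kept at single-strand quality.
Assembly fails when the overlap has fewer than 50 columns or under 80%
compatible calls — thresholds chosen to trigger on the simulated
indel-mixture trace and never on clean data. No merge rule or
assembler parameters are published for the original workflow; these
values are this package's declared substitutes.

## Read mapping and variant detection

References are under 1 kb, so each read is placed by a full semi-global
alignment (read end-to-end, reference overhangs free) under the panel
scoring — no seeding or indexing layer. A read is mapped when identity
over its aligned span is ≥0.8. By default the exact dynamic program runs
only inside a candidate window located by edlib (best edit-distance
placement ±16 nt); `method="full"` runs it over the whole reference, and
a property test checks the two agree on read-scale data. Pileups count
bases and deletions per position; insertions are recorded against the
reference position to their left.

Variant detection is a plain frequency caller: an alternative allele is
reported at depth ≥10 with count ≥2 and frequency ≥0.05. The frequency
floor is set to detect a 15% minority ITS component with margin while
suppressing sequencing error at rates ≤0.01, and the caller is monotone
in all three thresholds. A chloroplast indel mixture is reported when an
insertion or deletion allele sits at frequency 0.2–0.8 at adequate
depth — the two-haplotype situation that defeats Sanger assembly.

## ITS mixture deconvolution

Informative sites are the anchor-reference columns at which at least two
of the named variants differ (variants are aligned pairwise to the
anchor, advena variant I by default; columns where a variant carries a
gap are flagged). Each mapped read covering at least one informative
site is scored by Hamming distance to every variant restricted to the
sites it covers and votes for the minimum-distance variant(s).

A read that covers none of the sites separating two variants ties
between them. Splitting ties equally is simple but inconsistent: with 2
within-species SNPs in a 600 nt locus, roughly half of 150 nt reads
cannot separate sI from sII, and an equal split pulls a true 70/30 ratio
about 9 points toward 50/50 regardless of coverage. Tied mass is
therefore reallocated in proportion to the estimated proportions of the
tied variants and iterated to a fixed point (an EM iteration over
minimum-distance tie sets, initialized from the equal split, tolerance
1e-10). Its stationary point is consistent with the true mixture, and
for reads covering every informative site it reduces exactly to per-read
template identification, which an independent oracle test checks.
`tie_method="equal"` retains the naive rule for comparison. Labels
estimated below a noise floor of 0.03 — below the error-driven
false-vote rate at default error rates — are dropped and the remaining
mass renormalized, preventing spurious hybrid calls.

## Specimen verdicts

Each chloroplast locus is typed 'a' when every resolvable diagnostic
site carries the advena allele, 's' symmetrically, 'mixed' when any site
shows both species' alleles (a covering IUPAC code, or both alleles at
≥0.2 frequency in a pileup), and 'unresolved' when fewer than half the
sites are covered or resolved sites conflict. Consensus-based typing
aligns the consensus to the advena reference; pileup-based typing reads
allele frequencies directly.

A specimen is a hybrid when its ITS profile puts at least 10% (the
hybrid floor, chosen to accept the 15% and 30–40% minority components
of the hybrid scenarios while rejecting error-level noise) on at least
one variant of each species. Otherwise the ITS species must agree with
the chloroplast haplotypes; a nuclear/chloroplast conflict or a pair of
conflicting chloroplast loci yields an indeterminate verdict with a
note, never a forced call. The maternal lineage is the species of the
two agreeing chloroplast loci, hybrids included. Morphological range
checks (leaf width, leaf length, stipe length, inflorescence posture,
leaf blade; a measured range inside exactly one species' published range
votes for that species, and the verdict must be unanimous) are advisory
only and never override the molecular verdict. The report table carries,
per specimen, the two chloroplast haplotype letters, the detected ITS
variants with estimated percentages, the verdict, the maternal lineage,
and threshold-decision notes.

## Problem sizes and numerical choices

Default study conditions are 13 specimens at coverage 1000 and error
rate 0.001; mixture-consistency checks run at coverage 10,000 (ITS
only), where estimates sit within 2 points of truth. Deterministic
tie-breaks: the aligner's first-reported co-optimal alignment, leftmost
mapping placement, lexicographic ordering of variant calls. Degenerate
inputs have defined outcomes rather than errors where the field's tools
behave that way: an all-low-quality read trims to empty, a read pair
without credible overlap fails assembly, a read set covering no
informative site yields a flagged, empty profile.

## Known limitations

Reads are modelled single-end with substitution errors only; mapping
uses same-species panel references rather than an outgroup reference;
no base-quality-aware calling, no diploid/polyploid genotype
likelihoods, no chimera detection; ITS ratios are treated as mixture
proportions without modelling the copy-number mechanisms that may
underlie unequal ratios in real rDNA arrays; and the morphology module
encodes only the two-species character ranges, not a general
identification key.
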