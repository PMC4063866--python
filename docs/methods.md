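# Methods

This note documents the models, conventions, numerical choices and known
limitations of `bsmethy`.

## Coordinates and strand conventions

All files use 1-based, inclusive positions on the Watson strand; internal
arrays are 0-based, converted only at file boundaries.  A Crick-strand
cytosine is reported at the Watson coordinate of its paired guanine so both
strands share one axis.  Quality scores are Phred+33 with no autodetection.
BED input is 0-based half-open per the BED standard and converted on read.

## Bisulfite-aware alignment

Trimming removes, in order, (i) a 3′ adapter — the leftmost read suffix
matching an adapter prefix with overlap ≥ 3 and at most one mismatch per 10
overlap bases — and (ii) 3′ bases with Phred quality < 5 (5′ trimming exists
behind a flag and is off by default, since Illumina quality degrades at the
3′ end).  Reads shorter than 20 nt after trimming are dropped and counted.

Alignment is methylation neutral: queries are C→T converted and matched
against two C-depleted references (Watson with C→T; the reverse complement of
Watson with C→T).  In a directional (MethylC-seq style) library mate 1 is the
converted strand itself, while mate 2 is its complement, so the query for
mate 2 is the C→T conversion of its reverse complement.  The mismatch model
is substitutions only, no indels, with a default budget of 2 per read;
mismatches are counted between the converted read and the converted
reference.

The index is an exact k-mer table (default k = 20) over both converted
references.  For a mismatch budget *q*, a read is split into *q* + 1 disjoint
chunks and one seed is taken per chunk; by pigeonhole at least one seed is
exact for any placement within budget, so seeded candidate enumeration is
complete.  Reads too short for disjoint seeding (but at least 20 nt) fall
back to a vectorised scan over every offset.  The original algorithm used an
FM-index; the contract here is identical (all exact-substring occurrences,
testable against a naive scan) and only the data structure differs, a
performance rather than semantic choice at the genome sizes this package
targets.

Filtering is best-stratum unique: a read (or pair) is kept iff exactly one
placement exists at the minimum attained mismatch count and no placement at
that minimum lies on the other strand's reference; both-strand ties are
discarded as ambiguous.  For pairs, candidate placements require both mates
on the same chromosome and strand of origin, inward facing, with outer insert
(rightmost end − leftmost start + 1) inside [insert_min, insert_max]
(defaults 50–600); uniqueness is evaluated per pair over total mismatches.
Duplicate removal is fragment-level — key (chromosome, fragment start,
strand, insert size for pairs / read length for single-end) — keeping the
fragment with the greatest summed base quality, ties broken by smallest read
id.  Filtering precedes duplicate removal.

Because C→T conversion erases the methylation signal from the query, mapped
positions are provably independent of methylation state when sequencing
errors are absent; the test suite asserts exactly identical mapped-position
sets across simulated CpG levels of 5–100% with fragments held fixed (with
sequencing errors the error substitution drawn at a C/T site can differ
between methylation states, so exact set identity is only guaranteed at error
rate 0, which is how the property is tested).

## Methylation calling

For every reference cytosine the pileup counts sequenced Cs (methylated) and
Ts (converted, unmethylated).  Watson cytosines are informed only by
Watson-origin fragments and Crick cytosines only by Crick-origin fragments,
after orienting each read back onto Watson coordinates (in that orientation a
Crick methylated C reads as G and a converted one as A).  Read bases other
than C/T at a cytosine (sequencing errors, variants) are ignored rather than
counted as either state, since the methylation density is defined purely on
C and T counts.  When mates of one fragment overlap, each overlapped position
is counted once, taking the mate with the higher base quality (ties go to
mate 1).  Sites appear in the output at depth ≥ 1 by default; downstream
steps apply their own depth gates (5 for DMR validity, 10 for array
comparison).

Context is the trinucleotide starting at the cytosine read 5′→3′ on its own
strand: CpG when the next base is G, CHG when the base after next is G, CHH
otherwise (H ∈ {A, C, T}).  Positions within 2 bp of a chromosome end pad
with N and classify as CHH unless the CG dinucleotide is complete.  CpG calls
are reported per strand; pooling the two strands of a dinucleotide is an
option of the DMR caller and the array comparison, not of the call files.

The bisulfite conversion rate is estimated, when an unmethylated spike-in
chromosome (e.g. lambda) is configured, as 100·ΣT/(ΣC+ΣT) over every
cytosine of the spike.

## DMR detection

Parameters (defaults): window w = 500 bp; slide s = 100 bp; m = 5 valid CpGs
per window; n = 5 reads per valid CpG; extension bound k = 1000 bp; seed
threshold p < 0.01 (Mann–Whitney, two-sided); region threshold p ≤ 0.01
(χ², 1 df, no continuity correction); unchanged threshold p > 0.25; merge
distance 1000 bp; merge MD difference 10 percentage points.

A valid CpG must reach depth n in *both* samples at the same position and
strand (the stricter reading; per-sample independent validity would let the
two samples be tested on different site sets).  Windows start on the s-grid
anchored at the scan origin; after a region is finalised scanning resumes s
bases past its end.  Extension interrogates the next whole window only while
the current region is ≤ k long (so a pre-merge region is at most k + w), and
requires the next window to be a significant seed *in the same direction*;
the window is tested alone, not cumulatively.  Merging compares pooled
region-level MDs within each sample and includes gap CpGs in the merged
pooled counts.  The final χ² tests the pooled table [[ΣC₁,ΣT₁],[ΣC₂,ΣT₂]];
a zero marginal yields p = 1 (degenerate tables are never significant).
Direction is reported for sample 2 relative to sample 1, which makes the
caller exactly antisymmetric under sample swap — a property the tests assert.

The Mann–Whitney statistic uses midranks.  For pooled sizes ≤ 20 the p-value
is an exact permutation enumeration over all group assignments: with no ties
this equals the classical exact U distribution, and with ties it remains an
exact conditional test, where the tie-corrected normal approximation would
not be (the m = 5 default sits squarely in this range).  Larger pooled sizes
use the tie-corrected normal approximation with continuity correction.  All
values identical across both groups gives p = 1 by convention.

## Profiling, annotation and array concordance

Genome-wide profiles pool MD per fixed window (default 100 kb) per strand;
pooling all windows reproduces the genome-wide MD exactly (a conservation
identity under test).  The context spectrum reports pooled MD for each of the
16 CNN trinucleotides plus, per class, the *fractional methylated C* — the
share of all sequenced methylated Cs falling in CpG/CHG/CHH.  Region
profiling returns pooled MD per labelled region plus a per-cytosine
long-format table suitable for box plots.

DMR annotation takes gene intervals with strand; the TSS is the start of a
'+' gene and the end of a '−' gene; each DMR gets the closest gene by TSS
distance (0 if the TSS is inside the DMR; ties to the lexicographically
smallest name) and a promoter flag when it overlaps the 2-kb window
immediately upstream of the TSS.

Array concordance pools Watson+Crick CpG counts per dinucleotide (keyed at
the Watson C), keeps loci with ≥ 10 reads, converts MD to the beta fraction
scale, joins on position and reports the Pearson r.  Array-derived
gold-standard regions are 500-bp windows classified by the difference of
mean beta values (sample 2 − sample 1): > 0.25 hypermethylated, < −0.25
hypomethylated, within ±0.03 unchanged, otherwise unassigned; windows
lacking probes in either sample are dropped.  The 25% / 3% thresholds are
applied on the beta fraction scale.  Evaluation counts a gold window as
recovered when a call of the matching direction overlaps it by ≥ 1 bp (no
overlap-fraction requirement, since detection is reported as a proportion of
regions found).

## QC report

The run summary contains fragment totals, mappability (mapped / total),
duplication rate (duplicates / mapped), percentage of cytosines and of CpG
cytosines covered by ≥ 1 read (threshold configurable), mean depth over all
genomic cytosines, pooled MD per context class, and the spike-in conversion
rate when available.  Two diagnostics are embedded as base64 PNGs in a
single-file HTML report: per-cycle base composition (high T / low C expected
after conversion) and the paired-end insert-size histogram.  Missing
quantities render as "n/a"; single-end data renders a note instead of the
insert plot.

## Simulator

The generator reproduces the classic validation design without external
data.  Defaults: a 48,500-bp i.i.d. random genome at 50% GC (lambda-phage
scale and composition; the real lambda sequence is deliberately not bundled),
50,000 pairs of 75-base mates, inserts uniform on [75, 600], CpG methylation
100%, CHG/CHH 0%, complete bisulfite conversion, substitution error 10⁻³
(typical Illumina), constant Q40 qualities (a linear quality-decay option
exists for QC-plot realism).  Per fragment: start uniform, strand a fair
coin; each cytosine on the fragment's strand is methylated with its site
level; unmethylated cytosines convert C→T with the conversion probability;
errors are applied i.i.d. after conversion.  Mate 2 is the reverse
complement of the fragment's 3′ end.  Fragment coordinates come from an RNG
stream separate from the methylation/error stream so that a fixed seed
plants identical fragments across methylation settings.

What the simulator does *not* model: indels, PCR-duplicate amplification,
quality-dependent error rates, M-bias, CNVs/SNVs, and genome repeat
structure beyond what i.i.d. sequence produces.  Passing benchmarks on this
generator therefore demonstrate correctness of the pipeline's logic and
statistics, not robustness to every artefact of real libraries; the
alignment figures in particular are easier on a repeat-free random genome
than on a mammalian reference.

### Benchmark problem sizes

The recomputed benchmarks use: 50,000 pairs for the mappability/accuracy
experiment (matching the lambda-scale design; binomial noise on 50k pairs is
±0.1-point scale); 10,000 pairs for exact recovery of the fully methylated
CpG level (error 0, conversion 100%, where pooled CpG MD is exactly 100 by
construction — no converted T can appear); and 22,000 pairs at the 5% CpG
level, chosen because per-strand site depth is roughly half the raw
coverage, so ~68× raw coverage yields the ≥ 30× aggregate CpG depth the
design calls for (binomial standard error ≈ 0.05 points at that depth).

### Planted-DMR experiment

Each replicate is a 20-kb chromosome with CpG sites every 83 bp (≈ 6 per
500-bp window), every site covered by exactly 10 reads in both samples, and
one 1-kb block planted at a random interior position where sample 2's level
drops from 100% to 50% (a 50-point contrast); counts are Binomial(10,
level).  Background CpG methylation is a deterministic 100% in both samples,
mirroring the standard simulated-methylome design in which context classes
get fixed levels.  Under this design the background is free of
between-sample noise, so specificity is structural; sensitivity is governed
by the Binomial(10, 0.5) sampling inside the block.  A known limitation,
documented deliberately: with *noisy intermediate* background levels the
fixed-threshold Mann–Whitney → χ² cascade has a small but non-zero
per-window false-positive rate (it applies fixed p-value cutoffs with no
multiplicity control across the thousands of windows a genome-wide scan
tests), so on real genome-scale data some background calls are expected —
the original design accepts this in exchange for replicate-free operation.

## Design decisions on points the underlying algorithm leaves open

- Pair uniqueness is evaluated per pair (total mismatches of the placement
  pair), not per mate, matching "uniquely mapped" semantics for fragments.
- Both-strand filtering happens during resolution; duplicate removal runs
  last.
- Extension tests each next window alone (not cumulatively) and stops after
  the region length first exceeds k.
- The duplication-rate denominator is mapped fragments.
- DMR calling uses strand-separate CpG sites by default; `merge_strands`
  pools dinucleotides.
- The `.bsalign` format carries a `mate` column in addition to the aligned
  chromosome, position, strand, mismatch count, original bases and
  qualities, because the mate index is needed to re-orient stored reads onto
  Watson coordinates at pileup time.
- Single-end reads are treated as mate 1 (directional library assumption).
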