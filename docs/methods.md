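# Methods

## Overview

`stressmir` re-implements, as a tested library, the integrated
small-RNA + degradome analysis used in multi-condition plant stress
studies: four single-replicate libraries (one control, three stress
conditions), a degradome library, and transcript-level direction calls
from a companion transcriptome study. Every stage is deterministic given
its inputs; all randomness lives in the synthetic-data generator and is
controlled by one master seed.

## Read cleaning and tag collapsing (`preprocess`)

Instrument reads carry the insert followed by the 3' adapter. The
adapter is located by an exact match of its first 8 nt (the seed);
reads without a seed hit are discarded and counted as an adapter
failure (a `keep-untrimmed` switch admits pre-trimmed input at full
length). After trimming, reads that are ≥ 80 % adenosine are removed as
polyA artifacts, and survivors outside 18–30 nt are counted under
separate short/long discard classes, so raw reads always equal clean
reads plus the discard classes. Clean reads collapse into unique tags
with one raw count per library. The descriptive profiles — count-
weighted length distribution and per-length 5'-nucleotide fractions —
are computed on this table. Genome mapping is exact substring search on
both strands; at the scale of a miRNA analysis only perfect matches are
informative, and mismatch tolerance would blur locus assignment.

Choices the source protocols leave open: the polyA threshold (80 %)
and the treatment of > 30 nt reads (excluded under their own counter)
are this package's conventions, both config-exposed.

## Known-miRNA quantification (`mirna_quant`)

A tag is assigned to a known miRNA under two criteria applied in order:
(1) an exact, full-length, mismatch-free occurrence in the miRNA's
precursor; (2) at least 16 nt of overlap between the tag's precursor
interval and the annotated mature interval. End offsets ("isomiRs") are
otherwise unrestricted — the overlap bound is the only constraint, since
no tighter bound is standard. Tags matching several precursors count
once per distinct miRNA name (expression is reported per miRNA, not per
locus). Slash-grouped reference names (`lus-miR160a/e/f`) are expanded
to individual members on ingest; members sharing an identical mature
sequence necessarily receive identical counts.

## Novel-locus prediction (`novel_mirna`)

Mapped tags clustering within 30 nt on one strand define candidate
loci; each locus gets a window of ±250 nt (clusters wider than 200 nt —
which arise when background coverage chains across a region — are split
into one window per locally most-abundant tag, the same enumeration
Mireap performs inside large clusters). A window is accepted as a novel
miRNA hairpin when all of the community annotation criteria hold:

* the most abundant tag (the candidate mature) is 18–25 nt;
* a star partner region exists on the opposite arm forming an
  antiparallel duplex with ≤ 4 unpaired mature positions and no bulge
  greater than 2 nt, separated from the mature by a 3–60 nt loop;
* the duplex shows the canonical 2-nt 3' overhang (±1 nt), measured
  from star reads when any are observed and assumed canonical from the
  duplex geometry otherwise;
* the hairpin is stable: minimum free energy of the mature–star span
  ≤ −18 kcal/mol (thermodynamic backend) or ≥ 14 paired stem positions
  (fallback backend);
* reads on the precursor are duplex-biased: ≥ 90 % of the read counts
  within the hairpin span sit on the mature or star intervals. Counts
  in the flanking window are not evidence about the locus and are
  excluded from the denominator; star reads support the duplex rather
  than counting against the mature arm.

The star search is a direct complementarity scan (Watson–Crick plus
G:U, one optional star-side bulge of ≤ 2 nt), deliberately independent
of the folding backend so that the duplex criteria behave identically
under both backends; folding supplies only the stability criterion and
the reported dot-bracket structure. This avoids a failure mode of
structure-derived duplexes where the global MFE structure pairs part of
the mature into a competing flank helix and a genuine duplex is missed.

Accepted candidates are deduplicated by genomic interval, ordered by
(chromosome, start, strand) and named `novel_mir_1..n`, which makes
naming idempotent across reruns.

## Folding backends (`folding`)

The thermodynamic backend is ViennaRNA's MFE fold. The internal
fallback is a Nussinov-style maximum-weight dynamic program (GC = 3,
AU = 2, GU = 1, minimum hairpin loop 3 nt) reporting a pseudo-energy of
−1 per weight unit; it exists so the package runs with no external
thermodynamics and is validated against exhaustive structure
enumeration for short sequences. `backend="auto"` (the default) prefers
ViennaRNA when importable.

## Differential expression (`diffexpr`)

Counts are normalized to reads per million of the library's clean-read
total. No length term is used: miRNA lengths are nearly constant, so a
per-kilobase correction would only add noise. For ratio computation a
zero count is floored at 0.01 RPM (config-exposed), keeping fold-changes
finite while raw zeros are retained for presence/absence reporting.

With one library per condition, the comparison of two counts is the
Audic–Claverie conditional binomial test, the de-facto standard for
replicate-free count data of this design's era: conditional on
n = count_t + count_c, under the null count_t ~ Binomial(n, q) with
q = total_t/(total_t + total_c); the two-sided p-value is twice the
smaller exact tail, capped at 1. Benjamini–Hochberg step-up adjustment
follows. A miRNA is called up (down) when FDR < 0.001 **and**
log2FC > +1 (< −1), both inequalities strict; miRNAs with zero counts
in both libraries are labelled `absent`. The log2FC matrix for
clustering orders complete rows by average-linkage hierarchical
clustering on Euclidean distance, masking cells where either library
count is zero.

## Target scoring (`target_score`)

Complementarity is scored by the classical plant expectation penalty,
accumulated per miRNA position from the 5' end: mismatch 1.0, G:U
wobble 0.5, gap 2.0, each doubled in the seed region (positions 2–13).
At most two gaps are allowed and none at positions 10–11, which keeps
the cleavage position well defined. The minimum-expectation alignment
over a window is found by dynamic programming (validated against
exhaustive alignment enumeration); every sense-strand window whose
length is within the gap limit of the miRNA length is scored, sites at
or below the cutoff (default 5.0) are reported, and overlapping sites
of one miRNA–transcript pair keep the minimum-expectation one (ties:
fewer gaps, then 5'-most). Scores fall on a half-integer grid by
construction.

## Degradome analysis (`degradome`)

Degradome tags are trimmed fragments of 20–21 nt; tags matching a
user-supplied ncRNA set are removed. Exact sense-strand matches
increment the 5'-end position on every matching transcript. Each
occupied position is categorized: **4** — a single raw read; otherwise
with M the maximum and med the median count, **0** — the unique
maximum, **1** — a tied maximum, **2** — above the median but below the
maximum, **3** — at or below the median. The median is taken over
occupied positions (the CleaveLand convention; a switch includes
zero-coverage positions instead), and the 2/3 boundary is strict above,
inclusive below. A predicted site's expected cleavage position is
site_end − 9 — the transcript base paired with miRNA position 10 — and
an event is confirmed when an occupied position lies within ±1 nt of
it, taking the most abundant position in the window.

## Integration and qPCR (`integrate`)

Direction triples (Up/Down per stress condition) come from the sign of
log2FC regardless of significance, because published pair tables list
directions for miRNAs outside the significant set; a
`significant_only` switch restricts them. A miRNA/target pair is
considered only when a cleavage event links them (the three-way
integration: miRNA profile + degradome + transcript profile), and is
**inverse** when the two triples disagree in every condition. No
degradome-category filter is applied to pairs by default. Relative
qPCR expression is 2^−ΔΔCt with replicate-mean ΔCt and a standard-
deviation-propagated interval; concordance compares the sign of the
qPCR log2 ratio with the sequencing log2FC per miRNA and condition.

## Synthetic data (`synthetic_data`)

The generator emulates the four-library study design at desk scale and
records every planted entity:

* **Genome** (default 30 kb): i.i.d. uniform ACGT background with
  planted precursor hairpins, built as
  (mature)(loop)(reverse complement of mature with k = 2 interior
  substitutions) plus 2 nt so the star read carries its 3' overhang.
  Defaults: 20 known miRNA loci, 5 novel loci, 21 nt matures with
  balanced GC, 12 nt loops. The genome-length/depth ratio is chosen so
  that locus-level signal-to-background (reads on a hairpin vs random
  background read starts per nt) is in the realistic regime of a real
  genome; a miniature genome at full real depth would bury every locus
  in background.
* **Libraries** (default 10 000 reads each): half the depth is
  budgeted to known miRNAs with lognormal baseline abundances,
  per-condition multiplicative fold factors (default 4× up or down) for
  the planted-DE subset, 80 % exact mature reads and 20 % 1-nt-shifted
  isomiRs; novel loci contribute mature (mean 60) and star (mean 10)
  reads; the remainder is random genome windows with the 21/24-nt
  bimodal length mix and every read carries the Illumina small-RNA
  adapter prefix. Counts are gamma-Poisson with variance μ + φμ²
  (φ = 0.01 by default, mild overdispersion; φ = 0 degenerates to
  Poisson). 85 % of mature species start with U, reproducing the 5'-U
  bias.
* **Degradome**: each planted cleavage site gets a burst of 50 tags
  starting exactly at the site (sized to be a category-0 unique
  maximum); background tags occupy distinct random positions at count 1.
* **Transcripts and direction calls**: each planted target transcript
  contains the exact reverse complement of its miRNA and is called
  inverse to the miRNA's planted direction in every condition;
  non-targets are random.
* **qPCR**: Ct values constructed so 2^−ΔΔCt equals the planted fold
  factor exactly, for the fully-DE miRNAs.

One RNG stream per output file is derived from the master seed by label
hashing, so regenerating one file never perturbs another, and a fixed
seed yields byte-identical outputs (gzip headers are written with a
pinned mtime).

**What passing on synthetic data does and does not show.** The
generator plants exact-substring reads (no sequencing error), uniform
background composition, single-copy loci on one strand, and perfect
target complementarity. Recovery on this data validates the pipeline's
logic — criteria arithmetic, statistics, coordinate conventions — not
its robustness to real-data pathologies (repeats, cross-mapping
families, partial complementarity, RNA editing), and dataset-scale
counts from real studies (hundreds of miRNAs, ~100 DE calls per
condition) are not reproducible from a miniature simulation.

## Numerical and edge-case conventions

* Strict inequalities at both DE thresholds; boundary values are `ns`.
* `N` bases are unpairable in folding and rejected in target scoring.
* Alignment ties break toward fewer gaps, then the 5'-most site;
  candidate-window tag ties break by count, then position, then
  sequence.
* The conditional binomial p-value is computed from binomial
  CDF/survival functions, not pmf summation, and is exact to floating
  precision (validated against explicit tail summation for n ≤ 200).
* Degradome category 0 can hold at most one position per transcript by
  construction.

## Problem sizes

The default test and reproduction runs use the generator defaults
above (30 kb genome, 4 × 10 000 reads, 20 + 5 loci, 30 transcripts of
400 nt, 6 planted cleavage sites) plus 20 background-only replicates
(10 kb, 1 500 reads) for the hairpin false-positive rate; a full run
completes in well under a minute on one CPU.

## Known limitations

* Exact-match mapping only; a single sequencing error drops a read.
* The Audic–Claverie test assumes Poisson sampling; with strong
  overdispersion (φ ≫ 0.01) its p-values are anticonservative, which
  is inherent to replicate-free designs.
* The novel-locus scan evaluates one mature candidate per window after
  cluster splitting; two hairpins closer than ~60 nt would merge.
* psRNATarget releases differ in their default parameters; the scheme
  here (penalties 1/0.5/2, seed 2–13 doubled, cutoff 5) is the
  classical plant scheme consistent with half-integer published scores,
  and all of it is config-exposed.
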