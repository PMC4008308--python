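# Methods

This note documents the models, parameters and design choices behind
`exomir`: what each stage computes, why the defaults are what they are,
and what the synthetic-data tests do and do not demonstrate.

## Scope and data model

The pipeline operates at desk scale: toy genomes of a few hundred kb,
tens of precursors, tens of thousands of reads. Internally all
coordinates are 0-based half-open; the GFF3 writer/reader in
`exomir.io` is the single point where the format's 1-based inclusive
convention is applied. Sequences are normalized to uppercase DNA
(U→T) on read, so RNA- and DNA-alphabet references mix freely.

## Read cleaning, tags and ncRNA annotation

Inputs are assumed adaptor-trimmed. Cleaning retains reads of 18–30 nt
(`read_len_min/max`) with no ambiguous base and, when FASTQ qualities
are present and a threshold is set, sufficient mean phred quality.
Cleaned reads collapse to unique tags with counts (ordered by count,
then sequence, so the operation is deterministic and idempotent), and
tags matching a class-labeled ncRNA library — exact substring, either
strand — are annotated and excluded from discovery. Multi-class hits
resolve by the fixed priority rRNA > tRNA > snRNA > snoRNA > scRNA >
srpRNA > repeat. Exact matching keeps the behavior fully checkable; a
mismatch-tolerant annotator would need its own validation corpus.
Report percentages are rounded half-up to two decimals.

## Genome mapping

`genome_map` is an exact-match, multi-locus, strand-aware mapper: a
k-mer hash (k = 12) over the plus strand, minus-strand hits found by
querying the reverse complement. Every occurrence is reported; tags
with more than `max_hits` (20) loci are flagged `multi` but retained,
since discarding them would silently break multi-copy precursor
accounting. Exactness means the mapper has a perfect oracle (a naive
full scan), which the suite exercises on random genomes. isomiR
tolerance is handled downstream by precursor-relative placement, not by
mismatch alignment.

## The folding model

`rnafold` implements a Nussinov-style dynamic program extended with
nearest-neighbor stacking energies — deliberately not the full Turner
model, which would be out of proportion for this package. Rules:

* pairs: Watson–Crick plus G:U wobble; nested; hairpin loops ≥ 3 nt;
* each stacked pair of pairs adds the tabulated stacking energy
  (`exomir/data/stack_energies.tsv`; Watson–Crick entries follow
  published nearest-neighbor measurements, wobble-containing stacks are
  a flat −0.6 / −0.4 kcal/mol so that a wobble never outcompetes a
  Watson–Crick alternative — which also makes "the perfect complement
  is the optimal duplex partner" a provable invariant);
* flat loop penalties: hairpin +4.0 kcal/mol, bulge/internal loop +3.0
  per occurrence (≤ 12 unpaired nt per loop), multibranch loop +4.5
  (the multiloop constant was a free choice; anything in +4..+6 behaves
  the same at these scales);
* the exterior loop is free, so energies are ≤ 0.

Absolute energies therefore differ from Mfold/RNAhybrid; all thresholds
(−18, −20, −25 kcal/mol) are interpreted relative to this model, and
the synthetic generator plants hairpins that clear them under it. MFE
values are verified against exhaustive enumeration of all nested
structures for sequences ≤ 15 nt (the 12-nt internal-loop cap cannot
bind at that length, so the equality is exact). Tie-breaks prefer
extending a helix and the 5'-most branch, making structures
deterministic.

The duplex model reuses the stack table for intermolecular pairs
(antiparallel, no intramolecular structure), with interruptions of at
most 2 nt per side costing the flat internal-loop penalty. A perfect
n-mer duplex therefore scores the sum of its n−1 stacks, which the
tests hand-sum from the parameter file.

Dinucleotide-preserving shuffles use the Altschul–Erickson Euler-path
construction (exact doublet preservation, endpoints fixed); for short
sequences the outputs are checked against the brute-force-enumerated
valid set. The randomization p-value uses the +1/(n+1) permutation
estimator so p is never 0 and ties count against significance.

## Discovery

Unannotated tags' alignments chain into loci when their gap is ≤ 35 nt
(the maximal mature/star spacing — so both arms, loop reads and moRNAs
of one precursor land in one locus); each locus is widened to 90 nt and
extended by 10 nt flanks. The most abundant tag is the candidate
mature. Acceptance requires: mature 18–26 nt; window fold energy ≤ −18;
a star arm inferred from the fold (see below) within 35 nt; flanks
≥ 10 nt; and ≥ 75% of mature bases paired in the best mature:star
duplex.

Star inference: in an antiparallel duplex, `partner(b) + (b − ms)` is
constant over the helix, so the median of that offset across paired
mature bases identifies the register while ignoring stray pairs the
global fold may form with flanking sequence (taking the raw min/max of
partner positions instead produces absurd star intervals whenever two
or three mature bases pair a flank micro-helix). The star is the
mature-length interval at that register plus a 2-nt 3' overhang. The
pairing criterion is evaluated on the mature:star intermolecular
duplex, for the same robustness reason.

The pseudo-hairpin filter discards a candidate when its fold energy is
above −20 kcal/mol or its randomization p-value (1000 shuffles)
exceeds 0.05 — the discard reading of the rule, since keeping
high-energy hairpins would invert the filter's purpose. The test is
applied to the precursor proper (mature + loop + star with 10 nt of
context), not the padded 110-nt excision window: a window carrying
~50 nt of arbitrary flank folds well after shuffling simply because it
is long, which would sink genuine hairpins.

Status calls: *known* for an exact same-species match or an end-shift
of ≤ 2 nt of one (isomiRs collapse to the reference miRNA); *PS* within
4 edits of a foreign-species mature (4 being the largest edit observed
among conserved novel calls in the motivating study), with the edit
summarized in the "1nt sub / 2nt delete" style; *PC* otherwise. Edit
distances and alignments come from edlib.

Read-class profiling assigns each tag the class it maximally overlaps:
arm when > 20% of the read lies on a mature/star arm (larger overlap
wins, ties to 5p), loop when ≥ 80% of the read lies between the arms,
moRNA5/moRNA3 when ≥ 80% lies outside both arms between a precursor
end and the adjacent arm with a gap ≤ 2 nt, else other. "Both arms
observed" requires ≥ 1 read per arm, with no ratio threshold.
Candidates sharing a mature sequence are copies of one precursor and
collapse to one record; isomiRs (5' shift ≤ 1 nt, 3' shift ≤ 2 nt from
the dominant tag) pool their counts into it.

## Annotation

Clusters: single-linkage chaining of same-chromosome loci whose nearest
ends are strictly < 10 kb apart, strand-agnostic; singletons are not
reported. Families: identical 7-nt seed at mature positions 2–8
(1-based), ≥ 2 members; the 5p and 3p products of one precursor fall
into different families whenever their seeds differ. Copy numbers
histogram loci per distinct precursor, and the locus total always
reconciles with the raw count. Chromosome densities are loci per Mbp,
rounded half-up to two decimals; top-n abundance shares to one decimal.

## Target prediction

A site is a UTR 7-mer exactly Watson–Crick complementary (no wobble —
"perfect seed match" means perfect) to miRNA positions 2–8. Each site
is scored by the duplex energy of the full miRNA against the site ± 15
nt of context (an RNAhybrid-like local hybridization window,
configurable) and accepted at ≤ −25 kcal/mol. The reporter-construct
helper returns the wild-type insert, the deletion variant and the
deleted length, and the arithmetic always reconciles. The shipped
IGF-1R 3'UTR fragments behave as in the originating experiment: one
site per motif in the 104-nt wild type, none after the 12-nt deletion.

## The synthetic-data generator

`simulate` emulates the structures the pipeline must detect. A
precursor is a 20–24 nt arm, an 8–15 nt loop, and a near-reverse-
complement arm carrying 1–3 interior substitutions ≥ 5 nt apart, placed
with ≥ 25 nt of genomic context. Constraints and why they exist:

* **1–3 mismatches, spread out.** Zero mismatches makes a perfect
  inverted repeat — every arm read would map to both strands of its own
  locus, which no real pre-miRNA does; clustered mismatches leave
  isolated single pairs the duplex model rightly refuses, dropping
  below the 75% pairing criterion.
* **Mature GC ≤ 0.55.** Dinucleotide-preserving shuffles keep CG
  doublets, so a CG-rich stem re-folds well after shuffling and the
  randomization p-value loses its margin; real mature miRNAs sit in
  this GC range anyway.
* **Re-checks.** Each sampled hairpin is re-folded (energy must clear
  both the −18 and −20 cutoffs), its mature:star duplex must pair ≥ 80%
  of the mature, and a 99-shuffle randomization of the flank-padded
  hairpin must give p ≤ 0.02 — so planted precursors satisfy the
  discovery criteria by construction, which is the generator's contract.

Reads: per-precursor abundances are lognormal; the dominant arm
outnumbers the star 10:1; 5% of a precursor's budget is loop-derived
(only where the loop can host ≥ 80% of an 18-nt read), 4%/3% are
moRNA5/moRNA3 abutting the precursor ends with 0–2 nt gaps, and 15% of
all reads are exact substrings of the labeled synthetic ncRNA library.
isomiRs shift the 3' end by ±1–2 nt and the 5' end by ≤ 1 nt only when
the seed survives, at probability 0.25 by default. Multi-copy
precursors are exact duplicates at distinct loci; clustered loci are
placed 1–8 kb apart and everything else > 10 kb apart, so the planted
cluster plan is the unique correct answer. The per-class abundance
mix is a modeling choice — no published per-class distributions exist
for this material.

What the generator does **not** emulate: sequencing errors, adaptor
remnants, quality-score structure, expression noise between biological
replicates, repeat-derived multi-mapping ambiguity, or genome-scale
contamination diversity. Passing the recovery tests therefore shows the
rules are implemented correctly and are mutually consistent, not that
the pipeline would reach the same sensitivity on a real library.

## Problem sizes and determinism

The recovery tests and the acceptance script use 20 precursors and
50,000 reads per seed (seeds 1–5), with zero isomiR noise — the stated
measurement condition for read-class accuracy; recall and precision
held equally with the default isomiR rate in development runs. Every
stochastic step takes an explicit seed: the same seed reproduces the
genome bytes, the read set, the shuffle sequence and therefore every
downstream number. The thermodynamic DP is JIT-compiled (numba), making
a 110-nt fold ≈ 2 ms and a 1000-shuffle randomization of one candidate
a couple of seconds.

## Known limitations

* The energy scale is model-relative: −18 kcal/mol here is not
  −18 kcal/mol in Mfold, and no mapping between the scales is
  attempted.
* The pseudo-hairpin step is a randomization test on MFE only, not a
  trained classifier over structural features.
* Exact mapping cannot place reads carrying sequencing errors; at desk
  scale this is by design.
* One report table in the motivating study is internally inconsistent
  in its per-row arithmetic; only column-wise additivity
  (known + novel = total) is asserted anywhere in this package.
* Multi-hit reporting policy of the original aligner is unknown; this
  package reports all loci and flags tags above `max_hits`.
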