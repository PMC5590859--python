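# Methods

## The repeat model

A locus is modelled over a *motif family*: a set of distinct DNA 3-mers
(default {CAG, CAT, CAA}). A *repeat architecture* is an ordered list of
blocks, each a run of units attributed to one motif; a unit is either an
exact copy of its block's motif or a *variant* — a 3-mer at Hamming
distance 1 from the motif of an adjacent exact unit (e.g. CCG inside a CAG
run, CCA inside a CAA run). The parse is lossless: concatenating the unit
texts reproduces the source subsequence exactly, so no information is
discarded relative to the raw sequence.

### Decomposition objective

Published figures of such loci are colour-codings made by eye; to make the
parse reproducible we define it as an optimisation. Among all windows of
the input whose length is a multiple of 3 and whose end units are exact
family motifs, choose the one that lexicographically maximises

1. number of exact-match units (variants score 0),
2. −(number of blocks),
3. window length,

with ties broken by the leftmost window, and a variant compatible with
both neighbours attributed to the preceding block. Variant units are
admitted only between exact units, never adjacent to another variant. A
window qualifies only if it contains ≥ `min_run` *consecutive* exact units
of a single motif (default 3 for parsing isolated locus sequences; the
genome scan uses its own seed threshold, below). Inputs with no qualifying
window raise a distinct "no repeat found" signal, separate from the
malformed-input error for non-DNA characters.

The implementation is an O(n²) incremental window sweep; its correctness
is checked against an exhaustive brute-force enumeration of all phases,
windows and unit labellings on every input up to 30 nt (property-based and
seeded sampling).

### Consensus notation

Architectures serialise to a compact grammar: `(MOTIF)COUNT` for exact
runs, `[UNIT]` for a single variant placed between its neighbours, no
whitespace — e.g. `(CAG)2[CCG](CAG)1(CAT)3`. Counts must be ≥ 1. The
canonical form merges adjacent same-motif runs; parsing and serialising
are mutually inverse on canonical forms.

## Translation

Exonic repeats are translated unit-by-unit under the standard genetic
code; for the default family this yields glutamine (CAG/CAA), histidine
(CAT) and proline (CCG/CCA — the variant units). The reading frame comes
from annotation: for a locus inside a CDS feature the frame is derived
from the GFF3 phase column (`(offset_into_CDS − phase) mod 3`, computed on
the coding strand). A repeat whose units straddle codon boundaries raises
a frame error carrying all three candidate translations, since without
transcript evidence the true frame of an un-annotated sequence cannot be
fixed. Peptide comparisons reuse the unit-level codon alignment, so
residue classes (same / Q↔H swap / indel / other) are symmetric.

## Genome scan

Both strands of every contig are scanned in all three phases. A *seed* is
a run of ≥ `min_seed` consecutive exact units of one family motif; the
default of 5 mirrors the (X)₅-style query repeats conventionally used to
find such loci by sequence search. Around each seed the locus is extended across further
family units and across gaps of ≤ 1 interrupting unit (so single CCG/CCA
interruptions do not split a composite locus), then re-decomposed so the
reported span is maximal and lossless. Exonic loci are reported in coding
orientation with gene id, 5′→3′ exon index and frame; coordinates are
0-based half-open internally and GFF3 1-based inclusive on disk. A CDS
without a phase triggers a warning and a frame-unknown locus.

In-silico PCR is exact-match by design (the laboratory primers are
locus-specific): a product starts with the forward primer on one strand
and ends with the reverse complement of the reverse primer downstream on
the same strand, within `max_len`. Hybrid genomes, which carry two
homeologous contigs, yield one amplicon per contig. Degenerate or
mismatch-tolerant priming is out of scope.

Taxonomic specificity takes an ortholog-group × species presence matrix
(orthology is an input, not inferred) and an ordered, strictly nested
taxonomy (e.g. genus ⊂ family ⊂ class). Each group is labelled with the
smallest taxon containing every species where the repeat is present;
groups with no presence in the focal (smallest) taxon are labelled
`absent-in-focal`. The rule is monotone: adding a presence can only widen
a label.

## Architecture distance, trees, ecotypes, parentage

The distance between two architectures is the cost of a global alignment
over unit symbols: match 0, substitution = nucleotide Hamming distance
between the 3-mers divided by 3, indel 1. One slippage event (gain/loss of
a unit) therefore costs 1 and one intra-unit SNP costs 1/3, so run-length
changes dominate over point mutations — matching how the two signals are
read in practice. The dynamic program works in integer thirds, so the
metric axioms hold exactly (verified by property tests against a recursive
brute-force aligner). Distances are computed on the repeat window only;
flanking sequence is deliberately excluded because it is highly conserved
across strains and carries little signal.

Trees are built by standard neighbor joining (via scikit-bio) from the
pairwise distance matrix; negative branch lengths are clamped to zero and
branch lengths written to 6 decimals, without support values. On
tree-additive inputs NJ provably recovers the generating topology, which
the tests exercise on random 4- and 5-leaf trees with branch lengths
≥ 0.1. This distance + NJ substitute is not expected to reproduce a
maximum-likelihood analysis of full flanking alignments numerically; it is
a transparent, assumption-light replacement.

Ecotype grouping keys strains either on the multiset of allele lengths
(what fragment analysis sees) or on exact consensus notations, which
splits same-length alleles that differ by an internal SNP. Parentage
assignment computes architecture distances from each hybrid allele to each
candidate parent; when allele and parent counts match, the optimal
one-to-one matching (Hungarian algorithm) is used, otherwise each allele
takes its nearest parent. An allele whose margin (second-best minus best
distance) is below 1/3 — less than one SNP of evidence — is flagged
ambiguous rather than assigned.

## Synthetic data

The generator emulates the study conditions: two parent species with
paper-patterned default alleles —
small `(CAG)5(CAA)1(CAG)3(CAA)1(CAG)2(CAT)2(CAA)2` (a CAG region
interspersed with CAA, then short CAT/CAA runs) and large
`(CAG)12(CAT)2(CAA)1(CAT)1(CAA)3` (a long CAG run with a mixed CAT/CAA
tail) — each placed, in frame, wholly inside exon 3 of a three-exon gene
with correct GFF3 CDS phases. Flanks, introns and the two unique 20-nt
primer sites are generated once per configuration seed and shared by all
species, emulating the conserved flanking sequence of the real locus;
random segments are rejected if they contain consecutive family units, and
a skeleton is accepted only if the repeat-free assembly contains no
seed-length run on either strand and the primers form exactly one product.
TTT buffers insulate the planted repeat so its scanned span equals the
truth span exactly.

Ten hybrid strains in four ecotypes (sizes 5, 3, 1, 1) carry both parental
contigs; ecotypes differ by fixed run-length offsets of the first CAG
block ((0, 0, +4, 0) on the small allele, (0, −4, −2, +1) on the large),
giving four distinct allele-size pairs with the small allele conserved
except in ecotype 3. One ecotype-1 strain optionally carries a CAA→CAG SNP
in its large allele — same length, different architecture — so
architecture-based grouping separates it while size-based grouping cannot.

Mutation follows a stepwise model: slippage events are
Poisson(λs × units × t) with step ±k units (sign equiprobable, k geometric
with p = 0.5, blocks floored at one unit); substitutions are
Poisson(λm × 3 × units × t) at uniform positions; slippage is applied
before substitution, and the result is re-canonicalised by decomposition.
Defaults λs = 0.02, λm = 0.002 per branch-length unit give 0–3 slippage
and 0–2 substitution events per locus on a branch of length 1 — resembling
observed inter-strain differences; none of these rates is an estimate of a
real mutation process. The ±1 floor makes very long branches drift
slightly upward in length; within the simulated regime the drift is well
below one unit (checked by Monte-Carlo test).

What the generator does **not** emulate: genome-scale content (one gene
neighbourhood per contig), intron/exon evolution, primer-site mutation,
orthology, and realistic ORF content outside the repeat (the host gene's
codons are schematic). Passing tests therefore demonstrate correctness of
the algorithms under the stated repeat model, not robustness to features
of real genomes such as near-duplicate loci or degenerate primer sites.

## Problem sizes and determinism

Test and acceptance runs use deliberately small problems — 10-kb random
genomes, ≤ 30-nt oracle inputs, 60 parentage replicates, 4–5-leaf trees —
sized so the full suite completes in seconds while each check still has
discriminating power (e.g. the parentage simulation's binomial width at 60
replicates comfortably separates the ≥ 90% criterion from chance). Every
random draw flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations produce
byte-identical outputs, and pipeline TSVs embed the tool version and a
configuration hash rather than timestamps so reruns diff clean.

## Known limitations

- The decomposition objective is a formalisation of a visual convention;
  other tie-breaking choices are defensible. It is deterministic and
  oracle-verified, but not the only possible reading.
- Variant tolerance is fixed at Hamming distance 1 and single, isolated
  interruptions; heavily degraded repeats parse as shorter windows.
- The motif length is fixed at 3; there is no generalized period
  detection.
- Exact-match PCR means a single primer-site mismatch drops an allele,
  unlike laboratory PCR.
- NJ on the unit distance is a phenetic summary, not a likelihood-based
  phylogeny.
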