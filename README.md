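# ssrarch

Architecture-aware analysis of exonic tri-nucleotide simple-sequence
repeats (SSRs).

Compound microsatellites such as the fungal B10 locus are widely used to
genotype *Epichloë* grass endophytes, yet the marker is usually read as a
fragment length alone. The locus is in fact a succession of related
tri-nucleotide motif runs — (CAG)n(CAT)n(CAA)n, occasionally interrupted by
point-mutated units such as CCG or CCA — sitting inside an exon, where every
unit is a codon (CAG/CAA → Q, CAT → H, CCG/CCA → P). Two alleles of
identical length can therefore carry entirely different internal
structures, and that structure carries phylogenetic signal that length
cannot. `ssrarch` makes the structure first-class:

- **`repeat_core`** parses a nucleotide sequence into its repeat
  *architecture* — an ordered list of motif-run blocks with interspersed
  single variant units — and serialises it as consensus notation, e.g.
  `(CAG)2[CCG](CAG)1(CAT)5`. The parse is an explicit optimisation:
  lexicographically maximise (exact-match units, −block count, window
  length) over all phases and windows, with SNP-tolerant variant units
  admitted only between exact units at Hamming distance 1 from an adjacent
  block's motif.
- **`peptide_view`** translates architectures in coding frame and compares
  the encoded polyglutamine/polyhistidine peptides unit by unit.
- **`genome_scan`** finds exonic repeat loci across an annotated genome
  (seeded by ≥ 5 consecutive exact units, mirroring (X)₅-style queries),
  extracts alleles by exact-match in-silico PCR, and labels ortholog
  groups with the smallest taxonomic group containing every species where
  the repeat is present.
- **`comparative`** defines a unit-level alignment distance (one slippage
  event costs 1, one intra-unit SNP costs 1/3), builds distance matrices
  and neighbor-joining trees, groups strains into ecotypes by allele size
  or architecture, and assigns each allele of an interspecific hybrid to
  its closest ancestral parent.
- **`synthetic_data`** simulates the whole study system — two diverged
  parent species each carrying the repeat in the third exon of a
  three-exon gene, plus hybrid strains carrying one allele from each
  parent — under a stepwise slippage + substitution model, with full truth
  tables for validation.

Intended users: researchers working with compound SSR markers in fungi (or
any taxon) who want to genotype by repeat structure rather than fragment
size, and to resolve hybrid parentage from homeologous alleles.

## Worked example

Decompose a repeat with a point-mutated unit:

```sh
$ ssrarch decompose CAGCAGCCGCAGCATCATCATCATCAT
source_id  phase  span_start  span_end  notation                 n_blocks  n_units  n_variants
seq1       0      0           27        (CAG)2[CCG](CAG)1(CAT)5  2         9        1
```

The 27-nt input is parsed as a CAG block of 4 units — one of them the
variant `[CCG]`, a single SNP away from CAG — followed by a CAT block of 5;
`phase 0` and span `[0, 27)` locate the window on the input.

Compare a small (typhina-like) and large (bromicola-like) allele:

```python
from ssrarch import parse_notation, translate_architecture, align_units, diff

small = parse_notation("(CAG)5(CAA)1(CAG)3(CAA)1(CAG)2(CAT)2(CAA)2")
large = parse_notation("(CAG)12(CAT)2(CAA)1(CAT)1(CAA)3")
translate_architecture(small).aa_string   # 'QQQQQQQQQQQQHHQQ'
translate_architecture(large).aa_string   # 'QQQQQQQQQQQQHHQHQQQ'
align_units(small, large).distance        # 3.6666666666666665
diff(small, large).net                    # {'CAA': 0, 'CAG': 2, 'CAT': 1}
```

Both alleles encode a glutamine repeat with a histidine core, but their
architectures differ by 3⅔ units of alignment distance and a net gain of
two CAG and one CAT unit — structure that a fragment size would hide.

Run the whole pipeline on a simulated dataset (2 parents, 10 hybrid
strains in 4 ecotypes):

```sh
ssrarch run-all --seed 5 --out results/demo
```

writes eight report files (`loci.tsv`, `architectures.tsv`,
`peptides.tsv`, `amplicons.tsv`, `distances.tsv`, `tree.nwk`,
`assignments.tsv`, `ecotypes.tsv`), each TSV stamped with the tool version
and configuration hash; a rerun with the same seed is byte-identical.

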