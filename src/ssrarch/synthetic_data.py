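"""Synthetic genomes, hybrids and truth tables for end-to-end testing.

The generator emulates the study system: each parent species carries a
single-copy, three-block tri-nucleotide repeat — e.g. (CAG)n(CAT)n(CAA)n
with occasional single-unit interruptions — inside the third exon of a
three-exon gene, flanked by conserved primer sites; an interspecific hybrid
strain carries both parental copies (one allele per subgenome).  Repeats
evolve by stepwise slippage (±k units, k geometric, sign equiprobable) and
point substitution, both Poisson processes along branch lengths.  A truth
table records every planted locus, the true parent of every hybrid allele,
and every strain's ecotype, so scans, in-silico PCR, ecotype grouping and
parentage assignment can all be checked against ground truth.

All randomness flows from a single integer seed; identical configurations
produce byte-identical FASTA/GFF3/TSV outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .genome_scan import _revcomp, in_silico_pcr
from .repeat_core import (
    MotifFamily,
    NoRepeatFoundError,
    RepeatArchitecture,
    decompose,
    parse_notation,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "ParentGenome",
    "evolve_architecture",
    "apply_slippage",
    "apply_substitution",
    "build_parent_genome",
    "build_hybrid",
    "simulate",
]

# paper-patterned default parent alleles: the small allele is a CAG run
# interspersed with single CAA units plus short CAT/CAA runs; the large
# allele is a long CAG run followed by a mixed CAT/CAA tail
DEFAULT_PARENT_ARCHS = {
    "typhina_like": "(CAG)5(CAA)1(CAG)3(CAA)1(CAG)2(CAT)2(CAA)2",
    "bromicola_like": "(CAG)12(CAT)2(CAA)1(CAT)1(CAA)3",
}

# per-ecotype deterministic run-length offsets applied to the first CAG
# block of each parental allele; chosen so the four ecotypes have four
# distinct allele-size pairs with the small allele conserved except in
# ecotype 3 (patterned on the published allele table)
ECOTYPE_SMALL_OFFSETS = (0, 0, 4, 0)
ECOTYPE_LARGE_OFFSETS = (0, -4, -2, 1)


class SimConfig(BaseModel):
    """Configuration of one synthetic dataset.

    Rates are per unit (slippage) or per site (substitution) per unit of
    branch length; defaults give 0–3 slippage and 0–2 substitution events
    per locus on a branch of length 1, resembling observed inter-strain
    differences.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    family: tuple[str, ...] = ("CAG", "CAT", "CAA")
    ancestral: str = "(CAG)8(CAT)5(CAA)4"
    parent_archs: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_PARENT_ARCHS)
    )
    slippage_rate: float = Field(0.02, ge=0)
    substitution_rate: float = Field(0.002, ge=0)
    parent_branch_length: float = Field(0.0, ge=0)
    post_hyb_branch_length: float = Field(0.0, ge=0)
    n_hybrid_strains: int = Field(10, ge=1)
    ecotype_sizes: tuple[int, ...] = (5, 3, 1, 1)
    ecotype1_snp_strain: bool = True
    flank_len: int = Field(300, ge=60)
    intron_len: int = Field(60, ge=10)
    exon1_codons: int = Field(30, ge=2)
    exon2_codons: int = Field(33, ge=2)
    exon3_pad_codons: int = Field(12, ge=4)
    primer_len: int = Field(20, ge=12)
    scan_min_seed: int = Field(5, ge=3)

    @property
    def motif_family(self) -> MotifFamily:
        return MotifFamily(self.family)


@dataclass(frozen=True)
class LocusTruth:
    species_id: str
    contig: str
    span: tuple[int, int]
    notation: str
    frame: int
    gene_id: str
    exon_index: int


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    loci: dict[str, LocusTruth]  # contig -> planted locus
    allele_parents: dict[tuple[str, str], str]  # (strain, contig) -> parent species
    ecotypes: dict[str, int]  # strain -> ecotype id (1-based)
    primers: tuple[str, str]


# ---------------------------------------------------------------------------
# mutation model
# ---------------------------------------------------------------------------


def apply_slippage(
    arch: RepeatArchitecture, block_index: int, delta: int, min_run: int = 3
) -> RepeatArchitecture:
    """Add (delta > 0) or remove (delta < 0) units at the end of one block.

    Blocks are floored at one unit.  The result is re-canonicalised, so the
    span always starts at 0 of the rebuilt sequence.
    """
    blocks = [list(bl.units) for bl in arch.blocks]
    motif = arch.blocks[block_index].motif
    units = blocks[block_index]
    if delta >= 0:
        texts = [u.text for u in units] + [motif] * delta
    else:
        keep = max(1, len(units) + delta)
        texts = [u.text for u in units][:keep]
    blocks[block_index] = texts
    seq = "".join(
        "".join(t if isinstance(t, str) else t.text for t in bl) for bl in blocks
    )
    return decompose(seq, arch.family, min_run=min_run, source_id=arch.source_id)


def apply_substitution(
    arch: RepeatArchitecture, position: int, base: str, min_run: int = 3
) -> RepeatArchitecture:
    """Substitute one nucleotide of the repeat sequence and re-canonicalise.

    ``position`` indexes the concatenated unit texts.  If the substitution
    destroys the repeat (no qualifying window remains) the architecture is
    returned unchanged.
    """
    seq = arch.sequence
    if seq[position] == base:
        return arch
    new = seq[:position] + base + seq[position + 1 :]
    try:
        return decompose(new, arch.family, min_run=min_run, source_id=arch.source_id)
    except NoRepeatFoundError:
        return arch


def evolve_architecture(
    arch: RepeatArchitecture,
    branch_length: float,
    slippage_rate: float,
    substitution_rate: float,
    rng: np.random.Generator,
    min_run: int = 3,
) -> RepeatArchitecture:
    """Evolve a repeat along a branch by slippage then substitution.

    Slippage events are Poisson(slippage_rate × units × branch_length);
    each picks a uniform block and steps its length by ±k units (sign
    equiprobable, k geometric with p = 0.5), floored at one unit.
    Substitutions are Poisson(substitution_rate × 3 × units ×
    branch_length) at uniform positions.  The result is re-canonicalised;
    a branch of length 0 returns the architecture unchanged.
    """
    if branch_length == 0:
        return arch
    n_slip = rng.poisson(slippage_rate * arch.n_units * branch_length)
    for _ in range(n_slip):
        block = int(rng.integers(arch.n_blocks))
        k = int(rng.geometric(0.5))
        delta = k if rng.random() < 0.5 else -k
        try:
            arch = apply_slippage(arch, block, delta, min_run=min_run)
        except NoRepeatFoundError:
            pass  # contraction below the calling threshold: event rejected
    n_sub = rng.poisson(substitution_rate * 3 * arch.n_units * branch_length)
    for _ in range(n_sub):
        pos = int(rng.integers(3 * arch.n_units))
        old = arch.sequence[pos]
        base = str(rng.choice([b for b in "ACGT" if b != old]))
        arch = apply_substitution(arch, pos, base, min_run=min_run)
    return arch


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


@dataclass(frozen=True)
class _Skeleton:
    """Species-invariant gene neighbourhood; only the repeat varies."""

    flank_l: str
    exon1: str
    intron1: str
    exon2: str
    intron2: str
    e3_pre: str  # exon3 before the forward primer
    fwd: str
    noise1: str  # brings the repeat onto a codon boundary; ends with TTT
    e3_mid: str  # after the repeat, begins with TTT
    rev: str  # reverse primer (its reverse complement sits on the contig)
    e3_post: str
    flank_r: str

    def exon3(self, repeat_seq: str) -> str:
        return (
            self.e3_pre
            + self.fwd
            + self.noise1
            + repeat_seq
            + self.e3_mid
            + _revcomp(self.rev)
            + self.e3_post
        )

    def assemble(self, repeat_seq: str) -> tuple[str, tuple[int, int]]:
        """Full contig and the genomic span of the repeat."""
        pre = (
            self.flank_l
            + self.exon1
            + self.intron1
            + self.exon2
            + self.intron2
            + self.e3_pre
            + self.fwd
            + self.noise1
        )
        start = len(pre)
        contig = pre + repeat_seq + self.e3_mid + _revcomp(self.rev) + self.e3_post + self.flank_r
        return contig, (start, start + len(repeat_seq))


def _segment_clean(seq: str, family: MotifFamily) -> bool:
    """No two consecutive exact family units (either strand) in a segment."""
    for m in family:
        if m * 2 in seq or _revcomp(m) * 2 in seq:
            return False
    return True


def _clean_dna(rng: np.random.Generator, length: int, family: MotifFamily) -> str:
    for _ in range(200):
        seq = _random_dna(rng, length)
        if _segment_clean(seq, family):
            return seq
    raise RuntimeError("could not draw a repeat-free segment")  # pragma: no cover


def _make_skeleton(cfg: SimConfig, rng: np.random.Generator) -> _Skeleton:
    family = cfg.motif_family
    for _ in range(100):
        exon1 = "ATG" + _clean_dna(rng, 3 * cfg.exon1_codons - 3, family)
        exon2 = _clean_dna(rng, 3 * cfg.exon2_codons, family)
        e3_pre = _clean_dna(rng, 3 * cfg.exon3_pad_codons, family)
        fwd = _clean_dna(rng, cfg.primer_len, family)
        rev = _clean_dna(rng, cfg.primer_len, family)
        # pad to the next codon boundary so the repeat starts in frame;
        # the TTT buffers insulate the repeat from its neighbourhood
        cds_prefix = len(exon1) + len(exon2) + len(e3_pre) + len(fwd)
        noise = _clean_dna(rng, (-(cds_prefix + 3)) % 3, family)
        noise1 = noise + "TTT"
        e3_mid = "TTT" + _clean_dna(rng, 9, family)
        # close the CDS on a codon boundary with a stop
        cds_len_wo = (
            len(exon1)
            + len(exon2)
            + len(e3_pre)
            + len(fwd)
            + len(noise1)
            + len(e3_mid)
            + len(rev)
        )
        e3_post = _clean_dna(rng, (-cds_len_wo) % 3 + 6, family) + "TAA"
        intron1 = "GT" + _clean_dna(rng, cfg.intron_len - 4, family) + "AG"
        intron2 = "GT" + _clean_dna(rng, cfg.intron_len - 4, family) + "AG"
        flank_l = _clean_dna(rng, cfg.flank_len, family)
        flank_r = _clean_dna(rng, cfg.flank_len, family)
        sk = _Skeleton(
            flank_l,
            exon1,
            intron1,
            exon2,
            intron2,
            e3_pre,
            fwd,
            noise1,
            e3_mid,
            rev,
            e3_post,
            flank_r,
        )
        if _skeleton_valid(sk, cfg):
            return sk
    raise RuntimeError("could not build a valid gene skeleton")  # pragma: no cover


def _skeleton_valid(sk: _Skeleton, cfg: SimConfig) -> bool:
    family = cfg.motif_family
    contig, _ = sk.assemble("")
    # no spurious seed runs on either strand of the repeat-free assembly
    for m in family:
        if m * cfg.scan_min_seed in contig or _revcomp(m) * cfg.scan_min_seed in contig:
            return False
    # exactly one primer-delimited product, containing the planted repeat
    probe = parse_notation(cfg.ancestral, family).sequence
    contig, span = sk.assemble(probe)
    products = in_silico_pcr(
        {"probe": contig}, sk.fwd, sk.rev, max_len=len(contig)
    )
    if len(products) != 1:
        return False
    return products[0].span[0] < span[0] and span[1] < products[0].span[1]


@dataclass(frozen=True)
class ParentGenome:
    """One simulated species: a single contig carrying the repeat gene."""

    species_id: str
    contig_id: str
    sequence: str
    gff3: str
    arch: RepeatArchitecture
    truth: LocusTruth
    fwd_primer: str
    rev_primer: str

    def fasta_text(self) -> str:
        lines = [f">{self.contig_id}"]
        for i in range(0, len(self.sequence), 70):
            lines.append(self.sequence[i : i + 70])
        return "\n".join(lines) + "\n"


def _gff3_text(sk: _Skeleton, repeat_len: int, contig_id: str, gene_id: str) -> str:
    F = len(sk.flank_l)
    e1, i1, e2, i2 = len(sk.exon1), len(sk.intron1), len(sk.exon2), len(sk.intron2)
    e3 = len(sk.exon3("N" * repeat_len))
    # 1-based inclusive coordinates
    ex1 = (F + 1, F + e1)
    ex2 = (ex1[1] + i1 + 1, ex1[1] + i1 + e2)
    ex3 = (ex2[1] + i2 + 1, ex2[1] + i2 + e3)
    phase2 = (3 - e1 % 3) % 3
    phase3 = (3 - (e1 + e2) % 3) % 3
    rows = [
        "##gff-version 3",
        f"##sequence-region {contig_id} 1 {ex3[1] + len(sk.flank_r)}",
    ]

    def row(ftype, start, end, phase, attrs):
        return "\t".join(
            [contig_id, "ssrarch_sim", ftype, str(start), str(end), ".", "+", phase, attrs]
        )

    rows.append(row("gene", ex1[0], ex3[1], ".", f"ID={gene_id}"))
    rows.append(row("mRNA", ex1[0], ex3[1], ".", f"ID={gene_id}.t1;Parent={gene_id}"))
    for k, (s, e) in enumerate((ex1, ex2, ex3), start=1):
        rows.append(
            row("exon", s, e, ".", f"ID={gene_id}.t1.exon{k};Parent={gene_id}.t1")
        )
    for k, ((s, e), ph) in enumerate(
        zip((ex1, ex2, ex3), ("0", str(phase2), str(phase3))), start=1
    ):
        rows.append(
            row("CDS", s, e, ph, f"ID={gene_id}.t1.cds;Parent={gene_id}.t1")
        )
    return "\n".join(rows) + "\n"


def build_parent_genome(
    cfg: SimConfig,
    species_id: str,
    arch: RepeatArchitecture,
    skeleton: Optional[_Skeleton] = None,
    contig_id: Optional[str] = None,
) -> ParentGenome:
    """Assemble one species' contig + annotation around a repeat architecture.

    The gene neighbourhood (flanks, exons, introns, primer sites) is a
    deterministic function of the configuration seed alone, so it is
    identical — i.e. conserved — across all species built from one config;
    only the repeat differs.
    """
    if skeleton is None:
        skeleton = _make_skeleton(cfg, np.random.default_rng([cfg.seed, 0]))
    contig_id = contig_id or f"{species_id}_chr1"
    gene_id = f"{species_id}_g1"
    repeat_seq = arch.sequence
    sequence, span = skeleton.assemble(repeat_seq)
    placed = RepeatArchitecture(
        arch.blocks, arch.family, span[0] % 3, span, contig_id
    )
    truth = LocusTruth(
        species_id=species_id,
        contig=contig_id,
        span=span,
        notation=arch.notation,
        frame=0,
        gene_id=gene_id,
        exon_index=3,
    )
    return ParentGenome(
        species_id=species_id,
        contig_id=contig_id,
        sequence=sequence,
        gff3=_gff3_text(skeleton, len(repeat_seq), contig_id, gene_id),
        arch=placed,
        truth=truth,
        fwd_primer=skeleton.fwd,
        rev_primer=skeleton.rev,
    )


def build_hybrid(
    cfg: SimConfig,
    parent_a: ParentGenome,
    parent_b: ParentGenome,
    strain_id: str,
    allele_archs: Optional[dict[str, RepeatArchitecture]] = None,
    skeleton: Optional[_Skeleton] = None,
) -> tuple[dict[str, str], dict[tuple[str, str], str]]:
    """A hybrid strain: both parental contigs, renamed, with optional
    per-allele architecture overrides (e.g. post-hybridization mutation).

    Returns ``(contigs, allele_parents)`` where ``allele_parents`` maps
    ``(strain_id, contig_id)`` to the true parent species.
    """
    if (parent_a.fwd_primer, parent_a.rev_primer) != (
        parent_b.fwd_primer,
        parent_b.rev_primer,
    ):
        raise ValueError("parents do not share primer sites")
    if skeleton is None:
        skeleton = _make_skeleton(cfg, np.random.default_rng([cfg.seed, 0]))
    contigs: dict[str, str] = {}
    parents: dict[tuple[str, str], str] = {}
    for parent in (parent_a, parent_b):
        arch = (allele_archs or {}).get(parent.species_id, parent.arch)
        contig_id = f"{strain_id}_{parent.species_id}"
        sequence, _ = skeleton.assemble(arch.sequence)
        contigs[contig_id] = sequence
        parents[(strain_id, contig_id)] = parent.species_id
    return contigs, parents


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def _first_block_index(arch: RepeatArchitecture, motif: str) -> int:
    for i, bl in enumerate(arch.blocks):
        if bl.motif == motif:
            return i
    raise ValueError(f"no block with motif {motif}")


def _ecotype_alleles(
    cfg: SimConfig, small: RepeatArchitecture, large: RepeatArchitecture
) -> list[tuple[RepeatArchitecture, RepeatArchitecture]]:
    """Per-ecotype (small, large) allele architectures."""
    out = []
    n = len(cfg.ecotype_sizes)
    for e in range(n):
        ds = ECOTYPE_SMALL_OFFSETS[e % len(ECOTYPE_SMALL_OFFSETS)]
        dl = ECOTYPE_LARGE_OFFSETS[e % len(ECOTYPE_LARGE_OFFSETS)]
        s = apply_slippage(small, _first_block_index(small, "CAG"), ds) if ds else small
        l = apply_slippage(large, _first_block_index(large, "CAG"), dl) if dl else large
        out.append((s, l))
    return out


def _snp_variant(arch: RepeatArchitecture) -> RepeatArchitecture:
    """A CAA→CAG point change in the last CAA block (same length allele)."""
    seq = arch.sequence
    pos = seq.rfind("CAA")
    return apply_substitution(arch, pos + 2, "G")


def simulate(cfg: SimConfig, outdir: str | Path) -> SyntheticTruth:
    """Generate the full dataset: parent genomes, hybrid strains, primers and
    truth tables, written under ``outdir``.

    Layout: ``parents/<species>.fasta`` + ``.gff3``,
    ``hybrids/<strain>.fasta``, ``primers.tsv``, ``truth_loci.tsv``,
    ``truth_alleles.tsv``, ``truth_ecotypes.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "parents").mkdir(parents=True, exist_ok=True)
    (outdir / "hybrids").mkdir(parents=True, exist_ok=True)
    family = cfg.motif_family
    skeleton = _make_skeleton(cfg, np.random.default_rng([cfg.seed, 0]))

    species = sorted(cfg.parent_archs)
    if len(species) != 2:
        raise ValueError("the hybrid model needs exactly 2 parent species")
    genomes: dict[str, ParentGenome] = {}
    for k, sp in enumerate(species):
        arch = parse_notation(cfg.parent_archs[sp], family, source_id=sp)
        arch = evolve_architecture(
            arch,
            cfg.parent_branch_length,
            cfg.slippage_rate,
            cfg.substitution_rate,
            np.random.default_rng([cfg.seed, 1 + k]),
        )
        genomes[sp] = build_parent_genome(cfg, sp, arch, skeleton=skeleton)

    # order parents by allele length: small-allele donor first
    sp_small, sp_large = sorted(
        species, key=lambda s: (genomes[s].arch.n_units, s)
    )
    alleles = _ecotype_alleles(cfg, genomes[sp_small].arch, genomes[sp_large].arch)

    loci = {g.contig_id: g.truth for g in genomes.values()}
    allele_parents: dict[tuple[str, str], str] = {}
    ecotypes: dict[str, int] = {}
    strain_contigs: dict[str, dict[str, str]] = {}
    strain_no = 0
    for e, size in enumerate(cfg.ecotype_sizes):
        for rep in range(size):
            strain_no += 1
            strain = f"U{strain_no:02d}"
            ecotypes[strain] = e + 1
            small, large = alleles[e]
            if cfg.ecotype1_snp_strain and e == 0 and rep == 1:
                large = _snp_variant(large)
            overrides = {sp_small: small, sp_large: large}
            if cfg.post_hyb_branch_length > 0:
                rng = np.random.default_rng([cfg.seed, 100 + strain_no])
                overrides = {
                    sp: evolve_architecture(
                        a,
                        cfg.post_hyb_branch_length,
                        cfg.slippage_rate,
                        cfg.substitution_rate,
                        rng,
                    )
                    for sp, a in overrides.items()
                }
            contigs, parents = build_hybrid(
                cfg,
                genomes[sp_small],
                genomes[sp_large],
                strain,
                allele_archs=overrides,
                skeleton=skeleton,
            )
            strain_contigs[strain] = contigs
            allele_parents.update(parents)
            for contig_id, seq in contigs.items():
                sp = parents[(strain, contig_id)]
                arch = overrides[sp]
                _, span = skeleton.assemble(arch.sequence)
                loci[contig_id] = LocusTruth(
                    species_id=strain,
                    contig=contig_id,
                    span=span,
                    notation=arch.notation,
                    frame=0,
                    gene_id=f"{sp}_g1",
                    exon_index=3,
                )

    truth = SyntheticTruth(
        loci=loci,
        allele_parents=allele_parents,
        ecotypes=ecotypes,
        primers=(skeleton.fwd, skeleton.rev),
    )
    _write_dataset(cfg, outdir, genomes, strain_contigs, truth)
    return truth


def _write_fasta(path: Path, contigs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for cid in sorted(contigs):
            fh.write(f">{cid}\n")
            seq = contigs[cid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_dataset(cfg, outdir, genomes, strain_contigs, truth) -> None:
    for sp in sorted(genomes):
        g = genomes[sp]
        with open(outdir / "parents" / f"{sp}.fasta", "w") as fh:
            fh.write(g.fasta_text())
        with open(outdir / "parents" / f"{sp}.gff3", "w") as fh:
            fh.write(g.gff3)
    for strain in sorted(strain_contigs):
        _write_fasta(outdir / "hybrids" / f"{strain}.fasta", strain_contigs[strain])
    with open(outdir / "primers.tsv", "w") as fh:
        fh.write("locus\tfwd\trev\n")
        fh.write(f"B10_like\t{truth.primers[0]}\t{truth.primers[1]}\n")
    with open(outdir / "truth_loci.tsv", "w") as fh:
        fh.write("contig\tspecies\tstart\tend\tnotation\tframe\tgene\texon\n")
        for cid in sorted(truth.loci):
            t = truth.loci[cid]
            fh.write(
                f"{cid}\t{t.species_id}\t{t.span[0]}\t{t.span[1]}\t"
                f"{t.notation}\t{t.frame}\t{t.gene_id}\t{t.exon_index}\n"
            )
    with open(outdir / "truth_alleles.tsv", "w") as fh:
        fh.write("strain\tcontig\tparent\n")
        for (strain, cid) in sorted(truth.allele_parents):
            fh.write(f"{strain}\t{cid}\t{truth.allele_parents[(strain, cid)]}\n")
    with open(outdir / "truth_ecotypes.tsv", "w") as fh:
        fh.write("strain\tecotype\n")
        for strain in sorted(truth.ecotypes):
            fh.write(f"{strain}\t{truth.ecotypes[strain]}\n")
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg.model_dump(), fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
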