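"""Coding-frame translation of repeat architectures.

The B10-class repeats sit inside exons, so each tri-nucleotide unit is a
codon once the repeat is in frame: CAG/CAA encode glutamine (Q), CAT
histidine (H), and the point-mutated variant units CCG/CCA encode proline
(P).  This module translates an architecture under a coding context derived
from annotation (or supplied by the caller), and compares two peptide
repeats residue by residue via the unit-level alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from Bio.Data.CodonTable import standard_dna_table

from .repeat_core import RepeatArchitecture, unit_alignment

__all__ = [
    "CodingContext",
    "PeptideRepeat",
    "PeptideComparison",
    "FrameError",
    "translate_architecture",
    "translate_three_frames",
    "peptide_diff",
    "peptides_to_tsv",
]

_STOP = "*"


def _codon_to_aa(codon: str) -> str:
    table = standard_dna_table.forward_table
    return table.get(codon, _STOP)


@dataclass(frozen=True)
class CodingContext:
    """Where a repeat sits inside a coding sequence.

    ``frame_offset`` is the offset (0|1|2), in the repeat's source
    coordinate system, at which codons begin; the repeat is in frame when
    its span start is congruent to it modulo 3.
    """

    frame_offset: Literal[0, 1, 2] = 0
    strand: Literal["+", "-"] = "+"
    gene_id: str = ""
    exon_index: int = 1

    def __post_init__(self):
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.exon_index < 1:
            raise ValueError("exon_index is 1-based")


@dataclass(frozen=True)
class PeptideRepeat:
    """Translated repeat: residue string plus the per-unit codon→aa mapping."""

    aa_string: str
    unit_map: tuple[tuple[str, str], ...]  # (codon, amino acid) per unit

    def __post_init__(self):
        if len(self.aa_string) != len(self.unit_map):
            raise ValueError("one residue per translated codon")


class FrameError(ValueError):
    """The repeat units straddle codon boundaries under the given context.

    Carries the three candidate frame translations so a caller without
    annotation can inspect all of them.
    """

    def __init__(self, message: str, candidates: dict[int, str]):
        super().__init__(message)
        self.candidates = candidates


def translate_three_frames(seq: str) -> dict[int, str]:
    """Translate ``seq`` in each forward frame, dropping partial codons."""
    out = {}
    for f in range(3):
        codons = [seq[i : i + 3] for i in range(f, len(seq) - 2, 3)]
        out[f] = "".join(_codon_to_aa(c) for c in codons)
    return out


def translate_architecture(
    arch: RepeatArchitecture, ctx: CodingContext = CodingContext()
) -> PeptideRepeat:
    """Translate each repeat unit as a codon under the standard genetic code.

    The architecture must already be in coding orientation (a genome scan
    reports repeats that way).  Raises :class:`FrameError`, carrying all
    three candidate translations, when the span start is not congruent to
    the context's frame offset modulo 3.
    """
    if (arch.span[0] - ctx.frame_offset) % 3 != 0:
        raise FrameError(
            f"repeat at span {arch.span} is out of frame "
            f"(codon offset {ctx.frame_offset}); candidate translations attached",
            translate_three_frames(arch.sequence),
        )
    unit_map = tuple((u.text, _codon_to_aa(u.text)) for u in arch.units)
    return PeptideRepeat("".join(aa for _, aa in unit_map), unit_map)


_SWAP = frozenset({"Q", "H"})


@dataclass(frozen=True)
class PeptideComparison:
    """Unit-aligned residue comparison of two peptide repeats."""

    rows: tuple[tuple[Optional[str], Optional[str], str], ...]  # (aa_a, aa_b, class)
    counts: dict[str, int]

    CLASSES = ("same", "Q/H swap", "indel", "other")


def peptide_diff(a: PeptideRepeat, b: PeptideRepeat) -> PeptideComparison:
    """Compare two peptide repeats unit by unit.

    The residue pairing comes from the minimum-cost alignment of the
    underlying codons (substitution = Hamming/3, indel = 1), so it is
    symmetric: classes are {same, Q/H swap, indel, other}, where a swap is
    a glutamine↔histidine exchange — the signature consequence of the
    CAG/CAA ↔ CAT interconversions within these repeats.
    """
    ca = [codon for codon, _ in a.unit_map]
    cb = [codon for codon, _ in b.unit_map]
    _, pairs = unit_alignment(ca, cb)
    rows = []
    counts = dict.fromkeys(PeptideComparison.CLASSES, 0)
    for i, j in pairs:
        aa_a = a.aa_string[i] if i is not None else None
        aa_b = b.aa_string[j] if j is not None else None
        if aa_a is None or aa_b is None:
            cls = "indel"
        elif aa_a == aa_b:
            cls = "same"
        elif {aa_a, aa_b} == _SWAP:
            cls = "Q/H swap"
        else:
            cls = "other"
        counts[cls] += 1
        rows.append((aa_a, aa_b, cls))
    return PeptideComparison(tuple(rows), counts)


def peptides_to_tsv(
    entries: Iterable[tuple[str, CodingContext, RepeatArchitecture, PeptideRepeat]],
) -> str:
    """TSV of translated loci: (locus_id, gene_id, exon_index, frame, aa_string)."""
    lines = ["locus_id\tgene_id\texon_index\tframe\taa_string"]
    for locus_id, ctx, arch, pep in entries:
        lines.append(
            f"{locus_id}\t{ctx.gene_id}\t{ctx.exon_index}\t{ctx.frame_offset}\t{pep.aa_string}"
        )
    return "\n".join(lines) + "\n"
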