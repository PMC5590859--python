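"""Genome-wide discovery of exonic tri-nucleotide repeats, in-silico PCR and
taxonomic-specificity classification.

The scan finds every locus carrying ≥ ``min_seed`` consecutive exact units
of one family motif (mirroring (X)5-style query repeats), merges adjacent
motif runs separated by at most one interrupting unit into a single
composite locus, and annotates each locus with the gene, exon and CDS
reading frame it falls in.  Alleles are then extracted by exact-match
in-silico PCR with locus-specific primers, and ortholog-group
presence/absence across species is summarised into the smallest taxonomic
group containing every species where the repeat occurs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .repeat_core import (
    B10_FAMILY_MOTIFS,
    MotifFamily,
    NoRepeatFoundError,
    RepeatArchitecture,
    decompose,
)

__all__ = [
    "SSRLocus",
    "Amplicon",
    "PresenceMatrix",
    "TaxonomyConfig",
    "ScanError",
    "SpecificityConfigError",
    "load_fasta",
    "scan_genome",
    "in_silico_pcr",
    "classify_specificity",
    "loci_to_tsv",
    "amplicons_to_tsv",
]

GenomeLike = Union[str, Path, Mapping[str, str]]


class ScanError(Exception):
    """Genome/annotation inconsistency (e.g. contig mismatch)."""


class SpecificityConfigError(Exception):
    """A species in the presence matrix is missing from the taxonomy config."""


def load_fasta(genome: GenomeLike) -> dict[str, str]:
    """Read a FASTA file (or pass through a mapping) as ``{id: sequence}``."""
    if isinstance(genome, Mapping):
        return {k: str(v).upper() for k, v in genome.items()}
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")
    }


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SSRLocus:
    """A repeat located on a contig, with its gene/exon/frame context.

    ``span`` is 0-based half-open on the forward strand of the contig;
    ``strand`` is the orientation in which the repeat architecture reads as
    family motifs (the coding orientation for exonic loci); ``frame`` is 0
    when the repeat units coincide with codons, 1|2 when shifted, ``None``
    when unknown.
    """

    contig: str
    span: tuple[int, int]
    strand: str
    arch: RepeatArchitecture
    gene_id: Optional[str] = None
    exon_index: Optional[int] = None
    in_cds: bool = False
    frame: Optional[int] = None

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.span[0]}-{self.span[1]}({self.strand})"


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product: one allele at one locus in one strain."""

    strain_id: str
    locus_name: str
    sequence: str
    length: int
    arch: Optional[RepeatArchitecture]
    contig: str = ""
    span: tuple[int, int] = (0, 0)
    strand: str = "+"

    def __post_init__(self):
        if self.length != len(self.sequence):
            raise ValueError("length must equal |sequence|")


# ---------------------------------------------------------------------------
# repeat scan
# ---------------------------------------------------------------------------


def _find_candidate_regions(
    texts: list[bool | str],
    exact: list[bool],
    motifs: list[Optional[str]],
    min_seed: int,
    merge_gap: int,
) -> list[tuple[int, int]]:
    """Unit-index regions around seed runs of ≥ min_seed exact same-motif units.

    A region extends across exact family units and across gaps of at most
    ``merge_gap`` consecutive non-family units provided family units resume.
    """
    m = len(exact)
    regions = []
    # seed runs
    k = 0
    seeds = []
    while k < m:
        if exact[k]:
            start = k
            motif = motifs[k]
            while k < m and exact[k] and motifs[k] == motif:
                k += 1
            if k - start >= min_seed:
                seeds.append((start, k - 1))
        else:
            k += 1
    for s0, s1 in seeds:
        lo, hi = s0, s1
        # extend right
        k = hi + 1
        while k < m:
            if exact[k]:
                hi = k
                k += 1
            else:
                gap_end = k
                while gap_end < m and not exact[gap_end] and gap_end - k < merge_gap:
                    gap_end += 1
                if gap_end < m and exact[gap_end]:
                    hi = gap_end
                    k = gap_end + 1
                else:
                    break
        # extend left
        k = lo - 1
        while k >= 0:
            if exact[k]:
                lo = k
                k -= 1
            else:
                gap_end = k
                while gap_end >= 0 and not exact[gap_end] and k - gap_end < merge_gap:
                    gap_end -= 1
                if gap_end >= 0 and exact[gap_end]:
                    lo = gap_end
                    k = gap_end - 1
                else:
                    break
        regions.append((lo, hi))
    # merge overlapping regions
    regions.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in regions:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _scan_strand(
    seq: str, family: MotifFamily, min_seed: int, merge_gap: int
) -> list[tuple[int, int, RepeatArchitecture]]:
    """All loci on one orientation of a contig, as (start, end, arch) in that
    orientation's coordinates."""
    hits = []
    n = len(seq)
    for phase in range(3):
        m = (n - phase) // 3
        if m < min_seed:
            continue
        texts = [seq[phase + 3 * k : phase + 3 * k + 3] for k in range(m)]
        exact = [t in family for t in texts]
        motifs = [t if e else None for t, e in zip(texts, exact)]
        for lo, hi in _find_candidate_regions(texts, exact, motifs, min_seed, merge_gap):
            region_start = phase + 3 * lo
            region = seq[region_start : phase + 3 * (hi + 1)]
            try:
                arch = decompose(region, family, min_run=min_seed)
            except NoRepeatFoundError:
                continue
            start = region_start + arch.span[0]
            end = region_start + arch.span[1]
            arch = RepeatArchitecture(
                arch.blocks, arch.family, start % 3, (start, end), ""
            )
            hits.append((start, end, arch))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _exon_context(db, contig: str, start: int, end: int, strand: str):
    """(gene_id, exon_index, in_cds, frame, gene_strand) for a locus span."""
    genes = list(db.region(region=(contig, start + 1, end), featuretype="gene"))
    if not genes:
        return None, None, False, None, None
    gene = genes[0]
    exons = sorted(
        db.children(gene, featuretype="exon"), key=lambda f: f.start
    )
    if gene.strand == "-":
        exons = exons[::-1]  # exon index counted 5'→3' on the coding strand
    exon_index = None
    for idx, ex in enumerate(exons, start=1):
        if ex.start - 1 <= start and end <= ex.end:
            exon_index = idx
            break
    in_cds = False
    frame = None
    for cds in db.children(gene, featuretype="CDS"):
        if cds.start - 1 <= start and end <= cds.end:
            in_cds = True
            if cds.frame in ("0", "1", "2"):
                phase = int(cds.frame)
                if gene.strand == "-":
                    offset = cds.end - end
                else:
                    offset = start - (cds.start - 1)
                frame = (offset - phase) % 3
            else:
                warnings.warn(
                    f"CDS of {gene.id} lacks a phase; reporting frame-unknown locus",
                    stacklevel=2,
                )
            break
    return gene.id, exon_index, in_cds, frame, gene.strand


def scan_genome(
    genome: GenomeLike,
    annotation: Optional[Union[str, Path]] = None,
    family: MotifFamily | Iterable[str] = B10_FAMILY_MOTIFS,
    min_seed: int = 5,
    merge_gap: int = 1,
) -> list[SSRLocus]:
    """Find all family-motif repeat loci in a genome, annotated with gene context.

    Both strands are scanned; an exonic locus is reported in coding
    orientation, an intergenic one in forward orientation.  Loci are
    maximal: adjacent runs of family motifs separated by at most
    ``merge_gap`` interrupting units form a single composite locus.
    """
    if not isinstance(family, MotifFamily):
        family = MotifFamily(family)
    contigs = load_fasta(genome)

    db = None
    if annotation is not None:
        import gffutils

        db = gffutils.create_db(
            str(annotation),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        for f in db.all_features():
            if f.seqid not in contigs:
                raise ScanError(
                    f"annotation references contig {f.seqid!r} absent from FASTA"
                )

    loci: dict[tuple[str, int, int], SSRLocus] = {}
    for contig in sorted(contigs):
        seq = contigs[contig]
        L = len(seq)
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else _revcomp(seq)
            for s, e, arch in _scan_strand(oriented, family, min_seed, merge_gap):
                if strand == "+":
                    gstart, gend = s, e
                else:
                    gstart, gend = L - e, L - s
                key = (contig, gstart, gend)
                gene_id = exon_index = frame = None
                in_cds = False
                if db is not None:
                    gene_id, exon_index, in_cds, frame, gene_strand = _exon_context(
                        db, contig, gstart, gend, strand
                    )
                    if in_cds and gene_strand != strand:
                        # repeat motifs read on the opposite strand of the
                        # gene: not in coding orientation, frame unknowable
                        frame = None
                locus = SSRLocus(
                    contig=contig,
                    span=(gstart, gend),
                    strand=strand,
                    arch=arch,
                    gene_id=gene_id,
                    exon_index=exon_index,
                    in_cds=in_cds,
                    frame=frame,
                )
                # prefer the coding-orientation call when both strands hit
                if key not in loci or (in_cds and not loci[key].in_cds):
                    loci[key] = locus
    return [loci[k] for k in sorted(loci)]


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def in_silico_pcr(
    genome: GenomeLike,
    fwd: str,
    rev: str,
    max_len: int = 5000,
    strain_id: str = "",
    locus_name: str = "",
    family: Optional[MotifFamily | Iterable[str]] = None,
    min_run: int = 3,
) -> list[Amplicon]:
    """All products of an exact-match primer pair, one per template copy.

    A product starts with ``fwd`` on one strand and ends with the reverse
    complement of ``rev``; hybrids carrying two homeologous contigs yield
    one amplicon per contig.  Returns an empty list when no product forms.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 12 or len(rev) < 12:
        raise ValueError("primers must be at least 12 nt")
    if family is not None and not isinstance(family, MotifFamily):
        family = MotifFamily(family)
    contigs = load_fasta(genome)
    out: list[Amplicon] = []
    seen: set[tuple[str, int, int, str]] = set()
    for contig in sorted(contigs):
        seq = contigs[contig]
        L = len(seq)
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else _revcomp(seq)
            rev_site = _revcomp(rev)
            for i in _find_all(oriented, fwd):
                for j in _find_all(oriented, rev_site):
                    if j < i + len(fwd):
                        continue
                    end = j + len(rev)
                    if end - i > max_len:
                        continue
                    if strand == "+":
                        gspan = (i, end)
                    else:
                        gspan = (L - end, L - i)
                    key = (contig, *gspan, strand)
                    if key in seen:
                        continue
                    seen.add(key)
                    product = oriented[i:end]
                    arch = None
                    if family is not None:
                        try:
                            arch = decompose(product, family, min_run=min_run)
                        except NoRepeatFoundError:
                            arch = None
                    out.append(
                        Amplicon(
                            strain_id=strain_id,
                            locus_name=locus_name,
                            sequence=product,
                            length=len(product),
                            arch=arch,
                            contig=contig,
                            span=gspan,
                            strand=strand,
                        )
                    )
    out.sort(key=lambda a: (a.contig, a.span, a.strand))
    return out


# ---------------------------------------------------------------------------
# taxonomic specificity
# ---------------------------------------------------------------------------

ABSENT_IN_FOCAL = "absent-in-focal"


@dataclass(frozen=True)
class TaxonomyConfig:
    """Strictly nested, ordered taxonomy groups, smallest (focal) first.

    E.g. Epichloë ⊂ Clavicipitaceae ⊂ Sordariomycetes.
    """

    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("taxonomy needs at least one group")
        for (n1, s1), (n2, s2) in zip(self.groups, self.groups[1:]):
            if not (s1 < s2):
                raise ValueError(
                    f"group {n1!r} must be a strict subset of {n2!r}"
                )

    @property
    def focal(self) -> tuple[str, frozenset[str]]:
        return self.groups[0]

    @property
    def broadest(self) -> frozenset[str]:
        return self.groups[-1][1]

    @classmethod
    def from_dict(cls, data: Mapping) -> "TaxonomyConfig":
        return cls(
            tuple((g["name"], frozenset(g["species"])) for g in data["groups"])
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TaxonomyConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PresenceMatrix:
    """Ortholog-group × species repeat presence/absence."""

    table: pd.DataFrame  # bool, rows = ortholog groups, cols = species

    def __post_init__(self):
        object.__setattr__(self, "table", self.table.astype(bool))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, bool]], species: Iterable[str]
    ) -> "PresenceMatrix":
        """Build from (ortholog_group, species, present) triples."""
        species = list(species)
        df = pd.DataFrame(records, columns=["og", "species", "present"])
        table = df.pivot_table(
            index="og", columns="species", values="present", aggfunc="any"
        ).reindex(columns=species, fill_value=False)
        return cls(table)

    @property
    def ortholog_groups(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)


def classify_specificity(
    pm: PresenceMatrix, tc: TaxonomyConfig
) -> dict[str, str]:
    """Label each ortholog group with the smallest taxonomy group containing
    every species where its repeat is present.

    Groups with no presence in the focal (smallest) group are labelled
    ``"absent-in-focal"``.  Monotone: adding a presence outside the current
    label's group can only widen the label.
    """
    stray = set(pm.species) - set(tc.broadest)
    if stray:
        raise SpecificityConfigError(
            f"species not in any taxonomy group: {sorted(stray)}"
        )
    focal_name, focal_species = tc.focal
    labels: dict[str, str] = {}
    for og in pm.ortholog_groups:
        row = pm.table.loc[og]
        present = frozenset(row[row].index)
        if not (present & focal_species):
            labels[og] = ABSENT_IN_FOCAL
            continue
        for name, members in tc.groups:
            if present <= members:
                labels[og] = name
                break
    return labels


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def loci_to_tsv(loci: Iterable[SSRLocus], peptides: Optional[dict[str, str]] = None) -> str:
    """TSV of scanned loci; ``peptides`` optionally maps locus_id → aa string."""
    peptides = peptides or {}
    lines = ["contig\tstart\tend\tstrand\tgene\texon\tframe\tnotation\tpeptide"]
    fmt = lambda x: "." if x is None else str(x)  # noqa: E731
    for lc in loci:
        lines.append(
            "\t".join(
                [
                    lc.contig,
                    str(lc.span[0]),
                    str(lc.span[1]),
                    lc.strand,
                    fmt(lc.gene_id),
                    fmt(lc.exon_index),
                    fmt(lc.frame),
                    lc.arch.notation,
                    peptides.get(lc.locus_id, "."),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def amplicons_to_tsv(amps: Iterable[Amplicon]) -> str:
    lines = ["strain\tlocus\tcontig\tstart\tend\tstrand\tlength\tnotation"]
    for a in amps:
        lines.append(
            "\t".join(
                [
                    a.strain_id,
                    a.locus_name,
                    a.contig,
                    str(a.span[0]),
                    str(a.span[1]),
                    a.strand,
                    str(a.length),
                    a.arch.notation if a.arch is not None else ".",
                ]
            )
        )
    return "\n".join(lines) + "\n"
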