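"""Architecture-aware comparison of repeat alleles.

Length alone undersells these markers: two alleles of identical size can
carry entirely different motif-run structures.  This module defines a
unit-level alignment distance on repeat architectures (one slippage event
costs 1, one point substitution within a unit costs 1/3), builds pairwise
distance matrices and neighbor-joining trees from it, groups strains into
ecotypes by allele profile, and assigns each allele of an interspecific
hybrid to the ancestral parent whose allele it most resembles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genome_scan import Amplicon
from .repeat_core import FamilyMismatchError, RepeatArchitecture, unit_alignment

__all__ = [
    "AlignmentResult",
    "DistanceMatrix",
    "AllelePanel",
    "EcotypeGroup",
    "ParentAssignment",
    "align_units",
    "distance_matrix",
    "nj_tree",
    "group_ecotypes",
    "assign_parentage",
]

#: less than one point substitution of evidence → ambiguous parentage
TIE_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class AlignmentResult:
    """Unit-level global alignment of two architectures.

    ``cost_thirds`` is the exact integer cost in thirds of a unit
    (substitution = Hamming distance of the 3-mers, indel = 3);
    ``distance = cost_thirds / 3``.
    """

    cost_thirds: int
    pairs: tuple[tuple[Optional[int], Optional[int]], ...]

    @property
    def distance(self) -> float:
        return self.cost_thirds / 3.0


def align_units(a: RepeatArchitecture, b: RepeatArchitecture) -> AlignmentResult:
    """Align two architectures unit by unit and score their distance.

    Costs: exact unit match 0; unit substitution = nucleotide Hamming
    distance between the 3-mers / 3; unit indel 1.  A pure ±k run-length
    change therefore costs k, while a single SNP inside a unit costs 1/3,
    so length changes dominate over point mutations.
    """
    if a.family.motifs != b.family.motifs:
        raise FamilyMismatchError("architectures belong to different motif families")
    cost, pairs = unit_alignment(a.unit_texts(), b.unit_texts())
    return AlignmentResult(cost, tuple(pairs))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with ordered labels."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distances must be symmetric, nonnegative, zero-diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.ids.index(k) for k in pair)
        return float(self.values[i, j])

    def to_tsv(self) -> str:
        lines = ["id\t" + "\t".join(self.ids)]
        for i, lab in enumerate(self.ids):
            lines.append(
                lab + "\t" + "\t".join(f"{x:.6g}" for x in self.values[i])
            )
        return "\n".join(lines) + "\n"


def distance_matrix(
    archs: Sequence[tuple[str, RepeatArchitecture]]
) -> DistanceMatrix:
    """Pairwise unit-alignment distances among labelled architectures."""
    if len(archs) < 2:
        raise ValueError("need at least 2 architectures")
    labels = [lab for lab, _ in archs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in distance matrix input")
    n = len(archs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = align_units(archs[i][1], archs[j][1]).distance
    return DistanceMatrix(tuple(labels), d)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree from a distance matrix, as a newick string.

    Negative branch lengths are clamped to zero; branch lengths are written
    to 6 decimals; no support values.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    import skbio

    sk_dm = skbio.DistanceMatrix(dm.values, ids=list(dm.ids))
    tree = skbio.tree.nj(sk_dm, neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None:
            node.length = float(f"{node.length:.6f}")
    return str(tree).strip() + ("" if str(tree).strip().endswith(";") else ";")


# ---------------------------------------------------------------------------
# ecotype grouping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllelePanel:
    """Per-strain amplicon alleles at one or more loci, sorted by length.

    For a two-allele panel (one allele per parental subgenome of a hybrid)
    the sorted order gives the conventional "small"/"large" naming.
    """

    strain_id: str
    alleles: tuple[tuple[str, Amplicon], ...]  # (locus_name, amplicon)
    ecotype_label: Optional[str] = None

    def __post_init__(self):
        if any(a.length <= 0 for _, a in self.alleles):
            raise ValueError("allele sizes must be positive")
        ordered = tuple(sorted(self.alleles, key=lambda x: (x[1].length, x[0])))
        object.__setattr__(self, "alleles", ordered)

    def for_locus(self, locus: Optional[str] = None) -> tuple[Amplicon, ...]:
        return tuple(
            a for name, a in self.alleles if locus is None or name == locus
        )

    def allele_names(self, locus: Optional[str] = None) -> tuple[str, ...]:
        amps = self.for_locus(locus)
        if len(amps) == 2:
            return ("small", "large")
        return tuple(f"allele{i + 1}" for i in range(len(amps)))


@dataclass(frozen=True)
class EcotypeGroup:
    group_id: int
    key: tuple
    strain_ids: tuple[str, ...]


def group_ecotypes(
    panels: Sequence[AllelePanel],
    mode: Literal["by-size", "by-architecture"] = "by-size",
    locus: Optional[str] = None,
) -> list[EcotypeGroup]:
    """Group strains sharing an allele profile at a locus.

    ``by-size`` keys on the multiset of allele lengths (what a fragment
    analysis sees); ``by-architecture`` requires identical consensus
    notations, so a same-length allele carrying an internal SNP splits off.
    Groups are deterministic: ordered by smallest allele key, then by
    lexicographic smallest strain id.
    """
    keyed: dict[tuple, list[str]] = {}
    for panel in panels:
        amps = panel.for_locus(locus)
        if not amps:
            raise ValueError(f"panel {panel.strain_id} has no allele for locus")
        if mode == "by-size":
            key = tuple(sorted(a.length for a in amps))
        elif mode == "by-architecture":
            key = tuple(
                sorted(a.arch.notation if a.arch else a.sequence for a in amps)
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        keyed.setdefault(key, []).append(panel.strain_id)
    ordered = sorted(keyed.items(), key=lambda kv: (kv[0], sorted(kv[1])[0]))
    return [
        EcotypeGroup(i + 1, key, tuple(sorted(strains)))
        for i, (key, strains) in enumerate(ordered)
    ]


# ---------------------------------------------------------------------------
# parent assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParentAssignment:
    """Best ancestral-parent match for one hybrid allele."""

    allele_id: str
    parent_id: str
    distance: float
    margin: float  # distance(second-best parent) − distance(best parent)
    status: Literal["assigned", "ambiguous"]

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")


def _arch_of(x: Union[Amplicon, RepeatArchitecture]) -> RepeatArchitecture:
    if isinstance(x, RepeatArchitecture):
        return x
    if x.arch is None:
        raise ValueError(f"amplicon {x.strain_id}:{x.locus_name} has no architecture")
    return x.arch


def assign_parentage(
    hybrid: AllelePanel,
    parents: Sequence[tuple[str, Union[Amplicon, RepeatArchitecture]]],
    locus: Optional[str] = None,
    tie_threshold: float = TIE_THRESHOLD,
) -> list[ParentAssignment]:
    """Assign each hybrid allele to the closest candidate parent.

    Distances are unit-alignment distances on the repeat architectures.
    When the hybrid carries exactly as many alleles as there are candidate
    parents, the assignment is the optimal one-to-one matching (each parent
    used once, minimum total distance); otherwise each allele independently
    takes the argmin parent.  An allele whose margin — distance to the
    second-closest parent minus distance to the closest — is below
    ``tie_threshold`` is flagged ``ambiguous``.
    """
    if len(parents) < 2:
        raise ValueError("need at least 2 candidate parents")
    amps = hybrid.for_locus(locus)
    if not amps:
        raise ValueError("hybrid panel has no allele for locus")
    names = hybrid.allele_names(locus)
    parent_ids = [pid for pid, _ in parents]
    d = np.array(
        [
            [align_units(_arch_of(a), _arch_of(p)).distance for _, p in parents]
            for a in amps
        ]
    )
    if len(amps) == len(parents):
        rows, cols = linear_sum_assignment(d)
        chosen = dict(zip(rows.tolist(), cols.tolist()))
    else:
        chosen = {i: int(np.argmin(d[i])) for i in range(len(amps))}
    out = []
    for i, name in enumerate(names):
        j = chosen[i]
        best = float(d[i, j])
        others = np.delete(d[i], j)
        margin = float(others.min() - best) if others.size else 0.0
        margin = max(margin, 0.0)
        status = "ambiguous" if margin < tie_threshold else "assigned"
        out.append(
            ParentAssignment(
                allele_id=f"{hybrid.strain_id}:{name}",
                parent_id=parent_ids[j],
                distance=best,
                margin=margin,
                status=status,
            )
        )
    return out
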