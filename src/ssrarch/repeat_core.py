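"""Decomposition of tri-nucleotide simple-sequence repeats into motif-run architectures.

A compound SSR locus such as the *Epichloë* B10 repeat is a succession of
runs of related tri-nucleotide motifs (CAG, CAT, CAA) occasionally
interrupted by single point-mutated units (CCG, CCA).  This module parses a
nucleotide string into that structure — an ordered list of motif-run blocks
with interspersed single "variant" units — renders and parses a compact
consensus notation such as ``(CAG)2[CCG](CAG)1(CAT)3``, and diffs two
architectures unit by unit.

The parse is defined as an optimisation: among all in-phase windows of the
input whose endpoints are exact motif units, choose the one that
lexicographically maximises (number of exact-match units, −number of blocks,
window length).  A variant unit is admitted only between two exact units and
only when it is at Hamming distance 1 from the motif of an adjacent exact
unit; two variants may never be adjacent.  A window only qualifies as a
repeat if it contains at least ``min_run`` consecutive exact units of a
single motif (default 3).  Ties are broken by the leftmost window, and an
ambiguous variant (compatible with both neighbours) is attributed to the
preceding block.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "MotifFamily",
    "RepeatUnit",
    "RepeatBlock",
    "RepeatArchitecture",
    "ArchitectureDiff",
    "RepeatError",
    "MalformedSequenceError",
    "NoRepeatFoundError",
    "NotationParseError",
    "FamilyMismatchError",
    "decompose",
    "to_notation",
    "parse_notation",
    "notation_to_sequence",
    "diff",
    "hamming",
    "unit_alignment",
    "architectures_to_tsv",
]

DNA_ALPHABET = frozenset("ACGT")

# default family of the B10-class loci
B10_FAMILY_MOTIFS = ("CAG", "CAT", "CAA")


class RepeatError(Exception):
    """Base class for repeat-architecture errors."""


class MalformedSequenceError(RepeatError):
    """The input is not an uppercase DNA string of sufficient length."""


class NoRepeatFoundError(RepeatError):
    """No window of the input qualifies as a repeat under the family."""


class NotationParseError(RepeatError):
    """A consensus-notation string does not conform to the grammar."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class FamilyMismatchError(RepeatError):
    """Two architectures built over different motif families were combined."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class MotifFamily:
    """A set of distinct tri-nucleotide motifs composing one locus class."""

    motifs: frozenset[str]

    def __init__(self, motifs: Iterable[str] = B10_FAMILY_MOTIFS):
        motifs = frozenset(motifs)
        if not motifs:
            raise ValueError("motif family must be non-empty")
        for m in motifs:
            if len(m) != 3 or set(m) - DNA_ALPHABET:
                raise ValueError(f"motif {m!r} is not an uppercase DNA 3-mer")
        object.__setattr__(self, "motifs", motifs)

    def __contains__(self, text: str) -> bool:
        return text in self.motifs

    def __iter__(self):
        return iter(sorted(self.motifs))

    def variant_targets(self, text: str) -> tuple[str, ...]:
        """Family motifs at Hamming distance exactly 1 from ``text``."""
        return tuple(m for m in sorted(self.motifs) if hamming(text, m) == 1)


@dataclass(frozen=True)
class RepeatUnit:
    """One tri-nucleotide unit: its text and the motif it is attributed to."""

    text: str
    label: str
    is_variant: bool = False

    def __post_init__(self):
        if not self.is_variant and self.text != self.label:
            raise ValueError("exact unit text must equal its label motif")
        if self.is_variant and hamming(self.text, self.label) != 1:
            raise ValueError("variant unit must be Hamming-1 from its label motif")


@dataclass(frozen=True)
class RepeatBlock:
    """A maximal run of units attributed to a single motif."""

    motif: str
    units: tuple[RepeatUnit, ...]

    def __post_init__(self):
        if len(self.units) < 1:
            raise ValueError("block must contain at least one unit")
        if any(u.label != self.motif for u in self.units):
            raise ValueError("all units of a block share the block motif")
        for u, v in zip(self.units, self.units[1:]):
            if u.is_variant and v.is_variant:
                raise ValueError("adjacent variant units are not allowed")

    @property
    def count(self) -> int:
        return len(self.units)

    @property
    def sequence(self) -> str:
        return "".join(u.text for u in self.units)


@dataclass(frozen=True)
class RepeatArchitecture:
    """Ordered motif-run blocks locating a parsed repeat on its source.

    ``span`` is 0-based half-open on the forward orientation of the given
    sequence; ``phase`` is ``span[0] % 3``.  Concatenating all unit texts
    reproduces the source subsequence exactly (the parse is lossless).
    """

    blocks: tuple[RepeatBlock, ...]
    family: MotifFamily
    phase: int = 0
    span: tuple[int, int] = (0, 0)
    source_id: str = ""

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("architecture must contain at least one block")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.motif == b.motif:
                raise ValueError("adjacent blocks must have different motifs")
        for bl in self.blocks:
            if bl.motif not in self.family:
                raise ValueError(f"block motif {bl.motif} not in family")
        if self.span == (0, 0):
            object.__setattr__(self, "span", (0, 3 * self.n_units))
        if self.span[1] - self.span[0] != 3 * self.n_units:
            raise ValueError("span length must equal 3 × unit count")
        units = self.units
        if units[0].is_variant or units[-1].is_variant:
            raise ValueError("variant units are not allowed at window edges")

    @property
    def units(self) -> tuple[RepeatUnit, ...]:
        return tuple(u for bl in self.blocks for u in bl.units)

    @property
    def n_units(self) -> int:
        return sum(bl.count for bl in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_variants(self) -> int:
        return sum(u.is_variant for bl in self.blocks for u in bl.units)

    @property
    def sequence(self) -> str:
        """Concatenated unit texts == the source span substring."""
        return "".join(bl.sequence for bl in self.blocks)

    @property
    def notation(self) -> str:
        return to_notation(self)

    def unit_texts(self) -> tuple[str, ...]:
        return tuple(u.text for bl in self.blocks for u in bl.units)

    def motif_counts(self) -> Counter:
        """Units attributed to each motif (variants count toward their label)."""
        return Counter(u.label for bl in self.blocks for u in bl.units)

    def relabel(self, source_id: str) -> "RepeatArchitecture":
        return RepeatArchitecture(self.blocks, self.family, self.phase, self.span, source_id)


@dataclass(frozen=True)
class ArchitectureDiff:
    """Unit-level difference between two architectures of one family."""

    net: dict[str, int]  # motif -> (units in b) − (units in a)
    variant_changes: tuple[tuple[int, str, str], ...]  # (alignment column, from, to)
    block_structure_changed: bool

    def negate(self) -> "ArchitectureDiff":
        return ArchitectureDiff(
            net={m: -v for m, v in self.net.items()},
            variant_changes=tuple((i, b, a) for i, a, b in self.variant_changes),
            block_structure_changed=self.block_structure_changed,
        )


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------


def _validate_sequence(seq: str) -> None:
    if not isinstance(seq, str) or set(seq) - DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET) if isinstance(seq, str) else seq
        raise MalformedSequenceError(f"sequence contains non-DNA characters: {bad}")
    if len(seq) < 9:
        raise MalformedSequenceError("sequence shorter than 9 nt cannot hold a repeat")


def decompose(
    seq: str,
    family: MotifFamily | Iterable[str] = B10_FAMILY_MOTIFS,
    min_run: int = 3,
    source_id: str = "",
) -> RepeatArchitecture:
    """Parse ``seq`` into the optimal repeat architecture over ``family``.

    The optimum lexicographically maximises (exact-match units, −blocks,
    window length); ties go to the leftmost window, and variants compatible
    with both neighbours are attributed to the preceding block.  A window
    must contain ≥ ``min_run`` consecutive exact units of a single motif.

    Raises
    ------
    MalformedSequenceError
        for non-DNA input or input shorter than 9 nt.
    NoRepeatFoundError
        when no qualifying window exists.
    """
    if not isinstance(family, MotifFamily):
        family = MotifFamily(family)
    _validate_sequence(seq)

    best_key: Optional[tuple[int, int, int, int]] = None  # (exact, -blocks, span, -start)
    best: Optional[tuple[int, int, int]] = None  # (phase, start_nt, end_nt)

    n = len(seq)
    for phase in range(3):
        m = (n - phase) // 3
        if m == 0:
            continue
        texts = [seq[phase + 3 * k : phase + 3 * k + 3] for k in range(m)]
        exact = [t in family for t in texts]
        variant_ok = [bool(family.variant_targets(t)) for t in texts]

        for i in range(m):
            if not exact[i]:
                continue
            # extend window [i..j]; all scoring state is O(1)-incremental
            n_exact = 0
            n_blocks = 0  # motif switches among exact units define blocks
            last_exact_motif: Optional[str] = None
            run_len = 0  # current run of consecutive exact units of one motif
            best_run = 0
            pending_variant: Optional[int] = None  # unresolved variant index
            for j in range(i, m):
                t = texts[j]
                if exact[j]:
                    if pending_variant is not None:
                        # a variant must be Hamming-1 from the preceding or
                        # the following exact unit's motif
                        pv = texts[pending_variant]
                        if hamming(pv, last_exact_motif) != 1 and hamming(pv, t) != 1:
                            break
                        pending_variant = None
                    n_exact += 1
                    if t == last_exact_motif:
                        run_len += 1
                    else:
                        n_blocks += 1
                        run_len = 1
                    last_exact_motif = t
                    best_run = max(best_run, run_len)
                elif variant_ok[j]:
                    if pending_variant is not None or j == i:
                        break  # adjacent variants / variant at window start
                    pending_variant = j
                    run_len = 0  # a variant interrupts a consecutive exact run
                else:
                    break
                if exact[j] and best_run >= min_run:
                    start_nt = phase + 3 * i
                    end_nt = phase + 3 * (j + 1)
                    key = (n_exact, -n_blocks, end_nt - start_nt, -start_nt)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = (phase, start_nt, end_nt)

    if best is None:
        raise NoRepeatFoundError(
            f"no window with ≥ {min_run} consecutive exact units of a family motif"
        )

    phase, start_nt, end_nt = best
    return _build_architecture(seq, family, start_nt, end_nt, source_id)


def _build_architecture(
    seq: str,
    family: MotifFamily,
    start_nt: int,
    end_nt: int,
    source_id: str,
) -> RepeatArchitecture:
    texts = [seq[k : k + 3] for k in range(start_nt, end_nt, 3)]
    labels: list[str] = []
    for k, t in enumerate(texts):
        if t in family:
            labels.append(t)
        else:
            prev_motif = texts[k - 1]  # neighbours of a variant are exact
            next_motif = texts[k + 1]
            if hamming(t, prev_motif) == 1:
                labels.append(prev_motif)  # ambiguous → preceding block
            else:
                labels.append(next_motif)
    blocks: list[RepeatBlock] = []
    run: list[RepeatUnit] = []
    for t, lab in zip(texts, labels):
        unit = RepeatUnit(t, lab, is_variant=(t != lab))
        if run and run[-1].label != lab:
            blocks.append(RepeatBlock(run[-1].label, tuple(run)))
            run = []
        run.append(unit)
    blocks.append(RepeatBlock(run[-1].label, tuple(run)))
    return RepeatArchitecture(
        blocks=tuple(blocks),
        family=family,
        phase=start_nt % 3,
        span=(start_nt, end_nt),
        source_id=source_id,
    )


# ---------------------------------------------------------------------------
# consensus notation
# ---------------------------------------------------------------------------


def to_notation(arch: RepeatArchitecture) -> str:
    """Serialise an architecture as ``(MOTIF)COUNT`` / ``[UNIT]`` tokens.

    Exact runs become ``(MOTIF)n``; each variant unit becomes ``[UNIT]``
    placed between its neighbours, e.g. ``(CAG)2[CCG](CAG)1(CAT)3``.
    """
    out: list[str] = []
    run_motif: Optional[str] = None
    run_count = 0
    for unit in arch.units:
        if unit.is_variant:
            if run_count:
                out.append(f"({run_motif}){run_count}")
                run_motif, run_count = None, 0
            out.append(f"[{unit.text}]")
        elif unit.label == run_motif:
            run_count += 1
        else:
            if run_count:
                out.append(f"({run_motif}){run_count}")
            run_motif, run_count = unit.label, 1
    if run_count:
        out.append(f"({run_motif}){run_count}")
    return "".join(out)


_TOKEN_RUN = "run"
_TOKEN_VARIANT = "variant"


def _tokenize_notation(s: str):
    pos = 0
    n = len(s)
    while pos < n:
        c = s[pos]
        if c == "(":
            close = s.find(")", pos)
            if close != pos + 4 or set(s[pos + 1 : close]) - DNA_ALPHABET:
                raise NotationParseError("expected (MOTIF) with a DNA 3-mer", pos)
            motif = s[pos + 1 : close]
            pos = close + 1
            digits = ""
            while pos < n and s[pos].isdigit():
                digits += s[pos]
                pos += 1
            if not digits:
                raise NotationParseError("expected a count after (MOTIF)", pos)
            count = int(digits)
            if count < 1:
                raise NotationParseError("count must be ≥ 1", pos - len(digits))
            yield _TOKEN_RUN, motif, count, pos
        elif c == "[":
            close = s.find("]", pos)
            if close != pos + 4 or set(s[pos + 1 : close]) - DNA_ALPHABET:
                raise NotationParseError("expected [UNIT] with a DNA 3-mer", pos)
            yield _TOKEN_VARIANT, s[pos + 1 : close], 1, close + 1
            pos = close + 1
        else:
            raise NotationParseError(f"unexpected character {c!r}", pos)


def parse_notation(
    s: str,
    family: MotifFamily | Iterable[str] = B10_FAMILY_MOTIFS,
    source_id: str = "",
) -> RepeatArchitecture:
    """Parse a consensus-notation string back into an architecture.

    The result is canonical: adjacent same-motif runs are merged and each
    variant is attributed to the preceding block when compatible with it.
    ``to_notation(parse_notation(s))`` equals the canonical form of ``s``.
    """
    if not isinstance(family, MotifFamily):
        family = MotifFamily(family)
    entries: list[tuple[str, str, int, int]] = list(_tokenize_notation(s))
    if not entries:
        raise NotationParseError("empty notation", 0)

    # expand to unit texts, remembering variant positions
    texts: list[str] = []
    is_var: list[bool] = []
    positions: list[int] = []
    for kind, text, count, endpos in entries:
        if kind == _TOKEN_RUN:
            if text not in family:
                raise NotationParseError(f"motif {text} not in family", endpos)
            texts.extend([text] * count)
            is_var.extend([False] * count)
            positions.extend([endpos] * count)
        else:
            if text in family:
                raise NotationParseError(
                    f"[{text}] is an exact family motif, not a variant", endpos
                )
            texts.append(text)
            is_var.append(True)
            positions.append(endpos)

    if is_var[0] or is_var[-1]:
        bad = 0 if is_var[0] else len(texts) - 1
        raise NotationParseError("variant unit at window edge", positions[bad])
    for k in range(1, len(texts)):
        if is_var[k] and is_var[k - 1]:
            raise NotationParseError("adjacent variant units", positions[k])
    for k, (t, v) in enumerate(zip(texts, is_var)):
        if v:
            prev_m, next_m = texts[k - 1], texts[k + 1]
            if hamming(t, prev_m) != 1 and hamming(t, next_m) != 1:
                raise NotationParseError(
                    f"variant {t} is not Hamming-1 from a neighbouring motif",
                    positions[k],
                )

    seq = "".join(texts)
    return _build_architecture(seq, family, 0, len(seq), source_id)


def notation_to_sequence(s: str) -> str:
    """Expand a consensus-notation string into its literal nucleotides."""
    return "".join(
        text * count for _, text, count, _ in _tokenize_notation(s)
    )


# ---------------------------------------------------------------------------
# unit-level alignment and diff
# ---------------------------------------------------------------------------


def unit_alignment(
    a: Sequence[str], b: Sequence[str]
) -> tuple[int, list[tuple[Optional[int], Optional[int]]]]:
    """Global alignment of two unit-text sequences.

    Costs, in thirds of a unit: substitution = nucleotide Hamming distance
    between the 3-mers (0–3), indel = 3.  Returns ``(cost_in_thirds,
    pairs)`` where each pair holds unit indices into ``a`` and ``b`` (``None``
    marks a gap).  Traceback prefers substitution, then a gap in ``b``, then
    a gap in ``a``, making the alignment deterministic.
    """
    la, lb = len(a), len(b)
    INDEL = 3
    # DP over integer thirds keeps the metric exact
    dp = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        dp[i][0] = i * INDEL
    for j in range(1, lb + 1):
        dp[0][j] = j * INDEL
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            sub = dp[i - 1][j - 1] + hamming(ai, b[j - 1])
            dele = dp[i - 1][j] + INDEL
            ins = dp[i][j - 1] + INDEL
            dp[i][j] = min(sub, dele, ins)
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i][j] == dp[i - 1][j - 1] + hamming(a[i - 1], b[j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and dp[i][j] == dp[i - 1][j] + INDEL:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return dp[la][lb], pairs


def diff(a: RepeatArchitecture, b: RepeatArchitecture) -> ArchitectureDiff:
    """Unit-level difference ``b − a``: net motif gains/losses and changed units.

    ``net`` maps each motif to the signed change in unit count; variant
    changes list alignment columns whose unit texts differ, as
    ``(column, text_in_a, text_in_b)``.  Antisymmetric:
    ``diff(a, b).negate() == diff(b, a)``.
    """
    if a.family.motifs != b.family.motifs:
        raise FamilyMismatchError("architectures belong to different motif families")
    ca, cb = a.motif_counts(), b.motif_counts()
    net = {m: cb.get(m, 0) - ca.get(m, 0) for m in sorted(set(ca) | set(cb))}
    ta, tb = a.unit_texts(), b.unit_texts()
    _, pairs = unit_alignment(ta, tb)
    changes = tuple(
        (col, ta[i], tb[j])
        for col, (i, j) in enumerate(pairs)
        if i is not None and j is not None and ta[i] != tb[j]
    )
    structure_changed = [bl.motif for bl in a.blocks] != [bl.motif for bl in b.blocks]
    return ArchitectureDiff(net, changes, structure_changed)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

TSV_HEADER = (
    "source_id\tphase\tspan_start\tspan_end\tnotation\tn_blocks\tn_units\tn_variants"
)


def architectures_to_tsv(archs: Iterable[RepeatArchitecture]) -> str:
    """Render architectures as a TSV table (one row per architecture)."""
    lines = [TSV_HEADER]
    for a in archs:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    a.source_id,
                    a.phase,
                    a.span[0],
                    a.span[1],
                    a.notation,
                    a.n_blocks,
                    a.n_units,
                    a.n_variants,
                )
            )
        )
    return "\n".join(lines) + "\n"
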