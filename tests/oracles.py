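"""Independent brute-force oracles used to validate the package's algorithms.

These deliberately share no code with the implementation: the decomposition
oracle enumerates every phase, window and unit labelling; the alignment
oracle explores every global alignment recursively.
"""

from __future__ import annotations

import functools
from itertools import product


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_decompose(seq: str, motifs: set[str], min_run: int = 3):
    """Exhaustive search for the optimal repeat parse.

    Returns ``(start, end, labels)`` where ``labels`` is a list of
    ``(text, motif, is_variant)`` per unit, or ``None`` when no window
    qualifies.  Objective: lexicographic max of (exact units, −blocks,
    span length), leftmost window on ties, ambiguous variants attributed
    to the preceding unit's motif.
    """
    motifs = set(motifs)
    n = len(seq)
    best_key = None
    best = None
    for start in range(n - 2):
        max_units = (n - start) // 3
        for k in range(1, max_units + 1):
            end = start + 3 * k
            units = [seq[i : i + 3] for i in range(start, end, 3)]
            # per-unit label options, preceding-preference handled by
            # ordering variant options after resolving neighbours below
            opts = []
            feasible = True
            for u in units:
                if u in motifs:
                    opts.append([(u, False)])
                else:
                    var = [(m, True) for m in sorted(motifs) if _hamming(u, m) == 1]
                    if not var:
                        feasible = False
                        break
                    opts.append(var)
            if not feasible:
                continue
            for labelling in product(*opts):
                if not _valid(units, labelling):
                    continue
                n_exact = sum(not v for _, v in labelling)
                blocks = 1
                for (m1, _), (m2, _) in zip(labelling, labelling[1:]):
                    if m1 != m2:
                        blocks += 1
                runs = _max_exact_run(units, labelling)
                if runs < min_run:
                    continue
                key = (n_exact, -blocks, end - start, -start)
                cand = (start, end, [(u, m, v) for u, (m, v) in zip(units, labelling)])
                if best_key is None or key > best_key:
                    best_key, best = key, cand
                elif key == best_key:
                    # same window, variant-attribution tie: prefer preceding
                    if _pref_score(cand[2]) > _pref_score(best[2]):
                        best = cand
    return best


def _valid(units, labelling):
    if labelling[0][1] or labelling[-1][1]:
        return False  # variant at a window edge
    for (_, v1), (_, v2) in zip(labelling, labelling[1:]):
        if v1 and v2:
            return False  # adjacent variants
    for i, (m, v) in enumerate(labelling):
        if not v:
            continue
        neighbours = {units[i - 1], units[i + 1]}  # both exact
        if m not in neighbours:
            return False  # variant label must match an adjacent block motif
    return True


def _max_exact_run(units, labelling):
    best = run = 0
    last = None
    for u, (m, v) in zip(units, labelling):
        if not v and u == last:
            run += 1
        elif not v:
            run, last = 1, u
        else:
            run, last = 0, None
        best = max(best, run)
    return best


def _pref_score(labels):
    """Counts variants attributed to their preceding unit's motif."""
    return sum(
        1
        for i, (_, m, v) in enumerate(labels)
        if v and i > 0 and m == labels[i - 1][1]
    )


def brute_align(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Minimum global alignment cost in thirds of a unit, by exhaustive
    recursion (substitution = Hamming, indel = 3)."""

    @functools.lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(a):
            return 3 * (len(b) - j)
        if j == len(b):
            return 3 * (len(a) - i)
        return min(
            go(i + 1, j + 1) + _hamming(a[i], b[j]),
            go(i + 1, j) + 3,
            go(i, j + 1) + 3,
        )

    return go(0, 0)
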