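"""Precursor secondary structure: pair tables, folding, hairpin features.

The pair table maps every position of a folded precursor to its pairing
partner, with unpaired positions carrying a wildcard marker.  Structures
come either from a supplied RNAfold dot-bracket string or from the
built-in folder, a deterministic Nussinov-style dynamic program that
maximizes the number of canonical (Watson-Crick + G-U wobble) pairs
subject to a minimum hairpin-loop size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io_formats import RnaSequence, ViennaRecord

#: Wildcard marker for unpaired positions.
UNPAIRED = "*"

#: Canonical RNA pairs: Watson-Crick plus the G-U wobble.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class StructureError(ValueError):
    """Raised on malformed dot-bracket input or structure mismatches."""


def can_pair(a: str, b: str) -> bool:
    """True if the two bases form a canonical or wobble pair.

    IUPAC ambiguity letters never pair: inventing pairing rules for
    ambiguous bases would be less conservative than leaving them single
    stranded.
    """
    return (a, b) in CANONICAL_PAIRS


@dataclass(frozen=True)
class PairTable:
    """Per-position pairing partner of a folded precursor.

    ``partner[i]`` is the 0-based partner index, or ``None`` for
    unpaired positions (rendered as the ``*`` wildcard).  Valid tables
    are involutions without self-pairing, and their pairs are properly
    nested (no pseudoknots).
    """

    partner: tuple[Optional[int], ...]

    @property
    def n(self) -> int:
        return len(self.partner)

    def is_paired(self, i: int) -> bool:
        return self.partner[i] is not None

    def __getitem__(self, i: int) -> Optional[int]:
        return self.partner[i]

    def __post_init__(self) -> None:
        n = len(self.partner)
        for i, j in enumerate(self.partner):
            if j is None:
                continue
            if not (0 <= j < n):
                raise StructureError(f"partner of {i} out of range: {j}")
            if j == i:
                raise StructureError(f"self-pairing at position {i}")
            if self.partner[j] != i:
                raise StructureError(
                    f"involution violated at ({i}, {j})"
                )


def parse_dotbracket(structure: str) -> PairTable:
    """Build a :class:`PairTable` from dot-bracket notation.

    Stack-based matching: each ``)`` pairs with the most recent
    unmatched ``(``; dots are unpaired.  Nesting of the result is
    guaranteed by the stack discipline.

    Raises
    ------
    StructureError
        On unbalanced brackets or a foreign character, reporting the
        0-based position.
    """
    partner: list[Optional[int]] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"unbalanced ')' at position {i}"
                )
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif ch != ".":
            raise StructureError(
                f"foreign character {ch!r} at position {i}"
            )
    if stack:
        raise StructureError(
            f"unbalanced '(' at position {stack[-1]}"
        )
    return PairTable(partner=tuple(partner))


def render_dotbracket(pt: PairTable) -> str:
    """Inverse of :func:`parse_dotbracket`."""
    out = []
    for i, j in enumerate(pt.partner):
        if j is None:
            out.append(".")
        else:
            out.append("(" if i < j else ")")
    return "".join(out)


def fold(seq: str, min_loop: int = 3) -> str:
    """Fold an RNA sequence by maximum base pairing (Nussinov DP).

    Maximizes the count of canonical + wobble pairs over all nested
    structures, with every pair (i, j) required to satisfy
    ``j - i > min_loop``.  The traceback is deterministic: at each
    subinterval it prefers pairing the left end over leaving it
    unpaired, and among optimal partners picks the smallest index.

    Sequences too short to form any pair return the all-unpaired
    structure rather than raising.

    Parameters
    ----------
    seq : normalized RNA string (``ACGU`` + IUPAC letters).
    min_loop : minimum number of unpaired positions enclosed by a
        hairpin-closing pair; 3 is the standard minimal loop.
    """
    n = len(seq)
    if n <= min_loop + 1:
        return "." * n
    # dp[i][j] = max pairs in seq[i..j]
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(seq[i], seq[k]):
                    inner = dp[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    outer = dp[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + outer
                    if cand > best:
                        best = cand
            dp[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        # prefer pairing i; among optimal partners take the smallest k
        paired_here = False
        for k in range(i + min_loop + 1, j + 1):
            if not can_pair(seq[i], seq[k]):
                continue
            inner = dp[i + 1][k - 1] if k - 1 >= i + 1 else 0
            outer = dp[k + 1][j] if k + 1 <= j else 0
            if 1 + inner + outer == dp[i][j]:
                structure[i] = "("
                structure[k] = ")"
                if k + 1 <= j:
                    stack.append((k + 1, j))
                if k - 1 >= i + 1:
                    stack.append((i + 1, k - 1))
                paired_here = True
                break
        if not paired_here:
            stack.append((i + 1, j))
    return "".join(structure)


def structure_for(
    precursor: RnaSequence,
    supplied: Optional[ViennaRecord] = None,
    min_loop: int = 3,
) -> PairTable:
    """Pair table for a precursor: supplied structure if given, else fold.

    Raises
    ------
    StructureError
        If a supplied structure's length does not match the precursor.
    """
    if supplied is not None:
        if len(supplied.structure) != len(precursor.seq):
            raise StructureError(
                f"precursor {precursor.id!r}: supplied structure length "
                f"{len(supplied.structure)} != sequence length "
                f"{len(precursor.seq)}"
            )
        return parse_dotbracket(supplied.structure)
    return parse_dotbracket(fold(precursor.seq, min_loop=min_loop))


@dataclass(frozen=True)
class HairpinFeatures:
    """Structural annotation of a folded precursor.

    ``loops`` are terminal hairpin loops (maximal unpaired runs closed
    by a single pair); ``bulges`` are unpaired runs interrupting stems
    (bulges and internal-loop halves are not distinguished); ``stems``
    are maximal runs of stacked pairs, given as paired interval pairs.
    Intervals are 0-based inclusive.
    """

    loops: tuple[tuple[int, int], ...] = ()
    bulges: tuple[tuple[int, int], ...] = ()
    stems: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()

    @property
    def has_hairpin(self) -> bool:
        return bool(self.stems)


def annotate_features(pt: PairTable) -> HairpinFeatures:
    """Classify a pair table into terminal loops, bulges, and stems."""
    n = pt.n
    loops: list[tuple[int, int]] = []
    bulges: list[tuple[int, int]] = []
    stems: list[tuple[tuple[int, int], tuple[int, int]]] = []

    # unpaired runs
    i = 0
    while i < n:
        if pt.is_paired(i):
            i += 1
            continue
        j = i
        while j + 1 < n and not pt.is_paired(j + 1):
            j += 1
        if i > 0 and j < n - 1:
            if pt[i - 1] == j + 1:
                loops.append((i, j))
            else:
                bulges.append((i, j))
        # runs touching the molecule ends are exterior, not features
        i = j + 1

    # maximal stacked-pair runs on the 5' side
    i = 0
    while i < n:
        j = pt[i]
        if j is None or j < i:
            i += 1
            continue
        start = i
        while (
            i + 1 < n
            and pt[i + 1] is not None
            and pt[i + 1] == j - (i + 1 - start)
            and pt[i + 1] > i + 1
        ):
            i += 1
        stems.append(((start, i), (pt[i], j)))
        i += 1

    return HairpinFeatures(
        loops=tuple(loops), bulges=tuple(bulges), stems=tuple(stems)
    )
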