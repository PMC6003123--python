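"""Independent oracles used by the test suite.

Everything here is deliberately naive (brute force, exhaustive
enumeration, closed-form geometry) and shares no code path with the
implementation it checks.
"""

from __future__ import annotations

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
             ("G", "U"), ("U", "G")}


def rc(seq: str) -> str:
    """Reverse complement, written independently of the package."""
    return "".join(_COMP[c] for c in reversed(seq))


def brute_force_occurrences(needle: str, haystack: str) -> list[int]:
    """All (overlapping) start offsets of needle in haystack."""
    return [
        i
        for i in range(len(haystack) - len(needle) + 1)
        if haystack[i : i + len(needle)] == needle
    ]


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    """Maximum canonical pair count over ALL nested structures.

    Explicitly enumerates every nested set of pairs (feasible for
    n <= 12) and returns the largest cardinality; no dynamic
    programming, so it cannot share a bug with the folder's DP.
    """

    def enum(i: int, j: int):
        # yields pair counts of all nested structures on seq[i..j]
        if i > j:
            yield 0
            return
        for rest in enum(i + 1, j):  # i unpaired
            yield rest
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRABLE:
                for inner in enum(i + 1, k - 1):
                    for outer in enum(k + 1, j):
                        yield 1 + inner + outer

    return max(enum(0, len(seq) - 1)) if seq else 0


def closed_form_star(precursor: str, mature: str) -> tuple[int, int, str]:
    """Expected star for a perfect planted stem, by pure geometry.

    On a perfect duplex the opposite arm is exactly rc(mature); the
    star is that arm displaced two positions toward the precursor 3'
    end.  Locating rc(mature) by substring scan keeps this oracle
    independent of both the generator's internals and the extractor.
    Returns (star_start, star_end, star_seq), 0-based inclusive.
    """
    arm = rc(mature)
    q = precursor.find(arm)
    assert q != -1, "no perfect opposite arm present"
    assert precursor.find(arm, q + 1) == -1, "opposite arm not unique"
    lo = q + 2
    hi = q + len(mature) + 1
    return lo, hi, precursor[lo : hi + 1]


def pairs_are_nested(partner) -> bool:
    """Check the no-crossing condition on a partner table by brute force."""
    pairs = [
        (i, j)
        for i, j in enumerate(partner)
        if j is not None and i < j
    ]
    for a, (i, j) in enumerate(pairs):
        for k, l in pairs[a + 1:]:
            if i < k < j < l or k < i < l < j:
                return False
    return True
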