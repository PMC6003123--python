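"""Star-strand extraction: the core duplex computation.

Given a precursor, a mature miRNA occurring inside it, and the
precursor's pair table, the star strand is located by the two-nucleotide
3' overhang rule of RNase III (Dicer/DCL1) cleavage: the partners of the
mature's two endpoints, each displaced by two positions toward the
precursor 3' end, delimit the miRNA* interval.  Unpaired mature ends are
handled by walking inward to the nearest paired anchor and restoring the
skipped positions on the corresponding star end, so the output remains
the full opposite duplex strand.

Degenerate entries (mature entirely inside a loop, or a structure so
distorted that the star would overlap the mature) yield predictions with
a failure status rather than exceptions: a batch run never aborts on a
single bad hairpin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import RnaSequence
from .structure import PairTable

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_MATURE_IN_LOOP = "mature_in_loop"
STATUS_SELF_OVERLAP = "self_overlap"

#: Anchor-walk directions for the two mature ends.
INWARD_FROM_5P = "inward_from_5p_end"
INWARD_FROM_3P = "inward_from_3p_end"

#: Stars longer than this are flagged ``overlong``: well past the
#: canonical 21-24 nt mature range, typically caused by a large bulge
#: opposite a gap in the mature.
DEFAULT_OVERLONG_THRESHOLD = 30


class MatureInLoopError(Exception):
    """Signal: no paired position anywhere within the mature interval."""


@dataclass(frozen=True)
class Flag:
    """A qualifier on an otherwise successful prediction.

    ``kind`` is one of ``end_shifted_5p``, ``end_shifted_3p``,
    ``clipped_5p``, ``clipped_3p``, ``overlong``; ``amount`` carries the
    shift/clip size in nucleotides where applicable.
    """

    kind: str
    amount: Optional[int] = None

    def __str__(self) -> str:
        if self.amount is None:
            return self.kind
        return f"{self.kind}({self.amount})"


@dataclass(frozen=True)
class DuplexEntry:
    """One unit of work: a mature occurrence within a folded precursor."""

    precursor_id: str
    precursor_seq: str
    mature_id: str
    mature_seq: str
    mature_start: int  # 0-based
    mature_end: int  # 0-based inclusive
    pair_table: PairTable

    def __post_init__(self) -> None:
        sub = self.precursor_seq[self.mature_start : self.mature_end + 1]
        if sub != self.mature_seq:
            raise ValueError(
                f"mature {self.mature_id!r} does not occur at "
                f"[{self.mature_start}, {self.mature_end}] of "
                f"{self.precursor_id!r}"
            )
        if self.pair_table.n != len(self.precursor_seq):
            raise ValueError(
                f"pair table length {self.pair_table.n} != precursor "
                f"length {len(self.precursor_seq)}"
            )


@dataclass(frozen=True)
class StarPrediction:
    """Predicted miRNA* for one duplex entry.

    Star coordinates are 0-based inclusive and absent (``None``) when
    ``status`` is a failure.  ``duplicate_of`` is set by
    :func:`dedup_stars` on rows whose star sequence repeats an earlier
    prediction.
    """

    entry: DuplexEntry
    star_start: Optional[int] = None
    star_end: Optional[int] = None
    star_seq: Optional[str] = None
    status: str = STATUS_OK
    flags: tuple[Flag, ...] = ()
    duplicate_of: Optional[str] = None

    def flag(self, kind: str) -> Optional[Flag]:
        for f in self.flags:
            if f.kind == kind:
                return f
        return None


def match_matures(
    precursors: Sequence[RnaSequence],
    matures: Sequence[RnaSequence],
    structures: Mapping[str, PairTable],
) -> list[DuplexEntry]:
    """Pair every mature with every precursor that contains it.

    Every exact-substring occurrence (including overlapping occurrences
    within one precursor) becomes a :class:`DuplexEntry`; matching is
    many-to-many.  Entries with identical (precursor sequence, mature
    sequence, offset) are collapsed so the working set is non-redundant.

    ``structures`` maps precursor id to its pair table; every precursor
    that receives a match must have one.
    """
    entries: list[DuplexEntry] = []
    seen: set[tuple[str, str, int]] = set()
    for mature in matures:
        for prec in precursors:
            start = prec.seq.find(mature.seq)
            while start != -1:
                key = (prec.seq, mature.seq, start)
                if key not in seen:
                    seen.add(key)
                    entries.append(
                        DuplexEntry(
                            precursor_id=prec.id,
                            precursor_seq=prec.seq,
                            mature_id=mature.id,
                            mature_seq=mature.seq,
                            mature_start=start,
                            mature_end=start + len(mature.seq) - 1,
                            pair_table=structures[prec.id],
                        )
                    )
                start = prec.seq.find(mature.seq, start + 1)
    if not entries:
        logger.warning("no mature sequence matched any precursor")
    return entries


def resolve_paired_anchor(
    pt: PairTable,
    pos: int,
    direction: str,
    limit: tuple[int, int],
) -> tuple[int, int]:
    """Find the nearest paired position walking inward from a mature end.

    Returns ``(anchor, offset)`` where ``offset`` counts the steps
    taken; ``(pos, 0)`` when ``pos`` itself is paired.

    Raises
    ------
    MatureInLoopError
        If no position in ``limit`` (the mature's interval) is paired,
        i.e. the whole mature is single stranded.
    """
    lo, hi = limit
    step = 1 if direction == INWARD_FROM_5P else -1
    i = pos
    offset = 0
    while lo <= i <= hi:
        if pt.is_paired(i):
            return i, offset
        i += step
        offset += 1
    raise MatureInLoopError(
        f"no paired position in mature interval [{lo}, {hi}]"
    )


def extract_star(
    entry: DuplexEntry,
    overlong_threshold: int = DEFAULT_OVERLONG_THRESHOLD,
) -> StarPrediction:
    """Predict the miRNA* of one duplex entry by the shift-by-two rule.

    With mature interval [s, e] and pair table ``pt``, the paired
    anchors (s*, k_s) and (e*, k_e) are resolved by walking inward from
    each end, and the raw star interval is::

        star = [pt[e*] + 2 - k_e,  pt[s*] + 2 + k_s]

    The +2 encodes the two-nucleotide 3' overhang on both duplex ends;
    the +/- k terms restore the nucleotides skipped while searching for
    a paired anchor, so the star mirrors the full mature.  Intervals
    reaching past the precursor are clipped to its bounds and flagged.

    A mature with no paired position yields ``mature_in_loop``; a star
    interval that is inverted or overlaps the mature yields
    ``self_overlap``.  Both are statuses, never exceptions.
    """
    pt = entry.pair_table
    s, e = entry.mature_start, entry.mature_end
    try:
        s_anchor, k_s = resolve_paired_anchor(pt, s, INWARD_FROM_5P, (s, e))
        e_anchor, k_e = resolve_paired_anchor(pt, e, INWARD_FROM_3P, (s, e))
    except MatureInLoopError:
        return StarPrediction(entry=entry, status=STATUS_MATURE_IN_LOOP)

    p_lo = pt[e_anchor] + 2 - k_e
    p_hi = pt[s_anchor] + 2 + k_s
    if p_lo > p_hi:
        return StarPrediction(entry=entry, status=STATUS_SELF_OVERLAP)

    flags: list[Flag] = []
    if k_s > 0:
        flags.append(Flag("end_shifted_5p", k_s))
    if k_e > 0:
        flags.append(Flag("end_shifted_3p", k_e))

    n = pt.n
    if p_lo < 0:
        flags.append(Flag("clipped_5p", -p_lo))
        p_lo = 0
    if p_hi > n - 1:
        flags.append(Flag("clipped_3p", p_hi - (n - 1)))
        p_hi = n - 1

    if not (p_hi < s or p_lo > e):
        return StarPrediction(entry=entry, status=STATUS_SELF_OVERLAP)

    star_seq = entry.precursor_seq[p_lo : p_hi + 1]
    if len(star_seq) > overlong_threshold:
        flags.append(Flag("overlong", len(star_seq)))

    return StarPrediction(
        entry=entry,
        star_start=p_lo,
        star_end=p_hi,
        star_seq=star_seq,
        status=STATUS_OK,
        flags=tuple(flags),
    )


def dedup_stars(predictions: Sequence[StarPrediction]) -> list[StarPrediction]:
    """Mark repeated star sequences so the final star set is non-redundant.

    Order is stable and every input row is returned: among successful
    predictions with an identical star sequence, the first is the
    representative and later ones get ``duplicate_of`` pointing at it.
    The FASTA writer emits only representatives; the TSV report keeps
    full provenance.
    """
    from .io_formats import star_record_id

    out: list[StarPrediction] = []
    first_by_seq: dict[str, str] = {}
    for p in predictions:
        if p.status != STATUS_OK:
            out.append(p)
            continue
        rep = first_by_seq.get(p.star_seq)
        if rep is None:
            first_by_seq[p.star_seq] = star_record_id(p)
            out.append(replace(p, duplicate_of=None))
        else:
            out.append(replace(p, duplicate_of=rep))
    return out


@dataclass(frozen=True)
class EvaluationSummary:
    """Result of matching unique predicted stars against known matures."""

    matched: int
    unmatched: int
    total: int
    matched_pairs: tuple[tuple[str, str], ...]  # (star record id, known id)


def evaluate(
    predictions: Sequence[StarPrediction],
    known: Sequence[RnaSequence],
    substring: bool = False,
) -> EvaluationSummary:
    """Match each unique predicted star against a set of known sequences.

    A unique star sequence is matched iff it equals a known sequence
    exactly (both sides normalized).  Stars with no match are the novel
    candidates.  With ``substring=True`` a star also matches when it is
    contained within a known sequence.
    """
    from .io_formats import star_record_id

    uniques = [
        p
        for p in dedup_stars(predictions)
        if p.status == STATUS_OK and p.duplicate_of is None
    ]
    by_seq: dict[str, list[RnaSequence]] = {}
    matched_pairs: list[tuple[str, str]] = []
    matched = 0
    for p in uniques:
        hits = [k for k in known if p.star_seq == k.seq]
        if substring and not hits:
            hits = [k for k in known if p.star_seq in k.seq]
        if hits:
            matched += 1
            for k in hits:
                matched_pairs.append((star_record_id(p), k.id))
    total = len(uniques)
    return EvaluationSummary(
        matched=matched,
        unmatched=total - matched,
        total=total,
        matched_pairs=tuple(matched_pairs),
    )
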