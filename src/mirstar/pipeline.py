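"""End-to-end orchestration: files in, annotated predictions out.

This is the library face of the command-line ``predict`` workflow:
read -> structure (supplied or folded) -> match -> extract -> dedup.
Stage counts are collected along the way so a run can be audited
against the conservation rule ``entries == ok + failures``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .duplex import (
    STATUS_MATURE_IN_LOOP,
    STATUS_OK,
    STATUS_SELF_OVERLAP,
    DEFAULT_OVERLONG_THRESHOLD,
    StarPrediction,
    dedup_stars,
    extract_star,
    match_matures,
)
from .io_formats import RnaSequence, read_fasta, read_vienna
from .structure import PairTable, StructureError, fold, parse_dotbracket

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictRun:
    """Predictions plus the stage-count funnel of one pipeline run."""

    predictions: tuple[StarPrediction, ...]
    counts: dict


def build_structures(
    precursors: Sequence[RnaSequence],
    vienna_path: Optional[Union[str, Path]] = None,
    min_loop: int = 3,
) -> Mapping[str, PairTable]:
    """Pair tables for all precursors: supplied Vienna file, else folding.

    A supplied file must cover every precursor with a matching length;
    precursors absent from it are folded with the built-in folder.
    """
    supplied: dict[str, str] = {}
    if vienna_path is not None:
        for rec in read_vienna(vienna_path):
            supplied[rec.id] = rec.structure
    tables: dict[str, PairTable] = {}
    for prec in precursors:
        if prec.id in tables:
            continue
        db = supplied.get(prec.id)
        if db is not None:
            if len(db) != len(prec.seq):
                raise StructureError(
                    f"precursor {prec.id!r}: supplied structure length "
                    f"{len(db)} != sequence length {len(prec.seq)}"
                )
        else:
            db = fold(prec.seq, min_loop=min_loop)
        tables[prec.id] = parse_dotbracket(db)
    return tables


def run_prediction(
    precursors: Sequence[RnaSequence],
    matures: Sequence[RnaSequence],
    structures: Mapping[str, PairTable],
    overlong_threshold: int = DEFAULT_OVERLONG_THRESHOLD,
) -> PredictRun:
    """Match matures into precursors and extract every star strand."""
    entries = match_matures(precursors, matures, structures)
    predictions = [
        extract_star(e, overlong_threshold=overlong_threshold)
        for e in entries
    ]
    predictions = dedup_stars(predictions)
    counts = {
        "precursors": len(precursors),
        "matures": len(matures),
        "entries": len(entries),
        "ok": sum(1 for p in predictions if p.status == STATUS_OK),
        "mature_in_loop": sum(
            1 for p in predictions if p.status == STATUS_MATURE_IN_LOOP
        ),
        "self_overlap": sum(
            1 for p in predictions if p.status == STATUS_SELF_OVERLAP
        ),
        "unique_stars": sum(
            1
            for p in predictions
            if p.status == STATUS_OK and p.duplicate_of is None
        ),
    }
    for stage, value in counts.items():
        logger.info("%s: %d", stage, value)
    return PredictRun(predictions=tuple(predictions), counts=counts)


def predict_files(
    precursor_path: Union[str, Path],
    mature_path: Union[str, Path],
    structure_path: Optional[Union[str, Path]] = None,
    min_loop: int = 3,
    overlong_threshold: int = DEFAULT_OVERLONG_THRESHOLD,
) -> PredictRun:
    """File-level convenience wrapper around :func:`run_prediction`."""
    precursors = read_fasta(precursor_path)
    matures = read_fasta(mature_path)
    structures = build_structures(
        precursors, vienna_path=structure_path, min_loop=min_loop
    )
    return run_prediction(
        precursors, matures, structures,
        overlong_threshold=overlong_threshold,
    )
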