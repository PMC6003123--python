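"""Synthetic hairpin precursors with planted duplexes.

The generator builds pre-miRNA-like hairpins whose mature/star duplex
geometry is known by construction: the opposite arm is the reverse
complement of a random mature, displaced so that both duplex ends carry
exact two-nucleotide 3' overhangs, with unpaired flanks and a terminal
loop around the stem.  Structures are planted, not folded, which
isolates the star-extraction algorithm from folder behavior.

Perturbations model the distortions real hairpins show: bulges on the
star arm, stem mismatches, unpaired mature ends, and the fully
single-stranded (loop-resident) mature that cannot yield a star.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .io_formats import (
    RnaSequence,
    ViennaRecord,
    write_fasta,
    write_vienna,
)
from .structure import parse_dotbracket

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class Bulge:
    """Insert ``size`` unpaired nucleotides on the star arm, between the
    partners of mature positions ``position - 1`` and ``position``
    (0-based mature coordinates; must be stem-interior)."""

    position: int
    size: int


@dataclass(frozen=True)
class Mismatch:
    """Replace the partner of mature position ``position`` with a
    non-pairing base and unpair both."""

    position: int


@dataclass(frozen=True)
class UnpairedEnd:
    """Unpair ``size`` terminal positions at the mature's 5' or 3' end."""

    end: str  # "5p" | "3p"
    size: int


@dataclass(frozen=True)
class MatureInLoop:
    """Unpair the entire mature: no star strand exists."""


Perturbation = Union[Bulge, Mismatch, UnpairedEnd, MatureInLoop]


@dataclass(frozen=True)
class SyntheticHairpin:
    """A generated precursor with planted ground truth.

    ``true_star`` / ``true_star_interval`` are ``None`` when the planted
    perturbations destroy the duplex (loop-resident mature); intervals
    are 0-based inclusive.
    """

    precursor: RnaSequence
    structure: str
    mature: RnaSequence
    mature_interval: tuple[int, int]
    true_star: Optional[str]
    true_star_interval: Optional[tuple[int, int]]
    arm: str
    perturbations: tuple[Perturbation, ...] = ()
    expected_flags: tuple[str, ...] = ()


def _draw_base(rng: random.Random, gc_content: float) -> str:
    if rng.random() < gc_content:
        return rng.choice("GC")
    return rng.choice("AU")


def _draw_seq(rng: random.Random, n: int, gc_content: float) -> str:
    return "".join(_draw_base(rng, gc_content) for _ in range(n))


def _non_pairing_base(rng: random.Random, vs: str) -> str:
    # avoid Watson-Crick and wobble partners of `vs`
    partners = {"A": "U", "U": "AG", "G": "CU", "C": "G"}[vs]
    choices = [b for b in "ACGU" if b not in partners]
    return rng.choice(choices)


def generate_hairpin(
    mature_len: int = 21,
    loop_len: int = 5,
    arm: str = FIVE_PRIME,
    perturbations: Sequence[Perturbation] = (),
    seed: int = 0,
    flank5_len: int = 5,
    flank3_len: int = 5,
    gc_content: float = 0.5,
    name: Optional[str] = None,
) -> SyntheticHairpin:
    """Generate one hairpin with a planted mature/star duplex.

    The mature sits on the requested arm; the opposite arm is its
    reverse complement, and the planted structure pairs the two arms
    base by base.  The true star is the opposite strand displaced by
    the two-nucleotide 3' overhang, read directly off the construction
    geometry.  Deterministic for a fixed seed.

    Parameters
    ----------
    mature_len : mature length in nt (canonical miRNAs are 21-24).
    loop_len : terminal loop size in nt (>= 3).
    arm : which arm carries the mature (``five_prime``/``three_prime``).
    perturbations : distortions to plant (see the perturbation types).
    flank5_len, flank3_len : unpaired linker lengths outside the duplex.
    gc_content : probability that a drawn base is G or C.
    """
    if mature_len < 16:
        raise ValueError("mature_len must be >= 16")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if arm not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown arm {arm!r}")

    rng = random.Random(seed)
    mature = _draw_seq(rng, mature_len, gc_content)
    loop = _draw_seq(rng, loop_len, gc_content)
    flank5 = _draw_seq(rng, flank5_len, gc_content)
    flank3 = _draw_seq(rng, flank3_len, gc_content)

    # opposite arm: reverse complement of the mature, so item k (5'->3')
    # faces mature position mature_len - 1 - k
    opp = [COMPLEMENT[c] for c in reversed(mature)]

    unpaired_mature: set[int] = set()
    expected_flags: list[str] = []
    bulges: dict[int, int] = {}  # opp index after which to insert -> size
    loop_resident = False

    for p in perturbations:
        if isinstance(p, Mismatch):
            if not 0 <= p.position < mature_len:
                raise ValueError(f"mismatch position {p.position} not in stem")
            opp[mature_len - 1 - p.position] = _non_pairing_base(
                rng, mature[p.position]
            )
            unpaired_mature.add(p.position)
        elif isinstance(p, UnpairedEnd):
            if p.size < 1 or p.size >= mature_len:
                raise ValueError(f"unpaired-end size {p.size} out of range")
            if p.end == "5p":
                unpaired_mature.update(range(p.size))
                expected_flags.append(f"end_shifted_5p({p.size})")
            elif p.end == "3p":
                unpaired_mature.update(
                    range(mature_len - p.size, mature_len)
                )
                expected_flags.append(f"end_shifted_3p({p.size})")
            else:
                raise ValueError(f"unknown end {p.end!r}")
        elif isinstance(p, Bulge):
            if not 1 <= p.position <= mature_len - 1:
                raise ValueError(f"bulge position {p.position} not in stem")
            if p.size < 1:
                raise ValueError("bulge size must be >= 1")
            bulges[mature_len - 1 - p.position] = p.size
        elif isinstance(p, MatureInLoop):
            loop_resident = True
        else:
            raise TypeError(f"unknown perturbation {p!r}")

    if loop_resident:
        unpaired_mature.update(range(mature_len))

    # lay out the opposite arm with bulge insertions; record, per item,
    # which mature position it faces (None for bulge nucleotides)
    opp_chars: list[str] = []
    opp_mate: list[Optional[int]] = []
    for k, ch in enumerate(opp):
        opp_chars.append(ch)
        opp_mate.append(mature_len - 1 - k)
        if k in bulges:
            for _ in range(bulges[k]):
                opp_chars.append(rng.choice("ACGU"))
                opp_mate.append(None)
    opp_arm = "".join(opp_chars)

    if arm == FIVE_PRIME:
        mature_start = len(flank5)
        opp_start = mature_start + mature_len + loop_len
        precursor_seq = flank5 + mature + loop + opp_arm + flank3
    else:
        opp_start = len(flank5)
        mature_start = opp_start + len(opp_arm) + loop_len
        precursor_seq = flank5 + opp_arm + loop + mature + flank3
    mature_end = mature_start + mature_len - 1
    n = len(precursor_seq)

    db = ["."] * n
    geom_partner: dict[int, int] = {}  # mature pos -> opposite abs pos
    for t, mate in enumerate(opp_mate):
        if mate is None:
            continue
        a = opp_start + t
        b = mature_start + mate
        geom_partner[mate] = a
        if mate not in unpaired_mature:
            db[min(a, b)] = "("
            db[max(a, b)] = ")"
    structure = "".join(db)

    if loop_resident:
        true_star = None
        true_interval = None
    else:
        # shift-by-two overhang geometry, read off the construction
        lo = geom_partner[mature_len - 1] + 2
        hi = geom_partner[0] + 2
        if hi > n - 1:
            # star overhang runs off the precursor (short 3' flank):
            # the recoverable truth is the clipped interval
            expected_flags.append(f"clipped_3p({hi - (n - 1)})")
            hi = n - 1
        true_interval = (lo, hi)
        true_star = precursor_seq[lo : hi + 1]

    hp_name = name or f"synthetic-s{seed}"
    hairpin = SyntheticHairpin(
        precursor=RnaSequence(
            id=hp_name, seq=precursor_seq, description=f"seed={seed}"
        ),
        structure=structure,
        mature=RnaSequence(
            id=f"{hp_name}-mat", seq=mature, description=f"seed={seed}"
        ),
        mature_interval=(mature_start, mature_end),
        true_star=true_star,
        true_star_interval=true_interval,
        arm=arm,
        perturbations=tuple(perturbations),
        expected_flags=tuple(expected_flags),
    )
    _check_invariants(hairpin)
    return hairpin


def _check_invariants(hp: SyntheticHairpin) -> None:
    s, e = hp.mature_interval
    assert hp.precursor.seq[s : e + 1] == hp.mature.seq
    parse_dotbracket(hp.structure)  # raises if malformed
    if hp.true_star_interval is not None:
        lo, hi = hp.true_star_interval
        assert hp.precursor.seq[lo : hi + 1] == hp.true_star
        assert hi < s or lo > e, "planted star overlaps the mature"


@dataclass(frozen=True)
class DatasetConfig:
    """Distributions for :func:`generate_dataset`.

    Ranges are inclusive; each hairpin draws independently.  The same
    ``perturbations`` tuple is planted in every hairpin (empty by
    default: perfect stems).
    """

    mature_len_range: tuple[int, int] = (19, 24)
    loop_len_range: tuple[int, int] = (3, 10)
    flank5_range: tuple[int, int] = (2, 8)
    flank3_range: tuple[int, int] = (2, 8)
    arms: tuple[str, ...] = (FIVE_PRIME, THREE_PRIME)
    gc_content: float = 0.5
    perturbations: tuple[Perturbation, ...] = ()


@dataclass(frozen=True)
class DatasetPaths:
    precursors: Path
    matures: Path
    structures: Path
    truth: Path
    truth_stars: Path


def generate_dataset(
    n: int,
    config: DatasetConfig = DatasetConfig(),
    seed: int = 0,
    out_dir: Union[str, Path] = ".",
) -> DatasetPaths:
    """Write an n-hairpin dataset in the formats the predictor consumes.

    Produces a precursor FASTA, a mature FASTA, a Vienna file with the
    planted structures, a truth table TSV (1-based coordinates) listing
    every planted star, and a FASTA of the planted star sequences for
    direct use as an evaluation reference.  Deterministic for a fixed
    (config, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    hairpins: list[SyntheticHairpin] = []
    for i in range(n):
        child_seed = rng.randrange(2**31)
        hairpins.append(
            generate_hairpin(
                mature_len=rng.randint(*config.mature_len_range),
                loop_len=rng.randint(*config.loop_len_range),
                arm=rng.choice(config.arms),
                perturbations=config.perturbations,
                seed=child_seed,
                flank5_len=rng.randint(*config.flank5_range),
                flank3_len=max(2, rng.randint(*config.flank3_range)),
                gc_content=config.gc_content,
                name=f"synth-{i + 1:04d}",
            )
        )

    paths = DatasetPaths(
        precursors=out_dir / "precursors.fa",
        matures=out_dir / "matures.fa",
        structures=out_dir / "structures.vienna",
        truth=out_dir / "truth.tsv",
        truth_stars=out_dir / "truth_stars.fa",
    )
    write_fasta([hp.precursor for hp in hairpins], paths.precursors)
    write_fasta([hp.mature for hp in hairpins], paths.matures)
    write_vienna(
        [
            ViennaRecord(
                id=hp.precursor.id,
                seq=hp.precursor.seq,
                structure=hp.structure,
                description=hp.precursor.description,
            )
            for hp in hairpins
        ],
        paths.structures,
    )
    with open(paths.truth, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "precursor_id",
                "mature_id",
                "arm",
                "mature_start",
                "mature_end",
                "star_start",
                "star_end",
                "star_seq",
            ]
        )
        for hp in hairpins:
            s, e = hp.mature_interval
            if hp.true_star_interval is None:
                star_cols = ["", "", ""]
            else:
                lo, hi = hp.true_star_interval
                star_cols = [str(lo + 1), str(hi + 1), hp.true_star]
            writer.writerow(
                [
                    hp.precursor.id,
                    hp.mature.id,
                    hp.arm,
                    str(s + 1),
                    str(e + 1),
                    *star_cols,
                ]
            )
    with open(paths.truth_stars, "w") as fh:
        for hp in hairpins:
            if hp.true_star is not None:
                fh.write(f">{hp.precursor.id}-star seed planted\n")
                fh.write(hp.true_star + "\n")
    return paths
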