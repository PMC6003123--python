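"""Predict the star strand of Arabidopsis MIR156a.

Builds the precursor/mature pair in memory, folds the precursor with
the built-in maximum-pairing folder, and applies the shift-by-two
overhang rule.  The printed interval (1-based) locates the miRNA* on
the precursor; the flag notes that the mature's 3' end is unpaired in
the fold, so the algorithm anchored one position inward.
"""

from mirstar import (
    RnaSequence, extract_star, fold, match_matures, parse_dotbracket,
)

PRECURSOR = RnaSequence(
    "ath-MIR156a",
    "CAAGAGAAACGCAAAGAAACUGACAGAAGAGAGUGAGCACACAAAGGCAAUUUGCA"
    "UAUCAUUGCACUUGCUUCUCUUGCGUGCUCACUGCUCUUUCUGUCAGAUUCCGGUG"
    "CUGAUCUCUUU",
)
MATURE = RnaSequence("ath-miR156a", "GCUCACUGCUCUUUCUGUCAGA")

structure = fold(PRECURSOR.seq)
pair_table = parse_dotbracket(structure)
(entry,) = match_matures([PRECURSOR], [MATURE],
                         {PRECURSOR.id: pair_table})
prediction = extract_star(entry)

print(f"precursor : {PRECURSOR.id} ({len(PRECURSOR.seq)} nt)")
print(f"mature    : {MATURE.seq}  at "
      f"{entry.mature_start + 1}-{entry.mature_end + 1}")
print(f"status    : {prediction.status}")
print(f"star      : {prediction.star_seq}  at "
      f"{prediction.star_start + 1}-{prediction.star_end + 1}")
print(f"flags     : {[str(f) for f in prediction.flags]}")
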