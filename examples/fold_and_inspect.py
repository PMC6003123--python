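"""Fold a short hairpin and inspect its structural features.

The built-in folder maximizes canonical (Watson-Crick + G-U wobble)
base pairs with a minimum loop of 3 nt.  The feature annotation splits
the structure into stems, the terminal loop, and bulge/internal-loop
regions — the geometry the star-extraction algorithm navigates.
"""

from mirstar import annotate_features, fold, parse_dotbracket

seq = "GGGCUAUUAGCUCAGUUGGUUAGAGCGCACCC"
structure = fold(seq)
features = annotate_features(parse_dotbracket(structure))

print(seq)
print(structure)
print(f"pairs         : {structure.count('(')}")
print(f"terminal loops: {features.loops}")
print(f"bulges        : {features.bulges}")
print(f"stems         : {features.stems}")
print("(intervals are 0-based inclusive positions)")
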