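# Methods

## The extraction model

A pre-miRNA hairpin processed by an RNase III enzyme (Dicer/DCL1)
releases a miRNA:miRNA* duplex whose two ends each carry a
two-nucleotide 3′ overhang. mirstar inverts this: given the mature's
interval `[s, e]` on the precursor and the precursor's pair table, the
star interval is `[partner[e] + 2, partner[s] + 2]` in precursor
coordinates (0-based internally; the report boundary converts to
1-based inclusive).

The displacement direction — both endpoints' partners shifted *toward
the precursor 3′ end* — is the unique arm-symmetric choice that yields
a two-nucleotide 3′ overhang on **both** duplex ends, matching RNase
III cleavage geometry. It is applied identically whether the mature
sits on the 5′ or the 3′ arm; in the 3′-arm case the star's final two
nucleotides extend into the terminal loop, which is the correct
geometric consequence of the rule, not an artifact.

### Unpaired mature ends

Mature termini frequently sit in bulges or frayed stem ends and have
no partner. The extractor walks from the unpaired terminus toward the
mature interior until it meets a paired position (the *anchor*),
counting the `k` skipped positions, and then extends the corresponding
star endpoint outward by the same `k`:

```
star_lo = partner[e_anchor] + 2 - k_e
star_hi = partner[s_anchor] + 2 + k_s
```

so the star's extent mirrors the full mature. Each compensation is
recorded as an `end_shifted_5p(k)` / `end_shifted_3p(k)` flag (named
for the mature end that was unpaired). On stems where the duplex
geometry is otherwise intact, this recovers exactly the star that the
unperturbed structure would give; the test suite verifies this against
planted ground truth.

### Degenerate cases — statuses, not exceptions

A batch run over thousands of hairpins must not abort on one bad
entry, so pathological inputs produce a status on the prediction row:

* `mature_in_loop` — no position of the mature is paired (the mature
  lies in a loop); there is no opposite strand to report.
* `self_overlap` — the computed star interval is inverted or
  intersects the mature interval, which only happens on structures
  inconsistent with a mature-on-one-arm hairpin.
* Star intervals reaching past the precursor termini are clipped to
  `[0, n-1]` and flagged `clipped_5p(k)` / `clipped_3p(k)`; biological
  truncation at the precursor end seemed more useful than refusal.
* Stars longer than `overlong_threshold` (default 30 nt, configurable)
  are flagged `overlong`. A large unpaired gap inside the mature puts
  a long bulge on the opposite arm, stretching the star; 30 nt clears
  the canonical 21–24-nt mature range with margin while still
  catching these suspicious products.

## Secondary structure

Structures are consumed as dot-bracket strings and held as a pair
table: an involution over positions with a wildcard for unpaired
sites, pseudoknot-free by construction (single bracket family).

When no structure file is supplied, the built-in folder computes one:
a Nussinov-style dynamic program maximizing the number of canonical
pairs (A-U, G-C and the G-U wobble) subject to a minimum hairpin loop
of `min_loop = 3` unpaired nucleotides — the standard minimal loop.
IUPAC ambiguity letters are accepted in input sequences but never
pair; treating an ambiguous base as unpairable is conservative and
avoids inventing pairing rules. Maximum pairing is not free-energy
minimization: on real precursors RNAfold structures are preferable and
can be supplied via `--structures`; for the hairpin-like sequences
this tool targets, the two routes agree on the worked Arabidopsis
entry. The traceback is deterministic across platforms: at each
subinterval it prefers pairing the left end over leaving it unpaired
and, among equally good partners, takes the smallest index.

For sequences of length ≤ 12 the folder's pair count is checked in the
tests against explicit enumeration of every nested structure, an
oracle that shares no code with the DP.

## Matching, deduplication, evaluation

Every mature is matched into every precursor by exact substring scan,
including overlapping occurrences; matching is many-to-many (miRNA
families recur within and across species). Working entries identical
in (precursor sequence, mature sequence, offset) are collapsed so the
batch is non-redundant. After extraction, predictions with an
identical star sequence are deduplicated *by sequence string*: the
first occurrence is the representative (emitted in FASTA output), and
later rows remain in the TSV with a `duplicate_of` reference, keeping
the star count non-redundant without losing provenance.

Evaluation matches each unique star against a reference set of known
sequences by exact full-string equality after normalization — both
sides are complete mature-length sequences, so identity is the
appropriate predicate; substring containment is available behind a
flag for exploratory use. Matched + unmatched always equals the
unique-star total.

## The synthetic generator

`generate_hairpin` plants a duplex with known truth: a random mature
on the requested arm, the opposite arm its reverse complement, base-
by-base pairing in the planted structure, a terminal loop, and
unpaired flanks outside the duplex. The planted star is read directly
off the construction geometry (endpoint partners, displaced by two),
so `extract_star` can be tested against ground truth the extractor
never sees. Structures are **planted, not folded**, isolating the
extraction algorithm from folder behavior; the folder is exercised by
its own oracle instead.

Defaults model canonical biology: mature 21 nt (datasets draw 19–24),
loop 3–10 nt, both arms equally likely, uniform base composition
(`gc_content = 0.5`, adjustable for folder stress tests), flanks 2–8
nt so the 3′ overhang has room (a 5′-arm mature needs ≥ 2 nt of 3′
flank; shorter flanks deliberately produce clipped stars for testing).
Perturbations plant bulges on the star arm, stem mismatches (the
opposite base is redrawn to exclude both Watson–Crick and wobble
pairing), frayed mature ends of chosen size, and the fully
loop-resident mature. All randomness is seeded; identical (config,
seed) reproduce byte-identical files, and per-hairpin child seeds are
drawn below 2^31.

What the generator does *not* emulate: thermodynamically realistic
stems, miRBase family redundancy, sequencing error, or expression
levels. Passing the planted-truth tests therefore demonstrates that
the extraction rule is implemented exactly, not that real annotated
stars always obey the two-nucleotide-overhang rule — annotated
duplexes with three-nucleotide overhangs exist and are out of this
tool's contract by design.

## Problem sizes and determinism

The test suite and the acceptance script use cohorts of 1000 perfect
stems, 500 frayed-end cases, 50 loop-resident matures, 200 folding
oracles at n ≤ 12, and a 100-hairpin end-to-end dataset — large enough
that a systematic off-by-one anywhere in the coordinate arithmetic
would surface, while keeping a full run under a minute. `predict` is
fully deterministic given its inputs; randomness exists only in
`simulate`.

## Known limitations

* Maximum-pairing folding can differ substantially from MFE structures
  on long or multi-branched sequences; supply RNAfold structures for
  production use on real precursors.
* The extractor trusts the supplied structure; a structure inconsistent
  with a duplex-bearing hairpin yields `self_overlap`/`overlong`
  flags rather than a corrected prediction.
* Only nested structures are supported (no pseudoknots), matching
  standard dot-bracket conventions.
* Evaluation is identity-based; near-miss stars (e.g. one-nucleotide
  register shifts from non-canonical processing) count as unmatched.
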