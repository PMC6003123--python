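# mirstar

Predict the **miRNA\* (star) strand** of a miRNA:miRNA\* duplex from a
pre-miRNA hairpin, given the precursor and mature sequences.

MicroRNA biogenesis ends with an RNase III enzyme (Dicer in animals,
DCL1 in plants) excising a ~22-nt duplex from the precursor hairpin.
The cleavage leaves a signature **two-nucleotide 3′ overhang on each
duplex end**: each strand's 3′ terminus extends two nucleotides past
the other strand's 5′ terminus. mirstar exploits this geometry. With a
pair table `partner[·]` derived from the precursor's secondary
structure and a mature occupying the interval `[s, e]` on one arm, the
star strand is

```
star = [ partner[e] + 2 ,  partner[s] + 2 ]     (0-based, inclusive)
```

i.e. the partners of the mature's endpoints, each displaced two
positions toward the precursor 3′ end. When a mature endpoint is
unpaired (sitting in a bulge or frayed end), the algorithm walks inward
to the nearest paired anchor, counts the `k` positions skipped, and
adds them back to the corresponding star end, so the output is still
the full opposite strand. Degenerate hairpins are reported, not
crashed on: a mature that is entirely single-stranded yields
`mature_in_loop`; a structure whose implied star would collide with
the mature yields `self_overlap`; stars stretched past 30 nt by a
large bulge are flagged `overlong`.

Structures come from either of two routes:

* a **Vienna/RNAfold dot-bracket file** you supply (`--structures`),
  for thermodynamic folds, or
* the **built-in folder**: a deterministic Nussinov-style dynamic
  program that maximizes canonical (Watson–Crick + G-U wobble) pairs
  with a minimum hairpin loop of 3 nt.

The package is aimed at small-RNA analysts who have hairpin and mature
sequences (e.g. miRBase-style FASTA files) and want the passenger
strands — to annotate duplexes, or to build star-sequence queries for
small-RNA-seq data.

## Worked example

The Arabidopsis MIR156a precursor (123 nt) with its annotated mature
(`examples/predict_worked_entry.py`):

```
precursor : ath-MIR156a (123 nt)
mature    : GCUCACUGCUCUUUCUGUCAGA  at 83-104
status    : ok
star      : UGACAGAAGAGAGUGAGCAC  at 21-40
flags     : ['end_shifted_3p(1)']
```

The mature sits on the 3′ arm at positions 83–104 (1-based); its
predicted star lies on the 5′ arm at 21–40. The flag records that the
mature's 3′-terminal nucleotide is unpaired in the fold, so the
extraction anchored one position inward and compensated on the star's
end. The same star is produced from an RNAfold structure of this
precursor and from the built-in folder.

The same pipeline is available from the shell:

```sh
mirstar predict --precursors hairpins.fa --matures matures.fa \
    [--structures folds.vienna] --out predictions.tsv
mirstar fold --in hairpins.fa --out folds.vienna
mirstar evaluate --predictions predictions.tsv --known matures.fa
mirstar simulate --n 100 --seed 7 --out-dir data/
```

`predict` writes a TSV report (one row per precursor–mature pair,
1-based coordinates, status and flags, duplicate stars marked) and a
JSON run summary with the stage counts; `--format fasta|both` adds a
FASTA of the unique star sequences. `simulate` writes synthetic
hairpins with planted duplexes and a ground-truth table — see
`examples/synthetic_benchmark.py` for the library-level version, which
recovers 100/100 planted stars.

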