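import random

import pytest

from mirstar import (
    RnaSequence,
    dedup_stars,
    evaluate,
    extract_star,
    generate_hairpin,
    match_matures,
    parse_dotbracket,
    resolve_paired_anchor,
)
from mirstar.duplex import (
    INWARD_FROM_3P,
    INWARD_FROM_5P,
    DuplexEntry,
    MatureInLoopError,
    StarPrediction,
)
from .helpers import brute_force_occurrences, closed_form_star, rc


def _entry_from_hairpin(hp):
    pt = parse_dotbracket(hp.structure)
    s, e = hp.mature_interval
    return DuplexEntry(
        precursor_id=hp.precursor.id,
        precursor_seq=hp.precursor.seq,
        mature_id=hp.mature.id,
        mature_seq=hp.mature.seq,
        mature_start=s,
        mature_end=e,
        pair_table=pt,
    )


class TestMatchMatures:
    def test_worked_entry_single_occurrence(self, ath_precursor, ath_mature,
                                            ath_vienna):
        pt = parse_dotbracket(ath_vienna.structure)
        entries = match_matures([ath_precursor], [ath_mature],
                                {ath_precursor.id: pt})
        assert len(entries) == 1
        e = entries[0]
        occ = brute_force_occurrences(ath_mature.seq, ath_precursor.seq)
        assert occ == [e.mature_start]
        assert e.mature_end - e.mature_start + 1 == len(ath_mature.seq)

    def test_no_match_gives_empty_list(self):
        prec = RnaSequence("p", "GGGGAAAACCCC")
        mat = RnaSequence("m", "UUUUUUUUUUUU")
        assert match_matures([prec], [mat], {"p": parse_dotbracket("." * 12)}) == []

    def test_overlapping_occurrences_counted(self):
        prec = RnaSequence("p", "AAA")
        mat = RnaSequence("m", "AA")
        entries = match_matures([prec], [mat],
                                {"p": parse_dotbracket("...")})
        starts = sorted(e.mature_start for e in entries)
        assert starts == brute_force_occurrences("AA", "AAA") == [0, 1]

    def test_many_to_many_with_dedup(self):
        # two precursor records with the same sequence: entries collapse
        seq = "GG" + "ACGUACGUACGUACGUA" + "CC"
        pt = parse_dotbracket("." * len(seq))
        precs = [RnaSequence("p1", seq), RnaSequence("p2", seq)]
        mats = [RnaSequence("m", "ACGUACGU")]
        entries = match_matures(precs, mats, {"p1": pt, "p2": pt})
        starts = brute_force_occurrences("ACGUACGU", seq)
        assert len(entries) == len(starts)
        assert all(e.precursor_id == "p1" for e in entries)


class TestResolvePairedAnchor:
    def test_paired_position_is_identity(self):
        pt = parse_dotbracket("((((....))))")
        assert resolve_paired_anchor(pt, 0, INWARD_FROM_5P, (0, 3)) == (0, 0)

    def test_walk_from_unpaired_start(self):
        pt = parse_dotbracket("..((((....))))")
        assert resolve_paired_anchor(pt, 0, INWARD_FROM_5P, (0, 5)) == (2, 2)

    def test_walk_from_unpaired_end(self):
        pt = parse_dotbracket("((((....))))..")
        assert resolve_paired_anchor(pt, 13, INWARD_FROM_3P, (8, 13)) == (11, 2)

    def test_all_unpaired_raises_loop_signal(self):
        pt = parse_dotbracket("((((....))))")
        with pytest.raises(MatureInLoopError):
            resolve_paired_anchor(pt, 4, INWARD_FROM_5P, (4, 7))


class TestExtractStar:
    def test_closed_form_oracle_over_random_stems(self):
        # perfect stems: star == reverse-complement arm shifted by two
        for seed in range(200):
            arm = "five_prime" if seed % 2 else "three_prime"
            hp = generate_hairpin(mature_len=21, loop_len=5, arm=arm,
                                  seed=seed)
            pred = extract_star(_entry_from_hairpin(hp))
            lo, hi, star = closed_form_star(hp.precursor.seq, hp.mature.seq)
            assert pred.status == "ok" and pred.flags == ()
            assert (pred.star_start, pred.star_end, pred.star_seq) == \
                (lo, hi, star)

    def test_star_never_overlaps_mature(self):
        for seed in range(100):
            hp = generate_hairpin(seed=seed)
            pred = extract_star(_entry_from_hairpin(hp))
            s, e = hp.mature_interval
            assert pred.star_end < s or pred.star_start > e

    def test_mature_in_loop_status(self):
        seq = "GGGG" + "A" * 21 + "CCCC"
        db = "...." + "." * 21 + "...."
        entry = DuplexEntry("p", seq, "m", "A" * 21, 4, 24,
                            parse_dotbracket(db))
        pred = extract_star(entry)
        assert pred.status == "mature_in_loop"
        assert pred.star_start is None and pred.star_seq is None

    def test_overlong_flag_on_large_bulge(self):
        from mirstar import Bulge
        hp = generate_hairpin(mature_len=21, loop_len=5,
                              perturbations=[Bulge(position=10, size=15)],
                              seed=11)
        pred = extract_star(_entry_from_hairpin(hp))
        assert pred.status == "ok"
        assert len(pred.star_seq) == 21 + 15
        assert pred.flag("overlong") is not None

    def test_clipping_at_precursor_end(self):
        # 5'-arm mature with no 3' flank: the +2 overhang runs off the end
        hp = generate_hairpin(mature_len=21, loop_len=5, arm="five_prime",
                              flank3_len=0, seed=5)
        pred = extract_star(_entry_from_hairpin(hp))
        assert pred.status == "ok"
        clip = pred.flag("clipped_3p")
        assert clip is not None and clip.amount == 2
        assert pred.star_seq == hp.true_star

    def test_worked_entry_with_rnafold_structure(self, ath_precursor,
                                                 ath_mature, ath_vienna):
        pt = parse_dotbracket(ath_vienna.structure)
        (entry,) = match_matures([ath_precursor], [ath_mature],
                                 {ath_precursor.id: pt})
        pred = extract_star(entry)
        assert pred.status == "ok"
        # hand application of the shift rule to the folded structure
        assert (pred.star_start, pred.star_end) == (20, 39)
        assert pred.star_seq == "UGACAGAAGAGAGUGAGCAC"
        shift = pred.flag("end_shifted_3p")
        assert shift is not None and shift.amount == 1

    def test_duplex_reciprocity_on_perfect_stems(self):
        # using the extracted star as the query mature returns a region
        # consistently shifted back onto the original mature's arm
        for seed in range(20):
            hp = generate_hairpin(mature_len=21, loop_len=5,
                                  arm="five_prime", seed=seed)
            pt = parse_dotbracket(hp.structure)
            first = extract_star(_entry_from_hairpin(hp))
            occ = brute_force_occurrences(first.star_seq, hp.precursor.seq)
            assert len(occ) == 1
            star_as_mature = DuplexEntry(
                hp.precursor.id, hp.precursor.seq, "star", first.star_seq,
                occ[0], occ[0] + len(first.star_seq) - 1, pt,
            )
            second = extract_star(star_as_mature)
            assert second.status == "ok"
            s, e = hp.mature_interval
            # the round trip lands on the mature's arm, two positions in
            assert abs(second.star_start - s) <= 4
            assert abs(second.star_end - e) <= 4


class TestDedupAndEvaluate:
    def _ok(self, prec_id, seq, lo, hi):
        pt = parse_dotbracket("." * len(seq))
        entry = DuplexEntry(prec_id, seq, "m", seq[5:10], 5, 9, pt)
        return StarPrediction(entry=entry, star_start=lo, star_end=hi,
                              star_seq=seq[lo : hi + 1], status="ok")

    def test_duplicates_marked_not_dropped(self):
        seq1 = "AAAAA" + "GCGCA" + "UUUUUUUUUUGGGGGGGGGG"
        seq2 = "CCCCC" + "GCGCA" + "AAAAAAAAAAGGGGGGGGGG"
        p1 = self._ok("p1", seq1, 20, 29)
        p2 = self._ok("p2", seq2, 20, 29)  # same star string GGGGGGGGGG
        assert p1.star_seq == p2.star_seq
        out = dedup_stars([p1, p2])
        assert len(out) == 2
        assert out[0].duplicate_of is None
        assert out[1].duplicate_of is not None

    def test_distinct_stars_all_kept(self):
        preds = [
            self._ok("p", "AAAAAGCGCAUUUUUUUUUUGGGGGGGGGG", 20, 29),
            self._ok("p", "AAAAAGCGCAUUUUUUUUUUGCGCGCGCGC", 20, 29),
        ]
        out = dedup_stars(preds)
        assert all(p.duplicate_of is None for p in out)

    def test_empty_input(self):
        assert dedup_stars([]) == []

    def test_evaluate_all_known(self):
        p = self._ok("p", "AAAAAGCGCAUUUUUUUUUUGGGGGGGGGG", 20, 29)
        known = [RnaSequence("k", "GGGGGGGGGG")]
        summary = evaluate([p], known)
        assert (summary.matched, summary.unmatched, summary.total) == (1, 0, 1)
        assert summary.matched_pairs[0][1] == "k"

    def test_evaluate_empty_known(self):
        p = self._ok("p", "AAAAAGCGCAUUUUUUUUUUGGGGGGGGGG", 20, 29)
        summary = evaluate([p], [])
        assert summary.matched == 0 and summary.unmatched == 1

    def test_conservation(self):
        # matched + unmatched == number of unique stars
        rng = random.Random(0)
        preds = []
        for i in range(10):
            stem = "".join(rng.choice("ACGU") for _ in range(10))
            seq = "AAAAAGCGCAUUUUUUUUUU" + stem
            preds.append(self._ok(f"p{i}", seq, 20, 29))
        known = [RnaSequence("k", preds[0].star_seq)]
        summary = evaluate(preds, known)
        uniq = len({p.star_seq for p in preds})
        assert summary.matched + summary.unmatched == summary.total == uniq
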