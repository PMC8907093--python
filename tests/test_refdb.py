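"""Reference curation: primer location, trimming, padding, cutting."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amf_lsu.iupac import SequenceError, revcomp
from amf_lsu.refdb import (
    PrimerError, PrimerPair, ReadLengthCut, ReadPair, build_reference_db,
    cut_reference_to_read_lengths, find_primer_site, pad_to_region,
    trim_read_pair, trim_reference,
)

PRIMERS = PrimerPair()
F, R = PRIMERS.forward_seq, PRIMERS.reverse_seq

dna = st.text(alphabet="ACGT", min_size=30, max_size=120)


def brute_force_best_window(seq: str, primer: str):
    """Oracle: scan every window, count incompatible IUPAC positions."""
    from amf_lsu.iupac import IUPAC_MASK
    best = None
    for i in range(len(seq) - len(primer) + 1):
        mism = sum(1 for a, b in zip(seq[i:i + len(primer)], primer)
                   if not (IUPAC_MASK[a] & IUPAC_MASK[b]))
        if best is None or mism < best[1]:
            best = (i, mism)
    return best


class TestFindPrimerSite:
    @pytest.mark.parametrize("seq,primer,rate,interval,mism", [
        ("GGAAACC", "AAA", 0.0, (2, 5), 0),
        ("GGAGACC", "ARA", 0.0, (2, 5), 0),          # R matches A or G
        ("TTTTAAAT", "AAAA", 0.25, (3, 7), 1),       # one mismatch allowed
    ])
    def test_examples(self, seq, primer, rate, interval, mism):
        m = find_primer_site(seq, primer, rate)
        assert (m.start, m.end) == interval
        assert m.mismatches == mism

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
            primer = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8))
            m = find_primer_site(seq, primer, 0.5)
            pos, mism = brute_force_best_window(seq, primer)
            if m is not None:
                assert (m.start, m.mismatches) == (pos, mism)
            else:
                assert mism > int(0.5 * len(primer))

    def test_n_matches_anything(self):
        m = find_primer_site("GGNNNCC", "AAA", 0.0)
        assert m is not None and m.mismatches == 0

    def test_no_match_returns_none(self):
        assert find_primer_site("TTTTTTTT", "AAAA", 0.0) is None

    def test_invalid_characters_rejected(self):
        with pytest.raises(SequenceError):
            find_primer_site("ACGZ", "AA", 0.0)


class TestTrimReference:
    @given(payload=dna)
    @settings(max_examples=40, deadline=None)
    def test_round_trip_both_orientations(self, payload):
        construct = F + payload + revcomp(R)
        assert trim_reference(construct, PRIMERS).region == payload
        res = trim_reference(revcomp(construct), PRIMERS)
        assert res.region == payload
        assert res.orientation == "reverse"

    def test_untrimmed_fallback(self):
        raw = "ACGT" * 50
        res = trim_reference(raw, PRIMERS)
        assert not res.trimmed and res.region == raw

    def test_reverse_before_forward_is_malformed(self):
        raw = revcomp(R) + "ACGT" * 10 + F
        with pytest.raises(PrimerError):
            trim_reference(raw, PRIMERS)


class TestPadToRegion:
    def test_arithmetic(self):
        assert pad_to_region("ACGTACG", 10, "start") == ("ACGTACG" + "NNN", 0, 3)
        assert pad_to_region("ACGTACGTAC", 10) == ("ACGTACGTAC", 0, 0)
        assert pad_to_region("ACGTAC", 10, "end") == ("NNNN" + "ACGTAC", 4, 0)

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            pad_to_region("A" * 11, 10)

    @given(payload=dna, target_extra=st.integers(0, 20))
    @settings(max_examples=30, deadline=None)
    def test_strip_recovers_input(self, payload, target_extra):
        target = len(payload) + target_extra
        padded, pl, pr = pad_to_region(payload, target, "start")
        assert len(padded) == target
        assert padded.rstrip("N")[:len(payload)] == payload or set(payload) == {"N"}


def _synthetic_records(n=3, seed=5, region_len=60):
    rng = np.random.default_rng(seed)
    recs, fam_rows = [], []
    for i in range(n):
        x = "".join("ACGT"[j] for j in rng.integers(0, 4, size=region_len))
        recs.append((f"ref{i}", F + x + revcomp(R)))
        fam_rows.append({"id": f"ref{i}", "group_label": f"Fam{i % 2}",
                         "taxon": "", "accession": "", "is_amf": "1"})
    import pandas as pd
    return recs, pd.DataFrame(fam_rows)


class TestBuildReferenceDB:
    def test_known_construction(self):
        recs, fam = _synthetic_records()
        db = build_reference_db(recs, fam)
        assert len(db) == 3
        assert db.target_region_length == 60
        assert all(r.pad_left == r.pad_right == 0 for r in db.records)
        assert all(r.trimmed for r in db.records)

    def test_short_record_gets_padded(self):
        recs, fam = _synthetic_records()
        recs[1] = (recs[1][0], F + "ACGTACGTAC" + revcomp(R))  # 10 bp region
        db = build_reference_db(recs, fam)
        rec = db.get("ref1")
        assert rec.pad_right == 50 and rec.region_seq.endswith("N" * 50)

    def test_eleven_families(self, small_fixture):
        # a family map naming n families yields n family names in the DB
        import pandas as pd
        fam = small_fixture.family_map
        db = build_reference_db(list(small_fixture.reference_raw.items()), fam)
        assert len(db.family_names) == small_fixture.config.n_families

    def test_empty_fasta_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            build_reference_db([], pd.DataFrame(columns=["id", "group_label"]))

    def test_missing_family_entry_lists_offender(self):
        recs, fam = _synthetic_records()
        with pytest.raises(ValueError, match="ref2"):
            build_reference_db(recs, fam[fam["id"] != "ref2"])

    def test_duplicate_ids_rejected(self):
        recs, fam = _synthetic_records()
        recs.append(recs[0])
        with pytest.raises(ValueError, match="ref0"):
            build_reference_db(recs, fam)

    def test_order_independent_up_to_record_order(self):
        recs, fam = _synthetic_records()
        db1 = build_reference_db(recs, fam)
        db2 = build_reference_db(list(reversed(recs)), fam)
        assert {r.id: r.region_seq for r in db1.records} == \
               {r.id: r.region_seq for r in db2.records}


class TestCutReference:
    def test_small_example(self):
        recs = [("a", F + "AAACCCGGGTTT" + revcomp(R)),
                ("b", F + "ACGTACGTACGT" + revcomp(R))]
        import pandas as pd
        fam = pd.DataFrame([{"id": i, "group_label": "X", "is_amf": "1"}
                            for i in ("a", "b")])
        db = build_reference_db(recs, fam)
        frags = cut_reference_to_read_lengths(db, ReadLengthCut(3, 3))
        assert frags["a"] == ("AAA", revcomp("TTT"))
        assert frags["a"][1] == "AAA"

    def test_fragments_partition_region(self):
        recs, fam = _synthetic_records(region_len=60)
        db = build_reference_db(recs, fam)
        frags = cut_reference_to_read_lengths(db, ReadLengthCut(30, 30))
        for rec in db.records:
            r1, r2 = frags[rec.id]
            assert r1 + revcomp(r2) == rec.region_seq

    def test_cut_exceeding_region_rejected(self):
        recs, fam = _synthetic_records(region_len=60)
        db = build_reference_db(recs, fam)
        with pytest.raises(ValueError):
            cut_reference_to_read_lengths(db, ReadLengthCut(40, 40))

    def test_150_150_cut_on_600bp_region(self):
        rng = np.random.default_rng(9)
        region = "".join("ACGT"[j] for j in rng.integers(0, 4, size=600))
        import pandas as pd
        db = build_reference_db(
            [("a", F + region + revcomp(R)), ("b", F + region + revcomp(R))][:1]
            + [("b", F + region[::-1] + revcomp(R))],
            pd.DataFrame([{"id": i, "group_label": "X", "is_amf": "1"}
                          for i in ("a", "b")]))
        frags = cut_reference_to_read_lengths(db, ReadLengthCut(150, 150))
        assert all(len(r1) == 150 and len(r2) == 150 for r1, r2 in frags.values())


class TestTrimReadPair:
    def test_payload_recovered(self):
        pair = ReadPair("r", F + "ACGTACGT", R + "TTTTCCCC")
        out = trim_read_pair([pair], PRIMERS)
        assert out.pairs[0].r1_seq == "ACGTACGT"
        assert out.pairs[0].r2_seq == "TTTTCCCC"

    def test_missing_primer_dropped_and_counted(self):
        good = ReadPair("g", F + "ACGTACGT", R + "ACGTACGT")
        bad = ReadPair("b", "T" * 40, R + "ACGT")
        out = trim_read_pair([good, bad], PRIMERS, policy="drop")
        assert [p.id for p in out.pairs] == ["g"]
        assert out.n_missing_primer == 1 and out.dropped_ids == ["b"]

    def test_one_mismatch_within_rate_still_trimmed(self):
        # |LROR| = 17, rate 0.1 -> floor(1.7) = 1 mismatch allowed
        mutated = "T" + F[1:]
        assert mutated != F
        pair = ReadPair("r", mutated + "ACGTACGT", R + "GGGG")
        out = trim_read_pair([pair], PRIMERS)
        assert out.pairs[0].r1_seq == "ACGTACGT"
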