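import math
import random

import numpy as np
import pytest

from _oracles import sw_score_oracle
from orthored.seqdata import Dataset, SequenceRecord
from orthored.simsearch import (
    FILL_EVALUE,
    SimilarityHit,
    all_vs_all_matrix,
    evalue_from_score,
    local_align,
    search_one_vs_all,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA) for _ in range(n))


class TestLocalAlign:
    def test_identical_sequences_align_fully(self):
        seq = "MKVLHEAGAWGHEELLIAM"
        score, length, ident = local_align(seq, seq)
        assert length == len(seq)
        assert ident == len(seq)
        assert score > 0

    def test_textbook_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        score, _, _ = local_align(a, b)
        assert score == sw_score_oracle(a, b)

    def test_all_negative_scores_floor_at_zero(self):
        # tryptophan runs vs prolines: no positive-scoring cell
        score, length, ident = local_align("WWWW", "PPPP")
        assert (score, length, ident) == (0.0, 0, 0)

    def test_score_symmetric(self):
        rng = random.Random(7)
        for _ in range(20):
            a = random_protein(rng, rng.randint(10, 60))
            b = random_protein(rng, rng.randint(10, 60))
            assert local_align(a, b)[0] == local_align(b, a)[0]

    def test_random_pairs_match_dp_oracle(self):
        rng = random.Random(1234)
        for _ in range(25):
            a = random_protein(rng, rng.randint(8, 40))
            b = random_protein(rng, rng.randint(8, 40))
            got, _, _ = local_align(a, b)
            assert got == sw_score_oracle(a, b)


class TestEvalue:
    def test_monotone_decreasing_in_score(self):
        evs = [evalue_from_score(s, 100, 10_000) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_scales_with_search_space(self):
        assert evalue_from_score(50, 100, 1000) < evalue_from_score(50, 100, 100_000)


def _family_dataset():
    base = (
        "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHD"
    )
    variant1 = base[:40] + "A" + base[41:]
    variant2 = base[:20] + "GG" + base[22:60] + base[60:].replace("Q", "E")
    unrelated = "WWPWWPWWPGGWWPWWPWWHHHWWKWW"
    return Dataset(
        [
            SequenceRecord("A|q", "A", base),
            SequenceRecord("B|v1", "B", variant1),
            SequenceRecord("C|v2", "C", variant2),
            SequenceRecord("D|junk", "D", unrelated),
        ]
    )


class TestSearchOneVsAll:
    def test_self_hit_has_full_identity(self):
        ds = _family_dataset()
        hits = search_one_vs_all(ds.get("A|q"), ds)
        self_hit = next(h for h in hits if h.subject_id == "A|q")
        assert self_hit.percent_identity == 100.0
        assert self_hit.alignment_length == len(ds.get("A|q"))

    def test_sorted_ascending_and_below_cutoff(self):
        ds = _family_dataset()
        hits = search_one_vs_all(ds.get("A|q"), ds, evalue_cutoff=1e-3)
        evs = [h.evalue for h in hits]
        assert evs == sorted(evs)
        assert all(e < 1e-3 for e in evs)
        assert "D|junk" not in {h.subject_id for h in hits}

    def test_random_query_finds_nothing(self):
        ds = Dataset(
            [
                SequenceRecord("A|s1", "A", "MPPGHKLNDE"),
                SequenceRecord("B|s2", "B", "TSSIRQVCYW"),
            ]
        )
        query = SequenceRecord("C|rnd", "C", "WNDCLKHMIG")
        assert search_one_vs_all(query, ds) == []

    def test_tighter_cutoff_returns_subset(self):
        ds = _family_dataset()
        loose = {h.subject_id for h in search_one_vs_all(ds.get("A|q"), ds, evalue_cutoff=1e-2)}
        tight = {h.subject_id for h in search_one_vs_all(ds.get("A|q"), ds, evalue_cutoff=1e-20)}
        assert tight <= loose

    def test_ranking_matches_exhaustive_pairwise_oracle(self):
        ds = _family_dataset()
        query = ds.get("A|q")
        hits = search_one_vs_all(query, ds, evalue_cutoff=1e-3)
        oracle_scores = {
            rec.seq_id: sw_score_oracle(query.residues, rec.residues) for rec in ds
        }
        got_order = [h.subject_id for h in hits]
        expected = sorted(got_order, key=lambda s: -oracle_scores[s])
        assert got_order == expected


class TestAllVsAllMatrix:
    def test_unrelated_pair_gets_fill_value(self):
        ds = Dataset(
            [
                SequenceRecord("A|s1", "A", "MPPGHKLNDEMPPGHKLNDE"),
                SequenceRecord("B|s2", "B", "WCYTSSIRQVWCYTSSIRQV"),
            ]
        )
        m = all_vs_all_matrix(ds)
        assert m.evalue("A|s1", "B|s2") == FILL_EVALUE
        assert m.evalue("B|s2", "A|s1") == FILL_EVALUE
        assert m.evalue("A|s1", "A|s1") < 1e-3

    def test_single_record_dataset(self):
        ds = Dataset([SequenceRecord("A|s1", "A", "MKVLHEAGAWGHEELLIAM")])
        m = all_vs_all_matrix(ds)
        assert len(m) == 1
        assert m.evalue("A|s1", "A|s1") > 0

    def test_total_over_all_ordered_pairs(self):
        ds = _family_dataset()
        m = all_vs_all_matrix(ds)
        for a in m.ids:
            for b in m.ids:
                assert m.evalue(a, b) > 0

    def test_family_pairs_populated_and_consistent_with_pairwise_engine(self):
        ds = _family_dataset()
        sub = ds.subset({"A|q", "B|v1", "C|v2"})
        m = all_vs_all_matrix(sub)
        db_len = sub.total_residues()
        for a in sub.seq_ids:
            for b in sub.seq_ids:
                score, length, _ = local_align(sub.get(a).residues, sub.get(b).residues)
                expected = evalue_from_score(score, len(sub.get(a)), db_len)
                assert m.evalue(a, b) == pytest.approx(expected)


class TestSimilarityHitValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(evalue=0.0),
            dict(evalue=-1.0),
            dict(alignment_length=0),
            dict(percent_identity=101.0),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(
            query_id="q", subject_id="s", evalue=1e-5, percent_identity=90.0,
            alignment_length=50, score=100.0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimilarityHit(**base)
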