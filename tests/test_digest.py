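import random

import pytest

from cissers.digest import (
    FragmentLane,
    digest_sequence,
    link_lanes,
    predict_amplicons,
    rank_caps_candidates,
)
from cissers.enzyme_db import Enzyme, compile_motif, reverse_complement_pattern
from cissers.fixtures import make_polyT_probe, make_snp_allele_pair
from cissers.scanner import scan_record
from cissers.sequence_io import SequenceRecord

from conftest import random_iupac


class TestDigestSequence:
    def test_probe_single_cut(self, probe_60, ecori):
        lane = digest_sequence(probe_60, [ecori])
        assert lane.fragments == (28, 32)

    def test_no_sites_yields_full_length(self, ecori):
        rec = SequenceRecord("r", "G" * 60)
        assert digest_sequence(rec, [ecori]).fragments == (60,)

    def test_no_enzymes_yields_full_length(self):
        rec = SequenceRecord("r", "G" * 60)
        assert digest_sequence(rec, []).fragments == (60,)

    def test_coincident_isoschizomer_cuts_collapse(self, probe_60):
        iso1 = Enzyme("EcoRI", "GAATTC", 1)
        iso2 = Enzyme("FakeIso", "GAATTC", 1)
        lane = digest_sequence(probe_60, [iso1, iso2])
        assert lane.fragments == (28, 32)

    def test_missing_offset_falls_back_with_warning(self, probe_60):
        enz = Enzyme("NoOffset", "GAATTC")
        with pytest.warns(UserWarning, match="site start"):
            lane = digest_sequence(probe_60, [enz])
        assert lane.fragments == (27, 33)

    def test_type_iis_offset_clamped_at_end(self):
        # recognition site near the 3' end; cut lands past the sequence
        enz = Enzyme("BsgI", "GTGCAG", 16)
        rec = SequenceRecord("r", "C" * 40 + "GTGCAG" + "C" * 4)
        lane = digest_sequence(rec, [enz])
        assert lane.total_length == 50  # clamped cut produces no fragment
        assert lane.fragments == (50,)

    def test_length_conservation_random(self):
        rng = random.Random(21)
        for _ in range(100):
            seq = "".join(rng.choices("ACGT", k=rng.randint(30, 800)))
            rec = SequenceRecord("r", seq)
            enzymes = [
                Enzyme(f"E{j}", random_iupac(rng, rng.randint(3, 6), 0.2),
                       rng.randint(-2, 8))
                for j in range(rng.randint(1, 4))
            ]
            lane = digest_sequence(rec, enzymes)
            assert lane.total_length == len(seq)

    def test_adding_enzyme_never_decreases_fragment_count(self):
        rng = random.Random(8)
        seq = "".join(rng.choices("ACGT", k=600))
        rec = SequenceRecord("r", seq)
        pool = [Enzyme("TaqI", "TCGA", 1), Enzyme("EcoRI", "GAATTC", 1),
                Enzyme("Mse", "TTAA", 1)]
        for k in range(len(pool)):
            fewer = digest_sequence(rec, pool[:k])
            more = digest_sequence(rec, pool[: k + 1])
            assert len(more.fragments) >= len(fewer.fragments)
            assert more.total_length == fewer.total_length == 600

    def test_both_strand_digest_adds_minus_side_cuts(self):
        # non-palindromic site present only as its reverse complement
        enz = Enzyme("BsgI", "GTGCAG", 2)
        rec = SequenceRecord("r", "C" * 20 + "CTGCAC" + "C" * 20)
        assert digest_sequence(rec, [enz]).fragments == (46,)
        assert len(digest_sequence(rec, [enz], "both").fragments) == 2


class TestFragmentLane:
    def test_fragments_sorted_multiset(self):
        lane = FragmentLane("x", (300, 100, 100))
        assert lane.fragments == (100, 100, 300)
        assert lane.multiset[100] == 2
        assert lane.band_lengths() == [100, 300]

    def test_zero_length_fragment_rejected(self):
        with pytest.raises(ValueError):
            FragmentLane("x", (0, 10))


class TestLinkLanes:
    def test_multiset_union(self):
        het = link_lanes(
            [FragmentLane("wt", (100, 200)), FragmentLane("mut", (150,))], "het"
        )
        assert het.fragments == (100, 150, 200)
        assert het.source == "linked"

    def test_self_link_doubles_multiplicity(self):
        lane = FragmentLane("a", (100, 200))
        doubled = link_lanes([lane, lane], "aa")
        assert doubled.multiset == {100: 2, 200: 2}
        assert doubled.band_lengths() == [100, 200]  # one band per length

    def test_band_set_is_union(self):
        a = FragmentLane("a", (100, 250))
        b = FragmentLane("b", (250, 400))
        linked = link_lanes([a, b], "ab")
        assert set(linked.band_lengths()) == set(a.band_lengths()) | set(
            b.band_lengths()
        )

    def test_requires_two_lanes(self):
        with pytest.raises(ValueError):
            link_lanes([FragmentLane("a", (100,))], "x")


class TestPredictAmplicons:
    def test_constructed_template(self):
        # forward primer at 10, reverse primer binding ends at 160
        fwd = "GACCTAGGTC"[:8]
        rev_rc = "TTGCGCAA"  # what appears on the forward strand
        seq = "A" * 10 + fwd + "A" * (160 - 10 - 8 - 8) + rev_rc + "A" * 40
        rec = SequenceRecord("t", seq)
        from cissers.sequence_io import reverse_complement

        fwd_p = compile_motif("F", fwd)
        rev_p = compile_motif("R", reverse_complement(rev_rc))
        amps = predict_amplicons(rec, fwd_p, rev_p, max_len=500)
        assert amps == [(10, 160, 150)]

    def test_reverse_upstream_of_forward_gives_nothing(self):
        seq = "TTGCGCAA" + "C" * 30 + "GACCTAGG"
        rec = SequenceRecord("t", seq)
        from cissers.sequence_io import reverse_complement

        fwd_p = compile_motif("F", "GACCTAGG")
        rev_p = compile_motif("R", reverse_complement("TTGCGCAA"))
        assert predict_amplicons(rec, fwd_p, rev_p, 500) == []

    def test_two_forward_sites_share_one_reverse(self):
        from cissers.sequence_io import reverse_complement

        f = "GACCTAGG"
        r_rc = "TTGCGCAA"
        seq = f + "C" * 10 + f + "C" * 10 + r_rc
        rec = SequenceRecord("t", seq)
        amps = predict_amplicons(
            rec, compile_motif("F", f), compile_motif("R", reverse_complement(r_rc)), 500
        )
        assert len(amps) == 2
        assert all(end == len(seq) for _s, end, _l in amps)

    def test_max_len_filters(self):
        from cissers.sequence_io import reverse_complement

        f, r_rc = "GACCTAGG", "TTGCGCAA"
        seq = f + "C" * 100 + r_rc
        rec = SequenceRecord("t", seq)
        args = (rec, compile_motif("F", f), compile_motif("R", reverse_complement(r_rc)))
        assert len(predict_amplicons(*args, max_len=500)) == 1
        assert predict_amplicons(*args, max_len=50) == []

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(13)
        from cissers.enzyme_db import compile_motif as cm

        for _ in range(30):
            seq = "".join(rng.choices("ACGT", k=rng.randint(50, 300)))
            rec = SequenceRecord("t", seq)
            fwd = cm("F", "".join(rng.choices("ACGT", k=5)))
            rev = cm("R", "".join(rng.choices("ACGT", k=5)))
            max_len = rng.randint(10, 350)
            got = predict_amplicons(rec, fwd, rev, max_len)
            rc = reverse_complement_pattern(rev)
            expected = sorted(
                (i, j + rc.length, j + rc.length - i)
                for i in range(len(seq))
                if fwd.matches_at(seq, i)
                for j in range(len(seq))
                if rc.matches_at(seq, j)
                and j + rc.length > i
                and j + rc.length - i <= max_len
            )
            assert got == expected


class TestCapsRanking:
    def test_site_destroying_enzyme_ranked_first(self, taqi):
        ref, alt, _snp = make_snp_allele_pair(500, taqi, seed=5)
        bystander = Enzyme("NoCut", "GCGCGCGC", 1)
        ranked = rank_caps_candidates([ref, alt], [bystander, taqi])
        assert ranked[0].enzyme_name == "TaqI"
        assert ranked[0].resolvable_pairs == 1
        assert ranked[0].n_distinct_patterns == 2
        # ref digested into 2 fragments, alt left whole
        lanes = {l.label: l for l in ranked[0].lanes}
        assert len(lanes["allele_ref"].fragments) == 2
        assert len(lanes["allele_alt"].fragments) == 1

    def test_identical_alleles_indistinguishable(self, taqi):
        rec = SequenceRecord("a1", "C" * 50 + "TCGA" + "C" * 50)
        rec2 = SequenceRecord("a2", rec.seq)
        ranked = rank_caps_candidates([rec, rec2], [taqi])
        assert ranked[0].n_distinct_patterns == 1
        assert ranked[0].resolvable_pairs == 0

    def test_input_order_invariance(self, taqi, ecori):
        rng = random.Random(3)
        alleles = []
        for i in range(6):
            seq = "".join(rng.choices("ACGT", k=400))
            alleles.append(SequenceRecord(f"al{i}", seq))
        pool = [taqi, ecori, Enzyme("Mse", "TTAA", 1)]
        base = rank_caps_candidates(alleles, pool)
        shuffled = rank_caps_candidates(alleles[::-1], pool)
        assert [(c.enzyme_name, c.resolvable_pairs) for c in base] == [
            (c.enzyme_name, c.resolvable_pairs) for c in shuffled
        ]

    def test_resolution_merges_close_bands(self):
        # two alleles whose fragment sets differ by 2 bp: unresolvable on
        # agarose-like tolerance, resolvable at 1 bp resolution
        a = SequenceRecord("a", "C" * 100 + "TCGA" + "C" * 96)
        b = SequenceRecord("b", "C" * 102 + "TCGA" + "C" * 94)
        taq = Enzyme("TaqI", "TCGA", 1)
        loose = rank_caps_candidates([a, b], [taq])  # 5% default tolerance
        strict = rank_caps_candidates([a, b], [taq], resolution_bp=1)
        assert loose[0].resolvable_pairs == 0
        assert strict[0].resolvable_pairs == 1

    def test_requires_two_alleles(self, taqi):
        with pytest.raises(ValueError):
            rank_caps_candidates([SequenceRecord("a", "ACGT")], [taqi])

    def test_twelve_allele_ranking_deterministic(self, taqi, ecori):
        records = []
        for i in range(12):
            ref, alt, _ = make_snp_allele_pair(300, taqi, seed=100 + i)
            records.append(SequenceRecord(f"allele_{i}", (ref if i % 2 else alt).seq))
        pool = [taqi, ecori]
        first = rank_caps_candidates(records, pool)
        second = rank_caps_candidates(records, pool)
        assert [c.enzyme_name for c in first] == [c.enzyme_name for c in second]
        assert first[0].enzyme_name == "TaqI"
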