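"""BLAST filtering, conservation profiles and conserved-region detection."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from oligoface import motif_conservation as mc
from oligoface import synthetic_data as syn


def _hit(identity=50.0, length=80, evalue=1e-20, qlen=160):
    return mc.BlastHit(
        query_id="q", subject_id="s", percent_identity=identity,
        alignment_length=length, evalue=evalue, bitscore=100.0, query_length=qlen,
    )


class TestOrthologFilter:
    def test_boundary_values_are_kept(self):
        boundary = _hit(identity=40.0, length=56, evalue=1e-10, qlen=160)  # coverage 35.0
        assert boundary.coverage == pytest.approx(35.0)
        assert mc.filter_orthologs([boundary]) == [boundary]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"identity": 39.9},
            {"length": 55},  # coverage 34.375 < 35
            {"evalue": 2e-10},
        ],
    )
    def test_failing_one_threshold_drops_the_hit(self, kwargs):
        assert mc.filter_orthologs([_hit(**kwargs)]) == []

    def test_filter_is_idempotent(self):
        hits = [_hit(identity=i) for i in (30, 39.9, 40, 60, 95)]
        once = mc.filter_orthologs(hits)
        assert mc.filter_orthologs(once) == once

    def test_planted_table_keeps_exactly_n_passing(self, tmp_path):
        path = tmp_path / "hits.tsv"
        _, manifest = syn.make_blast_table(10, 4, seed=3, out_path=path)
        hits = mc.read_blast_table(path)
        kept = mc.filter_orthologs(hits)
        assert len(hits) == 10
        assert len(kept) == manifest.expected["n_passing"]
        flags = manifest.expected["pass_flags"]
        assert {h.subject_id for h in kept} == {
            f"subj_{i:03d}" for i, ok in enumerate(flags) if ok
        }

    def test_malformed_rows_are_skipped_with_warning(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q\ts\tnot_a_number\n" + "\t".join(
            ["q", "s", "50.0", "80", "5", "0", "1", "80", "1", "80", "1e-20", "90", "160", "160"]
        ) + "\n")
        with pytest.warns(UserWarning, match="bad.tsv:1"):
            hits = mc.read_blast_table(path)
        assert len(hits) == 1


class TestLengthFilter:
    def _rec(self, name, n, gaps=0):
        return SeqRecord(Seq("A" * n + "-" * gaps), id=name)

    def test_short_sequences_dropped_unless_exempt(self):
        records = [self._rec("short", 179), self._rec("anchor", 179), self._rec("ok", 180)]
        kept = mc.length_filter(records, min_length=180, exempt_ids=["anchor"])
        assert [r.id for r in kept] == ["anchor", "ok"]

    def test_gaps_do_not_count_toward_length(self):
        records = [self._rec("gappy", 179, gaps=50)]
        assert mc.length_filter(records, min_length=180) == []

    def test_all_long_is_identity(self):
        records = [self._rec(f"s{i}", 200) for i in range(4)]
        assert mc.length_filter(records) == records


def _msa(rows, group="test"):
    return mc.GroupMSA(group=group, ids=[f"s{i}" for i in range(len(rows))], rows=rows)


class TestConservationProfile:
    def test_uniform_twenty_letter_column_has_zero_bits(self):
        rows = [a + "A" for a in mc.AMINO_ACIDS]  # col 1 uniform, col 2 invariant
        profile = mc.conservation_profile(_msa(rows), correction=False)
        assert profile.bits[0] == pytest.approx(0.0, abs=1e-12)
        assert profile.bits[1] == pytest.approx(math.log2(20), rel=1e-12)

    def test_invariant_column_approaches_max_bits_with_n(self):
        profile_small = mc.conservation_profile(_msa(["W"] * 20))
        profile_large = mc.conservation_profile(_msa(["W"] * 2000))
        assert profile_small.bits[0] < profile_large.bits[0] < mc.MAX_BITS
        assert profile_large.bits[0] == pytest.approx(mc.MAX_BITS, abs=0.01)

    def test_hand_computed_profile_to_1e9(self):
        # column of 12 A + 4 C + 4 W over 20 sequences, no gaps
        rows = ["A"] * 12 + ["C"] * 4 + ["W"] * 4
        profile = mc.conservation_profile(_msa(rows), correction=True)
        p = np.array([0.6, 0.2, 0.2])
        entropy = float(-(p * np.log2(p)).sum())
        e_n = 19.0 / (2.0 * math.log(2.0) * 20)
        expected = math.log2(20) - entropy - e_n
        assert profile.bits[0] == pytest.approx(expected, abs=1e-9)
        heights = profile.letter_heights[0]
        assert heights.sum() == pytest.approx(profile.bits[0], abs=1e-9)
        assert heights[mc.AMINO_ACIDS.index("A")] == pytest.approx(0.6 * expected, abs=1e-9)

    def test_gap_fraction_reported_and_renormalized(self):
        rows = ["A-", "A-", "AC", "AC"]
        profile = mc.conservation_profile(_msa(rows), correction=False)
        assert profile.gap_fraction[0] == 0.0
        assert profile.gap_fraction[1] == 0.5
        # column 2 probabilities renormalized over the 2 observed residues
        assert profile.bits[1] == pytest.approx(math.log2(20), rel=1e-12)

    def test_all_gap_column_flagged_with_zero_bits(self):
        profile = mc.conservation_profile(_msa(["A-", "C-"]), correction=False)
        assert profile.all_gap[1]
        assert profile.bits[1] == 0.0

    def test_profile_invariant_to_row_order(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list(mc.AMINO_ACIDS), size=30)) for _ in range(25)]
        p1 = mc.conservation_profile(_msa(rows))
        p2 = mc.conservation_profile(_msa(rows[::-1]))
        assert np.allclose(p1.bits, p2.bits)
        assert np.allclose(p1.letter_heights, p2.letter_heights)

    def test_profile_bounds_on_corrected_profiles(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list(mc.AMINO_ACIDS), size=50)) for _ in range(30)]
        profile = mc.conservation_profile(_msa(rows), correction=True)
        assert np.all(profile.bits >= 0.0)
        assert np.all(profile.bits <= mc.MAX_BITS + 1e-12)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            mc.conservation_profile(_msa(["ACDE"]))


class TestConservedRegions:
    def test_flat_low_information_profile_has_no_segments(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list(mc.AMINO_ACIDS), size=60)) for _ in range(30)]
        profile = mc.conservation_profile(_msa(rows))
        assert mc.detect_conserved_regions(profile, min_bits=2.0) == []

    def test_planted_block_recovered_exactly(self, tmp_path):
        groups = {"g": syn.MsaGroupSpec(n_sequences=24, n_columns=120, blocks=[(40, 47)])}
        _, manifest = syn.make_msa(groups, seed=9, out_dir=tmp_path)
        msa = mc.read_group_msa(tmp_path / "g.afa", "g")
        profile = mc.conservation_profile(msa)
        segments = mc.detect_conserved_regions(profile, min_bits=2.0, min_run=3)
        assert [(s.start, s.end) for s in segments] == [(40, 47)]

    def test_two_planted_blocks_yield_two_segments(self, tmp_path):
        groups = {"g": syn.MsaGroupSpec(n_columns=120, blocks=[(20, 27), (70, 80)])}
        _, _ = syn.make_msa(groups, seed=10, out_dir=tmp_path)
        msa = mc.read_group_msa(tmp_path / "g.afa", "g")
        segments = mc.detect_conserved_regions(mc.conservation_profile(msa))
        assert [(s.start, s.end) for s in segments] == [(20, 27), (70, 80)]
        names = ["CR-I", "CR-II"]
        named = mc.detect_conserved_regions(mc.conservation_profile(msa), names=names)
        assert [s.label for s in named] == names

    def test_segment_coverage_monotone_in_min_bits(self, tmp_path):
        groups = {"g": syn.MsaGroupSpec(n_columns=100, blocks=[(10, 20), (50, 60)],
                                        block_mutation_rate=0.1)}
        syn.make_msa(groups, seed=11, out_dir=tmp_path)
        profile = mc.conservation_profile(mc.read_group_msa(tmp_path / "g.afa", "g"))
        covered = []
        for min_bits in (1.0, 2.0, 3.0, 4.0):
            segs = mc.detect_conserved_regions(profile, min_bits=min_bits)
            covered.append(sum(s.n_columns for s in segs))
        assert covered == sorted(covered, reverse=True)

    def test_min_run_filters_short_runs(self):
        profile = mc.ConservationProfile(
            group="g",
            bits=np.array([4.0, 4.0, 0.0, 4.0, 4.0, 4.0]),
            letter_heights=np.zeros((6, 20)),
            gap_fraction=np.zeros(6),
            all_gap=np.zeros(6, dtype=bool),
            n_sequences=30,
            small_sample_correction=True,
        )
        segs = mc.detect_conserved_regions(profile, min_bits=2.0, min_run=3)
        assert [(s.start, s.end) for s in segs] == [(4, 6)]

    def test_high_gap_columns_are_ineligible(self):
        profile = mc.ConservationProfile(
            group="g",
            bits=np.full(5, 4.0),
            letter_heights=np.zeros((5, 20)),
            gap_fraction=np.array([0.0, 0.0, 0.9, 0.0, 0.0]),
            all_gap=np.zeros(5, dtype=bool),
            n_sequences=30,
            small_sample_correction=True,
        )
        segs = mc.detect_conserved_regions(profile, min_bits=2.0, min_run=2, max_gap_frac=0.5)
        assert [(s.start, s.end) for s in segs] == [(1, 2), (4, 5)]


class TestCompareGroups:
    def _seg(self, group, label, start=1, end=5, bits=3.0):
        return mc.CRSegment(start=start, end=end, mean_bits=bits, group=group, label=label)

    def test_single_group_single_region(self):
        table = mc.compare_groups({"g1": [self._seg("g1", "CR-I")]})
        assert table.loc["CR-I", "g1"] == True  # noqa: E712
        assert table.loc["CR-I", "g1_mean_bits"] == pytest.approx(3.0)

    def test_planted_presence_absence_matrix(self):
        segs = {
            "trimeric": [self._seg("trimeric", "CR-III"), self._seg("trimeric", "CR-IV", 10, 15)],
            "marine": [self._seg("marine", "CR-V")],
        }
        table = mc.compare_groups(segs)
        assert bool(table.loc["CR-III", "trimeric"]) is True
        assert bool(table.loc["CR-III", "marine"]) is False
        assert bool(table.loc["CR-V", "marine"]) is True
        assert bool(table.loc["CR-V", "trimeric"]) is False

    def test_empty_segment_sets_give_all_false(self):
        table = mc.compare_groups({"g1": [], "g2": []})
        assert table.empty

    def test_unlabeled_segments_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="unlabeled"):
            table = mc.compare_groups({"g1": [self._seg("g1", None)]})
        assert table.empty
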