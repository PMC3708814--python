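import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicemre.formats_io import MRESite, ReferenceSequence
from splicemre.mre_mapping import (
    find_seed_matches,
    locate_mre,
    merge_regions,
    overlap_fraction,
    region_report,
    reverse_complement,
    summarize_region,
)


def _site(start, end, site_id=None, ratio=None, mirna="miR", ref="G1", **kw):
    return MRESite(
        site_id=site_id or f"s{start}-{end}",
        reference_id=ref,
        mirna_id=mirna,
        start=start,
        end=end,
        repressive_ratio=ratio,
        **kw,
    )


class TestLocateMre:
    REF = ReferenceSequence("g", "AAACGTACGTAAA")

    def test_exact_full_length_match(self):
        assert locate_mre(self.REF, "CGTACGT") == [(3, 10)]

    def test_rna_alphabet_normalized(self):
        assert locate_mre(self.REF, "CGUACGU") == [(3, 10)]

    def test_single_mismatch_rejected(self):
        assert locate_mre(self.REF, "CGTACGA") == []

    def test_overlapping_occurrences_all_reported(self):
        ref = ReferenceSequence("g", "ATATATA")
        assert locate_mre(ref, "ATA") == [(0, 3), (2, 5), (4, 7)]

    def test_n_never_matches(self):
        ref = ReferenceSequence("g", "AANCGT")
        assert locate_mre(ref, "ANC") == []
        assert locate_mre(ref, "NCG") == []

    def test_empty_site_sequence_is_error(self):
        with pytest.raises(ValueError):
            locate_mre(self.REF, "")

    @given(
        st.text(alphabet="ACGT", min_size=30, max_size=120),
        st.integers(min_value=0, max_value=100),
        st.integers(min_value=5, max_value=25),
    )
    def test_every_hit_is_the_query_substring(self, seq, pos, length):
        ref = ReferenceSequence("g", seq)
        start = pos % max(1, len(seq) - length)
        query = seq[start : start + length]
        hits = locate_mre(ref, query)
        assert (start, start + length) in hits
        for s, e in hits:
            assert ref.sequence[s:e] == query


class TestSeedMatches:
    LET7 = "UGAGGUAGUAGGUUGUAUAGUU"

    def test_seed_heptamer_match(self):
        target = ReferenceSequence("t", "AAACTACCTCAAA")
        (m,) = find_seed_matches(self.LET7, target)
        assert (m.start, m.end) == (3, 10)
        assert m.heptamer == "CTACCTC"
        assert reverse_complement(
            self.LET7.replace("U", "T")[1:8]
        ) == m.heptamer

    def test_no_complement_no_match(self):
        target = ReferenceSequence("t", "AAAAAAAAAAAA")
        assert find_seed_matches(self.LET7, target) == []

    def test_short_mirna_is_error(self):
        with pytest.raises(ValueError):
            find_seed_matches("UGAGGUA", ReferenceSequence("t", "ACGTACGT"))

    def test_search_interval_restricts_matches(self):
        target = ReferenceSequence("t", "CTACCTC" + "A" * 10 + "CTACCTC")
        all_hits = find_seed_matches(self.LET7, target)
        assert [(m.start, m.end) for m in all_hits] == [(0, 7), (17, 24)]
        window = find_seed_matches(self.LET7, target, search_interval=(10, 24))
        assert [(m.start, m.end) for m in window] == [(17, 24)]

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            target = ReferenceSequence("t", seq)
            mirna = "".join(rng.choice(list("ACGU"), size=22))
            heptamer = reverse_complement(mirna.replace("U", "T")[1:8])
            expected = [
                (i, i + 7) for i in range(194) if seq[i : i + 7] == heptamer
            ]
            got = [(m.start, m.end) for m in find_seed_matches(mirna, target)]
            assert got == expected


class TestMergeRegions:
    def test_pair_above_threshold_merges(self):
        regions = merge_regions([_site(100, 120), _site(101, 121)])
        assert len(regions) == 1
        assert regions[0].interval == (100, 121)

    def test_pair_below_threshold_stays_separate(self):
        regions = merge_regions([_site(100, 120), _site(110, 130)])
        assert overlap_fraction((100, 120), (110, 130)) == 0.5
        assert len(regions) == 2

    def test_transitive_chain_merges_to_one_region(self):
        # adjacent pairs overlap 19/20 = 0.95; ends overlap only 18/20
        chain = [_site(0, 20), _site(1, 21), _site(2, 22)]
        assert overlap_fraction((0, 20), (2, 22)) == 0.9  # also above, chain anyway
        regions = merge_regions(chain)
        assert len(regions) == 1
        assert regions[0].interval == (0, 22)

    def test_containment_counts_as_full_overlap(self):
        regions = merge_regions([_site(100, 200), _site(150, 160)])
        assert len(regions) == 1

    def test_mixed_references_rejected(self):
        with pytest.raises(ValueError, match="single reference"):
            merge_regions([_site(0, 20), _site(0, 20, site_id="x", ref="G2")])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=150),
                st.integers(min_value=1, max_value=40),
            ),
            min_size=1,
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_idempotent_order_invariant_partition(self, intervals, rnd):
        sites = [
            _site(s, s + ln, site_id=f"s{i}") for i, (s, ln) in enumerate(intervals)
        ]
        regions = merge_regions(sites)
        # every site in exactly one region
        member_ids = [m.site_id for r in regions for m in r.members]
        assert sorted(member_ids) == sorted(s.site_id for s in sites)
        # region intervals span their members
        for r in regions:
            assert r.start == min(m.start for m in r.members)
            assert r.end == max(m.end for m in r.members)
        # idempotent: merging one representative per region changes nothing
        again = merge_regions(
            [_site(r.start, r.end, site_id=f"r{r.region_index}") for r in regions]
        )
        assert len(again) <= len(regions)
        # order invariance
        shuffled = sites[:]
        rnd.shuffle(shuffled)
        regions2 = merge_regions(shuffled)
        key = lambda regs: sorted(
            tuple(sorted(m.site_id for m in r.members)) for r in regs
        )
        assert key(regions) == key(regions2)
        # indices are 1..K ascending by start
        starts = [r.start for r in regions]
        assert starts == sorted(starts)
        assert [r.region_index for r in regions] == list(range(1, len(regions) + 1))


class TestRegionSummary:
    def _region(self, ratios):
        sites = [
            _site(100, 120, site_id=f"m{i}", ratio=r, mirna=f"miR-{i}")
            for i, r in enumerate(ratios)
        ]
        (region,) = merge_regions(sites)
        return region

    def test_multi_mirna_range(self):
        region = self._region([35, 39, 41, 21, 35, 30, 30, 19, 28])
        s = summarize_region(region)
        assert (s.repression_min, s.repression_max) == (19, 41)
        assert s.highly_repressive and s.available
        assert s.n_mirnas == 9

    def test_single_weak_site_not_highly_repressive(self):
        s = summarize_region(self._region([13]))
        assert (s.repression_min, s.repression_max) == (13, 13)
        assert not s.highly_repressive

    def test_threshold_is_inclusive_at_30(self):
        assert summarize_region(self._region([30])).highly_repressive

    def test_no_ratio_flagged_unavailable(self):
        s = summarize_region(self._region([None, None]))
        assert not s.available and not s.highly_repressive
        assert s.repression_min is None


class TestRegionReport:
    def test_vegf_catalog_counts(self, vegf_catalog):
        regions = merge_regions(vegf_catalog)
        rep = region_report(regions)
        assert rep.n_regions == 13
        assert rep.n_highly_repressive == 9
        assert rep.n_supported_any == 5
        assert rep.n_supported_cancer == 4
        assert rep.n_supported_normal == 2
        assert rep.n_supported_and_highly_repressive == 5

    def test_empty_region_list_all_zero(self):
        rep = region_report([])
        assert rep.n_regions == rep.n_highly_repressive == 0
        assert rep.n_supported_any == rep.n_supported_cancer == 0
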