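"""Detection criteria, linkage removal, sharing and contamination flags."""

import numpy as np
import pytest

from malines.filtering import (
    CandidateMutation,
    FilterThresholds,
    find_candidates,
    flag_contaminated,
    pairwise_sharing,
    remove_linked,
    SharingMatrix,
)
from malines.io import ALT_HOM, ConfigurationError, GroupConfig

from conftest import make_call, make_site, uniform_site


class TestFindCandidates:
    def test_clean_unique_alt_hom_is_candidate(self, lines20, group20):
        site = uniform_site(100, lines20, focal="L05", focal_dp=8, focal_gq=50)
        (cand,) = find_candidates([site], group20)
        assert cand.line_id == "L05" and cand.pos == 100
        assert cand.mtype == "SNV" and (cand.ref, cand.alt) == ("A", "G")

    def test_focal_depth_below_five_rejected(self, lines20, group20):
        site = uniform_site(100, lines20, focal="L05", focal_dp=4)
        assert find_candidates([site], group20) == []
        # boundary: "no less than five reads" accepts exactly 5
        site = uniform_site(100, lines20, focal="L05", focal_dp=5)
        assert len(find_candidates([site], group20)) == 1

    def test_het_in_any_other_line_rejected(self, lines20, group20):
        site = uniform_site(100, lines20, focal="L05", het_lines=("L07",))
        assert find_candidates([site], group20) == []

    def test_all_ref_hom_yields_nothing(self, lines20, group20):
        site = uniform_site(100, lines20)
        assert find_candidates([site], group20) == []

    def test_focal_gq_threshold_is_strict(self, lines20, group20):
        site = uniform_site(100, lines20, focal="L05", focal_gq=20)
        assert find_candidates([site], group20) == []
        site = uniform_site(100, lines20, focal="L05", focal_gq=21)
        assert len(find_candidates([site], group20)) == 1

    def test_support_needs_dp_strictly_above_five(self, lines20, group20):
        # 19 ref-hom lines at DP=5 give zero supporting lines
        site = uniform_site(100, lines20, focal="L05", other_dp=5)
        assert find_candidates([site], group20) == []
        site = uniform_site(100, lines20, focal="L05", other_dp=6)
        assert len(find_candidates([site], group20)) == 1

    def test_support_line_count_threshold(self, lines20, group20):
        # exactly 10 well-covered ref-homs pass; 9 fail
        for n_good, expect in [(9, 0), (10, 1)]:
            calls = [make_call("L01", ALT_HOM, dp=8, gq=50)]
            for i, line in enumerate(lines20[1:]):
                dp = 10 if i < n_good else 3
                calls.append(make_call(line, "ref_hom", dp=dp))
            site = make_site(100, calls)
            assert len(find_candidates([site], group20)) == expect

    def test_second_alt_hom_line_rejected_even_for_other_allele(self, lines20, group20):
        calls = []
        for line in lines20:
            if line == "L01":
                calls.append(make_call(line, ALT_HOM, dp=9, gq=50, alt_index=0))
            elif line == "L02":
                calls.append(make_call(line, ALT_HOM, dp=9, gq=50, alt_index=1))
            else:
                calls.append(make_call(line, "ref_hom", dp=10))
        site = make_site(100, calls, ref="A", alts=("G", "T"))
        assert find_candidates([site], group20) == []

    def test_indel_typing_from_alleles(self, lines20, group20):
        site = uniform_site(100, lines20, focal="L05", ref="A", alts=("ATTG",))
        (cand,) = find_candidates([site], group20)
        assert cand.mtype == "insertion" and cand.length_delta == 3
        site = uniform_site(200, lines20, focal="L05", ref="ACC", alts=("A",))
        (cand,) = find_candidates([site], group20)
        assert cand.mtype == "deletion" and cand.length_delta == -2

    def test_small_group_is_configuration_error(self):
        group = GroupConfig("g", [f"L{i}" for i in range(10)], generations=100)
        with pytest.raises(ConfigurationError, match="active lines"):
            find_candidates([], group)

    def test_excluded_lines_do_not_contribute(self, lines20):
        group = GroupConfig("g", lines20, generations=100, excluded_lines=["L07"])
        # excluded line is het: would reject under (iii) if counted
        site = uniform_site(100, lines20, focal="L05", het_lines=("L07",))
        assert len(find_candidates([site], group)) == 1

    def test_dp_threshold_monotonicity(self, lines20, group20):
        from conftest import random_sites

        rng = np.random.default_rng(7)
        sites = random_sites(rng, lines20, n_sites=120)
        counts = []
        for dp_focal in range(0, 12):
            th = FilterThresholds(min_dp_focal=dp_focal)
            counts.append(len(find_candidates(sites, group20, th)))
        assert counts == sorted(counts, reverse=True)

    def test_per_site_exclusivity(self, lines20, group20):
        from conftest import random_sites

        rng = np.random.default_rng(11)
        sites = random_sites(rng, lines20, n_sites=200)
        cands = find_candidates(sites, group20)
        assert len({(c.contig, c.pos) for c in cands}) == len(cands)


class TestRemoveLinked:
    def test_same_line_pair_within_window_both_removed(self):
        a = CandidateMutation("L1", "chr1", 1000, "SNV", "A", "G")
        b = CandidateMutation("L1", "chr1", 1002, "SNV", "C", "T")
        assert remove_linked([a, b], window=100) == []

    def test_different_lines_never_interact(self):
        a = CandidateMutation("L1", "chr1", 1000, "SNV", "A", "G")
        b = CandidateMutation("L2", "chr1", 1002, "SNV", "C", "T")
        assert len(remove_linked([a, b], window=100)) == 2

    def test_singleton_kept_and_cluster_of_three_all_removed(self):
        solo = CandidateMutation("L1", "chr2", 5, "SNV", "A", "G")
        cluster = [
            CandidateMutation("L1", "chr1", p, "SNV", "A", "G") for p in (100, 150, 240)
        ]
        out = remove_linked(cluster + [solo], window=100)
        assert out == [solo]

    def test_window_boundary_inclusive(self):
        a = CandidateMutation("L1", "chr1", 1000, "SNV", "A", "G")
        b = CandidateMutation("L1", "chr1", 1100, "SNV", "C", "T")
        assert remove_linked([a, b], window=100) == []
        c = CandidateMutation("L1", "chr1", 1101, "SNV", "C", "T")
        assert len(remove_linked([a, c], window=100)) == 2


class TestPairwiseSharing:
    def _site(self, pos, lines, alt_hom_lines, dp=10):
        calls = []
        for line in lines:
            if line in alt_hom_lines:
                calls.append(make_call(line, ALT_HOM, dp=dp))
            else:
                calls.append(make_call(line, "ref_hom", dp=dp))
        return make_site(pos, calls)

    def test_low_depth_line_makes_locus_ineligible(self, lines20, group20):
        site = self._site(10, lines20, {"L01", "L02"})
        # one line at DP=5 ("more than five reads" excludes it)
        calls = list(site.calls)
        calls[5] = make_call("L06", "ref_hom", dp=5)
        site.calls = tuple(calls)
        m = pairwise_sharing([site], group20)
        assert m.n_eligible == 0 and m.get("L01", "L02") == 0

    def test_alt_hom_fraction_bound_is_strict(self, lines20, group20):
        seven = set(lines20[:7])  # 7/20 = 35% >= 30%
        m = pairwise_sharing([self._site(10, lines20, seven)], group20)
        assert m.n_eligible == 0
        five = set(lines20[:5])  # 25% < 30%
        m = pairwise_sharing([self._site(10, lines20, five)], group20)
        assert m.n_eligible == 1

    def test_counts_match_bruteforce_pair_enumeration(self, lines20, group20):
        sites = [self._site(p, lines20, {"L03", "L09"}) for p in (10, 20, 30)]
        m = pairwise_sharing(sites, group20)
        assert m.get("L03", "L09") == 3
        for a, b in m.pairs():
            if {a, b} != {"L03", "L09"}:
                assert m.get(a, b) == 0

    def test_different_alleles_do_not_count_as_shared(self, lines20, group20):
        calls = []
        for line in lines20:
            if line == "L01":
                calls.append(make_call(line, ALT_HOM, alt_index=0))
            elif line == "L02":
                calls.append(make_call(line, ALT_HOM, alt_index=1))
            else:
                calls.append(make_call(line, "ref_hom"))
        site = make_site(10, calls, ref="A", alts=("G", "T"))
        m = pairwise_sharing([site], group20)
        assert m.n_eligible == 1 and m.get("L01", "L02") == 0


class TestFlagContaminated:
    def _matrix(self, lines, counts):
        m = SharingMatrix(line_ids=lines)
        for (a, b), n in counts.items():
            for _ in range(n):
                m.increment(a, b)
        return m

    def test_all_zero_no_flags(self):
        lines = [f"L{i}" for i in range(20)]
        assert flag_contaminated(self._matrix(lines, {})) == []

    def test_single_outlier_pair_flagged(self):
        lines = [f"L{i}" for i in range(20)]  # 190 pairs
        rng = np.random.default_rng(0)
        counts = {}
        pairs = [(a, b) for i, a in enumerate(lines) for b in lines[i + 1:]]
        for a, b in pairs:
            counts[(a, b)] = int(rng.integers(0, 3))  # share <= 2
        counts[("L0", "L13")] = 50
        flagged = flag_contaminated(self._matrix(lines, counts))
        assert flagged == [("L0", "L13", 50)]

    def test_synthetic_contamination_detected_end_to_end(self):
        from malines.io import GroupConfig, read_vcf_matrix
        from malines.simulate import SimParams, emulate_calling, generate_founder, simulate_lines
        import tempfile

        p = SimParams(seed=9, genome_length=800_000,
                      contamination=("L03", "L11", 0.5))
        genome = generate_founder(p)
        truth = simulate_lines(genome, p)
        shared = {r.pos for r in truth.by_line["L03"]} & {
            r.pos for r in truth.by_line["L11"]}
        assert len(shared) > 5  # the injection took
        with tempfile.TemporaryDirectory() as d:
            calls = emulate_calling(genome, truth, p, d)
            group = GroupConfig("g", calls.line_ids, p.generations)
            sites = read_vcf_matrix(calls.vcf_path, group)
            matrix = pairwise_sharing(sites, group)
        flagged = flag_contaminated(matrix)
        assert flagged and set(flagged[0][:2]) == {"L03", "L11"}
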