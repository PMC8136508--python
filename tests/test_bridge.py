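import numpy as np
import pytest

from bridgethemes.alignment import AlignmentResult
from bridgethemes.bridge import (BridgeCandidate, CandidateGroup,
                                 align_candidate, best_hit_per_domain,
                                 bridges_to_table, cross_group_pairs,
                                 dedupe_longest, detect_bridges, filter_hits,
                                 flank_filter_alns, parse_aligned_pairs,
                                 select_representatives, split_context)
from bridgethemes.datamodel import DomainRecord, ThemeHit
from bridgethemes.synthetic import evolve_variation, sample_ancestor


def hit(theme="t1", domain="d1", start=0, end=30, e=1e-5, cov=0.9):
    return ThemeHit(theme, domain, start, end, e, cov)


def aln(n, score, identity=50.0, mode="local"):
    pairs = [(i, i) for i in range(n)]
    return AlignmentResult(pairs, score, n, identity, identity, mode, 11.0, 1.0)


def candidate(theme="t1", da="d1", db="d2", xa="101", xb="2004",
              theme_score=50.0, n_aligned=30, flank_score=0.0, e=1e-5):
    return BridgeCandidate(
        theme_id=theme, domain_a=da, domain_b=db, xgroup_a=xa, xgroup_b=xb,
        hit_a=hit(theme, da, e=e), hit_b=hit(theme, db, e=e),
        theme_aln=aln(n_aligned, theme_score),
        before_aln=aln(10, flank_score) if flank_score else None,
        after_aln=aln(10, flank_score) if flank_score else None,
        flank_pass_before=True, flank_pass_after=True, p_value=1e-4)


class TestFilterHits:
    @pytest.mark.parametrize("e,cov,kept", [
        (1e-4, 0.9, True),   # passes both thresholds
        (1e-2, 0.9, False),  # E-value too large
        (1e-4, 0.5, False),  # coverage too low
        (1e-3, 0.85, True),  # both thresholds inclusive
    ])
    def test_thresholds(self, e, cov, kept):
        out = filter_hits([hit(e=e, cov=cov)])
        assert bool(out) is kept

    def test_best_hit_per_domain(self):
        hits = [hit(e=1e-4, start=0, end=30), hit(e=1e-6, start=10, end=40)]
        (best,) = best_hit_per_domain(hits)
        assert best.e_value == 1e-6


class TestCrossGroupPairs:
    cls = {"d1": "1.101.1.1", "d2": "2.2004.1.1", "d3": "2.2004.2.1",
           "d4": "1.101.9.1", "d5": "3.604.1.1"}

    def test_single_cross_pair(self):
        out = cross_group_pairs([hit(domain="d1"), hit(domain="d2")], self.cls)
        assert len(out) == 1
        theme, pair, s1, s2 = out[0]
        assert pair == ("101", "2004")
        assert len(s1) == len(s2) == 1

    def test_same_group_only_gives_nothing(self):
        out = cross_group_pairs([hit(domain="d2"), hit(domain="d3")], self.cls)
        assert out == []

    def test_two_by_three_gives_six_candidates(self):
        hits = [hit(domain=d) for d in ("d1", "d4", "d2", "d3")]
        hits.append(hit(domain="d5"))
        out = cross_group_pairs(hits, self.cls)
        # X-groups 101 (2 domains), 2004 (2), 604 (1): three unordered pairs
        sizes = {pair: len(s1) * len(s2) for _, pair, s1, s2 in out}
        assert sizes == {("101", "2004"): 4, ("101", "604"): 2, ("2004", "604"): 2}

    def test_unclassified_domain_dropped(self):
        out = cross_group_pairs([hit(domain="d1"), hit(domain="dX")], self.cls)
        assert out == []


class TestSplitContext:
    def test_middle_hit(self):
        seq = "A" * 100
        b, t, a = split_context(seq, hit(start=30, end=70))
        assert (len(b), len(t), len(a)) == (30, 40, 30)
        assert b + t + a == seq

    def test_prefix_hit_empty_before(self):
        b, t, a = split_context("A" * 100, hit(start=0, end=50))
        assert b == "" and len(t) == 50

    def test_whole_domain_hit(self):
        b, t, a = split_context("A" * 100, hit(start=0, end=100))
        assert b == "" and a == "" and len(t) == 100

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            split_context("A" * 10, hit(start=0, end=30))


class TestAlignCandidate:
    def _domains(self, r1, r2, flank_len=30, seed=0):
        rng = np.random.default_rng(seed)
        b1 = sample_ancestor(flank_len, seed=rng)
        a1 = sample_ancestor(flank_len, seed=rng)
        b2 = sample_ancestor(flank_len, seed=rng)
        a2 = sample_ancestor(flank_len, seed=rng)
        d1 = DomainRecord("d1", b1 + r1 + a1, "1.101.1.1")
        d2 = DomainRecord("d2", b2 + r2 + a2, "2.2004.1.1")
        h1 = hit("t1", "d1", flank_len, flank_len + len(r1))
        h2 = hit("t1", "d2", flank_len, flank_len + len(r2))
        return d1, d2, h1, h2

    def test_similar_themes_stay_local(self):
        anc = sample_ancestor(49, seed=1)
        r1 = evolve_variation(anc, 0.2, seed=2)
        r2 = evolve_variation(anc, 0.2, seed=3)
        c = align_candidate(*self._domains(r1, r2), n_pvalue_samples=200)
        assert c.mode == "local"
        assert c.theme_aln.n_aligned > 20
        assert c.p_value < 0.01

    def test_short_local_alignment_falls_back_to_global(self):
        r1 = "ACDEFGHIKLMNPQRSTVW"  # 19 residues: local can never exceed 20
        r2 = "WYWYWYWYWYWYWYWMSTVW"
        c = align_candidate(*self._domains(r1, r2), n_pvalue_samples=200)
        assert c.mode == "global"

    def test_mismatched_themes_rejected(self):
        d1, d2, h1, h2 = self._domains("ACDEF" * 6, "ACDEF" * 6)
        h2.theme_id = "other"
        with pytest.raises(ValueError, match="different themes"):
            align_candidate(d1, d2, h1, h2)

    def test_empty_flanks_pass_by_length_rule(self):
        r = "ACDEFGHIKL" * 5
        d1 = DomainRecord("d1", r, "1.101.1.1")
        d2 = DomainRecord("d2", r, "2.2004.1.1")
        h1, h2 = hit("t1", "d1", 0, len(r)), hit("t1", "d2", 0, len(r))
        c = align_candidate(d1, d2, h1, h2, n_pvalue_samples=200)
        assert c.before_aln is None and c.after_aln is None
        assert c.flank_pass_before and c.flank_pass_after


class TestFlankFilter:
    @pytest.mark.parametrize("n,identity,passes", [
        (10, 40.0, True),   # too short to indicate shared context
        (30, 20.0, True),   # long but dissimilar
        (30, 30.0, False),  # long and similar: same context
    ])
    def test_rules(self, n, identity, passes):
        fp, _ = flank_filter_alns(aln(n, 50.0, identity), None)
        assert fp is passes


class TestSelectRepresentatives:
    def test_single_candidate_returned(self):
        g = CandidateGroup("t1", ("101", "2004"), [candidate()], 1, 1)
        assert select_representatives(g) == g.candidates

    def test_max_contrast_selected_first(self):
        cands = [candidate(da=f"a{i}", db=f"b{j}",
                           theme_score=40.0, flank_score=30.0)
                 for i in range(2) for j in range(3)]
        # one candidate with the best theme score and the worst flank score
        cands[3] = candidate(da="a1", db="b0", theme_score=90.0, flank_score=5.0)
        g = CandidateGroup("t1", ("101", "2004"), cands, 2, 3)
        reps = select_representatives(g)
        assert len(reps) == 2
        assert reps[0] is cands[3]
        assert all(any(r is c for c in cands) for r in reps)

    def test_zero_variance_ties_break_deterministically(self):
        cands = [candidate(da=f"a{i}", db="b0") for i in range(3)]
        g = CandidateGroup("t1", ("101", "2004"), cands, 3, 1)
        reps = select_representatives(g)
        assert [c.domain_a for c in reps] == ["a0", "a1"]


class TestDedupeLongest:
    def test_longest_theme_kept(self):
        c30 = candidate(theme="tA", n_aligned=30)
        c45 = candidate(theme="tB", n_aligned=45)
        assert dedupe_longest([c30, c45]) == [c45]

    def test_distinct_pairs_untouched(self):
        c1 = candidate(theme="tA", da="d1", db="d2")
        c2 = candidate(theme="tB", da="d3", db="d4")
        assert len(dedupe_longest([c1, c2])) == 2

    def test_tie_breaks_by_score(self):
        lo = candidate(theme="tA", n_aligned=30, theme_score=80.0)
        hi = candidate(theme="tB", n_aligned=30, theme_score=90.0)
        assert dedupe_longest([lo, hi]) == [hi]


class TestDetectEndToEnd:
    def test_planted_pairs_recovered(self, small_benchmark_data):
        data = small_benchmark_data
        domains = {
            d: DomainRecord(d, seq, data["classification"][d])
            for d, seq in data["fasta"].items()
        }
        reps, groups = detect_bridges(domains, data["hits"],
                                      n_pvalue_samples=200, seed=0)
        truth_pairs = set()
        for t in data["truth"]:
            if t.planted:
                for p in t.partners:
                    truth_pairs.add(frozenset((t.domain_id, p)))
        found_pairs = {c.domain_pair for c in reps}
        assert found_pairs == truth_pairs
        assert all(c.theme_aln.n_aligned > 20 for c in reps)
        assert all(c.p_value < 1e-3 for c in reps)

    def test_detection_is_deterministic(self, small_benchmark_data):
        data = small_benchmark_data
        domains = {
            d: DomainRecord(d, seq, data["classification"][d])
            for d, seq in data["fasta"].items()
        }
        t1 = bridges_to_table(detect_bridges(domains, data["hits"],
                                             n_pvalue_samples=100, seed=5)[0])
        t2 = bridges_to_table(detect_bridges(domains, data["hits"],
                                             n_pvalue_samples=100, seed=5)[0])
        assert t1.to_csv(sep="\t") == t2.to_csv(sep="\t")

    def test_aligned_pairs_round_trip(self):
        pairs = [(3, 5), (4, 6), (9, 10)]
        text = ";".join(f"{i}:{j}" for i, j in pairs)
        assert parse_aligned_pairs(text) == pairs
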