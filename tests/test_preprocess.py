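"""Elimination-pipeline operations: trimming, filters, collapsing, accounting."""

import numpy as np
import pytest

from hexamir import preprocess as pre


class TestTrimAdapter:
    def test_exact_seed_match_cuts_insert(self):
        assert pre.trim_adapter("ACGTACGTAGATCGGAAG", "AGATCGGAAGAGC", seed_len=8) == "ACGTACGT"

    def test_no_adapter_rejected_when_required(self):
        assert pre.trim_adapter("ACGTACGTACGTACGT", "AGATCGGAAGAGC") is None

    def test_no_adapter_passes_through_when_not_required(self):
        seq = "ACGTACGTACGTACGT"
        assert pre.trim_adapter(seq, "AGATCGGAAGAGC", require_adapter=False) == seq

    def test_read_equal_to_adapter_gives_empty_insert(self):
        assert pre.trim_adapter("AGATCGGAAGAGC", "AGATCGGAAGAGC") == ""

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            pre.trim_adapter("ACGT", "")


class TestFilterLength:
    def test_boundaries_inclusive(self):
        reads = ["A" * 15, "C" * 16, "G" * 30, "T" * 31]
        kept, removed = pre.filter_length(reads)
        assert sorted(len(r) for r in kept) == [16, 30]
        assert removed == 2

    def test_empty_input(self):
        assert pre.filter_length([]) == ([], 0)

    def test_planted_short_reads_all_removed(self, rng):
        short = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(10)]
        ok = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(50)]
        _, removed = pre.filter_length(short + ok)
        assert removed == 10

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            pre.filter_length([], min_len=20, max_len=10)


class TestIsInvalid:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGUN", True), ("ACGU", False), ("", True), ("ACGT", False), ("ACGX", True)],
    )
    def test_examples(self, seq, expected):
        assert pre.is_invalid(seq) is expected


class TestIsLowComplexity:
    def test_mononucleotide_run(self):
        assert pre.is_low_complexity("A" * 20) is True

    def test_dinucleotide_ssr(self):
        assert pre.is_low_complexity("AU" * 10) is True

    def test_trinucleotide_repeat(self):
        assert pre.is_low_complexity("ACG" * 7) is True

    def test_pseudo_random_sequence_below_coverage(self):
        seq = "AUGCUAGCAUCGGAUCCGUAA"

        def brute_force_max_coverage(s):
            best = 0
            for k in (1, 2, 3):
                for start in range(len(s) - k + 1):
                    w = s[start : start + k]
                    covered = set()
                    i = s.find(w)
                    while i != -1:
                        covered.update(range(i, i + k))
                        i = s.find(w, i + 1)
                    best = max(best, len(covered))
            return best

        assert brute_force_max_coverage(seq) < 0.8 * len(seq)
        assert pre.is_low_complexity(seq) is False

    def test_agrees_with_brute_force_on_random_reads(self, rng):
        # the shipped implementation prunes by k-mer counts; the oracle does not
        def brute(s):
            n = len(s)
            for k in (1, 2, 3):
                for start in range(n - k + 1):
                    w = s[start : start + k]
                    covered = set()
                    i = s.find(w)
                    while i != -1:
                        covered.update(range(i, i + k))
                        i = s.find(w, i + 1)
                    if len(covered) >= 0.8 * n:
                        return True
            return False

        pool = ["".join(rng.choice(list("ACGU"), size=int(rng.integers(16, 31))))
                for _ in range(150)]
        pool += ["AAAAAAAAAAAAAAAAAAAA", "ACACACACACACACACAC", "AAGAAGAAGAAGAAGAAG"]
        for s in pool:
            assert pre.is_low_complexity(s) is brute(s)


class TestFilterContaminants:
    def test_window_of_contaminant_removed(self):
        ref = "ACGTACGTTGCAGGCAGTTAACCGGTTAACCGGAA"
        read = ref[5:26]
        kept, removed = pre.filter_contaminants([read], [ref])
        assert removed == 1 and kept == []

    def test_reverse_complement_window_removed(self):
        from hexamir._seq import revcomp_dna

        ref = "ACGTACGTTGCAGGCAGTTAACCGGTTAACCGGAA"
        read = revcomp_dna(ref[5:26])
        _, removed = pre.filter_contaminants([read], [ref])
        assert removed == 1

    def test_planted_fragments_all_removed(self, rng):
        ref = "".join(rng.choice(list("ACGT"), size=500))
        frags = []
        for _ in range(50):
            start = int(rng.integers(0, 470))
            frags.append(ref[start : start + 21])
        others = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(20)]
        kept, removed = pre.filter_contaminants(frags + others, [ref])
        assert removed == 50
        assert len(kept) == 20

    def test_empty_set_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            kept, removed = pre.filter_contaminants(["ACGTACGTACGTACGTA"], [])
        assert removed == 0 and len(kept) == 1


class TestCollapseUnique:
    def test_per_library_counts_preserved(self):
        out = pre.collapse_unique({"A": ["ACGU" * 5, "ACGU" * 5, "GGGC" * 5], "B": ["ACGU" * 5]})
        by_seq = {u.seq: u.counts for u in out}
        assert by_seq["ACGU" * 5] == {"A": 2, "B": 1}
        assert by_seq["GGGC" * 5] == {"A": 1}

    def test_disjoint_libraries_sum_uniques(self):
        out = pre.collapse_unique({"A": ["AAAACCCCGGGGUUUUA"], "B": ["CCCCGGGGUUUUAAAAC"]})
        assert len(out) == 2

    def test_total_conserved_and_expansion_reproduces_multiset(self, rng):
        libs = {
            lib: ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(200)]
            for lib in ("x", "y", "z")
        }
        out = pre.collapse_unique(libs)
        assert sum(u.total_count for u in out) == 600
        expanded = sorted(
            seq for u in out for lib, n in u.counts.items() for seq in [u.seq] * n
        )
        original = sorted(s for reads in libs.values() for s in reads)
        assert expanded == original

    def test_t_and_u_collapse_to_one_sequence(self):
        out = pre.collapse_unique({"A": ["ACGTACGTACGTACGTA", "ACGUACGUACGUACGUA"]})
        assert len(out) == 1 and out[0].total_count == 2


class TestEliminationSummary:
    def test_printed_unique_tallies_give_putative_population(self):
        s = pre.elimination_summary(
            {"total": (59541021, 32574580), "length_filtered": (15178457, 11922873),
             "low_complexity": (21131, 6522), "invalid": (300657, 229912),
             "rRNA_tRNA": (2455844, 66367)}
        )
        assert s.unique["putative_population"] == 20348906
        assert s.redundant["putative_population"] == 41584932

    def test_zero_eliminations_keep_total(self):
        s = pre.elimination_summary(
            {"total": (100, 50), "length_filtered": (0, 0), "low_complexity": (0, 0),
             "invalid": (0, 0), "rRNA_tRNA": (0, 0)}
        )
        assert s.redundant["putative_population"] == 100
        assert s.unique["putative_population"] == 50

    def test_negative_tally_rejected(self):
        with pytest.raises(ValueError):
            pre.elimination_summary(
                {"total": (10, 10), "length_filtered": (-1, 0), "low_complexity": (0, 0),
                 "invalid": (0, 0), "rRNA_tRNA": (0, 0)}
            )


class TestLengthDistribution:
    def test_single_length_takes_all_mass(self):
        reads = [pre.UniqueRead("A" * 23 + "C", {"x": 1}) for _ in range(1)]
        reads[0].counts = {"x": 10}
        df = pre.length_distribution(reads)
        assert df.loc[df.length == 24, "redundant_pct"].item() == 100.0

    def test_even_split(self):
        reads = [
            pre.UniqueRead("ACGUA" * 4 + "C", {"x": 5}),       # 21 nt
            pre.UniqueRead("GCGAUCGA" * 3, {"x": 5}),           # 24 nt
        ]
        df = pre.length_distribution(reads)
        assert df.loc[df.length == 21, "redundant_pct"].item() == 50.0
        assert df.loc[df.length == 24, "unique_pct"].item() == 50.0

    def test_percentages_sum_to_100(self, rng):
        reads = [
            pre.UniqueRead(
                "".join(rng.choice(list("ACGU"), size=int(rng.integers(16, 31)))),
                {"x": int(rng.integers(1, 10))},
            )
            for _ in range(100)
        ]
        df = pre.length_distribution(reads)
        assert df.redundant_pct.sum() == pytest.approx(100.0, abs=0.1)
        assert df.unique_pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_sampled_distribution_matches_weights_within_binomial_bound(self, rng):
        # draw 10000 lengths from stated weights; empirical within 3 s.d. + mass check
        lengths = [21, 22, 23, 24]
        weights = [0.25, 0.15, 0.2, 0.4]
        n = 10_000
        draws = rng.choice(lengths, size=n, p=weights)
        ureads = [pre.UniqueRead("".join(rng.choice(list("ACGU"), size=int(l))), {"x": 1})
                  for l in draws]
        df = pre.length_distribution(ureads)
        for l, w in zip(lengths, weights):
            pct = df.loc[df.length == l, "redundant_pct"].item()
            sd = 100 * np.sqrt(w * (1 - w) / n)
            assert abs(pct - 100 * w) <= max(3 * sd, 3.0)


class TestRunElimination:
    def test_every_read_in_exactly_one_category(self, rng):
        contaminant = "".join(rng.choice(list("ACGT"), size=300))
        libs = {
            "L1": (
                ["".join(rng.choice(list("ACGU"), size=21)) for _ in range(100)]
                + ["A" * 12] * 5                 # length
                + ["AC" * 11] * 4                # low complexity
                + ["ACGUN" + "ACGU" * 4] * 3     # invalid
                + [contaminant[10:31]] * 6       # t/rRNA
            )
        }
        unique, summary = pre.run_elimination(libs, contaminants=[contaminant])
        r = summary.redundant
        assert r["total"] == 118
        assert r["length_filtered"] == 5
        assert r["low_complexity"] == 4
        assert r["invalid"] == 3
        assert r["rRNA_tRNA"] == 6
        assert r["putative_population"] == 100
        summary.validate()

    def test_rerun_reproduces_identical_tallies(self, rng):
        libs = {"a": ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(300)]}
        u1, s1 = pre.run_elimination(libs)
        u2, s2 = pre.run_elimination(libs)
        assert s1.redundant == s2.redundant and s1.unique == s2.unique
        assert [x.seq for x in u1] == [x.seq for x in u2]
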