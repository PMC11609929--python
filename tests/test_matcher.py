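"""Seed-index construction and seed-and-extend matching vs brute force."""

import numpy as np
import pytest

from scfishhook.amplicon import Fishhook, reverse_complement
from scfishhook.bruteforce import brute_force_match, brute_force_match_many
from scfishhook.matcher import (
    MatchCounters,
    MatcherParams,
    build_seed_index,
    match_read,
)

from conftest import random_read


def _result_key(r):
    return None if r is None else (
        r.fishhook_id, r.allele_id, r.mismatches, r.read_offset, r.orientation
    )


def _embed(probe_seq, rng, read_len=91):
    """Place a probe inside a random read; returns (read, offset)."""
    off = int(rng.integers(0, read_len - len(probe_seq) + 1))
    left = random_read(rng, off)
    right = random_read(rng, read_len - off - len(probe_seq))
    return left + probe_seq + right, off


class TestSeedIndex:
    def test_one_probe_yields_probe_len_minus_seed_plus_one_entries(self):
        probe = Fishhook("p", "v", "mutant", "ACGT" * 9 + "AC", 0, (0,))
        index = build_seed_index([probe], MatcherParams(seed_len=6))
        n_entries = sum(len(v) for _, v in index.items())
        assert n_entries == 38 - 6 + 1 == 33

    def test_lookup_of_probe_prefix_contains_probe_at_offset_zero(self, kras_index, kras_hooks):
        probe = kras_hooks[0]
        assert (probe.fishhook_id, 0) in kras_index.lookup(probe.sequence[:6])

    def test_index_contents_equal_exhaustive_substring_enumeration(self):
        rng = np.random.default_rng(17)
        probes = [
            Fishhook(f"p{i}", f"v{i}", "mutant", random_read(rng, 20), i, (3,))
            for i in range(5)
        ]
        index = build_seed_index(probes, MatcherParams(seed_len=6))
        expected: dict[str, list] = {}
        for p in probes:
            for off in range(20 - 6 + 1):
                expected.setdefault(p.sequence[off : off + 6], []).append((p.fishhook_id, off))
        assert dict(index.items()) == expected

    def test_unequal_probe_lengths_rejected(self):
        probes = [
            Fishhook("a", "v", "mutant", "ACGTACGTAC", 0, (0,)),
            Fishhook("b", "v", "mutant", "ACGTACGT", 0, (0,)),
        ]
        with pytest.raises(ValueError, match="unequal"):
            build_seed_index(probes, MatcherParams())


class TestMatchRead:
    def test_exact_probe_embedded_in_flank_matches_with_zero_mismatches(
        self, kras_index, kras_hooks
    ):
        rng = np.random.default_rng(23)
        probe = next(h for h in kras_hooks if h.fishhook_id == "G12D:mut")
        read, off = _embed(probe.sequence, rng)
        result = match_read(read, kras_index)
        assert result is not None
        assert result.mismatches == 0
        assert result.read_offset == off
        assert result.allele_id == "G12D"

    def test_three_mismatches_exceed_the_two_mismatch_budget(self, kras_index, kras_hooks):
        probe = next(h for h in kras_hooks if h.fishhook_id == "Q61H:mut")
        seq = list(probe.sequence)
        # three substitutions away from the discriminating offset
        for pos in (2, 9, 30):
            assert pos not in probe.discriminating_offsets
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        rng = np.random.default_rng(29)
        read, _ = _embed("".join(seq), rng)
        # guard: only evaluate the constructed placement, not a random one
        assert brute_force_match(read, kras_hooks) is None
        assert match_read(read, kras_index) is None

    def test_two_mismatches_accepted_and_counted(self, kras_index, kras_hooks):
        probe = next(h for h in kras_hooks if h.fishhook_id == "Q61H:mut")
        seq = list(probe.sequence)
        for pos in (2, 30):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        rng = np.random.default_rng(31)
        read, off = _embed("".join(seq), rng)
        result = match_read(read, kras_index)
        assert result is not None and result.mismatches == 2 and result.read_offset == off

    def test_reverse_complement_read_matches_with_reverse_orientation(
        self, kras_index, kras_hooks
    ):
        rng = np.random.default_rng(37)
        probe = next(h for h in kras_hooks if h.fishhook_id == "G12V:mut")
        read, _ = _embed(probe.sequence, rng)
        result = match_read(reverse_complement(read), kras_index)
        assert result is not None and result.orientation == "reverse"
        assert result.allele_id == "G12V"

    def test_error_at_discriminating_base_rejected_under_discriminant_exact(
        self, kras_index, kras_hooks
    ):
        probe = next(h for h in kras_hooks if h.fishhook_id == "G13D:mut")
        off = probe.discriminating_offsets[0]
        seq = list(probe.sequence)
        seq[off] = "T" if seq[off] != "T" else "G"  # G13D alt is A; move off both alleles
        rng = np.random.default_rng(41)
        read, _ = _embed("".join(seq), rng)
        result = match_read(read, kras_index)
        # neither mutant nor wildtype probe can claim the read at its locus
        assert result is None or result.variant_id != "G13D"

    def test_short_read_yields_none_and_is_counted(self, kras_index):
        counters = MatchCounters()
        assert match_read("ACGT" * 9, kras_index, counters=counters) is None  # 36 nt < 38
        assert counters.too_short == 1

    def test_non_acgtn_read_rejected_and_counted(self, kras_index):
        counters = MatchCounters()
        assert match_read("ACGU" * 23, kras_index, counters=counters) is None
        assert counters.rejected_bad_chars == 1

    def test_equal_score_candidates_with_conflicting_alleles_are_ambiguous(self):
        # two probes at different loci, one mutant and one wildtype, sharing
        # a sequence: any containing read ties at 0 mismatches across alleles
        probes = [
            Fishhook("m", "V1", "mutant", "ACGTACGTACGTACGTACGT", 0, (5,)),
            Fishhook("w", "V2", "wildtype", "ACGTACGTACGTACGTACGT", 30, (5,)),
        ]
        index = build_seed_index(probes, MatcherParams())
        counters = MatchCounters()
        read = "TT" + probes[0].sequence + "TT"
        assert match_read(read, index, counters=counters) is None
        assert counters.ambiguous == 1

    def test_wildtype_read_matching_duplicate_wildtype_probes_is_not_ambiguous(
        self, kras_index, kras_hooks
    ):
        # G12D:wt and G12V:wt are sequence-identical; the collapsed WILDTYPE
        # identity keeps such reads callable
        rng = np.random.default_rng(43)
        wt = next(h for h in kras_hooks if h.fishhook_id == "G12D:wt")
        read, _ = _embed(wt.sequence, rng)
        result = match_read(read, kras_index)
        assert result is not None and result.allele_id == "WILDTYPE"


class TestOracleEquivalence:
    def _simulated_reads(self, n, kras_ref, kras_hooks, seed, error_rate=0.01):
        """Reads drawn from mutant/wildtype amplicon windows plus pure noise."""
        rng = np.random.default_rng(seed)
        amplicon = kras_ref.sequence
        reads = []
        mut_probes = [h for h in kras_hooks if h.allele_class == "mutant"]
        for _ in range(n):
            kind = rng.integers(0, 4)
            if kind == 0:
                reads.append(random_read(rng, 91))
                continue
            template = list(amplicon)
            if kind == 2:  # mutant template
                fh = mut_probes[int(rng.integers(0, len(mut_probes)))]
                for off in fh.discriminating_offsets:
                    template[fh.amplicon_start + off] = fh.sequence[off]
            start = int(rng.integers(0, len(amplicon) - 91 + 1))
            read = template[start : start + 91]
            for i in range(91):
                if rng.random() < error_rate:
                    read[i] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            if kind == 3:
                read = reverse_complement(read)
            reads.append(read)
        return reads

    def test_matcher_agrees_with_brute_force_on_randomized_reads(
        self, kras_ref, kras_hooks, kras_index
    ):
        reads = self._simulated_reads(1500, kras_ref, kras_hooks, seed=101)
        expected = brute_force_match_many(reads, kras_hooks)
        for read, exp in zip(reads, expected):
            got = match_read(read, kras_index)
            assert _result_key(got) == _result_key(exp)

    def test_matched_mutant_reads_carry_alt_bases_verbatim(self, kras_ref, kras_hooks, kras_index):
        by_id = {h.fishhook_id: h for h in kras_hooks}
        for read in self._simulated_reads(800, kras_ref, kras_hooks, seed=7, error_rate=0.02):
            r = match_read(read, kras_index)
            if r is None or r.allele_class != "mutant":
                continue
            seq = read if r.orientation == "forward" else reverse_complement(read)
            probe = by_id[r.fishhook_id]
            for off in probe.discriminating_offsets:
                assert seq[r.read_offset + off] == probe.sequence[off]

    def test_loosening_parameters_never_loses_matches(self, kras_ref, kras_hooks):
        reads = self._simulated_reads(300, kras_ref, kras_hooks, seed=53, error_rate=0.03)
        def matched_set(params):
            index = build_seed_index(kras_hooks, params)
            return {
                i for i, read in enumerate(reads)
                if match_read(read, index, params) is not None
            }
        base = matched_set(MatcherParams())
        assert base <= matched_set(MatcherParams(max_mismatch=3))
        assert base <= matched_set(MatcherParams(seed_len=5))
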