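"""Motif parsing, ΔΔG scoring, scanning and affinity profiles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_rna, reduce_per_start_shortest, regex_perfect_sites
from utrkit.motifs import (
    MalformedSequenceError,
    MotifParseError,
    PenaltyMatrix,
    ScanConfig,
    UnsupportedMotifError,
    affinity_from_ddg,
    affinity_profile,
    BindingSite,
    consensus_penalty_matrix,
    count_catalog_matches,
    krel_from_ddg,
    normalize_sequence,
    parse_consensus,
    scan,
    site_ddg,
)


class TestNormalizeSequence:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("atgcu", "AUGCU"),
            ("", ""),
            ("ACGT", "ACGU"),
            ("ac g\nU t", "ACGUU"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_bad_character_position_reported(self):
        with pytest.raises(MalformedSequenceError, match="position 2"):
            normalize_sequence("AXG")


class TestParseConsensus:
    def test_mex3_pattern(self, mex3):
        assert len(mex3.left) == 4
        assert len(mex3.right) == 4
        assert (mex3.spacer_min, mex3.spacer_max) == (0, 8)
        assert mex3.left == (
            frozenset("AGU"), frozenset("GU"), frozenset("A"), frozenset("G"),
        )
        assert mex3.right == (
            frozenset("U"), frozenset("UAC"), frozenset("U"), frozenset("A"),
        )

    def test_minimal_fixed_spacer(self):
        m = parse_consensus("UAN{0-0}UA")
        assert m.left == (frozenset("U"), frozenset("A"))
        assert m.right == (frozenset("U"), frozenset("A"))
        assert (m.spacer_min, m.spacer_max) == (0, 0)

    @pytest.mark.parametrize(
        "bad,exc",
        [
            ("UAUA", UnsupportedMotifError),              # no spacer token
            ("UAN{0-2}UN{1-3}A", UnsupportedMotifError),  # two spacer tokens
            ("N{0-3}UA", MotifParseError),                # empty left half
            ("UAN{0-3}", MotifParseError),                # empty right half
            ("", MotifParseError),
            ("(X/Y)AN{0-1}UA", MotifParseError),          # bad base
        ],
    )
    def test_errors(self, bad, exc):
        with pytest.raises(exc):
            parse_consensus(bad)

    def test_single_half_site_optional(self):
        m = parse_consensus("UA(U/A)", require_spacer=False)
        assert m.right == ()
        assert len(m.left) == 3


class TestPenaltyMatrix:
    def test_consensus_matrix_shape_and_fixed_row(self, mex3, mex3_matrix):
        assert mex3_matrix.n_positions == 8
        # row 3 recognises the fixed A of the left half-site
        assert mex3_matrix.row_map(2) == {"A": 0.0, "C": 1.0, "G": 1.0, "U": 1.0}

    def test_singleton_consensus_one_zero_per_row(self):
        m = parse_consensus("UAN{0-0}GA")
        arr = consensus_penalty_matrix(m, 2.5).penalties
        assert ((arr == 0).sum(axis=1) == 1).all()

    def test_default_penalty_must_be_positive(self, mex3):
        with pytest.raises(ValueError):
            consensus_penalty_matrix(mex3, 0.0)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, 1.0, 1.0]]),          # wrong width
            np.array([[0.5, 1.0, 1.0, 1.0]]),     # no zero in row
            np.array([[0.0, -1.0, 1.0, 1.0]]),    # negative
            np.array([[0.0, np.inf, 1.0, 1.0]]),  # non-finite
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            PenaltyMatrix(bad)


class TestSiteDdg:
    def test_perfect_site_scores_zero(self, mex3_matrix):
        assert site_ddg(mex3_matrix, "AGAG", "UUUA") == 0.0

    def test_single_mismatch(self, mex3_matrix):
        assert site_ddg(mex3_matrix, "CGAG", "UUUA") == 1.0

    def test_three_mismatches_sum_against_bruteforce(self, mex3):
        matrix = consensus_penalty_matrix(mex3, default_penalty=1.5)
        left, right = "CGAG", "GUGA"  # mismatches at rows 0, 4, 6
        expected = sum(
            0.0 if base in allowed else 1.5
            for base, allowed in zip(left + right, mex3.positions)
        )
        assert expected == 4.5
        assert site_ddg(matrix, left, right) == pytest.approx(expected)

    def test_length_mismatch_is_error(self, mex3_matrix):
        with pytest.raises(ValueError, match="matrix rows"):
            site_ddg(mex3_matrix, "AGA", "UUUA")


class TestKrel:
    def test_endpoints_and_unit_argument(self):
        assert krel_from_ddg(0.0) == 1.0
        assert affinity_from_ddg(0.0) == 1.0
        assert krel_from_ddg(1.0, RT=1.0) == pytest.approx(math.e)
        assert affinity_from_ddg(50.0) == pytest.approx(0.0, abs=1e-20)

    def test_rt_scales_energy(self):
        assert krel_from_ddg(0.593, RT=0.593) == pytest.approx(math.e)

    @given(
        ddg=st.floats(0.0, 30.0),
        bump=st.floats(0.01, 5.0),
        rt=st.floats(0.1, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_affinity_strictly_decreasing_in_ddg(self, ddg, bump, rt):
        assert affinity_from_ddg(ddg + bump, rt) < affinity_from_ddg(ddg, rt)


class TestScan:
    def test_planted_site_in_c_background(self, mex3, mex3_matrix):
        seq = "C" * 21 + "GGAG" + "UUUA" + "C" * 21
        sites = scan(seq, mex3, mex3_matrix, utr_id="t")
        perfect = [s for s in sites if s.perfect]
        assert len(perfect) == 1
        (site,) = perfect
        assert (site.start, site.end, site.spacer_len) == (22, 29, 0)
        assert site.ddg == 0.0 and site.krel == 1.0 and site.affinity == 1.0
        # regex-enumeration oracle agrees
        assert regex_perfect_sites(seq, mex3) == {(22, 0)}

    def test_empty_and_short_sequences(self, mex3):
        assert scan("", mex3) == []
        assert scan("GGAGUUU", mex3) == []  # one short of the minimal site

    def test_per_start_best_and_shortest_spacer_tie(self, mex3, mex3_matrix):
        # GGAG C UUUA: perfect with spacer 1; spacer 0 alignment is imperfect
        seq = "GGAGCUUUA"
        sites = scan(seq, mex3, mex3_matrix)
        best = {s.start: s for s in sites}
        assert best[1].spacer_len == 1 and best[1].perfect

    def test_tie_rule_longest_spacer(self, mex3, mex3_matrix):
        # two perfect alignments from start 1: spacers 0 and 4
        seq = "GGAG" + "UUUA" + "UUUA" + "C" * 4
        shortest = scan(seq, mex3, mex3_matrix)
        longest = scan(seq, mex3, mex3_matrix, ScanConfig(tie_rule="longest_spacer"))
        assert {s.spacer_len for s in shortest if s.start == 1} == {0}
        assert {s.spacer_len for s in longest if s.start == 1} == {4}

    def test_max_ddg_cutoff_filters(self, mex3, mex3_matrix):
        seq = "C" * 40
        assert scan(seq, mex3, mex3_matrix, ScanConfig(max_ddg=3.0)) == []
        permissive = scan(seq, mex3, mex3_matrix, ScanConfig(max_ddg=8.0))
        assert permissive and all(not s.perfect for s in permissive)

    def test_site_coordinates_consistent(self, mex3, mex3_matrix):
        rng = np.random.default_rng(11)
        seq = random_rna(rng, 250)
        for s in scan(seq, mex3, mex3_matrix, ScanConfig(max_ddg=8.0)):
            assert s.end - s.start + 1 == 4 + s.spacer_len + 4
            assert s.affinity == pytest.approx(1.0 / s.krel)

    def test_oracle_equivalence_random_sequences(self, mex3, mex3_matrix):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            seq = random_rna(rng, int(rng.integers(10, 301)))
            found = {
                (s.start, s.spacer_len)
                for s in scan(seq, mex3, mex3_matrix)
                if s.perfect
            }
            expected = reduce_per_start_shortest(regex_perfect_sites(seq, mex3))
            assert found == expected

    def test_monotonicity_in_single_penalty(self, mex3):
        """Raising one position's penalty never raises any site's affinity."""
        rng = np.random.default_rng(5)
        seq = random_rna(rng, 150)
        base = consensus_penalty_matrix(mex3, 1.0)
        cfg = ScanConfig(max_ddg=100.0)
        before = {
            (s.start, s.spacer_len): s.affinity for s in scan(seq, mex3, base, cfg)
        }
        for row in range(8):
            for col in range(4):
                arr = base.penalties.copy()
                if arr[row, col] == 0:
                    continue  # keep the zero-per-row invariant
                arr[row, col] += 0.7
                bumped = PenaltyMatrix(arr)
                after = {
                    (s.start, s.spacer_len): s.affinity
                    for s in scan(seq, mex3, bumped, cfg)
                }
                for key, aff in after.items():
                    if key in before:
                        assert aff <= before[key] + 1e-12


class TestPerfectWordCounts:
    def test_spacer0_exhaustive_enumeration_is_18(self, mex3):
        fixed = parse_consensus("(A/G/U)(G/U)AGN{0-0}U(U/A/C)UA")
        words = {
            w
            for w in map("".join, itertools.product("ACGU", repeat=8))
            if regex_perfect_sites(w, fixed) == {(1, 0)}
        }
        assert len(words) == 18  # 3*2*1*1 * 1*3*1*1
        # every word is also seen by the scanner as a perfect site
        for w in words:
            sites = scan(w, fixed)
            assert len(sites) == 1 and sites[0].perfect

    def test_spacer1_distinct_9mer_count_is_72(self, mex3):
        fixed = parse_consensus("(A/G/U)(G/U)AGN{1-1}U(U/A/C)UA")
        count = sum(
            1
            for w in map("".join, itertools.product("ACGU", repeat=9))
            if regex_perfect_sites(w, fixed) >= {(1, 1)}
        )
        assert count == 72  # 18 half-site combinations x 4 spacer bases


class TestAffinityProfile:
    def test_no_sites_all_zero(self):
        prof = affinity_profile([], 30)
        assert prof.length == 30 and not prof.values.any()

    def test_perfect_site_marks_its_start(self, mex3, mex3_matrix):
        seq = "C" * 11 + "GGAGUUUA" + "C" * 11
        sites = [s for s in scan(seq, mex3, mex3_matrix) if s.perfect]
        prof = affinity_profile(sites, len(seq))
        assert prof.values[11] == 1.0  # position 12, 1-based

    def test_same_start_takes_max(self):
        mk = lambda aff, sp: BindingSite("u", 5, 12 + sp, sp, 1.0, 2.0, aff, False)
        prof = affinity_profile([mk(0.3, 0), mk(0.7, 1)], 20)
        assert prof.values[4] == 0.7

    def test_footprint_rule_covers_site(self):
        site = BindingSite("u", 3, 10, 0, 0.5, 1.6, 0.6, False)
        prof = affinity_profile([site], 15, rule="footprint")
        assert (prof.values[2:10] == 0.6).all()
        assert prof.values[:2].sum() == 0 and prof.values[10:].sum() == 0

    def test_out_of_bounds_site_is_error(self):
        site = BindingSite("u", 10, 25, 0, 0.0, 1.0, 1.0, True)
        with pytest.raises(ValueError, match="outside"):
            affinity_profile([site], 20)

    def test_values_always_within_unit_interval(self, mex3, mex3_matrix):
        rng = np.random.default_rng(17)
        for _ in range(20):
            seq = random_rna(rng, 200)
            sites = scan(seq, mex3, mex3_matrix, ScanConfig(max_ddg=10.0))
            prof = affinity_profile(sites, 200)
            assert prof.values.min() >= 0 and prof.values.max() <= 1


class TestCatalogMatches:
    def test_single_half_site_overlapping_matches(self):
        motif = parse_consensus("UA(U/A)", require_spacer=False)
        hits = count_catalog_matches("UAUUAA", [motif])[motif.name]
        assert [(h.start, h.end) for h in hits] == [(1, 3), (4, 6)]

    def test_absent_motif_empty(self):
        motif = parse_consensus("UA(U/A)", require_spacer=False)
        assert count_catalog_matches("GGGGGG", [motif])[motif.name] == []

    def test_sequence_equal_to_motif_instance(self):
        motif = parse_consensus("UAN{0-0}UA")
        hits = count_catalog_matches("UAUA", [motif])[motif.name]
        assert [(h.start, h.end, h.spacer_len) for h in hits] == [(1, 4, 0)]

    def test_all_spacers_reported_not_reduced(self, mex3):
        # perfect with both spacer 0 and spacer 4 from the same start
        seq = "GGAG" + "UUUA" + "UUUA"
        hits = count_catalog_matches(seq, [mex3])[mex3.name]
        assert {(h.start, h.spacer_len) for h in hits} >= {(1, 0), (1, 4)}
        assert {(h.start, h.spacer_len) for h in hits} == regex_perfect_sites(seq, mex3)
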