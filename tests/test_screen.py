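"""Mutant peptide windows, DAI, votes and the screening cascade."""

import dataclasses

import numpy as np
import pytest

from phlagraph.screen import (
    FilterThresholds,
    Mutation,
    candidates_to_frame,
    compute_dai,
    extract_peptide_pairs,
    heatmap_matrix,
    mutate_protein,
    screen_candidates,
    vote_immunogenicity,
)
from phlagraph.synth import gen_mutations, gen_toy_predictor_suite


class TestMutateProtein:
    def test_direct_substitution(self):
        assert mutate_protein("ACDEFGHIK", 5, "F", "L") == "ACDELGHIK"

    def test_reference_mismatch_quotes_observed(self):
        with pytest.raises(ValueError, match="'C'"):
            mutate_protein("ACDEFGHIK", 2, "A", "V")

    def test_last_position_boundary(self):
        assert mutate_protein("ACDEFGHIK", 9, "K", "R") == "ACDEFGHIR"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mutate_protein("ACDEF", 6, "F", "L")


def enumerate_windows_oracle(seq_len, position, lengths=range(8, 15)):
    """Brute force: all (length, start) windows covering the position."""
    out = []
    for L in lengths:
        for start in range(1, seq_len - L + 2):
            if start <= position <= start + L - 1:
                out.append((L, start))
    return out


class TestExtractPeptidePairs:
    @pytest.fixture
    def interior(self):
        wt = "ACDEFGHIKLMNPQRSTVWYACDEFGH"  # 27 residues, mutate center
        mt = mutate_protein(wt, 14, wt[13], "W")
        return wt, mt

    def test_interior_mutation_yields_77_pairs(self, interior):
        wt, mt = interior
        pairs = extract_peptide_pairs(wt, mt, 14)
        assert len(pairs) == sum(range(8, 15)) == 77
        oracle = enumerate_windows_oracle(27, 14)
        assert len(pairs) == len(oracle)

    def test_terminal_mutation_yields_7_pairs(self):
        wt = "ACDEFGHIKLMNPQRSTVWYACDEFGH"
        mt = mutate_protein(wt, 1, "A", "W")
        pairs = extract_peptide_pairs(wt, mt, 1)
        assert len(pairs) == 7  # one window per length
        assert all(p.offset_of_mutation == 1 for p in pairs)

    def test_windows_match_enumeration_oracle(self, interior):
        wt, mt = interior
        for pos in (1, 5, 14, 27):
            mt_seq = mutate_protein(wt, pos, wt[pos - 1],
                                    "W" if wt[pos - 1] != "W" else "Y")
            pairs = extract_peptide_pairs(wt, mt_seq, pos)
            assert len(pairs) == len(enumerate_windows_oracle(27, pos))

    def test_every_pair_differs_exactly_at_offset(self, interior):
        wt, mt = interior
        for p in extract_peptide_pairs(wt, mt, 14):
            diffs = [i for i, (a, b) in
                     enumerate(zip(p.mt_peptide, p.wt_peptide)) if a != b]
            assert diffs == [p.offset_of_mutation - 1]
            assert p.mt_peptide[p.offset_of_mutation - 1] == "W"

    def test_repetitive_sequence_pairs_stay_unique(self):
        # the mutated residue sits at a different offset in every window,
        # so even a poly-A background yields distinct (MT, WT) pairs
        wt = "A" * 30
        mt = mutate_protein(wt, 15, "A", "V")
        pairs = extract_peptide_pairs(wt, mt, 15)
        keys = [(p.mt_peptide, p.wt_peptide) for p in pairs]
        assert len(keys) == len(set(keys)) == 77

    def test_mismatched_sequences_rejected(self):
        with pytest.raises(ValueError):
            extract_peptide_pairs("ACDEFGHIK", "ACDEFGHIK", 3)


class TestDAI:
    def test_ratio(self):
        assert compute_dai(1000, 100) == pytest.approx(10.0)
        assert compute_dai(100, 1000) == pytest.approx(0.1)

    def test_equal_binding_fails_strict_filter(self):
        dai = compute_dai(500, 500)
        assert dai == 1.0
        assert not (dai > FilterThresholds().dai_min)

    @pytest.mark.parametrize("wt,mt", [(0, 100), (100, 0), (-5, 100)])
    def test_nonpositive_inputs_error(self, wt, mt):
        with pytest.raises(ValueError):
            compute_dai(wt, mt)


class TestVotes:
    def test_counting_with_mixed_tool_types(self):
        votes = vote_immunogenicity(
            {"A": 0.9, "B": 0.85, "C": 0.1, "prime_rank": 5.0},
            FilterThresholds(),
        )
        assert votes == 2

    def test_inclusive_score_boundary(self):
        assert vote_immunogenicity({"A": 0.8}, FilterThresholds()) == 1
        assert vote_immunogenicity({"A": 0.799}, FilterThresholds()) == 0

    def test_strict_rank_boundary(self):
        assert vote_immunogenicity({"x_rank": 2.0}, FilterThresholds()) == 0
        assert vote_immunogenicity({"x_rank": 1.99}, FilterThresholds()) == 1

    def test_all_below_threshold(self):
        assert vote_immunogenicity(
            {"A": 0.1, "B": 0.2, "c_rank": 50.0}, FilterThresholds()
        ) == 0

    def test_unknown_tool_type_errors(self):
        with pytest.raises(ValueError):
            vote_immunogenicity({"A": 0.9}, FilterThresholds(),
                                tool_types={"A": "banana"})

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            vote_immunogenicity({}, FilterThresholds())


@pytest.fixture(scope="module")
def screen_inputs():
    mutations, _ = gen_mutations(3, protein_length=41, seed=8)
    alleles = [f"HLA-A*{i + 1:02d}:01" for i in range(5)]
    suite = gen_toy_predictor_suite(seed=1)
    return mutations, alleles, suite


class TestScreenCandidates:
    def test_matches_bruteforce_oracle(self, screen_inputs):
        mutations, alleles, suite = screen_inputs
        thresholds = FilterThresholds()
        candidates, _ = screen_candidates(
            mutations, alleles, suite, thresholds, keep_all=True
        )
        # independent re-evaluation of every candidate from the suite
        expected_pass = set()
        for c in candidates:
            mt, wt = c.pair.mt_peptide, c.pair.wt_peptide
            ic50_mt, rank_mt = suite.binding(mt, c.allele)
            ic50_wt, _ = suite.binding(wt, c.allele)
            votes = 0
            for tool, ttype in suite.immunogenicity_tool_types.items():
                v = suite.immunogenicity(mt, c.allele)[tool]
                votes += (v < 2.0) if ttype == "rank" else (v >= 0.8)
            ok = (
                rank_mt < 2.0
                and ic50_wt / ic50_mt > 1.0
                and suite.stability(mt, c.allele) < 2.0
                and suite.processing(mt, c.allele) < 2.0
                and votes >= 3
            )
            if ok:
                expected_pass.add((c.mutation, c.allele, mt))
        got_pass = {
            (c.mutation, c.allele, c.pair.mt_peptide)
            for c in candidates if c.passed
        }
        assert got_pass == expected_pass

    def test_threshold_monotonicity(self, screen_inputs):
        mutations, alleles, suite = screen_inputs
        loose, _ = screen_candidates(
            mutations, alleles, suite,
            FilterThresholds(binding_rank_max=10, stability_rank_max=50,
                             processing_rank_max=50, min_votes=1),
        )
        for field, tight_value in [
            ("binding_rank_max", 2), ("dai_min", 3), ("stability_rank_max", 10),
            ("processing_rank_max", 10), ("min_votes", 2),
        ]:
            base = FilterThresholds(binding_rank_max=10, stability_rank_max=50,
                                    processing_rank_max=50, min_votes=1)
            tight = dataclasses.replace(base, **{field: tight_value})
            survivors, _ = screen_candidates(mutations, alleles, suite, tight)
            assert len(survivors) <= len(loose)

    def test_pass_is_conjunction_of_flags(self, screen_inputs):
        mutations, alleles, suite = screen_inputs
        candidates, _ = screen_candidates(
            mutations, alleles, suite, keep_all=True
        )
        for c in candidates:
            assert c.passed == all(c.flags.values())

    def test_keep_all_conserves_every_window(self, screen_inputs):
        mutations, alleles, suite = screen_inputs
        candidates, summary = screen_candidates(
            mutations, alleles, suite, keep_all=True
        )
        n_windows = sum(
            len(extract_peptide_pairs(
                m.protein_seq,
                mutate_protein(m.protein_seq, m.position, m.ref_aa, m.alt_aa),
                m.position,
            ))
            for m in mutations
        )
        assert len(candidates) == n_windows * len(alleles)
        assert summary["n_candidates"] == len(candidates)
        keys = [(c.mutation, c.allele, c.pair.mt_peptide, c.pair.length,
                 c.pair.offset_of_mutation) for c in candidates]
        assert len(keys) == len(set(keys))

    def test_deterministic_snapshot(self, screen_inputs):
        mutations, alleles, suite = screen_inputs
        a, _ = screen_candidates(mutations, alleles, suite, keep_all=True)
        b, _ = screen_candidates(mutations, alleles, suite, keep_all=True)
        fa, fb = candidates_to_frame(a), candidates_to_frame(b)
        assert fa.equals(fb)

    def test_empty_mutation_list(self, screen_inputs):
        _, alleles, suite = screen_inputs
        candidates, summary = screen_candidates([], alleles, suite)
        assert candidates == [] and summary["n_candidates"] == 0

    def test_predictor_failure_marks_candidate(self, screen_inputs):
        mutations, alleles, _ = screen_inputs

        class FailingSuite:
            immunogenicity_tool_types = {"a": "score"}

            def binding(self, peptide, allele):
                raise RuntimeError("boom")

            stability = processing = immunogenicity = binding

        candidates, summary = screen_candidates(
            mutations[:1], alleles[:1], FailingSuite(), keep_all=True
        )
        assert summary["n_errors"] == len(candidates)
        assert all(c.error for c in candidates)


class TestHeatmap:
    def test_shape_and_layout(self, screen_inputs):
        mutations, alleles, suite = screen_inputs
        candidates, _ = screen_candidates(
            mutations[:1], alleles[:2], suite, keep_all=True,
            lengths=[8],
        )
        three_windows = [c for c in candidates
                         if c.pair.mt_peptide in
                         {x.pair.mt_peptide for x in candidates[:3]}]
        mat = heatmap_matrix(three_windows)
        assert mat.shape[0] == 2
        mat_ic50 = heatmap_matrix(three_windows, value="ic50_mt")
        assert list(mat.columns) == list(mat_ic50.columns)
        assert list(mat.index) == list(mat_ic50.index)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            heatmap_matrix([])

    def test_mixed_mutations_error(self, screen_inputs):
        mutations, alleles, suite = screen_inputs
        candidates, _ = screen_candidates(
            mutations[:2], alleles[:1], suite, keep_all=True
        )
        with pytest.raises(ValueError):
            heatmap_matrix(candidates)


def test_mutation_invariants():
    with pytest.raises(ValueError):
        Mutation("G", "ACDEF", 2, "A", "V")  # ref mismatch
    with pytest.raises(ValueError):
        Mutation("G", "ACDEF", 2, "C", "C")  # not missense
    m = Mutation("G", "ACDEF", 2, "C", "Y")
    assert m.hgvs_p == "G:p.C2Y"
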