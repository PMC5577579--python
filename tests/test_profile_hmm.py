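import math

import numpy as np
import pytest

from venomhmm.io_formats import Msa
from venomhmm.profile_hmm import (
    AMINO_ACIDS,
    BuildParams,
    build_profile,
    forward_score,
    viterbi_best_domain,
)

from conftest import make_consensus_model, make_random_model, seq
from oracle import enumerate_local_paths


class TestBuildProfile:
    def test_identical_rows_give_high_cysteine_emission(self):
        msa = Msa("t", [("a", "CAC"), ("b", "CAC"), ("c", "CAC")])
        model = build_profile(msa, BuildParams(match_gap_fraction=0.5))
        assert model.length == 3
        c_idx = AMINO_ACIDS.index("C")
        assert np.argmax(model.match_emissions[0]) == c_idx

    def test_pseudocount_mixing_closed_form(self):
        # 3 observations of C with weight-1 uniform background:
        # (3 + 1 * 0.05) / (3 + 1) = 0.7625
        msa = Msa("t", [("a", "CAC"), ("b", "CAC"), ("c", "CAC")])
        model = build_profile(
            msa, BuildParams(pseudocount_weight=1.0,
                             background_choice="uniform"))
        c_idx = AMINO_ACIDS.index("C")
        assert model.match_emissions[0, c_idx] == pytest.approx(0.7625)
        # unobserved residue: (0 + 0.05) / 4
        assert model.match_emissions[0, 0] == pytest.approx(0.0125)

    def test_majority_gap_column_becomes_insert(self):
        rows = [("a", "CAC"), ("b", "C-C"), ("c", "C-C"),
                ("d", "C-C"), ("e", "CAC")]
        model = build_profile(Msa("t", rows),
                              BuildParams(match_gap_fraction=0.5))
        assert model.length == 2  # 60% gapped column dropped to insert

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError, match="match"):
            build_profile(Msa("t", [("a", "--"), ("b", "--")]))

    def test_transition_groups_normalised(self, toy_msa):
        model = build_profile(toy_msa)
        model.validate(atol=1e-9)


class TestViterbi:
    def test_consensus_score_closed_form(self, cak_model):
        # deterministic emissions against uniform 1/20 background:
        # 3 * log2(20) bits, covering the whole sequence
        hit = viterbi_best_domain(cak_model, seq("CAK"))
        assert hit.bit_score == pytest.approx(3 * math.log2(20), abs=1e-6)
        assert (hit.ali_from, hit.ali_to) == (1, 3)

    def test_no_positive_segment_returns_none(self, cak_model):
        assert viterbi_best_domain(cak_model, seq("WWWW")) is None

    def test_consensus_coordinates_cover_emitting_positions(self):
        rng = np.random.default_rng(5)
        for length in (1, 2, 3):
            model = make_random_model(rng, length, support="ACD")
            consensus = model.consensus()
            hit = viterbi_best_domain(model, seq(consensus))
            if hit is not None:
                assert 1 <= hit.ali_from <= hit.ali_to <= len(consensus)

    def test_local_alignment_inside_flanks(self, cak_model):
        hit = viterbi_best_domain(cak_model, seq("WWCAKWW"))
        assert (hit.ali_from, hit.ali_to) == (3, 5)
        assert hit.bit_score == pytest.approx(3 * math.log2(20), abs=1e-6)

    def test_empty_sequence_rejected(self, cak_model):
        with pytest.raises(ValueError):
            viterbi_best_domain(
                cak_model,
                type("S", (), {"seq_id": "x", "residues": ""})(),
            )

    def test_ambiguous_residues_score_neutrally(self, cak_model):
        plain = viterbi_best_domain(cak_model, seq("CAK"))
        with_x = viterbi_best_domain(cak_model, seq("CAKXXX"))
        assert with_x.bit_score == pytest.approx(plain.bit_score)


class TestForward:
    def test_forward_dominates_viterbi_on_random_pairs(self):
        rng = np.random.default_rng(42)
        letters = np.array(list(AMINO_ACIDS))
        checked = 0
        for _ in range(200):
            model = make_random_model(rng, int(rng.integers(1, 6)))
            residues = "".join(rng.choice(letters, size=rng.integers(1, 15)))
            hit = viterbi_best_domain(model, seq(residues))
            fwd = forward_score(model, seq(residues))
            if hit is not None:
                assert fwd >= hit.bit_score - 1e-9
                checked += 1
        assert checked > 50

    def test_single_path_model_forward_equals_viterbi(self):
        # M = 1 against L = 1: exactly one local path exists
        model = make_consensus_model("C")
        hit = viterbi_best_domain(model, seq("C"))
        fwd = forward_score(model, seq("C"))
        assert fwd == pytest.approx(hit.bit_score, abs=1e-9)

    def test_toy_forward_equals_path_enumeration(self):
        rng = np.random.default_rng(7)
        model = make_random_model(rng, 2, support="AC")
        _best, total = enumerate_local_paths(model, "AC")
        assert forward_score(model, seq("AC")) == pytest.approx(
            total, abs=1e-9)


class TestExhaustiveOracle:
    """Viterbi and Forward agree with explicit path enumeration for every
    sequence of length <= 4 over a reduced 3-letter alphabet."""

    @pytest.mark.parametrize("length", [1, 2, 3])
    @pytest.mark.parametrize("model_seed", [0, 1])
    def test_dp_matches_enumeration(self, length, model_seed):
        rng = np.random.default_rng(100 + model_seed)
        model = make_random_model(rng, length, support="ACD")
        alphabet = "ACD"
        sequences = []
        for L in range(1, 5):
            stack = [""]
            for _ in range(L):
                stack = [s + a for s in stack for a in alphabet]
            sequences.extend(stack)
        for residues in sequences:
            best, total = enumerate_local_paths(model, residues)
            hit = viterbi_best_domain(model, seq(residues))
            dp_best = hit.bit_score if hit is not None else None
            if best > 0:
                assert dp_best == pytest.approx(best, abs=1e-9), residues
            else:
                assert hit is None or dp_best <= 0 + 1e-9
            fwd = forward_score(model, seq(residues))
            assert fwd == pytest.approx(total, abs=1e-9), residues


class TestScoreProperties:
    def test_background_flanks_never_lower_best_domain(self):
        rng = np.random.default_rng(9)
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(50):
            model = make_random_model(rng, int(rng.integers(2, 5)))
            core = "".join(rng.choice(letters, size=6))
            flank = "".join(rng.choice(letters, size=3,
                                       p=model.background))
            h1 = viterbi_best_domain(model, seq(core))
            h2 = viterbi_best_domain(model, seq(flank + core + flank))
            if h1 is not None:
                assert h2 is not None
                assert h2.bit_score >= h1.bit_score - 1e-9

    def test_null_calibration_background_scores_below_consensus(self):
        rng = np.random.default_rng(2024)
        model = make_consensus_model("CAKWGCDR")
        consensus_hit = viterbi_best_domain(model, seq(model.consensus()))
        letters = np.array(list(AMINO_ACIDS))
        scores = []
        for _ in range(500):
            residues = "".join(rng.choice(letters, size=8))
            hit = viterbi_best_domain(model, seq(residues))
            scores.append(hit.bit_score if hit is not None else 0.0)
        assert np.mean(scores) < consensus_hit.bit_score
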