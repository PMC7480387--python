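"""Bipartite promoter matrix scoring and scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gblreg.promoter_scan import (
    AmbiguousBaseError,
    BASE_INDEX,
    BipartiteModel,
    PromoterMatrix,
    annotate_vs_tsp,
    build_combined,
    consensus_matrix,
    default_model,
    matrix_from_hexamers,
    read_matrix_tsv,
    scan_bipartite,
    score_window,
    write_matrix_tsv,
    SFB_PROMOTER_HEXAMERS,
)
from gblreg.synthetic_data import random_sequence


def random_matrix(rng, label="m"):
    return PromoterMatrix(label, rng.normal(size=(4, 13)))


class TestScoreWindow:
    def test_zero_matrix_scores_zero(self):
        m = PromoterMatrix("z", np.zeros((4, 13)))
        assert score_window(m, "ACGTACGTACGTA") == 0.0

    def test_one_hot_consensus_scores_13x_weight(self):
        seq = "TTGACAGGGGGGG"
        w = np.zeros((4, 13))
        for k, b in enumerate(seq):
            w[BASE_INDEX[b], k] = 1.5
        assert score_window(PromoterMatrix("m", w), seq) == pytest.approx(13 * 1.5)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_equals_per_column_hand_sum(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng)
        seq = random_sequence(rng, 13, 0.5)
        hand = sum(m.weights[BASE_INDEX[b], k] for k, b in enumerate(seq))
        assert score_window(m, seq) == pytest.approx(hand)

    def test_n_in_window_is_flagged(self):
        m = PromoterMatrix("m", np.ones((4, 13)))
        with pytest.raises(AmbiguousBaseError):
            score_window(m, "ACGTNCGTACGTA")


class TestBuildCombined:
    def test_widths_and_null_block(self, rng):
        model = BipartiteModel(random_matrix(rng, "c"), random_matrix(rng, "a"))
        assert build_combined(model, 0).shape == (4, 26)
        c = build_combined(model, 14)
        assert c.shape == (4, 40)
        assert np.all(c[:, 13:27] == 0)

    def test_negative_null_count_rejected(self, rng):
        model = BipartiteModel(random_matrix(rng, "c"), random_matrix(rng, "a"))
        with pytest.raises(ValueError):
            build_combined(model, -1)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_combined_scan_equals_two_window_sum(self, seed):
        """Null columns are exact no-ops: sliding the combined matrix equals
        scoring the two 13-nt windows independently at every offset."""
        rng = np.random.default_rng(seed)
        model = BipartiteModel(random_matrix(rng, "c"), random_matrix(rng, "a"))
        n = int(rng.integers(0, 20))
        combined = build_combined(model, n)
        seq = random_sequence(rng, 80, 0.6)
        width = combined.shape[1]
        for i in range(len(seq) - width + 1):
            window = seq[i : i + width]
            comb = sum(combined[BASE_INDEX[b], k] for k, b in enumerate(window))
            two = score_window(model.minus35, window[:13]) + score_window(
                model.minus10, window[width - 13 :]
            )
            assert comb == pytest.approx(two)


def brute_force_scan(seq, model):
    """Independent double loop over positions and spacers."""
    out = []
    for gap in range(model.spacer_range[0], model.spacer_range[1] + 1):
        n = model.null_columns(gap)
        if n < 0:
            continue
        width = 26 + n
        for i in range(len(seq) - width + 1):
            w35, w10 = seq[i : i + 13], seq[i + 13 + n : i + 26 + n]
            if "N" in w35 or "N" in w10:
                continue
            out.append((i, gap, score_window(model.minus35, w35) + score_window(model.minus10, w10)))
    return out


class TestScanBipartite:
    def test_implanted_consensus_recovered_at_spacer_17(self, rng):
        model = default_model("consensus")
        bg = random_sequence(rng, 150, 0.72)
        seq = bg[:60] + "TTGACA" + random_sequence(rng, 17, 0.72) + "TATAAT" + bg[60:110]
        hits = scan_bipartite(seq, model)
        top = hits[0]
        assert top.hexamer_spacer == 17
        assert top.hexamers(seq) == ("TTGACA", "TATAAT")

    def test_matches_brute_force_enumeration(self, rng):
        model = BipartiteModel(random_matrix(rng, "c"), random_matrix(rng, "a"))
        seq = random_sequence(rng, 90, 0.6)
        hits = scan_bipartite(seq, model)
        oracle = brute_force_scan(seq, model)
        assert len(hits) == len(oracle)
        assert {round(s, 9) for *_, s in oracle} == {
            round(h.score_total, 9) for h in hits
        }
        assert max(h.score_total for h in hits) == pytest.approx(max(s for *_, s in oracle))

    def test_flat_matrix_ties_broken_by_three_prime_most_minus10(self, rng):
        flat = PromoterMatrix("f", np.zeros((4, 13)))
        model = BipartiteModel(flat, flat, spacer_range=(14, 14))
        seq = random_sequence(rng, 60, 0.5)
        hits = scan_bipartite(seq, model)
        assert len({h.score_total for h in hits}) == 1
        m10_starts = [h.minus10_window.ordinals[0] for h in hits]
        assert m10_starts == sorted(m10_starts, reverse=True)

    def test_too_short_sequence_gives_empty(self, rng):
        model = default_model("consensus")
        assert scan_bipartite("ACGT", model) == []

    def test_invariant_under_appending_downstream_background(self, rng):
        model = default_model("consensus")
        seq = (
            random_sequence(rng, 40, 0.72)
            + "TTGACA" + random_sequence(rng, 17, 0.72) + "TATAAT"
            + random_sequence(rng, 20, 0.72)
        )
        h1 = scan_bipartite(seq, model)[0]
        extended = seq + random_sequence(rng, 40, 0.72)
        h2 = scan_bipartite(extended, model)[0]
        assert h1.score_total == pytest.approx(h2.score_total)
        # appending 40 nt 3' of all hits shifts every anchored position by −40
        assert h2.minus10_window.from_pos == h1.minus10_window.from_pos - 40

    def test_default_spacer_range_covers_all_mapped_promoters(self):
        model = default_model("sfb_learned")
        lo, hi = model.spacer_range
        for spacer in (14, 19, 22, 19, 21, 21):
            assert lo <= spacer <= hi


class TestTspAnnotation:
    def _hit_with_minus10_at(self, rng, m10_from):
        model = default_model("consensus", spacer_range=(17, 17))
        seq = random_sequence(rng, 80, 0.5)
        hits = scan_bipartite(seq, model)
        return next(h for h in hits if h.minus10_window.from_pos == m10_from)

    def test_hexamer_centered_ten_from_tsp(self, rng):
        # sfb2-style geometry: the −10 hexamer centre sits 10 nt upstream of
        # the TSP.  Window from −51 + hexamer offset 3 → hexamer −48..−43,
        # centre ordinal −45.5; TSP −35 (ordinal −35) → offset 10.5, and the
        # symmetric placement one step downstream gives 9.5 — the annotated
        # "10 nt" geometry brackets exactly these two.
        hit = self._hit_with_minus10_at(rng, -51)
        annotate_vs_tsp(hit, -35)
        assert hit.tsp_offset == pytest.approx(10.5)
        hit2 = self._hit_with_minus10_at(rng, -50)
        annotate_vs_tsp(hit2, -35)
        assert hit2.tsp_offset == pytest.approx(9.5)

    def test_hexamer_straddling_tsp_centers_near_zero(self, rng):
        # a hexamer whose centre coincides with the TSP as nearly as an
        # even-width box allows: |offset| = 0.5
        hit = self._hit_with_minus10_at(rng, -41)
        # hexamer −38..−33, centre ordinal −35.5; TSP −35
        annotate_vs_tsp(hit, -35)
        assert abs(hit.tsp_offset) == pytest.approx(0.5)

    def test_hexamer_ending_at_tsp_minus_one_gives_3_5(self, rng):
        # hexamer spans TSP−6..TSP−1 → centre TSP−3.5 → offset 3.5
        hit = self._hit_with_minus10_at(rng, -44)
        # hexamer −41..−36; with TSP = −35 the hexamer ends at TSP−1
        annotate_vs_tsp(hit, -35)
        assert hit.tsp_offset == pytest.approx(3.5)


class TestMatrixIO:
    def test_tsv_round_trip(self, rng, tmp_path):
        m = matrix_from_hexamers("classA_minus10", SFB_PROMOTER_HEXAMERS["minus10"])
        write_matrix_tsv(m, tmp_path / "m.tsv")
        back = read_matrix_tsv(tmp_path / "m.tsv", "classA_minus10")
        assert np.allclose(back.weights, m.weights)

    def test_consensus_matrix_prefers_its_hexamer(self):
        m = consensus_matrix("c", "TTGACA")
        best = "GGG" + "TTGACA" + "GGGG"
        worse = "GGG" + "TTGACC" + "GGGG"
        assert score_window(m, best) > score_window(m, worse)
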