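"""Footprint interval algebra and the operator information model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gblreg.cluster_io import AnchoredInterval, CdsFeature, ClusterRecord, revcomp
from gblreg.operator_model import (
    FootprintPair,
    build_info_model,
    call_consensus,
    dyad_symmetry,
    extract_core_sites,
    interval_length,
    ri_score,
    scan_ri,
    sfb_footprints,
    small_sample_correction,
    strand_displacement,
    strand_overlap,
)
from gblreg.synthetic_data import pfm_from_consensus, random_sequence, sample_pfm_site

OPERATOR_CONSENSUS = "AAACVGNNBVNNCSGTTT"


def iv(a, b, strand="top", gene="g"):
    return AnchoredInterval(gene, a, b, strand_of_read=strand)


class TestIntervalAlgebra:
    # the ten experimentally mapped protected regions and their printed summaries
    PRINTED = {
        "sfb2p": dict(lengths=(30, 28), displacement={2}, overlap=28),
        "sfbRp": dict(lengths=(29, 30), displacement={7, 8}),
        "sfb7p": dict(lengths=(28, 30), overlap=13),
        "sfbR2p": dict(lengths=(28, 29), displacement={8, 9}),
        "sfbAp": dict(lengths=(28, 28), displacement={0}),
    }

    def test_bundled_footprints_reproduce_published_summaries(self):
        pairs = {p.promoter: p for p in sfb_footprints()}
        assert set(pairs) == set(self.PRINTED)
        for name, expected in self.PRINTED.items():
            pair = pairs[name]
            lengths = (interval_length(pair.top), interval_length(pair.bottom))
            assert lengths == expected["lengths"], name
            if "displacement" in expected:
                assert strand_displacement(pair)[2] == expected["displacement"], name
            if "overlap" in expected:
                assert strand_overlap(pair) == expected["overlap"], name

    def test_single_base_interval(self):
        assert interval_length(iv(-7, -7)) == 1

    def test_identical_intervals_not_displaced(self):
        pair = FootprintPair("p", iv(-10, -40), iv(-10, -40, "bottom"))
        assert strand_displacement(pair) == (0, 0, {0})

    def test_nested_and_disjoint_overlap(self):
        assert strand_overlap(FootprintPair("p", iv(-50, -10), iv(-30, -20, "bottom"))) == 11
        assert strand_overlap(FootprintPair("p", iv(-50, -40), iv(-30, -20, "bottom"))) == 0

    @given(
        a=st.integers(-200, -1), b=st.integers(-200, -1),
        c=st.integers(-200, -1), d=st.integers(-200, -1),
    )
    @settings(max_examples=300, deadline=None)
    def test_algebra_matches_per_base_enumeration(self, a, b, c, d):
        top, bottom = iv(a, b), iv(c, d, "bottom")
        pair = FootprintPair("p", top, bottom)
        set_t, set_b = set(top.positions()), set(bottom.positions())
        assert interval_length(top) == len(set_t)
        assert strand_overlap(pair) == len(set_t & set_b)
        up, down, summary = strand_displacement(pair)
        assert up == abs(min(set_t) - min(set_b))
        assert down == abs(max(set_t) - max(set_b))
        assert summary == ({x for x in (up, down) if x} or {0})

    def test_mixed_gene_anchors_rejected(self):
        with pytest.raises(ValueError):
            FootprintPair("p", iv(-5, -1, gene="x"), iv(-5, -1, "bottom", gene="y"))


class TestInfoModel:
    def test_uniform_columns_give_zero_bits(self):
        sites = ["AC", "CG", "GT", "TA"]
        m = build_info_model(sites)
        assert m.R_sequence == pytest.approx(0.0)

    def test_invariant_columns_give_two_bits_each(self):
        sites = ["ACGTACGTACGTACGTAA"] * 4
        m = build_info_model(sites)
        assert m.R_sequence == pytest.approx(36.0)  # 2 bits × width 18

    def test_hand_computed_two_column_model(self):
        # col 1 invariant (2 bits), col 2 uniform (0 bits)
        m = build_info_model(["AA", "AC", "AG", "AT"])
        assert m.info[0] == pytest.approx(2.0)
        assert m.info[1] == pytest.approx(0.0)
        assert m.R_sequence == pytest.approx(2.0)

    def test_unequal_widths_rejected(self):
        with pytest.raises(ValueError):
            build_info_model(["AAA", "AA"])

    def test_small_sample_correction_exact_values(self):
        # n=1: the observed column is always a single base → E[H]=0 → e=2
        assert small_sample_correction(1) == pytest.approx(2.0)
        # n=2: H is 0 (same base twice, p=1/4) or 1 bit (different, p=3/4)
        assert small_sample_correction(2) == pytest.approx(2.0 - 0.75)
        # large n approaches the asymptote 3/(2 ln2 · n)
        assert small_sample_correction(200) == pytest.approx(3 / (2 * math.log(2) * 200), rel=0.02)

    def test_correction_lowers_r_sequence_by_width_times_e(self):
        sites = ["ACGTACGTAC"] * 5
        off = build_info_model(sites, correction=False)
        on = build_info_model(sites, correction=True)
        assert on.R_sequence == pytest.approx(off.R_sequence - 10 * small_sample_correction(5))

    @given(seed=st.integers(0, 2000))
    @settings(max_examples=50, deadline=None)
    def test_r_sequence_bounds_and_revcomp_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pfm = pfm_from_consensus(OPERATOR_CONSENSUS, strength=0.8)
        sites = [sample_pfm_site(rng, pfm) for _ in range(8)]
        m = build_info_model(sites)
        assert 0.0 <= m.R_sequence <= 2.0 * m.width + 1e-9
        m_rc = build_info_model([revcomp(s) for s in sites])
        assert m_rc.R_sequence == pytest.approx(m.R_sequence)
        assert m_rc.info[::-1] == pytest.approx(m.info)


class TestConsensus:
    def test_pure_column(self):
        m = build_info_model(["AA", "AA", "AA"])
        assert call_consensus(m)[0] == "A"

    def test_three_base_column_is_v(self):
        # f(A)=0.5, f(C)=0.3, f(G)=0.2 with min_freq 0.1 → {A,C,G} = V
        sites = ["A"] * 5 + ["C"] * 3 + ["G"] * 2
        m = build_info_model([s + "T" for s in sites])
        assert call_consensus(m, 0.1)[0] == "V"

    def test_all_four_is_n(self):
        m = build_info_model(["AT", "CT", "GT", "TT"])
        assert call_consensus(m, 0.1) == "NT"

    def test_min_freq_bounds(self):
        m = build_info_model(["AA", "AA"])
        with pytest.raises(ValueError):
            call_consensus(m, 0.0)


class TestDyadSymmetry:
    def test_perfect_palindrome(self):
        assert dyad_symmetry("AAATTT") == 1.0

    def test_no_symmetry(self):
        assert dyad_symmetry("AAAA") == 0.0

    def test_published_operator_consensus_is_16_of_18(self):
        assert dyad_symmetry(OPERATOR_CONSENSUS) == pytest.approx(16 / 18)

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError):
            dyad_symmetry("AAXTT")


class TestRiScanning:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(11)
        pfm = pfm_from_consensus(OPERATOR_CONSENSUS, strength=0.9)
        return build_info_model([sample_pfm_site(rng, pfm) for _ in range(10)])

    def test_training_site_scores_its_model_ri(self, model):
        site = model.sites[0]
        seq = "G" * 30 + site + "C" * 30
        hits = scan_ri(seq, model, threshold=-1e9)
        at_site = [h for h in hits if h.start == 31 and h.strand == "top"]
        assert at_site and at_site[0].ri == pytest.approx(ri_score(site, model))

    def test_scan_equals_brute_force_enumeration(self, model, rng):
        seq = random_sequence(rng, 200, 0.72)
        hits = scan_ri(seq, model, threshold=0.0)
        w = model.width
        expected = []
        for strand, s in (("top", seq), ("bottom", revcomp(seq))):
            for i in range(len(s) - w + 1):
                r = ri_score(s[i : i + w], model)
                if r >= 0.0:
                    start = i + 1 if strand == "top" else len(s) - w - i + 1
                    expected.append((start, strand, round(r, 9)))
        got = {(h.start, h.strand, round(h.ri, 9)) for h in hits}
        assert got == set(expected)
        assert [h.ri for h in hits] == sorted((h.ri for h in hits), reverse=True)

    def test_implanted_sites_recovered_on_both_strands(self, model, rng):
        site = model.sites[1]
        seq = (random_sequence(rng, 50, 0.72) + site
               + random_sequence(rng, 50, 0.72) + revcomp(site)
               + random_sequence(rng, 50, 0.72))
        starts = {(h.start, h.strand) for h in scan_ri(seq, model, 0.0)}
        assert (51, "top") in starts
        assert (119, "bottom") in starts

    def test_all_n_region_has_no_hits(self, model):
        assert scan_ri("N" * 60, model, threshold=-1e9) == []


def _record_with_upstream(seqs: dict[str, str]) -> ClusterRecord:
    """Build a record whose genes each carry one given upstream region."""
    parts, feats, pos = [], [], 0
    for gene, up in seqs.items():
        cds = "ATG" + "CAG" * 8 + "TGA"
        parts.append(up + cds)
        start = pos + len(up) + 1
        feats.append(CdsFeature(gene, start, start + len(cds) - 1, "+"))
        pos += len(up) + len(cds)
    return ClusterRecord("synth", "".join(parts), feats)


class TestCoreSiteExtraction:
    def test_recovers_implanted_core_from_padded_footprints(self):
        rng = np.random.default_rng(5)
        core = "AAACAGTTGCAACTGTTT"  # 18-nt dyad-symmetric core
        ups, pairs = {}, []
        for k in range(5):
            gene = f"g{k}"
            left = random_sequence(rng, 40, 0.72)
            right = random_sequence(rng, 12, 0.72)
            ups[gene] = left + core + right
            # protection covers core ± flanks: anchored positions of the
            # upstream region run −len(up)..−1
            up_len = 40 + 18 + 12
            start_anch = -(up_len - 40) - 4  # 4 nt of flank on the left
            end_anch = start_anch + 18 + 7  # and 4 on the right (26-nt protection)
            pairs.append(
                FootprintPair(
                    f"g{k}p",
                    AnchoredInterval(gene, start_anch, end_anch, strand_of_read="top"),
                    AnchoredInterval(gene, start_anch, end_anch, strand_of_read="bottom"),
                )
            )
        record = _record_with_upstream(ups)
        sites = extract_core_sites(record, pairs, width=18)
        assert len(sites) == 10
        # dyad-symmetric core: both strands read the same sequence
        assert all(s == core for s in sites)

    def test_width_equal_to_protection_returns_protection(self):
        rng = np.random.default_rng(6)
        up = random_sequence(rng, 60, 0.72)
        record = _record_with_upstream({"g0": up})
        pair = FootprintPair(
            "g0p",
            AnchoredInterval("g0", -40, -23, strand_of_read="top"),
            AnchoredInterval("g0", -40, -23, strand_of_read="bottom"),
        )
        sites = extract_core_sites(record, [pair, pair], width=18)
        top_seq = pair.top.sequence(record)
        assert sites[0] == top_seq
        assert sites[1] == revcomp(top_seq)

    def test_width_exceeding_protection_names_promoter(self):
        record = _record_with_upstream({"g0": "ACGT" * 15})
        pair = FootprintPair(
            "g0p",
            AnchoredInterval("g0", -20, -11, strand_of_read="top"),
            AnchoredInterval("g0", -20, -11, strand_of_read="bottom"),
        )
        with pytest.raises(ValueError, match="g0p"):
            extract_core_sites(record, [pair], width=18)

    def test_windows_maximize_ri_vs_exhaustive_oracle(self):
        # sites sampled from a strong PFM, centred at a known offset inside
        # wider protections: refinement must find windows that are a fixpoint
        # of per-site Ri maximisation under the final model
        rng = np.random.default_rng(9)
        pfm = pfm_from_consensus(OPERATOR_CONSENSUS, strength=0.95)
        ups, pairs = {}, []
        for k in range(6):
            gene = f"g{k}"
            site = sample_pfm_site(rng, pfm)
            left = random_sequence(rng, 30, 0.72)
            right = random_sequence(rng, 10, 0.72)
            ups[gene] = left + site + right
            up_len = len(ups[gene])
            start_anch = -(up_len - 30) - 5
            end_anch = start_anch + 18 + 9
            pairs.append(
                FootprintPair(
                    f"g{k}p",
                    AnchoredInterval(gene, start_anch, end_anch, strand_of_read="top"),
                    AnchoredInterval(gene, start_anch, end_anch, strand_of_read="bottom"),
                )
            )
        record = _record_with_upstream(ups)
        sites = extract_core_sites(record, pairs, width=18)
        model = build_info_model(sites)
        for pair, site in zip(pairs, sites[::2]):
            region = pair.top.sequence(record)
            best = max(
                ri_score(region[o : o + 18], model) for o in range(len(region) - 17)
            )
            assert ri_score(site, model) == pytest.approx(best)
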