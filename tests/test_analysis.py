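import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import count_motif_rotations
from spacerscan.analysis import (
    BiasSummary,
    bias_summary,
    bin_hits,
    build_pam_matrix,
    count_pam_sites,
    molar_excess,
    neutral_plasmid_share,
    plasmid_fraction,
    MG1655_GENOME_LENGTH,
    DEFAULT_PLASMID_LENGTH,
)


class TestBinHits:
    def test_example(self):
        b = bin_hits([100, 9_999, 10_001], 10_000, 100_000)
        assert b.counts[0] == 2 and b.counts[1] == 1
        assert b.counts.sum() == 3
        assert b.n_bins == 10

    def test_empty(self):
        b = bin_hits([], 50, 5_300)
        assert b.n_bins == math.ceil(5_300 / 50)
        assert b.counts.sum() == 0

    def test_short_last_bin(self):
        b = bin_hits([10_001], 10_000, 10_002)
        assert b.n_bins == 2 and b.counts[1] == 1

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bin_hits([100_000], 10_000, 100_000)

    def test_planted_hotspot_is_argmax(self, rng):
        # heavy enrichment in bin 7 against a uniform background
        background = rng.integers(0, 100_000, size=200)
        hotspot = rng.integers(70_000, 70_050, size=100)
        b = bin_hits(np.concatenate([background, hotspot]), 10_000, 100_000)
        assert int(b.counts.argmax()) == 7

    @given(st.lists(st.integers(min_value=0, max_value=9_999), max_size=60))
    def test_conservation(self, starts):
        assert bin_hits(starts, 137, 10_000).counts.sum() == len(starts)


class TestRatios:
    def test_fraction_example(self):
        assert plasmid_fraction(91, 9) == pytest.approx(0.09)

    def test_all_plasmid(self):
        assert plasmid_fraction(0, 5) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            plasmid_fraction(0, 0)

    def test_all_spacer_rule_differs_from_unique(self):
        # duplicates concentrated on the plasmid: the two rules disagree,
        # the ratio must use all spacers
        tally = {"AAA": 10, "CCC": 1, "GGG": 1}
        source = {"AAA": "plasmid", "CCC": "chromosome", "GGG": "chromosome"}
        all_p = sum(c for s, c in tally.items() if source[s] == "plasmid")
        all_c = sum(c for s, c in tally.items() if source[s] == "chromosome")
        uniq_p = sum(1 for s in tally if source[s] == "plasmid")
        uniq_c = sum(1 for s in tally if source[s] == "chromosome")
        assert plasmid_fraction(all_c, all_p) == pytest.approx(10 / 12)
        assert plasmid_fraction(uniq_c, uniq_p) == pytest.approx(1 / 3)


class TestMolarExcess:
    def test_paper_scale_arithmetic(self):
        value = molar_excess(MG1655_GENOME_LENGTH, DEFAULT_PLASMID_LENGTH, 40)
        assert value == pytest.approx(21.89, abs=0.01)

    def test_identity(self):
        assert molar_excess(1234, 1234, 1) == 1.0

    def test_copy_number_proportionality(self):
        assert molar_excess(1e6, 5e3, 80) == pytest.approx(
            molar_excess(1e6, 5e3, 40) / 2)

    def test_non_positive(self):
        with pytest.raises(ValueError):
            molar_excess(0, 1, 1)


class TestBiasSummary:
    def test_neutral_share_arithmetic(self):
        s = neutral_plasmid_share(4_641_652, 5_300, 40)
        assert s == pytest.approx(0.0437, abs=5e-4)

    def test_neutral_gives_index_one(self):
        s = neutral_plasmid_share(4_641_652, 5_300, 40)
        n = 100_000
        n_p = round(s * n)
        b = bias_summary(n - n_p, n_p, 4_641_652, 5_300, 40)
        assert b.bias_index == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_flags(self):
        assert bias_summary(10, 0, 1e6, 5e3, 40).degenerate == "zero"
        inf_case = bias_summary(0, 10, 1e6, 5e3, 40)
        assert inf_case.degenerate == "infinite"
        assert math.isinf(inf_case.bias_index)

    def test_simulated_neutral_planting(self):
        # binomial oracle: planting at the neutral share gives index ~ 1
        rng = np.random.default_rng(8)
        s = neutral_plasmid_share(4_641_652, 5_300, 40)
        n = 5_000
        n_p = int(rng.binomial(n, s))
        b = bias_summary(n - n_p, n_p, 4_641_652, 5_300, 40)
        se = math.sqrt(s * (1 - s) / n)
        # 3 SE on the fraction scale maps to ~3 SE/(s(1-s)) on log-odds
        assert abs(math.log(b.bias_index)) <= 3 * se / (s * (1 - s))


class TestPamMatrix:
    def test_uniform_aag(self):
        pm = build_pam_matrix(["AAG"] * 100)
        assert pm.consensus == "AAG"
        assert np.allclose(pm.information_content, [2.0, 2.0, 2.0])
        assert pm.counts.sum(axis=0).tolist() == [100, 100, 100]

    def test_uniform_column_zero_bits(self):
        pm = build_pam_matrix(["A", "C", "G", "T"] * 25)
        assert pm.information_content[0] == pytest.approx(0.0)

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            build_pam_matrix(["AAG", "AA"])

    def test_information_bounds(self, rng):
        for _ in range(20):
            pams = ["".join("ACGT"[i] for i in rng.integers(0, 4, 3))
                    for _ in range(30)]
            pm = build_pam_matrix(pams)
            assert np.all(pm.information_content >= -1e-12)
            assert np.all(pm.information_content <= 2.0 + 1e-12)

    def test_pseudocount_never_increases_information(self, rng):
        for _ in range(20):
            pams = ["".join("ACGT"[i] for i in rng.integers(0, 2, 4))
                    for _ in range(25)]
            raw = build_pam_matrix(pams)
            smoothed = build_pam_matrix(pams, pseudocount=1.0)
            assert np.all(smoothed.information_content
                          <= raw.information_content + 1e-12)

    def test_planted_bias_recovery(self):
        import math as _m
        from spacerscan.mapping import SpacerMapper, extract_pam
        from spacerscan.simulate import SimulationConfig, generate_references, \
            plant_events
        cfg = SimulationConfig(seed=21, n_events=200, pam_bias=50.0)
        rng = np.random.default_rng(cfg.seed)
        refs, model, _ = generate_references(cfg, rng)
        events = plant_events(refs, model, cfg, rng)
        pm = build_pam_matrix([e.pam for e in events])
        assert pm.consensus == "AAG"


class TestCountPamSites:
    def test_linear_forward(self):
        assert count_pam_sites("AAGTTAAG", "AAG", circular=False,
                               both_strands=False) == 2

    def test_linear_both_strands(self):
        assert count_pam_sites("AAGTTAAG", "AAG", circular=False,
                               both_strands=True) == 2

    def test_circular_wrap_occurrence(self):
        # AG|...|A wraps to form AAG across the origin (forward strand)
        seq = "AGTTTTA"
        fwd_only = count_pam_sites(seq, "AAG", circular=True, both_strands=False)
        assert fwd_only == 1
        assert count_pam_sites(seq, "AAG", circular=False, both_strands=False) == 0

    def test_overlapping_counted(self):
        assert count_pam_sites("AAAA", "AA", circular=False,
                               both_strands=False) == 3

    def test_empty_motif(self):
        with pytest.raises(ValueError):
            count_pam_sites("ACGT", "")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=40),
           st.booleans(), st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_rotation_oracle(self, seq, circular, both):
        assert count_pam_sites(seq, "AAG", circular=circular, both_strands=both) \
            == count_motif_rotations(seq, "AAG", circular, both)
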