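"""Posterior genotype calling, sliding-window smoothing, breakpoint and bin
construction, recombination fractions and map functions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ssivarscape as sv
from ssivarscape.binmap import (
    AA, AB, BB, MISSING_CODE, detect_breakpoints, window_states_from_calls,
)

from conftest import selfed_population, true_marker_codes


class TestGenotypeCalling:
    def test_zero_counts_are_missing(self):
        g = sv.call_genotype(0, 0)
        assert g.call == MISSING_CODE

    def test_three_concordant_reads_below_threshold(self):
        # direct Bayes arithmetic: 0.25*0.99^3 / (0.25*0.99^3 + 0.5*0.125 + 0.25e-6)
        g = sv.call_genotype(3, 0, sv.CallParams(base_error=0.01))
        assert g.p_aa == pytest.approx(0.7951, abs=1e-3)
        assert g.call == MISSING_CODE

    def test_six_concordant_reads_called_homozygous(self):
        g = sv.call_genotype(6, 0, sv.CallParams(base_error=0.01))
        assert g.p_aa == pytest.approx(0.9679, abs=1e-3)
        assert g.call == AA

    def test_balanced_reads_called_heterozygous(self):
        g = sv.call_genotype(2, 2, sv.CallParams(base_error=0.01))
        assert g.call == AB

    def test_posteriors_sum_to_one(self, rng):
        n_a = rng.integers(0, 12, 200)
        n_b = rng.integers(0, 12, 200)
        post, _ = sv.call_genotypes(n_a, n_b, sv.CallParams(base_error=0.02))
        nz = (n_a + n_b) > 0
        assert np.allclose(post[nz].sum(axis=1), 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sv.call_genotypes(np.array([-1]), np.array([0]))

    def test_zero_error_edge_case(self):
        g = sv.call_genotype(8, 0, sv.CallParams(base_error=0.0))
        assert g.call == AA


class TestWindows:
    def test_all_homozygous_calls(self):
        assert sv.window_genotype([AA] * 15) == AA

    def test_balanced_calls_heterozygous(self):
        calls = [AA] * 5 + [BB] * 5  # f_b = 0.5
        assert sv.window_genotype(calls) == AB

    def test_too_few_called_sites_missing(self):
        calls = [AA] * 4 + [MISSING_CODE] * 11
        assert sv.window_genotype(calls) == MISSING_CODE

    def test_hom_threshold_boundary(self):
        # 1 of 10 b alleles: f_b = 0.05 <= 0.1 -> aa; 3 of 30 -> 0.1 -> aa
        assert sv.window_genotype([AB] + [AA] * 9) == AA
        assert sv.window_genotype([AB] * 3 + [AA] * 12) == AA
        assert sv.window_genotype([AB] * 4 + [AA] * 11) == AB  # 4/30 > 0.1

    def test_reads_and_calls_paths_agree(self, rng):
        calls = rng.choice([MISSING_CODE, AA, AB, BB], 60)
        a = window_states_from_calls(calls)
        called = calls >= 0
        n_b = np.where(called, calls, 0)
        n_a = np.where(called, 2 - calls, 0)
        b = sv.window_states(n_a, n_b)
        assert (a == b).all()

    def test_short_sequence_yields_no_windows(self):
        assert sv.window_states(np.array([1, 2]), np.array([0, 1])).size == 0


class TestBreakpoints:
    def test_constant_states_no_breakpoints(self):
        states = np.full(40, AA, np.int8)
        centers = np.arange(40) * 100 + 50
        segments, bps = detect_breakpoints(states, centers)
        assert bps.size == 0
        assert len(segments) == 1 and segments[0][0] == AA

    def test_all_missing_zero_segments(self):
        states = np.full(10, MISSING_CODE, np.int8)
        segments, bps = detect_breakpoints(states, np.arange(10))
        assert segments == [] and bps.size == 0

    def test_single_discordant_window_absorbed(self):
        states = np.array([AA] * 10 + [AB] + [AA] * 10, np.int8)
        centers = np.arange(21) * 10
        segments, bps = detect_breakpoints(states, centers)
        assert bps.size == 0
        assert len(segments) == 1 and segments[0][0] == AA

    def test_clean_transition_midpoint_with_threshold_offset(self):
        states = np.array([AA] * 10 + [AB] * 10, np.int8)
        centers = np.arange(20) * 100 + 100
        segments, bps = detect_breakpoints(states, centers)
        assert len(segments) == 2
        assert [s[0] for s in segments] == [AA, AB]
        # raw midpoint 1050, shifted right by the hom->het window entry
        # offset (W/2 - k* + 1 = 4.5 sites) at 100 bp/site
        assert bps.tolist() == [1050 + 450]
        # the reverse transition shifts by the het->hom offset (3.5 sites)
        _, bps2 = detect_breakpoints(states[::-1].copy(), centers)
        assert bps2.tolist() == [1050 - 350]

    def test_segments_alternate_states(self, rng):
        states = rng.choice([MISSING_CODE, AA, AB, BB], 200).astype(np.int8)
        centers = np.arange(200) * 7 + 3
        segments, bps = detect_breakpoints(states, centers)
        for a, b in zip(segments[:-1], segments[1:]):
            assert a[0] != b[0]
        assert len(bps) == max(len(segments) - 1, 0)

    def test_recovers_planted_crossover_within_one_window(self):
        """Error-free, fully covered line with a single crossover: exactly one
        breakpoint, within one window span of the true position."""
        layout = sv.GenomeLayout.from_spec([("c1", 1_000_000, 100.0)])
        cfg = sv.SimulationConfig(n_lines=60, het_rate_variant=2e-3,
                                  het_rate_recipient=0.0, mut_rate_variant=0.0)
        _, founders, pop, truth = selfed_population(layout, cfg, 21)
        midx, b, codes = true_marker_codes(founders, pop)
        pos = founders.sites["pos"].to_numpy()[midx]
        W = sv.WindowParams().window
        xo = truth.crossovers
        tested = 0
        for line in range(pop.n_lines):
            line_xo = xo[xo["line"] == line]["pos"].to_numpy()
            if len(line_xo) != 1:
                continue
            states = window_states_from_calls(codes[line])
            centers = pos[W // 2: W // 2 + states.size]
            segments, bps = detect_breakpoints(states, centers)
            assert len(bps) == 1
            true_pos = line_xo[0]
            k = np.searchsorted(pos, true_pos)
            lo = pos[max(k - W, 0)]
            hi = pos[min(k + W, len(pos) - 1)]
            assert lo <= bps[0] <= hi
            tested += 1
        assert tested >= 5  # enough single-crossover lines exercised


class TestBins:
    def test_no_breakpoints_one_bin_per_chromosome(self):
        layout = sv.rice_layout(0.001)
        bins = sv.build_bins({}, layout)
        assert len(bins) == 12
        assert (bins["start"] == 1).all()

    def test_partition_from_two_breakpoints(self, one_chrom_layout):
        bins = sv.build_bins({"c1": np.array([100, 200])}, one_chrom_layout)
        assert bins[["start", "end"]].values.tolist() == \
            [[1, 100], [100, 200], [200, 1_000_001]]
        assert bins["length"].tolist() == [99, 100, 999_801]

    def test_bins_tile_each_chromosome(self, rng):
        layout = sv.rice_layout(0.001)
        bps = {c.name: rng.integers(2, c.length_bp, rng.integers(0, 30))
               for c in layout.chromosomes}
        bins = sv.build_bins(bps, layout)
        for c in layout.chromosomes:
            sub = bins[bins["chrom"] == c.name]
            assert sub["start"].iloc[0] == 1
            assert sub["end"].iloc[-1] == c.length_bp + 1
            assert (sub["end"].to_numpy()[:-1] == sub["start"].to_numpy()[1:]).all()
        assert len(bins) == sum(len(np.unique(v)) + 1 for v in bps.values())

    def test_breakpoint_outside_chromosome_rejected(self, one_chrom_layout):
        with pytest.raises(ValueError):
            sv.build_bins({"c1": np.array([2_000_000])}, one_chrom_layout)

    def test_bin_genotypes_match_truth_on_clean_data(self):
        """Full-coverage, error-free population: bin genotypes agree with the
        true genotypes at bin midpoints for >= 99% of entries."""
        layout = sv.GenomeLayout.from_spec([("c1", 1_000_000, 150.0)])
        cfg = sv.SimulationConfig(n_lines=40, het_rate_variant=2e-3,
                                  het_rate_recipient=0.0, mut_rate_variant=0.0)
        _, founders, pop, truth = selfed_population(layout, cfg, 8)
        midx, b_all, codes = true_marker_codes(founders, pop)
        pos = founders.sites["pos"].to_numpy()[midx]
        W = sv.WindowParams().window
        line_segments = {}
        all_bps = []
        for line in range(pop.n_lines):
            states = window_states_from_calls(codes[line])
            centers = pos[W // 2: W // 2 + states.size]
            segments, bps = detect_breakpoints(states, centers)
            line_segments[pop.line_ids[line]] = {"c1": (segments, bps)}
            all_bps.extend(bps.tolist())
        bins = sv.build_bins({"c1": np.array(all_bps, dtype=np.int64)}, layout)
        matrix = sv.bin_genotypes(line_segments, bins)
        mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
        nearest = np.searchsorted(pos, mid).clip(0, len(pos) - 1)
        agree = total = 0
        for li, line_id in enumerate(pop.line_ids):
            est = matrix.loc[line_id].to_numpy()
            true = codes[li][nearest]
            ok = est >= 0
            agree += int((est[ok] == true[ok]).sum())
            total += int(ok.sum())
        assert total > 0 and agree / total >= 0.99

    def test_uncovered_chromosome_missing(self, one_chrom_layout):
        bins = sv.build_bins({"c1": np.array([500_000])}, one_chrom_layout)
        matrix = sv.bin_genotypes({"L1": {}}, bins)
        assert (matrix.loc["L1"] == MISSING_CODE).all()


def simulate_two_locus_f2(r, n, rng):
    """Independent oracle for F2 genotypes at two loci in coupling: draw each
    individual's two gametes directly from the gamete frequencies."""
    gametes = np.array([[0, 0], [1, 1], [0, 1], [1, 0]])
    probs = np.array([(1 - r) / 2, (1 - r) / 2, r / 2, r / 2])
    g1 = gametes[rng.choice(4, n, p=probs)]
    g2 = gametes[rng.choice(4, n, p=probs)]
    return (g1 + g2)[:, 0], (g1 + g2)[:, 1]


class TestRecombinationFraction:
    def test_identical_columns_zero(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 1, 0, 2])
        assert sv.estimate_rf(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_recovery_of_linked_loci(self):
        rng = np.random.default_rng(123)
        est = [sv.estimate_rf(*simulate_two_locus_f2(0.2, 500, rng))
               for _ in range(100)]
        se = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(np.mean(est) - 0.2) < 3 * se

    def test_unlinked_loci_near_half(self):
        rng = np.random.default_rng(7)
        g1, g2 = simulate_two_locus_f2(0.5, 500, rng)
        r = sv.estimate_rf(g1, g2)
        assert abs(r - 0.5) < 3 * 0.5 / math.sqrt(500)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            sv.estimate_rf(np.array([0, -1]), np.array([-1, 0]))


class TestMapFunctions:
    def test_zero_recombination_zero_distance(self):
        assert sv.to_centimorgans(0.0, "haldane") == 0.0
        assert sv.to_centimorgans(0.0, "kosambi") == 0.0

    def test_closed_forms_at_quarter(self):
        assert sv.to_centimorgans(0.25, "haldane") == pytest.approx(34.657, abs=1e-3)
        assert sv.to_centimorgans(0.25, "kosambi") == pytest.approx(27.465, abs=1e-3)

    def test_r_at_half_rejected(self):
        with pytest.raises(ValueError):
            sv.to_centimorgans(0.5, "haldane")

    @given(st.floats(0.0, 200.0))
    def test_round_trip_both_functions(self, d):
        for fn in ("haldane", "kosambi"):
            assert sv.to_centimorgans(sv.from_centimorgans(d, fn), fn) == \
                pytest.approx(d, abs=1e-9)


# the per-chromosome genetic lengths of the study's F2 map (cM)
TABLE3_CM = [234.8, 150.9, 187.2, 95.8, 91.7, 98.7, 126.5, 126.8, 92.2, 78.2,
             104.5, 102.4]


class TestMapSize:
    def test_empty_map_zero(self):
        assert sv.map_size(pd.DataFrame(columns=["chrom", "cM"])) == 0.0

    def test_study_chromosome_lengths_total(self):
        gmap = pd.DataFrame({
            "chrom": [f"chr{i + 1:02d}" for i in range(12)],
            "cM": TABLE3_CM})
        assert sv.map_size(gmap) == pytest.approx(1489.7, abs=0.05)

    def test_random_map_matches_recomputation(self, rng):
        chroms = rng.choice(["a", "b", "c"], 30)
        cm = np.sort(rng.uniform(0, 100, 30))
        gmap = pd.DataFrame({"chrom": chroms, "cM": cm})
        expected = sum(cm[chroms == c].max() for c in np.unique(chroms))
        assert sv.map_size(gmap) == pytest.approx(expected)


class TestGeneticMapRecovery:
    def test_map_length_approaches_simulated_length(self):
        """Error-free fully covered lines: estimated map length within
        3 sigma of the simulated genetic length at n=500."""
        layout = sv.GenomeLayout.from_spec([("c1", 500_000, 80.0)])
        cfg = sv.SimulationConfig(n_lines=500, het_rate_variant=2e-3,
                                  het_rate_recipient=0.0, mut_rate_variant=0.0)
        _, founders, pop, truth = selfed_population(layout, cfg, 31)
        midx, b_all, codes = true_marker_codes(founders, pop)
        pos = founders.sites["pos"].to_numpy()[midx]
        # use every 20th marker as a pseudo-bin: genotypes are exact
        sel = np.arange(0, len(pos), 20)
        sub = codes[:, sel]
        total = 0.0
        for j in range(len(sel) - 1):
            r = sv.estimate_rf(sub[:, j], sub[:, j + 1])
            total += sv.to_centimorgans(min(r, 0.495), "haldane")
        span_cM = 80.0 * (pos[sel[-1]] - pos[sel[0]]) / 500_000
        # binomial noise on each adjacent r-hat propagates to the sum
        sigma = 100 * math.sqrt((len(sel) - 1) * 0.25 / (2 * 500))
        assert abs(total - span_cM) < 3 * sigma
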