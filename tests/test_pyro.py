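"""Pyrosequencing: dispensation construction, simulation, quantification."""

import numpy as np
import pytest

from methassay.pyro import (
    Pyrogram,
    build_dispensation,
    conversion_qc,
    frame_to_pyrogram,
    pyrogram_to_frame,
    quantify,
    simulate_pyrogram,
)

from .conftest import random_dna


def region_with_cpgs(n_cpg: int, seed: int = 0) -> str:
    """A target region with exactly n_cpg CpGs plus some non-CpG cytosines."""
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_cpg):
        parts.append("CG")
        parts.append("".join(rng.choice(list("ATG"), size=4)) + "CA")
    return "T" + "".join(parts)


class TestBuildDispensation:
    def test_region_without_cpg_is_error(self):
        with pytest.raises(ValueError, match="nothing to quantify"):
            build_dispensation("TAGT")

    def test_eleven_cpgs_give_eleven_pairs(self):
        disp = build_dispensation(region_with_cpgs(11))
        assert len(disp.cpg_pairs) == 11
        assert len(disp.control_pairs) >= 1
        # control steps disjoint from quantification steps by construction
        quant = {i for c, t, _ in disp.cpg_pairs for i in (c, t)}
        ctrl = {i for c, t, _ in disp.control_pairs for i in (c, t)}
        assert not (quant & ctrl)

    def test_fully_methylated_replay_matches_converted_target(self):
        """With m=1 everywhere and no noise, nonzero peaks occur exactly at
        dispensations matching the methylated-converted target."""
        region = region_with_cpgs(5, seed=3)
        disp = build_dispensation(region)
        pg = simulate_pyrogram(disp, {off: 1.0 for _, _, off in disp.cpg_pairs})
        cpg_t = {t for _, t, _ in disp.cpg_pairs}
        ctrl_c = {c for c, _, _ in disp.control_pairs}
        for i, h in enumerate(pg.peak_heights):
            if i in cpg_t or i in ctrl_c:
                assert h == 0.0  # T at a methylated CpG / C at a converted C
            else:
                assert h > 0.0

    def test_homopolymer_weights_scale_with_run_length(self):
        disp = build_dispensation("TTTTCGAA")
        assert disp.bases[0] == "T" and disp.weights[0] == 4.0


class TestSimulateAndQuantify:
    def test_fully_methylated_zero_noise_has_zero_t_peaks(self):
        disp = build_dispensation(region_with_cpgs(4))
        pg = simulate_pyrogram(disp, {off: 1.0 for _, _, off in disp.cpg_pairs})
        assert all(pg.peak_heights[t] == 0.0 for _, t, _ in disp.cpg_pairs)
        assert all(v == pytest.approx(100.0) for v in quantify(pg).per_cpg.values())

    def test_same_seed_identical_pyrogram(self):
        disp = build_dispensation(region_with_cpgs(6))
        m = {off: 0.3 for _, _, off in disp.cpg_pairs}
        a = simulate_pyrogram(disp, m, noise_cv=0.1, seed=5)
        b = simulate_pyrogram(disp, m, noise_cv=0.1, seed=5)
        np.testing.assert_array_equal(a.peak_heights, b.peak_heights)

    def test_zero_noise_round_trip_on_m_grid(self):
        disp = build_dispensation(region_with_cpgs(11))
        offsets = [off for _, _, off in disp.cpg_pairs]
        for m in np.linspace(0, 1, 11):
            pg = simulate_pyrogram(disp, {off: float(m) for off in offsets})
            q = quantify(pg)
            for off in offsets:
                assert q.per_cpg[off] == pytest.approx(100.0 * m, abs=1e-9)

    def test_equal_peaks_give_fifty_percent(self):
        disp = build_dispensation("TCGT")
        heights = np.ones(len(disp))
        c_i, t_i, off = disp.cpg_pairs[0]
        heights[c_i] = heights[t_i] = 0.7
        pg = Pyrogram(disp, heights)
        assert quantify(pg).per_cpg[off] == pytest.approx(50.0)

    def test_estimates_invariant_to_global_scaling(self):
        disp = build_dispensation(region_with_cpgs(5, seed=2))
        m = {off: 0.42 for _, _, off in disp.cpg_pairs}
        pg = simulate_pyrogram(disp, m, noise_cv=0.05, seed=1)
        scaled = Pyrogram(disp, pg.peak_heights * 7.3)
        assert quantify(pg).per_cpg == pytest.approx(quantify(scaled).per_cpg)

    def test_region_mean_is_mean_of_per_cpg(self):
        disp = build_dispensation(region_with_cpgs(7, seed=4))
        m = {off: float(x) for (_, _, off), x in
             zip(disp.cpg_pairs, np.linspace(0.1, 0.9, 7))}
        q = quantify(simulate_pyrogram(disp, m))
        assert q.region_mean == pytest.approx(np.mean(list(q.per_cpg.values())))

    def test_noisy_recovery_error_below_three_points(self):
        """100 seeded simulations with uniform random truth and 5% peak CV:
        mean absolute recovery error stays below 3 percentage points."""
        disp = build_dispensation(region_with_cpgs(11))
        offsets = [off for _, _, off in disp.cpg_pairs]
        rng = np.random.default_rng(123)
        errors = []
        for i in range(100):
            truth = {off: float(rng.uniform()) for off in offsets}
            pg = simulate_pyrogram(disp, truth, noise_cv=0.05, seed=int(rng.integers(2**31)))
            q = quantify(pg)
            errors.extend(abs(q.per_cpg[o] - 100 * truth[o]) for o in offsets)
        assert np.mean(errors) < 3.0

    def test_invalid_fractions_rejected(self):
        disp = build_dispensation("TCGT")
        with pytest.raises(ValueError):
            simulate_pyrogram(disp, {1: 1.5})


class TestConversionQC:
    def test_zero_control_signal_passes_with_zero_background(self):
        disp = build_dispensation(region_with_cpgs(3))
        pg = simulate_pyrogram(disp, {off: 0.5 for _, _, off in disp.cpg_pairs})
        ok, background = conversion_qc(pg)
        assert ok and background == 0.0

    def test_ten_percent_background_fails_five_percent_threshold(self):
        disp = build_dispensation(region_with_cpgs(3))
        pg = simulate_pyrogram(
            disp,
            {off: 0.5 for _, _, off in disp.cpg_pairs},
            incomplete_conversion_rate=0.10,
        )
        ok, background = conversion_qc(pg, threshold_pct=5.0)
        assert not ok and background == pytest.approx(10.0)

    def test_background_recovers_conversion_rate(self):
        """Across 50 seeds the estimated background tracks 100 * rate within
        2 percentage points for rates of 2% and 8%."""
        disp = build_dispensation(region_with_cpgs(6))
        m = {off: 0.5 for _, _, off in disp.cpg_pairs}
        for rate in (0.02, 0.08):
            estimates = [
                conversion_qc(
                    simulate_pyrogram(
                        disp, m, noise_cv=0.05,
                        incomplete_conversion_rate=rate, seed=s,
                    )
                )[1]
                for s in range(50)
            ]
            assert abs(np.mean(estimates) - 100 * rate) < 2.0

    def test_no_controls_is_error(self):
        disp = build_dispensation("TCGT")  # no non-CpG C available
        assert not disp.control_pairs
        pg = simulate_pyrogram(disp, {1: 0.5})
        with pytest.raises(ValueError):
            conversion_qc(pg)


class TestTsvRoundTrip:
    def test_frame_round_trip_preserves_quantification(self):
        disp = build_dispensation(region_with_cpgs(5, seed=9))
        m = {off: 0.37 for _, _, off in disp.cpg_pairs}
        pg = simulate_pyrogram(disp, m, noise_cv=0.05, seed=2)
        back = frame_to_pyrogram(pyrogram_to_frame(pg))
        assert quantify(back).per_cpg == pytest.approx(quantify(pg).per_cpg)
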