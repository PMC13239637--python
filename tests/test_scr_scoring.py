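"""Trough-to-peak scoring: criteria, windows, oracle equivalence, blocks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from fearcon.paradigm import CSType, Phase
from fearcon.scr_scoring import (
    BLOCK_SIZES,
    ScoringParams,
    block_average,
    lowpass_filter,
    score_experiment,
    score_window,
)
from fearcon.scr_synth import SCRGenParams, SCRTrace, simulate_participant, single_deflection_trace


def brute_force_score(y, fs, w0, w1, p: ScoringParams) -> float:
    """Scalar reference implementation: walk every (trough, later sample) pair.

    A pair qualifies when the trough is a local minimum inside the window,
    the candidate sample sets a new running maximum, no intermediate sample
    drops below the trough or falls from the running maximum by the minimum
    amplitude, and the amplitude/rise-time criteria hold.
    """
    n = len(y)
    i0 = int(np.ceil(w0 * fs - 1e-9))
    i1 = int(np.floor(w1 * fs + 1e-9))
    min_gap = int(np.ceil(p.min_rise_time * fs - 1e-9))
    best = 0.0
    for i in range(i0, min(i1, n)):
        is_min = (i == 0 or y[i] <= y[i - 1]) and i < n - 1 and y[i] < y[i + 1]
        if not is_min:
            continue
        run_max = y[i]
        for j in range(i + 1, n):
            if y[j] < y[i]:
                break
            if y[j] > run_max:
                run_max = y[j]
                if j - i >= min_gap:
                    amp = run_max - y[i]
                    if amp >= p.min_amplitude - 1e-12:
                        best = max(best, amp)
            elif run_max - y[j] >= p.min_amplitude:
                break
    return best


class TestScoreWindow:
    def test_flat_trace_scores_zero(self):
        y = np.full(2000, 2.0)
        assert score_window(y, 100.0, 1.0, 8.5, prefiltered=True) == 0.0

    def test_recovers_single_deflection(self):
        y = single_deflection_trace(100.0, 30.0, 10.0, 0.5, 1.5)
        got = score_window(y, 100.0, 9.0, 16.5, prefiltered=True)
        assert got == pytest.approx(0.5, rel=0.02)

    @pytest.mark.parametrize(
        "amp,rise,expect_zero",
        [(0.005, 1.5, True), (0.5, 0.2, True), (0.5, 1.5, False)],
    )
    def test_minimum_criteria(self, amp, rise, expect_zero):
        y = single_deflection_trace(100.0, 30.0, 10.0, amp, rise)
        got = score_window(y, 100.0, 9.0, 16.5, prefiltered=True)
        assert (got == 0.0) == expect_zero

    def test_window_outside_trace_raises(self):
        y = np.zeros(100)
        with pytest.raises(ValueError):
            score_window(y, 100.0, 0.5, 2.0, prefiltered=True)

    def test_onset_must_lie_in_window(self):
        # deflection starts after the window closes: peak alone is not enough
        y = single_deflection_trace(100.0, 40.0, onset=20.0, amplitude=0.5,
                                    rise_time=1.5)
        assert score_window(y, 100.0, 5.0, 12.0, prefiltered=True) == 0.0
        assert score_window(y, 100.0, 15.0, 22.0, prefiltered=True) > 0.4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exhaustive_oracle_equivalence(self, seed):
        """Vectorized scorer equals the scalar all-pairs search on short traces."""
        rng = np.random.default_rng(seed)
        fs = 100.0
        y = np.full(1500, 2.0)
        # a few random deflections, some sub-threshold
        for _ in range(4):
            onset = rng.uniform(1.0, 11.0)
            amp = rng.uniform(0.003, 0.8)
            rise = rng.uniform(0.2, 2.0)
            d = single_deflection_trace(fs, 15.0, onset, amp, rise) - 2.0
            y += d
        y += rng.normal(0, 0.02, size=y.size)
        y = lowpass_filter(y, fs, 10.0)
        p = ScoringParams()
        got = score_window(y, fs, 1.0, 8.5, p, prefiltered=True)
        assert got == pytest.approx(brute_force_score(y, fs, 1.0, 8.5, p), abs=1e-12)

    def test_monotone_in_added_deflection(self):
        """Superposing a larger qualifying deflection never lowers the score."""
        fs = 100.0
        base = single_deflection_trace(fs, 30.0, 10.0, 0.2, 1.5)
        s0 = score_window(base, fs, 9.0, 16.5, prefiltered=True)
        bigger = base + (single_deflection_trace(fs, 30.0, 12.5, 0.7, 1.5) - 2.0)
        s1 = score_window(bigger, fs, 9.0, 16.5, prefiltered=True)
        assert s1 >= s0


@pytest.fixture(scope="module")
def clean_participant(design_a=None):
    from fearcon.paradigm import build_experiment

    design = build_experiment("A", seed=7)
    params = SCRGenParams(noise_sd=0, amp_noise_sd=0, nonresponse_prob=0)
    return design, simulate_participant(design, params, seed=0)


class TestScoreExperiment:
    def test_score_count_contract(self, clean_participant):
        design, traces = clean_participant
        df = score_experiment(traces[Phase.ACQUISITION], Phase.ACQUISITION)
        assert len(df) == 64
        assert (df["window"] == "CS").sum() == 32

    def test_ur_window_stimulus_classes(self, clean_participant):
        design, traces = clean_participant
        df = score_experiment(traces[Phase.ACQUISITION], Phase.ACQUISITION)
        ur = df[df["window"] == "UR"]
        assert set(ur["stim_class"]) == {"CS+/US", "CS+/no-US", "CS-"}
        # only reinforced trials carry a US response in this noise-free trace
        assert (ur[ur["stim_class"] == "CS+/US"]["amplitude"] > 0.5).all()
        assert (ur[ur["stim_class"] == "CS-"]["amplitude"] == 0).all()

    def test_us_response_does_not_leak_into_cs_window(self, clean_participant):
        """A US response at CS onset + 7.9 s scores in the UR window only."""
        design, _ = clean_participant
        params = SCRGenParams(gain_expectancy=0, gain_orienting=0,
                              noise_sd=0, amp_noise_sd=0, nonresponse_prob=0)
        traces = simulate_participant(design, params, seed=0)
        df = score_experiment(traces[Phase.ACQUISITION], Phase.ACQUISITION)
        reinforced = df[df["reinforced"]]
        assert (reinforced[reinforced["window"] == "UR"]["amplitude"] > 0.5).all()
        assert (reinforced[reinforced["window"] == "CS"]["amplitude"] == 0).all()

    def test_all_zero_trace_scores_all_zero(self, clean_participant):
        design, traces = clean_participant
        ref = traces[Phase.RECALL]
        flat = dataclasses.replace(ref, samples=np.full_like(ref.samples, 2.0))
        df = score_experiment(flat, Phase.RECALL)
        assert len(df) == 48
        assert (df["amplitude"] == 0).all()

    def test_truncated_trace_raises_with_indices(self, clean_participant):
        design, traces = clean_participant
        ref = traces[Phase.RECALL]
        cut = dataclasses.replace(ref, samples=ref.samples[: ref.samples.size // 2])
        with pytest.raises(ValueError, match="trials"):
            score_experiment(cut, Phase.RECALL)


def _toy_scores(amplitudes_by_trial, phase=Phase.ACQUISITION, pid="p0"):
    rows = []
    for cs, amps in amplitudes_by_trial.items():
        for k, a in enumerate(amps, start=1):
            rows.append({"participant": pid, "phase": phase.value,
                         "index_in_phase": k, "cs_type": cs, "reinforced": False,
                         "window": "CS", "stim_class": cs, "amplitude": a})
    return pd.DataFrame(rows)


class TestBlockAverage:
    def test_cell_value_is_log1p_of_mean(self):
        scores = _toy_scores({
            "CS+": [0.1, 0.3] * 8,
            "CS-": [0.0] * 16,
        })
        out = block_average(scores, Phase.ACQUISITION)
        early_csp = out[(out["block"] == "early") & (out["cs_type"] == "CS+")]
        assert early_csp["mean_log_scr"].iloc[0] == pytest.approx(np.log(1.2))

    def test_early_block_is_first_eight_by_presentation_order(self):
        amps = list(np.linspace(1.0, 0.0, 16))
        scores = _toy_scores({"CS+": amps, "CS-": [0.0] * 16})
        out = block_average(scores, Phase.ACQUISITION)
        early = out[(out["block"] == "early") & (out["cs_type"] == "CS+")]
        assert early["mean_raw_scr"].iloc[0] == pytest.approx(np.mean(amps[:8]))

    def test_recall_blocks_of_six(self):
        scores = _toy_scores({"CS+": [0.2] * 12, "CS-": [0.1] * 12}, Phase.RECALL)
        out = block_average(scores, Phase.RECALL)
        assert set(out["block"]) == {"early", "late"}
        diff = out[out["cs_type"] == "CS+"]["scr_diff"].iloc[0]
        assert diff == pytest.approx(np.log1p(0.2) - np.log1p(0.1))

    def test_all_zero_amplitudes_give_zero_cells(self):
        scores = _toy_scores({"CS+": [0.0] * 16, "CS-": [0.0] * 16})
        out = block_average(scores, Phase.ACQUISITION)
        assert (out["mean_log_scr"] == 0).all()
        assert (out["scr_diff"] == 0).all()

    def test_wrong_trial_count_raises(self):
        scores = _toy_scores({"CS+": [0.1] * 15, "CS-": [0.0] * 16})
        with pytest.raises(ValueError):
            block_average(scores, Phase.ACQUISITION)

    def test_log_transform_preserves_block_ranking(self):
        rng = np.random.default_rng(0)
        amps = {"CS+": list(rng.uniform(0, 1, 16)), "CS-": list(rng.uniform(0, 1, 16))}
        out = block_average(_toy_scores(amps), Phase.ACQUISITION)
        raw_rank = out["mean_raw_scr"].rank().to_list()
        log_rank = out["mean_log_scr"].rank().to_list()
        assert raw_rank == log_rank
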