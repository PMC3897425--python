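"""Self-test, parallelism test, decision table and end-to-end calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pscc.calling import (
    CnvCall,
    call_cnvs,
    classify,
    parallelism_test,
    report_sample_quality,
    self_test,
    TestResult,
    _copy_number,
)
from pscc.correction import ControlPanel, RcrTrack, build_panel, gc_correct, normalize
from pscc.simulator import sample_counts, spike_case, make_truth, TruthSet, Event

from conftest import make_windows


# ---------------------------------------------------------------------------
# self-test (ST)
# ---------------------------------------------------------------------------

def test_self_test_identical_distributions_not_significant():
    assert self_test(np.full(20, 1.0), np.full(500, 1.0)) == 1.0


def test_self_test_strong_shift_is_significant():
    rng = np.random.default_rng(0)
    seg = rng.normal(0.5, 0.08, 50)
    bg = rng.normal(1.0, 0.08, 10_000)
    assert self_test(seg, bg) < 1e-3


def test_three_window_segment_cannot_reach_alpha():
    # with n1 = 3 the U statistic cannot produce p <= 0.001 even under
    # complete separation: the resolution floor of the self-test
    rng = np.random.default_rng(1)
    bg = rng.normal(1.0, 0.08, 10_000)
    seg = np.full(3, 1.0 + 0.1 * 0.08)
    assert self_test(seg, bg) > 1e-3
    assert self_test(np.full(3, 50.0), bg) > 1e-3


def test_self_test_whole_genome_segment_warns_and_returns_one():
    with pytest.warns(UserWarning):
        assert self_test(np.ones(10), np.empty(0)) == 1.0


# ---------------------------------------------------------------------------
# parallelism test (PT)
# ---------------------------------------------------------------------------

def test_pt_null_center_gives_zero_stat():
    z, p = parallelism_test(1.0, np.full(50, 0.08))
    assert z == 0.0
    assert p == 1.0


def test_pt_z_matches_hand_computed_se():
    # SE = sqrt(100 * 0.08^2) / 100 = 0.008 -> z = -0.5 / 0.008 = -62.5
    z, p = parallelism_test(0.5, np.full(100, 0.08))
    assert z == pytest.approx(-62.5, rel=1e-12)
    assert p < 1e-300


def test_pt_unstable_region_weakens_significance():
    # tandem-repeat-like sigma/mu = 0.6 over 25 windows:
    # SE = sqrt(25*0.36)/25 = 0.12 -> z = -4.1667 (still beyond |z|=3.29,
    # but 5x weaker than the stable-region z above)
    z, p = parallelism_test(0.5, np.full(25, 0.6))
    assert z == pytest.approx(-0.5 / 0.12, rel=1e-12)
    z_stable, _ = parallelism_test(0.5, np.full(25, 0.08))
    assert abs(z) < abs(z_stable) / 5


def test_pt_drops_undefined_windows_with_warning():
    rel = np.array([0.1, np.nan, 0.1, 0.1])
    with pytest.warns(UserWarning):
        z, p = parallelism_test(0.8, rel)
    se = np.sqrt(3 * 0.01) / 3
    assert z == pytest.approx(-0.2 / se, rel=1e-12)
    with pytest.warns(UserWarning):
        assert parallelism_test(0.5, np.array([np.nan]))[1] == 1.0


# ---------------------------------------------------------------------------
# decision table
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "st_p,pt_p,expected",
    [
        (0.5, 0.5, "normal"),
        (1e-6, 1e-6, "cnv"),
        (1e-6, 0.2, "unstable_region"),
        (0.2, 1e-6, "sample_quality"),
        (0.001, 0.001, "cnv"),  # significance is inclusive at alpha
    ],
)
def test_four_situation_decision_table(st_p, pt_p, expected):
    assert classify(st_p, pt_p) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.floats(0, 1), st.floats(0, 1))
def test_classify_is_exhaustive_and_consistent(st_p, pt_p):
    cat = classify(st_p, pt_p)
    table = {
        (True, True): "cnv",
        (True, False): "unstable_region",
        (False, True): "sample_quality",
        (False, False): "normal",
    }
    assert cat == table[(st_p <= 0.001, pt_p <= 0.001)]


# ---------------------------------------------------------------------------
# copy number and call emission
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mean,cn",
    [(0.5, 1), (1.5, 3), (0.02, 0), (1.24, 2), (1.25, 3), (2.6, 5), (0.0, 0)],
)
def test_copy_number_rounding(mean, cn):
    assert _copy_number(mean) == cn


def _toy_call_setup(values, usable=None, n=600):
    """RCR track + flat panel over uniform 1 kb windows."""
    windows = make_windows(n)
    if usable is None:
        usable = np.ones(n, bool)
    rcr = RcrTrack(sample="t", values=values, usable=usable)
    panel = ControlPanel(
        mu=np.full(n, 150.0),
        sigma=np.full(n, 12.0),
        usable=np.ones(n, bool),
        n_controls=10,
        target_median=150.0,
    )
    return rcr, panel, windows


def test_spiked_deletion_is_called_with_cn1():
    rng = np.random.default_rng(2)
    values = rng.normal(1.0, 0.08, 600)
    values[200:350] = rng.normal(0.5, 0.06, 150)
    rcr, panel, windows = _toy_call_setup(values)
    calls, results = call_cnvs(rcr, panel, windows)
    assert len(calls) == 1
    c = calls[0]
    assert (c.state, c.copy_number) == ("deletion", 1)
    assert abs(c.start - 200_000) <= 3_000 and abs(c.end - 350_000) <= 3_000


def test_min_size_filter_drops_small_calls():
    rng = np.random.default_rng(3)
    values = rng.normal(1.0, 0.08, 600)
    values[300:330] = 0.5  # 30 kb event at 1 kb windows
    rcr, panel, windows = _toy_call_setup(values)
    calls, _ = call_cnvs(rcr, panel, windows, min_size=100_000)
    assert calls == []
    calls, _ = call_cnvs(rcr, panel, windows, min_size=10_000)
    assert len(calls) == 1


def test_adjacent_same_state_calls_merge_across_unusable_gap():
    rng = np.random.default_rng(4)
    values = rng.normal(1.0, 0.08, 600)
    values[200:250] = rng.normal(0.42, 0.05, 50)
    values[258:310] = rng.normal(0.58, 0.05, 52)
    usable = np.ones(600, bool)
    usable[250:258] = False
    values[~usable] = np.nan
    rcr, panel, windows = _toy_call_setup(values, usable=usable)
    calls, _ = call_cnvs(rcr, panel, windows, min_size=10_000)
    dels = [c for c in calls if c.state == "deletion"]
    assert len(dels) == 1
    assert dels[0].start == 200_000 and dels[0].end >= 309_000


def test_tightening_alpha_never_adds_calls():
    rng = np.random.default_rng(5)
    values = rng.normal(1.0, 0.08, 600)
    values[100:160] -= 0.5
    values[400:460] += 0.5
    rcr, panel, windows = _toy_call_setup(values)
    counts = []
    for alpha in (1e-2, 1e-3, 1e-5, 1e-8):
        calls, _ = call_cnvs(rcr, panel, windows, alpha_st=alpha, alpha_pt=alpha, min_size=10_000)
        counts.append(len(calls))
    assert counts == sorted(counts, reverse=True)


def test_whole_chromosome_trisomy_called_as_cn3(small_experiment):
    cfg, windows, gc, bias, controls = small_experiment
    rng = np.random.default_rng(7)
    # chromosome 2 spans windows 1000..1999 -> spike CN 3 across all of it
    truth = TruthSet(
        events=[Event(chrom="sim2", start_win=1000, end_win=2000, cn=3)],
        window_bp=cfg.window_bp,
    )
    case = spike_case(cfg, gc, bias, truth, rng)
    panel = build_panel([gc_correct(t) for t in controls])
    rcr = normalize(gc_correct(case), panel)
    calls, _ = call_cnvs(rcr, panel, windows)
    assert len(calls) == 1
    c = calls[0]
    assert (c.chrom, c.state, c.copy_number) == ("sim2", "duplication", 3)
    assert c.n_windows >= 990


def test_diploid_sample_yields_no_calls(small_experiment):
    cfg, windows, gc, bias, controls = small_experiment
    panel = build_panel([gc_correct(t) for t in controls])
    rng = np.random.default_rng(8)
    for _ in range(3):
        case = sample_counts(cfg, gc, bias, rng, sample="null")
        rcr = normalize(gc_correct(case), panel)
        calls, _ = call_cnvs(rcr, panel, windows)
        assert calls == []


# ---------------------------------------------------------------------------
# sample-quality report
# ---------------------------------------------------------------------------

def _results(n, n_sq):
    out = [TestResult(0.5, 0.5, 0.0, "normal") for _ in range(n - n_sq)]
    out += [TestResult(0.5, 1e-5, 4.0, "sample_quality") for _ in range(n_sq)]
    return out


@pytest.mark.parametrize(
    "n,n_sq,flagged",
    [(100, 0, False), (100, 5, True), (100, 1, False)],  # boundary 1% strict
)
def test_sample_quality_flagging(n, n_sq, flagged):
    rep = report_sample_quality(_results(n, n_sq))
    assert rep["n_segments"] == n
    assert rep["n_sample_quality"] == n_sq
    assert rep["flagged"] is flagged
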