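"""Two-step bias correction: GC medians, control panel, RCR normalization."""

import numpy as np
import pytest

from pscc.correction import (
    build_panel,
    cv_profile,
    gc_correct,
    normalize,
)
from pscc.simulator import SimConfig, generate_panel, sample_counts
from pscc.windows import ReadCountTrack


def _track(counts, gc, sample="s"):
    counts = np.asarray(counts, dtype=float)
    return ReadCountTrack(
        sample=sample,
        counts=counts,
        gc=np.asarray(gc, dtype=float),
        usable=np.ones(len(counts), dtype=bool),
    )


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

def test_gc_correction_scales_by_bin_and_overall_median():
    # window 2 sits in a GC bin with median 80 while the sample-wide median
    # is 120 -> corrected = 100 * 120 / 80 = 150
    counts = [70, 80, 100] + [120] * 5
    gc = [0.30, 0.30, 0.30] + [0.45] * 5
    out = gc_correct(_track(counts, gc), min_bin_count=1)
    assert out.counts[2] == pytest.approx(150.0, rel=1e-12)


def test_gc_correction_is_identity_when_bin_matches_overall():
    counts = [100, 120, 140, 100, 120, 140]
    gc = [0.3, 0.3, 0.3, 0.5, 0.5, 0.5]  # both bin medians = overall = 120
    out = gc_correct(_track(counts, gc), min_bin_count=1)
    np.testing.assert_allclose(out.counts, counts, rtol=1e-12)


def test_gc_correction_noop_on_flat_poisson_counts():
    rng = np.random.default_rng(0)
    gc = rng.beta(28, 40, size=20_000)
    counts = rng.poisson(150.0, size=20_000)
    out = gc_correct(_track(counts, gc))
    ratio = out.counts[counts > 0] / counts[counts > 0]
    # bin medians fluctuate by ~ median sampling noise only
    assert np.abs(ratio - 1).max() < 0.1
    assert np.median(ratio) == pytest.approx(1.0, abs=0.02)


def test_gc_correction_marks_zero_median_bins_unusable():
    counts = [0, 0, 0, 120, 130, 110]
    gc = [0.2, 0.2, 0.2, 0.45, 0.45, 0.45]
    out = gc_correct(_track(counts, gc), min_bin_count=3)
    assert not out.usable[:3].any()
    assert out.usable[3:].all()


def test_gc_correction_rejects_empty_track():
    with pytest.raises(ValueError):
        gc_correct(_track([0, 0, 0], [0.4, 0.4, 0.4]))


@pytest.mark.parametrize("width", [0.0, 0.2, -0.01])
def test_gc_bin_width_validated(width):
    with pytest.raises(ValueError):
        gc_correct(_track([1, 2, 3], [0.4, 0.4, 0.4]), gc_bin_width=width)


# ---------------------------------------------------------------------------
# control panel
# ---------------------------------------------------------------------------

def test_panel_identical_controls_have_zero_sd():
    a = _track([150] * 9, [0.4] * 9, "a")
    b = _track([150] * 9, [0.4] * 9, "b")
    panel = build_panel([a, b])
    assert panel.mu[0] == pytest.approx(150.0, rel=1e-12)
    assert panel.sigma[0] == pytest.approx(0.0, abs=1e-12)


def test_panel_mean_and_unbiased_sd_of_two_values():
    # both tracks have overall median 150 so depth rescaling is a no-op;
    # window 0 holds (140, 160): mu = 150, ddof-1 SD = 10*sqrt(2)
    a = _track([140] + [150] * 8, [0.4] * 9, "a")
    b = _track([160] + [150] * 8, [0.4] * 9, "b")
    panel = build_panel([a, b])
    assert panel.mu[0] == pytest.approx(150.0, rel=1e-12)
    assert panel.sigma[0] == pytest.approx(14.142135623730951, rel=1e-12)


def test_panel_rescales_controls_at_different_depths():
    rng = np.random.default_rng(1)
    deep = _track(rng.poisson(300, 5000), np.full(5000, 0.4), "deep")
    shallow = _track(rng.poisson(150, 5000), np.full(5000, 0.4), "shallow")
    panel = build_panel([deep, shallow])
    # mu sits at the common target median, not between the two raw depths
    assert np.median(panel.mu) == pytest.approx(panel.target_median, rel=0.02)
    # relative SD reflects per-depth Poisson noise, far below the 2x gap
    rel = panel.relative_sd[panel.usable]
    assert np.mean(rel) < 0.2


def test_panel_sd_matches_poisson_noise():
    rng = np.random.default_rng(2)
    tracks = [
        _track(rng.poisson(150, 10_000), np.full(10_000, 0.4), f"c{i}")
        for i in range(90)
    ]
    panel = build_panel(tracks)
    assert np.mean(panel.sigma) == pytest.approx(np.sqrt(150), rel=0.05)


def test_panel_validates_inputs():
    a = _track([1, 2], [0.4, 0.4])
    with pytest.raises(ValueError):
        build_panel([a])
    with pytest.raises(ValueError):
        build_panel([a, _track([1, 2, 3], [0.4] * 3)])


def test_panel_mu_floor_flags_dead_windows():
    a = _track([150] * 9 + [0.1], [0.4] * 10, "a")
    b = _track([150] * 9 + [0.1], [0.4] * 10, "b")
    panel = build_panel([a, b])
    assert not panel.usable[9]
    assert panel.usable[:9].all()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "count,expected",
    [(150.0, 1.0), (225.0, 1.5), (75.0, 0.5)],
)
def test_rcr_ratio(count, expected):
    # median of the case track equals the panel target, so no rescaling
    case = _track([count] + [150.0] * 8, [0.4] * 9)
    controls = [_track([150.0] * 9, [0.4] * 9, f"c{i}") for i in range(2)]
    rcr = normalize(case, build_panel(controls))
    assert rcr.values[0] == pytest.approx(expected, rel=1e-12)


def test_self_normalization_identity():
    rng = np.random.default_rng(3)
    raw = _track(rng.poisson(150, 2000), rng.beta(28, 40, 2000))
    corr = gc_correct(raw)
    panel = build_panel([corr.copy_with(), corr.copy_with()])
    rcr = normalize(corr, panel)
    np.testing.assert_allclose(rcr.values[rcr.usable], 1.0, rtol=1e-9)


def test_diploid_sample_median_rcr_is_one(small_experiment):
    cfg, windows, gc, bias, controls = small_experiment
    rng = np.random.default_rng(99)
    case = sample_counts(cfg, gc, bias, rng, sample="case")
    panel = build_panel([gc_correct(t) for t in controls])
    rcr = normalize(gc_correct(case), panel)
    med = np.median(rcr.values[rcr.usable])
    assert 0.99 <= med <= 1.01


def test_normalize_rejects_mismatched_lengths():
    case = _track([150] * 5, [0.4] * 5)
    controls = [_track([150] * 9, [0.4] * 9, f"c{i}") for i in range(2)]
    with pytest.raises(ValueError):
        normalize(case, build_panel(controls))


# ---------------------------------------------------------------------------
# CV diagnostics
# ---------------------------------------------------------------------------

def test_cv_of_constant_track_is_zero():
    out = cv_profile(np.full(200, 5.0), np.full(200, 0.4))
    assert (out["cv"] == 0).all()


def test_cv_of_poisson_counts_matches_theory():
    rng = np.random.default_rng(4)
    counts = rng.poisson(150, 50_000).astype(float)
    gc = rng.uniform(0.35, 0.45, 50_000)
    out = cv_profile(counts, gc)
    big = out[out["n"] >= 500]
    assert np.mean(big["cv"]) == pytest.approx(1 / np.sqrt(150), rel=0.1)


def test_two_step_correction_reduces_cv_in_every_gc_bin():
    cfg = SimConfig(n_windows=16_000, n_chroms=4, n_controls=20, seed=5)
    rng = np.random.default_rng(5)
    _, gc, bias, controls = generate_panel(cfg, rng)
    case = sample_counts(cfg, gc, bias, rng, sample="case")
    panel = build_panel([gc_correct(t) for t in controls])
    rcr = normalize(gc_correct(case), panel)
    before = cv_profile(case.counts, gc, rcr.usable)
    after = cv_profile(rcr.values, gc, rcr.usable)
    merged = before.merge(after, on=["gc_low", "gc_high"], suffixes=("_raw", "_rcr"))
    merged = merged[merged["n_raw"] >= 200]
    assert len(merged) >= 5
    assert (merged["cv_rcr"] <= merged["cv_raw"]).all()


def test_correction_restores_unbiased_noise_floor():
    """Both injected biases removed: RCR CV within 15% of a bias-free run."""
    rng = np.random.default_rng(6)
    biased = SimConfig(n_windows=12_000, n_chroms=3, n_controls=20, seed=6)
    clean = SimConfig(
        n_windows=12_000, n_chroms=3, n_controls=20, seed=6,
        gc_bias=False, multiplex_sigma=0.0,
    )
    cvs = {}
    for name, cfg in (("biased", biased), ("clean", clean)):
        r = np.random.default_rng(6)
        _, gc, bias, controls = generate_panel(cfg, r)
        case = sample_counts(cfg, gc, bias, r, sample="case")
        panel = build_panel([gc_correct(t) for t in controls])
        rcr = normalize(gc_correct(case), panel)
        v = rcr.values[rcr.usable]
        cvs[name] = v.std() / v.mean()
    assert cvs["biased"] <= 1.15 * cvs["clean"]
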