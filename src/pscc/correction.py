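"""Two-step bias correction yielding the relative copy ratio (RCR) track.

Step 1 removes within-sample GC bias: each window's count is scaled by the
ratio of the sample's overall median count to the median count of windows
in the same GC bin,

    corrected_i = m_i * M_overall / M_gc(i).

Step 2 removes window-specific bias shared across samples (mappability,
genome structure, library chemistry — "multiplex-related" bias): a panel
of N control samples provides a per-window mean mu_i and standard
deviation sigma_i of GC-corrected counts, and the test sample's relative
copy ratio is

    r_i = corrected_i / mu_i,

with expectation 1 at diploid copy number.  sigma_i quantifies how
polymorphic/unstable each window is across the population and is consumed
later by the parallelism test.

Controls and cases may be sequenced at different depths, so every sample
is rescaled to a common overall median before panel statistics and
normalization (the rescaling constant cancels in r_i and in
sigma_i / mu_i, so its exact value is immaterial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import ReadCountTrack

GC_BIN_WIDTH = 0.01
MIN_BIN_COUNT = 50
MU_FLOOR_FRACTION = 0.1


@dataclass
class ControlPanel:
    """Per-window mean/SD of depth-rescaled, GC-corrected control counts."""

    mu: np.ndarray
    sigma: np.ndarray
    usable: np.ndarray
    n_controls: int
    target_median: float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if self.n_controls < 2:
            raise ValueError("a control panel needs at least 2 samples")

    @property
    def relative_sd(self) -> np.ndarray:
        """sigma_i / mu_i — the panel SD on the RCR scale."""
        out = np.full(len(self.mu), np.nan)
        ok = self.usable & (self.mu > 0)
        out[ok] = self.sigma[ok] / self.mu[ok]
        return out


@dataclass
class RcrTrack:
    """Per-window relative copy ratio for one test sample."""

    sample: str
    values: np.ndarray
    usable: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if len(self.values) != len(self.usable):
            raise ValueError("values/usable length mismatch")


def _gc_bins(gc: np.ndarray, width: float) -> np.ndarray:
    b = np.floor(np.clip(gc, 0.0, 1.0 - 1e-12) / width).astype(int)
    return b


def gc_correct(
    track: ReadCountTrack,
    gc_bin_width: float = GC_BIN_WIDTH,
    min_bin_count: int = MIN_BIN_COUNT,
) -> ReadCountTrack:
    """Per-GC-bin median scaling (default 1% GC bins).

    Bins holding fewer than ``min_bin_count`` usable windows borrow the
    median of the nearest populated bin; a populated bin whose median is 0
    cannot rescale its windows, which are marked unusable.
    """
    if not (0 < gc_bin_width <= 0.1):
        raise ValueError("gc_bin_width must be in (0, 0.1]")
    usable = track.usable & np.isfinite(track.gc)
    if not np.any(usable) or not np.any(track.counts[usable] > 0):
        raise ValueError("all-zero or all-unusable track cannot be GC-corrected")

    m = track.counts
    m_overall = float(np.median(m[usable]))
    bins = _gc_bins(track.gc, gc_bin_width)
    nbins = int(bins[usable].max()) + 1

    bin_median = np.full(nbins, np.nan)
    bin_count = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = usable & (bins == b)
        bin_count[b] = int(sel.sum())
        if bin_count[b] > 0:
            bin_median[b] = float(np.median(m[sel]))

    populated = np.nonzero(bin_count >= min_bin_count)[0]
    if len(populated) == 0:
        # no bin reaches the occupancy floor: fall back to the overall median
        m_gc_per_bin = np.full(nbins, m_overall)
    else:
        m_gc_per_bin = bin_median.copy()
        for b in range(nbins):
            if bin_count[b] < min_bin_count:
                nearest = populated[np.argmin(np.abs(populated - b))]
                m_gc_per_bin[b] = bin_median[nearest]

    m_gc = m_gc_per_bin[bins]
    corrected = np.zeros_like(m, dtype=float)
    new_usable = usable.copy()
    bad = usable & ~(m_gc > 0)
    new_usable[bad] = False
    ok = new_usable
    corrected[ok] = m[ok] * m_overall / m_gc[ok]
    return track.copy_with(counts=corrected, usable=new_usable)


def rescale_to_median(track: ReadCountTrack, target: float) -> ReadCountTrack:
    """Multiply counts so the usable-window median equals ``target``."""
    med = float(np.median(track.counts[track.usable]))
    if med <= 0:
        raise ValueError("cannot rescale a track with non-positive median")
    return track.copy_with(counts=track.counts * (target / med))


def build_panel(
    corrected_tracks: list[ReadCountTrack],
    mu_floor_fraction: float = MU_FLOOR_FRACTION,
) -> ControlPanel:
    """Panel mean/SD across controls after depth equalization.

    Each GC-corrected control is rescaled to a common overall median (the
    mean of the controls' medians) so controls sequenced at different
    depths are comparable; mu_i is the mean and sigma_i the ddof=1 SD of
    the rescaled counts.  Windows where mu_i falls below
    ``mu_floor_fraction`` times the panel median of mu are flagged
    unusable to avoid division blow-ups in barely-mappable regions.
    """
    if len(corrected_tracks) < 2:
        raise ValueError("need >= 2 control tracks")
    n = len(corrected_tracks[0].counts)
    for t in corrected_tracks[1:]:
        if len(t.counts) != n:
            raise ValueError("control tracks have mismatched window counts")

    usable = np.logical_and.reduce([t.usable for t in corrected_tracks])
    medians = [float(np.median(t.counts[t.usable])) for t in corrected_tracks]
    target = float(np.mean(medians))
    mat = np.vstack(
        [t.counts * (target / med) for t, med in zip(corrected_tracks, medians)]
    )
    mu = mat.mean(axis=0)
    sigma = mat.std(axis=0, ddof=1)

    floor = mu_floor_fraction * float(np.median(mu[usable]))
    usable = usable & (mu >= floor)
    return ControlPanel(
        mu=mu,
        sigma=sigma,
        usable=usable,
        n_controls=len(corrected_tracks),
        target_median=target,
    )


def normalize(corrected: ReadCountTrack, panel: ControlPanel) -> RcrTrack:
    """RCR = depth-rescaled corrected count / panel mean, per window."""
    if len(corrected.counts) != len(panel.mu):
        raise ValueError("track and panel have mismatched window counts")
    usable = corrected.usable & panel.usable
    med = float(np.median(corrected.counts[corrected.usable]))
    if med <= 0:
        raise ValueError("cannot normalize a track with non-positive median")
    scaled = corrected.counts * (panel.target_median / med)
    values = np.full(len(scaled), np.nan)
    if np.any(usable & ~(panel.mu > 0)):
        raise RuntimeError("panel mean is 0 on a usable window (floor failed)")
    values[usable] = scaled[usable] / panel.mu[usable]
    return RcrTrack(sample=corrected.sample, values=values, usable=usable)


def cv_profile(
    values: np.ndarray,
    gc: np.ndarray,
    usable: np.ndarray | None = None,
    gc_bin_width: float = GC_BIN_WIDTH,
) -> pd.DataFrame:
    """Coefficient of variation of a per-window statistic by GC bin.

    Diagnostic reproducing the before/after-correction CV comparison:
    rows are populated GC bins with columns ``gc_low, gc_high, n, mean,
    sd, cv``; empty bins are omitted.
    """
    values = np.asarray(values, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if usable is None:
        usable = np.isfinite(values) & np.isfinite(gc)
    else:
        usable = np.asarray(usable, bool) & np.isfinite(values) & np.isfinite(gc)
    bins = _gc_bins(gc, gc_bin_width)
    rows = []
    for b in np.unique(bins[usable]):
        v = values[usable & (bins == b)]
        if len(v) < 2:
            continue
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        rows.append(
            (
                b * gc_bin_width,
                (b + 1) * gc_bin_width,
                len(v),
                mean,
                sd,
                sd / mean if mean != 0 else np.inf,
            )
        )
    return pd.DataFrame(rows, columns=["gc_low", "gc_high", "n", "mean", "sd", "cv"])
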