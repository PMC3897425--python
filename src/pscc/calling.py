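"""Segment genotyping with combined self-test / parallelism-test.

Each segment is judged twice:

* self-test (ST): a two-sided Mann–Whitney U test of the segment's window
  RCRs against all other usable windows of the same sample — does this
  segment deviate from the sample's own baseline?
* parallelism test (PT): a z-test of the segment's mean RCR against 1,
  with the standard error implied by the control panel's per-window
  relative SDs, SE = sqrt(sum_i (sigma_i/mu_i)^2) / n — is the deviation
  larger than the window-to-window polymorphism seen across the normal
  population?  Segments in unstable regions (tandem repeats, structurally
  polymorphic loci) have large sigma_i and cannot reach PT significance,
  which is exactly the intended false-positive filter.

The 2x2 grid of (ST significant, PT significant) at alpha = 0.001 each
classifies every segment: both -> high-credibility CNV; ST only -> false
signal from sequence instability / shared bias; PT only -> suspect sample
quality (flag the sample if frequent); neither -> normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm

from .correction import ControlPanel, RcrTrack
from .segmentation import segment_genome

ALPHA_ST = 0.001
ALPHA_PT = 0.001
MIN_CALL_SIZE_BP = 100_000
SAMPLE_QUALITY_FRACTION = 0.01

CATEGORIES = ("normal", "cnv", "unstable_region", "sample_quality")


@dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    st_p: float
    pt_p: float
    pt_stat: float
    category: str


@dataclass
class CnvCall:
    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    n_windows: int
    mean_rcr: float
    state: str  # deletion | duplication
    copy_number: int
    st_p: float
    pt_p: float
    sample: str

    @property
    def size(self) -> int:
        return self.end - self.start


def self_test(segment_values: np.ndarray, background_values: np.ndarray) -> float:
    """Mann–Whitney U of segment windows vs the rest of the sample."""
    segment_values = np.asarray(segment_values, dtype=float)
    background_values = np.asarray(background_values, dtype=float)
    if len(background_values) == 0:
        warnings.warn("segment spans the whole genome; self-test is undefined", stacklevel=2)
        return 1.0
    pooled = np.concatenate([segment_values, background_values])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = mannwhitneyu(
        segment_values, background_values, alternative="two-sided", method="asymptotic"
    )
    return float(res.pvalue)


def parallelism_test(
    segment_mean: float, relative_sd: np.ndarray
) -> tuple[float, float]:
    """z-score of the segment mean against the panel-implied SE.

    ``relative_sd`` holds sigma_i / mu_i for the segment's windows;
    non-finite entries are dropped with a warning (all dropped -> p = 1).
    Returns (z, two-sided p).
    """
    rel = np.asarray(relative_sd, dtype=float)
    ok = np.isfinite(rel)
    if not np.all(ok):
        warnings.warn("dropping windows with undefined panel SD from PT", stacklevel=2)
        rel = rel[ok]
    n = len(rel)
    if n == 0:
        return 0.0, 1.0
    se = float(np.sqrt(np.sum(rel**2)) / n)
    if se == 0:
        return (0.0, 1.0) if segment_mean == 1.0 else (np.inf * np.sign(segment_mean - 1.0), 0.0)
    z = (segment_mean - 1.0) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def classify(
    st_p: float,
    pt_p: float,
    alpha_st: float = ALPHA_ST,
    alpha_pt: float = ALPHA_PT,
) -> str:
    """Four-situation decision table over (ST, PT) significance."""
    st_sig = st_p <= alpha_st
    pt_sig = pt_p <= alpha_pt
    if st_sig and pt_sig:
        return "cnv"
    if st_sig:
        return "unstable_region"
    if pt_sig:
        return "sample_quality"
    return "normal"


def _copy_number(mean_rcr: float) -> int:
    # round-half-up keeps 2*1.25 -> 3 and avoids banker's rounding surprises
    return max(0, int(np.floor(2.0 * mean_rcr + 0.5)))


def call_cnvs(
    rcr: RcrTrack,
    panel: ControlPanel,
    windows: pd.DataFrame,
    alpha_st: float = ALPHA_ST,
    alpha_pt: float = ALPHA_PT,
    min_size: int = MIN_CALL_SIZE_BP,
    **segment_kwargs,
) -> tuple[list[CnvCall], list[TestResult]]:
    """End-to-end segment -> test -> classify for one sample.

    Returns the CNV calls and the per-segment test results for
    sample-quality reporting.  A call requires category ``cnv``, an
    integer copy-number state different from 2 (a segment whose mean RCR
    rounds back to the diploid state is statistically significant noise,
    not a CNV), and size >= ``min_size`` bp; adjacent same-state calls
    separated only by unusable windows are merged.
    """
    chroms = windows["chrom"].to_numpy()
    segs = segment_genome(rcr.values, rcr.usable, chroms, **segment_kwargs)

    rel_sd = panel.relative_sd
    values = rcr.values
    usable = rcr.usable
    usable_idx = np.nonzero(usable)[0]
    all_vals = values[usable_idx]

    results: list[TestResult] = []
    raw_calls: list[CnvCall] = []
    for row in segs.itertuples(index=False):
        in_seg = (usable_idx >= row.first_win) & (usable_idx <= row.last_win)
        seg_vals = all_vals[in_seg]
        bg_vals = all_vals[~in_seg]
        st_p = self_test(seg_vals, bg_vals)
        seg_rel = rel_sd[usable_idx[in_seg]]
        pt_z, pt_p = parallelism_test(float(row.mean_rcr), seg_rel)
        cat = classify(st_p, pt_p, alpha_st, alpha_pt)
        results.append(TestResult(st_p=st_p, pt_p=pt_p, pt_stat=pt_z, category=cat))
        if cat != "cnv" or _copy_number(float(row.mean_rcr)) == 2:
            continue
        raw_calls.append(
            CnvCall(
                chrom=str(row.chrom),
                start=int(windows["start"].iloc[row.first_win]),
                end=int(windows["end"].iloc[row.last_win]),
                n_windows=int(row.n_windows),
                mean_rcr=float(row.mean_rcr),
                state="deletion" if row.mean_rcr < 1.0 else "duplication",
                copy_number=_copy_number(float(row.mean_rcr)),
                st_p=st_p,
                pt_p=pt_p,
                sample=rcr.sample,
            )
        )

    merged = _merge_adjacent(raw_calls, windows, usable)
    calls = [c for c in merged if c.size >= min_size]
    return calls, results


def _merge_adjacent(
    calls: list[CnvCall], windows: pd.DataFrame, usable: np.ndarray
) -> list[CnvCall]:
    """Merge same-state neighbors separated only by unusable windows."""
    if not calls:
        return []
    calls = sorted(calls, key=lambda c: (c.chrom, c.start))
    start_bp = windows["start"].to_numpy()
    end_bp = windows["end"].to_numpy()
    chrom_arr = windows["chrom"].to_numpy()
    out = [calls[0]]
    for c in calls[1:]:
        prev = out[-1]
        if c.chrom == prev.chrom and c.state == prev.state:
            between = (
                (chrom_arr == c.chrom) & (start_bp >= prev.end) & (end_bp <= c.start)
            )
            if not np.any(between & usable):
                n = prev.n_windows + c.n_windows
                mean = (
                    prev.mean_rcr * prev.n_windows + c.mean_rcr * c.n_windows
                ) / n
                out[-1] = CnvCall(
                    chrom=prev.chrom,
                    start=prev.start,
                    end=c.end,
                    n_windows=n,
                    mean_rcr=mean,
                    state=prev.state,
                    copy_number=_copy_number(mean),
                    st_p=min(prev.st_p, c.st_p),
                    pt_p=min(prev.pt_p, c.pt_p),
                    sample=prev.sample,
                )
                continue
        out.append(c)
    return out


def report_sample_quality(
    results: list[TestResult], threshold: float = SAMPLE_QUALITY_FRACTION
) -> dict:
    """Flag a sample when sample_quality segments are unusually frequent.

    The flag is raised on strict inequality (fraction > threshold), so a
    sample sitting exactly at the threshold is not flagged.
    """
    n = len(results)
    n_sq = sum(1 for r in results if r.category == "sample_quality")
    frac = n_sq / n if n else 0.0
    return {
        "n_segments": n,
        "n_sample_quality": n_sq,
        "fraction": frac,
        "flagged": frac > threshold,
    }
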