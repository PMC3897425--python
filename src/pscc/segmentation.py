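"""Binary segmentation of the RCR track via Wald–Wolfowitz runs tests.

Candidate breakpoints are found by scanning every interior window and
comparing the ``block`` windows on each side with a two-sample runs test:
pool the two blocks, sort, label each value by block of origin, and count
runs R of consecutive same-label values.  Under exchangeability R has the
classical null distribution with mean 1 + 2*n1*n2/(n1+n2); a location
shift between the blocks drags values of one block to one end of the
sorted order and makes R small, so the test is lower-tail on R (perfectly
interleaved blocks, R maximal, are no evidence of a copy-number step).
The exact null pmf is used for small pooled sizes and the normal
approximation beyond that.

Local minima of the p-value curve below ``p_enter`` become ordered
candidates; an iterative pruning pass then re-tests every surviving
candidate against its full flanking segments (capped at ``max_flank``
windows) and repeatedly deletes the least significant candidate until all
survivors clear the genome-wide threshold (Bonferroni 0.05 over tested
positions by default).  Segmentation is deterministic: ties in value are
resolved by an alternating label rule and ties in p during pruning by
removing the higher window index first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

BLOCK = 10
# With block 10 the exact runs pmf is strongly quantized (achievable p jump
# from 4.5e-3 straight to 1.9e-2), so a 0.01 entry threshold would demand
# R <= 5 and silently drop real but noisy step edges; 0.05 admits R <= 7 and
# leaves the genome-wide decision to the Bonferroni pruning threshold.
P_ENTER = 0.05
MAX_FLANK = 200
MIN_SEGMENT_WINDOWS = 3
MIN_BLOCK = 5
_EXACT_MAX_N = 128  # pooled size up to which the exact runs pmf is used


@dataclass
class Breakpoint:
    """Window index b where a new segment starts, with its current p-value."""

    index: int
    p_value: float
    state: str = "candidate"  # candidate | pruned | final


@dataclass
class Segment:
    """Inclusive usable-window index range [start, end] with its mean RCR."""

    chrom: str
    start: int
    end: int
    mean_rcr: float

    @property
    def n_windows(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Runs-test machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def runs_pmf(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of the two-sample runs count R.

    Returns (support, probabilities) for R in [2, n1+n2] under random
    arrangement of n1+n2 exchangeable values.
    """
    n = n1 + n2
    denom = math.comb(n, n1)
    rs, ps = [], []
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            num = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            num = math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k) + math.comb(
                n1 - 1, k
            ) * math.comb(n2 - 1, k - 1)
        if num:
            rs.append(r)
            ps.append(num / denom)
    return np.asarray(rs), np.asarray(ps)


def runs_p_value(r: int, n1: int, n2: int) -> float:
    """Lower-tail p-value P(R <= r) for the runs count."""
    if n1 + n2 <= _EXACT_MAX_N:
        rs, ps = runs_pmf(n1, n2)
        return float(min(1.0, ps[rs <= r].sum()))
    mean = 1 + 2 * n1 * n2 / (n1 + n2)
    var = (
        2 * n1 * n2 * (2 * n1 * n2 - n1 - n2)
        / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    )
    # continuity-corrected lower tail
    z = (r - mean + 0.5) / math.sqrt(var)
    return float(norm.cdf(z))


def _ordered_labels(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Block-of-origin labels in sorted order, ties resolved alternately.

    Within a group of tied values the labels are laid out alternately,
    starting with the block holding more members of the group (left on a
    tie), which makes the statistic deterministic and conservative for
    tied data.
    """
    x = np.concatenate([left, right])
    lab = np.concatenate(
        [np.zeros(len(left), dtype=np.int8), np.ones(len(right), dtype=np.int8)]
    )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ls = lab[order]
    i = 0
    while i < len(xs):
        j = i
        while j + 1 < len(xs) and xs[j + 1] == xs[i]:
            j += 1
        if j > i:
            seg = ls[i : j + 1]
            n0 = int((seg == 0).sum())
            n1 = len(seg) - n0
            first = 0 if n0 >= n1 else 1
            out = np.empty(len(seg), dtype=np.int8)
            a, b = (n0, n1) if first == 0 else (n1, n0)
            k = 0
            cur = first
            while a > 0 or b > 0:
                if a > 0:
                    out[k] = cur
                    a -= 1
                    k += 1
                if b > 0:
                    out[k] = 1 - cur
                    b -= 1
                    k += 1
            ls[i : j + 1] = out
        i = j + 1
    return ls


def runs_count(left, right) -> int:
    ls = _ordered_labels(np.asarray(left, float), np.asarray(right, float))
    return 1 + int(np.count_nonzero(np.diff(ls)))


def runs_test(left, right, min_block: int = MIN_BLOCK) -> float:
    """Two-sample Wald–Wolfowitz runs test p-value (lower tail on R)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if len(left) < min_block or len(right) < min_block:
        return 1.0
    pooled = np.concatenate([left, right])
    if np.all(pooled == pooled[0]):
        return 1.0
    r = runs_count(left, right)
    return runs_p_value(r, len(left), len(right))


def _sliding_p(values: np.ndarray, block: int) -> np.ndarray:
    """p-value of block-vs-block runs tests at every interior boundary.

    Entry k corresponds to boundary b = k + block (the segment starting at
    b).  Continuous data is assumed in the vectorized path; rows with tied
    values are recomputed with the scalar tie-aware test.
    """
    n = len(values)
    if n < 2 * block:
        return np.empty(0)
    w = sliding_window_view(values, 2 * block)  # rows = boundaries
    order = np.argsort(w, axis=1, kind="stable")
    lab = order >= block
    runs = 1 + np.count_nonzero(np.diff(lab, axis=1), axis=1)
    rs, ps = runs_pmf(block, block)
    cdf = np.cumsum(ps)
    table = np.ones(2 * block + 1)
    table[rs] = np.minimum(1.0, cdf)
    p = table[runs]
    sorted_vals = np.take_along_axis(w, order, axis=1)
    tie_rows = np.nonzero((np.diff(sorted_vals, axis=1) == 0).any(axis=1))[0]
    for k in tie_rows:
        p[k] = runs_test(w[k, :block], w[k, block:])
    return p


def _thin_candidates(cands: list[Breakpoint], min_gap: int) -> list[Breakpoint]:
    """Collapse candidate clusters closer than ``min_gap`` windows.

    Two true edges cannot sit closer than the runs test can resolve, and
    candidates separated by fewer than ``min_gap`` windows give each other
    degenerate (sentinel p = 1) flanks during pruning; within each chain
    of near-adjacent candidates only the most significant one (ties: the
    leftmost) is kept.
    """
    out: list[Breakpoint] = []
    for c in sorted(cands, key=lambda c: c.index):
        if out and c.index - out[-1].index < min_gap:
            if c.p_value < out[-1].p_value:
                out[-1] = c
        else:
            out.append(c)
    return out


def initial_breakpoints(
    values: np.ndarray, block: int = BLOCK, p_enter: float = P_ENTER
) -> list[Breakpoint]:
    """Candidate breakpoints: local minima of the sliding p-curve <= p_enter.

    Clusters of candidates closer than the minimum testable block are
    thinned to their strongest member before pruning.
    """
    if block < MIN_BLOCK:
        raise ValueError(f"block must be >= {MIN_BLOCK}")
    values = np.asarray(values, dtype=float)
    p = _sliding_p(values, block)
    cands = []
    for k in range(len(p)):
        if p[k] > p_enter:
            continue
        prev = p[k - 1] if k > 0 else np.inf
        nxt = p[k + 1] if k + 1 < len(p) else np.inf
        if p[k] < prev and p[k] <= nxt:  # leftmost point of a plateau
            cands.append(Breakpoint(index=k + block, p_value=float(p[k])))
    return _thin_candidates(cands, MIN_BLOCK)


def n_tested_positions(n_usable: int, block: int = BLOCK) -> int:
    return max(0, n_usable - 2 * block + 1)


def _flank_p(
    positions: list[int], k: int, values: np.ndarray, max_flank: int
) -> float:
    """Runs-test p for breakpoint k using full inter-breakpoint flanks."""
    b = positions[k]
    lo = positions[k - 1] if k > 0 else 0
    hi = positions[k + 1] if k + 1 < len(positions) else len(values)
    left = values[max(lo, b - max_flank) : b]
    right = values[b : min(hi, b + max_flank)]
    return runs_test(left, right)


def prune_breakpoints(
    candidates: list[Breakpoint],
    values: np.ndarray,
    p_genome: float,
    max_flank: int = MAX_FLANK,
) -> list[Breakpoint]:
    """Iteratively delete the least significant breakpoint until all clear.

    Each surviving breakpoint's p-value is computed against its full
    flanking segments (previous to next survivor, capped at ``max_flank``
    windows per side); the breakpoint with the largest p-value is removed
    if it exceeds ``p_genome`` (ties: highest index first) and its
    neighbors' p-values are refreshed.  An empty survivor set is valid.
    """
    values = np.asarray(values, dtype=float)
    positions = sorted(c.index for c in candidates)
    ps = [ _flank_p(positions, k, values, max_flank) for k in range(len(positions)) ]
    while positions:
        worst = max(range(len(positions)), key=lambda k: (ps[k], positions[k]))
        if ps[worst] <= p_genome:
            break
        del positions[worst], ps[worst]
        for k in (worst - 1, worst):
            if 0 <= k < len(positions):
                ps[k] = _flank_p(positions, k, values, max_flank)
    return [Breakpoint(index=b, p_value=p, state="final") for b, p in zip(positions, ps)]


def segments_from_breakpoints(
    final: list[Breakpoint],
    values: np.ndarray,
    chrom: str = "",
    min_windows: int = MIN_SEGMENT_WINDOWS,
) -> list[Segment]:
    """Partition [0, n) at the final breakpoints; absorb short slivers.

    Segments with fewer than ``min_windows`` windows are merged into the
    neighbor whose mean RCR is closer, repeatedly, so the returned
    segments always partition the chromosome's usable windows.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    bounds = [0] + sorted(b.index for b in final) + [n]
    segs = [
        Segment(chrom, a, b - 1, float(values[a:b].mean()))
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, s in enumerate(segs):
            if s.n_windows >= min_windows:
                continue
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i + 1 < len(segs) else None
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                target = (
                    left
                    if abs(left.mean_rcr - s.mean_rcr)
                    <= abs(right.mean_rcr - s.mean_rcr)
                    else right
                )
            a = min(target.start, s.start)
            b = max(target.end, s.end)
            merged = Segment(chrom, a, b, float(values[a : b + 1].mean()))
            j = segs.index(target)
            segs[min(i, j)] = merged
            del segs[max(i, j)]
            changed = True
            break
    return segs


def segment_genome(
    rcr_values: np.ndarray,
    usable: np.ndarray,
    chroms: np.ndarray,
    block: int = BLOCK,
    p_enter: float = P_ENTER,
    p_genome: float | None = None,
    max_flank: int = MAX_FLANK,
    min_windows: int = MIN_SEGMENT_WINDOWS,
) -> pd.DataFrame:
    """Segment every chromosome of an RCR track.

    Operates in usable-window index space per chromosome and maps results
    back to global window indices.  Returns a DataFrame with columns
    ``chrom, first_win, last_win`` (global indices, inclusive),
    ``n_windows`` (usable windows in the segment) and ``mean_rcr``.
    If ``p_genome`` is None it defaults to Bonferroni 0.05 over the total
    number of tested positions genome-wide.
    """
    rcr_values = np.asarray(rcr_values, dtype=float)
    usable = np.asarray(usable, dtype=bool)
    chroms = np.asarray(chroms)

    chrom_names = pd.unique(chroms)
    per_chrom = []
    total_tested = 0
    for c in chrom_names:
        idx = np.nonzero(usable & (chroms == c))[0]
        per_chrom.append((c, idx, rcr_values[idx]))
        total_tested += n_tested_positions(len(idx), block)
    if p_genome is None:
        p_genome = 0.05 / max(1, total_tested)

    rows = []
    for c, idx, vals in per_chrom:
        if len(idx) == 0:
            continue
        if len(vals) >= 2 * block:
            cands = initial_breakpoints(vals, block=block, p_enter=p_enter)
            finals = prune_breakpoints(cands, vals, p_genome, max_flank=max_flank)
        else:
            finals = []
        for seg in segments_from_breakpoints(finals, vals, chrom=str(c), min_windows=min_windows):
            rows.append(
                (
                    str(c),
                    int(idx[seg.start]),
                    int(idx[seg.end]),
                    seg.n_windows,
                    seg.mean_rcr,
                )
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "first_win", "last_win", "n_windows", "mean_rcr"]
    )
    df.attrs["p_genome"] = float(p_genome)
    df.attrs["n_tested_positions"] = int(total_tested)
    return df
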