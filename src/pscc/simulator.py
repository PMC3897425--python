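"""Window-level synthetic data and the in-silico power study.

The generator emulates the count statistics the caller sees after
alignment and window counting, directly at window level:

* every window has expected RC ``expected_rc`` (default 150) regardless of
  depth, because windows are rebuilt per depth at constant expected RC —
  the window bp-width is ``expected_rc * read_length / depth``, so depth
  changes how many windows a CNV of a given bp size spans, not the
  per-window expectation;
* per-window GC drawn from a Beta distribution matched to the human
  genome's GC composition, with a unimodal multiplicative GC-rate curve
  suppressing GC-poor (<35%) and GC-rich (>50%) windows;
* a per-window lognormal multiplicative bias shared by every sample of an
  experiment (the "multiplex-related" bias: mappability and genome
  structure affect all libraries alike);
* counts drawn Poisson with a mild gamma over-dispersion (20% CV
  inflation over the Poisson floor) as a conservative stand-in for
  real-library noise;
* spiked CNVs multiply the rate by CN/2 over their window span.

``power_cell``/``power_study`` run the full pipeline (two-step correction,
segmentation, combined tests) on spiked cases against a synthetic control
panel and score detection at call level by reciprocal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calling import call_cnvs, CnvCall
from .correction import build_panel, gc_correct, normalize
from .windows import ReadCountTrack

DEFAULT_N_CONTROLS = 90
DEFAULT_READ_LENGTH = 36
EVENT_MARGIN_WINDOWS = 15


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    n_windows: int = 45_000
    n_chroms: int = 10
    expected_rc: float = 150.0
    depth: float = 2.0  # coverage relative to 1x; rescales window width only
    read_length: int = DEFAULT_READ_LENGTH
    gc_beta: tuple[float, float] = (28.0, 40.0)  # mean ~0.41, SD ~0.06
    gc_bias: bool = True
    gc_bias_floor: float = 0.3
    gc_bias_center: float = 0.425
    gc_bias_width: float = 0.08
    multiplex_sigma: float = 0.1  # lognormal sigma of the shared window bias
    overdispersion: float = 1.2  # CV inflation over the Poisson floor
    n_controls: int = DEFAULT_N_CONTROLS
    seed: int = 0

    def __post_init__(self):
        if self.expected_rc <= 0 or self.depth <= 0:
            raise ValueError("rates must be positive")
        if self.n_chroms < 1 or self.n_windows < self.n_chroms:
            raise ValueError("need at least one window per chromosome")

    @property
    def window_bp(self) -> int:
        return max(1, int(round(self.expected_rc * self.read_length / self.depth)))

    def gc_curve(self, gc: np.ndarray) -> np.ndarray:
        """Multiplicative GC-rate curve g(GC), max 1, unimodal."""
        if not self.gc_bias:
            return np.ones_like(gc)
        f = self.gc_bias_floor
        return f + (1.0 - f) * np.exp(
            -(((np.asarray(gc) - self.gc_bias_center) / self.gc_bias_width) ** 2)
        )


@dataclass
class Event:
    """One spiked CNV on the window grid ([start_win, end_win) half-open)."""

    chrom: str
    start_win: int
    end_win: int
    cn: int  # 1 (het deletion) or 3 (het duplication) by default

    @property
    def type(self) -> str:
        return "deletion" if self.cn < 2 else "duplication"

    def n_windows(self) -> int:
        return self.end_win - self.start_win


@dataclass
class TruthSet:
    events: list[Event]
    window_bp: int

    def __post_init__(self):
        by_chrom: dict[str, list[Event]] = {}
        for e in self.events:
            by_chrom.setdefault(e.chrom, []).append(e)
        for evs in by_chrom.values():
            evs = sorted(evs, key=lambda e: e.start_win)
            for a, b in zip(evs[:-1], evs[1:]):
                if b.start_win < a.end_win:
                    raise ValueError("overlapping spiked events")


def simulate_genome(cfg: SimConfig, rng: np.random.Generator):
    """Windows table + per-window GC and shared multiplex bias.

    The same (windows, gc, bias) triple must be reused for every control
    and case of one experiment — the shared-bias contract.
    """
    per = cfg.n_windows // cfg.n_chroms
    sizes = [per] * cfg.n_chroms
    sizes[-1] += cfg.n_windows - per * cfg.n_chroms
    rows = []
    for c, sz in enumerate(sizes):
        starts = np.arange(sz, dtype=np.int64) * cfg.window_bp
        for s in starts:
            rows.append((f"sim{c + 1}", int(s), int(s + cfg.window_bp)))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    windows["n_sim"] = 0
    windows["partial"] = False
    gc = rng.beta(cfg.gc_beta[0], cfg.gc_beta[1], size=cfg.n_windows)
    bias = rng.lognormal(mean=0.0, sigma=cfg.multiplex_sigma, size=cfg.n_windows)
    return windows, gc, bias


def sample_counts(
    cfg: SimConfig,
    gc: np.ndarray,
    bias: np.ndarray,
    rng: np.random.Generator,
    cn: np.ndarray | None = None,
    sample: str = "sim",
) -> ReadCountTrack:
    """Draw one sample's per-window counts.

    rate_i = expected_rc * g(GC_i) * bias_i * CN_i/2, with a per-window
    gamma factor inflating the Poisson CV by ``overdispersion``.
    """
    rate = cfg.expected_rc * cfg.gc_curve(gc) * bias
    if cn is not None:
        rate = rate * (np.asarray(cn, dtype=float) / 2.0)
    if cfg.overdispersion > 1.0:
        # CV^2 = 1/m + 1/k  =>  k = m / (od^2 - 1) at the nominal rate
        k = cfg.expected_rc / (cfg.overdispersion**2 - 1.0)
        rate = rate * rng.gamma(shape=k, scale=1.0 / k, size=len(rate))
    counts = rng.poisson(rate)
    return ReadCountTrack(
        sample=sample,
        counts=counts,
        gc=np.asarray(gc, dtype=float),
        usable=np.ones(len(counts), dtype=bool),
    )


def generate_panel(cfg: SimConfig, rng: np.random.Generator | None = None):
    """(windows, gc, bias, control tracks) for one experiment."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    windows, gc, bias = simulate_genome(cfg, rng)
    controls = [
        sample_counts(cfg, gc, bias, rng, sample=f"control{j + 1}")
        for j in range(cfg.n_controls)
    ]
    return windows, gc, bias, controls


def make_truth(
    cfg: SimConfig,
    windows: pd.DataFrame,
    size_range_bp: tuple[float, float],
    rng: np.random.Generator,
    n_events: int | None = None,
    cn_choices: tuple[int, ...] = (1, 3),
    margin: int = EVENT_MARGIN_WINDOWS,
) -> TruthSet:
    """Spike plan: log-uniform sizes, at most one event per chromosome.

    ``n_events`` chromosomes (all, if None) each receive one event whose
    bp size is drawn log-uniformly over ``size_range_bp``, converted to
    windows at the current depth's window width and capped so a
    ``margin``-window diploid flank remains on each side.  Keeping the
    spiked fraction of the genome modest matters: the per-sample median
    used for depth rescaling assumes a mostly-diploid genome, as it does
    in real samples.
    """
    wbp = cfg.window_bp
    chrom_names = list(pd.unique(windows["chrom"]))
    if n_events is None:
        chosen = chrom_names
    else:
        if n_events > len(chrom_names):
            raise ValueError("at most one event per chromosome")
        chosen = list(rng.choice(chrom_names, size=n_events, replace=False))
    gidx_by_chrom = {
        str(c): sub.index.to_numpy() for c, sub in windows.groupby("chrom", sort=False)
    }
    events: list[Event] = []
    for chrom in chosen:
        gidx = gidx_by_chrom[str(chrom)]
        lo, hi = gidx[0], gidx[-1] + 1
        length = hi - lo
        size_bp = float(
            np.exp(rng.uniform(np.log(size_range_bp[0]), np.log(size_range_bp[1])))
        )
        n_win = max(1, int(round(size_bp / wbp)))
        n_win = min(n_win, length - 2 * margin)
        if n_win < 1:
            raise ValueError("chromosome too short for the requested event sizes")
        start = int(rng.integers(lo + margin, hi - margin - n_win + 1))
        events.append(
            Event(
                chrom=str(chrom),
                start_win=start,
                end_win=start + n_win,
                cn=int(rng.choice(cn_choices)),
            )
        )
    return TruthSet(events=events, window_bp=wbp)


def spike_case(
    cfg: SimConfig,
    gc: np.ndarray,
    bias: np.ndarray,
    truth: TruthSet,
    rng: np.random.Generator,
    sample: str = "case",
) -> ReadCountTrack:
    """Case sample: control generative model with CN/2 rate inside events."""
    cn = np.full(len(gc), 2, dtype=int)
    for e in truth.events:
        cn[e.start_win : e.end_win] = e.cn
    return sample_counts(cfg, gc, bias, rng, cn=cn, sample=sample)


# ---------------------------------------------------------------------------
# Call-level scoring
# ---------------------------------------------------------------------------

def _event_bp(e: Event, windows: pd.DataFrame) -> tuple[str, int, int]:
    return (
        e.chrom,
        int(windows["start"].iloc[e.start_win]),
        int(windows["end"].iloc[e.end_win - 1]),
    )


def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def evaluate_calls(
    calls: list[CnvCall],
    truth: TruthSet,
    windows: pd.DataFrame,
    criterion: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score truth events and calls by reciprocal overlap (inclusive >=).

    Returns (events, calls): a per-event table with columns ``chrom,
    start, end, size_bp, type, cn, detected`` and a per-call table with a
    ``false`` column (a call matching no same-state truth event at >=
    ``criterion`` reciprocal overlap is false).
    """
    ev_rows = []
    call_matched = [False] * len(calls)
    for e in truth.events:
        chrom, s, t = _event_bp(e, windows)
        detected = False
        for k, c in enumerate(calls):
            if c.chrom != chrom or c.state != e.type:
                continue
            if _reciprocal_overlap(s, t, c.start, c.end) >= criterion:
                detected = True
                call_matched[k] = True
        ev_rows.append((chrom, s, t, t - s, e.type, e.cn, detected))
    events = pd.DataFrame(
        ev_rows, columns=["chrom", "start", "end", "size_bp", "type", "cn", "detected"]
    )
    call_rows = [
        (c.chrom, c.start, c.end, c.size, c.state, c.copy_number, not m)
        for c, m in zip(calls, call_matched)
    ]
    calls_df = pd.DataFrame(
        call_rows, columns=["chrom", "start", "end", "size_bp", "state", "cn", "false"]
    )
    return events, calls_df


def power_cell(
    depth: float,
    size_range_bp: tuple[float, float],
    n_samples: int = 100,
    events_per_sample: int = 5,
    seed: int = 0,
    cfg: SimConfig | None = None,
    criterion: float = 0.5,
    min_call_size: int = 100_000,
    **call_kwargs,
) -> dict:
    """One grid cell of the power study: full pipeline on spiked cases.

    A single 90-control panel (shared windows/GC/bias) serves all cases;
    each case carries ``events_per_sample`` events (one per chromosome,
    chromosomes drawn at random) with log-uniform sizes in
    ``size_range_bp``.  Returns pooled sensitivity/specificity plus the
    per-event and per-call tables.
    """
    if cfg is None:
        cfg = SimConfig()
    cfg = replace(cfg, depth=depth, seed=seed)
    rng = np.random.default_rng(seed)
    windows, gc, bias, controls = generate_panel(cfg, rng)
    corrected_controls = [gc_correct(t) for t in controls]
    panel = build_panel(corrected_controls)

    event_tables = []
    call_tables = []
    cn_rows = []
    for s in range(n_samples):
        truth = make_truth(cfg, windows, size_range_bp, rng, n_events=events_per_sample)
        case = spike_case(cfg, gc, bias, truth, rng, sample=f"case{s + 1}")
        rcr = normalize(gc_correct(case), panel)
        calls, _ = call_cnvs(rcr, panel, windows, min_size=min_call_size, **call_kwargs)
        ev, ct = evaluate_calls(calls, truth, windows, criterion=criterion)
        ev["sample"] = s
        event_tables.append(ev)
        ct["sample"] = s
        call_tables.append(ct)
        for e, row in zip(truth.events, ev.itertuples(index=False)):
            if not row.detected:
                continue
            match = [
                c
                for c in calls
                if c.chrom == row.chrom
                and c.state == row.type
                and _reciprocal_overlap(row.start, row.end, c.start, c.end) >= criterion
            ]
            best = max(
                match,
                key=lambda c: _reciprocal_overlap(row.start, row.end, c.start, c.end),
            )
            cn_rows.append((e.cn, best.copy_number))

    events = pd.concat(event_tables, ignore_index=True)
    calls_df = pd.concat(call_tables, ignore_index=True)
    cn_df = pd.DataFrame(cn_rows, columns=["true_cn", "called_cn"])
    out = {
        "depth": depth,
        "window_bp": cfg.window_bp,
        "n_events": len(events),
        "sensitivity": float(events["detected"].mean()) if len(events) else float("nan"),
        "events": events,
        "calls": calls_df,
        "cn": cn_df,
    }
    for t in ("deletion", "duplication"):
        sub = events[events["type"] == t]
        out[f"sensitivity_{t}"] = float(sub["detected"].mean()) if len(sub) else float("nan")
    return out


GENOME_BP = 121_500_000  # 10 chromosome-equivalents of 12.15 Mb


def study_cell(
    depth: float,
    size_range_bp: tuple[float, float],
    seed: int,
    n_samples: int = 100,
    events_per_sample: int = 5,
    n_controls: int = DEFAULT_N_CONTROLS,
    **kwargs,
) -> dict:
    """Power-study cell at the package's standard study conditions.

    A fixed 121.5 Mb genome over 10 chromosome-equivalents with windows
    rebuilt per depth at constant expected RC 150 (so the window count is
    ``GENOME_BP / window_bp``: 45 000 windows at 2x, 4 500 at 0.2x), a
    90-control panel, and 100 case samples carrying 5 events each —
    500 spiked events per cell.
    """
    base = SimConfig(depth=depth, n_controls=n_controls)
    n_windows = int(round(GENOME_BP / base.window_bp))
    cfg = replace(base, n_windows=n_windows, n_chroms=10)
    return power_cell(
        depth,
        size_range_bp,
        n_samples=n_samples,
        events_per_sample=events_per_sample,
        seed=seed,
        cfg=cfg,
        **kwargs,
    )


def specificity(calls_df: pd.DataFrame, min_size_bp: float = 0.0) -> float:
    """1 - (false calls / calls) among calls larger than ``min_size_bp``.

    With no qualifying calls there is no false positive, so 1.0.
    """
    sub = calls_df[calls_df["size_bp"] > min_size_bp]
    if len(sub) == 0:
        return 1.0
    return 1.0 - float(sub["false"].mean())


def sensitivity_above(events: pd.DataFrame, min_size_bp: float, type_: str | None = None) -> float:
    sub = events[events["size_bp"] > min_size_bp]
    if type_ is not None:
        sub = sub[sub["type"] == type_]
    return float(sub["detected"].mean()) if len(sub) else float("nan")


def power_study(
    depths=(0.2, 2.0),
    size_ranges=((100_000, 300_000), (300_000, 10_000_000)),
    n_samples: int = 10,
    events_per_sample: int | None = None,
    seed: int = 0,
    cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity/specificity grid over depth x size-range cells.

    Deterministic given ``seed`` (each cell derives its own sub-seed).
    Binomial 95% CIs use the normal approximation.
    """
    if events_per_sample is None:
        events_per_sample = min(5, (cfg or SimConfig()).n_chroms)
    rows = []
    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(len(depths) * len(size_ranges))
    k = 0
    for d in depths:
        for sr in size_ranges:
            cell_seed = int(subs[k].generate_state(1)[0] % (2**31))
            k += 1
            cell = power_cell(
                d,
                sr,
                n_samples=n_samples,
                events_per_sample=events_per_sample,
                seed=cell_seed,
                cfg=cfg,
            )
            sens = cell["sensitivity"]
            n = cell["n_events"]
            half = 1.96 * np.sqrt(max(sens * (1 - sens), 1e-12) / n) if n else np.nan
            rows.append(
                (
                    d,
                    sr[0],
                    sr[1],
                    n,
                    sens,
                    max(0.0, sens - half),
                    min(1.0, sens + half),
                    cell["sensitivity_deletion"],
                    cell["sensitivity_duplication"],
                    specificity(cell["calls"]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "depth",
            "size_min_bp",
            "size_max_bp",
            "n_events",
            "sensitivity",
            "ci_low",
            "ci_high",
            "sensitivity_deletion",
            "sensitivity_duplication",
            "specificity",
        ],
    )
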