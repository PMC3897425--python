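# Methods

## Model and assumptions

`pscc` models the read count of window *i* in sample *j* as

    m_ij ~ Poisson( E · g(GC_i) · b_i · CN_ij / 2 · s_j )

where *E* is the expected count at diploid copy number in an
equal-expected-count window, *g* a smooth multiplicative GC-rate curve,
*b_i* a window-specific factor shared by all samples sequenced the same
way (mappability, genome structure, library chemistry), *CN* the local
copy number and *s_j* a per-sample depth scale. The method estimates and
removes every nuisance term without knowing any of them:

* `g` is removed per sample by per-GC-bin median scaling — valid because
  the median over a GC bin is dominated by diploid windows as long as
  CNVs cover a modest fraction of the genome;
* `s_j` is removed by rescaling every sample to a common overall median
  (same caveat: the median assumes a mostly-diploid genome);
* `b_i` is removed by dividing by the control-panel mean μ_i, because it
  is *shared* — this is the step a single matched control cannot do
  reliably, and the panel additionally yields σ_i, the across-population
  variability of each window, which prices how trustworthy a signal from
  that window can ever be.

What remains is the relative copy ratio, `RCR ≈ CN/2` plus sampling
noise, on which segmentation and genotyping operate.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `expected_rc` | 150 | expected reads per window at diploid CN; balances the overlap of the CN 1/2/3 count distributions against genomic resolution |
| `gc_bin_width` | 0.01 | 1 % GC bins for the median correction, the granularity of per-GC-percentage corrections in depth-based callers |
| `min_bin_count` | 50 | GC bins with fewer usable windows borrow the nearest populated bin's median instead of trusting a noisy one |
| `mu_floor_fraction` | 0.1 | windows with panel mean below 10 % of the panel median are unusable (division blow-ups in barely mappable regions) |
| `block` | 10 | windows per side of the sliding runs test; the breakpoint localisation scale |
| `p_enter` | 0.05 | candidate-entry threshold on the sliding p-curve (see below) |
| `p_genome` | 0.05 / #tested positions | Bonferroni family-wise control of final breakpoints |
| `max_flank` | 200 | cap on the flank used when re-testing a breakpoint during pruning, so a decision never depends on megabase-distant data |
| `min_segment_windows` | 3 | shorter segments merge into the neighbor with the closer mean |
| `alpha_st`, `alpha_pt` | 0.001 | significance levels of the self-test and parallelism test (inclusive: p ≤ α is significant) |
| `min_size` | 100 kb | smallest reportable call, in bp so it is depth-independent |
| `overlap criterion` | 0.5 | reciprocal overlap (inclusive ≥) for call-level scoring |

## The runs test and its discreteness

The two-sample Wald–Wolfowitz statistic counts runs R of same-origin
values in the sorted pool of two blocks. A copy-number step drags one
block to one end of the sort and makes R small, so the test is
**lower-tail on R**; perfectly interleaved blocks (R maximal) are no
evidence of separation. The exact null pmf
(`P(R=2k) = 2·C(n1−1,k−1)·C(n2−1,k−1)/C(n,n1)`, odd case analogous) is
used up to a pooled size of 128; beyond that a continuity-corrected
normal tail with the classical mean `1 + 2n1n2/n` and variance. Ties
across blocks get alternating labels (starting with the block holding
more of the tied group), making the statistic deterministic; an
all-identical pool returns p = 1.

Discreteness drives two design choices. With `block = 10` the achievable
p-values jump 1.1e-5, 1.1e-4, 9.9e-4, 4.5e-3, **1.9e-2**, 5.1e-2, … — an
entry threshold of 0.01 would demand R ≤ 5 of 20 and silently drop real
but noisy step edges, so `p_enter = 0.05` (R ≤ 7) admits them and leaves
the genome-wide decision to the Bonferroni pruning threshold, where
flanks of up to 200 windows make the test sharp. Second, candidate
clusters closer than the 5-window minimum block are thinned to their
strongest member before pruning: such neighbors give each other
degenerate sentinel flanks (p = 1), and the remove-largest-p tie rule
(highest window index first) would otherwise consume a true edge before
its spurious neighbors.

## Genotyping conventions

* Self-test background: all usable windows of the sample excluding the
  tested segment, so whole-chromosome events are tested against the rest
  of the genome without self-contamination.
* Parallelism SE: `√(Σ (σ_i/μ_i)²)/n` over the segment's windows — σ_i
  is mapped to the RCR scale as σ_i/μ_i, so the depth-rescaling constant
  cancels. Windows with undefined panel SD are dropped with a warning.
* A call requires the `cnv` category **and** an integer copy-number
  state `round(2·RCR̄) ≠ 2`. With very large n, the rank and z tests flag
  shifts of a few percent that round back to the diploid state — such
  segments are statistically real (e.g. residual depth-scale error) but
  are not copy-number events. Copy number uses round-half-up, clipped at 0.
* Adjacent same-state calls separated only by unusable windows merge;
  the sample-quality flag is raised when more than 1 % of segments land
  in the quality category (strict inequality).

## The synthetic-data generator

The simulator emulates what the caller sees *after* alignment and window
counting, directly at window level: per-window GC from Beta(28, 40)
(mean ≈ 0.41, SD ≈ 0.06, matching human genome composition); a unimodal
GC-rate curve `0.3 + 0.7·exp(−((gc−0.425)/0.08)²)` suppressing GC-poor
(< 35 %) and GC-rich (> 50 %) windows; a shared lognormal window bias
(σ_log = 0.1); and gamma-mixed Poisson counts whose CV is inflated 20 %
over the Poisson floor as a conservative stand-in for real library
noise, since the panel noise a caller meets in practice is not exactly
Poisson. Depth is realized through the window grid, not the rate: window
width is `E·read_length/depth` (2 700 bp at 2×, 27 000 bp at 0.2× for
36 bp reads at E = 150), so an event of fixed bp size spans ~10× fewer
windows at 0.2× — this is what makes small events undetectable at low
depth. Spiked events multiply the rate by CN/2 (CN 1 or 3 by default,
non-overlapping, at most one per chromosome-equivalent).

What the generator does **not** emulate: alignment artifacts and
mappability holes (every window is usable), GC curves that differ
between batches, mosaic or multi-allelic states, and correlated noise
along the genome beyond the shared window bias. Passing tests therefore
demonstrate the statistical machinery under the stated noise model, not
robustness to every artifact of real libraries.

## Study sizes

The power cells use a 121.5 Mb genome (10 chromosome-equivalents;
45 000 windows at 2×, 4 500 at 0.2×), a 90-control panel, and 100 case
samples carrying 5 events each — 500 events per cell, kept to ≤ ~12 % of
the genome per sample so the median-based rescaling operates in its
design regime. Event sizes are log-uniform over the cell's range,
capped so a 15-window diploid flank remains at each chromosome end. The
runs-test calibration uses 10⁴ null replicates at 300 windows per side,
the flank scale the pruning stage actually tests; null false-positive
control uses 200 diploid replicates at 0.2×.

## Known limitations

* Breakpoint localisation is limited to roughly ± block/2 windows; at
  0.2× that is ~±70 kb in bp terms.
* Events spanning fewer than ~5 windows fall below the runs-test
  resolution and are missed by design.
* The per-sample median rescaling assumes a mostly diploid genome; a
  sample whose CNV burden approaches half the genome will mis-scale.
* The parallelism-test SE treats panel windows as independent; long-range
  correlated panel noise would make it anti-conservative.
* Mosaic states and CNVs in regions absent from the control panel's
  usable windows are out of scope.
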